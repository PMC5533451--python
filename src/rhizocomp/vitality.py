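"""Vitality: the normalized inverse of total plant--soil hydraulic resistance.

Vitality maps the effective resistance of a root system at a given soil
water state onto [0, 1]: 1 means water uptake is unimpeded, 0 means uptake
is blocked.  Two fitted functional forms are used inside the simulator:

* without topsoil hydrophobicity, vitality depends on the profile-averaged
  saturation through a saturating exponential,

  ``V(theta) = (1 - exp(-k * theta)) / (1 - exp(-k))``,

  with published decay constants k = 98.79 (intermediate root stage) and
  k = 63.88 (fully developed);

* with an hydrophobic topsoil, the top and sub soil saturations act
  separately,

  ``V(theta_top, theta_sub) =
      (1 - exp(a * theta_top + b)) / (1 + exp(c * theta_sub + d))``,

  with the four parameters fitted per architecture and stage (published
  best estimates shipped as defaults).  With a < 0 and c <= 0 the surface
  increases monotonically in both saturations; e.g. the fibrous system at
  the developed stage with a bone-dry topsoil and saturated subsoil retains
  only V = 0.25.

The module also provides the normalization of raw resistance curves and
damped least-squares fitting of both forms, so the pipeline raster ->
resistance curve -> vitality surface can be re-run end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .hydraulics import ResistanceCurve

__all__ = [
    "VitalityTotalParams",
    "VitalitySplitParams",
    "VitalitySample",
    "FitResult",
    "K_BY_STAGE",
    "SPLIT_PARAMS",
    "eval_vitality_total",
    "eval_vitality_split",
    "normalize_curve",
    "fit_vitality_total",
    "fit_vitality_split",
]

#: published decay constants of the total-saturation form, by root stage
K_BY_STAGE = {2: 98.79, 3: 63.88}


@dataclass(frozen=True)
class VitalityTotalParams:
    k: float
    stage: int | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("decay constant k must be positive")


@dataclass(frozen=True)
class VitalitySplitParams:
    a: float
    b: float
    c: float
    d: float
    architecture: str | None = None
    stage: int | None = None


#: published best-estimate parameters of the split-saturation form
SPLIT_PARAMS = {
    ("fibrous", 2): VitalitySplitParams(-52.70, -0.00, -3.49, -5.21, "fibrous", 2),
    ("tap", 2): VitalitySplitParams(-33.17, -2.35, -118.71, 0.32, "tap", 2),
    ("fibrous", 3): VitalitySplitParams(-48.64, -0.29, -30.08, -0.74, "fibrous", 3),
    ("tap", 3): VitalitySplitParams(-20.00, -2.96, -15.16, -3.03, "tap", 3),
}


@dataclass(frozen=True)
class VitalitySample:
    saturation: object  # theta_total or (theta_top, theta_sub)
    vitality: float


@dataclass
class FitResult:
    params: object
    residual_norm: float
    success: bool
    message: str = ""


def _check_unit_interval(name, *values) -> None:
    for v in values:
        arr = np.asarray(v, dtype=float)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"{name} must lie in [0, 1]")


def eval_vitality_total(theta_total, params: VitalityTotalParams | float):
    """Saturating-exponential vitality of the uniform-saturation case."""
    k = params.k if isinstance(params, VitalityTotalParams) else float(params)
    if k <= 0:
        raise ValueError("decay constant k must be positive")
    _check_unit_interval("theta_total", theta_total)
    th = np.asarray(theta_total, dtype=float)
    kk = np.asarray(k, dtype=float)
    v = -np.expm1(-kk * th) / -np.expm1(-kk)
    return v if v.ndim else float(v)


def eval_vitality_split(theta_top, theta_sub, params: VitalitySplitParams):
    """Split-saturation vitality under topsoil hydrophobicity, clipped to [0, 1]."""
    _check_unit_interval("theta_top", theta_top)
    _check_unit_interval("theta_sub", theta_sub)
    tt = np.asarray(theta_top, dtype=float)
    ts = np.asarray(theta_sub, dtype=float)
    v = _split_surface(tt, ts, params.a, params.b, params.c, params.d)
    v = np.clip(v, 0.0, 1.0)
    return v if v.ndim else float(v)


def _split_surface(tt, ts, a, b, c, d):
    # exponents are bounded by the fitting box, so plain exp is safe
    return (1.0 - np.exp(a * tt + b)) / (1.0 + np.exp(c * ts + d))


def _is_zero_saturation(cfg) -> bool:
    if np.isscalar(cfg):
        return float(cfg) == 0.0
    return all(float(x) == 0.0 for x in cfg)


def normalize_curve(curves) -> list[VitalitySample]:
    """Turn resistance curves into vitality samples.

    ``curves`` is a single :class:`ResistanceCurve` or a family of them that
    share a normalization.  The reference resistance is the second-highest
    resistance observed at zero saturation across the family (the single
    zero-saturation value if only one exists); vitality is ``R_ref / R``
    clipped to [0, 1].
    """
    if isinstance(curves, ResistanceCurve):
        curves = [curves]
    curves = list(curves)
    if not curves or not any(c.samples for c in curves):
        raise ValueError("cannot normalize an empty curve family")

    zero_rs = [r for c in curves for cfg, r in c.samples if _is_zero_saturation(cfg)]
    if not zero_rs:
        # fall back to the sample nearest zero total saturation
        def total(cfg):
            return float(cfg) if np.isscalar(cfg) else float(np.mean(cfg))

        nearest = min(
            (s for c in curves for s in c.samples), key=lambda s: total(s[0])
        )
        zero_rs = [nearest[1]]
    zero_rs.sort(reverse=True)
    r_ref = zero_rs[1] if len(zero_rs) > 1 else zero_rs[0]

    samples = []
    for curve in curves:
        for cfg, r in curve.samples:
            samples.append(VitalitySample(cfg, float(np.clip(r_ref / r, 0.0, 1.0))))
    return samples


def fit_vitality_total(theta_total, vitality, stage: int | None = None) -> FitResult:
    """Damped least-squares fit of the decay constant k.

    Requires at least three samples spanning the saturation range; multiple
    deterministic starting points guard against the flat large-k regime.
    """
    th = np.asarray(theta_total, dtype=float)
    v = np.asarray(vitality, dtype=float)
    if th.size < 3:
        raise ValueError("need at least 3 samples to fit the total form")

    def residual(x):
        return eval_vitality_total(th, float(x[0])) - v

    best = None
    for k0 in (1.0, 10.0, 50.0, 100.0):
        sol = least_squares(residual, x0=[k0], bounds=([1e-6], [1e6]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    norm = float(np.sqrt(2.0 * best.cost))
    return FitResult(
        params=VitalityTotalParams(float(best.x[0]), stage=stage),
        residual_norm=norm,
        success=bool(best.success),
        message=best.message,
    )


def fit_vitality_split(
    theta_top,
    theta_sub,
    vitality,
    architecture: str | None = None,
    stage: int | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Multi-start damped least-squares fit of the four split-form parameters.

    The surface can be ill-identified (flat directions when the subsoil
    sigmoid saturates), so recovery of the generating *surface* rather than
    the parameter vector is the meaningful contract.  Starts are drawn
    within the bounds a, c in [-200, 0] and b, d in [-20, 20] from a seeded
    generator; the best of all starts is returned and flagged unsuccessful
    if no start converged.
    """
    tt = np.asarray(theta_top, dtype=float)
    ts = np.asarray(theta_sub, dtype=float)
    v = np.asarray(vitality, dtype=float)
    if tt.size < 8:
        raise ValueError("need at least 8 samples on a saturation mesh")

    lower = np.array([-200.0, -20.0, -200.0, -20.0])
    upper = np.array([0.0, 20.0, 0.0, 20.0])

    def residual(x):
        return _split_surface(tt, ts, *x) - v

    rng = np.random.default_rng(seed)
    starts = [np.array([-40.0, -1.0, -20.0, -1.0])]
    starts += [rng.uniform(lower, upper) for _ in range(max(0, n_starts - 1))]

    best = None
    any_success = False
    for x0 in starts:
        sol = least_squares(residual, x0=x0, bounds=(lower, upper),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        any_success |= bool(sol.success)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-18:
            break
    norm = float(np.sqrt(2.0 * best.cost))
    params = VitalitySplitParams(*map(float, best.x), architecture, stage)
    return FitResult(params=params, residual_norm=norm,
                     success=any_success, message=best.message)
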