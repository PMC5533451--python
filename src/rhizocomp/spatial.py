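"""Point-pattern analysis of plant locations.

Univariate and cross-species pair correlation functions g(r) with
translation edge correction on the rectangular simulation window, compared
against pointwise envelopes from Monte Carlo simulations of complete
spatial randomness (CSR, a homogeneous Poisson process with the observed
point count).  g = 1 indicates randomness, g > 1 aggregation and g < 1
inhibition at distance r; an observation outside the 199-fold envelope is
classified as significant attraction or inhibition at that distance.

Plant positions live on a lattice; a seeded sub-cell jitter (uniform within
the patch) is applied by default so that the many exactly-coincident
inter-point distances of the grid do not break the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ibm import ModelState, SPECIES_NAMES

__all__ = [
    "PointPattern",
    "PCFEstimate",
    "EnvelopeResult",
    "extract_pattern",
    "pcf",
    "cross_pcf",
    "csr_envelope",
    "aggregate_classifications",
]

RANDOM, ATTRACTION, INHIBITION = "random", "attraction", "inhibition"


@dataclass
class PointPattern:
    points: np.ndarray  # (n, 2) x/y coordinates in patch units
    window: tuple[float, float]  # (width, height)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        w, h = self.window
        if self.points.size and (
            self.points.min() < 0
            or self.points[:, 0].max() > w
            or self.points[:, 1].max() > h
        ):
            raise ValueError("points must lie inside the window")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        return self.window[0] * self.window[1]


@dataclass
class PCFEstimate:
    r: np.ndarray  # bin centers
    g: np.ndarray
    kind: str  # "univariate" or "cross"
    valid: bool = True


@dataclass
class EnvelopeResult:
    r: np.ndarray
    g_obs: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    classification: list[str]
    kind: str
    n_sim: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.r, "g_obs": self.g_obs, "lower": self.lower,
             "upper": self.upper, "class": self.classification}
        )


def extract_pattern(state: ModelState, species, jitter: bool = True,
                    seed: int = 0) -> PointPattern:
    """Point pattern of the living plants of one species.

    Points sit at patch centers plus, by default, a seeded uniform sub-cell
    jitter of +/- half a patch in each coordinate.
    """
    if isinstance(species, str):
        species = SPECIES_NAMES.index(species)
    mask = state.species == species
    h, w = state.params.grid_shape
    x = state.col[mask] + 0.5
    y = state.row[mask] + 0.5
    pts = np.column_stack([x, y]).astype(float)
    if jitter and len(pts):
        rng = np.random.default_rng(seed)
        pts += rng.uniform(-0.5, 0.5, size=pts.shape)
        pts = np.clip(pts, 0.0, [w, h])
    return PointPattern(pts, (float(w), float(h)))


def _pair_weights(pattern_a: PointPattern, pattern_b: PointPattern | None,
                  r_max: float):
    """Pair distances and translation-correction weights.

    Returns ordered-pair distances and the weight 1/((W-|dx|)(H-|dy|)) for
    each pair with separation below ``r_max``.  For the univariate case each
    unordered pair is counted twice.
    """
    w, h = pattern_a.window
    a = pattern_a.points
    if pattern_b is None:
        tree = cKDTree(a)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        if len(pairs) == 0:
            return np.empty(0), np.empty(0)
        d = a[pairs[:, 0]] - a[pairs[:, 1]]
        mult = 2.0  # ordered pairs
    else:
        b = pattern_b.points
        coo = cKDTree(a).sparse_distance_matrix(
            cKDTree(b), r_max, output_type="coo_matrix"
        )
        if coo.nnz == 0:
            return np.empty(0), np.empty(0)
        d = a[coo.row] - b[coo.col]
        mult = 1.0
    dist = np.hypot(d[:, 0], d[:, 1])
    keep = dist > 0
    d, dist = d[keep], dist[keep]
    weights = mult / ((w - np.abs(d[:, 0])) * (h - np.abs(d[:, 1])))
    return dist, weights


def _binned_pcf(dist, weights, r_edges, intensity_product):
    annulus = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)
    idx = np.searchsorted(r_edges, dist, side="right") - 1
    ok = (idx >= 0) & (idx < len(annulus))
    sums = np.bincount(idx[ok], weights=weights[ok], minlength=len(annulus))
    return sums / (annulus * intensity_product)


def _r_edges(r_max: float, bin_width: float) -> np.ndarray:
    n_bins = int(round(r_max / bin_width))
    return np.linspace(0.0, n_bins * bin_width, n_bins + 1)


def pcf(pattern: PointPattern, r_max: float = 25.0,
        bin_width: float = 1.0) -> PCFEstimate:
    """Univariate pair correlation function with translation edge correction.

    The estimator counts the n(n-1) ordered pairs per distance annulus,
    weights each by the translation correction, and normalizes by the
    annulus area and the unbiased squared intensity n(n-1)/|W|^2.
    """
    edges = _r_edges(r_max, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if pattern.n < 2:
        return PCFEstimate(centers, np.full(len(centers), np.nan),
                           "univariate", valid=False)
    dist, wts = _pair_weights(pattern, None, edges[-1])
    lam2 = pattern.n * (pattern.n - 1) / pattern.area**2
    g = _binned_pcf(dist, wts, edges, lam2)
    return PCFEstimate(centers, g, "univariate")


def cross_pcf(pattern_a: PointPattern, pattern_b: PointPattern,
              r_max: float = 25.0, bin_width: float = 1.0) -> PCFEstimate:
    """Cross-species pair correlation function (ordered a-to-b pairs)."""
    if pattern_a.window != pattern_b.window:
        raise ValueError("patterns must share a window")
    edges = _r_edges(r_max, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if pattern_a.n < 1 or pattern_b.n < 1:
        return PCFEstimate(centers, np.full(len(centers), np.nan),
                           "cross", valid=False)
    dist, wts = _pair_weights(pattern_a, pattern_b, edges[-1])
    lam_ab = pattern_a.n * pattern_b.n / pattern_a.area**2
    g = _binned_pcf(dist, wts, edges, lam_ab)
    return PCFEstimate(centers, g, "cross")


def csr_envelope(
    pattern: PointPattern,
    pattern_b: PointPattern | None = None,
    n_sim: int = 199,
    seed: int = 0,
    r_max: float = 25.0,
    bin_width: float = 1.0,
) -> EnvelopeResult:
    """Pointwise min/max envelope from CSR simulations, with classification.

    Each simulation draws the same point count(s) uniformly in the window
    (binomial process); the envelope is the pointwise minimum and maximum of
    the simulated g(r).  Bins where the observation lies above the upper
    bound are classified as attraction, below the lower bound as
    inhibition, otherwise as random.
    """
    if pattern.n == 0 or (pattern_b is not None and pattern_b.n == 0):
        raise ValueError("cannot build an envelope for an empty pattern")
    rng = np.random.default_rng(seed)
    if pattern_b is None:
        obs = pcf(pattern, r_max, bin_width)
    else:
        obs = cross_pcf(pattern, pattern_b, r_max, bin_width)

    sims = np.empty((n_sim, len(obs.r)))
    w, h = pattern.window
    for s in range(n_sim):
        pa = PointPattern(rng.uniform((0, 0), (w, h), size=(pattern.n, 2)),
                          pattern.window)
        if pattern_b is None:
            sims[s] = pcf(pa, r_max, bin_width).g
        else:
            pb = PointPattern(
                rng.uniform((0, 0), (w, h), size=(pattern_b.n, 2)),
                pattern.window,
            )
            sims[s] = cross_pcf(pa, pb, r_max, bin_width).g
    lower = sims.min(axis=0)
    upper = sims.max(axis=0)
    classification = [
        ATTRACTION if go > up else INHIBITION if go < lo else RANDOM
        for go, lo, up in zip(obs.g, lower, upper)
    ]
    return EnvelopeResult(obs.r, obs.g, lower, upper, classification,
                          obs.kind, n_sim)


def aggregate_classifications(results) -> pd.DataFrame:
    """Relative frequency of envelope outcomes across replicates.

    ``results`` maps a label (e.g. an evaluation step) to a list of
    :class:`EnvelopeResult`; the output has one row per (label, r) with the
    fraction of replicates classified random/attraction/inhibition.
    """
    rows = []
    for label, envs in results.items():
        envs = list(envs)
        if not envs:
            raise ValueError(f"no replicates for {label!r}")
        r = envs[0].r
        classes = np.array([e.classification for e in envs])
        for j, rj in enumerate(r):
            col = classes[:, j]
            rows.append(
                {
                    "label": label,
                    "r": float(rj),
                    "frac_random": float((col == RANDOM).mean()),
                    "frac_attraction": float((col == ATTRACTION).mean()),
                    "frac_inhibition": float((col == INHIBITION).mean()),
                }
            )
    return pd.DataFrame(rows)
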