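"""Statistical calling of ambiguous cell pairs against an antitonic null.

The null model says correspondence probability can only decay with
geodesic distance: a cubic smoothing spline is fit to the consensus
self-coupling as a function of geodesic distance and projected onto the
cone of monotone non-increasing functions.  A cell pair whose observed
correspondence exceeds the null expectation by a significant margin is
"ambiguous": the manifold cannot tell the two cells apart even though
they are far from each other.

Pairs closer than a configurable geodesic quantile are never called:
nearby cells legitimately share correspondence mass, only far-apart
look-alikes indicate ambiguity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline
from sklearn.isotonic import IsotonicRegression

from .manifold import GeodesicMatrix

__all__ = ["NullSpline", "AmbiguityResult", "fit_null_spline", "ambiguity_pvalues"]

_GRID_SIZE = 1000
_MAD_SCALE = 1.4826  # normal-consistency constant for the MAD


@dataclass
class NullSpline:
    """Monotone non-increasing fit of correspondence vs geodesic distance.

    Evaluation interpolates linearly between the ``grid`` knots (the
    antitonic projection of the smoothing spline evaluated on a dense
    grid) and extends flat beyond the fitted range.
    """

    grid: np.ndarray
    values: np.ndarray
    smoothing: float | None
    d_min: float
    d_max: float

    def __call__(self, d: np.ndarray | float) -> np.ndarray | float:
        return np.interp(d, self.grid, self.values)

    def to_json(self) -> str:
        return json.dumps(
            {
                "knots": self.grid.tolist(),
                "coefficients": self.values.tolist(),
                "smoothing": self.smoothing,
                "d_min": self.d_min,
                "d_max": self.d_max,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NullSpline":
        obj = json.loads(text)
        return cls(
            grid=np.asarray(obj["knots"]),
            values=np.asarray(obj["coefficients"]),
            smoothing=obj["smoothing"],
            d_min=obj["d_min"],
            d_max=obj["d_max"],
        )


@dataclass
class AmbiguityResult:
    """Per-pair ambiguity calls (upper triangle, i < j)."""

    cell_i: np.ndarray
    cell_j: np.ndarray
    geodesic_dist: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    deviation: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    alpha: float
    excluded_local_quantile: float
    local_radius: float = field(default=np.nan)
    fold_change: np.ndarray | None = field(default=None)

    @property
    def n_pairs(self) -> int:
        return self.cell_i.size

    @property
    def significant_pairs(self) -> np.ndarray:
        """(m, 2) array of significant (i, j) index pairs."""
        mask = self.significant
        return np.column_stack([self.cell_i[mask], self.cell_j[mask]])

    @property
    def significant_fraction(self) -> float:
        return float(self.significant.mean()) if self.n_pairs else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_i": self.cell_i,
                "cell_j": self.cell_j,
                "geodesic_dist": self.geodesic_dist,
                "observed": self.observed,
                "expected": self.expected,
                "deviation": self.deviation,
                "p_value": self.p_value,
                "significant": self.significant,
            }
        )


def _upper_triangle(consensus: np.ndarray, K: np.ndarray):
    n = consensus.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju, K[iu, ju], consensus[iu, ju]


def _binned_means(d: np.ndarray, g: np.ndarray, n_bins: int):
    """Equal-count distance bins; returns (bin centers, bin mean gamma)."""
    order = np.argsort(d, kind="stable")
    ds, gs = d[order], g[order]
    edges = np.linspace(0, ds.size, n_bins + 1).astype(int)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        centers.append(ds[lo:hi].mean())
        means.append(gs[lo:hi].mean())
    centers = np.asarray(centers)
    means = np.asarray(means)
    # merge duplicate centers (heavy distance ties)
    uniq, inv = np.unique(centers, return_inverse=True)
    if uniq.size < centers.size:
        agg = np.zeros(uniq.size)
        cnt = np.zeros(uniq.size)
        np.add.at(agg, inv, means)
        np.add.at(cnt, inv, 1)
        centers, means = uniq, agg / cnt
    return centers, means


def fit_null_spline(
    consensus: np.ndarray,
    K: GeodesicMatrix | np.ndarray,
    smoothing: float | None = None,
    n_bins: int = 100,
) -> NullSpline:
    """Fit the antitonic null: expected correspondence vs geodesic distance.

    Upper-triangle pairs are reduced to ``n_bins`` equal-count distance
    bins; a cubic smoothing spline (generalized cross-validation when
    ``smoothing`` is None) is fit to the bin means and its dense-grid
    evaluation is projected through pool-adjacent-violators onto the
    monotone non-increasing cone, then clamped at zero.
    """
    Kd = np.asarray(K.dist if isinstance(K, GeodesicMatrix) else K, dtype=float)
    consensus = np.asarray(consensus, dtype=float)
    if consensus.shape != Kd.shape:
        raise ValueError("consensus and geodesic matrices must share dimensions")
    if not np.allclose(consensus, consensus.T, atol=1e-8 * max(consensus.max(), 1e-30)):
        raise ValueError("consensus coupling must be symmetric")

    _, _, d, g = _upper_triangle(consensus, Kd)
    centers, means = _binned_means(d, g, n_bins)
    d_min, d_max = float(d.min()), float(d.max())
    grid = np.linspace(d_min, d_max, _GRID_SIZE)

    if centers.size < 10:
        warnings.warn(
            f"only {centers.size} distinct distances; falling back to "
            "antitonic step-function regression",
            stacklevel=2,
        )
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        iso.fit(d, g)
        vals = iso.predict(grid)
    else:
        spline = make_smoothing_spline(centers, means, lam=smoothing)
        vals = spline(grid)
        # antitonic projection (pool-adjacent-violators) enforces monotone
        # non-increase exactly at grid granularity
        iso = IsotonicRegression(increasing=False)
        vals = iso.fit_transform(grid, vals)
    vals = np.maximum(vals, 0.0)
    return NullSpline(
        grid=grid, values=vals, smoothing=smoothing, d_min=d_min, d_max=d_max
    )


def ambiguity_pvalues(
    consensus: np.ndarray,
    K: GeodesicMatrix | np.ndarray,
    spline: NullSpline | None = None,
    alpha: float = 0.01,
    local_quantile: float = 0.20,
    n_scale_bins: int = 100,
    pseudo_count_frac: float = 1e-2,
    min_fold_change: float = 2.0,
) -> AmbiguityResult:
    """Call significant ambiguous cell pairs.

    Correspondence mass is multiplicative and strongly heteroscedastic:
    values (and their residual spread) shrink by orders of magnitude as
    geodesic distance grows.  The test therefore operates on
    ``log(observed + delta)`` with the pseudo-count
    ``delta = pseudo_count_frac / n^2`` (a fixed fraction of the uniform
    coupling value; mass below it is physically negligible), standardized
    by the robust location/scale (median, 1.4826 * MAD; the ambiguous
    pairs themselves would inflate a naive standard deviation) *within
    equal-count distance bins*, and converted to one-sided upper-tail
    p-values under the standard normal.

    A pair is significant iff (i) ``p <= alpha``, (ii) its geodesic
    distance exceeds the ``local_quantile`` of off-diagonal distances
    (self-correspondence of nearby cells is not ambiguity), and (iii) its
    mass is at least ``min_fold_change`` times the same-distance typical
    mass — a minimum-effect-size clause: ambiguity means a distant pair
    couples like a neighbor, not a few-percent wobble around the null.
    """
    Kd = np.asarray(K.dist if isinstance(K, GeodesicMatrix) else K, dtype=float)
    consensus = np.asarray(consensus, dtype=float)
    if spline is None:
        spline = fit_null_spline(consensus, Kd)
    if not 0 <= local_quantile < 1:
        raise ValueError("local_quantile must be in [0, 1)")

    iu, ju, d, g = _upper_triangle(consensus, Kd)
    expected = np.asarray(spline(d), dtype=float)
    deviation = g - expected

    n_cells = consensus.shape[0]
    delta = pseudo_count_frac / n_cells**2

    order = np.argsort(d, kind="stable")
    n_bins = min(n_scale_bins, max(d.size // 20, 1))
    edges = np.linspace(0, d.size, n_bins + 1).astype(int)

    # robust antitonic center through the bin *medians* (the ambiguous
    # pairs themselves cannot drag it); interpolating it across bin
    # centers also removes the within-bin distance trend that would
    # otherwise inflate the scale estimate
    centers, medians = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = order[lo:hi]
        if idx.size:
            centers.append(d[idx].mean())
            medians.append(np.median(g[idx]))
    centers = np.asarray(centers)
    medians = np.asarray(medians)
    iso = IsotonicRegression(increasing=False)
    medians = iso.fit_transform(centers, medians)
    mu = np.interp(d, centers, medians)
    resid = g - mu
    # fold change vs the same-distance typical mass, on the pseudo-counted
    # scale so physically negligible mass cannot register large folds
    log_fold = np.log(np.maximum(g, 0.0) + delta) - np.log(np.maximum(mu, 0.0) + delta)

    z = np.zeros_like(resid)
    degenerate = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = order[lo:hi]
        if idx.size == 0:
            continue
        r = resid[idx]
        med = np.median(r)
        scale = _MAD_SCALE * np.median(np.abs(r - med))
        if scale <= 0:
            degenerate += 1
        else:
            z[idx] = (r - med) / scale
    if degenerate == n_bins:
        warnings.warn(
            "zero spread in deviations; all p-values set to 0.5", stacklevel=2
        )
    pvals = stats.norm.sf(z)

    local_radius = float(np.quantile(d, local_quantile)) if local_quantile > 0 else 0.0
    significant = (
        (pvals <= alpha)
        & (d > local_radius)
        & (log_fold >= np.log(min_fold_change))
    )
    return AmbiguityResult(
        cell_i=iu,
        cell_j=ju,
        geodesic_dist=d,
        observed=g,
        expected=expected,
        deviation=deviation,
        p_value=pvals,
        significant=significant,
        alpha=alpha,
        excluded_local_quantile=local_quantile,
        local_radius=local_radius,
        fold_change=np.exp(log_fold),
    )
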