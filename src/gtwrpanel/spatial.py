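"""Spatial weights and autocorrelation statistics for city cross-sections.

Implements the exploratory-spatial-analysis layer: neighbor-weight
construction (k-nearest, distance band, inverse distance), global Moran's I
with analytic (normality) and permutation inference, local Moran (LISA) with
HH/LL/HL/LH cluster labels under conditional permutation, and the Getis-Ord
Gi* hot/cold-spot statistic with confidence-tier categories.

Conventions
-----------
* Permutation pseudo-p uses the +1 correction,
  p = (1 + #{permuted statistic as-or-more extreme}) / (1 + n_permutations),
  and is two-sided: extremity is measured by distance from the null expectation
  (global I) or by absolute value (local statistics).
* Units left with no neighbors under a weighting scheme ("isolates", e.g.
  remote cities under a small distance band) are excluded from the statistic
  with an :class:`IsolateWarning` rather than raising.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from scipy.spatial import distance_matrix

from .panel import DegenerateInputError

__all__ = [
    "SpatialWeights",
    "AutocorrResult",
    "IsolateWarning",
    "build_weights",
    "weights_from_recipe",
    "min_connectivity_distance",
    "morans_i",
    "morans_i_by_period",
    "percent_change",
    "local_moran",
    "getis_ord_gi_star",
    "write_weights_csv",
    "read_weights_csv",
]

_SCHEMES = ("knn", "distance_band", "inverse_distance")


class IsolateWarning(UserWarning):
    """A unit ended up with no neighbors under the requested scheme."""


class WeightsConfigError(ValueError):
    """Invalid weights construction parameters."""


@dataclasses.dataclass
class SpatialWeights:
    """Sparse neighbor weights over one cross-section of units.

    ``matrix`` is an n × n CSR matrix with w_ij >= 0; the diagonal is zero
    unless ``includes_self`` (the Gi* variant). When ``row_standardized``,
    every nonempty row sums to one.
    """

    ids: np.ndarray
    matrix: sparse.csr_matrix
    scheme: str
    row_standardized: bool
    includes_self: bool

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def neighbor_counts(self) -> np.ndarray:
        return np.diff(self.matrix.indptr)

    def isolates(self) -> np.ndarray:
        """Indices of units with an empty row."""
        return np.flatnonzero(self.neighbor_counts() == 0)


@dataclasses.dataclass
class AutocorrResult:
    """A global autocorrelation statistic with analytic and permutation inference."""

    statistic: float
    expected_value: float
    variance: float
    z_score: float
    p_analytic: float
    p_permutation: float
    n_permutations: int
    seed: int | None


def min_connectivity_distance(coords: np.ndarray) -> float:
    """Smallest distance band under which every unit has >= 1 neighbor:
    the maximum over units of the distance to their nearest neighbor."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise WeightsConfigError("need at least two units")
    D = distance_matrix(coords, coords)
    np.fill_diagonal(D, np.inf)
    return float(D.min(axis=1).max())


def build_weights(
    coords: np.ndarray,
    ids: Sequence | None = None,
    scheme: str = "inverse_distance",
    k: int | None = None,
    band_distance: float | None = None,
    decay_power: float = 1.0,
    row_standardize: bool = True,
    include_self: bool = False,
) -> SpatialWeights:
    """Construct spatial weights over one set of planar coordinates.

    Schemes
    -------
    knn:
        exactly ``k`` neighbors per unit, nearest first; distance ties break
        by id (row) order.
    distance_band:
        binary weight 1 for all pairs with 0 < d <= band.
    inverse_distance:
        w_ij = d_ij ** (-decay_power) for pairs within the band.

    ``band_distance=None`` applies the minimum-spanning-distance rule: the
    smallest band under which every unit has at least one neighbor. Isolates
    under an explicit band trigger an :class:`IsolateWarning` and keep an
    empty row. ``include_self`` sets w_ii = 1 before any row standardization
    (required by Gi*).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise WeightsConfigError("need at least two units to build weights")
    if scheme not in _SCHEMES:
        raise WeightsConfigError(f"unknown scheme {scheme!r}; choose from {_SCHEMES}")
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    if len(np.unique(ids)) != n:
        raise WeightsConfigError("unit ids must be distinct")

    D = distance_matrix(coords, coords)
    W = np.zeros((n, n))

    if scheme == "knn":
        if k is None or k < 1:
            raise WeightsConfigError("knn scheme requires k >= 1")
        if k >= n:
            raise WeightsConfigError(f"k={k} must be smaller than the number of units n={n}")
        for i in range(n):
            order = np.lexsort((np.arange(n), D[i]))  # distance, then id order
            order = order[order != i][:k]
            W[i, order] = 1.0
    else:
        if band_distance is None:
            band = min_connectivity_distance(coords)
        else:
            band = float(band_distance)
        with np.errstate(divide="ignore"):
            inside = (D > 0) & (D <= band)
            if scheme == "distance_band":
                W[inside] = 1.0
            else:
                W[inside] = D[inside] ** (-decay_power)

    if include_self:
        np.fill_diagonal(W, 1.0)

    row_sums = W.sum(axis=1)
    iso = np.flatnonzero(row_sums == 0)
    if iso.size:
        warnings.warn(
            f"{iso.size} unit(s) have no neighbors under scheme {scheme!r} "
            f"(ids: {list(np.asarray(ids)[iso][:5])}); they are excluded from statistics",
            IsolateWarning,
            stacklevel=2,
        )
    if row_standardize:
        nz = row_sums > 0
        W[nz] = W[nz] / row_sums[nz, None]

    return SpatialWeights(
        ids=ids,
        matrix=sparse.csr_matrix(W),
        scheme=scheme,
        row_standardized=row_standardize,
        includes_self=include_self,
    )


#: Default recipe used across the pipeline: inverse-distance weights inside
#: the minimum-spanning band, row-standardized (Moran/LISA flavor).
DEFAULT_RECIPE: dict = {
    "scheme": "inverse_distance",
    "band_distance": None,
    "decay_power": 1.0,
    "row_standardize": True,
    "include_self": False,
}


def weights_from_recipe(coords: np.ndarray, recipe: Mapping | None = None, ids=None) -> SpatialWeights:
    """Build weights from a plain-dict recipe (config-file friendly)."""
    merged = dict(DEFAULT_RECIPE)
    if recipe:
        merged.update(recipe)
    return build_weights(coords, ids=ids, **merged)


def _active_subset(values: np.ndarray, W: SpatialWeights) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop isolates (empty rows) from the statistic, returning the reduced
    value vector, dense weight matrix and the retained indices."""
    values = np.asarray(values, dtype=float)
    if len(values) != W.n:
        raise ValueError(f"values length {len(values)} != weights order {W.n}")
    keep = np.flatnonzero(W.neighbor_counts() > 0)
    Wd = W.matrix.toarray()
    if keep.size < W.n:
        Wd = Wd[np.ix_(keep, keep)]
        values = values[keep]
    return values, Wd, keep


def morans_i(
    values: np.ndarray,
    W: SpatialWeights,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AutocorrResult:
    """Global Moran's I with analytic (normality) and permutation inference.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the mean deviates
    and S0 the total weight. The expectation under no autocorrelation is
    -1/(n-1); the analytic variance uses the standard normality-assumption
    moments. The permutation p relabels values uniformly at random.
    """
    x, Wd, _ = _active_subset(values, W)
    n = len(x)
    if n < 3:
        raise DegenerateInputError("Moran's I needs at least 3 non-isolated units")
    z = x - x.mean()
    den = float(z @ z)
    if den == 0.0:
        raise DegenerateInputError("Moran's I undefined: values have zero variance")
    S0 = float(Wd.sum())
    I = n / S0 * float(z @ Wd @ z) / den

    E = -1.0 / (n - 1)
    S1 = 0.5 * float(((Wd + Wd.T) ** 2).sum())
    col = Wd.sum(axis=0)
    row = Wd.sum(axis=1)
    S2 = float(((row + col) ** 2).sum())
    var = (n**2 * S1 - n * S2 + 3 * S0**2) / ((n**2 - 1) * S0**2) - E**2
    zsc = (I - E) / np.sqrt(var) if var > 0 else np.nan
    p_an = float(2 * sps.norm.sf(abs(zsc))) if np.isfinite(zsc) else np.nan

    p_perm = np.nan
    if n_permutations and n_permutations > 0:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
        perms = rng.permuted(np.tile(z, (n_permutations, 1)), axis=1)
        nums = np.einsum("pi,ij,pj->p", perms, Wd, perms)
        I_perm = n / S0 * nums / den
        extreme = np.abs(I_perm - E) >= abs(I - E) - 1e-14
        p_perm = (1.0 + int(extreme.sum())) / (1.0 + n_permutations)

    return AutocorrResult(
        statistic=float(I),
        expected_value=float(E),
        variance=float(var),
        z_score=float(zsc),
        p_analytic=p_an,
        p_permutation=float(p_perm),
        n_permutations=int(n_permutations),
        seed=seed,
    )


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100 * (after - before) / before; an increase is
    positive. Undefined (NaN) when the baseline is zero."""
    if before == 0:
        return float("nan")
    return 100.0 * (after - before) / before


def morans_i_by_period(
    panel,
    period_a_years: Sequence[int],
    period_b_years: Sequence[int],
    weights_recipe: Mapping | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
    pooling: str = "city_mean",
) -> dict:
    """Moran's I of the city-level mean birth rate in two disjoint periods.

    ``pooling='city_mean'`` (default) averages each city's birth rate over the
    period's years before computing I; ``pooling='stacked'`` concatenates the
    annual cross-sections, replicating each city's coordinates per year.
    Returns ``{"I_a", "I_b", "percent_change", "result_a", "result_b"}``;
    percent change is 100·(I_b − I_a)/I_a, NaN when I_a = 0.
    """
    a, b = set(map(int, period_a_years)), set(map(int, period_b_years))
    if not a or not b:
        raise ValueError("both periods must be non-empty")
    if a & b:
        raise ValueError(f"periods must be disjoint; overlap: {sorted(a & b)}")

    results = {}
    for key, years in (("a", a), ("b", b)):
        sub = panel.data[panel.data["year"].isin(years)]
        if sub.empty:
            raise ValueError(f"no records in period {sorted(years)}")
        if pooling == "city_mean":
            agg = sub.groupby("city_id", sort=True).agg(
                u=("u", "first"), v=("v", "first"), birth_rate=("birth_rate", "mean")
            )
            coords = agg[["u", "v"]].to_numpy()
            vals = agg["birth_rate"].to_numpy()
            ids = agg.index.to_numpy()
        elif pooling == "stacked":
            coords = sub[["u", "v"]].to_numpy()
            vals = sub["birth_rate"].to_numpy()
            ids = np.arange(len(sub))
        else:
            raise ValueError("pooling must be 'city_mean' or 'stacked'")
        W = weights_from_recipe(coords, weights_recipe, ids=ids)
        results[key] = morans_i(vals, W, n_permutations=n_permutations, seed=seed)

    I_a, I_b = results["a"].statistic, results["b"].statistic
    return {
        "I_a": I_a,
        "I_b": I_b,
        "percent_change": percent_change(I_a, I_b),
        "result_a": results["a"],
        "result_b": results["b"],
    }


def local_moran(
    values: np.ndarray,
    W: SpatialWeights,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Local Moran (LISA) with conditional-permutation inference.

    I_i = (z_i / m2) * sum_j w_ij z_j with z the mean deviates and
    m2 = sum z^2 / n. For each unit the permutation holds z_i fixed and draws
    its neighbors' values from the remaining units without replacement;
    p_i is two-sided on |I_i| with the +1 correction. Quadrant labels:
    HH (z_i > 0, lag > 0), LL, HL (high value among low neighbors), LH —
    assigned only to units significant at ``alpha`` (Benjamini-Hochberg
    adjusted when ``fdr``).

    Returns a frame: id, local_i, z, lag, p_permutation, label.
    """
    x, Wd, keep = _active_subset(values, W)
    n_all = W.n
    n = len(x)
    if n < 3:
        raise DegenerateInputError("local Moran needs at least 3 non-isolated units")
    z = x - x.mean()
    m2 = float(z @ z) / n
    if m2 == 0.0:
        raise DegenerateInputError("local Moran undefined: values have zero variance")
    lag = Wd @ z
    I_loc = z / m2 * lag

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    p = np.ones(n)
    if n_permutations and n_permutations > 0:
        for i in range(n):
            nbr = np.flatnonzero(Wd[i])
            card = nbr.size
            if card == 0:
                continue
            others = np.delete(z, i)
            # without-replacement draws: first `card` slots of row-wise random orderings
            r = rng.random((n_permutations, n - 1))
            pick = np.argpartition(r, card - 1, axis=1)[:, :card]
            sampled = others[pick]
            lag_perm = sampled @ Wd[i, nbr]
            I_perm = z[i] / m2 * lag_perm
            extreme = np.abs(I_perm) >= abs(I_loc[i]) - 1e-14
            p[i] = (1.0 + int(extreme.sum())) / (1.0 + n_permutations)

    p_eff = p.copy()
    if fdr:
        order = np.argsort(p)
        ranked = p[order] * n / (np.arange(n) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        p_eff[order] = np.minimum(adj, 1.0)

    labels = np.full(n, "not_significant", dtype=object)
    sig = p_eff <= alpha
    hh = sig & (z > 0) & (lag > 0)
    ll = sig & (z < 0) & (lag < 0)
    hl = sig & (z > 0) & (lag < 0)
    lh = sig & (z < 0) & (lag > 0)
    labels[hh], labels[ll], labels[hl], labels[lh] = "HH", "LL", "HL", "LH"

    out = pd.DataFrame(
        {
            "id": np.asarray(W.ids)[keep],
            "local_i": I_loc,
            "z": z,
            "lag": lag,
            "p_permutation": p,
            "label": labels,
        }
    )
    if keep.size < n_all:
        dropped = np.setdiff1d(np.arange(n_all), keep)
        pad = pd.DataFrame(
            {
                "id": np.asarray(W.ids)[dropped],
                "local_i": np.nan,
                "z": np.nan,
                "lag": np.nan,
                "p_permutation": np.nan,
                "label": "isolate",
            }
        )
        out = pd.concat([out, pad], ignore_index=True)
    return out


#: Two-sided normal quantiles for the Gi* confidence tiers.
_GI_TIERS = ((0.99, "99"), (0.95, "95"), (0.90, "90"))


def getis_ord_gi_star(
    values: np.ndarray,
    W_with_self: SpatialWeights,
    alpha_levels: Sequence[float] = (0.90, 0.95, 0.99),
) -> pd.DataFrame:
    """Getis-Ord Gi* hot/cold-spot z-scores with confidence-tier categories.

    z_i = [sum_j w_ij x_j - xbar * sum_j w_ij]
          / (S * sqrt{[n * sum_j w_ij^2 - (sum_j w_ij)^2] / (n - 1)})

    with xbar and S the global mean and (population) standard deviation and
    the self-weight included (w_ii > 0). Categories hot_90/95/99 and
    cold_90/95/99 apply the two-sided normal quantiles to the z-score.

    Returns a frame: id, gi_star_z, category.
    """
    if not W_with_self.includes_self or (W_with_self.matrix.diagonal() <= 0).any():
        raise ValueError("Gi* requires weights with positive self-weight (include_self=True)")
    x = np.asarray(values, dtype=float)
    if len(x) != W_with_self.n:
        raise ValueError("values length does not match weights order")
    n = len(x)
    xbar = x.mean()
    S = np.sqrt((x**2).mean() - xbar**2)
    if S == 0.0:
        raise DegenerateInputError("Gi* undefined: values have zero variance")
    Wd = W_with_self.matrix.toarray()
    wsum = Wd.sum(axis=1)
    w2sum = (Wd**2).sum(axis=1)
    num = Wd @ x - xbar * wsum
    den = S * np.sqrt(np.maximum(n * w2sum - wsum**2, 0.0) / (n - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        zi = np.where(den > 0, num / den, 0.0)

    cats = np.full(n, "not_significant", dtype=object)
    for conf in sorted(alpha_levels):
        thr = sps.norm.ppf(1 - (1 - conf) / 2)
        tier = f"{conf * 100:.0f}"
        cats[zi >= thr] = f"hot_{tier}"
        cats[zi <= -thr] = f"cold_{tier}"
    return pd.DataFrame({"id": np.asarray(W_with_self.ids), "gi_star_z": zi, "category": cats})


# -- weights serialization ---------------------------------------------------

def write_weights_csv(W: SpatialWeights, path: str | Path) -> None:
    """Export weights as a sparse triplet table (i, j, w) keyed by unit id."""
    coo = W.matrix.tocoo()
    pd.DataFrame(
        {"i": np.asarray(W.ids)[coo.row], "j": np.asarray(W.ids)[coo.col], "w": coo.data}
    ).to_csv(path, index=False)


def read_weights_csv(path: str | Path, ids: Sequence) -> SpatialWeights:
    """Read a triplet CSV back into a weights object over the given id order."""
    df = pd.read_csv(path)
    ids = np.asarray(ids)
    pos = {val: i for i, val in enumerate(ids)}
    rows = df["i"].map(pos).to_numpy()
    cols = df["j"].map(pos).to_numpy()
    mat = sparse.csr_matrix((df["w"].to_numpy(float), (rows, cols)), shape=(len(ids), len(ids)))
    row_sums = np.asarray(mat.sum(axis=1)).ravel()
    std = bool(np.allclose(row_sums[row_sums > 0], 1.0, atol=1e-9))
    return SpatialWeights(
        ids=ids,
        matrix=mat,
        scheme="imported",
        row_standardized=std,
        includes_self=bool((mat.diagonal() > 0).any()),
    )
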