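"""Distance-based multivariate statistics over whole-plate substrate profiles.

Replicate plates are compared as points in 95-dimensional substrate space
using the Bray-Curtis dissimilarity, and group structure (infected vs cured
strain) is tested by three classical permutation procedures implemented here
from first principles:

* PERMANOVA - a pseudo-F on sums of squared distances, with
  SS_total = (1/N) sum_{i<j} d_ij^2 and SS_within accumulated per group;
* ANOSIM - Clarke's rank statistic R = (rb - rw) / (M/2) on the M = N(N-1)/2
  pairwise distances, mid-ranks for ties;
* MRPP - the chance-corrected within-group agreement A = 1 - delta/E(delta),
  where delta is the weighted mean within-group distance.

All three share the permutation scheme: sample labels are shuffled uniformly,
the observed labeling counts as one permutation, and
p = (1 + #{stat_perm at least as extreme}) / (1 + n_perm). For small N the
null can be enumerated exactly over all distinct labelings, in which case
p = #{at least as extreme} / #labelings (the observed labeling is in the
enumeration).

Hierarchical clustering (UPGMA by default) renders each time point's distance
matrix as a Newick dendrogram, and the global scan runs the three tests at
every read time to locate where the strain effect is largest.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .kinetics import endpoint_matrix
from .plate_data import (
    WAVELENGTH_TURBIDITY,
    GlobalComparison,
    KineticDataset,
    PlateLayout,
)

logger = logging.getLogger("ffpm")

__all__ = [
    "DistanceMatrix",
    "PermutationSettings",
    "bray_curtis",
    "bray_curtis_matrix",
    "PermanovaResult",
    "permanova",
    "AnosimResult",
    "anosim",
    "MrppResult",
    "mrpp",
    "upgma_dendrogram",
    "global_scan",
]


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative dissimilarity matrix with labeled samples."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count must match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between two profiles.

    Negative entries (blank-corrected noise) are clamped to zero with a
    logged warning; two all-zero profiles have no defined dissimilarity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    n_neg = int((x < 0).sum() + (y < 0).sum())
    if n_neg:
        logger.warning("bray_curtis: clamped %d negative entries to 0", n_neg)
        x = np.clip(x, 0, None)
        y = np.clip(y, 0, None)
    denom = float((x + y).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero profiles")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances among the rows of a sample x substrate table.

    Row labels become sample labels (a (strain, replicate) MultiIndex is
    joined as ``strain_r<replicate>``). Negative cells are clamped to zero
    once, with the clamp count logged.
    """
    values = table.to_numpy(dtype=float)
    n_neg = int((values < 0).sum())
    if n_neg:
        logger.warning("bray_curtis_matrix: clamped %d negative cells to 0", n_neg)
        values = np.clip(values, 0, None)
    n = values.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = float((values[i] + values[j]).sum())
            if denom == 0:
                raise ValueError("Bray-Curtis is undefined for two all-zero profiles")
            d[i, j] = d[j, i] = float(np.abs(values[i] - values[j]).sum() / denom)
    if isinstance(table.index, pd.MultiIndex):
        labels = tuple(f"{s}_r{r}" for s, r in table.index)
    else:
        labels = tuple(str(ix) for ix in table.index)
    return DistanceMatrix(labels=labels, values=d)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationSettings:
    """Permutation-null configuration shared by the three tests."""

    n_perm: int = 1000
    seed: int | None = None
    exact_enumeration: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")


def _encode_groups(groups: Sequence[str]) -> np.ndarray:
    groups = np.asarray(groups)
    uniq, codes = np.unique(groups, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    return codes


def _all_labelings(codes: np.ndarray) -> Iterable[np.ndarray]:
    """All distinct assignments of the label multiset to the samples."""
    seen = set()
    for perm in itertools.permutations(codes.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm)


def _permuted_labelings(
    codes: np.ndarray, settings: PermutationSettings
) -> Iterable[np.ndarray]:
    rng = np.random.default_rng(settings.seed)
    for _ in range(settings.n_perm):
        yield rng.permutation(codes)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

class PermanovaResult(NamedTuple):
    F: float
    r2: float
    p: float


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    if ss_within == 0:
        f = np.inf
    else:
        f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2)


def permanova(
    d: DistanceMatrix, groups: Sequence[str], settings: PermutationSettings
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F and R^2 are computed from sums of squared distances; the p-value
    comes from uniform relabeling (or exhaustive enumeration of all distinct
    labelings when ``settings.exact_enumeration``).
    """
    codes = _encode_groups(groups)
    a = int(codes.max()) + 1
    d2 = d.values**2
    f_obs, r2 = _permanova_stats(d2, codes, a)
    if settings.exact_enumeration:
        stats_null = [_permanova_stats(d2, lab, a)[0] for lab in _all_labelings(codes)]
        p = sum(f >= f_obs for f in stats_null) / len(stats_null)
    else:
        count = sum(
            _permanova_stats(d2, lab, a)[0] >= f_obs
            for lab in _permuted_labelings(codes, settings)
        )
        p = (1 + count) / (1 + settings.n_perm)
    return PermanovaResult(F=f_obs, r2=r2, p=float(p))


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

class AnosimResult(NamedTuple):
    R: float
    p: float


def _anosim_stat(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (m / 2.0))


def _within_mask(codes: np.ndarray) -> np.ndarray:
    """Condensed-form boolean mask of within-group pairs."""
    same = codes[:, None] == codes[None, :]
    return squareform(same, checks=False).astype(bool)


def anosim(
    d: DistanceMatrix, groups: Sequence[str], settings: PermutationSettings
) -> AnosimResult:
    """Clarke's analysis of similarities on a distance matrix.

    All N(N-1)/2 distances are ranked once (mid-ranks for ties); R contrasts
    the mean rank of between-group pairs with that of within-group pairs and
    lies in [-1, 1], reaching 1 exactly under complete separation.
    """
    codes = _encode_groups(groups)
    ranks = rankdata(d.condensed())
    r_obs = _anosim_stat(ranks, _within_mask(codes))
    if settings.exact_enumeration:
        stats_null = [
            _anosim_stat(ranks, _within_mask(lab)) for lab in _all_labelings(codes)
        ]
        p = sum(r >= r_obs for r in stats_null) / len(stats_null)
    else:
        count = sum(
            _anosim_stat(ranks, _within_mask(lab)) >= r_obs
            for lab in _permuted_labelings(codes, settings)
        )
        p = (1 + count) / (1 + settings.n_perm)
    return AnosimResult(R=r_obs, p=float(p))


# ---------------------------------------------------------------------------
# MRPP
# ---------------------------------------------------------------------------

class MrppResult(NamedTuple):
    A: float
    p: float
    delta: float
    expected_delta: float


_MRPP_WEIGHTINGS = ("fraction", "dof", "pairs")


def _mrpp_delta(d: np.ndarray, codes: np.ndarray, n_groups: int, weighting: str) -> float:
    n = d.shape[0]
    sizes = np.bincount(codes, minlength=n_groups)
    if weighting == "fraction":
        weights = sizes / n
    elif weighting == "dof":
        weights = (sizes - 1) / (n - n_groups)
    elif weighting == "pairs":
        pairs = sizes * (sizes - 1)
        weights = pairs / pairs.sum()
    else:
        raise ValueError(f"unknown MRPP weighting {weighting!r}")
    delta = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        k = len(idx)
        mean_within = d[np.ix_(idx, idx)].sum() / (k * (k - 1))
        delta += weights[g] * mean_within
    return float(delta)


def mrpp(
    d: DistanceMatrix,
    groups: Sequence[str],
    settings: PermutationSettings,
    weighting: str = "fraction",
) -> MrppResult:
    """Multi-response permutation procedure on a distance matrix.

    delta is the weighted mean within-group distance (group weights n_g/N by
    default; ``dof`` and ``pairs`` select the (n_g-1)/(N-a) and
    n_g(n_g-1)/sum alternatives). The chance-corrected agreement is
    A = 1 - delta/E(delta) with E(delta) the mean delta over the permuted
    labelings; small delta (tight groups) is the extreme direction, so
    p counts permutations with delta at most the observed.
    """
    codes = _encode_groups(groups)
    a = int(codes.max()) + 1
    delta_obs = _mrpp_delta(d.values, codes, a, weighting)
    if settings.exact_enumeration:
        deltas = [
            _mrpp_delta(d.values, lab, a, weighting) for lab in _all_labelings(codes)
        ]
        p = sum(x <= delta_obs for x in deltas) / len(deltas)
        expected = float(np.mean(deltas))
    else:
        deltas = [
            _mrpp_delta(d.values, lab, a, weighting)
            for lab in _permuted_labelings(codes, settings)
        ]
        p = (1 + sum(x <= delta_obs for x in deltas)) / (1 + settings.n_perm)
        expected = float(np.mean(deltas))
    A = 1.0 - delta_obs / expected if expected > 0 else 0.0
    return MrppResult(A=float(A), p=float(p), delta=delta_obs, expected_delta=expected)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def upgma_dendrogram(d: DistanceMatrix, linkage: str = "average") -> str:
    """Agglomerative cluster dendrogram as a Newick string.

    UPGMA (average linkage) by default; ``single`` and ``complete`` are also
    accepted. The tree is ultrametric: a cluster merged at distance h sits at
    height h/2, and branch lengths are differences of merge heights. Ties are
    broken deterministically by input label order.
    """
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if d.n < 2:
        raise ValueError("need at least 2 samples to cluster")
    z = hierarchy.linkage(d.condensed(), method=linkage)
    heights = {i: 0.0 for i in range(d.n)}

    def min_leaf(node: int) -> int:
        if node < d.n:
            return node
        left, right, _, _ = z[node - d.n]
        return min(min_leaf(int(left)), min_leaf(int(right)))

    def render(node: int) -> str:
        if node < d.n:
            return d.labels[node]
        left, right, dist, _ = z[node - d.n]
        h = dist / 2.0
        heights[node] = h
        children = sorted((int(left), int(right)), key=min_leaf)
        parts = []
        for child in children:
            sub = render(child)
            parts.append(f"{sub}:{h - heights[child]:.6g}")
        return "(" + ",".join(parts) + ")"

    root = d.n + len(z) - 1
    return render(root) + ";"


# ---------------------------------------------------------------------------
# per-time-point global scan
# ---------------------------------------------------------------------------

def global_scan(
    dataset: KineticDataset,
    layout: PlateLayout,
    settings: PermutationSettings = PermutationSettings(),
    wavelength: int = WAVELENGTH_TURBIDITY,
    include_water: bool = False,
) -> list[GlobalComparison]:
    """Run PERMANOVA, ANOSIM and MRPP at every read time point.

    At each time the raw per-plate substrate profiles (95 columns, water
    excluded by default) are reduced to a Bray-Curtis distance matrix among
    the replicate plates and tested for a strain effect. Each time point
    draws its permutation stream from a seed spawned deterministically from
    ``settings.seed``.
    """
    results: list[GlobalComparison] = []
    seeds = np.random.SeedSequence(settings.seed).generate_state(len(dataset.time_grid))
    for t, seed_t in zip(dataset.time_grid, seeds):
        table = endpoint_matrix(
            dataset, layout, wavelength=wavelength, time=t, include_water=include_water
        )
        dm = bray_curtis_matrix(table)
        groups = [s for s, _ in table.index]
        local = PermutationSettings(
            n_perm=settings.n_perm,
            seed=int(seed_t) % (2**31),
            exact_enumeration=settings.exact_enumeration,
        )
        perm = permanova(dm, groups, local)
        ano = anosim(dm, groups, local)
        mr = mrpp(dm, groups, local)
        results.append(
            GlobalComparison(
                time=float(t),
                permanova_F=perm.F,
                permanova_R2=perm.r2,
                permanova_p=perm.p,
                anosim_R=ano.R,
                anosim_p=ano.p,
                mrpp_A=mr.A,
                mrpp_p=mr.p,
                n_perm=settings.n_perm,
            )
        )
    return results
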