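"""Count matrices, group comparisons and PCA over TAP family sizes.

The comparative layer works on a families x species matrix of
non-negative integer counts (one column per genome, five-letter
species codes). Group comparisons follow a normality-gated protocol:
a Shapiro-Wilk test per group decides between a two-sample t-test and
a Wilcoxon rank-sum test. For the small group sizes typical of genome
panels (n = 3-6 per group) the Wilcoxon p-value is computed exactly by
enumerating all rank assignments; larger samples or ties fall back to
the tie-corrected normal approximation.

PCA treats species as observations and families as variables, centers
columns without variance scaling (scaling is available as a flag), and
fixes component signs by making each component's largest-magnitude
loading positive so that scores are reproducible across runs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "CountMatrix",
    "GroupComparison",
    "PCAResult",
    "build_count_matrix",
    "select_families_with_presence",
    "compare_groups",
    "exact_rank_sum_p",
    "run_pca",
]

PathLike = Union[str, Path]

TOTAL = "total"


@dataclass
class CountMatrix:
    """Families x species grid of non-negative integer TAP counts."""

    data: pd.DataFrame  # index = families, columns = species

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate family labels")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate species labels")
        if len(self.data) and (self.data.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: PathLike) -> None:
        self.data.to_csv(path, sep="\t", index_label="family")

    @classmethod
    def from_tsv(cls, path: PathLike) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = None
        return cls(df.astype(int))


@dataclass
class GroupComparison:
    """Result of one normality-gated two-group comparison."""

    family_or_total: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    normality_p: float  # min Shapiro-Wilk p over the two groups
    test_used: str  # "t-test" or "Wilcoxon"
    p_value: float
    degenerate: bool = False  # constant data forced the Wilcoxon route


@dataclass
class PCAResult:
    scores: pd.DataFrame  # species x components
    variance_fraction: np.ndarray
    loadings: pd.DataFrame  # families x components


def build_count_matrix(
    profiles: Mapping[str, Mapping[str, int]], family_universe: Sequence[str] | None = None
) -> CountMatrix:
    """Assemble per-species family counts into a CountMatrix.

    ``profiles`` maps species -> (family -> count). Missing cells are
    zero-filled. Row order follows ``family_universe`` when given,
    otherwise order of first appearance across species; column order
    is input order.
    """
    species = list(profiles)
    if family_universe is None:
        seen: dict[str, None] = {}
        for sp in species:
            for fam in profiles[sp]:
                seen.setdefault(fam, None)
        families = list(seen)
    else:
        families = list(family_universe)
    grid = np.zeros((len(families), len(species)), dtype=int)
    fam_idx = {f: i for i, f in enumerate(families)}
    for j, sp in enumerate(species):
        for fam, count in profiles[sp].items():
            if count < 0:
                raise ValueError(f"negative count for {fam!r} in {sp!r}")
            if fam in fam_idx:
                grid[fam_idx[fam], j] = count
    return CountMatrix(pd.DataFrame(grid, index=families, columns=species))


def select_families_with_presence(matrix: CountMatrix, focal_species: Iterable[str]) -> CountMatrix:
    """Keep the families with at least one member in at least one focal species.

    Used to restrict a broad count matrix to the families actually
    present in the lineage under study before PCA or comparison. The
    species columns are unchanged.
    """
    focal = list(focal_species)
    unknown = [s for s in focal if s not in matrix.data.columns]
    if unknown:
        raise KeyError(f"focal species not in matrix: {unknown}")
    mask = (matrix.data[focal] >= 1).any(axis=1)
    return CountMatrix(matrix.data.loc[mask])


def _values_for(matrix: CountMatrix, family_or_total: str, group: Sequence[str]) -> np.ndarray:
    if family_or_total == TOTAL:
        return matrix.data[list(group)].sum(axis=0).to_numpy(dtype=float)
    if family_or_total not in matrix.data.index:
        raise KeyError(f"family {family_or_total!r} not in matrix")
    return matrix.data.loc[family_or_total, list(group)].to_numpy(dtype=float)


def exact_rank_sum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sided Wilcoxon rank-sum p-value by full enumeration.

    Enumerates all C(n_a+n_b, n_a) assignments of the pooled ranks to
    group a and counts those whose rank-sum deviates from its mean at
    least as much as observed. Requires tie-free data (ranks are then
    a permutation of 1..N).
    """
    pooled = list(a) + list(b)
    n, m = len(a), len(pooled)
    if len(set(pooled)) != m:
        raise ValueError("exact enumeration requires tie-free data")
    ranks = stats.rankdata(pooled)
    w_obs = float(np.sum(ranks[:n]))
    mean_w = n * (m + 1) / 2.0
    dev = abs(w_obs - mean_w)
    hits = 0
    total = 0
    for combo in itertools.combinations(range(1, m + 1), n):
        total += 1
        if abs(sum(combo) - mean_w) >= dev - 1e-12:
            hits += 1
    return hits / total


def _rank_sum_normal_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p via the tie-corrected normal approximation."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def compare_groups(
    matrix: CountMatrix,
    family_or_total: str,
    group_a: Iterable[str],
    group_b: Iterable[str],
    alpha_normality: float = 0.05,
    exact_max_n: int = 10,
) -> GroupComparison:
    """Compare one family's size (or the per-species total) between two species groups.

    Shapiro-Wilk is run per group at ``alpha_normality``; if both
    groups look normal a two-sided Welch t-test is used, otherwise a
    two-sided Wilcoxon rank-sum test (exact by enumeration when both
    groups have <= ``exact_max_n`` members and the pooled data are
    tie-free, else the tie-corrected normal approximation). Constant
    data in a group make Shapiro-Wilk undefined; the comparison is
    then flagged degenerate and routed to Wilcoxon.
    """
    ga = tuple(group_a)
    gb = tuple(group_b)
    if not ga or not gb:
        raise ValueError("both groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    va = _values_for(matrix, family_or_total, ga)
    vb = _values_for(matrix, family_or_total, gb)

    degenerate = bool(np.ptp(va) == 0 or np.ptp(vb) == 0)
    if degenerate:
        normality_p = float("nan")
        normal = False
    else:
        pa = float(stats.shapiro(va).pvalue)
        pb = float(stats.shapiro(vb).pvalue)
        normality_p = min(pa, pb)
        normal = pa > alpha_normality and pb > alpha_normality

    if normal:
        p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        test = "t-test"
    else:
        test = "Wilcoxon"
        pooled = np.concatenate([va, vb])
        if np.ptp(pooled) == 0:
            p = 1.0  # perfectly identical data: no evidence of a shift
        elif (
            len(va) <= exact_max_n
            and len(vb) <= exact_max_n
            and len(np.unique(pooled)) == len(pooled)
        ):
            p = exact_rank_sum_p(va, vb)
        else:
            p = _rank_sum_normal_p(va, vb)
    return GroupComparison(family_or_total, ga, gb, normality_p, test, p, degenerate)


def run_pca(matrix: CountMatrix, scale: bool = False) -> PCAResult:
    """PCA of species (observations) in TAP family space (variables).

    Columns (families) are mean-centered; ``scale=True`` additionally
    divides by the per-family standard deviation. Variance fractions
    are singular_value^2 over their total and sum to 1 across all
    returned components. Signs are fixed per component: the loading
    with the largest magnitude is made positive.
    """
    if len(matrix.species) < 2:
        raise ValueError("PCA requires at least 2 species")
    X = matrix.data.to_numpy(dtype=float).T  # species x families
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    n_comp = min(X.shape[0] - 1, X.shape[1])
    n_comp = max(n_comp, 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # families x components
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    ev = pca.explained_variance_
    total = ev.sum()
    frac = ev / total if total > 0 else np.zeros_like(ev)
    comp_names = [f"PC{k + 1}" for k in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.species, columns=comp_names),
        variance_fraction=frac,
        loadings=pd.DataFrame(loadings, index=matrix.families, columns=comp_names),
    )
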