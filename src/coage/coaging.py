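"""Apparent tissue age from aging-gene expression and cross-tissue co-aging.

Each tissue's samples are projected on the first principal component of the
aging-gene submatrix; PC1 is sign-oriented so larger coordinates mean older
(non-negative Spearman with chronological age).  The co-aging coefficient of
a tissue pair is the Spearman correlation of those coordinates across shared
donors.  A donor's rank deviation ``d`` measures how far its per-tissue
apparent-age ranks sit from its chronological-age rank; donors in the upper
tail of a normal fit to the ``d`` distribution are flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import DonorTable, ExpressionMatrix, TissueSampleMap
from .aging import compute_expression_pcs

__all__ = [
    "ApparentAgeTable",
    "CoagingMatrix",
    "RankDeviationResult",
    "apparent_age_pc1",
    "coaging_matrix",
    "young_old_partition",
    "rank_deviation",
    "deviation_age_trend",
]


@dataclass
class ApparentAgeTable:
    tissue: str
    sample_ids: List[str]
    pc1_coordinate: np.ndarray  # oriented: larger => older
    rank: np.ndarray  # 1..n, ties broken by sample id
    spearman_vs_age: float

    def coordinate_of(self) -> pd.Series:
        return pd.Series(self.pc1_coordinate, index=self.sample_ids)


@dataclass
class CoagingMatrix:
    tissues: List[str]
    coefficients: pd.DataFrame  # tissue x tissue Spearman, NaN where undefined
    n_shared_donors: pd.DataFrame


@dataclass
class RankDeviationResult:
    donor_id: str
    rank_vector: Tuple[int, ...]
    chrono_rank: int
    d: float
    p_value: float
    is_outlier: bool


def _display_ranks(values: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """1..n ranks ascending in value, ties broken by id (deterministic)."""
    order = sorted(range(len(ids)), key=lambda i: (values[i], ids[i]))
    ranks = np.empty(len(ids), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def apparent_age_pc1(expr: ExpressionMatrix, ages: np.ndarray) -> ApparentAgeTable:
    """PC1 coordinates of the aging-gene submatrix, oriented toward age."""
    if expr.n_genes < 2:
        raise ValueError("no signature available: need at least 2 aging genes")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples")
    pcs = compute_expression_pcs(expr, np.asarray(ages, float), k=1)
    coord = pcs.coordinates[:, 0].copy()
    rho = _safe_spearman(coord, np.asarray(ages, float))
    if rho < 0:
        coord = -coord
        rho = -rho
    ranks = _display_ranks(coord, expr.sample_ids)
    return ApparentAgeTable(expr.tissue, expr.sample_ids, coord, ranks, rho)


def _safe_spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def coaging_matrix(
    tables: Dict[str, ApparentAgeTable], smap: TissueSampleMap, min_shared: int = 3
) -> CoagingMatrix:
    """Pairwise Spearman of apparent ages across donors shared by each tissue pair."""
    tissues = list(tables)
    donor_series: Dict[str, pd.Series] = {}
    for t, tab in tables.items():
        donors = smap.donors_of(tab.sample_ids)
        donor_series[t] = pd.Series(tab.pc1_coordinate, index=donors)
    coef = pd.DataFrame(np.eye(len(tissues)), index=tissues, columns=tissues)
    nshared = pd.DataFrame(0, index=tissues, columns=tissues, dtype=int)
    for t in tissues:
        nshared.loc[t, t] = len(donor_series[t])
    for i, ta in enumerate(tissues):
        for tb in tissues[i + 1 :]:
            shared = donor_series[ta].index.intersection(donor_series[tb].index)
            nshared.loc[ta, tb] = nshared.loc[tb, ta] = len(shared)
            if len(shared) < min_shared:
                coef.loc[ta, tb] = coef.loc[tb, ta] = np.nan
                continue
            rho = _safe_spearman(
                donor_series[ta][shared].to_numpy(), donor_series[tb][shared].to_numpy()
            )
            coef.loc[ta, tb] = coef.loc[tb, ta] = rho
    return CoagingMatrix(tissues, coef, nshared)


def young_old_partition(
    expr: ExpressionMatrix, ages: np.ndarray
) -> Tuple[pd.Series, float]:
    """Ward clustering of samples into two groups plus an age t-test.

    Returns labels ('young'/'old' per sample; the lower-mean-age cluster is
    'young') and the two-sided two-sample t-test p-value on ages.
    """
    if expr.n_samples < 4:
        raise ValueError("need at least 4 samples")
    X = expr.values.T  # samples x genes
    if np.allclose(X, X[0]):
        raise ValueError("degenerate clustering: all samples identical")
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=2, criterion="maxclust")
    ages = np.asarray(ages, float)
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate clustering: single cluster")
    m1, m2 = ages[labels == 1].mean(), ages[labels == 2].mean()
    young = 1 if m1 <= m2 else 2
    named = np.where(labels == young, "young", "old")
    t, p = stats.ttest_ind(ages[labels == 1], ages[labels == 2])
    return pd.Series(named, index=expr.sample_ids), float(p)


def rank_deviation(
    tables: Dict[str, ApparentAgeTable],
    donors: DonorTable,
    smap: TissueSampleMap,
    outlier_alpha: float = 0.05,
    method: str = "rms",
) -> List[RankDeviationResult]:
    """Per-donor deviation of tissue apparent-age ranks from chronological rank.

    Restricted to donors present in every tissue; ranks are recomputed within
    that overlap.  ``method='rms'`` gives d = sqrt(mean((r_i - r)^2)) (size
    comparable across tissue sets); ``'euclidean'`` the unnormalized distance.
    The outlier p-value is the upper tail of a normal with moments estimated
    from the observed d values.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tissues")
    if method not in ("rms", "euclidean"):
        raise ValueError(f"unknown method {method!r}")
    tissues = list(tables)
    per_tissue: Dict[str, pd.Series] = {}
    for t, tab in tables.items():
        ids = smap.donors_of(tab.sample_ids)
        per_tissue[t] = pd.Series(tab.pc1_coordinate, index=ids)
    shared = per_tissue[tissues[0]].index
    for t in tissues[1:]:
        shared = shared.intersection(per_tissue[t].index)
    shared = sorted(shared)
    if len(shared) < 3:
        raise ValueError("fewer than 3 donors shared by all tissues")

    rank_matrix = np.column_stack(
        [
            _display_ranks(per_tissue[t][shared].to_numpy(), shared)
            for t in tissues
        ]
    )
    chrono = _display_ranks(donors.ages(shared), shared)
    diffs = rank_matrix - chrono[:, None]
    if method == "rms":
        d = np.sqrt((diffs**2).mean(axis=1))
    else:
        d = np.sqrt((diffs**2).sum(axis=1))
    mu, sd = float(d.mean()), float(d.std(ddof=1))
    if sd == 0:
        pvals = np.ones(len(shared))
    else:
        pvals = stats.norm.sf(d, loc=mu, scale=sd)
    return [
        RankDeviationResult(
            donor_id=did,
            rank_vector=tuple(int(r) for r in rank_matrix[i]),
            chrono_rank=int(chrono[i]),
            d=float(d[i]),
            p_value=float(pvals[i]),
            is_outlier=bool(pvals[i] < outlier_alpha),
        )
        for i, did in enumerate(shared)
    ]


def deviation_age_trend(
    table_a: ApparentAgeTable,
    table_b: ApparentAgeTable,
    donors: DonorTable,
    smap: TissueSampleMap,
) -> Tuple[float, float]:
    """Slope (and its t-test p) of |rank_a - rank_b| on chronological age.

    Ranks are recomputed within the two tissues' shared donors.
    """
    da = pd.Series(table_a.pc1_coordinate, index=smap.donors_of(table_a.sample_ids))
    db = pd.Series(table_b.pc1_coordinate, index=smap.donors_of(table_b.sample_ids))
    shared = sorted(da.index.intersection(db.index))
    if len(shared) < 5:
        raise ValueError("need at least 5 shared donors")
    ra = _display_ranks(da[shared].to_numpy(), shared)
    rb = _display_ranks(db[shared].to_numpy(), shared)
    dev = np.abs(ra - rb).astype(float)
    ages = donors.ages(shared)
    if np.std(ages) == 0:
        raise ValueError("zero age variance among shared donors")
    if np.std(dev) == 0:
        return 0.0, 1.0
    fit = stats.linregress(ages, dev)
    return float(fit.slope), float(fit.pvalue)
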