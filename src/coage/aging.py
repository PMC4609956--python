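"""Per-tissue detection of age-associated genes.

The detection model regresses each gene's expression on donor age plus a
configurable set of nuisance covariates (sex, top genotype PCs, and a subset
of the top expression PCs).  Nine correction models M1-M9 define which
expression PCs enter:

* M1 - no covariates at all;
* M2 - sex + 3 genotype PCs;
* M3-M7 - additionally the expression PCs whose absolute Pearson correlation
  with age is below 0.1, 0.2, 0.3, 0.4, 0.5 respectively;
* M8 - the PC subset that maximizes the number of BH-significant age genes
  (exhaustive search over subsets of the top PCs);
* M9 - the PCs not significantly correlated with age (p > 0.05).

Significance is a two-sided t-test on the age coefficient with BH FDR
control, followed by removal of the lowest-expressed fifth of the called
genes (ranked by each gene's mean over its top-quarter samples).  Stability
is assessed by bootstrap consensus and a permutation null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    AnalysisConfig,
    DonorTable,
    ExpressionMatrix,
    TissueSampleMap,
    aligned_covariates,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionPCs",
    "CorrectionModel",
    "AgingGeneSet",
    "PermutationSummary",
    "compute_expression_pcs",
    "build_correction_model",
    "select_m8_subset",
    "fit_gene_age_regression",
    "bh_adjust",
    "low_expression_filter",
    "call_aging_genes",
    "bootstrap_consensus",
    "permutation_null",
    "subsample_power_curve",
    "select_model_by_reference_enrichment",
]

M3_M7_THRESHOLDS = {"M3": 0.1, "M4": 0.2, "M5": 0.3, "M6": 0.4, "M7": 0.5}


@dataclass
class ExpressionPCs:
    sample_ids: List[str]
    coordinates: np.ndarray  # samples x components
    variance_explained: np.ndarray
    age_corr_r: np.ndarray
    age_corr_p: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class CorrectionModel:
    model_id: str
    include_sex: bool
    n_genotype_pcs: int
    expression_pc_indices: Tuple[int, ...]  # 1-based indices into the top PCs


@dataclass
class AgingGeneSet:
    tissue: str
    up: List[str]
    down: List[str]
    bootstrap_support: Dict[str, int] = field(default_factory=dict)
    filtered_out: List[str] = field(default_factory=list)

    @property
    def genes(self) -> List[str]:
        return self.up + self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class PermutationSummary:
    n_permutations: int
    counts: np.ndarray
    frequency_ge_observed: int
    mean_count: float
    observed_count: int
    exceeds_threshold: bool


def compute_expression_pcs(
    expr: ExpressionMatrix, ages: np.ndarray, k: int
) -> ExpressionPCs:
    """Sample-space PCs of the gene-centered expression matrix.

    Genes are centered (not variance-scaled) before the decomposition; the
    returned coordinates are the samples' projections on the top ``k``
    components, each oriented so its largest-magnitude gene loading is
    positive (PCA signs are otherwise arbitrary).
    """
    n_genes, n_samples = expr.data.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples for PCA")
    if k > min(n_genes, n_samples):
        raise ValueError(f"k={k} exceeds min(genes, samples)={min(n_genes, n_samples)}")
    X = expr.values
    Xc = X - X.mean(axis=1, keepdims=True)
    total_var = float((Xc**2).sum())
    if total_var == 0.0:
        raise ValueError("zero variance expression matrix")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for i in range(len(S)):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            Vt[i] = -Vt[i]
    coords = (Vt[:k].T * S[:k])  # samples x k
    var_exp = (S[:k] ** 2) / (S**2).sum()
    ages = np.asarray(ages, dtype=float)
    rs, ps = np.zeros(k), np.ones(k)
    for i in range(k):
        if np.std(coords[:, i]) == 0 or np.std(ages) == 0:
            rs[i], ps[i] = 0.0, 1.0
        else:
            rs[i], ps[i] = stats.pearsonr(coords[:, i], ages)
    return ExpressionPCs(expr.sample_ids, coords, var_exp, rs, ps)


def build_correction_model(model_id: str, pcs: Optional[ExpressionPCs] = None) -> CorrectionModel:
    """Resolve a model id into its covariate recipe (M8 requires the search in
    :func:`select_m8_subset` and is rejected here)."""
    if model_id == "M1":
        return CorrectionModel("M1", include_sex=False, n_genotype_pcs=0, expression_pc_indices=())
    if model_id == "M2":
        return CorrectionModel("M2", include_sex=True, n_genotype_pcs=3, expression_pc_indices=())
    if model_id in M3_M7_THRESHOLDS:
        if pcs is None:
            raise ValueError(f"{model_id} requires expression PCs")
        t = M3_M7_THRESHOLDS[model_id]
        idx = tuple(i + 1 for i in range(pcs.n_components) if abs(pcs.age_corr_r[i]) < t)
        return CorrectionModel(model_id, True, 3, idx)
    if model_id == "M9":
        if pcs is None:
            raise ValueError("M9 requires expression PCs")
        idx = tuple(i + 1 for i in range(pcs.n_components) if pcs.age_corr_p[i] > 0.05)
        return CorrectionModel("M9", True, 3, idx)
    if model_id == "M8":
        raise ValueError("M8 requires the exhaustive subset search (select_m8_subset)")
    raise ValueError(f"unknown correction model: {model_id!r}")


def _design_matrix(
    ages: np.ndarray,
    model: CorrectionModel,
    sex01: np.ndarray,
    geno: np.ndarray,
    pcs: Optional[ExpressionPCs],
) -> Tuple[np.ndarray, List[str]]:
    cols = [np.ones_like(ages, dtype=float), np.asarray(ages, dtype=float)]
    names = ["intercept", "age"]
    if model.include_sex:
        cols.append(sex01)
        names.append("sex")
    for k in range(model.n_genotype_pcs):
        cols.append(geno[:, k])
        names.append(f"geno_pc{k + 1}")
    for i in model.expression_pc_indices:
        if pcs is None:
            raise ValueError("expression PC covariates requested without PCs")
        cols.append(pcs.coordinates[:, i - 1])
        names.append(f"expr_pc{i}")
    return np.column_stack(cols), names


def fit_gene_age_regression(
    expr: ExpressionMatrix,
    ages: np.ndarray,
    model: CorrectionModel,
    sex01: Optional[np.ndarray] = None,
    geno: Optional[np.ndarray] = None,
    pcs: Optional[ExpressionPCs] = None,
) -> pd.DataFrame:
    """OLS of every gene on intercept + age + the model's covariates.

    Returns a frame indexed by gene id with columns gamma, std_error,
    p_value, fdr, direction.  Zero-variance genes are reported as
    gamma = 0, p = 1 rather than raising (resampling can create them).
    """
    n = expr.n_samples
    if sex01 is None:
        sex01 = np.zeros(n)
    if geno is None:
        geno = np.zeros((n, 3))
    X, names = _design_matrix(np.asarray(ages, float), model, sex01, geno, pcs)
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError(f"too few samples ({n}) for {p} design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name columns collinear with the preceding ones via QR diagnostics
        bad = []
        for j in range(1, p):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    Y = expr.values  # genes x samples
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T  # genes x p
    resid = Y - beta @ X.T
    dof = n - p
    sigma2 = (resid**2).sum(axis=1) / dof
    age_j = names.index("age")
    gamma = beta[:, age_j]
    se = np.sqrt(sigma2 * XtX_inv[age_j, age_j])

    zero_var = Y.var(axis=1) == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = gamma / se  # se == 0: inf for a perfect fit, nan for gamma == 0
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    pvals = np.where((se == 0) & (gamma == 0), 1.0, pvals)
    gamma = np.where(zero_var, 0.0, gamma)
    se = np.where(zero_var, 0.0, se)
    pvals = np.where(zero_var, 1.0, pvals)
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)

    out = pd.DataFrame(
        {
            "gamma": gamma,
            "std_error": se,
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
            "direction": np.where(gamma > 0, "up", "down"),
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def low_expression_filter(
    expr: ExpressionMatrix,
    aging_ids: Sequence[str],
    top_frac: float = 0.25,
    drop_frac: float = 0.20,
) -> Tuple[List[str], List[str]]:
    """Drop the lowest-expressed fraction of called genes.

    Each gene is scored by the mean of its expression over the top
    ``ceil(top_frac * n_samples)`` samples; genes rank by score descending
    (ties by gene id ascending) and the bottom ``floor(drop_frac * m)``
    are dropped.  Returns (kept, dropped), kept in input order.
    """
    aging_ids = list(aging_ids)
    if not aging_ids:
        return [], []
    missing = set(aging_ids) - set(expr.data.index)
    if missing:
        raise KeyError(f"aging genes not in matrix: {sorted(missing)}")
    n = expr.n_samples
    n_top = max(1, math.ceil(top_frac * n))
    sub = expr.data.loc[aging_ids].to_numpy()
    top_means = np.sort(sub, axis=1)[:, -n_top:].mean(axis=1)
    ranked = sorted(zip(aging_ids, top_means), key=lambda kv: (-kv[1], kv[0]))
    n_drop = math.floor(drop_frac * len(aging_ids))
    dropped = [g for g, _ in ranked[len(ranked) - n_drop :]] if n_drop else []
    dropped_set = set(dropped)
    kept = [g for g in aging_ids if g not in dropped_set]
    return kept, dropped


def select_m8_subset(
    expr: ExpressionMatrix,
    ages: np.ndarray,
    pcs: ExpressionPCs,
    sex01: np.ndarray,
    geno: np.ndarray,
    fdr_alpha: float = 0.05,
) -> CorrectionModel:
    """Exhaustive search for the expression-PC subset maximizing discoveries.

    Every subset of the top-k PCs is evaluated with the full per-gene
    regression plus BH at ``fdr_alpha``; ties break toward the smaller
    subset, then lexicographically.
    """
    k = pcs.n_components
    if 2**k > 256:
        raise ValueError(
            f"M8 search space 2^{k} exceeds 256 subsets; lower n_expr_pcs"
        )
    from itertools import combinations

    best: Tuple[int, int, Tuple[int, ...]] | None = None  # (-count, size, indices)
    best_model: CorrectionModel | None = None
    for size in range(k + 1):
        for subset in combinations(range(1, k + 1), size):
            model = CorrectionModel("M8", True, 3, subset)
            res = fit_gene_age_regression(expr, ages, model, sex01, geno, pcs)
            count = int((res["fdr"] < fdr_alpha).sum())
            key = (-count, size, subset)
            if best is None or key < best:
                best, best_model = key, model
    assert best_model is not None
    return best_model


def _resolve_model(
    model_id: str,
    expr: ExpressionMatrix,
    ages: np.ndarray,
    pcs: ExpressionPCs,
    sex01: np.ndarray,
    geno: np.ndarray,
    fdr_alpha: float,
) -> CorrectionModel:
    if model_id == "M8":
        return select_m8_subset(expr, ages, pcs, sex01, geno, fdr_alpha)
    return build_correction_model(model_id, pcs)


def call_aging_genes(
    expr: ExpressionMatrix,
    donors: DonorTable,
    smap: TissueSampleMap,
    config: AnalysisConfig,
    model_id: Optional[str] = None,
    apply_filter: bool = True,
    ages_override: Optional[np.ndarray] = None,
) -> Tuple[AgingGeneSet, pd.DataFrame]:
    """Full single-tissue pipeline: PCs -> model -> regression -> BH -> filter."""
    ages, sex01, geno, _ = aligned_covariates(expr, donors, smap)
    if ages_override is not None:
        ages = np.asarray(ages_override, dtype=float)
    model_id = model_id or config.correction_model
    k = min(config.n_expr_pcs, expr.n_genes, expr.n_samples - 1)
    pcs = compute_expression_pcs(expr, ages, k)
    model = _resolve_model(model_id, expr, ages, pcs, sex01, geno, config.fdr_alpha)
    results = fit_gene_age_regression(expr, ages, model, sex01, geno, pcs)
    sig = results.index[results["fdr"] < config.fdr_alpha].tolist()
    if apply_filter:
        kept, dropped = low_expression_filter(
            expr, sig, config.low_expr_top_frac, config.low_expr_drop_frac
        )
    else:
        kept, dropped = sig, []
    results["significant"] = results["fdr"] < config.fdr_alpha
    results["passed_low_expression_filter"] = results.index.isin(kept)
    results["in_final_set"] = results.index.isin(kept)
    up = [g for g in kept if results.at[g, "direction"] == "up"]
    down = [g for g in kept if results.at[g, "direction"] == "down"]
    return AgingGeneSet(expr.tissue, up, down, filtered_out=dropped), results


def _resample(
    expr: ExpressionMatrix, smap: TissueSampleMap, idx: np.ndarray, tag: str
) -> Tuple[ExpressionMatrix, TissueSampleMap]:
    cols = [expr.sample_ids[i] for i in idx]
    new_ids = [f"{s}#{tag}{j}" for j, s in enumerate(cols)]
    df = expr.data[cols].copy()
    df.columns = new_ids
    rows = smap.data.loc[cols].copy()
    rows.index = pd.Index(new_ids, name="sample_id")
    # resampled donors may repeat; relabel so the donor/tissue pair stays unique
    rows["donor_id"] = [f"{d}#{tag}{j}" for j, d in enumerate(rows["donor_id"])]
    return ExpressionMatrix(expr.tissue, df), rows


def bootstrap_consensus(
    expr: ExpressionMatrix,
    donors: DonorTable,
    smap: TissueSampleMap,
    config: AnalysisConfig,
    rng: Optional[np.random.Generator] = None,
    apply_filter: bool = False,
) -> Tuple[AgingGeneSet, pd.DataFrame]:
    """Bootstrap the samples, rerun the full pipeline, and keep consensus genes.

    A gene enters the final signature if it is BH-significant in at least
    ``bootstrap_support_min`` of ``bootstrap_runs`` resamples (strictly more
    when ``bootstrap_strict``) *and* BH-significant in the full-sample run.
    Within a resample "significant" means BH FDR < alpha in that resample,
    mirroring the full-sample rule.  The low-expression filter is evaluated
    once on the full-sample call and reported (``filtered_out`` and the
    per-gene ``passed_low_expression_filter`` flag) but does not gate the
    consensus set unless ``apply_filter`` is set; its score ranking is a
    population quantity, so letting it fluctuate per resample would only
    erode support for genes near the score boundary.  PCs are recomputed
    inside each resample.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    full_set, full_results = call_aging_genes(expr, donors, smap, config)
    n = expr.n_samples
    ages_full, _, _, _ = aligned_covariates(expr, donors, smap)
    min_distinct = _min_distinct_samples(config)
    support: Dict[str, int] = {g: 0 for g in expr.gene_ids}
    for b in range(config.bootstrap_runs):
        for attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(idx)) >= min_distinct and np.std(ages_full[idx]) > 0:
                break
            logger.warning("bootstrap %d: degenerate resample redrawn", b)
        expr_b, rows_b = _resample(expr, smap, idx, f"b{b}.")
        smap_b, donors_b = _expand_donors(rows_b, donors)
        gene_set, _ = call_aging_genes(expr_b, donors_b, smap_b, config, apply_filter=False)
        for g in gene_set.genes:
            support[g] += 1
    threshold = config.bootstrap_support_min
    if config.bootstrap_strict:
        ok = {g for g, c in support.items() if c > threshold}
    else:
        ok = {g for g, c in support.items() if c >= threshold}
    if apply_filter:
        full_sig = full_set.genes
    else:
        full_sig = full_results.index[full_results["significant"]].tolist()
    final = [g for g in full_sig if g in ok]
    up = [g for g in final if full_results.at[g, "direction"] == "up"]
    down = [g for g in final if full_results.at[g, "direction"] == "down"]
    out = AgingGeneSet(
        expr.tissue,
        up,
        down,
        bootstrap_support={g: support[g] for g in expr.gene_ids},
        filtered_out=full_set.filtered_out,
    )
    full_results = full_results.copy()
    full_results["bootstrap_support"] = [support[g] for g in full_results.index]
    full_results["in_final_set"] = full_results.index.isin(final)
    return out, full_results


def _min_distinct_samples(config: AnalysisConfig) -> int:
    # worst-case covariate count: intercept + age + sex + geno PCs + expr PCs
    return 2 + 1 + config.n_geno_pcs + config.n_expr_pcs + 3


def _expand_donors(rows: pd.DataFrame, donors: DonorTable) -> Tuple[TissueSampleMap, DonorTable]:
    """Donor table for resampled data whose donor ids carry a #tag suffix."""
    base = [d.split("#")[0] for d in rows["donor_id"]]
    ddf = donors.data.loc[base].copy()
    ddf.index = pd.Index(rows["donor_id"].tolist(), name="donor_id")
    return TissueSampleMap(rows), DonorTable(ddf)


def permutation_null(
    expr: ExpressionMatrix,
    donors: DonorTable,
    smap: TissueSampleMap,
    config: AnalysisConfig,
    observed_count: int,
    rng: Optional[np.random.Generator] = None,
    apply_filter: bool = True,
) -> PermutationSummary:
    """Null distribution of the aging-gene count under age permutation.

    Ages are shuffled across the tissue's samples (sex and genotype PCs stay
    attached); the regression + BH (+ low-expression filter) pipeline reruns
    per permutation under ``config.permutation_model`` (default M8).  A
    tissue whose observed count is matched or beaten more than 5 times in
    1,000 permutations is flagged.
    """
    if config.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    ages, _, _, _ = aligned_covariates(expr, donors, smap)
    counts = np.zeros(config.n_permutations, dtype=int)
    for i in range(config.n_permutations):
        perm = rng.permutation(ages)
        gene_set, _ = call_aging_genes(
            expr,
            donors,
            smap,
            config,
            model_id=config.permutation_model,
            apply_filter=apply_filter,
            ages_override=perm,
        )
        counts[i] = len(gene_set)
    freq = int((counts >= observed_count).sum())
    return PermutationSummary(
        n_permutations=config.n_permutations,
        counts=counts,
        frequency_ge_observed=freq,
        mean_count=float(counts.mean()),
        observed_count=observed_count,
        exceeds_threshold=freq > 5,
    )


def subsample_power_curve(
    expr: ExpressionMatrix,
    donors: DonorTable,
    smap: TissueSampleMap,
    config: AnalysisConfig,
    sizes: Sequence[int],
    repeats: int,
    rng: Optional[np.random.Generator] = None,
    model_id: Optional[str] = None,
) -> pd.DataFrame:
    """Mean aging-gene count at increasing subsample sizes (without replacement)."""
    if rng is None:
        rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    model_id = model_id or config.permutation_model
    n = expr.n_samples
    if max(sizes) > n:
        raise ValueError("subsample size exceeds available samples")
    min_n = _min_distinct_samples(config)
    records = []
    for size in sizes:
        if size < min_n:
            logger.warning("subsample size %d below minimum fittable %d; skipped", size, min_n)
            continue
        counts = []
        for _ in range(repeats):
            idx = rng.choice(n, size=size, replace=False)
            cols = [expr.sample_ids[i] for i in sorted(idx)]
            sub = expr.subset_samples(cols)
            gene_set, _ = call_aging_genes(sub, donors, smap, config, model_id=model_id)
            counts.append(len(gene_set))
        records.append({"size": size, "mean_count": float(np.mean(counts))})
    return pd.DataFrame.from_records(records)


def select_model_by_reference_enrichment(
    expr: ExpressionMatrix,
    donors: DonorTable,
    smap: TissueSampleMap,
    reference: Sequence[str],
    background: Sequence[str],
    config: AnalysisConfig,
    model_ids: Sequence[str] = tuple(f"M{i}" for i in range(1, 10)),
) -> Tuple[str, pd.DataFrame]:
    """Score M1-M9 by over-representation of a curated reference gene list.

    Each model's called genes (with and without the low-expression filter)
    are tested one-tailed against ``reference`` on ``background``; the model
    with the smallest filtered p wins.
    """
    from .enrich import fisher_overlap

    background = set(background)
    reference = set(reference) & background
    records = []
    for mid in model_ids:
        gene_set_f, _ = call_aging_genes(expr, donors, smap, config, model_id=mid)
        gene_set_u, _ = call_aging_genes(
            expr, donors, smap, config, model_id=mid, apply_filter=False
        )
        row = {"model_id": mid}
        for label, gs in (("filtered", gene_set_f), ("unfiltered", gene_set_u)):
            called = set(gs.genes) & background
            if reference:
                p = fisher_overlap(
                    len(background), len(reference), len(called), len(called & reference)
                )
            else:
                p = 1.0
            row[f"n_aging_{label}"] = len(called)
            row[f"p_{label}"] = p
        records.append(row)
    table = pd.DataFrame.from_records(records).set_index("model_id")
    best = table["p_filtered"].idxmin()
    return str(best), table
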