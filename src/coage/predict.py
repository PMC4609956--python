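"""Supervised apparent age: elastic-net prediction with repeated cross-validation.

Samples are split into near-equal folds; each fold's ages are predicted by an
elastic net trained on the remaining folds, with penalty strength and L1/L2
mixing chosen by inner cross-validation on the training portion.  The whole
split is repeated and the per-sample mean across repeats is the predicted
age.  Co-aging on predicted ages mirrors the PC1-based co-aging contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV

from .containers import ExpressionMatrix, TissueSampleMap
from .coaging import CoagingMatrix, _safe_spearman

__all__ = ["PredictionResult", "repeated_cv_predict", "prediction_rmse", "predicted_age_coaging"]


@dataclass
class PredictionResult:
    tissue: str
    sample_ids: List[str]
    predicted_age: np.ndarray  # mean over repeats, years
    per_repeat_predictions: Optional[np.ndarray]  # repeats x samples
    rmse: float
    spearman_vs_age: float


def prediction_rmse(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Root mean squared error, in years."""
    predicted = np.asarray(predicted, float)
    actual = np.asarray(actual, float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    if predicted.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


def _fold_assignment(n: int, folds: int, rng: np.random.Generator) -> List[np.ndarray]:
    """Random near-equal split; remainder samples spread one per fold."""
    perm = rng.permutation(n)
    return [perm[f::folds] for f in range(folds)]


def repeated_cv_predict(
    expr: ExpressionMatrix,
    ages: np.ndarray,
    folds: int = 10,
    repeats: int = 100,
    seed: int = 0,
    l1_ratios: Sequence[float] = (0.1, 0.5, 0.9),
    n_alphas: int = 10,
    inner_cv: int = 5,
    keep_per_repeat: bool = False,
) -> PredictionResult:
    """Repeated k-fold out-of-sample elastic-net age prediction."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ages = np.asarray(ages, float)
    n = expr.n_samples
    if n < 2 * folds:
        raise ValueError(f"need at least {2 * folds} samples for {folds} folds")
    if np.std(ages) == 0:
        raise ValueError("constant ages")
    # canonical internal ordering by id so results do not depend on the
    # caller's gene/sample ordering
    sample_order = np.argsort(np.asarray(expr.sample_ids, dtype=object))
    gene_order = np.argsort(np.asarray(expr.gene_ids, dtype=object))
    X = expr.values[np.ix_(gene_order, sample_order)].T  # samples x genes
    ages_c = ages[sample_order]
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    preds_c = np.zeros((repeats, n))
    for r in range(repeats):
        for test_idx in _fold_assignment(n, folds, rng):
            train = np.setdiff1d(np.arange(n), test_idx)
            # standardize features on the training fold only
            mu = X[train].mean(axis=0)
            sd = X[train].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (X[train] - mu) / sd
            Xte = (X[test_idx] - mu) / sd
            model = ElasticNetCV(
                l1_ratio=list(l1_ratios),
                alphas=n_alphas,
                cv=inner_cv,
                max_iter=5000,
                tol=1e-3,
                random_state=0,
            )
            with warnings.catch_warnings():
                # the low-penalty end of the CV path may hit max_iter on
                # near-noiseless targets; harmless for prediction
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(Xtr, ages_c[train])
            preds_c[r, test_idx] = model.predict(Xte)
    preds = np.empty_like(preds_c)
    preds[:, sample_order] = preds_c
    mean_pred = preds.mean(axis=0)
    return PredictionResult(
        tissue=expr.tissue,
        sample_ids=expr.sample_ids,
        predicted_age=mean_pred,
        per_repeat_predictions=preds if keep_per_repeat else None,
        rmse=prediction_rmse(mean_pred, ages),
        spearman_vs_age=_safe_spearman(mean_pred, ages),
    )


def predicted_age_coaging(
    results: Dict[str, PredictionResult], smap: TissueSampleMap, min_shared: int = 3
) -> CoagingMatrix:
    """Spearman of mean predicted ages across donors shared by each tissue pair."""
    tissues = list(results)
    donor_series: Dict[str, pd.Series] = {}
    for t, res in results.items():
        donors = smap.donors_of(res.sample_ids)
        donor_series[t] = pd.Series(res.predicted_age, index=donors)
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
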