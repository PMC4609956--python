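"""Predict chronological age with a repeated cross-validated elastic net.

Every sample's age is predicted out-of-fold by an elastic net trained on the
other folds (penalties chosen by inner CV); the split is repeated and mean
predictions compared with the unsupervised PC1 apparent age.
"""

from coage import (
    CohortSpec,
    TissueSpec,
    apparent_age_pc1,
    generate_cohort,
    repeated_cv_predict,
)
from coage.containers import aligned_covariates

spec = CohortSpec(
    n_donors=150,
    n_genes=300,
    tissues=[TissueSpec("blood", 150, frac_aging_genes=1.0, fixed_effect_size=0.1,
                        batch_sd=2.5)],
    deviation_sd=0.0,
    seed=3,
)
matrices, donors, sample_map, _ = generate_cohort(spec)
ages, _, _, _ = aligned_covariates(matrices["blood"], donors, sample_map)

result = repeated_cv_predict(matrices["blood"], ages, folds=10, repeats=5, seed=3)
pc1 = apparent_age_pc1(matrices["blood"], ages)

print(f"elastic net RMSE: {result.rmse:.2f} years")
print(f"elastic net Spearman vs age: {result.spearman_vs_age:.3f}")
print(f"unsupervised PC1 Spearman vs age: {pc1.spearman_vs_age:.3f}")
print("the supervised predictor tracks age far more tightly than PC1 here:")
print("strong batch structure dominates the leading variance direction, so the")
print("unsupervised projection mixes batch with age while the elastic net does not.")
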