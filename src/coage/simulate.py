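"""Synthetic multi-tissue cohort generator with known ground truth.

The generator emulates the statistical structure the detection pipeline
assumes: donors aged 20-70 sampled by several tissues with partial overlap, a
latent per-tissue "biological age" whose cross-tissue correlation is
configurable, planted signed age effects on a subset of genes, sex /
genotype-PC / batch confounding, and log-normal baseline expression so the
low-expression filter has something to rank.

Expression is left real-valued (log-scale semantics, no clipping at zero) so
the linear-model assumptions of the detection stage hold exactly.  The model
for sample s of donor d in tissue t is

    Y_gs = beta_g + gamma_g * b_dt + delta_g * sex_d
           + sum_k mu_gk * geno_dk + sum_f lambda_gf * batch_fs + eps_gs

with b_dt = age_d + deviation_sd * z_dt and z_d ~ MVN(0, coaging_corr).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import (
    DonorTable,
    ExpressionMatrix,
    GeneSetCollection,
    HomologMap,
    TissueSampleMap,
)

__all__ = [
    "TissueSpec",
    "CohortSpec",
    "SyntheticTruth",
    "generate_cohort",
    "generate_reference_and_disease_sets",
    "generate_species_pair",
]


@dataclass
class TissueSpec:
    """Per-tissue sampling and effect-size settings."""

    name: str
    n_samples: int
    frac_aging_genes: float = 0.1
    effect_size_sd: float = 0.05  # expression units per year, sd of gamma ~ N(0, sd)
    fixed_effect_size: Optional[float] = None  # |gamma| fixed, random sign, if set
    noise_sd: float = 1.0
    n_batch_factors: int = 2
    batch_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.frac_aging_genes <= 1:
            raise ValueError("frac_aging_genes must be in [0,1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


@dataclass
class CohortSpec:
    """Full design of a synthetic cohort."""

    n_donors: int = 150
    n_genes: int = 1000
    tissues: Sequence[TissueSpec] = field(
        default_factory=lambda: [TissueSpec("tissue1", 100)]
    )
    age_range: Tuple[int, int] = (20, 70)
    coaging_corr: Optional[np.ndarray] = None  # tissue x tissue; identity if None
    deviation_sd: float = 10.0  # years
    sex_effect_sd: float = 0.3
    geno_effect_sd: float = 0.1
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = len(self.tissues)
        if self.coaging_corr is None:
            self.coaging_corr = np.eye(t)
        self.coaging_corr = np.asarray(self.coaging_corr, dtype=float)
        if self.coaging_corr.shape != (t, t):
            raise ValueError("coaging_corr shape must match number of tissues")
        if not np.allclose(self.coaging_corr, self.coaging_corr.T):
            raise ValueError("coaging_corr must be symmetric")
        if not np.allclose(np.diag(self.coaging_corr), 1.0):
            raise ValueError("coaging_corr must have unit diagonal")
        eigvals = np.linalg.eigvalsh(self.coaging_corr)
        if eigvals.min() < -1e-10:
            raise ValueError(
                f"coaging_corr is not positive semidefinite (min eigenvalue {eigvals.min():.3g})"
            )
        for ts in self.tissues:
            if ts.n_samples > self.n_donors:
                raise ValueError(
                    f"tissue {ts.name!r}: n_samples ({ts.n_samples}) exceeds n_donors ({self.n_donors})"
                )
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] <= 0:
            raise ValueError("age_range must be (min, max) with 0 < min < max")


@dataclass
class SyntheticTruth:
    """Ground truth recorded at generation time for parameter-recovery tests."""

    aging_genes: Dict[str, Dict[str, float]]  # tissue -> gene -> gamma
    biological_age: pd.DataFrame  # donors x tissues, years
    batch_assignments: Dict[str, Dict[str, int]]  # tissue -> sample -> batch
    reference_set: Optional[frozenset] = None
    planted_disease_sets: Optional[GeneSetCollection] = None
    design: dict = field(default_factory=dict)

    def aging_gene_union(self) -> frozenset:
        out: set = set()
        for d in self.aging_genes.values():
            out |= set(d)
        return frozenset(out)


def _stream(seed: int, label: str) -> np.random.Generator:
    """Deterministic sub-stream keyed by a label, stable under list reordering."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def generate_cohort(
    spec: CohortSpec,
    _aging_assignment: Optional[Dict[str, Dict[str, float]]] = None,
) -> Tuple[Dict[str, ExpressionMatrix], DonorTable, TissueSampleMap, SyntheticTruth]:
    """Draw one cohort from the generative model described in the module docstring.

    ``_aging_assignment`` optionally pins the aging-gene set and effects per
    tissue (used by :func:`generate_species_pair` to plant shared homologs).
    """
    n_t = len(spec.tissues)
    tissue_names = [t.name for t in spec.tissues]
    if len(set(tissue_names)) != n_t:
        raise ValueError("tissue names must be unique")

    donor_rng = _stream(spec.seed, "donors")
    donor_ids = [f"D{i:04d}" for i in range(spec.n_donors)]
    ages = donor_rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=spec.n_donors)
    sex = donor_rng.choice(["female", "male"], size=spec.n_donors)
    geno = donor_rng.normal(size=(spec.n_donors, 3))
    chol = np.linalg.cholesky(
        spec.coaging_corr + 1e-12 * np.eye(n_t)
    )
    z = donor_rng.normal(size=(spec.n_donors, n_t)) @ chol.T
    bio_age = ages[:, None] + spec.deviation_sd * z  # donors x tissues

    donors = DonorTable(
        pd.DataFrame(
            {
                "age": ages,
                "sex": sex,
                "geno_pc1": geno[:, 0],
                "geno_pc2": geno[:, 1],
                "geno_pc3": geno[:, 2],
            },
            index=pd.Index(donor_ids, name="donor_id"),
        )
    )

    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    matrices: Dict[str, ExpressionMatrix] = {}
    aging_truth: Dict[str, Dict[str, float]] = {}
    batch_truth: Dict[str, Dict[str, int]] = {}
    map_rows: List[Tuple[str, str, str]] = []

    for ti, ts in enumerate(spec.tissues):
        rng = _stream(spec.seed, f"tissue:{ts.name}")
        chosen = rng.choice(spec.n_donors, size=ts.n_samples, replace=False)
        chosen.sort()
        sample_ids = [f"{ts.name}-{donor_ids[d]}" for d in chosen]
        for s, d in zip(sample_ids, chosen):
            map_rows.append((s, donor_ids[d], ts.name))

        baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, size=spec.n_genes)
        if _aging_assignment is not None and ts.name in _aging_assignment:
            gammas_map = _aging_assignment[ts.name]
            gamma = np.array([gammas_map.get(g, 0.0) for g in gene_ids])
        else:
            n_aging = int(round(ts.frac_aging_genes * spec.n_genes))
            aging_idx = rng.choice(spec.n_genes, size=n_aging, replace=False)
            gamma = np.zeros(spec.n_genes)
            if ts.fixed_effect_size is not None:
                gamma[aging_idx] = ts.fixed_effect_size * rng.choice([-1.0, 1.0], size=n_aging)
            else:
                draws = rng.normal(0.0, ts.effect_size_sd, size=n_aging)
                # reject exact zeros so "aging gene" always means a real effect
                draws[draws == 0.0] = ts.effect_size_sd
                gamma[aging_idx] = draws
        delta = rng.normal(0.0, spec.sex_effect_sd, size=spec.n_genes)
        mu = rng.normal(0.0, spec.geno_effect_sd, size=(spec.n_genes, 3))
        lam = rng.normal(0.0, ts.batch_sd, size=(spec.n_genes, ts.n_batch_factors))
        batches = rng.integers(0, max(ts.n_batch_factors, 1), size=ts.n_samples)
        batch_ind = np.zeros((max(ts.n_batch_factors, 1), ts.n_samples))
        batch_ind[batches, np.arange(ts.n_samples)] = 1.0

        b = bio_age[chosen, ti]
        sex01 = (donors.data.loc[[donor_ids[d] for d in chosen], "sex"] == "male").to_numpy(float)
        geno_s = geno[chosen]

        Y = (
            baseline[:, None]
            + gamma[:, None] * b[None, :]
            + delta[:, None] * sex01[None, :]
            + mu @ geno_s.T
            + (lam @ batch_ind if ts.n_batch_factors > 0 else 0.0)
            + rng.normal(0.0, ts.noise_sd, size=(spec.n_genes, ts.n_samples))
        )
        matrices[ts.name] = ExpressionMatrix(
            ts.name, pd.DataFrame(Y, index=gene_ids, columns=sample_ids)
        )
        aging_truth[ts.name] = {
            g: float(gm) for g, gm in zip(gene_ids, gamma) if gm != 0.0
        }
        batch_truth[ts.name] = {s: int(bb) for s, bb in zip(sample_ids, batches)}

    smap = TissueSampleMap(
        pd.DataFrame(map_rows, columns=["sample_id", "donor_id", "tissue"]).set_index("sample_id")
    )
    truth = SyntheticTruth(
        aging_genes=aging_truth,
        biological_age=pd.DataFrame(bio_age, index=donor_ids, columns=tissue_names),
        batch_assignments=batch_truth,
        design={
            "seed": spec.seed,
            "n_donors": spec.n_donors,
            "n_genes": spec.n_genes,
            "deviation_sd": spec.deviation_sd,
            "age_range": list(spec.age_range),
            "coaging_corr": spec.coaging_corr.tolist(),
        },
    )
    return matrices, donors, smap, truth


def _weighted_sample_without_replacement(
    rng: np.random.Generator, items: List[str], weights: np.ndarray, size: int
) -> List[str]:
    w = np.asarray(weights, dtype=float)
    p = w / w.sum()
    idx = rng.choice(len(items), size=size, replace=False, p=p)
    return [items[i] for i in idx]


def generate_reference_and_disease_sets(
    truth: SyntheticTruth,
    n_sets: int,
    planted_enrichment: float,
    seed: int,
    universe: Optional[Sequence[str]] = None,
    reference_size: int = 100,
    set_size_range: Tuple[int, int] = (10, 40),
) -> GeneSetCollection:
    """Build a curated-reference analog plus disease sets, half enriched.

    Genes that are true aging genes (in any tissue) are given
    ``planted_enrichment``-fold odds of inclusion in the reference set and in
    the enriched half of the disease sets; the other half is drawn uniformly.
    """
    if planted_enrichment < 1:
        raise ValueError("planted_enrichment must be >= 1")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    aging = truth.aging_gene_union()
    if universe is None:
        genes = sorted(
            set().union(*[set(d) for d in truth.aging_genes.values()])
            | {f"G{i:05d}" for i in range(truth.design.get("n_genes", 0))}
        )
    else:
        genes = sorted(universe)
    if not genes:
        raise ValueError("empty gene universe")
    weights = np.array([planted_enrichment if g in aging else 1.0 for g in genes])

    ref = frozenset(
        _weighted_sample_without_replacement(rng, genes, weights, min(reference_size, len(genes)))
    )
    sets: Dict[str, frozenset] = {}
    design: Dict[str, bool] = {}
    for i in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        size = min(size, len(genes))
        enriched = i < n_sets // 2 + n_sets % 2
        w = weights if enriched else np.ones(len(genes))
        name = f"disease_{i:03d}"
        sets[name] = frozenset(_weighted_sample_without_replacement(rng, genes, w, size))
        design[name] = enriched
    collection = GeneSetCollection(dict(sets), provenance="synthetic disease sets")
    truth.reference_set = ref
    truth.planted_disease_sets = collection
    truth.design["disease_set_enriched"] = design
    truth.design["planted_enrichment"] = planted_enrichment
    return collection


def generate_species_pair(
    spec_a: CohortSpec,
    spec_b: CohortSpec,
    shared_frac: float,
    homolog_frac: float,
    seed: int,
) -> Tuple[tuple, tuple, HomologMap]:
    """Two cohorts linked by a homolog map with a planted fraction of shared aging genes.

    Species-B gene ids are prefixed ``B_``.  ``shared_frac`` of species-A aging
    genes whose homolog exists are forced to be aging (same-sign effect) in B;
    B's remaining aging genes are drawn independently to honour its own
    ``frac_aging_genes``.
    """
    if not 0 <= shared_frac <= 1 or not 0 <= homolog_frac <= 1:
        raise ValueError("shared_frac and homolog_frac must be in [0,1]")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)

    cohort_a = generate_cohort(spec_a)
    truth_a = cohort_a[3]
    genes_a = [f"G{i:05d}" for i in range(spec_a.n_genes)]
    genes_b = [f"B_G{i:05d}" for i in range(spec_b.n_genes)]

    n_map = int(round(homolog_frac * min(spec_a.n_genes, spec_b.n_genes)))
    map_a = rng.choice(spec_a.n_genes, size=n_map, replace=False)
    map_a.sort()
    map_b = rng.choice(spec_b.n_genes, size=n_map, replace=False)
    map_b.sort()
    pairs = [(genes_a[i], genes_b[j]) for i, j in zip(map_a, map_b)]
    hmap = HomologMap(pairs)
    a2b = hmap.a_to_b()

    assignment: Dict[str, Dict[str, float]] = {}
    for ts in spec_b.tissues:
        ts_a_name = spec_a.tissues[0].name
        gammas_a = truth_a.aging_genes.get(ts_a_name, {})
        forced: Dict[str, float] = {}
        mapped_aging = [g for g in gammas_a if g in a2b]
        for g in mapped_aging:
            if rng.random() < shared_frac:
                forced[a2b[g]] = gammas_a[g]
        n_target = int(round(ts.frac_aging_genes * spec_b.n_genes))
        pool = [g for g in genes_b if g not in forced]
        n_extra = max(0, n_target - len(forced))
        extra = rng.choice(len(pool), size=min(n_extra, len(pool)), replace=False)
        for i in extra:
            if ts.fixed_effect_size is not None:
                forced[pool[i]] = ts.fixed_effect_size * float(rng.choice([-1.0, 1.0]))
            else:
                g = float(rng.normal(0.0, ts.effect_size_sd))
                forced[pool[i]] = g if g != 0 else ts.effect_size_sd
        assignment[ts.name] = forced

    import copy

    spec_b2 = copy.deepcopy(spec_b)
    cohort_b = _generate_with_gene_prefix(spec_b2, assignment)
    return cohort_a, cohort_b, hmap


def _generate_with_gene_prefix(spec: CohortSpec, assignment: Dict[str, Dict[str, float]]):
    # assignment keys already use B_ ids; generate with plain ids pinned, then rename
    plain_assignment = {
        t: {g.removeprefix("B_"): v for g, v in d.items()} for t, d in assignment.items()
    }
    mats, donors, smap, truth = generate_cohort(spec, _aging_assignment=plain_assignment)
    renamed = {}
    for t, m in mats.items():
        df = m.data.copy()
        df.index = ["B_" + g for g in df.index]
        renamed[t] = ExpressionMatrix(t, df)
    truth.aging_genes = {
        t: {"B_" + g: v for g, v in d.items()} for t, d in truth.aging_genes.items()
    }
    return renamed, donors, smap, truth


def truth_to_json_dict(truth: SyntheticTruth) -> dict:
    """Serializable manifest of the planted ground truth."""
    return {
        "aging_genes": truth.aging_genes,
        "biological_age": {
            d: {t: float(truth.biological_age.at[d, t]) for t in truth.biological_age.columns}
            for d in truth.biological_age.index
        },
        "batch_assignments": truth.batch_assignments,
        "reference_set": sorted(truth.reference_set) if truth.reference_set else None,
        "design": truth.design,
    }
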