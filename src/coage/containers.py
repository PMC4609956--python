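"""Core data containers shared by every stage of the pipeline.

Expression is stored gene-by-sample, already library-normalized by whatever
upstream pipeline produced it; no internal re-normalization is performed and
the (possibly log) scale of the values is the caller's responsibility.  All
stages align by identifier, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DonorTable",
    "TissueSampleMap",
    "GeneSetCollection",
    "HomologMap",
    "AnalysisConfig",
]


@dataclass
class ExpressionMatrix:
    """Normalized expression for one tissue: genes in rows, samples in columns."""

    tissue: str
    data: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = set(gene_ids) - set(self.data.index)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)}")
        return ExpressionMatrix(self.tissue, self.data.loc[list(gene_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = set(sample_ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)}")
        return ExpressionMatrix(self.tissue, self.data[list(sample_ids)])


GENO_PC_COLUMNS = ("geno_pc1", "geno_pc2", "geno_pc3")


@dataclass
class DonorTable:
    """Donor-level covariates: age (years), sex, and the top genotype PCs."""

    data: pd.DataFrame  # index = donor id; columns age, sex, geno_pc1..3

    def __post_init__(self) -> None:
        required = {"age", "sex", *GENO_PC_COLUMNS}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"donor table missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate donor ids")
        if (self.data["age"] <= 0).any():
            raise ValueError("ages must be positive")
        bad_sex = set(self.data["sex"]) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"sex must be male/female, got {sorted(bad_sex)}")
        pcs = self.data[list(GENO_PC_COLUMNS)].to_numpy(dtype=float)
        if pcs.size and not np.all(np.isfinite(pcs)):
            raise ValueError("non-finite genotype PC")

    @property
    def donor_ids(self) -> List[str]:
        return list(self.data.index)

    def ages(self, donor_ids: Sequence[str]) -> np.ndarray:
        return self.data.loc[list(donor_ids), "age"].to_numpy(dtype=float)

    def sex_indicator(self, donor_ids: Sequence[str]) -> np.ndarray:
        """0/1 indicator, reference level female."""
        return (self.data.loc[list(donor_ids), "sex"] == "male").to_numpy(dtype=float)

    def genotype_pcs(self, donor_ids: Sequence[str], k: int = 3) -> np.ndarray:
        return self.data.loc[list(donor_ids), list(GENO_PC_COLUMNS[:k])].to_numpy(dtype=float)


@dataclass
class TissueSampleMap:
    """Maps each sample id to its (donor, tissue); at most one sample per pair."""

    data: pd.DataFrame  # index = sample id; columns donor_id, tissue

    def __post_init__(self) -> None:
        required = {"donor_id", "tissue"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"sample map missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        pair_dups = self.data.duplicated(subset=["donor_id", "tissue"])
        if pair_dups.any():
            raise ValueError(
                "more than one sample for donor/tissue pair(s): "
                f"{self.data.loc[pair_dups, ['donor_id', 'tissue']].to_records(index=False).tolist()}"
            )

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.index)

    def donors_of(self, sample_ids: Sequence[str]) -> List[str]:
        return self.data.loc[list(sample_ids), "donor_id"].tolist()

    def samples_for_tissue(self, tissue: str) -> List[str]:
        return list(self.data.index[self.data["tissue"] == tissue])

    def tissues(self) -> List[str]:
        return list(dict.fromkeys(self.data["tissue"]))


@dataclass
class GeneSetCollection:
    """Named gene sets (disease genes, curated aging references, ...)."""

    sets: Dict[str, frozenset]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set: {name!r}")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> List[str]:
        return list(self.sets)


@dataclass
class HomologMap:
    """One-to-one gene pairing between two species."""

    pairs: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("homolog map is not one-to-one")

    def a_to_b(self) -> Dict[str, str]:
        return dict(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AnalysisConfig:
    """Tunable thresholds for the detection / validation pipeline.

    Defaults mirror the study design: BH FDR 0.05, top 5 expression PCs and
    3 genotype PCs as candidate covariates, model M9, 100 bootstrap runs with
    support threshold 50, the 20%-of-bottom low-expression filter scored on
    the top-25% samples, and 1,000 age permutations.
    """

    fdr_alpha: float = 0.05
    n_expr_pcs: int = 5
    n_geno_pcs: int = 3
    correction_model: str = "M9"
    bootstrap_runs: int = 100
    bootstrap_support_min: int = 50
    bootstrap_strict: bool = False  # True: support must exceed the threshold
    bootstrap_recompute_pcs: bool = True
    low_expr_top_frac: float = 0.25
    low_expr_drop_frac: float = 0.20
    n_permutations: int = 1000
    permutation_model: str = "M8"
    en_folds: int = 10
    en_repeats: int = 100
    disease_fdr: float = 0.02
    min_set_size: int = 5
    cross_species_p: float = 0.001
    outlier_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_alpha", "low_expr_top_frac", "low_expr_drop_frac",
                     "disease_fdr", "cross_species_p", "outlier_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for name in ("n_expr_pcs", "n_geno_pcs", "bootstrap_runs", "n_permutations",
                     "en_folds", "en_repeats", "min_set_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("correction_model", "permutation_model"):
            v = getattr(self, name)
            if v not in {f"M{i}" for i in range(1, 10)}:
                raise ValueError(f"unknown correction model: {v!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def aligned_covariates(
    expr: ExpressionMatrix, donors: DonorTable, smap: TissueSampleMap
) -> tuple[np.ndarray, np.ndarray, np.ndarray, List[str]]:
    """Ages, sex indicator and genotype PCs aligned to the matrix's columns.

    Returns (ages, sex01, geno_pcs, donor_ids) in sample-column order.
    """
    donor_ids = smap.donors_of(expr.sample_ids)
    ages = donors.ages(donor_ids)
    sex = donors.sex_indicator(donor_ids)
    geno = donors.genotype_pcs(donor_ids)
    return ages, sex, geno, donor_ids
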