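"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices travel as TSV (first column ``gene_id``, remaining columns
sample ids) or GCT v1.2; donor metadata as a seven-column TSV; gene sets as
GMT; homolog maps as two-column TSV.  Round trips preserve values to full
precision.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Dict, List, Tuple

import pandas as pd

from .containers import (
    AnalysisConfig,
    DonorTable,
    ExpressionMatrix,
    GeneSetCollection,
    HomologMap,
    TissueSampleMap,
    GENO_PC_COLUMNS,
)

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "donor_id", "tissue", "age", "sex", *GENO_PC_COLUMNS]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def read_expression(path: str) -> pd.DataFrame:
    """Read a gene x sample table from TSV or GCT v1.2 (by extension)."""
    if str(path).lower().endswith(".gct"):
        return _read_gct(path)
    return _read_expression_tsv(path)


def _check_header_duplicates(header_fields, path):
    seen, dups = set(), []
    for f in header_fields:
        if f in seen:
            dups.append(f)
        seen.add(f)
    if dups:
        raise FormatError(f"{path}: duplicate sample ids {dups}")


def _read_expression_tsv(path: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_header_duplicates(header[1:], path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return _validate_expression_frame(df, path)


def _read_gct(path: str) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed GCT dimension line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        header_pos = fh.tell()
        header = fh.readline().rstrip("\n").split("\t")
        _check_header_duplicates([h for h in header[1:] if h != "Description"], path)
        fh.seek(header_pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if "Description" in df.columns:
        df = df.drop(columns=["Description"])
    if df.shape != (n_genes, n_samples):
        raise FormatError(
            f"{path}: header declares {n_genes}x{n_samples}, found {df.shape[0]}x{df.shape[1]}"
        )
    return _validate_expression_frame(df, path)


def _validate_expression_frame(df: pd.DataFrame, path: str) -> pd.DataFrame:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        gi, si = [(g, s) for g in df.index for s in df.columns if bad.at[g, s]][0]
        raise FormatError(f"{path}: non-numeric expression value at gene {gi!r}, sample {si!r}")
    if numeric.isna().to_numpy().any():
        raise FormatError(f"{path}: missing expression values")
    numeric = numeric.astype(float)
    numeric.index = numeric.index.astype(str)
    numeric.index.name = "gene_id"
    numeric.columns = numeric.columns.astype(str)
    numeric.columns.name = None
    return numeric


def write_expression_tsv(expr: ExpressionMatrix, path: str) -> None:
    out = expr.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def write_gct(expr: ExpressionMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
        out = expr.data.copy()
        out.insert(0, "Description", "na")
        out.index.name = "Name"
        out.to_csv(fh, sep="\t", float_format="%.17g")


def read_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    return meta


def write_metadata(donors: DonorTable, smap: TissueSampleMap, path: str) -> None:
    rows = smap.data.reset_index()
    rows.columns = ["sample_id", "donor_id", "tissue"]
    merged = rows.merge(
        donors.data.reset_index().rename(columns={"index": "donor_id"}),
        on="donor_id",
        how="left",
    )
    merged[METADATA_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_dataset(
    expression_path: str, metadata_path: str
) -> Tuple[Dict[str, ExpressionMatrix], DonorTable, TissueSampleMap]:
    """Load one expression table plus metadata and split it into per-tissue matrices.

    Sample columns are assigned to tissues via the metadata's ``tissue`` column;
    within each tissue, samples keep metadata file order (the canonical order).
    """
    frame = read_expression(expression_path)
    meta = read_metadata(metadata_path)

    expr_samples = set(frame.columns)
    meta_samples = set(meta["sample_id"])
    missing = sorted(expr_samples - meta_samples)
    if missing:
        raise FormatError(f"expression samples missing from metadata: {missing}")
    extra = sorted(meta_samples - expr_samples)
    if extra:
        raise FormatError(f"metadata samples missing from expression: {extra}")

    donor_rows = meta.drop_duplicates(subset="donor_id").set_index("donor_id")
    inconsistent = (
        meta.groupby("donor_id")[["age", "sex", *GENO_PC_COLUMNS]].nunique() > 1
    )
    if inconsistent.to_numpy().any():
        bad = inconsistent.index[inconsistent.any(axis=1)].tolist()
        raise FormatError(f"inconsistent donor covariates for donors: {bad}")
    donors = DonorTable(donor_rows[["age", "sex", *GENO_PC_COLUMNS]])
    smap = TissueSampleMap(meta.set_index("sample_id")[["donor_id", "tissue"]])

    tissues: Dict[str, ExpressionMatrix] = {}
    for tissue in smap.tissues():
        cols = [s for s in meta["sample_id"] if smap.data.at[s, "tissue"] == tissue]
        tissues[tissue] = ExpressionMatrix(tissue, frame[cols])
    return tissues, donors, smap


def read_gene_sets(gmt_path: str, min_size: int = 1) -> GeneSetCollection:
    """Read a GMT file, dropping sets smaller than ``min_size`` after de-duplication."""
    sets: Dict[str, frozenset] = {}
    n_lines = 0
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{gmt_path}:{lineno}: GMT line has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{gmt_path}: duplicate set name {name!r}")
            members = frozenset(m for m in parts[2:] if m)
            if len(members) >= min_size and members:
                sets[name] = members
    if n_lines == 0:
        raise FormatError(f"{gmt_path}: empty GMT file")
    return GeneSetCollection(sets, provenance=os.path.basename(str(gmt_path)))


def write_gene_sets(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, collection.provenance or "na", *members]) + "\n")


def read_homolog_map(tsv_path: str) -> HomologMap:
    """Two-column TSV of gene pairs; pairs violating one-to-one are dropped."""
    with open(tsv_path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        raise FormatError(f"{tsv_path}: empty homolog file")
    if lines[0].split("\t")[:2] == ["species_a", "species_b"]:
        lines = lines[1:]
    pairs: List[Tuple[str, str]] = []
    for lineno, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{tsv_path}:{lineno}: expected 2 columns")
        pairs.append((parts[0], parts[1]))
    from collections import Counter

    a_counts = Counter(a for a, _ in pairs)
    b_counts = Counter(b for _, b in pairs)
    kept = [(a, b) for a, b in pairs if a_counts[a] == 1 and b_counts[b] == 1]
    dropped = len(pairs) - len(kept)
    if dropped:
        logger.warning("dropped %d homolog pairs violating one-to-one mapping", dropped)
    return HomologMap(kept)


def write_run_summary(path: str, config: AnalysisConfig, extra: dict | None = None) -> None:
    import numpy, pandas, scipy, sklearn

    summary = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "expression_scale": "as supplied by caller (no internal re-normalization)",
    }
    if extra:
        summary.update(extra)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
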