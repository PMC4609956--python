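"""One-tail Fisher over-representation tests and their three applications.

``fisher_overlap`` is the upper-tail hypergeometric probability
P(X >= overlap) of seeing at least the observed intersection when one set is
drawn uniformly from the universe.  On top of it sit: a disease-gene scan of
per-tissue up/down aging signatures, a cross-species homolog overlap test,
and a cross-study signature overlap test.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .aging import AgingGeneSet, bh_adjust
from .containers import GeneSetCollection, HomologMap

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_overlap",
    "disease_enrichment_scan",
    "cross_species_overlap",
    "cross_study_overlap",
]


def fisher_overlap(universe_size: int, size_a: int, size_b: int, overlap: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap) for the intersection of two sets.

    ``size_a`` genes are marked in a universe of ``universe_size``; ``size_b``
    are drawn without replacement; X counts marked draws.  Equivalent to the
    one-tail (over-representation) Fisher exact test on the 2x2 table.
    """
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    if size_a > universe_size or size_b > universe_size:
        raise ValueError("set size exceeds universe size")
    if overlap > min(size_a, size_b):
        raise ValueError(f"overlap {overlap} exceeds min(set sizes) {min(size_a, size_b)}")
    if size_a + size_b - overlap > universe_size:
        raise ValueError("sets cannot fit in the universe with the given overlap")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, size_a, size_b))


def disease_enrichment_scan(
    signatures: Dict[str, AgingGeneSet],
    sets: GeneSetCollection,
    universe: Dict[str, Sequence[str]],
    top_k: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every gene set against every tissue's up/down signature.

    ``universe`` maps tissue -> background gene ids (the genes tested in that
    tissue); signatures and sets are intersected with it before testing.
    Per tissue/direction the ``top_k`` smallest-p sets are selected; the
    union of selections forms the display matrix and ``normalized_score`` is
    each -log10 p divided by the display maximum.
    """
    records = []
    for tissue, sig in signatures.items():
        uni = set(universe[tissue])
        for direction, genes in (("up", sig.up), ("down", sig.down)):
            sig_genes = set(genes) & uni
            if not sig_genes:
                logger.warning("empty %s signature for %s; all p = 1", direction, tissue)
            for name in sets.names():
                members = set(sets.sets[name]) & uni
                if not members or not sig_genes:
                    p = 1.0
                    ov = 0
                else:
                    ov = len(members & sig_genes)
                    p = fisher_overlap(len(uni), len(members), len(sig_genes), ov)
                records.append(
                    {
                        "tissue": tissue,
                        "direction": direction,
                        "set_name": name,
                        "overlap": ov,
                        "set_size": len(members),
                        "signature_size": len(sig_genes),
                        "universe_size": len(uni),
                        "p_value": p,
                        "neg_log10_p": -np.log10(max(p, np.finfo(float).tiny)),
                    }
                )
    out = pd.DataFrame.from_records(records)
    if out.empty:
        out["fdr"] = []
        out["displayed"] = []
        out["normalized_score"] = []
        return out
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    displayed_sets: Set[str] = set()
    for (tissue, direction), grp in out.groupby(["tissue", "direction"]):
        top = grp.nsmallest(top_k, "p_value", keep="first")
        displayed_sets |= set(top["set_name"])
    out["displayed"] = out["set_name"].isin(displayed_sets)
    disp = out.loc[out["displayed"], "neg_log10_p"]
    max_score = float(disp.max()) if len(disp) and disp.max() > 0 else 1.0
    out["normalized_score"] = (out["neg_log10_p"] / max_score).clip(0, 1)
    out["significant"] = out["p_value"] < alpha
    return out


def cross_species_overlap(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    homolog_map: HomologMap,
    p_threshold: float = 0.001,
) -> Tuple[List[Tuple[str, str]], float, dict]:
    """Overlap of aging genes between two species across a homolog map.

    The universe is the set of homolog pairs with regression results in both
    species; species-wise aging calls use the raw per-gene p-value threshold
    (not FDR).  Returns (common pairs, one-tail Fisher p, report).
    """
    pairs = [
        (a, b)
        for a, b in homolog_map.pairs
        if a in results_a.index and b in results_b.index
    ]
    if not pairs:
        raise ValueError("empty homolog universe")
    aging_a = {a for a, _ in pairs if results_a.at[a, "p_value"] < p_threshold}
    aging_b = {b for _, b in pairs if results_b.at[b, "p_value"] < p_threshold}
    common = [(a, b) for a, b in pairs if a in aging_a and b in aging_b]
    p = fisher_overlap(len(pairs), len(aging_a), len(aging_b), len(common))
    report = {
        "universe_size": len(pairs),
        "n_aging_a": len(aging_a),
        "n_aging_b": len(aging_b),
        "n_common": len(common),
        "p_threshold": p_threshold,
    }
    return common, p, report


def cross_study_overlap(
    sig_a: AgingGeneSet, sig_b: AgingGeneSet, shared_universe: Sequence[str]
) -> Tuple[List[str], float]:
    """Fisher overlap of two studies' signatures on a shared gene universe."""
    uni = set(shared_universe)
    if not uni:
        raise ValueError("empty shared universe")
    a = set(sig_a.genes) & uni
    b = set(sig_b.genes) & uni
    common = sorted(a & b)
    p = fisher_overlap(len(uni), len(a), len(b), len(common))
    return common, p
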