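"""Cell-type-specific per-gene variant sets from ABC enhancer-gene predictions.

Activity-by-Contact (ABC) tables link cis-regulatory elements (enhancers and
promoters) to the genes they are predicted to regulate in a given cell type.
A gene's rare-variant test set is the union of variants falling inside any of
its linked elements with an ABC score at or above the threshold (default
0.02). Because one element can regulate several genes, a single variant may
belong to several gene sets.

Intervals are half-open 0-based internally; variant positions arrive 1-based
(VCF) and are converted at the point-containment check. Indels are tested by
their start position only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import GenotypeBlock

logger = logging.getLogger(__name__)

__all__ = ["CreRecord", "GeneRegionSet", "read_cre_table", "build_gene_sets", "overlap_report"]


@dataclass
class CreRecord:
    """One cis-regulatory element linked to a target gene in one cell type."""

    contig: str
    start: int  # 0-based, half-open
    end: int
    element_class: str  # "enhancer" | "promoter"
    target_gene: str
    cell_type: str
    abc_score: float

    def __post_init__(self) -> None:
        if self.abc_score < 0:
            raise ValueError("ABC score must be nonnegative")


@dataclass
class GeneRegionSet:
    """A gene's qualifying CRE intervals and the variants falling in them."""

    gene: str
    cell_type: str
    intervals: list[CreRecord] = field(default_factory=list)
    variant_ids: list[str] = field(default_factory=list)
    variant_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _norm_contig(c: str, strip_chr: bool = True) -> str:
    return c[3:] if strip_chr and c.lower().startswith("chr") else c


def read_cre_table(path: str, strip_chr: bool = True) -> list[CreRecord]:
    """Read an ABC-style TSV (chr, start, end, class, TargetGene, CellType, ABC.Score).

    Records with ``end <= start`` are rejected with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {"chr": "contig", "class": "element_class", "TargetGene": "target_gene",
              "CellType": "cell_type", "ABC.Score": "abc_score"}
    df = df.rename(columns=rename)
    records: list[CreRecord] = []
    for row in df.itertuples(index=False):
        if row.end <= row.start:
            warnings.warn(
                f"rejected CRE with end <= start: {row.contig}:{row.start}-{row.end}"
            )
            continue
        records.append(
            CreRecord(
                _norm_contig(str(row.contig), strip_chr),
                int(row.start),
                int(row.end),
                str(row.element_class),
                str(row.target_gene),
                str(row.cell_type),
                float(row.abc_score),
            )
        )
    return records


def build_gene_sets(
    cres: list[CreRecord],
    block: GenotypeBlock,
    cell_type: str,
    abc_min: float = 0.02,
    strip_chr: bool = True,
) -> dict[str, GeneRegionSet]:
    """Map each gene to the block variants inside its qualifying CREs.

    Only CREs of ``cell_type`` with ``abc_score >= abc_min`` contribute. A
    variant inside CREs of k genes is assigned to all k gene sets. Genes with
    zero qualifying variants are omitted. Both enhancers and promoters are
    included; the element class is carried for reporting only.
    """
    contigs = np.array([_norm_contig(c, strip_chr) for c in block.contigs])
    pos0 = block.positions - 1  # 1-based VCF POS -> 0-based point
    out: dict[str, GeneRegionSet] = {}
    for cre in cres:
        if cre.cell_type != cell_type or cre.abc_score < abc_min:
            continue
        if cre.end <= cre.start:
            warnings.warn(f"rejected CRE with end <= start for gene {cre.target_gene}")
            continue
        grs = out.setdefault(cre.target_gene, GeneRegionSet(cre.target_gene, cell_type))
        grs.intervals.append(cre)
        hit = (contigs == cre.contig) & (pos0 >= cre.start) & (pos0 < cre.end)
        for i in np.flatnonzero(hit):
            if block.variant_ids[i] not in grs.variant_ids:
                grs.variant_ids.append(block.variant_ids[i])
    result = {}
    for gene, grs in out.items():
        if not grs.variant_ids:
            continue
        idx = {v: i for i, v in enumerate(block.variant_ids)}
        grs.variant_indices = np.array([idx[v] for v in grs.variant_ids], dtype=int)
        result[gene] = grs
    logger.info(
        "build_gene_sets[%s]: %d genes with >=1 variant (ABC >= %g)",
        cell_type, len(result), abc_min,
    )
    return result


def overlap_report(gene_sets_by_cell_type: dict[str, dict[str, GeneRegionSet]]) -> pd.DataFrame:
    """Upset-style exclusive variant counts per nonempty cell-type combination.

    Each variant in the union is counted exactly once, under the exact set of
    cell types whose gene sets contain it, so the counts sum to the union size.
    """
    if not gene_sets_by_cell_type:
        raise ValueError("at least one cell type required")
    per_ct: dict[str, set[str]] = {}
    for ct, gsets in gene_sets_by_cell_type.items():
        per_ct[ct] = set().union(*(g.variant_ids for g in gsets.values())) if gsets else set()
    cts = sorted(per_ct)
    rows = []
    for r in range(1, len(cts) + 1):
        for combo in combinations(cts, r):
            inside = set.intersection(*(per_ct[c] for c in combo))
            outside = set().union(*(per_ct[c] for c in cts if c not in combo), set())
            exclusive = inside - outside
            if exclusive:
                rows.append({"cell_types": "+".join(combo), "n_cell_types": r,
                             "n_variants": len(exclusive)})
    return pd.DataFrame(rows, columns=["cell_types", "n_cell_types", "n_variants"])


def export_bed6(gene_sets: dict[str, GeneRegionSet], path: str) -> None:
    """Write qualifying CRE intervals as BED6 (name = gene, score = ABC x 1000)."""
    rows = []
    for grs in gene_sets.values():
        for cre in grs.intervals:
            rows.append(
                (cre.contig, cre.start, cre.end, grs.gene,
                 int(round(min(cre.abc_score, 1.0) * 1000)), ".")
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
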