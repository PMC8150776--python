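"""Cross-comparison gene sets and methylome-transcriptome intersection.

A gene enters the regulatory set of a comparison when a supporting DMR
overlaps its regulatory union: the 2 kb flanks plus the first/last 400 bp of
the gene body (after the start codon / before the stop codon).  Shared and
comparison-specific methylated/de-methylated sets are simple set partitions;
DMGs are finally intersected with an externally computed differential
expression table.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from mcseed.egb_annotation import (
    GeneModel,
    GeneRegionCall,
    STATUS_DEMETHYLATED,
    STATUS_METHYLATED,
)
from mcseed.errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryGeneSet:
    """Genes methylated (or de-methylated) over their regulatory union."""

    comparison: str
    status: str  # methylated | de-methylated
    gene_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class DEGRecord:
    """One differentially expressed gene from an external DE analysis."""

    gene_id: str
    log_fold_change: float
    deg_status: str  # up | down
    fdr: float

    def __post_init__(self) -> None:
        expected = "up" if self.log_fold_change > 0 else "down"
        if self.deg_status != expected:
            raise FormatError(
                f"gene {self.gene_id}: deg_status {self.deg_status!r} "
                f"inconsistent with logFC {self.log_fold_change}"
            )


@dataclass
class DMGxDEGRecord:
    """A gene both differentially methylated and differentially expressed."""

    gene_id: str
    annotations: list[tuple[str, str, str]]  # (context, region, meth status)
    deg_status: str
    log_fold_change: float
    concordance: str


def _regulatory_union(
    g: GeneModel, flank: int = 2000, core: int = 400
) -> list[tuple[int, int]]:
    """Genomic intervals of the regulatory union for one gene.

    Flanks plus the ``core`` bp of gene body adjacent to each codon anchor;
    cores are clipped to the gene body (short genes: the whole body).
    """
    up_iv = (
        (max(0, g.start - flank), g.start)
        if g.strand == "+"
        else (g.end, g.end + flank)
    )
    down_iv = (
        (g.end, g.end + flank) if g.strand == "+" else (max(0, g.start - flank), g.start)
    )
    head = (g.start, min(g.end, g.start + core))  # genomic-left core
    tail = (max(g.start, g.end - core), g.end)  # genomic-right core
    # strand does not matter for the core pair as a union: it is symmetric
    return [up_iv, head, tail, down_iv]


def regulatory_gene_set(
    calls: Sequence[GeneRegionCall],
    genes: Sequence[GeneModel],
    flank: int = 2000,
    core: int = 400,
    comparison: str = "",
) -> tuple[RegulatoryGeneSet, RegulatoryGeneSet]:
    """Build the (methylated, de-methylated) regulatory gene sets.

    A gene qualifies when one of its supporting DMRs overlaps the regulatory
    union; its status is the single direction of the qualifying DMRs, and
    genes with both directions over the union are excluded.
    """
    gene_index = {g.gene_id: g for g in genes}
    directions: dict[str, set[str]] = defaultdict(set)
    for call in calls:
        g = gene_index.get(call.gene_id)
        if g is None:
            raise ConfigurationError(f"call references unknown gene {call.gene_id!r}")
        union = _regulatory_union(g, flank=flank, core=core)
        for dmr in call.supporting_dmrs:
            if dmr.chrom != g.chrom:
                continue
            if any(dmr.overlaps(s, e) for s, e in union):
                directions[call.gene_id].add(dmr.direction)
    meth, demeth = set(), set()
    for gene_id, dirs in directions.items():
        if dirs == {STATUS_METHYLATED}:
            meth.add(gene_id)
        elif dirs == {STATUS_DEMETHYLATED}:
            demeth.add(gene_id)
        # both directions over the union: excluded
    return (
        RegulatoryGeneSet(comparison, STATUS_METHYLATED, frozenset(meth)),
        RegulatoryGeneSet(comparison, STATUS_DEMETHYLATED, frozenset(demeth)),
    )


def venn_sets(
    set_a: RegulatoryGeneSet, set_b: RegulatoryGeneSet
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Partition two same-status gene sets into (shared, A-specific, B-specific)."""
    if set_a.status != set_b.status:
        raise ConfigurationError(
            f"status mismatch: {set_a.status!r} vs {set_b.status!r}"
        )
    shared = set_a.gene_ids & set_b.gene_ids
    a_only = set_a.gene_ids - set_b.gene_ids
    b_only = set_b.gene_ids - set_a.gene_ids
    assert shared | a_only | b_only == set_a.gene_ids | set_b.gene_ids
    assert not (shared & a_only or shared & b_only or a_only & b_only)
    return frozenset(shared), frozenset(a_only), frozenset(b_only)


def read_deg_table(path) -> list[DEGRecord]:
    """Read a DE table TSV with columns gene_id, logFC, FDR."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "logFC", "FDR"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"DE table missing columns: {sorted(missing)}")
    return [
        DEGRecord(
            gene_id=str(row.gene_id),
            log_fold_change=float(row.logFC),
            deg_status="up" if row.logFC > 0 else "down",
            fdr=float(row.FDR),
        )
        for row in df.itertuples()
    ]


def cross_dmg_deg(
    dmg_calls: Sequence[GeneRegionCall],
    deg_table: Sequence[DEGRecord],
) -> list[DMGxDEGRecord]:
    """Inner join of differentially methylated and differentially expressed genes.

    Each shared gene is reported once, with all its supporting
    (context, region, status) annotations and a concordance note such as
    "6mA gene_body methylated + downregulated".
    """
    deg_index = {d.gene_id: d for d in deg_table}
    ann: dict[str, list[tuple[str, str, str]]] = defaultdict(list)
    for call in dmg_calls:
        if call.status not in (STATUS_METHYLATED, STATUS_DEMETHYLATED):
            continue
        ann[call.gene_id].append((call.context, call.region, call.status))
    shared = sorted(set(ann) & set(deg_index))
    if not shared:
        logger.info("DMG x DEG join is empty")
    out = []
    for gene_id in shared:
        deg = deg_index[gene_id]
        notes = "; ".join(
            f"{ctx} {region} {status} + {deg.deg_status}regulated"
            for ctx, region, status in ann[gene_id]
        )
        out.append(
            DMGxDEGRecord(
                gene_id=gene_id,
                annotations=list(ann[gene_id]),
                deg_status=deg.deg_status,
                log_fold_change=deg.log_fold_change,
                concordance=notes,
            )
        )
    return out


def write_venn_tsv(
    shared: frozenset[str], a_only: frozenset[str], b_only: frozenset[str], path
) -> None:
    rows = (
        [("shared", g) for g in sorted(shared)]
        + [("a_specific", g) for g in sorted(a_only)]
        + [("b_specific", g) for g in sorted(b_only)]
    )
    pd.DataFrame(rows, columns=["partition", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_dmg_deg_tsv(records: Sequence[DMGxDEGRecord], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "deg_status": [r.deg_status for r in records],
            "logFC": [r.log_fold_change for r in records],
            "annotations": [
                "; ".join(f"{c}:{reg}:{s}" for c, reg, s in r.annotations)
                for r in records
            ],
            "concordance": [r.concordance for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
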