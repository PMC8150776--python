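"""Extended gene bodies (EGBs): region disaggregation, DMR assignment,
per-gene-region methylation calls, summary tables and metagene profiles.

An EGB is a gene body plus 2 kb of flank on each side.  ``upstream`` and
``downstream`` are strand-relative (5' and 3' of transcription).  A gene
region is called ``methylated`` or ``de-methylated`` when every overlapping
DMR agrees in direction; regions hit by both directions in one comparison are
``ambiguous`` and excluded from downstream gene sets.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd

from mcseed.dmr_calling import DMR
from mcseed.errors import FormatError
from mcseed.locus_matrix import CONTEXTS

logger = logging.getLogger(__name__)

REGION_UPSTREAM = "upstream"
REGION_GENE_BODY = "gene_body"
REGION_DOWNSTREAM = "downstream"
REGIONS = (REGION_UPSTREAM, REGION_GENE_BODY, REGION_DOWNSTREAM)

STATUS_METHYLATED = "methylated"
STATUS_DEMETHYLATED = "de-methylated"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_NONE = "none"

CYTOSINE_CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class GeneModel:
    """A gene as 0-based half-open genomic span with exon structure.

    When a gene has several transcripts the longest one defines the span and
    exons used here.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    utrs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.start >= self.end:
            raise FormatError(f"gene {self.gene_id}: empty span")

    @property
    def atg_anchor(self) -> int:
        """Genomic coordinate of the transcription-direction start (ATG proxy)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def stop_anchor(self) -> int:
        """Genomic coordinate of the transcription-direction end (stop proxy)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class EGBRegion:
    """One of the three EGB regions of a gene, as a genomic interval."""

    gene_id: str
    region: str  # upstream | gene_body | downstream
    chrom: str
    start: int
    end: int

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class GeneRegionCall:
    """Methylation status of one gene region in one context/comparison."""

    gene_id: str
    region: str
    context: str
    comparison: str
    status: str
    supporting_dmrs: list[DMR] = field(default_factory=list)


def load_gene_models(path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon, UTRs optional).

    Coordinates are converted to 0-based half-open.  Genes without a strand
    are skipped with a warning; for multi-transcript genes the longest
    transcript wins.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"malformed GFF3 {path}: {exc}") from exc
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            warnings.warn(
                f"gene {gene.id} has no strand; skipped", stacklevel=2
            )
            continue
        transcripts = list(db.children(gene, featuretype="mRNA"))
        if transcripts:
            best = max(transcripts, key=lambda t: t.end - t.start)
            start0, end0 = best.start - 1, best.end
            exon_parent = best
        else:
            start0, end0 = gene.start - 1, gene.end
            exon_parent = gene
        exons = tuple(
            sorted(
                (e.start - 1, e.end)
                for e in db.children(exon_parent, featuretype="exon")
            )
        )
        utrs = tuple(
            sorted(
                (u.start - 1, u.end)
                for u in db.children(
                    exon_parent,
                    featuretype=("five_prime_UTR", "three_prime_UTR"),
                )
            )
        )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=start0,
                end=end0,
                exons=exons,
                utrs=utrs,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def disaggregate_egb(
    g: GeneModel, flank: int = 2000, chrom_length: int | None = None
) -> tuple[EGBRegion, EGBRegion, EGBRegion]:
    """Split a gene's EGB into (upstream, gene_body, downstream) intervals.

    Upstream is the ``flank`` bp 5' of the transcription start on the coding
    strand; flanks are clipped to [0, chrom_length).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    left = (max(0, g.start - flank), g.start)
    right_end = g.end + flank if chrom_length is None else min(g.end + flank, chrom_length)
    right = (g.end, right_end)
    if g.strand == "+":
        up, down = left, right
    else:
        up, down = right, left
    mk = lambda region, iv: EGBRegion(g.gene_id, region, g.chrom, iv[0], iv[1])
    return (
        mk(REGION_UPSTREAM, up),
        mk(REGION_GENE_BODY, (g.start, g.end)),
        mk(REGION_DOWNSTREAM, down),
    )


def build_egb_regions(
    genes: Sequence[GeneModel],
    flank: int = 2000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[EGBRegion]:
    regions: list[EGBRegion] = []
    for g in genes:
        cl = chrom_lengths.get(g.chrom) if chrom_lengths else None
        regions.extend(disaggregate_egb(g, flank=flank, chrom_length=cl))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def assign_dmrs_to_regions(
    dmrs: Sequence[DMR], regions: Sequence[EGBRegion]
) -> list[tuple[DMR, EGBRegion]]:
    """All (DMR, region) half-open interval overlaps, each emitted once.

    A DMR may hit several regions and several genes; zero-length overlaps are
    not overlaps.
    """
    by_chrom: dict[str, list[EGBRegion]] = defaultdict(list)
    for reg in regions:
        if reg.start < reg.end:  # fully clipped flanks are empty
            by_chrom[reg.chrom].append(reg)
    for chrom_regions in by_chrom.values():
        chrom_regions.sort(key=lambda r: (r.start, r.end))
    out: list[tuple[DMR, EGBRegion]] = []
    for dmr in dmrs:
        chrom_regions = by_chrom.get(dmr.chrom, [])
        starts = [r.start for r in chrom_regions]
        # regions starting at/after dmr.end cannot overlap; walk back is not
        # bounded in general, so scan all earlier regions (region counts per
        # chromosome are modest here)
        hi = bisect_left(starts, dmr.end)
        for reg in chrom_regions[:hi]:
            if reg.end > dmr.start:
                out.append((dmr, reg))
    return out


def classify_gene_regions(
    overlaps: Sequence[tuple[DMR, EGBRegion]],
    context: str | None = None,
    comparison: str = "",
) -> list[GeneRegionCall]:
    """Call each overlapped (gene, region) by the direction of its DMRs.

    All overlaps must come from a single context/comparison; mixed-direction
    regions are ``ambiguous`` (the contradictory-pattern filter).  Regions
    with no overlap do not appear (status ``none`` is implicit).
    """
    grouped: dict[tuple[str, str], list[DMR]] = defaultdict(list)
    for dmr, reg in overlaps:
        grouped[(reg.gene_id, reg.region)].append(dmr)
    if context is None:
        ctxs = {d.context for d, _ in overlaps}
        if len(ctxs) > 1:
            raise ValueError(f"mixed contexts in overlaps: {sorted(ctxs)}")
        context = next(iter(ctxs)) if ctxs else ""
    calls = []
    for (gene_id, region), hit_dmrs in sorted(grouped.items()):
        directions = {d.direction for d in hit_dmrs}
        if directions == {STATUS_METHYLATED}:
            status = STATUS_METHYLATED
        elif directions == {STATUS_DEMETHYLATED}:
            status = STATUS_DEMETHYLATED
        else:
            status = STATUS_AMBIGUOUS
        calls.append(
            GeneRegionCall(
                gene_id=gene_id,
                region=region,
                context=context,
                comparison=comparison,
                status=status,
                supporting_dmrs=list(hit_dmrs),
            )
        )
    return calls


@dataclass
class RegionSummary:
    """Per-context DMR totals and per (context, region, status) gene-region counts.

    The same aggregation path serves pipeline output and externally supplied
    count tables (``from_counts``), so headline totals are always produced by
    one code path.
    """

    dmr_counts: dict[str, int]
    region_status_counts: dict[tuple[str, str, str], int]
    comparison: str = ""

    @classmethod
    def from_calls(
        cls,
        calls: Sequence[GeneRegionCall],
        dmrs_per_context: dict[str, Sequence[DMR]] | None = None,
        comparison: str = "",
    ) -> "RegionSummary":
        region_status: dict[tuple[str, str, str], int] = defaultdict(int)
        for c in calls:
            region_status[(c.context, c.region, c.status)] += 1
        dmr_counts = {
            ctx: len(ds) for ctx, ds in (dmrs_per_context or {}).items()
        }
        return cls(
            dmr_counts=dmr_counts,
            region_status_counts=dict(region_status),
            comparison=comparison,
        )

    @classmethod
    def from_counts(
        cls,
        dmr_counts: dict[str, int],
        region_status_counts: dict[tuple[str, str, str], int] | None = None,
        comparison: str = "",
    ) -> "RegionSummary":
        return cls(
            dmr_counts=dict(dmr_counts),
            region_status_counts=dict(region_status_counts or {}),
            comparison=comparison,
        )

    def total_dmrs(self, contexts: Iterable[str] | None = None) -> int:
        contexts = list(contexts) if contexts is not None else list(self.dmr_counts)
        return sum(self.dmr_counts.get(c, 0) for c in contexts)

    def cytosine_dmr_total(self) -> int:
        return self.total_dmrs(CYTOSINE_CONTEXTS)

    def region_count(self, context: str, region: str, status: str) -> int:
        return self.region_status_counts.get((context, region, status), 0)

    def region_overlap_total(
        self, region: str, contexts: Iterable[str] = CYTOSINE_CONTEXTS
    ) -> int:
        """Gene regions overlapped at least once: Meth + De-meth over contexts."""
        return sum(
            self.region_count(c, region, s)
            for c in contexts
            for s in (STATUS_METHYLATED, STATUS_DEMETHYLATED)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ctx in CONTEXTS:
            row: dict[str, object] = {
                "context": ctx,
                "dmrs": self.dmr_counts.get(ctx, 0),
            }
            for region in REGIONS:
                for status, label in (
                    (STATUS_METHYLATED, "meth"),
                    (STATUS_DEMETHYLATED, "demeth"),
                    (STATUS_AMBIGUOUS, "ambiguous"),
                ):
                    row[f"{region}_{label}"] = self.region_count(ctx, region, status)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def summarize_region_counts(
    calls: Sequence[GeneRegionCall],
    dmrs_per_context: dict[str, Sequence[DMR]] | None = None,
    comparison: str = "",
) -> RegionSummary:
    """Tabulate gene-region calls into the summary structure described above."""
    return RegionSummary.from_calls(calls, dmrs_per_context, comparison)


@dataclass
class MetageneProfile:
    """DMP counts in 100-bp bins around the start- and stop-codon anchors."""

    context: str
    bin_width: int
    span: int
    atg_counts: np.ndarray
    stop_counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return 2 * self.span // self.bin_width

    def bin_edges(self) -> np.ndarray:
        return np.arange(-self.span, self.span + self.bin_width, self.bin_width)

    def to_frame(self) -> pd.DataFrame:
        edges = self.bin_edges()
        return pd.DataFrame(
            {
                "bin_start": edges[:-1],
                "bin_end": edges[1:],
                "atg_count": self.atg_counts,
                "stop_count": self.stop_counts,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def metagene_profile(
    dmps_in_dmrs: Sequence,
    genes: Sequence[GeneModel],
    bin_width: int = 100,
    span: int = 2000,
) -> MetageneProfile:
    """Bin DMP offsets from each gene's ATG and stop anchors, strand-resolved.

    ``dmps_in_dmrs`` should be restricted to DMPs that are members of DMRs.
    Offsets are measured in the transcription direction, so mirrored genes on
    opposite strands produce identical bins.  Counts are summed across genes;
    a DMP near two genes contributes to both.
    """
    if span % bin_width != 0:
        raise ValueError("span must be a multiple of bin_width")
    n_bins = 2 * span // bin_width
    atg = np.zeros(n_bins, dtype=np.int64)
    stop = np.zeros(n_bins, dtype=np.int64)
    contexts = {d.context for d in dmps_in_dmrs}
    context = next(iter(contexts)) if len(contexts) == 1 else ""
    by_chrom: dict[str, list] = defaultdict(list)
    for d in dmps_in_dmrs:
        by_chrom[d.chrom].append(d)
    for g in genes:
        for d in by_chrom.get(g.chrom, []):
            for anchor, counts in ((g.atg_anchor, atg), (g.stop_anchor, stop)):
                offset = d.pos - anchor if g.strand == "+" else anchor - d.pos
                if -span <= offset < span:
                    counts[offset // bin_width + span // bin_width] += 1
    return MetageneProfile(
        context=context,
        bin_width=bin_width,
        span=span,
        atg_counts=atg,
        stop_counts=stop,
    )


def dmr_feature_counts(
    dmrs: Sequence[DMR], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Count DMRs overlapping exons, introns and intergenic space.

    A DMR is counted once per feature class it touches; intergenic means any
    part of the DMR lies outside every gene body.
    """
    gene_by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        gene_by_chrom[g.chrom].append(g)
    n_exon = n_intron = n_intergenic = 0
    for d in dmrs:
        hit_exon = hit_intron = False
        covered: list[tuple[int, int]] = []
        for g in gene_by_chrom.get(d.chrom, []):
            if not d.overlaps(g.start, g.end):
                continue
            covered.append((max(d.start, g.start), min(d.end, g.end)))
            exons = g.exons if g.exons else ((g.start, g.end),)
            if any(d.overlaps(s, e) for s, e in exons):
                hit_exon = True
            # intron = gene-body bp not covered by an exon
            intron_cursor = g.start
            for s, e in sorted(exons):
                if intron_cursor < s and d.overlaps(intron_cursor, s):
                    hit_intron = True
                intron_cursor = max(intron_cursor, e)
            if intron_cursor < g.end and d.overlaps(intron_cursor, g.end):
                hit_intron = True
        # merge covered intervals to see whether the DMR pokes outside genes
        covered.sort()
        cursor = d.start
        outside = False
        for s, e in covered:
            if s > cursor:
                outside = True
                break
            cursor = max(cursor, e)
        if cursor < d.end:
            outside = True
        n_exon += hit_exon
        n_intron += hit_intron
        n_intergenic += outside
    return pd.DataFrame(
        {
            "feature": ["exon", "intron", "intergenic"],
            "n_dmrs": [n_exon, n_intron, n_intergenic],
        }
    )


def write_gene_region_calls(calls: Sequence[GeneRegionCall], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "region": [c.region for c in calls],
            "context": [c.context for c in calls],
            "comparison": [c.comparison for c in calls],
            "status": [c.status for c in calls],
            "n_dmrs": [len(c.supporting_dmrs) for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)
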