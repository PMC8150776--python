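"""End-to-end pipeline driver: counts -> DMPs -> DMRs -> EGB calls -> sets.

``run_pipeline`` executes every stage for each context present in the inputs
and writes TSV/BED outputs plus a JSON manifest recording parameters and the
object count at every stage, so a run is auditable and reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from mcseed._version import __version__
from mcseed.comparative_sets import (
    cross_dmg_deg,
    read_deg_table,
    regulatory_gene_set,
    write_dmg_deg_tsv,
)
from mcseed.dmp_calling import call_dmps, relative_methylation, write_dmp_bed, write_dmp_tsv
from mcseed.dmr_calling import (
    DEFAULT_LENGTH_GRID,
    call_dmrs,
    optimize_window,
    write_dmr_bed,
    write_dmr_tsv,
)
from mcseed.egb_annotation import (
    assign_dmrs_to_regions,
    build_egb_regions,
    classify_gene_regions,
    dmr_feature_counts,
    load_gene_models,
    metagene_profile,
    summarize_region_counts,
    write_gene_region_calls,
)
from mcseed.errors import ConfigurationError
from mcseed.locus_matrix import (
    filter_by_cv,
    normalize_counts,
    read_count_table,
    read_sample_sheet,
    subset_metadata,
)
from mcseed.report import pca_variance

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one comparison run; values mirror the analysis defaults."""

    counts: dict[str, str]  # context -> count table TSV
    sample_sheet: str
    gff3: str
    outdir: str
    comparison: str = "comparison"
    deg_table: str | None = None
    window_lengths: dict[str, int] | str = "auto"  # or per-context lengths
    fdr: float = 0.05
    flank: int = 2000
    core: int = 400
    bin_width: int = 100
    cv_colog_threshold: float = -0.35
    pseudo_coverage: int = 100
    min_cluster_size: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.fdr < 1:
            raise ConfigurationError(f"fdr out of range: {self.fdr}")
        for name in ("flank", "core", "bin_width", "pseudo_coverage"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for label, path in [("sample_sheet", self.sample_sheet), ("gff3", self.gff3)]:
            if not Path(path).is_file():
                raise ConfigurationError(f"{label} file not found: {path}")
        for ctx, path in self.counts.items():
            if not Path(path).is_file():
                raise ConfigurationError(f"count table for {ctx} not found: {path}")
        if self.deg_table is not None and not Path(self.deg_table).is_file():
            raise ConfigurationError(f"DE table not found: {self.deg_table}")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages and return the output directory."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "version": __version__,
        "comparison": cfg.comparison,
        "seed": cfg.seed,
        "parameters": {
            "fdr": cfg.fdr,
            "flank": cfg.flank,
            "core": cfg.core,
            "bin_width": cfg.bin_width,
            "cv_colog_threshold": cfg.cv_colog_threshold,
            "pseudo_coverage": cfg.pseudo_coverage,
            "min_cluster_size": cfg.min_cluster_size,
            "window_lengths": cfg.window_lengths
            if isinstance(cfg.window_lengths, str)
            else dict(cfg.window_lengths),
        },
        "stages": {},
    }
    metadata_all = read_sample_sheet(cfg.sample_sheet)
    genes = load_gene_models(cfg.gff3)
    regions = build_egb_regions(genes, flank=cfg.flank)
    manifest["stages"]["genes"] = len(genes)

    all_calls = []
    dmrs_per_context = {}
    for ctx, counts_path in sorted(cfg.counts.items()):
        stage: dict = {}
        meta = subset_metadata(metadata_all, context=ctx)
        raw = read_count_table(counts_path, meta)
        stage["loci"] = raw.n_positions
        norm = normalize_counts(raw)
        filtered, cv_report = filter_by_cv(norm, cfg.cv_colog_threshold)
        cv_report.write_tsv(outdir / f"cv_filter_{ctx}.tsv")
        stage["loci_after_cv"] = filtered.n_positions
        relmeth = relative_methylation(filtered)
        relmeth.write_tsv(outdir / f"relmeth_{ctx}.tsv")
        dmps = call_dmps(
            relmeth, fdr=cfg.fdr, pseudo_coverage=cfg.pseudo_coverage
        )
        stage["dmps"] = len(dmps)
        write_dmp_tsv(dmps, outdir / f"dmps_{ctx}.tsv")
        write_dmp_bed(dmps, outdir / f"dmps_{ctx}.bed")
        if dmps:
            pca = pca_variance(relmeth, dmps)
            stage["pc1_variance_pct"] = float(pca.variance_pct[0])
        if isinstance(cfg.window_lengths, str):
            scan = optimize_window(
                dmps,
                relmeth,
                lengths=DEFAULT_LENGTH_GRID,
                min_cluster_size=cfg.min_cluster_size,
                fdr=cfg.fdr,
                pseudo_coverage=cfg.pseudo_coverage,
            )
            scan.write_tsv(outdir / f"window_scan_{ctx}.tsv")
            window = scan.chosen_length
        else:
            if ctx not in cfg.window_lengths:
                raise ConfigurationError(f"no window length configured for {ctx}")
            window = int(cfg.window_lengths[ctx])
        stage["window_length"] = window
        dmrs = call_dmrs(
            dmps,
            relmeth,
            window_length=window,
            min_cluster_size=cfg.min_cluster_size,
            fdr=cfg.fdr,
            pseudo_coverage=cfg.pseudo_coverage,
            comparison=cfg.comparison,
        )
        stage["dmrs"] = len(dmrs)
        write_dmr_tsv(dmrs, outdir / f"dmrs_{ctx}.tsv")
        write_dmr_bed(dmrs, outdir / f"dmrs_{ctx}.bed")
        dmrs_per_context[ctx] = dmrs
        dmr_feature_counts(dmrs, genes).to_csv(
            outdir / f"dmr_features_{ctx}.tsv", sep="\t", index=False
        )
        overlaps = assign_dmrs_to_regions(dmrs, regions)
        calls = classify_gene_regions(
            overlaps, context=ctx, comparison=cfg.comparison
        )
        stage["gene_region_calls"] = len(calls)
        write_gene_region_calls(calls, outdir / f"gene_region_calls_{ctx}.tsv")
        all_calls.extend(calls)
        dmr_spans = {(d.chrom, d.start, d.end) for d in dmrs}
        dmps_in_dmrs = [
            d
            for d in dmps
            if any(
                c == d.chrom and s <= d.pos < e for c, s, e in dmr_spans
            )
        ]
        profile = metagene_profile(
            dmps_in_dmrs, genes, bin_width=cfg.bin_width, span=cfg.flank
        )
        profile.write_tsv(outdir / f"metagene_{ctx}.tsv")
        manifest["stages"][ctx] = stage

    summary = summarize_region_counts(
        all_calls, dmrs_per_context, comparison=cfg.comparison
    )
    summary.write_tsv(outdir / "region_summary.tsv")
    manifest["stages"]["summary"] = {
        "total_dmrs": summary.total_dmrs(),
        "cytosine_dmrs": summary.cytosine_dmr_total(),
    }

    meth_set, demeth_set = regulatory_gene_set(
        all_calls, genes, flank=cfg.flank, core=cfg.core, comparison=cfg.comparison
    )
    manifest["stages"]["regulatory_sets"] = {
        "methylated": len(meth_set),
        "de-methylated": len(demeth_set),
    }
    with open(outdir / "regulatory_genes.tsv", "w") as fh:
        fh.write("gene_id\tstatus\n")
        for s in (meth_set, demeth_set):
            for g in sorted(s.gene_ids):
                fh.write(f"{g}\t{s.status}\n")

    if cfg.deg_table is not None:
        deg = read_deg_table(cfg.deg_table)
        crossed = cross_dmg_deg(all_calls, deg)
        write_dmg_deg_tsv(crossed, outdir / "dmg_x_deg.tsv")
        manifest["stages"]["dmg_x_deg"] = len(crossed)

    manifest["runtime_s"] = round(time.time() - t0, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished in %.1fs", manifest["runtime_s"])
    return outdir
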