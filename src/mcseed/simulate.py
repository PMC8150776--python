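"""Synthetic restriction-locus methylation data with a planted truth table.

Counts follow the pipeline's own convention — expected count
``nb_mean * (1 - methylation)``, so count anti-correlates with methylation —
with NB1 negative-binomial noise (variance ``mean * (1 + nb_dispersion)``).
Effect loci shift the two groups' methylation by ``±effect_size/2`` around a
Uniform(0.1, 0.9) baseline; part of them are laid out in tight blocks
(planted DMRs), the rest isolated (planted singleton DMPs that must never
become DMRs).  Everything is reproducible from the seed, and the truth table
records the planted positions, directions and block intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from mcseed.dmp_calling import DIRECTION_DEMETHYLATED, DIRECTION_METHYLATED
from mcseed.egb_annotation import GeneModel
from mcseed.errors import ConfigurationError
from mcseed.locus_matrix import CONTEXTS, LocusCountMatrix, SampleMetadata

# minimum distance between a planted effect element (block or singleton) and
# any other effect element; larger than the 2000 bp window-grid maximum so
# singletons can never chain into a cluster with other true effects
EFFECT_ISOLATION_BP = 3000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset (per context)."""

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    n_background_loci: int = 500
    replicates: int = 3
    group1: str = "group1"
    group2: str = "group2"
    nb_mean: float = 200.0
    nb_dispersion: float = 0.1  # NB1: var = mean * (1 + dispersion)
    effect_size: float = 0.5
    n_blocks: int = 20
    block_size: int = 4
    block_spacing: int = 150
    n_singletons: int = 10
    n_genes: int = 30
    gene_length_min: int = 1500
    gene_length_max: int = 6000

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size <= 1.0:
            raise ConfigurationError("effect_size must be in [0, 1]")
        if self.replicates < 2:
            raise ConfigurationError("replicates must be >= 2")
        if self.block_spacing <= 0:
            raise ConfigurationError("block_spacing must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")


@dataclass
class SimulationTruth:
    """Planted signal: effect DMPs, DMR blocks, and per-locus baselines."""

    dmp_positions: list[tuple[str, int, str]]  # (chrom, pos, direction)
    blocks: list[tuple[str, int, int, str]]  # (chrom, start, end, direction)
    singletons: list[tuple[str, int, str]]
    baseline: dict[tuple[str, int], float]  # latent methylation per locus

    def dmp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dmp_positions, columns=["chrom", "pos", "direction"]
        )

    def block_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.blocks, columns=["chrom", "start", "end", "direction"]
        )

    def write_tsv(self, dmp_path, block_path) -> None:
        self.dmp_frame().to_csv(dmp_path, sep="\t", index=False)
        self.block_frame().to_csv(block_path, sep="\t", index=False)


def _negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB1 draws: var = mean * (1 + dispersion); Poisson when dispersion ~ 0."""
    mean = np.maximum(mean, 1e-9)
    if dispersion < 1e-9:
        return rng.poisson(mean)
    size = mean / dispersion  # NB1: shape grows with the mean
    p = 1.0 / (1.0 + dispersion)
    return rng.negative_binomial(size, p)


def _context_rng(cfg: SimConfig, context: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, CONTEXTS.index(context), salt])


def _layout_loci(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[tuple[str, int]], list[dict]]:
    """Place blocks, singletons and background loci along the chromosomes.

    Returns (sorted locus list, effect elements) where each element is a dict
    with kind, chrom, loci (positions) and a random direction to be assigned
    by the caller.
    """
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    elements = [{"kind": "block"} for _ in range(cfg.n_blocks)] + [
        {"kind": "singleton"} for _ in range(cfg.n_singletons)
    ]
    rng.shuffle(elements)
    loci: list[tuple[str, int]] = []
    per_chrom = np.array_split(np.arange(len(elements)), cfg.n_chrom)
    n_bg_per_chrom = np.array_split(np.arange(cfg.n_background_loci), cfg.n_chrom)
    placed_elements: list[dict] = []
    for ci, chrom in enumerate(chrom_names):
        cursor = int(rng.integers(500, 1500))
        chrom_elements = [elements[i] for i in per_chrom[ci]]
        n_bg = len(n_bg_per_chrom[ci])
        bg_between = max(1, len(chrom_elements) + 1)
        bg_chunks = np.array_split(np.arange(n_bg), bg_between)
        for slot in range(bg_between):
            for _ in bg_chunks[slot]:
                cursor += int(rng.integers(100, 600))
                loci.append((chrom, cursor))
            if slot == len(chrom_elements):
                break
            el = chrom_elements[slot]
            cursor += EFFECT_ISOLATION_BP + int(rng.integers(0, 1000))
            if el["kind"] == "block":
                positions = [
                    cursor + j * cfg.block_spacing for j in range(cfg.block_size)
                ]
            else:
                positions = [cursor]
            loci.extend((chrom, p) for p in positions)
            cursor = positions[-1] + EFFECT_ISOLATION_BP
            placed_elements.append(
                {"kind": el["kind"], "chrom": chrom, "loci": positions}
            )
        if cursor >= cfg.chrom_length:
            raise ConfigurationError(
                f"layout exceeds chrom_length ({cursor} >= {cfg.chrom_length}); "
                "increase chrom_length or reduce loci"
            )
    loci.sort()
    return loci, placed_elements


def simulate_counts(
    cfg: SimConfig, context: str = "CG"
) -> tuple[LocusCountMatrix, list[SampleMetadata], SimulationTruth]:
    """Simulate one context's raw count matrix plus metadata and truth table.

    Libraries are named ``<group>_<context>_r<replicate>``; the returned
    matrix is raw (normalize and CV-filter it like real data).
    """
    if context not in CONTEXTS:
        raise ConfigurationError(f"unknown context {context!r}")
    rng = _context_rng(cfg, context)
    loci, elements = _layout_loci(cfg, rng)
    n_loci = len(loci)
    pos_index = {lp: i for i, lp in enumerate(loci)}

    baseline = rng.uniform(0.1, 0.9, size=n_loci)
    meth1 = baseline.copy()
    meth2 = baseline.copy()
    dmp_positions: list[tuple[str, int, str]] = []
    blocks: list[tuple[str, int, int, str]] = []
    singletons: list[tuple[str, int, str]] = []
    for el in elements:
        sign = 1 if rng.random() < 0.5 else -1
        direction = DIRECTION_METHYLATED if sign > 0 else DIRECTION_DEMETHYLATED
        for p in el["loci"]:
            i = pos_index[(el["chrom"], p)]
            meth1[i] = np.clip(baseline[i] + sign * cfg.effect_size / 2.0, 0.0, 1.0)
            meth2[i] = np.clip(baseline[i] - sign * cfg.effect_size / 2.0, 0.0, 1.0)
            if cfg.effect_size > 0:
                dmp_positions.append((el["chrom"], p, direction))
        if cfg.effect_size > 0:
            if el["kind"] == "block":
                blocks.append(
                    (el["chrom"], el["loci"][0], el["loci"][-1] + 1, direction)
                )
            else:
                singletons.append((el["chrom"], el["loci"][0], direction))

    metadata = [
        SampleMetadata(
            library_id=f"{group}_{context}_r{rep + 1}",
            group=group,
            replicate=rep + 1,
            context=context,
        )
        for group in (cfg.group1, cfg.group2)
        for rep in range(cfg.replicates)
    ]
    counts = np.zeros((n_loci, len(metadata)), dtype=np.int64)
    for s, m in enumerate(metadata):
        meth = meth1 if m.group == cfg.group1 else meth2
        expected = cfg.nb_mean * (1.0 - meth)
        counts[:, s] = _negative_binomial(rng, expected, cfg.nb_dispersion)

    matrix = LocusCountMatrix(
        chroms=np.array([c for c, _ in loci], dtype=object),
        positions=np.array([p for _, p in loci], dtype=np.int64),
        counts=counts.astype(float),
        metadata=metadata,
        context=context,
        normalized=False,
    )
    truth = SimulationTruth(
        dmp_positions=dmp_positions,
        blocks=blocks,
        singletons=singletons,
        baseline={lp: float(b) for lp, b in zip(loci, baseline)},
    )
    return matrix, metadata, truth


def simulate_gene_models(cfg: SimConfig) -> list[GeneModel]:
    """Place non-overlapping single-exon genes with random strands."""
    rng = np.random.default_rng([cfg.seed, 97])
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    per_chrom = np.array_split(np.arange(cfg.n_genes), cfg.n_chrom)
    genes: list[GeneModel] = []
    idx = 0
    for ci, chrom in enumerate(chrom_names):
        cursor = 2500  # leave room for the upstream flank
        for _ in per_chrom[ci]:
            length = int(rng.integers(cfg.gene_length_min, cfg.gene_length_max + 1))
            start = cursor + int(rng.integers(4500, 8000))
            end = start + length
            if end + 2500 > cfg.chrom_length:
                raise ConfigurationError(
                    "gene packing exceeds chrom_length; "
                    "increase chrom_length or reduce n_genes"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            idx += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{idx:04d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=((start, end),),
                )
            )
            cursor = end
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene + mRNA + exons), 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            exons = g.exons if g.exons else ((g.start, g.end),)
            for j, (s, e) in enumerate(exons, start=1):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{j};Parent={mrna_id}\n"
                )


def simulate_deg_table(
    genes: Sequence[GeneModel],
    n_deg: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Random differential-expression table over a subset of the gene models."""
    rng = np.random.default_rng([seed, 131])
    if n_deg > len(genes):
        raise ConfigurationError("n_deg exceeds number of genes")
    chosen = rng.choice(len(genes), size=n_deg, replace=False)
    logfc = rng.normal(0.0, 2.0, size=n_deg)
    logfc[logfc == 0.0] = 0.1
    return pd.DataFrame(
        {
            "gene_id": [genes[i].gene_id for i in sorted(chosen)],
            "logFC": np.round(logfc, 3),
            "FDR": np.round(rng.uniform(1e-6, 0.05, size=n_deg), 6),
        }
    )
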