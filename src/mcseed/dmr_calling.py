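"""DMR identification: directional window clustering of DMPs plus a
region-level test.

The scan works per chromosome, left to right.  A window of the candidate
length is anchored at the first unclustered DMP; each subsequent DMP that
falls inside the window and shares the cluster's direction joins it, and the
window re-anchors at the newly included position.  A significant DMP of the
opposite direction inside the window terminates the cluster (a region with
"the same methylation pattern" cannot contain a contradicting position) and
becomes the next anchor; alternatively ``opposite='skip'`` leaves such DMPs
out of the cluster without terminating it.  Clusters reaching the minimum
size are tested at region level by pooling member pseudo-counts per library
into the same binomial likelihood-ratio test used per site, with BH
adjustment across all clusters of the context.

The candidate window length is chosen by scanning a grid (100..2000 bp by
default) and keeping the length that maximizes the DMR count, smallest length
on ties.  Per-context defaults used in the original analyses are provided in
:data:`DEFAULT_WINDOW_LENGTHS`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from mcseed.dmp_calling import (
    DMP,
    RelativeMethylationMatrix,
    binomial_lrt,
    mn_dispersion,
)
from mcseed.errors import ConfigurationError, DataError, StateError
from mcseed.locus_matrix import SampleMetadata

#: Window lengths (bp) chosen for each comparison and context in the original
#: analyses; auto-optimization via :func:`optimize_window` is the fallback.
DEFAULT_WINDOW_LENGTHS: dict[str, dict[str, int]] = {
    "FVS": {"CG": 900, "CHG": 1000, "CHH": 700, "6mA": 400},
    "AVS": {"CG": 1000, "CHG": 900, "CHH": 700, "6mA": 400},
    "AVF": {"CG": 700, "CHG": 900, "CHH": 900, "6mA": 400},
}

DEFAULT_LENGTH_GRID: tuple[int, ...] = tuple(range(100, 2001, 100))


@dataclass
class DMPCluster:
    """A maximal run of same-direction DMPs linked by gaps within the window."""

    chrom: str
    members: list[DMP]
    direction: str
    window_length: int

    @property
    def start(self) -> int:
        return self.members[0].pos

    @property
    def end(self) -> int:
        # half-open span covering first to last member
        return self.members[-1].pos + 1

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class DMR:
    """A directional cluster of DMPs that passed the region-level test."""

    chrom: str
    start: int  # 0-based half-open, first member DMP
    end: int  # last member DMP + 1
    context: str
    direction: str
    n_dmps: int
    region_q: float
    comparison: str = ""
    window_length: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty DMR span [{self.start}, {self.end})")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class WindowScanResult:
    """DMR count per candidate window length and the chosen length."""

    counts: dict[int, int]
    chosen_length: int
    empty_input: bool = False

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(self.counts)
        return pd.DataFrame(
            {
                "window_length": lengths,
                "n_dmrs": [self.counts[L] for L in lengths],
                "chosen": [L == self.chosen_length for L in lengths],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_sorted(dmps: Sequence[DMP]) -> None:
    keys = [(d.chrom, d.pos) for d in dmps]
    if keys != sorted(keys):
        raise StateError("DMP list must be sorted by (chrom, pos)")


def cluster_dmps(
    dmps: Sequence[DMP],
    window_length: int,
    min_cluster_size: int = 2,
    opposite: Literal["terminate", "skip"] = "terminate",
) -> list[DMPCluster]:
    """Group sorted, single-context DMPs into directional clusters.

    See the module docstring for the scan rules.  Only clusters with at least
    ``min_cluster_size`` members are returned.
    """
    if window_length <= 0:
        raise ConfigurationError("window_length must be positive")
    _check_sorted(dmps)
    contexts = {d.context for d in dmps}
    if len(contexts) > 1:
        raise ConfigurationError(f"mixed contexts in DMP list: {sorted(contexts)}")
    clusters: list[DMPCluster] = []
    by_chrom: dict[str, list[DMP]] = {}
    for d in dmps:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom, chrom_dmps in by_chrom.items():
        used = [False] * len(chrom_dmps)
        while not all(used):
            anchor_idx = used.index(False)
            anchor = chrom_dmps[anchor_idx]
            members = [anchor]
            used[anchor_idx] = True
            window_start = anchor.pos
            for j in range(anchor_idx + 1, len(chrom_dmps)):
                if used[j]:
                    continue
                d = chrom_dmps[j]
                if d.pos - window_start > window_length:  # gap <= L joins
                    break  # outside the re-anchored window: cluster closes
                if d.direction == anchor.direction:
                    members.append(d)
                    used[j] = True
                    window_start = d.pos  # re-anchor at the newest member
                elif opposite == "terminate":
                    break
                # opposite == "skip": leave it unclustered, keep scanning
            if len(members) >= min_cluster_size:
                clusters.append(
                    DMPCluster(
                        chrom=chrom,
                        members=members,
                        direction=anchor.direction,
                        window_length=window_length,
                    )
                )
    clusters.sort(key=lambda c: (c.chrom, c.start))
    return clusters


@dataclass(frozen=True)
class ClusterTestResult:
    """Region-level test outcome for one cluster (pre-BH)."""

    p_value: float
    statistic: float  # raw pooled 1-df likelihood-ratio deviance
    phi: float  # dispersion the statistic was scaled by
    delta: float
    direction: str


def test_cluster(
    c: DMPCluster,
    r: RelativeMethylationMatrix,
    meta: Sequence[SampleMetadata] | None = None,
    fdr: float = 0.05,
    pseudo_coverage: int = 100,
    group_pair: tuple[str, str] | None = None,
    overdispersion: str = "MN",
    test: str = "F",
) -> ClusterTestResult:
    """Region-level test for one cluster.

    Member positions' pseudo-counts are pooled per library (sum of methylated
    events, sum of coverage) and fed through the same dispersion-corrected
    binomial likelihood-ratio test as the per-site calls.  BH adjustment
    across clusters is the caller's responsibility (see :func:`call_dmrs`).
    """
    if meta is not None and [m.library_id for m in meta] != r.library_ids:
        raise ConfigurationError("metadata does not match matrix column order")
    groups = r.groups() if group_pair is None else list(group_pair)
    if len(groups) != 2:
        raise ConfigurationError(f"exactly two groups required, got {groups}")
    g1 = r.group_columns(groups[0])
    g2 = r.group_columns(groups[1])
    pos_index = {
        (str(ch), int(p)): i
        for i, (ch, p) in enumerate(zip(r.chroms, r.positions))
    }
    rows = []
    for d in c.members:
        key = (d.chrom, d.pos)
        if key not in pos_index:
            raise DataError(f"cluster member {key} absent from methylation matrix")
        rows.append(pos_index[key])
    num_c = np.rint(r.relmeth[rows] * pseudo_coverage).astype(np.int64)
    # pool member positions per library: one binomial observation per library
    lib_k = num_c.sum(axis=0)[None, :].astype(float)
    lib_cov = float(len(rows) * pseudo_coverage)
    k1 = lib_k[:, g1].sum(axis=1)
    n1 = np.array([lib_cov * g1.size])
    k2 = lib_k[:, g2].sum(axis=1)
    n2 = np.array([lib_cov * g2.size])
    stat, _ = binomial_lrt(k1, n1, k2, n2)
    if overdispersion == "MN":
        phi = mn_dispersion(lib_k.astype(np.int64), lib_cov, g1, g2)
    else:
        phi = np.ones(1)
    scaled = stat / phi
    df_resid = g1.size + g2.size - 2
    if test == "F" and df_resid > 0:
        p = float(f_dist.sf(scaled[0], 1, df_resid))
    else:
        p = float(chi2_dist.sf(scaled[0], df=1))
    if scaled[0] == 0.0:
        p = 1.0
    sub = r.relmeth[rows]
    delta = float(sub[:, g1].mean() - sub[:, g2].mean())
    return ClusterTestResult(
        p_value=p,
        statistic=float(stat[0]),
        phi=float(phi[0]),
        delta=delta,
        direction=c.direction,
    )


def call_dmrs(
    dmps: Sequence[DMP],
    r: RelativeMethylationMatrix,
    window_length: int,
    min_cluster_size: int = 2,
    fdr: float = 0.05,
    pseudo_coverage: int = 100,
    comparison: str = "",
    opposite: Literal["terminate", "skip"] = "terminate",
    group_pair: tuple[str, str] | None = None,
    overdispersion: str = "MN",
    test: str = "F",
) -> list[DMR]:
    """Cluster DMPs at one window length and run the region tests with BH."""
    clusters = cluster_dmps(dmps, window_length, min_cluster_size, opposite)
    if not clusters:
        return []
    pvals = []
    for c in clusters:
        res = test_cluster(
            c,
            r,
            fdr=fdr,
            pseudo_coverage=pseudo_coverage,
            group_pair=group_pair,
            overdispersion=overdispersion,
            test=test,
        )
        pvals.append(res.p_value)
    _, qvals, _, _ = multipletests(np.array(pvals), method="fdr_bh")
    out = []
    for c, q in zip(clusters, qvals):
        if q < fdr:
            out.append(
                DMR(
                    chrom=c.chrom,
                    start=c.start,
                    end=c.end,
                    context=c.members[0].context,
                    direction=c.direction,
                    n_dmps=c.size,
                    region_q=float(q),
                    comparison=comparison,
                    window_length=window_length,
                )
            )
    return out


def optimize_window(
    dmps: Sequence[DMP],
    r: RelativeMethylationMatrix,
    lengths: Sequence[int] = DEFAULT_LENGTH_GRID,
    min_cluster_size: int = 2,
    fdr: float = 0.05,
    pseudo_coverage: int = 100,
    group_pair: tuple[str, str] | None = None,
    overdispersion: str = "MN",
    test: str = "F",
) -> WindowScanResult:
    """Scan candidate window lengths; pick the one maximizing the DMR count.

    Ties break toward the smallest length.  An empty DMP list yields the
    smallest candidate, flagged via ``empty_input``.
    """
    lengths = sorted(set(int(L) for L in lengths))
    if not lengths:
        raise ConfigurationError("empty candidate length grid")
    if not dmps:
        return WindowScanResult(
            counts={L: 0 for L in lengths},
            chosen_length=lengths[0],
            empty_input=True,
        )
    counts: dict[int, int] = {}
    for L in lengths:
        counts[L] = len(
            call_dmrs(
                dmps,
                r,
                window_length=L,
                min_cluster_size=min_cluster_size,
                fdr=fdr,
                pseudo_coverage=pseudo_coverage,
                group_pair=group_pair,
                overdispersion=overdispersion,
                test=test,
            )
        )
    best = max(counts.values())
    chosen = min(L for L in lengths if counts[L] == best)
    return WindowScanResult(counts=counts, chosen_length=chosen)


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "context": [d.context for d in dmrs],
            "direction": [d.direction for d in dmrs],
            "n_dmps": [d.n_dmps for d in dmrs],
            "region_q": [d.region_q for d in dmrs],
            "window_length": [d.window_length for d in dmrs],
            "comparison": [d.comparison for d in dmrs],
        }
    )


def write_dmr_tsv(dmrs: Sequence[DMR], path) -> None:
    dmrs_to_frame(dmrs).to_csv(path, sep="\t", index=False)


def write_dmr_bed(dmrs: Sequence[DMR], path) -> None:
    with open(path, "w") as fh:
        for d in dmrs:
            score = min(1000, int(round(-10.0 * np.log10(max(d.region_q, 1e-300)))))
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t"
                f"{d.context}:{d.direction}\t{score}\t.\n"
            )
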