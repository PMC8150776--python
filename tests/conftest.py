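import numpy as np
import pytest

from mcseed.dmp_calling import (
    DIRECTION_DEMETHYLATED,
    DIRECTION_METHYLATED,
    DMP,
    RelativeMethylationMatrix,
)
from mcseed.locus_matrix import LocusCountMatrix, SampleMetadata


def make_metadata(n1=3, n2=3, context="CG", g1="group1", g2="group2"):
    return [
        SampleMetadata(f"{g1}_r{i + 1}", g1, i + 1, context) for i in range(n1)
    ] + [
        SampleMetadata(f"{g2}_r{i + 1}", g2, i + 1, context) for i in range(n2)
    ]


def make_matrix(counts, metadata=None, chrom="chr1", normalized=False, context="CG"):
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    if metadata is None:
        s = counts.shape[1]
        metadata = make_metadata(s // 2, s - s // 2, context=context)
    return LocusCountMatrix(
        chroms=np.array([chrom] * n, dtype=object),
        positions=np.arange(n, dtype=np.int64) * 100,
        counts=counts,
        metadata=metadata,
        context=context,
        normalized=normalized,
    )


def make_relmeth(values, metadata=None, chrom="chr1", positions=None, context="CG"):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if metadata is None:
        s = values.shape[1]
        metadata = make_metadata(s // 2, s - s // 2, context=context)
    if positions is None:
        positions = np.arange(n, dtype=np.int64) * 100
    return RelativeMethylationMatrix(
        chroms=np.array([chrom] * n, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        relmeth=values,
        metadata=metadata,
        context=context,
    )


def make_dmp(pos, direction=DIRECTION_METHYLATED, chrom="chr1", context="CG", q=0.01):
    delta = 0.5 if direction == DIRECTION_METHYLATED else -0.5
    return DMP(
        chrom=chrom,
        pos=pos,
        context=context,
        delta=delta,
        direction=direction,
        p_value=q / 2,
        q_value=q,
    )


def chain_oracle(dmps, window_length, min_cluster_size=2):
    """Brute-force clustering oracle: maximal runs of consecutive
    same-direction DMPs with gaps <= window_length, per chromosome, split at
    any direction change."""
    out = []
    by_chrom = {}
    for d in sorted(dmps, key=lambda x: (x.chrom, x.pos)):
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom, ds in by_chrom.items():
        run = [ds[0]]
        for d in ds[1:]:
            if (
                d.direction == run[-1].direction
                and d.pos - run[-1].pos <= window_length
            ):
                run.append(d)
            else:
                if len(run) >= min_cluster_size:
                    out.append(run)
                run = [d]
        if len(run) >= min_cluster_size:
            out.append(run)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
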