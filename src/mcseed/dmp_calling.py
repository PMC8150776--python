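"""Relative methylation and differentially methylated position (DMP) calling.

At a methylation-sensitive restriction site, methylation blocks digestion, so
read count anti-correlates with methylation.  The per-site relative
methylation of library *s* is ``1 - n_s / max_t(n_t)`` over the normalized
counts of the site: the deepest library defines the fully unmethylated state.

DMPs are called with a grouped logistic regression: each library's relative
methylation is mapped onto ``round(relmeth * pseudo_coverage)`` methylated
events out of ``pseudo_coverage`` trials, and a binomial GLM of proportion on
the group indicator is compared to the intercept-only model by a 1-df
likelihood-ratio test.  With a single binary covariate and equal trial counts
the group-model MLE is the pooled per-group proportion, so the deviance
difference has the closed form implemented in :func:`binomial_lrt` —
vectorized across positions.

Replicates of sequencing libraries are overdispersed relative to the
binomial, so by default the likelihood-ratio statistic is scaled by the
McCullagh-Nelder dispersion estimate (Pearson chi-square of the group model
over its residual df, clamped at 1) and referred to an F(1, df) distribution;
``overdispersion="none"``/``test="chisq"`` recover the uncorrected test.
P-values are Benjamini-Hochberg adjusted within the context.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mcseed.errors import ConfigurationError, StateError
from mcseed.locus_matrix import LocusCountMatrix, SampleMetadata

DIRECTION_METHYLATED = "methylated"
DIRECTION_DEMETHYLATED = "de-methylated"


@dataclass
class RelativeMethylationMatrix:
    """Per-site relative methylation in [0, 1], same layout as the count matrix."""

    chroms: np.ndarray
    positions: np.ndarray
    relmeth: np.ndarray  # shape (n_positions, n_libraries)
    metadata: list[SampleMetadata]
    context: str

    @property
    def n_positions(self) -> int:
        return self.relmeth.shape[0]

    @property
    def library_ids(self) -> list[str]:
        return [m.library_id for m in self.metadata]

    def group_columns(self, group: str) -> np.ndarray:
        idx = np.array([i for i, m in enumerate(self.metadata) if m.group == group])
        if idx.size == 0:
            raise ConfigurationError(f"no libraries with group {group!r}")
        return idx

    def groups(self) -> list[str]:
        seen: list[str] = []
        for m in self.metadata:
            if m.group not in seen:
                seen.append(m.group)
        return seen

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.relmeth, columns=self.library_ids)
        df.insert(0, "pos", self.positions)
        df.insert(0, "chrom", self.chroms)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DMP:
    """A position with a significant between-group methylation difference."""

    chrom: str
    pos: int
    context: str
    delta: float  # mean relmeth(group1) - mean relmeth(group2)
    direction: str  # methylated <=> delta > 0 (hyper-methylated in group1)
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        expected = DIRECTION_METHYLATED if self.delta > 0 else DIRECTION_DEMETHYLATED
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with delta {self.delta}"
            )


def relative_methylation(m: LocusCountMatrix) -> RelativeMethylationMatrix:
    """Compute ``relmeth = 1 - count / row_max`` on a normalized, filtered matrix.

    Rows with an all-zero count vector cannot occur after the CV filter's
    mean > 0 rule and are rejected here.
    """
    if not m.normalized:
        raise StateError("relative_methylation requires a normalized matrix")
    row_max = m.counts.max(axis=1)
    if np.any(row_max == 0):
        raise StateError(
            "rows with zero maximum count present; run filter_by_cv first"
        )
    relmeth = 1.0 - m.counts / row_max[:, None]
    return RelativeMethylationMatrix(
        chroms=m.chroms.copy(),
        positions=m.positions.copy(),
        relmeth=relmeth,
        metadata=list(m.metadata),
        context=m.context,
    )


def _xlogx(x: np.ndarray) -> np.ndarray:
    # x*log(x) with the 0*log(0) = 0 convention
    out = np.zeros_like(x, dtype=float)
    nz = x > 0
    out[nz] = x[nz] * np.log(x[nz])
    return out


def binomial_lrt(
    successes1: np.ndarray,
    trials1: np.ndarray,
    successes2: np.ndarray,
    trials2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """1-df likelihood-ratio test of two binomial proportions, vectorized.

    This is the deviance difference of a binomial GLM with a binary group
    covariate versus the intercept-only model, computed in closed form
    (grouped data: the group-model MLE is each group's pooled proportion).
    Returns (statistic, p_value) arrays.
    """
    k1 = np.asarray(successes1, dtype=float)
    n1 = np.asarray(trials1, dtype=float)
    k2 = np.asarray(successes2, dtype=float)
    n2 = np.asarray(trials2, dtype=float)
    k = k1 + k2
    n = n1 + n2
    # log-likelihood up to the binomial coefficient, which cancels in the LRT
    ll_full = (
        _xlogx(k1) + _xlogx(n1 - k1) - _xlogx(n1)
        + _xlogx(k2) + _xlogx(n2 - k2) - _xlogx(n2)
    )
    ll_null = _xlogx(k) + _xlogx(n - k) - _xlogx(n)
    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = stats.chi2.sf(stat, df=1)
    # a zero statistic means identical proportions: p = 1 exactly
    p = np.where(stat == 0.0, 1.0, p)
    return stat, p


def two_proportion_chisq(
    successes1: np.ndarray,
    trials1: np.ndarray,
    successes2: np.ndarray,
    trials2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-proportion chi-square with Yates continuity correction (fallback path).

    Kept as a documented alternative to :func:`binomial_lrt` for degenerate
    tables; vectorized like the main test.
    """
    a = np.asarray(successes1, dtype=float)
    b = np.asarray(trials1, dtype=float) - a
    c = np.asarray(successes2, dtype=float)
    d = np.asarray(trials2, dtype=float) - c
    total = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        num = total * np.square(np.maximum(np.abs(a * d - b * c) - total / 2.0, 0.0))
        den = (a + b) * (c + d) * (a + c) * (b + d)
        stat = np.where(den > 0, num / den, 0.0)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(stat == 0.0, 1.0, p)
    return stat, p


def pseudo_counts(
    r: RelativeMethylationMatrix, pseudo_coverage: int = 100
) -> np.ndarray:
    """Map relative methylation onto integer methylated-event counts."""
    return np.rint(r.relmeth * pseudo_coverage).astype(np.int64)


def mn_dispersion(
    num_c: np.ndarray, coverage: float, g1_cols: np.ndarray, g2_cols: np.ndarray
) -> np.ndarray:
    """McCullagh-Nelder dispersion of the group model, per position.

    Pearson chi-square of each library's pseudo-counts around its group's
    pooled proportion, divided by the residual df (libraries - 2), clamped at
    1 so under-dispersion is never used to sharpen the test.
    """
    n_lib = g1_cols.size + g2_cols.size
    df = n_lib - 2
    if df <= 0:
        return np.ones(num_c.shape[0])
    x2 = np.zeros(num_c.shape[0], dtype=float)
    for cols in (g1_cols, g2_cols):
        k = num_c[:, cols].astype(float)
        p_hat = k.sum(axis=1) / (coverage * cols.size)
        var = coverage * p_hat * (1.0 - p_hat)
        resid = np.square(k - coverage * p_hat[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(var[:, None] > 0, resid / var[:, None], 0.0)
        x2 += contrib.sum(axis=1)
    return np.maximum(x2 / df, 1.0)


def dmp_test_table(
    r: RelativeMethylationMatrix,
    fdr: float = 0.05,
    pseudo_coverage: int = 100,
    group_pair: tuple[str, str] | None = None,
    overdispersion: str = "MN",
    test: str = "F",
) -> pd.DataFrame:
    """Per-position test results (all positions, significant or not).

    Columns: chrom, pos, delta, statistic, phi, p_value, q_value,
    significant.  The statistic is the raw 1-df likelihood-ratio deviance;
    ``phi`` the dispersion it is scaled by before the reference distribution
    (F(1, df) by default, chi-square(1) with ``test='chisq'``).
    """
    groups = r.groups() if group_pair is None else list(group_pair)
    if len(groups) != 2:
        raise ConfigurationError(f"exactly two groups required, got {groups}")
    g1_cols = r.group_columns(groups[0])
    g2_cols = r.group_columns(groups[1])
    if g1_cols.size < 2 or g2_cols.size < 2:
        raise ConfigurationError(
            f"each group needs >=2 replicates "
            f"(got {g1_cols.size} and {g2_cols.size})"
        )
    if overdispersion not in ("MN", "none"):
        raise ConfigurationError(f"unknown overdispersion mode {overdispersion!r}")
    if test not in ("F", "chisq"):
        raise ConfigurationError(f"unknown test {test!r}")
    num_c = pseudo_counts(r, pseudo_coverage)
    k1 = num_c[:, g1_cols].sum(axis=1)
    n1 = np.full(r.n_positions, pseudo_coverage * g1_cols.size, dtype=float)
    k2 = num_c[:, g2_cols].sum(axis=1)
    n2 = np.full(r.n_positions, pseudo_coverage * g2_cols.size, dtype=float)
    stat, _ = binomial_lrt(k1, n1, k2, n2)
    if overdispersion == "MN":
        phi = mn_dispersion(num_c, float(pseudo_coverage), g1_cols, g2_cols)
    else:
        phi = np.ones(r.n_positions)
    scaled = stat / phi
    df_resid = g1_cols.size + g2_cols.size - 2
    if test == "F" and df_resid > 0:
        p = stats.f.sf(scaled, 1, df_resid)
    else:
        p = stats.chi2.sf(scaled, df=1)
    p = np.where(scaled == 0.0, 1.0, p)
    if p.size:
        _, q, _, _ = multipletests(p, method="fdr_bh")
    else:
        q = np.array([])
    delta = r.relmeth[:, g1_cols].mean(axis=1) - r.relmeth[:, g2_cols].mean(axis=1)
    return pd.DataFrame(
        {
            "chrom": r.chroms,
            "pos": r.positions,
            "delta": delta,
            "statistic": stat,
            "phi": phi,
            "p_value": p,
            "q_value": q,
            "significant": q < fdr,
        }
    )


def call_dmps(
    r: RelativeMethylationMatrix,
    meta: Sequence[SampleMetadata] | None = None,
    fdr: float = 0.05,
    pseudo_coverage: int = 100,
    group_pair: tuple[str, str] | None = None,
    overdispersion: str = "MN",
    test: str = "F",
) -> list[DMP]:
    """Call DMPs between two groups at the given FDR.

    ``group_pair`` fixes (group1, group2); by default the two groups in
    metadata order of first appearance.  Returns DMPs sorted by coordinate.
    """
    meta = list(meta) if meta is not None else list(r.metadata)
    if [m.library_id for m in meta] != r.library_ids:
        raise ConfigurationError("metadata does not match matrix column order")
    r = replace_metadata(r, meta)
    table = dmp_test_table(
        r,
        fdr=fdr,
        pseudo_coverage=pseudo_coverage,
        group_pair=group_pair,
        overdispersion=overdispersion,
        test=test,
    )
    out: list[DMP] = []
    for row in table[table["significant"]].itertuples():
        d = float(row.delta)
        out.append(
            DMP(
                chrom=str(row.chrom),
                pos=int(row.pos),
                context=r.context,
                delta=d,
                direction=DIRECTION_METHYLATED if d > 0 else DIRECTION_DEMETHYLATED,
                p_value=float(row.p_value),
                q_value=float(row.q_value),
            )
        )
    out.sort(key=lambda x: (x.chrom, x.pos))
    return out


def replace_metadata(
    r: RelativeMethylationMatrix, meta: Sequence[SampleMetadata]
) -> RelativeMethylationMatrix:
    return RelativeMethylationMatrix(
        chroms=r.chroms,
        positions=r.positions,
        relmeth=r.relmeth,
        metadata=list(meta),
        context=r.context,
    )


def dmps_to_frame(dmps: Sequence[DMP]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmps],
            "pos": [d.pos for d in dmps],
            "context": [d.context for d in dmps],
            "delta": [d.delta for d in dmps],
            "direction": [d.direction for d in dmps],
            "p_value": [d.p_value for d in dmps],
            "q_value": [d.q_value for d in dmps],
        }
    )


def write_dmp_tsv(dmps: Sequence[DMP], path) -> None:
    dmps_to_frame(dmps).to_csv(path, sep="\t", index=False)


def write_dmp_bed(dmps: Sequence[DMP], path) -> None:
    """BED6: name=context:direction, score=-10*log10(q) capped at 1000."""
    with open(path, "w") as fh:
        for d in dmps:
            score = min(1000, int(round(-10.0 * np.log10(max(d.q_value, 1e-300)))))
            strand = "."
            fh.write(
                f"{d.chrom}\t{d.pos}\t{d.pos + 1}\t"
                f"{d.context}:{d.direction}\t{score}\t{strand}\n"
            )
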