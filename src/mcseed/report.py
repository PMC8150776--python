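"""Reporting helpers: PCA variance on DMP methylation, count aggregations.

The aggregation helpers are the single code path for headline totals —
per-context DMR sums, cytosine-context ("5mC") totals, region-overlap totals
and context shares — whether the inputs come from a pipeline run or from an
externally tabulated summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

from mcseed.dmp_calling import DMP, RelativeMethylationMatrix
from mcseed.errors import ConfigurationError

CYTOSINE_CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class PCAResult:
    """Variance explained per component (percent) and per-sample scores."""

    variance_pct: np.ndarray
    scores: np.ndarray  # (n_samples, n_components)
    library_ids: list[str]

    def __post_init__(self) -> None:
        if np.any(self.variance_pct < -1e-9):
            raise ValueError("negative variance percentage")
        if self.variance_pct.sum() > 100.0 + 1e-6:
            raise ValueError("variance percentages exceed 100")


def pca_variance(
    r: RelativeMethylationMatrix,
    dmps: Sequence[DMP] | None = None,
    n_components: int | None = None,
) -> PCAResult:
    """Centered PCA of samples on relative methylation, DMP rows by default.

    When ``dmps`` is given only those rows enter the PCA (the discrimination
    the first component reports is then between-group methylation structure).
    """
    X = r.relmeth
    if dmps is not None:
        index = {(str(c), int(p)): i for i, (c, p) in enumerate(zip(r.chroms, r.positions))}
        rows = [index[(d.chrom, d.pos)] for d in dmps if (d.chrom, d.pos) in index]
        if not rows:
            raise ConfigurationError("no DMP rows present in the matrix")
        X = X[rows]
    if X.shape[1] < 2:
        raise ConfigurationError("PCA requires at least 2 samples")
    samples = X.T  # samples as observations
    n_comp = n_components or min(samples.shape)
    pca = PCA(n_components=min(n_comp, min(samples.shape)))
    scores = pca.fit_transform(samples - samples.mean(axis=0))
    return PCAResult(
        variance_pct=pca.explained_variance_ratio_ * 100.0,
        scores=scores,
        library_ids=r.library_ids,
    )


def total_count(per_context: Mapping[str, int], contexts: Iterable[str] | None = None) -> int:
    """Sum per-context counts over the requested contexts (all by default)."""
    contexts = list(contexts) if contexts is not None else list(per_context)
    missing = [c for c in contexts if c not in per_context]
    if missing:
        raise ConfigurationError(f"missing contexts in count table: {missing}")
    return sum(int(per_context[c]) for c in contexts)


def cytosine_total(per_context: Mapping[str, int]) -> int:
    """Total over the three cytosine contexts (the 5mC aggregate)."""
    return total_count(per_context, CYTOSINE_CONTEXTS)


def context_share_percent(per_context: Mapping[str, int], context: str) -> float:
    """Share of one context in the total, in percent."""
    total = total_count(per_context)
    if total == 0:
        raise ConfigurationError("empty count table")
    return 100.0 * per_context[context] / total
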