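"""Count-level transformations applied before diversity and network analysis.

Order of operations for network construction: subsample every sample to a
common depth (multivariate hypergeometric, i.e. without replacement),
apply the prevalence filter (>= ``min_reads`` reads in >= ``min_samples``
samples, defaults 6 and 3) on those equal-depth raw counts, then close the
filtered table to relative abundances.  Copy-number adjustment divides reads
by the mean 16S rRNA gene copies per genome of the deepest classifiable
taxon, and the resulting per-sample discrepancy rescales qPCR totals to
genome-equivalent abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import CopyNumberTable, CountTable, TaxonomyTable


@dataclass
class PreprocessConfig:
    """Subsampling depth, seed, and network prevalence-filter thresholds."""

    subsample_depth: int | str = "auto-min"
    seed: int = 0
    filter_min_reads: int = 6
    filter_min_samples: int = 3

    def __post_init__(self) -> None:
        if self.filter_min_reads < 1 or self.filter_min_samples < 1:
            raise ValueError("filter thresholds must be >= 1")
        if self.subsample_depth != "auto-min" and int(self.subsample_depth) < 1:
            raise ValueError("subsample depth must be positive or 'auto-min'")


def subsample_counts(
    table: CountTable, depth: int | str = "auto-min", seed: int = 0
) -> CountTable:
    """Rarefy each sample to ``depth`` reads without replacement.

    ``depth="auto-min"`` uses the minimum sample sum, mirroring the usual
    subsample-to-smallest-library convention.  The per-sample draw is
    multivariate hypergeometric, so a sample already at the target depth is
    returned unchanged.
    """
    if table.is_relative:
        raise ValueError("subsampling requires raw counts")
    sums = table.sample_sums()
    if depth == "auto-min":
        depth = int(sums.min())
    depth = int(depth)
    too_small = sums[sums < depth]
    if len(too_small):
        raise ValueError(
            f"depth {depth} exceeds reads in sample(s) {list(too_small.index)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty(table.shape, dtype=np.int64)
    arr = table.counts.to_numpy()
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(
        pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    )


def to_relative(table: CountTable) -> CountTable:
    """Close each sample to proportions; all-zero samples stay zero."""
    arr = table.counts.to_numpy(dtype=float)
    sums = arr.sum(axis=0)
    if (sums == 0).any():
        warnings.warn(
            f"all-zero sample(s) left at zero: "
            f"{list(table.counts.columns[sums == 0])}",
            stacklevel=2,
        )
    safe = np.where(sums == 0, 1.0, sums)
    rel = arr / safe
    return CountTable(
        pd.DataFrame(rel, index=table.counts.index, columns=table.counts.columns),
        is_relative=True,
    )


def hellinger_transform(table: CountTable) -> pd.DataFrame:
    """Square root of relative abundance; unit-norm per non-empty sample."""
    rel = table if table.is_relative else to_relative(table)
    return np.sqrt(rel.counts)


def copy_number_adjust(
    table: CountTable, tax: TaxonomyTable, cn: CopyNumberTable
) -> CountTable:
    """Divide reads by mean 16S copies of the nearest classifiable taxon.

    For each OTU the lookup walks genus -> family -> ... -> domain over its
    classified ranks and falls back to the table's root average, so the
    adjustment never fails silently on unclassified lineages.
    """
    if table.is_relative:
        raise ValueError("copy-number adjustment requires raw counts")
    divisors = np.empty(len(table.otu_ids))
    for i, otu in enumerate(table.otu_ids):
        if otu in tax.lineage.index:
            lineage = tax.classified_lineage(otu)
        else:
            lineage = []
        divisors[i] = cn.lookup(lineage)
    adjusted = table.counts.to_numpy(dtype=float) / divisors[:, None]
    return CountTable(
        pd.DataFrame(
            adjusted, index=table.counts.index, columns=table.counts.columns
        )
    )


def correct_qpcr_total(
    qpcr_total: float, raw: CountTable, adjusted: CountTable, sample: str
) -> float:
    """Rescale a qPCR 16S total (copies per g dry weight) to genome equivalents.

    The correction factor is the per-sample ratio of copy-number-adjusted to
    raw read sums, i.e. the discrepancy the adjustment introduced.
    """
    if list(raw.otu_ids) != list(adjusted.otu_ids):
        raise ValueError("raw and adjusted tables must share the same OTUs")
    raw_sum = float(raw.counts[sample].sum())
    if raw_sum == 0:
        raise ValueError(f"sample {sample!r} has zero raw reads")
    adj_sum = float(adjusted.counts[sample].sum())
    return qpcr_total * adj_sum / raw_sum


def prevalence_filter(
    table: CountTable, min_reads: int = 6, min_samples: int = 3
) -> CountTable:
    """Keep OTUs with >= ``min_reads`` reads in >= ``min_samples`` samples."""
    if table.is_relative:
        raise ValueError("prevalence filter operates on raw counts")
    hits = (table.counts >= min_reads).sum(axis=1)
    keep = hits >= min_samples
    return CountTable(table.counts.loc[keep].copy())
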