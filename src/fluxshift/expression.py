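"""Expression quantification and discretization.

Expression abundance is carried as FPKM (fragments per kilobase of exon per
million mapped reads).  For model integration each sample's genes are
discretized into trilean states: the top ``high_q`` fraction of genes is
"highly expressed" (+1), the bottom ``low_q`` fraction "lowly expressed"
(-1), the rest moderate (0); both quantile fractions default to 15%.
Between-sample regulation calls use the FPKM fold-change rule: fold change
above 2 is up-regulated, below 0.5 down-regulated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "ExpressionStateMap",
    "GeneFoldChange",
    "compute_fpkm",
    "discretize",
    "discretize_values",
    "gene_fold_changes",
]


class ExpressionTable:
    """Gene x sample matrix of non-negative FPKM values."""

    def __init__(self, values: pd.DataFrame) -> None:
        if values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression table")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression table")
        data = values.astype(float)
        if (data.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        self.values = data

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def sample(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.columns:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.values[sample_id]

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionTable":
        frame = pd.read_csv(path, sep="\t", index_col="gene_id", comment="#")
        return cls(frame)

    def to_tsv(self, path: str, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            if header_comment:
                handle.write(f"# {header_comment}\n")
            out = self.values.copy()
            out.index.name = "gene_id"
            out.to_csv(handle, sep="\t", float_format="%.9g", lineterminator="\n")


def compute_fpkm(
    fragments: Mapping[str, float] | pd.Series,
    exon_length_bp: Mapping[str, float] | pd.Series,
    mapped_reads: float,
) -> pd.Series:
    """FPKM per gene: fragments / (mapped reads in millions x exon length in kb).

    ``fragments`` and ``exon_length_bp`` must cover the same genes;
    ``mapped_reads`` is the library's total mapped read count.
    """
    frag = pd.Series(fragments, dtype=float)
    length = pd.Series(exon_length_bp, dtype=float).reindex(frag.index)
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be positive")
    if length.isna().any():
        missing = list(length.index[length.isna()])[:5]
        raise ValueError(f"missing exon length for genes {missing}")
    if (length <= 0).any():
        raise ValueError("exon lengths must be positive")
    if (frag < 0).any():
        raise ValueError("fragment counts must be non-negative")
    return frag / ((mapped_reads / 1e6) * (length / 1e3))


@dataclass
class SampleStates:
    """Trilean gene states of one sample plus the FPKM cutoffs used."""

    states: dict[str, int]
    low_cutoff: float
    high_cutoff: float


class ExpressionStateMap:
    """Per-sample trilean gene states (-1 low, 0 moderate, +1 high)."""

    def __init__(self, per_sample: dict[str, SampleStates]) -> None:
        self.per_sample = per_sample

    @property
    def samples(self) -> list[str]:
        return list(self.per_sample)

    def states(self, sample: str) -> dict[str, int]:
        return self.per_sample[sample].states

    def cutoffs(self, sample: str) -> tuple[float, float]:
        entry = self.per_sample[sample]
        return entry.low_cutoff, entry.high_cutoff

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (gene, sample, state)
            for sample, entry in self.per_sample.items()
            for gene, state in entry.states.items()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "sample", "state"])

    def to_tsv(self, path: str, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            if header_comment:
                handle.write(f"# {header_comment}\n")
            self.to_frame().to_csv(handle, sep="\t", index=False, lineterminator="\n")


def discretize_values(
    values: np.ndarray, low_q: float = 0.15, high_q: float = 0.15
) -> tuple[np.ndarray, float, float]:
    """Discretize one sample's value vector into trilean states.

    The cutoffs are the k-th order statistics with k = ceil(q*n).  Ties at
    a cutoff join the extreme class only when the tie block itself is no
    larger than k, so an extreme class can exceed its nominal fraction by
    at most one tie block and a value shared by more than the nominal
    fraction of genes (e.g. a large block of zeros) stays moderate.  A value
    claimed by both extremes (degenerate overlap at tiny n or constant
    vectors) is moderate.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return np.zeros(0, dtype=int), math.nan, math.nan
    k_low = math.ceil(low_q * n)
    k_high = math.ceil(high_q * n)
    ordered = np.sort(values)
    low_cutoff = ordered[k_low - 1]
    high_cutoff = ordered[n - k_high]

    low_tie = int(np.sum(values == low_cutoff))
    high_tie = int(np.sum(values == high_cutoff))
    low_mask = values < low_cutoff
    if low_tie <= k_low:
        low_mask |= values == low_cutoff
    high_mask = values > high_cutoff
    if high_tie <= k_high:
        high_mask |= values == high_cutoff
    both = low_mask & high_mask
    low_mask &= ~both
    high_mask &= ~both

    states = np.zeros(n, dtype=int)
    states[low_mask] = -1
    states[high_mask] = 1
    return states, float(low_cutoff), float(high_cutoff)


def discretize(
    table: ExpressionTable, low_q: float = 0.15, high_q: float = 0.15
) -> ExpressionStateMap:
    """Per-sample quantile discretization of an expression table."""
    if not (0 < low_q and 0 < high_q and low_q + high_q < 1):
        raise ValueError("need 0 < low_q, high_q and low_q + high_q < 1")
    n = len(table.genes)
    min_n = math.ceil(1 / min(low_q, high_q))
    if n < min_n:
        warnings.warn(
            f"only {n} genes; fewer than {min_n} means the low/high cutoffs "
            "may coincide",
            stacklevel=2,
        )
    per_sample: dict[str, SampleStates] = {}
    for sample in table.samples:
        values = table.values[sample].to_numpy()
        states, lc, hc = discretize_values(values, low_q=low_q, high_q=high_q)
        per_sample[sample] = SampleStates(
            states=dict(zip(table.genes, (int(s) for s in states))),
            low_cutoff=lc,
            high_cutoff=hc,
        )
    return ExpressionStateMap(per_sample)


@dataclass(frozen=True)
class GeneFoldChange:
    gene: str
    fc: float
    call: str  # "up" | "down" | "unchanged"


def gene_fold_changes(
    table: ExpressionTable,
    sample1: str,
    sample2: str,
    pseudocount: float = 1.0,
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
) -> list[GeneFoldChange]:
    """Fold change (sample2 vs sample1) per gene with up/down calls.

    fc = (fpkm2 + pseudocount) / (fpkm1 + pseudocount); calls use the
    fold-change rule fc > 2 -> up, fc < 0.5 -> down.  The default
    pseudocount of 1 keeps zero-FPKM genes finite; pseudocount=0 gives the
    literal ratio (infinite for 0 -> x transitions).
    """
    f1 = table.sample(sample1).to_numpy()
    f2 = table.sample(sample2).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (f2 + pseudocount) / (f1 + pseudocount)
    out = []
    for gene, value in zip(table.genes, fc):
        if np.isnan(value):  # 0/0 with pseudocount 0
            call = "unchanged"
        elif value > up_threshold:
            call = "up"
        elif value < down_threshold:
            call = "down"
        else:
            call = "unchanged"
        out.append(GeneFoldChange(gene=gene, fc=float(value), call=call))
    return out
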