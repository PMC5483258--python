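"""Allele-specific expression comparison between haplotype gene copies.

Expression of the two alleles of a pair is compared on the FPKM scale
(fragments per kilobase of transcript per million fragments); pairs whose
CDS lengths differ by 100 bp or more are excluded as not comparable, fold
ratios are binned cumulatively (>1.5, >2, >5) and the higher FPKM of each
pair is correlated against the lower (Pearson).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def compute_fpkm(count: int, length: int, total_fragments: int) -> float:
    """FPKM = count / ((length/1000) * (total_fragments/1e6))."""
    if length <= 0:
        raise ValueError(f"CDS length must be positive, got {length}")
    if total_fragments <= 0:
        raise ValueError(f"total fragment count must be positive, got {total_fragments}")
    return count / ((length / 1_000) * (total_fragments / 1_000_000))


@dataclass
class AllelicExpressionRecord:
    gene_a: str
    gene_b: str
    cds_len_a: int
    cds_len_b: int
    count_a: int
    count_b: int
    fpkm_a: float
    fpkm_b: float

    @property
    def fpkm_low(self) -> float:
        return min(self.fpkm_a, self.fpkm_b)

    @property
    def fpkm_high(self) -> float:
        return max(self.fpkm_a, self.fpkm_b)

    @property
    def fold_ratio(self) -> float:
        """high/low; inf when only one allele is expressed, 1 when neither."""
        if self.fpkm_low > 0:
            return self.fpkm_high / self.fpkm_low
        return math.inf if self.fpkm_high > 0 else 1.0

    @property
    def bins(self) -> dict[str, bool]:
        r = self.fold_ratio
        return {">1.5": r > 1.5, ">2": r > 2.0, ">5": r > 5.0}


def build_records(counts: pd.DataFrame, pairs: list[tuple[str, str]],
                  total_fragments: int | None = None,
                  ) -> list[AllelicExpressionRecord]:
    """Per-pair records from a count table (gene_id, cds_length,
    fragment_count).  ``total_fragments`` defaults to the table total."""
    table = counts.set_index("gene_id")
    if total_fragments is None:
        total_fragments = int(counts["fragment_count"].sum())
    records = []
    for ga, gb in pairs:
        ra, rb = table.loc[ga], table.loc[gb]
        records.append(AllelicExpressionRecord(
            gene_a=ga, gene_b=gb,
            cds_len_a=int(ra["cds_length"]), cds_len_b=int(rb["cds_length"]),
            count_a=int(ra["fragment_count"]), count_b=int(rb["fragment_count"]),
            fpkm_a=compute_fpkm(int(ra["fragment_count"]), int(ra["cds_length"]),
                                total_fragments),
            fpkm_b=compute_fpkm(int(rb["fragment_count"]), int(rb["cds_length"]),
                                total_fragments),
        ))
    return records


def select_comparable_pairs(records: list[AllelicExpressionRecord],
                            max_cds_length_difference: int = 100,
                            ) -> list[AllelicExpressionRecord]:
    """Keep pairs whose CDS lengths differ by strictly less than the cutoff."""
    return [r for r in records
            if abs(r.cds_len_a - r.cds_len_b) < max_cds_length_difference]


@dataclass
class ExpressionComparison:
    n_pairs: int
    bin_counts: dict[str, int]         # cumulative: >1.5 contains >2 contains >5
    n_undefined_ratio: int             # one allele silent (low = 0, high > 0)
    n_correlated: int
    pearson_r: float | None
    pearson_p: float | None

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "bin_counts": self.bin_counts,
            "n_undefined_ratio": self.n_undefined_ratio,
            "n_correlated": self.n_correlated,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
        }


def compare_pairs(records: list[AllelicExpressionRecord],
                  ) -> tuple[ExpressionComparison, pd.DataFrame]:
    """Cumulative fold-change bins plus the higher-vs-lower correlation.

    Pairs with one silent allele are reported separately (their ratio is
    undefined) and excluded from the correlation; the returned scatter
    table holds (low, high) per pair.
    """
    bins = {">1.5": 0, ">2": 0, ">5": 0}
    undefined = 0
    lows, highs, rows = [], [], []
    for r in records:
        low, high = r.fpkm_low, r.fpkm_high
        rows.append((r.gene_a, r.gene_b, low, high,
                     r.fold_ratio if low > 0 else np.nan))
        if low == 0 and high > 0:
            undefined += 1
            continue
        for name, flag in r.bins.items():
            bins[name] += bool(flag)
        if low > 0:
            lows.append(low)
            highs.append(high)
    pearson_r = pearson_p = None
    if len(lows) >= 3 and np.std(lows) > 0 and np.std(highs) > 0:
        res = stats.pearsonr(lows, highs)
        pearson_r, pearson_p = float(res.statistic), float(res.pvalue)
    scatter = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "fpkm_low", "fpkm_high", "fold_ratio"]
    )
    comparison = ExpressionComparison(
        n_pairs=len(records),
        bin_counts=bins,
        n_undefined_ratio=undefined,
        n_correlated=len(lows),
        pearson_r=pearson_r,
        pearson_p=pearson_p,
    )
    return comparison, scatter
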