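"""Mutational-landscape statistics from per-target allele tables.

The allele table is the output of an upstream allele quantifier: one row per
(target, variant) with a read count. Variant types are 'insertion',
'deletion', 'SNV' and 'WT'. Positions are 0-based offsets within the analysis
window on the PAM-carrying strand (deletion position = 5'-most deleted base;
insertion position = base to the left of the insert). All frequencies are
read-count-weighted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VARIANT_TYPES = ("insertion", "deletion", "SNV", "WT")
INDEL_TYPES = ("insertion", "deletion")
DEFAULT_WINDOW = 39


def indel_spectrum(records: pd.DataFrame) -> pd.DataFrame:
    """Read-weighted frequency table of indels by (variant_type, length).

    Frequencies are normalised over indel reads only and sum to 1. Lengths run
    up to the maximum observed. Empty input yields an empty table.
    """
    indels = records[records["variant_type"].isin(INDEL_TYPES)]
    if indels.empty:
        return pd.DataFrame(columns=["variant_type", "length", "reads", "frequency"])
    tab = (
        indels.groupby(["variant_type", "length"])["read_count"]
        .sum()
        .reset_index()
        .rename(columns={"read_count": "reads"})
    )
    tab["frequency"] = tab["reads"] / tab["reads"].sum()
    return tab.sort_values(["variant_type", "length"]).reset_index(drop=True)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardised mean difference with the pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    s1, s2 = a.var(ddof=1), b.var(ddof=1)
    pooled = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    if pooled == 0:
        return 0.0
    return (a.mean() - b.mean()) / math.sqrt(pooled)


@dataclass
class DelInsStats:
    ratio: float  # total deletion reads / total insertion reads
    ratio_infinite: bool  # True when there were zero insertion reads
    welch_t: float
    welch_p: float
    cohens_d: float
    n_targets: int


def del_ins_stats(records: pd.DataFrame) -> DelInsStats:
    """Deletion:insertion read ratio plus per-target Welch t and Cohen's d.

    The t/d statistics compare per-target deletion vs insertion read
    frequencies (type reads / total reads of the target).
    """
    del_reads = int(
        records.loc[records["variant_type"] == "deletion", "read_count"].sum()
    )
    ins_reads = int(
        records.loc[records["variant_type"] == "insertion", "read_count"].sum()
    )
    if ins_reads == 0:
        ratio, infinite = float("inf"), True
    else:
        ratio, infinite = del_reads / ins_reads, False

    totals = records.groupby("target_id")["read_count"].sum()
    per_type = (
        records.groupby(["target_id", "variant_type"])["read_count"]
        .sum()
        .unstack(fill_value=0)
        .reindex(columns=list(VARIANT_TYPES), fill_value=0)
    )
    del_freq = (per_type["deletion"] / totals).to_numpy(dtype=float)
    ins_freq = (per_type["insertion"] / totals).to_numpy(dtype=float)
    if np.allclose(del_freq, del_freq.mean()) and np.allclose(
        ins_freq, ins_freq.mean()
    ) and np.isclose(del_freq.mean(), ins_freq.mean()):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(del_freq, ins_freq, equal_var=False)
    return DelInsStats(
        ratio=ratio,
        ratio_infinite=infinite,
        welch_t=float(t),
        welch_p=float(p),
        cohens_d=cohens_d(del_freq, ins_freq),
        n_targets=len(totals),
    )


def snv_positional_distribution(
    records: pd.DataFrame, window_length: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Per-position % of SNV reads plus the uniform expectation.

    Percentages sum to 100 over the window. The uniform expectation is
    100 / window_length (2.56% for the default 39-nt window). SNV rows with a
    position outside [0, window_length) are rejected (dropped with a warning).
    Result columns: position, reads, percent; attrs['uniform_expectation'].
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    snvs = records[records["variant_type"] == "SNV"].copy()
    bad = ~snvs["position"].between(0, window_length - 1)
    if bad.any():
        logger.warning(
            "rejected %d SNV record(s) outside the %d-nt window",
            int(bad.sum()),
            window_length,
        )
        snvs = snvs[~bad]
    reads = (
        snvs.groupby("position")["read_count"]
        .sum()
        .reindex(range(window_length), fill_value=0)
    )
    total = reads.sum()
    out = pd.DataFrame(
        {
            "position": np.arange(window_length),
            "reads": reads.to_numpy(),
            "percent": (100.0 * reads / total).to_numpy() if total > 0 else 0.0,
        }
    )
    out.attrs["uniform_expectation"] = 100.0 / window_length
    return out


def snv_read_fraction_filter(
    summaries: pd.DataFrame, threshold: float = 0.01
) -> pd.DataFrame:
    """Keep targets whose SNV reads exceed `threshold` of total reads (strict >).

    `summaries` has columns target_id, snv_reads, total_reads. Targets with
    zero total reads are skipped.
    """
    usable = summaries[summaries["total_reads"] > 0]
    frac = usable["snv_reads"] / usable["total_reads"]
    return usable[frac > threshold].reset_index(drop=True)


def snv_fraction_of_variants(records: pd.DataFrame) -> float:
    """% of variant (non-WT) reads that are SNVs; NaN when there are none."""
    variants = records[records["variant_type"].isin(("SNV",) + INDEL_TYPES)]
    total = variants["read_count"].sum()
    if total == 0:
        return float("nan")
    snv = variants.loc[variants["variant_type"] == "SNV", "read_count"].sum()
    return 100.0 * snv / total


def target_efficiency(records: pd.DataFrame) -> pd.DataFrame:
    """Per-target editing efficiency (% non-WT reads) and per-type totals."""
    per_type = (
        records.groupby(["target_id", "variant_type"])["read_count"]
        .sum()
        .unstack(fill_value=0)
        .reindex(columns=list(VARIANT_TYPES), fill_value=0)
    )
    total = per_type.sum(axis=1)
    edited = total - per_type["WT"]
    out = per_type.copy()
    out.columns = [f"{c}_reads" for c in out.columns]
    out["total_reads"] = total
    out["efficiency"] = 100.0 * edited / total
    return out.reset_index()
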