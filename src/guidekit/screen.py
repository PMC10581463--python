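"""Pooled knockout-screen processing: log-fold-change efficiency inference,
essentiality (Bayes-Factor) filtering and chromatin-accessibility annotation.

Screen tables are DataFrames with one row per guide: guide_id, gene, contig,
start, end, strand, an optional `context` sequence column, a reference count
column and one count column per post-reference timepoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_BF_THRESHOLD = 6.0

NARROWPEAK_COLUMNS = [
    "contig", "start", "end", "name", "score",
    "strand", "signal", "p_value", "q_value", "peak",
]


def cpm(counts: pd.Series | np.ndarray) -> np.ndarray:
    """Counts-per-million within one library."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("library total is zero; cpm undefined")
    return counts * 1e6 / total


def log_fold_change(
    counts: pd.DataFrame, timepoint: str, reference: str = "count_ref"
) -> pd.Series:
    """Per-guide log2((cpm_t + 1) / (cpm_ref + 1)).

    Each column is normalised to counts-per-million within its own library
    before the pseudocount of 1 is added.
    """
    ref = cpm(counts[reference])
    t = cpm(counts[timepoint])
    return pd.Series(
        np.log2((t + 1.0) / (ref + 1.0)), index=counts.index, name=f"lfc_{timepoint}"
    )


def infer_efficiency(
    counts: pd.DataFrame,
    timepoints: list[str] | None = None,
    reference: str = "count_ref",
    method: str = "mean",
) -> pd.Series:
    """Efficiency score per guide from its LFC trajectory.

    Default score is the negative mean LFC over post-reference timepoints
    (higher = more depleted = more efficient). ``method='slope'`` instead fits
    a least-squares line of LFC against timepoint index 1..T and negates the
    slope.
    """
    if timepoints is None:
        timepoints = [
            c for c in counts.columns if c.startswith("count_") and c != reference
        ]
    if not timepoints:
        raise ValueError("no post-reference timepoints")
    lfc = np.column_stack([log_fold_change(counts, t, reference) for t in timepoints])
    if method == "mean":
        score = -lfc.mean(axis=1)
    elif method == "slope":
        x = np.arange(1, len(timepoints) + 1, dtype=float)
        xc = x - x.mean()
        score = -(lfc - lfc.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(score, index=counts.index, name="efficiency_score")


def essentiality_filter(
    guides: pd.DataFrame,
    bf_table: pd.DataFrame,
    bf_threshold: float = DEFAULT_BF_THRESHOLD,
) -> pd.DataFrame:
    """Keep guides whose gene has a Bayes Factor >= bf_threshold.

    Gene symbols join case-insensitively; guides without a BF row are dropped
    with a logged count. An empty BF table drops everything (with a warning).
    """
    if bf_table.empty:
        logger.warning("empty Bayes-Factor table: all %d guides dropped", len(guides))
        return guides.iloc[0:0].copy()
    bf = bf_table.copy()
    bf["_gene_key"] = bf["gene"].str.upper()
    if bf["_gene_key"].duplicated().any():
        raise ValueError("Bayes-Factor table has duplicate gene symbols")
    merged = guides.assign(_gene_key=guides["gene"].str.upper()).merge(
        bf[["_gene_key", "bf"]], on="_gene_key", how="left"
    )
    missing = merged["bf"].isna()
    if missing.any():
        logger.warning(
            "%d guide(s) had no Bayes-Factor entry and were dropped", int(missing.sum())
        )
    kept = merged[~missing & (merged["bf"] >= bf_threshold)]
    return kept.drop(columns=["_gene_key"]).reset_index(drop=True)


def read_narrowpeak(path) -> pd.DataFrame:
    """Read a standard 10-column narrowPeak BED file."""
    return pd.read_csv(
        path, sep="\t", header=None, names=NARROWPEAK_COLUMNS, comment="#"
    )


def annotate_accessibility(guides: pd.DataFrame, peaks: pd.DataFrame) -> pd.Series:
    """0/1 accessibility label per guide: 1 iff its [start, end) interval
    overlaps any peak by >= 1 bp (half-open; abutting intervals do not count).

    Guides on contigs absent from the peak table get 0; their number is logged.
    """
    trees: dict[str, IntervalTree] = {}
    for contig, sub in peaks.groupby("contig"):
        trees[contig] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(sub["start"], sub["end"]) if s < e
        )
    labels = []
    missing_contig = 0
    for row in guides.itertuples():
        tree = trees.get(row.contig)
        if tree is None:
            missing_contig += 1
            labels.append(0)
            continue
        labels.append(1 if tree.overlap(int(row.start), int(row.end)) else 0)
    if missing_contig:
        logger.info(
            "%d guide(s) on contigs absent from the peak file (labelled 0)",
            missing_contig,
        )
    return pd.Series(labels, index=guides.index, name="accessible", dtype=int)


@dataclass
class CohortStats:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    welch_t: float
    df: float
    p: float


def cohort_stats(a, b) -> CohortStats:
    """Welch two-sample comparison (Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    n1, n2 = len(a), len(b)
    if v1 == 0 and v2 == 0:
        if a.mean() == b.mean():
            t, p, df = 0.0, 1.0, float(n1 + n2 - 2)
        else:
            t, p, df = float("inf") * np.sign(a.mean() - b.mean()), 0.0, float(n1 + n2 - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    return CohortStats(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        welch_t=t, df=float(df), p=p,
    )


def build_training_table(
    counts: pd.DataFrame,
    bf_table: pd.DataFrame,
    peaks: pd.DataFrame | None = None,
    bf_threshold: float = DEFAULT_BF_THRESHOLD,
    method: str = "mean",
    scale: bool = True,
) -> pd.DataFrame:
    """Assemble the labelled training table: guide_id, context sequence,
    inferred efficiency and (optionally) accessibility label.

    Applies LFC-based efficiency inference then the essentiality filter. With
    ``scale=True`` the retained guides' scores are min-max scaled to [0, 100]
    efficiency units (the scale the efficiency models train and predict on);
    the raw negative-mean-LFC score is kept in `efficiency_raw`. Requires a
    `context` column on the counts table.
    """
    if "context" not in counts.columns:
        raise ValueError("counts table needs a 'context' sequence column")
    scored = counts.copy()
    scored["efficiency"] = infer_efficiency(counts, method=method)
    kept = essentiality_filter(scored, bf_table, bf_threshold)
    if scale and len(kept) > 0:
        raw = kept["efficiency"].to_numpy(dtype=float)
        kept = kept.assign(efficiency_raw=raw)
        span = raw.max() - raw.min()
        kept["efficiency"] = (
            100.0 * (raw - raw.min()) / span if span > 0 else 50.0
        )
    cols = ["guide_id", "gene", "contig", "start", "end", "strand",
            "context", "efficiency", "bf"]
    if "efficiency_raw" in kept.columns:
        cols.append("efficiency_raw")
    out = kept[cols].copy()
    if peaks is not None:
        out["accessible"] = annotate_accessibility(out, peaks).to_numpy()
    return out
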