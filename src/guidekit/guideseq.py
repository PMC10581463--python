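"""Meta-analysis statistics over GUIDE-seq-style off-target read-count tables.

Input is a curated per-site table (one row per detected site) with columns
guide_id, site_id, mismatches, read_count, is_on_target. No raw sequencing
reads are processed here.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["guide_id", "site_id", "mismatches", "read_count", "is_on_target"]


def relative_cleavage(obs: pd.DataFrame) -> dict[int, list[float]]:
    """Per-site cleavage efficiency relative to the on-target site, in %.

    `obs` holds the observations for a single guide and must contain exactly
    one row flagged is_on_target with read_count > 0. Returns
    {mismatches: [100 * read_count / on_target_reads, ...]}.
    """
    on = obs[obs["is_on_target"].astype(bool)]
    if len(on) != 1:
        raise ValueError(f"expected exactly one on-target record, got {len(on)}")
    on_reads = float(on["read_count"].iloc[0])
    if on_reads <= 0:
        raise ValueError("on-target read count is zero; relative cleavage undefined")
    out: dict[int, list[float]] = {}
    for row in obs.itertuples():
        out.setdefault(int(row.mismatches), []).append(
            100.0 * float(row.read_count) / on_reads
        )
    return out


def relative_cleavage_table(obs: pd.DataFrame) -> pd.DataFrame:
    """Pooled relative-cleavage distribution over all guides.

    Guides whose on-target read count is zero (or which lack an on-target
    record) are excluded with a logged warning. Returns a tidy frame with
    columns guide_id, site_id, mismatches, relative_efficiency.
    """
    rows = []
    skipped = []
    for guide_id, sub in obs.groupby("guide_id"):
        try:
            per_site = relative_cleavage(sub)
        except ValueError:
            skipped.append(guide_id)
            continue
        for row in sub.itertuples():
            on_reads = float(
                sub.loc[sub["is_on_target"].astype(bool), "read_count"].iloc[0]
            )
            rows.append(
                {
                    "guide_id": guide_id,
                    "site_id": row.site_id,
                    "mismatches": int(row.mismatches),
                    "relative_efficiency": 100.0 * float(row.read_count) / on_reads,
                }
            )
        del per_site
    if skipped:
        logger.warning(
            "excluded %d guide(s) without usable on-target reads: %s",
            len(skipped),
            ", ".join(map(str, skipped)),
        )
    return pd.DataFrame(
        rows, columns=["guide_id", "site_id", "mismatches", "relative_efficiency"]
    )


def cleaved_fraction(
    predicted: dict[int, int], observed: pd.DataFrame
) -> dict[int, float]:
    """% of predicted off-target sites at each mismatch level with >=1 read.

    `predicted` maps mismatch level -> number of sequence-predicted sites;
    `observed` is the site table (a site counts as cleaved iff read_count >= 1).
    Levels with zero predicted sites are reported as NaN. Observed cleaved
    sites exceeding the predicted count at a level is a consistency error.
    """
    cleaved = (
        observed.loc[observed["read_count"] >= 1]
        .groupby("mismatches")["site_id"]
        .nunique()
        .to_dict()
    )
    out: dict[int, float] = {}
    for mm, n_pred in predicted.items():
        n_obs = int(cleaved.get(mm, 0))
        if n_pred == 0:
            out[mm] = float("nan")
            continue
        if n_obs > n_pred:
            raise ValueError(
                f"{n_obs} cleaved sites exceed {n_pred} predicted at {mm} mismatches"
            )
        out[mm] = 100.0 * n_obs / n_pred
    return out
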