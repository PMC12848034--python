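"""Table summaries of long-format metric results.

`summarize` aggregates per-(structure, source) mean ± sample SD for each
metric, skipping undefined (NaN) entries but reporting how many were
defined.  Cells whose mean crosses the conventional attention thresholds
(DSC < 0.7, RVD > 30%, HD95 > 5 mm, ASSD > 3 mm) are flagged — the same
rules used to bold problem structures in published evaluation tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["AttentionThresholds", "summarize"]


@dataclass(frozen=True)
class AttentionThresholds:
    """Means beyond these values are flagged for clinical review."""

    dsc_min: float = 0.7
    rvd_max_pct: float = 30.0
    hd95_max_mm: float = 5.0
    assd_max_mm: float = 3.0


_METRICS = ("dsc", "rvd_pct", "hd95_mm", "assd_mm")


def summarize(
    results: pd.DataFrame,
    thresholds: AttentionThresholds = AttentionThresholds(),
) -> pd.DataFrame:
    """Mean ± SD per (structure, source) from long-format metric rows.

    Expects columns ``structure, source`` plus any of ``dsc, rvd_pct,
    hd95_mm, assd_mm``.  Sample (n-1) standard deviations; undefined entries
    excluded with per-metric defined-counts reported.
    """
    if results.empty:
        logger.warning("summarize called with an empty results table")
        return pd.DataFrame()

    rows = []
    for (structure, source), group in results.groupby(["structure", "source"], sort=True):
        row: dict = {"structure": structure, "source": source, "n_rows": len(group)}
        for metric in _METRICS:
            if metric not in group.columns:
                continue
            vals = pd.to_numeric(group[metric], errors="coerce").dropna()
            row[f"{metric}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{metric}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[f"{metric}_n"] = len(vals)
        rows.append(row)
    out = pd.DataFrame(rows)

    flag_rules = {
        "dsc": lambda m: m < thresholds.dsc_min,
        "rvd_pct": lambda m: m > thresholds.rvd_max_pct,
        "hd95_mm": lambda m: m > thresholds.hd95_max_mm,
        "assd_mm": lambda m: m > thresholds.assd_max_mm,
    }
    for metric, rule in flag_rules.items():
        mean_col = f"{metric}_mean"
        if mean_col in out.columns:
            means = out[mean_col]
            out[f"{metric}_flag"] = np.where(means.notna() & rule(means), True, False)
    return out
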