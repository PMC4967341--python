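"""5mC / 5hmC inference from paired bisulfite and oxidative-bisulfite counts.

Bisulfite sequencing reads both 5mC and 5hmC as cytosine while oxBS reads
only 5mC, so per CpG

    fraction_5mc  = oxbs_meth / oxbs_total
    fraction_5hmc = max(0, bs_meth / bs_total - fraction_5mc)

with a ``clipped`` flag whenever the raw difference was negative. Standard
errors come from the delta method for a difference of two independent
binomial proportions. No hierarchical shrinkage is applied; the estimator is
the straight maximum-likelihood difference, which is unbiased before
clipping.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .regions import RegionSet

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["bs_meth", "bs_total", "oxbs_meth", "oxbs_total"]


def estimate_5hmc(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-site 5mC/5hmC estimates from paired BS/oxBS counts.

    ``pairs`` must carry :data:`PAIR_COLUMNS`; any other columns (chrom, pos,
    sample, timepoint, ...) are passed through. Sites with zero total in
    either assay are skipped (logged), so the output may have fewer rows.
    """
    for col in PAIR_COLUMNS:
        if col not in pairs.columns:
            raise ValueError(f"missing column {col}")
        if (pairs[col] < 0).any():
            raise ValueError(f"negative counts in {col}")
    if (pairs["bs_meth"] > pairs["bs_total"]).any() or (
        pairs["oxbs_meth"] > pairs["oxbs_total"]
    ).any():
        raise ValueError("requires meth <= total in both assays")
    usable = (pairs["bs_total"] > 0) & (pairs["oxbs_total"] > 0)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("skipping %d sites with zero coverage in one assay", n_skipped)
    out = pairs[usable].copy()
    p_bs = out["bs_meth"] / out["bs_total"]
    p_ox = out["oxbs_meth"] / out["oxbs_total"]
    raw = p_bs - p_ox
    out["fraction_5mc"] = p_ox
    out["fraction_5hmc"] = np.maximum(0.0, raw)
    out["clipped"] = raw < 0
    out["se_5mc"] = np.sqrt(p_ox * (1 - p_ox) / out["oxbs_total"])
    out["se_5hmc"] = np.sqrt(
        p_bs * (1 - p_bs) / out["bs_total"] + p_ox * (1 - p_ox) / out["oxbs_total"]
    )
    return out.reset_index(drop=True)


class HydroxymethylEstimator(BaseEstimator, TransformerMixin):
    """Transformer view of :func:`estimate_5hmc` for pipeline composition."""

    def fit(self, pairs: pd.DataFrame, y=None) -> "HydroxymethylEstimator":
        return self

    def transform(self, pairs: pd.DataFrame) -> pd.DataFrame:
        return estimate_5hmc(pairs)


def timecourse_summary(
    estimates: pd.DataFrame,
    regions: RegionSet,
    timepoint_col: str = "timepoint",
    timepoints: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Coverage-weighted region means of 5mC and 5hmC per timepoint.

    ``estimates`` is the output of :func:`estimate_5hmc` with additional
    ``chrom``, ``pos`` and timepoint columns. Regions without covered sites
    at a timepoint yield missing values. Rows are ordered by timepoint then
    region.
    """
    if timepoint_col not in estimates.columns:
        raise ValueError(f"missing column {timepoint_col}")
    tps = list(timepoints) if timepoints is not None else sorted(
        estimates[timepoint_col].unique()
    )
    rows = []
    for tp in tps:
        sub_t = estimates[estimates[timepoint_col] == tp]
        for i, r in enumerate(regions):
            sub = sub_t[
                (sub_t["chrom"] == r.chrom)
                & (sub_t["pos"] >= r.start)
                & (sub_t["pos"] < r.end)
            ]
            if len(sub):
                w = (sub["bs_total"] + sub["oxbs_total"]) / 2.0
                mc = float(np.average(sub["fraction_5mc"], weights=w))
                hmc = float(np.average(sub["fraction_5hmc"], weights=w))
            else:
                mc = hmc = np.nan
            rows.append(
                {
                    "timepoint": tp,
                    "region": r.attrs.get("name", f"region{i + 1}"),
                    "mean_5mc": mc,
                    "mean_5hmc": hmc,
                    "n_sites": len(sub),
                }
            )
    return pd.DataFrame(rows)
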