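"""Tri-category dialysis-clearance classification of changed features.

Among features significantly changed in disease (PRE vs CTRL):

* category I — elevated pre-dialysis and cleared by dialysis (significant
  >= clear_fc-fold drop in POST vs PRE);
* category II — elevated pre-dialysis but retained (no such drop);
* category III — decreased in disease relative to healthy controls.

Everything else is 'none'. The headline summary reports each category's
share of the total changed set (I + II + III).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CategoryCall:
    feature_id: str
    category: str  # I | II | III | none
    elevated: bool
    cleared: bool


@dataclass
class CategorySummary:
    counts: dict[str, int]
    total_changed: int
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fractions:
            self.fractions = {
                c: (round(100.0 * self.counts.get(c, 0) / self.total_changed, 1)
                    if self.total_changed else 0.0)
                for c in ("I", "II", "III")
            }


def classify_feature(
    log2fc_pre_ctrl: float,
    p_pre_ctrl: float,
    q_pre_ctrl: float,
    log2fc_post_pre: float,
    p_post_pre: float,
    elev_fc: float = 2.0,
    clear_fc: float = 2.0,
    alpha: float = 0.05,
    q_alpha: float = 0.05,
    cleared_requires_fc: bool = True,
) -> str:
    """Category call for one feature from its two contrast records.

    ``elevated`` means an up flag on PRE vs CTRL (p < alpha, q < q_alpha,
    log2fc >= log2(elev_fc)); ``cleared`` means a significant post-dialysis
    drop (p < alpha and, when ``cleared_requires_fc``, log2fc <=
    -log2(clear_fc); otherwise any significant decrease counts). Category
    III is the symmetric down flag on PRE vs CTRL, regardless of the
    dialysis response.
    """
    if any(np.isnan(v) for v in (log2fc_pre_ctrl, p_pre_ctrl, q_pre_ctrl)):
        return "none"
    sig_ec = p_pre_ctrl < alpha and q_pre_ctrl < q_alpha
    elevated = sig_ec and log2fc_pre_ctrl >= np.log2(elev_fc)
    decreased = sig_ec and log2fc_pre_ctrl <= -np.log2(elev_fc)
    if decreased:
        return "III"
    if not elevated:
        return "none"
    if np.isnan(p_post_pre) or np.isnan(log2fc_post_pre):
        cleared = False
    elif cleared_requires_fc:
        cleared = p_post_pre < alpha and log2fc_post_pre <= -np.log2(clear_fc)
    else:
        cleared = p_post_pre < alpha and log2fc_post_pre < 0
    return "I" if cleared else "II"


def classify_table(
    records: pd.DataFrame,
    elev_fc: float = 2.0,
    clear_fc: float = 2.0,
    alpha: float = 0.05,
    q_alpha: float = 0.05,
    cleared_requires_fc: bool = True,
) -> pd.Series:
    """Vectorized category calls over a differential-record frame.

    Expects the wide columns produced by ``run_contrasts``:
    ``log2fc_pre_ctrl``, ``p_pre_ctrl``, ``q_pre_ctrl``,
    ``log2fc_post_pre``, ``p_post_pre``.
    """
    required = ["log2fc_pre_ctrl", "p_pre_ctrl", "q_pre_ctrl",
                "log2fc_post_pre", "p_post_pre"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"differential records missing columns: {missing}")
    return pd.Series(
        [
            classify_feature(
                row.log2fc_pre_ctrl, row.p_pre_ctrl, row.q_pre_ctrl,
                row.log2fc_post_pre, row.p_post_pre,
                elev_fc=elev_fc, clear_fc=clear_fc,
                alpha=alpha, q_alpha=q_alpha,
                cleared_requires_fc=cleared_requires_fc,
            )
            for row in records.itertuples()
        ],
        index=records.index,
        name="category",
    )


def summarize_categories(categories) -> CategorySummary:
    """Counts and one-decimal percentages over the changed set (I+II+III).

    Accepts a sequence/Series of category labels or a mapping of
    pre-tabulated counts.
    """
    if isinstance(categories, dict):
        counts = {c: int(categories.get(c, 0)) for c in ("I", "II", "III")}
    else:
        vc = pd.Series(list(categories)).value_counts()
        counts = {c: int(vc.get(c, 0)) for c in ("I", "II", "III")}
    total = counts["I"] + counts["II"] + counts["III"]
    return CategorySummary(counts=counts, total_changed=total)
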