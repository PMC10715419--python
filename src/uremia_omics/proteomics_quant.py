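"""TMT reporter-intensity normalization and differential protein calls.

Reporter intensities are log2-transformed (zeros replaced by half the
smallest positive value) and quantile-normalized jointly across all 15
channels, after which each channel carries exactly the same sorted value
vector. Differential proteins are then called per contrast with the same
Welch/paired machinery as the metabolite stage, at the protein thresholds
(fold change > 1.5, p < 0.05, q < 0.05 by default).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ProteinQuantTable
from .differential_stats import adjust_fdr_bh, flag_significance, pseudocount
from scipy import stats

PROTEIN_CONTRASTS = {
    "pre_ctrl": ("PRE", "CTRL"),
    "post_pre": ("POST", "PRE"),
    "post_ctrl": ("POST", "CTRL"),
}


def quantile_normalize(values: pd.DataFrame, log_base: float | None = 2.0) -> pd.DataFrame:
    """Quantile-normalize columns (optionally after log transform).

    Each column's values are replaced by the across-column means of the
    order statistics at their rank; ties receive the mean over their rank
    block (pandas average ranks). After normalization every column has an
    identical sorted value vector. ``log_base=None`` skips the log step.
    """
    X = values.copy().astype(float)
    if (X.to_numpy() < 0).any():
        raise ValueError("intensities must be nonnegative")
    if ((X != 0).sum(axis=0) == 0).any():
        raise ValueError("all-zero channel cannot be normalized")
    if log_base is not None:
        pc = pseudocount(X)
        X = np.log(X.where(X > 0, pc)) / np.log(log_base)
    n = len(X)
    # rank-wise means over sorted columns
    sorted_means = np.sort(X.to_numpy(), axis=0).mean(axis=1)
    out = {}
    for c in X.columns:
        ranks = X[c].rank(method="average").to_numpy()  # 1-based, may be half-integer
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[c] = 0.5 * (sorted_means[lo] + sorted_means[hi])
    return pd.DataFrame(out, index=X.index)


def quantile_normalize_table(table: ProteinQuantTable, log_base: float = 2.0) -> pd.DataFrame:
    """Normalized log-scale matrix for a protein quant table."""
    return quantile_normalize(table.intensities, log_base=log_base)


def test_differential_proteins(
    table: ProteinQuantTable,
    fc_min: float = 1.5,
    alpha: float = 0.05,
    q_alpha: float = 0.05,
    contrasts: dict[str, tuple[str, str]] | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Differential protein records on quantile-normalized log2 values.

    Returns a wide frame with ``log2fc_<c>``, ``p_<c>``, ``q_<c>`` and
    ``flag_<c>`` per contrast (default: PRE vs CTRL, POST vs PRE, POST vs
    CTRL, all unpaired Welch tests — TMT channels are not subject-paired).
    """
    specs = contrasts or PROTEIN_CONTRASTS
    L = quantile_normalize_table(table)
    out = pd.DataFrame(index=L.index)
    for name, (ga, gb) in specs.items():
        cols_a = table.channels_with_group(ga)
        cols_b = table.channels_with_group(gb)
        if len(cols_a) < min_n or len(cols_b) < min_n:
            raise ValueError(f"contrast {name}: needs >= {min_n} channels per group")
        A = L[cols_a].to_numpy()
        B = L[cols_b].to_numpy()
        lfc = A.mean(axis=1) - B.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.asarray(
                stats.ttest_ind(A, B, axis=1, equal_var=False).pvalue, dtype=float
            )
        zero_var = (A.std(axis=1, ddof=1) == 0) & (B.std(axis=1, ddof=1) == 0)
        p = np.where(zero_var & np.isclose(lfc, 0.0), 1.0, p)
        p = np.where(zero_var & ~np.isclose(lfc, 0.0), 0.0, p)
        q = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            q[ok] = adjust_fdr_bh(p[ok])
        out[f"log2fc_{name}"] = lfc
        out[f"p_{name}"] = p
        out[f"q_{name}"] = q
        out[f"flag_{name}"] = flag_significance(
            lfc, p, q, fc_min=fc_min, alpha=alpha, q_alpha=q_alpha
        )
    return out
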