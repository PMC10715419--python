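"""Normalization and differential abundance for the three cohort contrasts.

The contrasts are PRE vs CTRL (disease effect), POST vs PRE (dialysis
effect, paired within patient) and POST vs CTRL (residual elevation).
Testing is on log2 intensities: Welch's t-test for unpaired contrasts, a
paired t-test when PRE/POST columns share subjects. Fold changes are
geometric — 2**(difference of group log2 means) — and multiple testing is
controlled per contrast with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable

CONTRASTS = ("pre_ctrl", "post_pre", "post_ctrl")

#: contrast name -> (numerator role, denominator role, paired by default)
CONTRAST_ROLES = {
    "pre_ctrl": ("PRE", "CTRL", False),
    "post_pre": ("POST", "PRE", True),
    "post_ctrl": ("POST", "CTRL", False),
}


@dataclass
class ContrastSpec:
    """One two-group comparison: role A vs role B (log2fc = A - B)."""

    name: str
    group_a: str
    group_b: str
    paired: bool = False

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")
        if self.paired and {self.group_a, self.group_b} != {"POST", "PRE"}:
            raise ValueError("paired testing is only defined for POST vs PRE")


def default_contrasts(paired_post_pre: bool = True) -> list[ContrastSpec]:
    return [
        ContrastSpec(name, a, b, paired and paired_post_pre)
        for name, (a, b, paired) in CONTRAST_ROLES.items()
    ]


def pseudocount(intensities: pd.DataFrame) -> float:
    """Half the smallest positive intensity: replaces zeros before log2."""
    arr = intensities.to_numpy()
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("intensity matrix has no positive values")
    return float(positive.min() / 2.0)


def log2_with_pseudocount(intensities: pd.DataFrame) -> pd.DataFrame:
    pc = pseudocount(intensities)
    return np.log2(intensities.where(intensities > 0, pc))


def normalize_intensities(table: FeatureTable, method: str = "median") -> FeatureTable:
    """Median scaling: each sample column is multiplied by the factor that
    brings its median (over its nonzero features) to the global target,
    the median of the biological columns' medians. QC and blank columns
    do not influence the target but are rescaled by their own factors.
    ``method='none'`` returns the table unchanged.
    """
    if method == "none":
        return table
    if method != "median":
        raise ValueError(f"unknown normalization method {method!r}")
    X = table.intensities
    col_medians = {}
    for c in X.columns:
        v = X[c].to_numpy()
        pos = v[v > 0]
        if pos.size == 0:
            raise ValueError(f"sample {c!r} is all zero; cannot normalize")
        col_medians[c] = np.median(pos)
    bio = table.biological_samples()
    target = float(np.median([col_medians[c] for c in bio]))
    scaled = X.copy()
    for c in X.columns:
        scaled[c] = X[c] * (target / col_medians[c])
    return FeatureTable(features=table.features.copy(), intensities=scaled,
                        roles=table.roles.copy(),
                        subjects=None if table.subjects is None else table.subjects.copy())


def test_contrast(
    table: FeatureTable,
    spec: ContrastSpec,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-feature log2 fold change, p and BH q for one contrast.

    Returns a frame indexed by feature id with columns ``log2fc``, ``p``,
    ``q``, ``n_a``, ``n_b`` and ``testable``. Features with fewer than
    ``min_n`` values in either group are flagged untestable and excluded
    from the FDR adjustment. Zero-variance cases are resolved exactly:
    equal means give p = 1, unequal means with zero spread give p = 0.
    """
    cols_a = table.samples_with_role(spec.group_a)
    cols_b = table.samples_with_role(spec.group_b)
    if len(cols_a) < min_n or len(cols_b) < min_n:
        raise ValueError(
            f"contrast {spec.name}: needs >= {min_n} samples per group "
            f"(got {len(cols_a)} vs {len(cols_b)})"
        )
    L = log2_with_pseudocount(table.intensities)
    if spec.paired:
        if table.subjects is None:
            raise ValueError("paired testing requires subject metadata")
        subj_a = {table.subjects[c]: c for c in cols_a}
        subj_b = {table.subjects[c]: c for c in cols_b}
        common = sorted(set(subj_a) & set(subj_b))
        if len(common) < min_n:
            raise ValueError("paired testing requires >= min_n complete pairs")
        A = L[[subj_a[s] for s in common]].to_numpy()
        B = L[[subj_b[s] for s in common]].to_numpy()
        diff = A - B
        lfc = diff.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # zero-variance features trip scipy's precision-loss warning;
            # they are resolved exactly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_rel(A, B, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
        zero_var = diff.std(axis=1, ddof=1) == 0
        n_a = n_b = len(common)
    else:
        A = L[cols_a].to_numpy()
        B = L[cols_b].to_numpy()
        lfc = A.mean(axis=1) - B.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(A, B, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        zero_var = (A.std(axis=1, ddof=1) == 0) & (B.std(axis=1, ddof=1) == 0)
        n_a, n_b = len(cols_a), len(cols_b)

    # exact resolution of degenerate (zero spread) features
    p = np.where(zero_var & np.isclose(lfc, 0.0), 1.0, p)
    p = np.where(zero_var & ~np.isclose(lfc, 0.0), 0.0, p)

    testable = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if testable.any():
        q[testable] = adjust_fdr_bh(p[testable])
    return pd.DataFrame(
        {"log2fc": lfc, "p": p, "q": q,
         "n_a": n_a, "n_b": n_b, "testable": testable},
        index=table.intensities.index,
    )


def adjust_fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, in [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flag_significance(
    log2fc: float | np.ndarray,
    p: float | np.ndarray,
    q: float | np.ndarray,
    fc_min: float = 2.0,
    alpha: float = 0.05,
    q_alpha: float = 0.05,
):
    """'up' / 'down' / 'ns' calls: p < alpha AND q < q_alpha AND
    |log2fc| >= log2(fc_min), with the sign giving the direction.
    Scalar inputs yield a scalar flag; array inputs an object array.
    """
    lfc = np.asarray(log2fc, dtype=float)
    pp = np.asarray(p, dtype=float)
    qq = np.asarray(q, dtype=float)
    thr = np.log2(fc_min)
    with np.errstate(invalid="ignore"):
        sig = (pp < alpha) & (qq < q_alpha)
        up = sig & (lfc >= thr)
        down = sig & (lfc <= -thr)
    flags = np.where(up, "up", np.where(down, "down", "ns"))
    if flags.ndim == 0:
        return str(flags)
    return flags.astype(object)


def run_contrasts(
    table: FeatureTable,
    contrasts: list[ContrastSpec] | None = None,
    fc_min: float = 2.0,
    alpha: float = 0.05,
    q_alpha: float = 0.05,
    min_n: int = 3,
) -> pd.DataFrame:
    """Differential records for all contrasts in one wide frame.

    Columns are ``log2fc_<name>``, ``p_<name>``, ``q_<name>`` and
    ``flag_<name>`` for each contrast.
    """
    specs = contrasts if contrasts is not None else default_contrasts(
        paired_post_pre=table.subjects is not None
    )
    out = pd.DataFrame(index=table.intensities.index)
    for spec in specs:
        res = test_contrast(table, spec, min_n=min_n)
        out[f"log2fc_{spec.name}"] = res["log2fc"]
        out[f"p_{spec.name}"] = res["p"]
        out[f"q_{spec.name}"] = res["q"]
        out[f"flag_{spec.name}"] = flag_significance(
            res["log2fc"].to_numpy(), res["p"].to_numpy(), res["q"].to_numpy(),
            fc_min=fc_min, alpha=alpha, q_alpha=q_alpha,
        )
    return out
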