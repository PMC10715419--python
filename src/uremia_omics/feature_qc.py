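"""Feature-level quality filters for untargeted LC-MS tables.

Four conjunctive rules remove unreliable features before statistics:

* CV of intensity across the pooled-QC injections >= 50% (unstable);
* mean biological intensity no more than 5-fold above the blank
  injections (background/carryover);
* chromatographic signal-to-noise <= 3;
* peak width < 6 scans (under-sampled peaks).

Boundary semantics: CV >= cv_max removed, blank ratio <= blank_ratio_min
removed, S/N <= snr_min removed, width < peak_width_min removed (a 6-scan
peak survives).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable


@dataclass
class FilterThresholds:
    cv_max: float = 50.0            # percent
    blank_ratio_min: float = 5.0    # fold over blank mean
    snr_min: float = 3.0
    peak_width_min: float = 6.0     # scans

    def validate(self) -> None:
        for name in ("cv_max", "blank_ratio_min", "snr_min", "peak_width_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class QCReport:
    """Per-rule firing counts plus the surviving feature ids.

    A feature can fire several rules; ``n_removed`` counts distinct
    features, so rule counts may sum to more than ``n_removed``.
    """

    n_input: int
    n_removed: int
    removed_by_cv: int
    removed_by_blank_ratio: int
    removed_by_snr: int
    removed_by_peak_width: int
    surviving: list[str] = field(default_factory=list)

    @property
    def n_surviving(self) -> int:
        return len(self.surviving)


def compute_cv(values) -> float:
    """Coefficient of variation, percent: 100 * sample SD / mean.

    Requires at least two values and a positive mean (sample SD uses the
    n-1 denominator).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires at least two values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined for nonpositive mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def blank_ratio(sample_mean: float, blank_mean: float, eps: float = 1e-12) -> float:
    """Fold change of mean biological intensity over mean blank intensity.

    A zero blank mean is floored at ``eps`` so blank-absent features pass
    the filter rather than dividing by zero.
    """
    if sample_mean < 0 or blank_mean < 0:
        raise ValueError("intensity means must be nonnegative")
    return float(sample_mean / max(blank_mean, eps))


def apply_feature_filters(
    table: FeatureTable,
    thresholds: FilterThresholds | None = None,
    cv_source: str = "QC",
) -> tuple[FeatureTable, QCReport]:
    """Apply the four filters in one conjunctive pass.

    A feature is removed if ANY rule fires; the report counts each rule's
    firings independently. ``cv_source`` selects the columns the CV uses:
    the pooled QC injections (default) or all biological samples.

    The blank-division floor is the smallest positive intensity in the
    table times 1e-3, so features absent from blanks keep a large, finite
    ratio.
    """
    t = thresholds or FilterThresholds()
    t.validate()
    if cv_source not in ("QC", "biological"):
        raise ValueError("cv_source must be 'QC' or 'biological'")

    cv_cols = table.samples_with_role("QC") if cv_source == "QC" else table.biological_samples()
    if len(cv_cols) < 2:
        raise ValueError(f"CV filter needs >= 2 {cv_source} samples")
    blank_cols = table.samples_with_role("BLANK")
    if not blank_cols:
        raise ValueError("blank-ratio filter needs >= 1 BLANK sample")
    bio_cols = table.biological_samples()

    X = table.intensities
    cv_vals = X[cv_cols].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = 100.0 * cv_vals.std(axis=1, ddof=1) / cv_vals.mean(axis=1)
    cv = np.where(np.isfinite(cv), cv, np.inf)  # zero/negative mean -> removed

    positive = X.to_numpy()
    positive = positive[positive > 0]
    eps = (positive.min() * 1e-3) if positive.size else 1e-12
    sample_mean = X[bio_cols].mean(axis=1).to_numpy()
    blank_mean = X[blank_cols].mean(axis=1).to_numpy()
    ratio = sample_mean / np.maximum(blank_mean, eps)

    fire_cv = cv >= t.cv_max
    fire_blank = ratio <= t.blank_ratio_min
    fire_snr = table.features["snr"].to_numpy() <= t.snr_min
    fire_width = table.features["peak_width_scans"].to_numpy() < t.peak_width_min
    fire_any = fire_cv | fire_blank | fire_snr | fire_width

    surviving = [fid for fid, rm in zip(table.features.index, fire_any) if not rm]
    report = QCReport(
        n_input=table.n_features,
        n_removed=int(fire_any.sum()),
        removed_by_cv=int(fire_cv.sum()),
        removed_by_blank_ratio=int(fire_blank.sum()),
        removed_by_snr=int(fire_snr.sum()),
        removed_by_peak_width=int(fire_width.sum()),
        surviving=surviving,
    )
    return table.subset(surviving), report
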