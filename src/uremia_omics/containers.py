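"""Core tabular containers shared across the pipeline.

The central object is :class:`FeatureTable`: an untargeted LC-MS feature
table (features x samples) carrying per-feature chromatographic metadata
(m/z, retention time, ionization mode, peak width, signal-to-noise) and a
role label per sample column (healthy control, pre-dialysis, post-dialysis,
pooled QC, or blank injection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

#: valid sample roles
ROLES = ("CTRL", "PRE", "POST", "QC", "BLANK")

#: per-feature metadata columns, in canonical order
FEATURE_META_COLUMNS = ("mz", "rt_min", "mode", "peak_width_scans", "snr")


@dataclass
class FeatureTable:
    """LC-MS feature table with sample roles and optional subject pairing.

    Parameters
    ----------
    features : pandas.DataFrame
        Indexed by feature id, with columns ``mz`` (Da), ``rt_min``
        (minutes), ``mode`` (``positive``/``negative``), ``peak_width_scans``
        and ``snr``.
    intensities : pandas.DataFrame
        Feature x sample intensity matrix; index must equal
        ``features.index``; all values nonnegative.
    roles : pandas.Series
        Maps each sample (column of ``intensities``) to one of
        ``CTRL``, ``PRE``, ``POST``, ``QC``, ``BLANK``.
    subjects : pandas.Series, optional
        Maps samples to subject ids; PRE/POST columns of the same patient
        share a subject id, which enables paired testing.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    roles: pd.Series
    subjects: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("feature metadata and intensity matrix indexes differ")
        missing = set(FEATURE_META_COLUMNS) - set(self.features.columns)
        if missing:
            raise ValueError(f"feature metadata missing columns: {sorted(missing)}")
        if set(self.intensities.columns) != set(self.roles.index):
            raise ValueError("every intensity column needs exactly one role")
        bad = set(self.roles.unique()) - set(ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be nonnegative")
        if (self.features["mz"] <= 0).any():
            raise ValueError("m/z values must be positive")
        if (self.features["rt_min"] < 0).any():
            raise ValueError("retention times must be nonnegative")

    # -- convenience selectors -------------------------------------------

    def samples_with_role(self, role: str) -> list[str]:
        """Sample names carrying ``role``, in column order."""
        keep = {s for s, r in self.roles.items() if r == role}
        return [c for c in self.intensities.columns if c in keep]

    def biological_samples(self) -> list[str]:
        """CTRL/PRE/POST columns (excludes QC pools and blanks)."""
        keep = {s for s, r in self.roles.items() if r in ("CTRL", "PRE", "POST")}
        return [c for c in self.intensities.columns if c in keep]

    @property
    def n_features(self) -> int:
        return len(self.features)

    def subset(self, feature_ids: Iterable[str]) -> "FeatureTable":
        """Restrict to the given feature ids (order preserved)."""
        idx = [f for f in self.features.index if f in set(feature_ids)]
        return FeatureTable(
            features=self.features.loc[idx].copy(),
            intensities=self.intensities.loc[idx].copy(),
            roles=self.roles.copy(),
            subjects=None if self.subjects is None else self.subjects.copy(),
        )

    # -- TSV round trip ---------------------------------------------------

    def to_tsv(self, feature_path: str | Path, roles_path: str | Path) -> None:
        """Write the table as two TSVs: features+intensities, and a
        sample-role sidecar (columns ``sample``, ``role``, ``subject``)."""
        out = self.features.loc[:, list(FEATURE_META_COLUMNS)].join(self.intensities)
        out.index.name = "feature_id"
        out.to_csv(feature_path, sep="\t")
        sidecar = pd.DataFrame(
            {
                "sample": list(self.intensities.columns),
                "role": [self.roles[s] for s in self.intensities.columns],
                "subject": [
                    "" if self.subjects is None or s not in self.subjects.index
                    else self.subjects[s]
                    for s in self.intensities.columns
                ],
            }
        )
        sidecar.to_csv(roles_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, feature_path: str | Path, roles_path: str | Path) -> "FeatureTable":
        df = pd.read_csv(feature_path, sep="\t", index_col="feature_id")
        sidecar = pd.read_csv(roles_path, sep="\t", dtype={"subject": str})
        features = df.loc[:, list(FEATURE_META_COLUMNS)]
        samples = [s for s in sidecar["sample"]]
        intensities = df.loc[:, samples]
        features.index.name = intensities.index.name = "feature_id"
        roles = pd.Series(sidecar["role"].values, index=samples)
        subj = sidecar["subject"].fillna("")
        subjects = None
        if (subj != "").any():
            mask = subj != ""
            subjects = pd.Series(
                subj[mask].values, index=sidecar["sample"][mask].values
            )
        return cls(features=features, intensities=intensities, roles=roles,
                   subjects=subjects)


@dataclass
class ProteinQuantTable:
    """TMT reporter-intensity matrix for serum proteins.

    ``intensities`` is protein x channel (15 channels by default: five per
    condition for CTRL, PRE and POST); ``channel_groups`` maps each channel
    to its condition; ``gene`` maps protein accession to gene symbol.
    """

    intensities: pd.DataFrame
    channel_groups: pd.Series
    gene: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        if set(self.intensities.columns) != set(self.channel_groups.index):
            raise ValueError("every channel needs exactly one group label")
        bad = set(self.channel_groups.unique()) - {"CTRL", "PRE", "POST"}
        if bad:
            raise ValueError(f"unknown channel groups: {sorted(bad)}")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("reporter intensities must be nonnegative")

    def channels_with_group(self, group: str) -> list[str]:
        keep = {c for c, g in self.channel_groups.items() if g == group}
        return [c for c in self.intensities.columns if c in keep]

    def to_tsv(self, table_path: str | Path, channel_map_path: str | Path) -> None:
        out = self.intensities.copy()
        out.insert(0, "gene", [self.gene.get(p, "") for p in out.index])
        out.index.name = "accession"
        out.to_csv(table_path, sep="\t")
        pd.DataFrame(
            {"channel": list(self.intensities.columns),
             "group": [self.channel_groups[c] for c in self.intensities.columns]}
        ).to_csv(channel_map_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, table_path: str | Path, channel_map_path: str | Path) -> "ProteinQuantTable":
        df = pd.read_csv(table_path, sep="\t", index_col="accession")
        cmap = pd.read_csv(channel_map_path, sep="\t")
        gene = df["gene"].fillna("")
        channels = list(cmap["channel"])
        return cls(
            intensities=df.loc[:, channels],
            channel_groups=pd.Series(cmap["group"].values, index=channels),
            gene=gene,
        )
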