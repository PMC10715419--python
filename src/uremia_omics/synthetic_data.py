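"""Synthetic cohort generator with planted ground truth.

Emulates the three-arm hemodialysis study design — healthy controls (CTRL),
matched end-stage kidney disease patients sampled before (PRE) and after
(POST) one dialysis session — at the level of processed data products:

* an LC-MS feature-intensity table with pooled-QC injections and blank
  runs, log-normal intensity noise, and planted effect features in three
  clearance categories (I: elevated in disease and removed by dialysis;
  II: elevated and retained; III: decreased in disease);
* a built-in library of 21 reference standards (uremic solutes confirmed
  in serum) with synthetic MS2 fragment spectra;
* a 15-channel TMT reporter-intensity protein matrix (five channels per
  condition) with planted differential proteins;
* STITCH-style metabolite-protein association edges with planted pairs;
* pathway sets (GMT) with one planted enriched set;
* four-parameter-logistic dose-viability tables.

Every generator is deterministic given its seed, and every planted effect
is reported in a ground-truth table so downstream stages can be scored for
recovery.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable, ProteinQuantTable
from .cytotox import DoseResponse
from .identification import MS2Spectrum, ReferenceStandard, adduct_mz, monoisotopic_mass
from .network import AssociationEdge

CATEGORIES = ("I", "II", "III", "unchanged")

#: the 21 serum metabolites confirmed by reference standards:
#: name, formula, observed m/z, mean RT (min), adduct, accession
_REFERENCE_COMPOUNDS: list[tuple[str, str, float, float, str, str]] = [
    ("2,3-Dihydroxybenzoic acid", "C7H6O4", 153.01921, 31.0, "[M-H]-", "HMDB0000397"),
    ("4-Hydroxyquinoline", "C9H7NO", 146.05943, 18.6, "[M+H]+", "PUBCHEMCID69141"),
    ("6-Methylcoumarin", "C10H8O2", 161.05898, 24.9, "[M+H]+", "HMDB0032394"),
    ("Caffeine", "C8H10N4O2", 195.08676, 15.0, "[M+H]+", "HMDB0001847"),
    ("Creatine anhydrous", "C4H9N3O2", 132.07625, 0.8, "[M+H]+", "HMDB0000064"),
    ("Creatinine", "C4H7N3O", 114.06605, 0.4, "[M+H]+", "HMDB0000562"),
    ("Famotidine", "C8H15N7O2S3", 338.05096, 10.3, "[M+H]+", "HMDB0001919"),
    ("L-Arginine", "C6H14N4O2", 175.1183, 0.2, "[M+H]+", "HMDB0000517"),
    ("L-Glutamine", "C5H10N2O3", 147.07596, 1.3, "[M+H]+", "HMDB0000641"),
    ("L-Kynurenine", "C10H12N2O3", 209.09135, 11.5, "[M+H]+", "HMDB0000684"),
    ("L-Leucine", "C6H13NO2", 132.10136, 4.5, "[M+H]+", "HMDB0000687"),
    ("L-Phenylalanine", "C9H11NO2", 166.08556, 10.4, "[M+H]+", "HMDB0000159"),
    ("L-Proline", "C5H9NO2", 116.07044, 2.9, "[M+H]+", "HMDB0000162"),
    ("L-Tryptophan", "C11H12N2O2", 205.09622, 12.3, "[M+H]+", "HMDB0000929"),
    ("L-Tyrosine", "C9H11NO3", 182.08064, 4.3, "[M+H]+", "HMDB0000158"),
    ("LPC 16:0", "C24H50NO7P", 496.3385, 35.5, "[M+H]+", "HMDB0010382"),
    ("Piperine", "C17H19NO3", 286.1423, 31.3, "[M+H]+", "HMDB0029377"),
    ("Riboflavin", "C17H20N4O6", 375.13385, 15.5, "[M-H]-", "HMDB0000244"),
    ("Taurine", "C2H7NO3S", 124.00748, 1.3, "[M-H]-", "HMDB0000251"),
    ("Theobromine", "C7H8N4O2", 181.07126, 12.2, "[M+H]+", "HMDB0002825"),
    ("Uracil", "C4H4N2O2", 113.03434, 7.5, "[M+H]+", "HMDB0000300"),
]

REFERENCE_COMPOUND_NAMES = tuple(row[0] for row in _REFERENCE_COMPOUNDS)


@dataclass
class SynthConfig:
    """Study-design parameters for the synthetic cohort.

    ``n_per_group`` mirrors the real cohort (10 patients, matched PRE/POST,
    10 healthy controls). Effect sizes are fold changes on the raw
    intensity scale: ``effect_fc_up`` for the disease elevation (or the
    reciprocal depletion of category III), ``clearance_fc`` for the
    post-dialysis drop of category-I features. ``noise_sigma`` is the
    log2-scale SD of the per-measurement noise; ``subject_sigma`` the
    log2-scale SD of the shared patient baseline carried by each PRE/POST
    pair (0 keeps noiseless runs fully deterministic).
    """

    n_features: int = 2000
    n_per_group: int = 10
    frac_catI: float = 0.083
    frac_catII: float = 0.056
    frac_catIII: float = 0.022
    effect_fc_up: float = 8.0
    clearance_fc: float = 4.0
    noise_sigma: float = 0.25
    subject_sigma: float = 0.0
    n_qc: int = 5
    n_blank: int = 3
    seed: int = 0
    #: blanks sit at 1/50 of the mean biological intensity, so genuine
    #: features clear the default blank-ratio filter (ratio 50 >> 5)
    blank_attenuation: float = 50.0
    #: QC pools re-measure the pooled mean with a fraction of the sample noise
    qc_noise_frac: float = 0.2

    def validate(self) -> None:
        fr = self.frac_catI + self.frac_catII + self.frac_catIII
        if not (0 <= self.frac_catI and 0 <= self.frac_catII and 0 <= self.frac_catIII):
            raise ValueError("category fractions must be nonnegative")
        if fr > 1 + 1e-12:
            raise ValueError(f"category fractions sum to {fr:.3f} > 1")
        for name in ("n_features", "n_per_group", "n_qc", "n_blank"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.effect_fc_up <= 0 or self.clearance_fc <= 0:
            raise ValueError("fold changes must be positive")
        if self.noise_sigma < 0 or self.subject_sigma < 0:
            raise ValueError("noise SDs must be nonnegative")


def _category_counts(config: SynthConfig) -> dict[str, int]:
    n = config.n_features
    nI = int(round(config.frac_catI * n))
    nII = int(round(config.frac_catII * n))
    nIII = int(round(config.frac_catIII * n))
    if nI + nII + nIII > n:
        raise ValueError("rounded category counts exceed n_features")
    return {"I": nI, "II": nII, "III": nIII, "unchanged": n - nI - nII - nIII}


def generate_cohort(
    config: SynthConfig,
    standards: list[ReferenceStandard] | None = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Simulate the three-arm cohort feature table plus ground truth.

    Intensities are log-normal: each measurement is 2**(mu + noise) where
    mu encodes the planted group means. Category I features are elevated
    ``effect_fc_up``-fold in PRE vs CTRL and drop ``clearance_fc``-fold in
    POST vs PRE; category II features stay at the elevated level post
    dialysis; category III features are depleted in both patient arms.
    PRE/POST columns of one patient share a subject baseline offset, so
    the table supports paired testing. QC columns resample the pooled mean
    of all biological samples; blank columns sit near zero.

    When ``standards`` are supplied, the first planted elevated features
    adopt each standard's identity (theoretical adduct m/z, RT, polarity),
    which lets the identification stage be exercised against the library.

    Returns the feature table and a ground-truth frame with columns
    ``planted_category``, ``planted_log2fc_pre_ctrl``,
    ``planted_log2fc_post_pre`` and ``planted_identity``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = _category_counts(config)
    n = config.n_features
    categories = np.array(
        ["I"] * counts["I"] + ["II"] * counts["II"] + ["III"] * counts["III"]
        + ["unchanged"] * counts["unchanged"]
    )

    up = np.log2(config.effect_fc_up)
    clear = np.log2(config.clearance_fc)
    lfc_pre_ctrl = np.select(
        [categories == "I", categories == "II", categories == "III"],
        [up, up, -up], default=0.0,
    )
    lfc_post_pre = np.where(categories == "I", -clear, 0.0)

    feature_ids = [f"F{i + 1:05d}" for i in range(n)]
    mz = rng.uniform(70.0, 1000.0, size=n)
    rt = rng.uniform(0.2, 40.0, size=n)
    mode = np.where(rng.random(n) < 0.6, "positive", "negative")
    peak_width = rng.integers(6, 31, size=n)
    snr = rng.uniform(5.0, 100.0, size=n)

    identity = np.array([""] * n, dtype=object)
    if standards:
        elevated_idx = np.flatnonzero((categories == "I") | (categories == "II"))
        if len(standards) > elevated_idx.size:
            raise ValueError(
                f"{len(standards)} identities requested but only "
                f"{elevated_idx.size} elevated features planted"
            )
        for k, std in enumerate(standards):
            i = elevated_idx[k]
            identity[i] = std.name
            mz[i] = std.theoretical_mz
            rt[i] = std.rt
            mode[i] = std.mode

    base = rng.uniform(14.0, 20.0, size=n)  # log2 CTRL group mean

    npg = config.n_per_group
    ctrl_cols = [f"CTRL_{j + 1:02d}" for j in range(npg)]
    pre_cols = [f"PRE_{j + 1:02d}" for j in range(npg)]
    post_cols = [f"POST_{j + 1:02d}" for j in range(npg)]
    qc_cols = [f"QC_{j + 1:02d}" for j in range(config.n_qc)]
    blank_cols = [f"BLANK_{j + 1:02d}" for j in range(config.n_blank)]

    sigma = config.noise_sigma
    subj = rng.normal(0.0, config.subject_sigma, size=npg) if config.subject_sigma > 0 else np.zeros(npg)

    log2 = {}
    for j, c in enumerate(ctrl_cols):
        log2[c] = base + rng.normal(0.0, sigma, size=n) if sigma > 0 else base.copy()
    for j, c in enumerate(pre_cols):
        mu = base + subj[j] + lfc_pre_ctrl
        log2[c] = mu + rng.normal(0.0, sigma, size=n) if sigma > 0 else mu
    for j, c in enumerate(post_cols):
        mu = base + subj[j] + lfc_pre_ctrl + lfc_post_pre
        log2[c] = mu + rng.normal(0.0, sigma, size=n) if sigma > 0 else mu

    bio = pd.DataFrame({c: 2.0 ** v for c, v in log2.items()}, index=feature_ids)
    pooled_mean = bio.mean(axis=1).to_numpy()

    qc_sigma = sigma * config.qc_noise_frac
    data = {c: bio[c].to_numpy() for c in bio.columns}
    for c in qc_cols:
        noise = rng.normal(0.0, qc_sigma, size=n) if qc_sigma > 0 else 0.0
        data[c] = pooled_mean * 2.0 ** noise
    blank_level = pooled_mean / config.blank_attenuation
    for c in blank_cols:
        noise = rng.normal(0.0, sigma, size=n) if sigma > 0 else 0.0
        data[c] = blank_level * 2.0 ** noise

    all_cols = ctrl_cols + pre_cols + post_cols + qc_cols + blank_cols
    index = pd.Index(feature_ids, name="feature_id")
    intensities = pd.DataFrame({c: data[c] for c in all_cols}, index=index)
    roles = pd.Series(
        ["CTRL"] * npg + ["PRE"] * npg + ["POST"] * npg
        + ["QC"] * config.n_qc + ["BLANK"] * config.n_blank,
        index=all_cols,
    )
    subjects = pd.Series(
        {**{c: f"C{j + 1:02d}" for j, c in enumerate(ctrl_cols)},
         **{c: f"S{j + 1:02d}" for j, c in enumerate(pre_cols)},
         **{c: f"S{j + 1:02d}" for j, c in enumerate(post_cols)}}
    )
    features = pd.DataFrame(
        {"mz": mz, "rt_min": rt, "mode": mode,
         "peak_width_scans": peak_width, "snr": snr},
        index=index,
    )
    table = FeatureTable(features=features, intensities=intensities,
                         roles=roles, subjects=subjects)
    truth = pd.DataFrame(
        {
            "planted_category": categories,
            "planted_log2fc_pre_ctrl": lfc_pre_ctrl,
            "planted_log2fc_post_pre": lfc_post_pre,
            "planted_identity": identity,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return table, truth


def synthetic_spectrum(name: str, precursor_mz: float, mode: str,
                       n_fragments: int = 12) -> MS2Spectrum:
    """Deterministic synthetic MS2 fragment spectrum for a compound.

    Fragment positions and intensities are drawn from an RNG seeded by a
    CRC32 of the compound name, so the same compound always yields the
    same spectrum without any global seed.
    """
    rng = np.random.default_rng(zlib.crc32(name.encode("utf8")) & 0x7FFFFFFF)
    lo = min(50.0, precursor_mz * 0.4)
    frag_mz = np.sort(rng.uniform(lo, max(precursor_mz - 1.0, lo + 1.0), size=n_fragments))
    frag_int = rng.uniform(0.05, 1.0, size=n_fragments)
    return MS2Spectrum(precursor_mz=precursor_mz, mode=mode,
                       mz=frag_mz, intensities=frag_int)


def generate_reference_library(names: list[str] | None = None) -> list[ReferenceStandard]:
    """Build reference standards from the built-in 21-compound table.

    ``names=None`` returns the full library; unknown names raise KeyError.
    Each standard carries its formula, adduct, observed m/z and RT from
    the standards run, plus a synthetic MS2 fragment list.
    """
    by_name = {row[0]: row for row in _REFERENCE_COMPOUNDS}
    if names is None:
        names = list(REFERENCE_COMPOUND_NAMES)
    out = []
    for name in names:
        if name not in by_name:
            raise KeyError(f"unknown reference compound {name!r}")
        _, formula, obs_mz, rt, adduct, accession = by_name[name]
        mode = "positive" if adduct.endswith("+") else "negative"
        out.append(
            ReferenceStandard(
                name=name, formula=formula, adduct=adduct, observed_mz=obs_mz,
                rt=rt, spectrum=synthetic_spectrum(name, obs_mz, mode),
                accession=accession,
            )
        )
    return out


def perturb_spectrum(spectrum: MS2Spectrum, jitter_da: float = 0.0,
                     drop_frac: float = 0.0, seed: int = 0) -> MS2Spectrum:
    """Degrade a spectrum: drop floor(drop_frac * n) random fragments and
    jitter each surviving m/z by Uniform(-jitter_da, +jitter_da)."""
    if not 0 <= drop_frac < 1:
        raise ValueError("drop_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = spectrum.n_peaks
    n_drop = int(np.floor(drop_frac * n))
    keep = np.sort(rng.choice(n, size=n - n_drop, replace=False))
    mz = spectrum.mz[keep].copy()
    if jitter_da > 0:
        mz = mz + rng.uniform(-jitter_da, jitter_da, size=mz.size)
    return MS2Spectrum(precursor_mz=spectrum.precursor_mz, mode=spectrum.mode,
                       mz=mz, intensities=spectrum.intensities[keep].copy())


def generate_tmt_proteome(
    n_proteins: int = 600,
    n_diff: int = 83,
    fc: float = 2.0,
    n_channels_per_group: int = 5,
    noise_sigma: float = 0.2,
    seed: int = 0,
    persistent: bool = True,
) -> tuple[ProteinQuantTable, pd.DataFrame]:
    """Simulate a TMT reporter-intensity matrix with planted up proteins.

    Three conditions (CTRL, PRE, POST) with ``n_channels_per_group``
    channels each (default five, i.e. a 15-plex split). The first
    ``n_diff`` proteins are elevated ``fc``-fold in the patient arms; with
    ``persistent`` they remain elevated post dialysis (the dominant
    pattern in serum, where dialysis barely shifts the proteome).
    """
    if n_diff > n_proteins:
        raise ValueError("n_diff cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    ids = [f"P{i + 1:05d}" for i in range(n_proteins)]
    genes = pd.Series([f"GENE{i + 1}" for i in range(n_proteins)], index=ids)
    base = rng.uniform(16.0, 24.0, size=n_proteins)
    lfc = np.zeros(n_proteins)
    lfc[:n_diff] = np.log2(fc)

    groups, cols = [], []
    for g in ("CTRL", "PRE", "POST"):
        for j in range(n_channels_per_group):
            cols.append(f"{g}_{j + 1:02d}")
            groups.append(g)
    data = {}
    for col, g in zip(cols, groups):
        mu = base.copy()
        if g == "PRE" or (g == "POST" and persistent):
            mu = mu + lfc
        noise = rng.normal(0.0, noise_sigma, size=n_proteins) if noise_sigma > 0 else 0.0
        data[col] = 2.0 ** (mu + noise)
    table = ProteinQuantTable(
        intensities=pd.DataFrame(data, index=ids),
        channel_groups=pd.Series(groups, index=cols),
        gene=genes,
    )
    truth = pd.DataFrame(
        {"planted_diff": lfc != 0, "planted_log2fc": lfc,
         "gene": genes.values},
        index=pd.Index(ids, name="protein_id"),
    )
    return table, truth


def generate_association_edges(
    metabolite_ids: list[str],
    protein_ids: list[str],
    density: float = 0.0,
    planted_pairs: list[tuple[str, str]] | None = None,
    seed: int = 0,
    planted_score: float = 0.9,
) -> list[AssociationEdge]:
    """STITCH-style metabolite-protein edges: all planted pairs (at a high
    confidence score) plus Bernoulli(density) random extra edges with
    scores uniform on (0, 1]."""
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    planted = {(m, p) for m, p in (planted_pairs or [])}
    edges = [AssociationEdge(m, p, planted_score) for m, p in sorted(planted)]
    if density > 0:
        hit = rng.random((len(metabolite_ids), len(protein_ids))) < density
        scores = rng.uniform(0.0, 1.0, size=hit.shape)
        for i, m in enumerate(metabolite_ids):
            for j, p in enumerate(protein_ids):
                if hit[i, j] and (m, p) not in planted:
                    edges.append(AssociationEdge(m, p, max(scores[i, j], 1e-9)))
    return edges


def generate_pathway_sets(
    universe_ids: list[str],
    planted_members: list[str],
    n_random_sets: int = 20,
    set_size: int = 15,
    seed: int = 0,
    planted_name: str = "planted_pathway",
) -> dict[str, list[str]]:
    """Pathway sets for enrichment testing: one planted set composed of
    the given members, plus random sets drawn from the universe."""
    rng = np.random.default_rng(seed)
    sets = {planted_name: list(planted_members)}
    size = min(set_size, len(universe_ids))
    for k in range(n_random_sets):
        members = rng.choice(universe_ids, size=size, replace=False)
        sets[f"random_pathway_{k + 1:02d}"] = sorted(members.tolist())
    return sets


def generate_dose_response(
    ic50: float,
    hill: float = 1.0,
    top: float = 1.0,
    bottom: float = 0.0,
    doses: list[float] | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 5,
    seed: int = 0,
    compound: str = "compound",
) -> DoseResponse:
    """Simulate a viability dose-response experiment from a 4PL curve.

    Default doses follow the assay's serial dilution (100 uM down to
    10 nM); each dose is measured in ``n_replicates`` wells with additive
    Gaussian noise on the viability fraction.
    """
    if doses is None:
        doses = [100.0, 10.0, 1.0, 0.1, 0.01]
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be strictly positive")
    rng = np.random.default_rng(seed)
    d = np.repeat(doses, n_replicates)
    y = bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    replicate = np.tile(np.arange(1, n_replicates + 1), doses.size)
    return DoseResponse(compound=compound, doses=d, responses=y, replicates=replicate)
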