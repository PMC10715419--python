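"""Reference-standard identity confirmation for LC-MS features.

A putative metabolite is confirmed against an authentic chemical standard by
three orthogonal criteria, each with its own tolerance:

* accurate mass — ppm deviation of the observed feature m/z from the
  theoretical adduct m/z computed from the standard's molecular formula
  (default tolerance 1 ppm in positive mode, 2 ppm in negative mode);
* retention time — absolute RT shift within a window (default 2.0 min);
* MS2 similarity — cosine score between the feature's fragmentation
  spectrum and the standard's, on square-root intensities after greedy
  nearest-peak pairing within a fragment m/z tolerance (default 0.05 Da),
  confirmed at score >= 0.7.

All three must pass for a confirmed identification (``--allow-no-ms2``
relaxes the spectral criterion for features acquired without MS2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _ptmass
from pyteomics.auxiliary import PyteomicsError

#: mass of a proton, Da (charge carrier for [M+H]+ / [M-H]-)
PROTON_MASS = 1.007276466621

SUPPORTED_ADDUCTS = ("[M+H]+", "[M-H]-")

#: default accurate-mass tolerance per ionization mode, ppm
DEFAULT_PPM_TOL = {"positive": 1.0, "negative": 2.0}


@dataclass
class MS2Spectrum:
    """Fragmentation spectrum: precursor m/z, polarity and (m/z, intensity)
    peak list kept sorted by m/z."""

    precursor_mz: float
    mode: str
    mz: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz.size == 0:
            raise ValueError("spectrum must contain at least one peak")
        if self.mz.size != self.intensities.size:
            raise ValueError("m/z and intensity arrays differ in length")
        if (self.intensities < 0).any():
            raise ValueError("peak intensities must be nonnegative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensities = self.intensities[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class ReferenceStandard:
    """Authentic chemical standard: the identity ground truth for one
    compound (molecular formula, adduct, observed m/z and RT from the
    standards run, MS2 spectrum, database accession)."""

    name: str
    formula: str
    adduct: str
    observed_mz: float
    rt: float
    spectrum: MS2Spectrum | None = None
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.formula:
            raise ValueError("reference standard requires a molecular formula")
        if self.adduct not in SUPPORTED_ADDUCTS:
            raise ValueError(f"unsupported adduct {self.adduct!r}")

    @property
    def mode(self) -> str:
        return "positive" if self.adduct.endswith("+") else "negative"

    @property
    def theoretical_mz(self) -> float:
        """Theoretical adduct m/z from the molecular formula."""
        return adduct_mz(monoisotopic_mass(self.formula), self.adduct)


@dataclass
class MatchResult:
    """Outcome of matching one feature against one reference standard."""

    feature_id: str
    standard_name: str
    ppm_error: float
    rt_delta: float
    ms2_score: float | None
    mass_ok: bool
    rt_ok: bool
    ms2_ok: bool
    confirmed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.confirmed = self.mass_ok and self.rt_ok and self.ms2_ok


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a molecular formula, Da.

    An empty formula has mass 0; unknown element symbols raise ValueError.
    """
    if not formula:
        return 0.0
    try:
        return float(_ptmass.calculate_mass(formula=formula))
    except PyteomicsError as exc:
        raise ValueError(f"cannot parse molecular formula {formula!r}: {exc}") from exc


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged adduct: M + p for [M+H]+, M - p for [M-H]-."""
    if adduct == "[M+H]+":
        return neutral_mass + PROTON_MASS
    if adduct == "[M-H]-":
        return neutral_mass - PROTON_MASS
    raise ValueError(f"unsupported adduct {adduct!r}; expected one of {SUPPORTED_ADDUCTS}")


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass deviation |obs - theo| / theo * 1e6, ppm."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return abs(observed - theoretical) / theoretical * 1e6


def _greedy_peak_pairs(mz_a: np.ndarray, mz_b: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """Greedy one-to-one peak pairing by ascending m/z distance.

    Candidate pairs within ``tol`` are accepted smallest-distance first;
    exact distance ties go to the pair with the lower m/z.
    """
    ia, ib = np.nonzero(np.abs(mz_a[:, None] - mz_b[None, :]) <= tol)
    if ia.size == 0:
        return []
    dist = np.abs(mz_a[ia] - mz_b[ib])
    order = sorted(range(ia.size), key=lambda k: (dist[k], mz_a[ia[k]], mz_b[ib[k]]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for k in order:
        i, j = int(ia[k]), int(ib[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def spectral_similarity(a: MS2Spectrum, b: MS2Spectrum, frag_tol: float = 0.05) -> float:
    """Square-root-intensity cosine similarity between two MS2 spectra.

    Peaks are paired greedily within ``frag_tol`` Da; the score is the dot
    product of sqrt intensities over matched pairs divided by the product
    of the full sqrt-intensity vector norms, so unmatched peaks in either
    spectrum lower the score. Identical spectra score 1, spectra with no
    shared fragments score 0.
    """
    pairs = _greedy_peak_pairs(a.mz, b.mz, frag_tol)
    sa = np.sqrt(a.intensities)
    sb = np.sqrt(b.intensities)
    denom = np.linalg.norm(sa) * np.linalg.norm(sb)
    if denom == 0:
        return 0.0
    num = sum(sa[i] * sb[j] for i, j in pairs)
    return float(min(1.0, num / denom))


def match_feature_to_standard(
    feature_id: str,
    feature_mz: float,
    feature_rt: float,
    feature_mode: str,
    spectrum: MS2Spectrum | None,
    standard: ReferenceStandard,
    rt_window: float = 2.0,
    ppm_tol_pos: float = 1.0,
    ppm_tol_neg: float = 2.0,
    frag_tol: float = 0.05,
    score_min: float = 0.7,
    allow_no_ms2: bool = False,
) -> MatchResult:
    """Confirm one feature against one reference standard.

    Accurate mass is compared against the *theoretical* adduct m/z computed
    from the standard's formula (not its observed m/z from the standards
    run), with the mode-dependent ppm tolerance. The feature's polarity
    must match the standard's adduct polarity.
    """
    if feature_mode != standard.mode:
        raise ValueError(
            f"polarity mismatch: feature is {feature_mode}, standard "
            f"{standard.name!r} is {standard.mode}"
        )
    theo = standard.theoretical_mz
    ppm = ppm_error(feature_mz, theo)
    tol = ppm_tol_pos if feature_mode == "positive" else ppm_tol_neg
    mass_ok = ppm <= tol
    rt_delta = feature_rt - standard.rt
    rt_ok = abs(rt_delta) <= rt_window
    if spectrum is None or standard.spectrum is None:
        score = None
        ms2_ok = bool(allow_no_ms2)
    else:
        score = spectral_similarity(spectrum, standard.spectrum, frag_tol)
        ms2_ok = score >= score_min
    return MatchResult(
        feature_id=feature_id,
        standard_name=standard.name,
        ppm_error=ppm,
        rt_delta=rt_delta,
        ms2_score=score,
        mass_ok=mass_ok,
        rt_ok=rt_ok,
        ms2_ok=ms2_ok,
    )
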