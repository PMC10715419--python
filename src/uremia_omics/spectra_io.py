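"""Read/write MS2 spectra and reference-standard libraries (MSP, MGF).

MSP carries the reference library (matchms under the hood); MGF carries
per-feature experimental spectra (pyteomics under the hood).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
from matchms import Spectrum as _MatchmsSpectrum
from matchms.exporting import save_as_msp
from matchms.importing import load_from_msp
from pyteomics import mgf as _mgf

from .identification import MS2Spectrum, ReferenceStandard


def write_standards_msp(standards: Iterable[ReferenceStandard], path: str | Path) -> None:
    """Write a reference-standard library as an MSP spectral library."""
    records = []
    for std in standards:
        if std.spectrum is None:
            raise ValueError(f"standard {std.name!r} has no spectrum to export")
        records.append(
            _MatchmsSpectrum(
                mz=np.asarray(std.spectrum.mz, dtype=float),
                intensities=np.asarray(std.spectrum.intensities, dtype=float),
                metadata={
                    "compound_name": std.name,
                    "formula": std.formula,
                    "adduct": std.adduct,
                    "precursor_mz": float(std.observed_mz),
                    "retention_time": float(std.rt),
                    "ionmode": std.mode,
                    "accession": std.accession,
                },
                metadata_harmonization=False,
            )
        )
    path = Path(path)
    if path.exists():  # matchms appends to existing MSP files
        path.unlink()
    save_as_msp(records, str(path))


def read_standards_msp(path: str | Path) -> list[ReferenceStandard]:
    """Load a reference-standard library from MSP."""
    out = []
    for rec in load_from_msp(str(path), metadata_harmonization=False):
        meta = rec.metadata
        precursor = float(meta["precursor_mz"])
        adduct = meta["adduct"]
        out.append(
            ReferenceStandard(
                name=meta["compound_name"],
                formula=meta["formula"],
                adduct=adduct,
                observed_mz=precursor,
                rt=float(meta["retention_time"]),
                spectrum=MS2Spectrum(
                    precursor_mz=precursor,
                    mode="positive" if adduct.endswith("+") else "negative",
                    mz=rec.peaks.mz,
                    intensities=rec.peaks.intensities,
                ),
                accession=str(meta.get("accession", "")),
            )
        )
    return out


def write_spectra_mgf(spectra: dict[str, MS2Spectrum], path: str | Path) -> None:
    """Write feature MS2 spectra as MGF; the TITLE field holds the feature id."""
    entries = []
    for feature_id, spec in spectra.items():
        entries.append(
            {
                "m/z array": spec.mz,
                "intensity array": spec.intensities,
                "params": {
                    "title": feature_id,
                    "pepmass": (spec.precursor_mz, None),
                    "ionmode": spec.mode,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_spectra_mgf(path: str | Path) -> dict[str, MS2Spectrum]:
    """Load feature MS2 spectra from MGF keyed by TITLE (feature id)."""
    out: dict[str, MS2Spectrum] = {}
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            out[params["title"]] = MS2Spectrum(
                precursor_mz=float(params["pepmass"][0]),
                mode=params.get("ionmode", "positive"),
                mz=entry["m/z array"],
                intensities=entry["intensity array"],
            )
    return out
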