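"""Readers and writers for the formats the pipeline touches.

Peak lists are read from MGF or mzML through pyteomics; FASTA likewise.
Tabular outputs are TSV (composition strings contain parentheses, so tabs are
the safe delimiter), written with deterministic column and row order; every
writer goes through a temp-then-rename step so an error never leaves a partial
primary output behind.  m/z values are reported to 4 decimal places.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import fasta as _pfasta
from pyteomics import mgf as _pmgf

from .annotation import AnnotationResult, Spectrum

__all__ = [
    "read_peaklists",
    "read_fasta",
    "write_fasta",
    "write_mgf",
    "write_tsv",
    "write_json",
    "annotation_report",
]


class PeaklistError(ValueError):
    """Raised for malformed peak-list entries."""


def _atomic_write(path, write_fn, mode="w"):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    try:
        with os.fdopen(fd, mode) as handle:
            write_fn(handle)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_peaklists(
    path, scan_low: float = 115.0, scan_high: float = 2000.0
) -> list[Spectrum]:
    """Read spectra from an MGF or mzML file (by extension).

    MGF TITLE/PEPMASS/CHARGE are honored; a spectrum lacking PEPMASS raises,
    while a missing charge keeps the spectrum with charge 0 (flagged unknown).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    out: list[Spectrum] = []
    if suffix == ".mgf":
        with _pmgf.MGF(str(path)) as reader:
            for ordinal, entry in enumerate(reader, 1):
                params = entry.get("params", {})
                title = str(params.get("title", f"spectrum{ordinal}"))
                pepmass = params.get("pepmass")
                if not pepmass or pepmass[0] is None:
                    raise PeaklistError(f"spectrum {ordinal}: missing PEPMASS")
                charge_field = params.get("charge")
                charge = int(charge_field[0]) if charge_field else 0
                peaks = tuple(
                    zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())
                )
                out.append(
                    Spectrum(
                        spectrum_id=title,
                        precursor_mz=float(pepmass[0]),
                        precursor_charge=charge,
                        peaks=peaks,
                        scan_low=scan_low,
                        scan_high=scan_high,
                    )
                )
    elif suffix == ".mzml":
        from pyteomics import mzml as _pmzml

        with _pmzml.MzML(str(path)) as reader:
            for ordinal, entry in enumerate(reader, 1):
                if entry.get("ms level") != 2:
                    continue
                try:
                    precursor = entry["precursorList"]["precursor"][0][
                        "selectedIonList"]["selectedIon"][0]
                    pmz = float(precursor["selected ion m/z"])
                    charge = int(precursor.get("charge state", 0))
                except (KeyError, IndexError) as exc:
                    raise PeaklistError(
                        f"spectrum {ordinal}: missing precursor information"
                    ) from exc
                peaks = tuple(
                    zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())
                )
                out.append(
                    Spectrum(
                        spectrum_id=str(entry.get("id", f"spectrum{ordinal}")),
                        precursor_mz=pmz,
                        precursor_charge=charge,
                        peaks=peaks,
                        scan_low=scan_low,
                        scan_high=scan_high,
                    )
                )
    else:
        raise PeaklistError(f"unsupported peak-list format: {path.suffix!r}")
    return out


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra to MGF with deterministic formatting."""

    def _write(handle):
        for spec in spectra:
            handle.write("BEGIN IONS\n")
            handle.write(f"TITLE={spec.spectrum_id}\n")
            handle.write(f"PEPMASS={spec.precursor_mz:.4f}\n")
            if spec.precursor_charge:
                handle.write(f"CHARGE={spec.precursor_charge}+\n")
            for mz, inten in spec.peaks:
                handle.write(f"{mz:.4f} {inten:.4f}\n")
            handle.write("END IONS\n")

    _atomic_write(path, _write)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an accession -> sequence mapping."""
    out: dict[str, str] = {}
    with _pfasta.FASTA(str(path)) as reader:
        for header, seq in reader:
            acc = header.split()[0]
            out[acc] = seq
    return out


def write_fasta(entries: Mapping[str, str], path, width: int = 60) -> None:
    def _write(handle):
        for acc in entries:
            handle.write(f">{acc}\n")
            seq = entries[acc]
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")

    _atomic_write(path, _write)


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a DataFrame as TSV (no index), atomically."""

    def _write(handle):
        df.to_csv(handle, sep="\t", index=False, float_format=float_format)

    _atomic_write(path, _write)


def write_json(obj, path) -> None:
    def _write(handle):
        json.dump(obj, handle, indent=1, sort_keys=True, default=str)
        handle.write("\n")

    _atomic_write(path, _write)


def annotation_report(results: Sequence[tuple[str, AnnotationResult]]) -> pd.DataFrame:
    """One row per matched ion across spectra, m/z to 4 decimals."""
    rows = []
    for spectrum_id, res in results:
        for ion, idx, ppm in res.matches:
            mz_obs = res.spectrum.peaks[idx][0]
            rows.append(
                {
                    "spectrum_id": spectrum_id,
                    "ion": ion.label,
                    "series": ion.series,
                    "charge": ion.charge,
                    "mz_theoretical": round(ion.mz, 4),
                    "mz_observed": round(mz_obs, 4),
                    "ppm_error": round(ppm, 2),
                    "intensity": res.spectrum.peaks[idx][1],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "spectrum_id", "ion", "series", "charge", "mz_theoretical",
            "mz_observed", "ppm_error", "intensity",
        ],
    )
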