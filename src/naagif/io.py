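"""Reading and writing spectra, time-series manifests, and fit reports.

File formats are deliberately plain: a spectrum is a two-column CSV
(wavelength_nm, value) with an optional header; a time series is a
manifest CSV (time_s, path, pH) pointing at per-time spectrum files; fit
reports are JSON. All lengths are nm, times s.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, ParseError
from .kinetics import ReleaseFit
from .spectrum import SpectralTimeSeries, Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_timeseries",
    "write_timeseries",
    "write_fit_report",
]

logger = logging.getLogger("naagif")


def _parse_float(token: str, line_no: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"cannot parse {what} from {token!r}", line_no) from None


def read_spectrum(path, kind: str = "auto") -> Spectrum:
    """Read a two-column (wavelength_nm, value) CSV.

    An optional single header line is skipped; rows are sorted by
    wavelength (with a warning if they were unsorted); duplicate
    wavelengths are an error. ``kind="auto"`` classifies values entirely
    inside [0, 1] as reflectance, anything else as raw intensity.
    """
    path = Path(path)
    wavelengths: list = []
    values: list = []
    with open(path, newline="") as fh:
        for line_no, row in enumerate(csv.reader(fh), start=1):
            row = [c.strip() for c in row if c.strip() != ""]
            if not row:
                continue
            if len(row) < 2:
                raise ParseError("expected at least 2 columns", line_no)
            if line_no == 1:
                try:
                    float(row[0])
                except ValueError:
                    continue  # header line
            wavelengths.append(_parse_float(row[0], line_no, "wavelength"))
            values.append(_parse_float(row[1], line_no, "value"))
    if not wavelengths:
        raise ParseError(f"no data rows in {path}")
    wl = np.asarray(wavelengths)
    vals = np.asarray(values)
    uniq, counts = np.unique(wl, return_counts=True)
    if uniq.size != wl.size:
        raise ParseError(f"duplicate wavelengths in {path}: {uniq[counts > 1][:5]}")
    order = np.argsort(wl)
    if not np.array_equal(order, np.arange(wl.size)):
        logger.warning("rows of %s were not sorted by wavelength; sorting", path)
        wl, vals = wl[order], vals[order]
    if kind == "auto":
        kind = "reflectance" if (vals.min() >= 0 and vals.max() <= 1) else "intensity"
    return Spectrum(wl, vals, kind=kind)


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as CSV with 6 significant digits per value."""
    if len(spectrum) == 0:
        raise InvalidParameterError("refusing to write an empty spectrum")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("wavelength_nm,value\n")
        for w, v in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{w:.6g},{v:.6g}\n")


def write_timeseries(series: SpectralTimeSeries, directory,
                     prefix: str = "spectrum") -> Path:
    """Write per-time spectrum CSVs plus a manifest; returns the manifest path.

    Manifest columns: time_s, path (relative to the manifest), pH (empty
    during the dry lead-in).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "path", "pH"])
        for i, (t, s) in enumerate(zip(series.times, series.spectra)):
            name = f"{prefix}_{i:05d}.csv"
            write_spectrum(s, directory / name)
            ph = series.ph_at(t)
            writer.writerow([f"{t:.6g}", name, "" if ph is None else f"{ph:g}"])
    return manifest


def read_timeseries(manifest_path) -> SpectralTimeSeries:
    """Read a manifest CSV (time_s, path, pH) and its spectrum files."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    times: list = []
    spectra: list = []
    phs: list = []
    with open(manifest_path, newline="") as fh:
        for line_no, row in enumerate(csv.reader(fh), start=1):
            row = [c.strip() for c in row]
            if not any(row):
                continue
            if line_no == 1 and row and not _is_number(row[0]):
                continue
            if len(row) < 2:
                raise ParseError("manifest rows need time_s and path", line_no)
            t = _parse_float(row[0], line_no, "time_s")
            spath = base / row[1]
            if not spath.exists():
                raise ParseError(f"spectrum file {row[1]!r} not found", line_no)
            ph = None
            if len(row) > 2 and row[2] != "":
                ph = _parse_float(row[2], line_no, "pH")
            times.append(t)
            spectra.append(read_spectrum(spath, kind="intensity"))
            phs.append(ph)
    if not times:
        raise ParseError(f"no data rows in {manifest_path}")
    order = np.argsort(times)
    times = [times[i] for i in order]
    spectra = [spectra[i] for i in order]
    phs = [phs[i] for i in order]
    schedule = []
    for t, ph in zip(times, phs):
        if not schedule or schedule[-1][1] != ph:
            schedule.append((t, ph))
    return SpectralTimeSeries(np.asarray(times), spectra, schedule)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_fit_report(fit: ReleaseFit, path) -> None:
    """Serialize a release fit as JSON."""
    payload = {
        "r_max": fit.r_max,
        "t_max_s": fit.t_max,
        "amplitude": fit.amplitude,
        "t_release_s": fit.t_release,
        "residual_sum": fit.residual_sum,
        "n_points_fit": fit.n_points_fit,
        "degenerate": fit.degenerate,
        "message": fit.message,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
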