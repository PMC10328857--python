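"""Readers/writers for portable 1D spectrum formats.

Supported formats:

``csv``
    Two columns ``ppm,intensity`` with ``#``-prefixed ``key=value`` metadata
    header lines.  Written with 17 significant digits, so a write/read cycle
    is bit-exact for double precision data.
``jcampdx``
    Minimal JCAMP-DX 4.24 with an AFFN ``(X++(Y..Y))`` XYDATA table on a
    uniform grid.
``bruker_processed``
    Optional reader for a Bruker processed-data directory (``1r`` + ``procs``)
    as found in public deposits of pre-processed spectra.  Never required by
    the pipeline, which runs entirely on simulated spectra.

All readers honour the package-wide convention of a strictly decreasing ppm
axis: ascending input is reversed together with its intensities.
"""

from __future__ import annotations

import os
import re
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .spectrum import Spectrum1D, SpectrumMeta

__all__ = ["read_spectrum", "write_spectrum"]

_META_FIELDS = (
    "pulse_sequence",
    "sample_role",
    "calibration_level",
    "replicate_index",
    "spectrometer_frequency",
    "provenance",
)


def _meta_to_pairs(meta: SpectrumMeta) -> list[tuple[str, str]]:
    pairs = []
    for key, value in asdict(meta).items():
        if value is None:
            continue
        pairs.append((key, str(value)))
    return pairs


def _meta_from_dict(d: dict) -> SpectrumMeta:
    kwargs = {}
    for key in _META_FIELDS:
        if key not in d:
            continue
        value = d[key]
        if key == "calibration_level":
            value = int(value)
        elif key == "replicate_index":
            value = int(value)
        elif key == "spectrometer_frequency":
            value = float(value)
        kwargs[key] = value
    return SpectrumMeta(**kwargs)


def _orient(ppm: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Enforce the strictly decreasing axis convention."""
    if ppm.size >= 2 and ppm[0] < ppm[-1]:
        return ppm[::-1].copy(), intensity[::-1].copy()
    return ppm, intensity


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _write_csv(spectrum: Spectrum1D, path: Path) -> None:
    with open(path, "w") as fh:
        for key, value in _meta_to_pairs(spectrum.meta):
            fh.write(f"# {key}={value}\n")
        fh.write("ppm,intensity\n")
        for x, y in zip(spectrum.ppm_axis, spectrum.intensity):
            fh.write(f"{x:.17g},{y:.17g}\n")


def _read_csv(path: Path) -> Spectrum1D:
    meta_dict: dict[str, str] = {}
    ppm: list[float] = []
    intensity: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta_dict[key.strip()] = value.strip()
                continue
            fields = line.split(",")
            if fields[0].strip().lower() == "ppm":
                continue  # column header
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 comma-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                ppm.append(float(fields[0]))
                intensity.append(float(fields[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
    x, y = _orient(np.asarray(ppm), np.asarray(intensity))
    return Spectrum1D(ppm_axis=x, intensity=y, meta=_meta_from_dict(meta_dict))


# ---------------------------------------------------------------------------
# JCAMP-DX (minimal, uniform-grid AFFN)
# ---------------------------------------------------------------------------

def _write_jcampdx(spectrum: Spectrum1D, path: Path) -> None:
    x = spectrum.ppm_axis
    y = spectrum.intensity
    with open(path, "w") as fh:
        fh.write("##TITLE=qnmrbench spectrum\n")
        fh.write("##JCAMP-DX=4.24\n")
        fh.write("##DATA TYPE=NMR SPECTRUM\n")
        fh.write("##XUNITS=PPM\n")
        fh.write("##YUNITS=ARBITRARY UNITS\n")
        for key, value in _meta_to_pairs(spectrum.meta):
            fh.write(f"##${key.upper()}={value}\n")
        fh.write(f"##NPOINTS={x.size}\n")
        fh.write(f"##FIRSTX={x[0]:.17g}\n")
        fh.write(f"##LASTX={x[-1]:.17g}\n")
        fh.write("##XFACTOR=1\n")
        fh.write("##YFACTOR=1\n")
        fh.write("##XYDATA=(X++(Y..Y))\n")
        per_line = 4
        for start in range(0, y.size, per_line)        :
            chunk = y[start : start + per_line]
            vals = " ".join(f"{v:.17g}" for v in chunk)
            fh.write(f"{x[start]:.17g} {vals}\n")
        fh.write("##END=\n")


def _read_jcampdx(path: Path) -> Spectrum1D:
    labels: dict[str, str] = {}
    y: list[float] = []
    in_table = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper()
                if key == "XYDATA":
                    in_table = True
                    continue
                if key == "END":
                    in_table = False
                    continue
                labels[key] = value.strip()
                continue
            if in_table:
                parts = line.split()
                try:
                    vals = [float(p) for p in parts]
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
                y.extend(vals[1:])  # first token is the X check value
    for required in ("NPOINTS", "FIRSTX", "LASTX"):
        if required not in labels:
            raise ValueError(f"{path}: missing ##{required}= record")
    npoints = int(labels["NPOINTS"])
    if npoints != len(y):
        raise ValueError(
            f"{path}: NPOINTS={npoints} but XYDATA table holds {len(y)} ordinates"
        )
    yfactor = float(labels.get("YFACTOR", "1"))
    xfactor = float(labels.get("XFACTOR", "1"))
    firstx = float(labels["FIRSTX"]) * xfactor
    lastx = float(labels["LASTX"]) * xfactor
    x = np.linspace(firstx, lastx, npoints)
    yy = np.asarray(y) * yfactor
    meta_dict = {
        key.lower().lstrip("$"): value
        for key, value in labels.items()
        if key.startswith("$")
    }
    x, yy = _orient(x, yy)
    return Spectrum1D(ppm_axis=x, intensity=yy, meta=_meta_from_dict(meta_dict))


# ---------------------------------------------------------------------------
# Bruker processed directory (optional)
# ---------------------------------------------------------------------------

def _parse_bruker_params(path: Path) -> dict[str, str]:
    params: dict[str, str] = {}
    text = path.read_text(errors="replace")
    for match in re.finditer(r"^##\$?([A-Za-z_0-9]+)=\s*(.*)$", text, re.MULTILINE):
        params[match.group(1)] = match.group(2).strip()
    return params


def _read_bruker_processed(path: Path) -> Spectrum1D:
    """Read a Bruker processed dataset directory containing ``1r`` + ``procs``."""
    one_r = path / "1r"
    procs = path / "procs"
    if not one_r.exists() or not procs.exists():
        raise FileNotFoundError(f"{path}: expected Bruker files '1r' and 'procs'")
    params = _parse_bruker_params(procs)
    try:
        si = int(params["SI"])
        offset = float(params["OFFSET"])     # ppm of the first (left-most) point
        sw_p = float(params["SW_p"])         # processed spectral width, Hz
        sf = float(params["SF"])             # spectrometer frequency, MHz
    except KeyError as exc:
        raise ValueError(f"{procs}: missing required parameter {exc}") from exc
    byte_order = "<" if params.get("BYTORDP", "0") == "0" else ">"
    dtype = np.dtype(f"{byte_order}i4")
    if params.get("DTYPP", "0") == "2":
        dtype = np.dtype(f"{byte_order}f8")
    raw = np.fromfile(one_r, dtype=dtype)
    if raw.size != si:
        raise ValueError(f"{one_r}: expected {si} points per procs, found {raw.size}")
    nc_proc = int(params.get("NC_proc", "0"))
    intensity = raw.astype(float) * 2.0 ** nc_proc
    sw_ppm = sw_p / sf
    x = offset - np.arange(si) * sw_ppm / si
    freq = sf
    meta = SpectrumMeta(provenance=f"bruker:{path}", spectrometer_frequency=freq)
    x, intensity = _orient(x, intensity)
    return Spectrum1D(ppm_axis=x, intensity=intensity, meta=meta)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_spectrum(path: str | os.PathLike, format: str = "csv") -> Spectrum1D:
    """Read a spectrum; see module docstring for the supported dialects."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if format == "csv":
        return _read_csv(p)
    if format == "jcampdx":
        return _read_jcampdx(p)
    if format == "bruker_processed":
        return _read_bruker_processed(p)
    raise ValueError(f"unknown format {format!r}")


def write_spectrum(spectrum: Spectrum1D, path: str | os.PathLike, format: str = "csv") -> None:
    """Write a spectrum losslessly (double precision) in ``csv`` or ``jcampdx``."""
    p = Path(path)
    if format == "csv":
        _write_csv(spectrum, p)
    elif format == "jcampdx":
        _write_jcampdx(spectrum, p)
    else:
        raise ValueError(f"unknown format {format!r}")
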