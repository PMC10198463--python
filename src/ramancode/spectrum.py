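"""The :class:`Spectrum` container and plain-text spectrum I/O.

A spectrum is a pair of equal-length vectors — a strictly increasing,
evenly spaced wavenumber grid (cm^-1) and non-negative-ish intensities
(arbitrary units) — plus a free-form metadata dict (bead id, number of
averaged frames, exposure tag, provenance of preprocessing steps).

The canonical on-disk format is a two-column CSV (wavenumber, intensity)
with an optional JSON sidecar for metadata; a minimal JCAMP-DX reader
(AFFN ``(X++(Y..Y))`` tables) is provided read-only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GridMismatchError, SpectrumParseError

logger = logging.getLogger(__name__)

__all__ = ["Spectrum", "read_spectrum", "write_spectrum", "read_batch", "write_batch"]


@dataclass
class Spectrum:
    """A single Raman spectrum on an evenly spaced wavenumber grid."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise SpectrumParseError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise SpectrumParseError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size < 2:
            raise SpectrumParseError("a spectrum needs at least 2 points")
        steps = np.diff(self.wavenumbers)
        if not np.all(steps > 0):
            raise SpectrumParseError("wavenumber grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise SpectrumParseError("wavenumber grid must have a constant step")

    @property
    def step(self) -> float:
        """Grid spacing in cm^-1."""
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    def copy(self) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), self.intensities.copy(), dict(self.meta))

    def crop(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to wavenumbers in [lo, hi] (inclusive)."""
        mask = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        if mask.sum() < 2:
            raise GridMismatchError(f"crop range ({lo}, {hi}) leaves fewer than 2 points")
        return Spectrum(self.wavenumbers[mask], self.intensities[mask], dict(self.meta))

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), self.intensities * factor, dict(self.meta))

    def allclose(self, other: "Spectrum", rtol: float = 1e-9, atol: float = 1e-12) -> bool:
        return (
            self.wavenumbers.shape == other.wavenumbers.shape
            and np.allclose(self.wavenumbers, other.wavenumbers, rtol=rtol, atol=atol)
            and np.allclose(self.intensities, other.intensities, rtol=rtol, atol=atol)
        )


def write_spectrum(spectrum: Spectrum, path: str | Path, write_meta: bool = True) -> Path:
    """Write a two-column CSV; metadata goes to a ``.meta.json`` sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("wavenumber_cm1,intensity\n")
        for w, i in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{float(w)!r},{float(i)!r}\n")
    if write_meta and spectrum.meta:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(spectrum.meta, indent=1, default=str))
    return path


def _read_csv(path: Path) -> Spectrum:
    wavenumbers: list[float] = []
    intensities: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace("\t", ",").split(",") if p.strip()]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                w, i = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric value in {parts[:2]}"
                ) from None
            wavenumbers.append(w)
            intensities.append(i)
    if len(wavenumbers) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Spectrum(np.array(wavenumbers), np.array(intensities), meta)


def _read_jcamp(path: Path) -> Spectrum:
    """Minimal JCAMP-DX reader: AFFN ``##XYDATA=(X++(Y..Y))`` tables only."""
    xfactor = yfactor = 1.0
    deltax = None
    in_table = False
    xs: list[float] = []
    ys: list[float] = []
    meta: dict = {"format": "jcamp"}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "XFACTOR":
                    xfactor = float(value)
                elif key == "YFACTOR":
                    yfactor = float(value)
                elif key == "DELTAX":
                    deltax = float(value)
                elif key == "TITLE":
                    meta["title"] = value
                elif key == "XYDATA":
                    in_table = True
                elif key == "END":
                    in_table = False
                continue
            if in_table:
                try:
                    values = [float(v) for v in line.replace(",", " ").split()]
                except ValueError:
                    raise SpectrumParseError(
                        f"{path}: line {lineno}: non-numeric JCAMP table entry"
                    ) from None
                if len(values) < 2:
                    raise SpectrumParseError(f"{path}: line {lineno}: short JCAMP row")
                x0 = values[0] * xfactor
                step = deltax if deltax is not None else 1.0
                for k, y in enumerate(values[1:]):
                    xs.append(x0 + k * step * xfactor if deltax is None else x0 + k * deltax)
                    ys.append(y * yfactor)
    if len(xs) < 2:
        raise SpectrumParseError(f"{path}: no JCAMP XYDATA table found")
    return Spectrum(np.array(xs), np.array(ys), meta)


def read_spectrum(path: str | Path, format: str = "csv") -> Spectrum:
    """Read a spectrum; descending-grid files are reversed with a log note."""
    path = Path(path)
    if format not in ("csv", "jcamp"):
        raise SpectrumParseError(f"unknown format {format!r} (expected 'csv' or 'jcamp')")
    # parse leniently, then normalize grid direction before validation
    try:
        return _read_csv(path) if format == "csv" else _read_jcamp(path)
    except SpectrumParseError as err:
        if "strictly increasing" not in str(err):
            raise
    # descending grid: reparse without Spectrum validation and flip
    if format == "jcamp":
        raise SpectrumParseError(f"{path}: non-monotone JCAMP grid")
    ws, xs = [], []
    with open(path) as fh:
        for raw in fh:
            parts = [p for p in raw.strip().replace("\t", ",").split(",") if p.strip()]
            if len(parts) < 2:
                continue
            try:
                ws.append(float(parts[0]))
                xs.append(float(parts[1]))
            except ValueError:
                continue
    w = np.array(ws)
    if np.all(np.diff(w) < 0):
        logger.info("read_spectrum: %s had a descending grid; reversed to ascending", path)
        return Spectrum(w[::-1].copy(), np.array(xs)[::-1].copy())
    raise SpectrumParseError(f"{path}: wavenumber grid is not monotone")


def write_batch(
    items: list[tuple[str, Spectrum]],
    directory: str | Path,
    truth_codes: dict[str, int] | None = None,
) -> Path:
    """Write spectra into *directory* with a TSV index (bead_id, file, truth_code)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for bead_id, spectrum in items:
        fname = f"{bead_id}.csv"
        write_spectrum(spectrum, directory / fname, write_meta=False)
        truth = "" if truth_codes is None or bead_id not in truth_codes else truth_codes[bead_id]
        rows.append({"bead_id": bead_id, "file": fname, "truth_code": truth})
    index = directory / "index.tsv"
    pd.DataFrame(rows).to_csv(index, sep="\t", index=False)
    return index


def read_batch(directory: str | Path) -> list[tuple[str, Spectrum, int | None]]:
    """Read a batch directory written by :func:`write_batch`.

    Returns (bead_id, spectrum, truth_code-or-None) triples in index order.
    """
    directory = Path(directory)
    index = pd.read_csv(directory / "index.tsv", sep="\t")
    out = []
    for _, row in index.iterrows():
        truth = row.get("truth_code")
        truth = None if pd.isna(truth) or truth == "" else int(truth)
        out.append((str(row["bead_id"]), read_spectrum(directory / row["file"]), truth))
    return out
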