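"""Ratio-based decoding of encoded bead spectra.

The decoded quantity per code region is the coding/reference peak-height
ratio, which is invariant to overall brightness (laser power, focus, bead
size).  Level assignment is a per-region 1-D nearest-centroid classification
against calibration standards measured right after each code was
synthesized; the centroid table (mean ratio and replicate sd per level) is
the :class:`CalibrationSet`.

Isolated peaks are quantified as the baseline-corrected maximum within a
20 cm^-1 window.  For the region ratio, where the two pair members sit only
25-50 cm^-1 apart, heights are instead sampled at the nominal band centers
and unmixed through the pair's analytic 2x2 tail-overlap matrix — without
the correction the raw ratio carries a few-percent cross-talk bias (which
calibration would absorb anyway, since standards are measured identically).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CalibrationError, LowSignalError, RangeError
from .preprocess import PreprocessParams, preprocess
from .scheme import Code, CodeScheme, CompoundPair, code_to_sequence
from .simulate import gaussian, lorentzian
from .spectrum import Spectrum

__all__ = [
    "CalibrationSet",
    "DecodedBead",
    "quantify_peak",
    "peak_height_at",
    "region_ratio",
    "calibrate_levels",
    "classify_level",
    "decode_bead",
    "decode_batch",
    "decoded_to_frame",
]

REGIONS = ("X", "Y", "Z")
DEFAULT_WINDOW = 20.0  # cm^-1
DEFAULT_MIN_REFERENCE = 5.0  # a.u.; below this the bead is undecodable


def quantify_peak(spectrum: Spectrum, center: float, window: float = DEFAULT_WINDOW) -> float:
    """Peak height: maximum intensity within ``center +/- window/2``, clipped at 0.

    Assumes a baseline-corrected spectrum; height (not area) is used so a
    misestimated linewidth cannot bias the level ratio.
    """
    half = window / 2.0
    w = spectrum.wavenumbers
    if center - half < w[0] or center + half > w[-1]:
        raise RangeError(
            f"window {center}+/-{half} cm^-1 outside grid [{w[0]}, {w[-1]}]"
        )
    mask = np.abs(w - center) <= half
    return float(max(spectrum.intensities[mask].max(), 0.0))


def peak_height_at(spectrum: Spectrum, center: float) -> float:
    """Baseline-corrected intensity at *center* (linear interpolation), >= 0.

    Unlike :func:`quantify_peak` this does not search a window, so the
    overlapping tail of a nearby band cannot masquerade as the maximum —
    the form needed for the analytic pair cross-talk correction.
    """
    w = spectrum.wavenumbers
    if center < w[0] or center > w[-1]:
        raise RangeError(f"center {center} cm^-1 outside grid [{w[0]}, {w[-1]}]")
    return float(max(np.interp(center, w, spectrum.intensities), 0.0))


def _profile_at(center: float, fwhm: float, x: float, lineshape: str) -> float:
    shape = lorentzian if lineshape == "lorentzian" else gaussian
    return float(shape(np.array([x]), center, fwhm)[0])


def _nearest_grid_point(spectrum: Spectrum, center: float) -> float:
    w = spectrum.wavenumbers
    if center < w[0] or center > w[-1]:
        raise RangeError(f"center {center} cm^-1 outside grid [{w[0]}, {w[-1]}]")
    return float(w[int(np.argmin(np.abs(w - center)))])


def _pair_heights(
    spectrum: Spectrum, pair: CompoundPair, lineshape: str
) -> tuple[float, float]:
    """Cross-talk-corrected pair amplitudes (reference, coding).

    Each peak is sampled at the grid point nearest its nominal center and
    rescaled by the known lineshape attenuation at that offset (band centers
    need not sit on the instrument grid).  The two sampled heights are then
    unmixed through the analytic 2x2 tail-overlap matrix of the pair.
    """
    ref, cod = pair.reference, pair.coding
    g_ref = _nearest_grid_point(spectrum, ref.peak_center)
    g_cod = _nearest_grid_point(spectrum, cod.peak_center)
    att_ref = _profile_at(ref.peak_center, ref.linewidth_fwhm, g_ref, lineshape)
    att_cod = _profile_at(cod.peak_center, cod.linewidth_fwhm, g_cod, lineshape)
    y = spectrum.intensities
    w = spectrum.wavenumbers
    h_ref = float(y[int(np.argmin(np.abs(w - g_ref)))]) / att_ref
    h_cod = float(y[int(np.argmin(np.abs(w - g_cod)))]) / att_cod
    # partner tail contributions at the same sample points, same normalization
    t_cr = _profile_at(cod.peak_center, cod.linewidth_fwhm, g_ref, lineshape) / att_ref
    t_rc = _profile_at(ref.peak_center, ref.linewidth_fwhm, g_cod, lineshape) / att_cod
    det = 1.0 - t_rc * t_cr
    a_ref = (h_ref - t_cr * h_cod) / det
    a_cod = (h_cod - t_rc * h_ref) / det
    return a_ref, a_cod


def region_ratio(
    spectrum: Spectrum,
    pair: CompoundPair,
    window: float = DEFAULT_WINDOW,
    min_reference: float = DEFAULT_MIN_REFERENCE,
    correct_crosstalk: bool = True,
    lineshape: str = "lorentzian",
) -> float:
    """Coding/reference height ratio for one code region.

    Heights are sampled at the grid points nearest the nominal band centers
    (the pair members sit 25-50 cm^-1 apart, so a windowed maximum would
    ride up the partner's tail and defeat the cross-talk correction), then
    unmixed through the pair's analytic tail-overlap matrix.  Raises
    :class:`LowSignalError` when the reference (internal-standard) peak is
    below *min_reference* — such a bead is undecodable, not guessed.
    """
    if correct_crosstalk:
        a_ref, a_cod = _pair_heights(spectrum, pair, lineshape)
        if a_ref < min_reference:
            raise LowSignalError(
                f"region {pair.region_label}: corrected reference amplitude "
                f"{a_ref:.3g} a.u. below floor {min_reference} a.u."
            )
        return max(a_cod / a_ref, 0.0)
    h_ref = peak_height_at(spectrum, pair.reference.peak_center)
    h_cod = peak_height_at(spectrum, pair.coding.peak_center)
    if h_ref < min_reference:
        raise LowSignalError(
            f"region {pair.region_label}: reference height {h_ref:.3g} a.u. below "
            f"floor {min_reference} a.u."
        )
    return max(h_cod / h_ref, 0.0)


@dataclass
class CalibrationSet:
    """Per-region, per-level ratio centroids with replicate dispersion."""

    centroids: dict[str, np.ndarray]  # region -> (n_levels,) means
    dispersions: dict[str, np.ndarray]  # region -> (n_levels,) sds (floored)
    n_replicates: dict[str, np.ndarray]  # region -> (n_levels,) counts
    n_levels: int

    def __post_init__(self) -> None:
        for region in REGIONS:
            if region not in self.centroids:
                raise CalibrationError(f"missing calibration for region {region}")
            mu = np.asarray(self.centroids[region], dtype=float)
            if mu.size != self.n_levels:
                raise CalibrationError(
                    f"region {region}: {mu.size} centroids for {self.n_levels} levels"
                )
            if np.any(np.diff(mu) <= 0):
                raise CalibrationError(
                    f"region {region}: centroids not strictly increasing in level — "
                    "measure more replicates per standard"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in REGIONS:
            for level in range(self.n_levels):
                rows.append(
                    {
                        "region": region,
                        "level": level,
                        "centroid": self.centroids[region][level],
                        "dispersion": self.dispersions[region][level],
                        "n": int(self.n_replicates[region][level]),
                    }
                )
        return pd.DataFrame(rows)

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.tsv`` plus a small JSON manifest."""
        prefix = Path(prefix)
        self.to_frame().to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        manifest = {
            "n_levels": self.n_levels,
            "regions": list(REGIONS),
            "total_replicates": int(sum(self.n_replicates[r].sum() for r in REGIONS)),
        }
        prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "CalibrationSet":
        prefix = Path(prefix)
        frame = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
        n_levels = int(frame["level"].max()) + 1
        centroids, dispersions, counts = {}, {}, {}
        for region, sub in frame.groupby("region"):
            sub = sub.sort_values("level")
            centroids[region] = sub["centroid"].to_numpy()
            dispersions[region] = sub["dispersion"].to_numpy()
            counts[region] = sub["n"].to_numpy()
        return cls(centroids, dispersions, counts, n_levels)


def calibrate_levels(
    standards: list[tuple[Code, Spectrum]],
    scheme: CodeScheme,
    preprocess_params: PreprocessParams | None = None,
    min_sigma: float = 1e-3,
    window: float = DEFAULT_WINDOW,
    min_reference: float = DEFAULT_MIN_REFERENCE,
) -> CalibrationSet:
    """Build the centroid table from labeled standard spectra.

    Every (region, level) combination must be represented; centroids are
    replicate means and dispersions replicate standard deviations, floored
    at *min_sigma* so single-replicate calibrations still define a margin
    scale.
    """
    buckets: dict[tuple[str, int], list[float]] = {}
    for code, spectrum in standards:
        processed = preprocess(spectrum, preprocess_params)
        for region, digit in zip(REGIONS, (code.x, code.y, code.z)):
            ratio = region_ratio(
                processed, scheme.pair(region), window=window, min_reference=min_reference
            )
            buckets.setdefault((region, digit), []).append(ratio)
    missing = [
        (region, level)
        for region in REGIONS
        for level in range(scheme.n_levels)
        if (region, level) not in buckets
    ]
    if missing:
        raise CalibrationError(f"incomplete calibration; missing (region, level): {missing}")
    centroids, dispersions, counts = {}, {}, {}
    for region in REGIONS:
        values = [np.asarray(buckets[(region, level)]) for level in range(scheme.n_levels)]
        centroids[region] = np.array([v.mean() for v in values])
        dispersions[region] = np.array([max(v.std(ddof=0), min_sigma) for v in values])
        counts[region] = np.array([v.size for v in values])
    return CalibrationSet(centroids, dispersions, counts, scheme.n_levels)


def classify_level(
    ratio: float, centroids: np.ndarray, dispersions: np.ndarray
) -> tuple[int, float, list[str]]:
    """Nearest-centroid level assignment.

    Returns ``(level, margin, flags)`` where *margin* is the gap between the
    second-nearest and nearest centroid distances in units of the assigned
    level's dispersion.  Exact distance ties resolve to the lower level;
    ratios beyond the extreme centroids clamp with an ``out_of_range`` flag.
    """
    d = np.abs(ratio - centroids)
    level = int(np.argmin(d))  # argmin takes the first (lower) index on ties
    flags: list[str] = []
    if ratio < centroids[0] or ratio > centroids[-1]:
        flags.append("out_of_range")
    if d.size == 1:
        return level, np.inf, flags
    second = float(np.partition(d, 1)[1])
    margin = (second - d[level]) / dispersions[level]
    return level, float(margin), flags


@dataclass
class DecodedBead:
    """Decoding result for one bead."""

    bead_id: str
    ratios: tuple[float, float, float]  # (R_X, R_Y, R_Z)
    code: Code
    sequence: str
    confidence: float
    margins: tuple[float, float, float] = (np.inf, np.inf, np.inf)
    flags: tuple[str, ...] = ()


def _confidence(min_margin: float) -> float:
    """Monotone map from the worst per-region margin (sigma units) to [0, 1]."""
    if not np.isfinite(min_margin):
        return 1.0
    return float(1.0 - np.exp(-max(min_margin, 0.0)))


def decode_bead(
    spectrum: Spectrum,
    scheme: CodeScheme,
    calibration: CalibrationSet,
    preprocess_params: PreprocessParams | None = None,
    bead_id: str | None = None,
    window: float = DEFAULT_WINDOW,
    min_reference: float = DEFAULT_MIN_REFERENCE,
) -> DecodedBead:
    """Preprocess, ratio, classify — one spectrum to one code and sequence.

    Raises :class:`LowSignalError` if any region's reference peak is below
    the noise floor; an undecodable bead is reported, never imputed.
    """
    if calibration.n_levels != scheme.n_levels:
        raise CalibrationError(
            f"calibration has {calibration.n_levels} levels, scheme {scheme.n_levels}"
        )
    processed = preprocess(spectrum, preprocess_params)
    ratios = []
    levels = []
    margins = []
    flags: list[str] = []
    for region in REGIONS:
        ratio = region_ratio(
            processed, scheme.pair(region), window=window, min_reference=min_reference
        )
        level, margin, region_flags = classify_level(
            ratio, calibration.centroids[region], calibration.dispersions[region]
        )
        ratios.append(ratio)
        levels.append(level)
        margins.append(margin)
        flags.extend(f"{region}:{f}" for f in region_flags)
    code = Code(*levels)
    return DecodedBead(
        bead_id=bead_id or str(spectrum.meta.get("bead_id", "")),
        ratios=tuple(ratios),  # type: ignore[arg-type]
        code=code,
        sequence=code_to_sequence(code, scheme),
        confidence=_confidence(min(margins)),
        margins=tuple(margins),  # type: ignore[arg-type]
        flags=tuple(flags),
    )


def decode_batch(
    items: list[tuple[str, Spectrum]] | list[tuple[str, Spectrum, Code | None]],
    scheme: CodeScheme,
    calibration: CalibrationSet,
    preprocess_params: PreprocessParams | None = None,
    window: float = DEFAULT_WINDOW,
    min_reference: float = DEFAULT_MIN_REFERENCE,
) -> tuple[list[DecodedBead], dict]:
    """Decode a collection of beads; per-bead failures are collected, not fatal.

    Items are ``(bead_id, spectrum)`` or ``(bead_id, spectrum, truth_code)``;
    when truth codes are present the summary carries overall accuracy and a
    per-region confusion tally.
    """
    if not items:
        warnings.warn("decode_batch called with no spectra", stacklevel=2)
        return [], {"n_total": 0, "n_decoded": 0, "n_undecodable": 0, "errors": {}}
    decoded: list[DecodedBead] = []
    errors: dict[str, str] = {}
    truths: dict[str, Code] = {}
    for item in items:
        bead_id, spectrum = item[0], item[1]
        truth = item[2] if len(item) > 2 else None
        if truth is not None:
            truths[bead_id] = truth
        try:
            decoded.append(
                decode_bead(
                    spectrum,
                    scheme,
                    calibration,
                    preprocess_params,
                    bead_id=bead_id,
                    window=window,
                    min_reference=min_reference,
                )
            )
        except LowSignalError as err:
            errors[bead_id] = str(err)
    summary: dict = {
        "n_total": len(items),
        "n_decoded": len(decoded),
        "n_undecodable": len(errors),
        "errors": errors,
    }
    if truths:
        correct = sum(
            1 for d in decoded if d.bead_id in truths and d.code == truths[d.bead_id]
        )
        evaluated = sum(1 for d in decoded if d.bead_id in truths)
        summary["accuracy"] = correct / evaluated if evaluated else float("nan")
        confusion = {region: 0 for region in REGIONS}
        for d in decoded:
            truth = truths.get(d.bead_id)
            if truth is None:
                continue
            for region, got, want in zip(
                REGIONS, (d.code.x, d.code.y, d.code.z), (truth.x, truth.y, truth.z)
            ):
                if got != want:
                    confusion[region] += 1
        summary["region_errors"] = confusion
    return decoded, summary


def decoded_to_frame(decoded: list[DecodedBead]) -> pd.DataFrame:
    """Tabular decoding output (one row per bead)."""
    rows = []
    for d in decoded:
        rows.append(
            {
                "bead_id": d.bead_id,
                "R_X": d.ratios[0],
                "R_Y": d.ratios[1],
                "R_Z": d.ratios[2],
                "x": d.code.x,
                "y": d.code.y,
                "z": d.code.z,
                "code_number": d.code.code_number,
                "sequence": d.sequence,
                "confidence": d.confidence,
                "flags": ";".join(d.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bead_id", "R_X", "R_Y", "R_Z", "x", "y", "z",
            "code_number", "sequence", "confidence", "flags",
        ],
    )
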