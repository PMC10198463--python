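"""Synthetic encoded-bead spectra: calibration standards, split-and-pool
libraries, binding screens, and before/after reagent treatments.

The generator emulates what a confocal Raman microscope sees on a single
encoded polystyrene bead:

* three reference/coding Lorentzian pairs whose reference amplitudes follow
  ``base_amplitude * native_scale * allocation_fraction * decay^round`` —
  the amino-group allocation (~60/30/10%) chosen so that, together with the
  per-round signal decay of sequential solid-phase synthesis, the three code
  regions land at similar signal levels;
* the coding peak at ``reference * r_level`` for the bead's code digit;
* the bead matrix's native polystyrene band (internal standard, 1001 cm^-1);
* noise: per-point additive Gaussian (sd shrinking with the number of
  averaged frames), a bead-to-bead multiplicative lognormal factor common to
  all chemical peaks, and a slowly varying random quadratic baseline.

All randomness flows through explicit ``numpy.random.Generator`` objects or
integer seeds; the same seed reproduces the same spectra bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ConfigurationError
from .scheme import Code, CodeScheme, code_to_sequence, default_scheme, enumerate_codes
from .spectrum import Spectrum

__all__ = [
    "NoiseModel",
    "SimulationConfig",
    "BeadGroundTruth",
    "lorentzian",
    "gaussian",
    "simulate_spectrum",
    "simulate_standards",
    "simulate_full_loading",
    "simulate_library",
    "simulate_screen",
    "simulate_treatment",
    "rgd_binding_model",
    "diagonal_codes",
    "reference_amplitudes",
]

CELL_TYPES = ("none", "U87MG", "HeLa", "MCF7")


def lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Height-normalized Lorentzian (value 1 at *center*)."""
    g = 0.5 * fwhm
    return g * g / ((x - center) ** 2 + g * g)


def gaussian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Height-normalized Gaussian (value 1 at *center*)."""
    s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((x - center) / s) ** 2)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters for simulated bead spectra.

    additive_sd
        Per-point Gaussian sd (a.u.) of a single 2-s frame; averaging
        ``n_frames`` frames shrinks it by ``1/sqrt(n_frames)``.
    multiplicative_cv
        Coefficient of variation of the lognormal bead-to-bead brightness
        factor (bead size, focus); applied to all chemical peaks at once,
        so it cancels in every intensity ratio.
    baseline_amplitude
        Scale (a.u.) of a random quadratic background drift.
    """

    additive_sd: float = 2.0
    multiplicative_cv: float = 0.08
    baseline_amplitude: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.multiplicative_cv < 0 or self.baseline_amplitude < 0:
            raise ConfigurationError("noise dispersions must be >= 0")

    def off(self) -> "NoiseModel":
        """A copy with every noise source disabled."""
        return NoiseModel(0.0, 0.0, 0.0, self.seed)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to render a bead spectrum for a given code."""

    scheme: CodeScheme = field(default_factory=default_scheme)
    noise: NoiseModel = field(default_factory=NoiseModel)
    base_amplitude: float = 100.0  # a.u. per unit of native_scale x allocation
    polystyrene_amplitude: float = 400.0
    coupling_decay: float = 0.4  # per-round signal decay of sequential synthesis
    lineshape: str = "lorentzian"
    wavenumber_start: float = 600.0
    wavenumber_stop: float = 3200.0
    wavenumber_step: float = 2.0  # instrument spectral resolution
    n_frames: int = 5

    def __post_init__(self) -> None:
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ConfigurationError(f"unknown lineshape {self.lineshape!r}")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if not 0 < self.coupling_decay <= 1:
            raise ConfigurationError("coupling_decay must be in (0, 1]")

    def grid(self) -> np.ndarray:
        n = int(round((self.wavenumber_stop - self.wavenumber_start) / self.wavenumber_step)) + 1
        return self.wavenumber_start + self.wavenumber_step * np.arange(n)

    def profile(self, x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
        shape = lorentzian if self.lineshape == "lorentzian" else gaussian
        return shape(x, center, fwhm)


@dataclass(frozen=True)
class BeadGroundTruth:
    """What a simulated bead actually carries."""

    bead_id: str
    code: Code
    sequence: str
    bound_cell_type: str = "none"

    def __post_init__(self) -> None:
        if self.bound_cell_type not in CELL_TYPES:
            raise ConfigurationError(f"unknown cell type {self.bound_cell_type!r}")


def reference_amplitudes(cfg: SimulationConfig) -> tuple[float, float, float]:
    """Noise-free reference-peak amplitudes (a.u.) for regions X, Y, Z.

    Region k (synthesis round k) gets ``base * native_scale * allocation *
    decay^k``.  With the defaults (scales 1/5/50, allocation 0.6/0.3/0.1,
    decay 0.4) the three regions land at 60/60/80 a.u. — the equalization
    the allocation design aims for.
    """
    amps = []
    for k, pair in enumerate(cfg.scheme.pairs):
        amps.append(
            cfg.base_amplitude
            * pair.reference.native_scale
            * pair.allocation_fraction
            * cfg.coupling_decay**k
        )
    return tuple(amps)  # type: ignore[return-value]


def _peak_table(cfg: SimulationConfig) -> list[tuple[float, float]]:
    """(center, fwhm) for all 7 peaks: 3 pairs + polystyrene, in pair order."""
    peaks = []
    for pair in cfg.scheme.pairs:
        peaks.append((pair.reference.peak_center, pair.reference.linewidth_fwhm))
        peaks.append((pair.coding.peak_center, pair.coding.linewidth_fwhm))
    peaks.append((cfg.scheme.polystyrene_peak, cfg.scheme.polystyrene_fwhm))
    return peaks


@lru_cache(maxsize=8)
def _cached_basis(cfg: SimulationConfig) -> np.ndarray:
    x = cfg.grid()
    return np.vstack([cfg.profile(x, c, f) for c, f in _peak_table(cfg)])


def _basis(cfg: SimulationConfig, x: np.ndarray) -> np.ndarray:
    """(7, n_grid) matrix of height-normalized peak profiles (cached per config)."""
    return _cached_basis(cfg)


def _amplitude_vector(code: Code, cfg: SimulationConfig) -> np.ndarray:
    """Clean peak amplitudes (7,) for a code, polystyrene last."""
    for name, digit in (("x", code.x), ("y", code.y), ("z", code.z)):
        if digit >= cfg.scheme.n_levels:
            raise ConfigurationError(f"code digit {name}={digit} >= n_levels")
    refs = reference_amplitudes(cfg)
    levels = (code.x, code.y, code.z)
    amps = np.empty(7)
    for i, (ref_amp, level) in enumerate(zip(refs, levels)):
        amps[2 * i] = ref_amp
        amps[2 * i + 1] = ref_amp * cfg.scheme.level_ratios[level]
    amps[6] = cfg.polystyrene_amplitude
    return amps


def _apply_noise(
    clean_chemical: np.ndarray,
    polystyrene: np.ndarray,
    x: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    noise = cfg.noise
    y = clean_chemical.copy()
    if noise.multiplicative_cv > 0:
        sigma = np.sqrt(np.log1p(noise.multiplicative_cv**2))
        y *= rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
    y = y + polystyrene
    if noise.baseline_amplitude > 0:
        t = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0  # [-1, 1]
        c0, c1, c2 = rng.uniform(-1.0, 1.0, size=3)
        drift = noise.baseline_amplitude * (0.5 * (c0 + 1.0) + c1 * t + c2 * t**2)
        y = y + drift
    if noise.additive_sd > 0:
        y = y + rng.normal(0.0, noise.additive_sd / np.sqrt(cfg.n_frames), size=y.shape)
    return y


def _resolve_rng(rng: np.random.Generator | int | None, cfg: SimulationConfig) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is not None:
        return np.random.default_rng(rng)
    return np.random.default_rng(cfg.noise.seed)


def simulate_spectrum(
    code: Code,
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    noise: bool = True,
    meta: dict | None = None,
) -> Spectrum:
    """Render one bead spectrum for *code*.

    With ``noise=False`` the spectrum is the exact sum of lineshapes: each
    coding peak amplitude is its reference amplitude times the level ratio
    ``r_l`` of the code digit.
    """
    x = cfg.grid()
    amps = _amplitude_vector(code, cfg)
    basis = _basis(cfg, x)
    chemical = amps[:6] @ basis[:6]
    polystyrene = amps[6] * basis[6]
    if noise:
        y = _apply_noise(chemical, polystyrene, x, cfg, _resolve_rng(rng, cfg))
    else:
        y = chemical + polystyrene
    m = {"code": code.code_number, "n_frames": cfg.n_frames}
    if meta:
        m.update(meta)
    return Spectrum(x, y, m)


def diagonal_codes(scheme: CodeScheme) -> list[Code]:
    """Codes (l, l, l) for every level — the smallest set covering all
    (region, level) combinations for calibration."""
    return [Code(l, l, l) for l in range(scheme.n_levels)]


def simulate_standards(
    cfg: SimulationConfig,
    replicates_per_code: int = 5,
    codes: list[Code] | None = None,
    rng: np.random.Generator | int | None = None,
    noise: bool = True,
) -> list[tuple[Code, Spectrum]]:
    """Labeled calibration-standard spectra, sampled right after encoding.

    Defaults to all ``n_levels**3`` codes; pass ``codes=diagonal_codes(scheme)``
    for the minimal per-level calibration set.
    """
    if replicates_per_code < 1:
        raise ConfigurationError("replicates_per_code must be >= 1")
    if codes is None:
        codes = enumerate_codes(cfg.scheme)
    gen = _resolve_rng(rng, cfg)
    out = []
    for code in codes:
        for rep in range(replicates_per_code):
            out.append(
                (code, simulate_spectrum(code, cfg, gen, noise=noise, meta={"replicate": rep}))
            )
    return out


def simulate_full_loading(
    region_label: str,
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    noise: bool = True,
) -> Spectrum:
    """A bead with one pair attached to 100% of its amino groups.

    Both pair members are dosed to the same amplitude (``base_amplitude *
    native_scale``), the protocol used to compare the native signal strengths
    of the three compound groups.
    """
    pair = cfg.scheme.pair(region_label)
    x = cfg.grid()
    amp = cfg.base_amplitude * pair.reference.native_scale
    chemical = amp * cfg.profile(x, pair.reference.peak_center, pair.reference.linewidth_fwhm)
    chemical = chemical + amp * cfg.profile(x, pair.coding.peak_center, pair.coding.linewidth_fwhm)
    polystyrene = cfg.polystyrene_amplitude * cfg.profile(
        x, cfg.scheme.polystyrene_peak, cfg.scheme.polystyrene_fwhm
    )
    if noise:
        y = _apply_noise(chemical, polystyrene, x, cfg, _resolve_rng(rng, cfg))
    else:
        y = chemical + polystyrene
    return Spectrum(x, y, {"full_loading": region_label})


def simulate_library(
    n_beads: int,
    cfg: SimulationConfig,
    seed: np.random.Generator | int | None = None,
) -> list[tuple[BeadGroundTruth, Spectrum]]:
    """A split-and-pool library: each bead carries one uniformly random code."""
    if n_beads < 1:
        raise ConfigurationError("n_beads must be >= 1")
    rng = _resolve_rng(seed, cfg)
    codes = enumerate_codes(cfg.scheme)
    picks = rng.integers(0, len(codes), size=n_beads)
    library = []
    for i, pick in enumerate(picks):
        code = codes[pick]
        truth = BeadGroundTruth(
            bead_id=f"bead{i:05d}", code=code, sequence=code_to_sequence(code, cfg.scheme)
        )
        spectrum = simulate_spectrum(code, cfg, rng, meta={"bead_id": truth.bead_id})
        library.append((truth, spectrum))
    return library


def rgd_binding_model(
    scheme: CodeScheme, p_modal: float = 1.0, p_other: float = 0.1
):
    """Binding-probability model of the integrin screen.

    Only beads whose 5th/6th residues form the -RG- of the RGD motif
    (digits x=5, y=7 under the default alphabet) can bind; the 7th residue
    is most favorable at z=5 (the cGRGDdvc ligand) but any z can bind.
    """

    def probability(code: Code) -> float:
        if code.x != 5 or code.y != 7:
            return 0.0
        return p_modal if code.z == 5 else p_other

    return probability


def simulate_screen(
    library: list[tuple[BeadGroundTruth, Spectrum]],
    binding_probs,
    seed: np.random.Generator | int | None = None,
    cell_type: str = "U87MG",
) -> list[BeadGroundTruth]:
    """Bernoulli cell-binding screen; returns the positive beads.

    *binding_probs* is a callable ``Code -> p`` or a mapping keyed by
    code number (missing codes bind with probability 0).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if callable(binding_probs):
        prob = binding_probs
    else:
        prob = lambda code: binding_probs.get(code.code_number, 0.0)  # noqa: E731
    positives = []
    for truth, _ in library:
        p = prob(truth.code)
        if not 0 <= p <= 1:
            raise ConfigurationError(f"binding probability {p} outside [0, 1]")
        if rng.random() < p:
            positives.append(
                BeadGroundTruth(truth.bead_id, truth.code, truth.sequence, cell_type)
            )
    return positives


def simulate_treatment(
    spectrum: Spectrum,
    compound_peak: float,
    degradation_factor: float,
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    fwhm: float | None = None,
) -> Spectrum:
    """Spectrum after a reagent treatment degrading one compound.

    The compound's peak amplitude (estimated from the local
    polystyrene-free height at its center) is reduced by
    ``degradation_factor``; the polystyrene internal standard is untouched.
    Fresh measurement noise is applied when *rng* is given.
    """
    if not 0 <= degradation_factor <= 1:
        raise ConfigurationError("degradation_factor must be in [0, 1]")
    if fwhm is None:
        fwhm = 10.0
        for pair in cfg.scheme.pairs:
            for compound in (pair.reference, pair.coding):
                if compound.peak_center == compound_peak:
                    fwhm = compound.linewidth_fwhm
    x = spectrum.wavenumbers
    idx = int(np.argmin(np.abs(x - compound_peak)))
    height = max(spectrum.intensities[idx], 0.0)
    y = spectrum.intensities - degradation_factor * height * cfg.profile(x, compound_peak, fwhm)
    out = Spectrum(x.copy(), y, dict(spectrum.meta))
    out.meta["treated"] = {"peak": compound_peak, "degradation_factor": degradation_factor}
    if rng is not None and cfg.noise.additive_sd > 0:
        gen = _resolve_rng(rng, cfg)
        out.intensities = out.intensities + gen.normal(
            0.0, cfg.noise.additive_sd / np.sqrt(cfg.n_frames), size=y.shape
        )
    return out
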