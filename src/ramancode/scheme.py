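"""The combinatorial code book: compounds, pairs, levels, and code↔sequence maps.

Three pairs of chemically survivable Raman reporter compounds occupy three
disjoint frequency regions (Group I 2200-2300, Group II 2100-2200, Group III
1100-1600 cm^-1).  Within each pair one compound is an internal-standard
*reference* whose dosage is fixed, and the other is a *coding* compound whose
dosage relative to the reference sets one of ``n_levels`` (default 10)
intensity levels.  The three levels form a base-10 code ``#XYZ`` (X hundreds,
Y tens, Z units), giving 10 x 10 x 10 = 1000 codes, each mapped one-to-one to
an 8-mer cyclic peptide ``-cZYXDdvc-`` whose 5th, 6th, 7th residues (X, Y, Z)
are drawn from a 10-letter chiral amino-acid alphabet.

Split-and-pool synthesis allocates a fraction of the bead's amino groups to
each region (default ~60/30/10%) by partial Dde deprotection; the stepwise
deprotection fractions (of the *remaining* groups) are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import yaml

from .errors import ConfigurationError, InfeasiblePlanError, SequenceParseError

__all__ = [
    "EncodingCompound",
    "CompoundPair",
    "Code",
    "CodeScheme",
    "AllocationPlan",
    "GROUP_WINDOWS",
    "default_scheme",
    "enumerate_codes",
    "code_to_sequence",
    "sequence_to_code",
    "allocation_remainder",
    "design_allocation",
    "simulate_sequential_deprotection",
    "scheme_to_dict",
    "scheme_from_dict",
    "save_scheme",
    "load_scheme",
]

#: Frequency windows (cm^-1) of the three compound groups.  Groups I and II sit
#: in the cell-silent alkyne/nitrile window; Group III uses the fingerprint region.
GROUP_WINDOWS: dict[str, tuple[float, float]] = {
    "I": (2200.0, 2300.0),
    "II": (2100.0, 2200.0),
    "III": (1100.0, 1600.0),
}

DEFAULT_ALPHABET: tuple[str, ...] = ("S", "M", "Q", "d", "F", "G", "D", "R", "f", "v")
DEFAULT_TEMPLATE = "c{Z}{Y}{X}Ddvc"


@dataclass(frozen=True)
class EncodingCompound:
    """A Raman reporter compound defined by its marker band.

    ``native_scale`` is the relative Raman cross-section of the compound's
    pair group at equal loading (Group I : II : III = 5 : 1 : 50).
    """

    name: str
    group: str
    role: str  # "reference" | "coding"
    peak_center: float  # cm^-1
    linewidth_fwhm: float = 10.0  # cm^-1
    native_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in GROUP_WINDOWS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.role not in ("reference", "coding"):
            raise ConfigurationError(f"role must be 'reference' or 'coding', got {self.role!r}")
        lo, hi = GROUP_WINDOWS[self.group]
        if not (lo <= self.peak_center <= hi):
            raise ConfigurationError(
                f"{self.name}: peak {self.peak_center} cm^-1 outside Group "
                f"{self.group} window {lo}-{hi} cm^-1"
            )
        if self.native_scale <= 0:
            raise ConfigurationError(f"{self.name}: native_scale must be > 0")
        if self.linewidth_fwhm <= 0:
            raise ConfigurationError(f"{self.name}: linewidth_fwhm must be > 0")


@dataclass(frozen=True)
class CompoundPair:
    """A reference/coding compound pair encoding one code region (X, Y, or Z)."""

    region_label: str
    reference: EncodingCompound
    coding: EncodingCompound
    allocation_fraction: float

    def __post_init__(self) -> None:
        if self.region_label not in ("X", "Y", "Z"):
            raise ConfigurationError(f"region_label must be X, Y, or Z, got {self.region_label!r}")
        if self.reference.group != self.coding.group:
            raise ConfigurationError(
                f"pair {self.region_label}: reference ({self.reference.group}) and coding "
                f"({self.coding.group}) compounds must be in the same group"
            )
        if self.reference.peak_center == self.coding.peak_center:
            raise ConfigurationError(
                f"pair {self.region_label}: reference and coding peaks coincide"
            )
        if not 0 < self.allocation_fraction <= 1:
            raise ConfigurationError(
                f"pair {self.region_label}: allocation_fraction must be in (0, 1]"
            )


@dataclass(frozen=True, order=True)
class Code:
    """A three-digit combinatorial code (x, y, z), numbered ``100x + 10y + z``."""

    x: int
    y: int
    z: int

    def __post_init__(self) -> None:
        for name, digit in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not 0 <= int(digit) <= 9:
                raise ConfigurationError(f"code digit {name}={digit} outside 0-9")

    @property
    def code_number(self) -> int:
        return 100 * self.x + 10 * self.y + self.z

    @classmethod
    def from_number(cls, number: int) -> "Code":
        if not 0 <= number <= 999:
            raise ConfigurationError(f"code number {number} outside 0-999")
        return cls(number // 100, (number // 10) % 10, number % 10)

    def __str__(self) -> str:
        return f"#{self.code_number:03d}"


@dataclass(frozen=True)
class CodeScheme:
    """The full code book: pairs, level map, alphabet, and sequence template."""

    pairs: tuple[CompoundPair, CompoundPair, CompoundPair]
    n_levels: int = 10
    level_ratios: tuple[float, ...] = ()
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    template: str = DEFAULT_TEMPLATE
    polystyrene_peak: float = 1001.0
    polystyrene_fwhm: float = 12.0

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ConfigurationError(f"n_levels must be >= 1, got {self.n_levels}")
        if len(self.pairs) != 3:
            raise ConfigurationError("a scheme needs exactly 3 compound pairs (X, Y, Z)")
        labels = tuple(p.region_label for p in self.pairs)
        if labels != ("X", "Y", "Z"):
            raise ConfigurationError(f"pairs must be ordered (X, Y, Z), got {labels}")
        if not self.level_ratios:
            # linear dosage ladder r_l = l/(n-1) * r_max, r_0 = 0
            r_max = 1.5
            object.__setattr__(
                self,
                "level_ratios",
                tuple(
                    r_max * l / (self.n_levels - 1) if self.n_levels > 1 else 0.0
                    for l in range(self.n_levels)
                ),
            )
        if len(self.level_ratios) != self.n_levels:
            raise ConfigurationError(
                f"level_ratios has {len(self.level_ratios)} entries for n_levels={self.n_levels}"
            )
        if self.level_ratios[0] != 0.0:
            raise ConfigurationError("level 0 ratio must be exactly 0 (no coding compound)")
        if any(b <= a for a, b in zip(self.level_ratios, self.level_ratios[1:])):
            raise ConfigurationError("level_ratios must be strictly increasing")
        if len(set(self.alphabet)) != self.n_levels:
            raise ConfigurationError(
                f"alphabet needs {self.n_levels} distinct symbols, got {self.alphabet}"
            )
        total = sum(p.allocation_fraction for p in self.pairs)
        if total > 1 + 1e-12:
            raise InfeasiblePlanError(f"pair allocation fractions sum to {total} > 1")
        for slot in ("{X}", "{Y}", "{Z}"):
            if self.template.count(slot) != 1:
                raise ConfigurationError(f"template must contain {slot} exactly once")

    @property
    def capacity(self) -> int:
        return self.n_levels ** len(self.pairs)

    def pair(self, region_label: str) -> CompoundPair:
        for p in self.pairs:
            if p.region_label == region_label:
                return p
        raise ConfigurationError(f"no pair for region {region_label!r}")


def default_scheme() -> CodeScheme:
    """The packaged default: I-2245/I-2220, II-2160/II-2110, III-1140/III-1105.

    Region X is synthesized first on ~60% of amino groups with the Group II
    pair, then Y (Group I, ~30%) and Z (Group III, ~10%).  The first-listed
    compound of each pair is the reference (internal standard).
    """
    pair_x = CompoundPair(
        "X",
        EncodingCompound("II-2160", "II", "reference", 2160.0, native_scale=1.0),
        EncodingCompound("II-2110", "II", "coding", 2110.0, native_scale=1.0),
        allocation_fraction=0.6,
    )
    pair_y = CompoundPair(
        "Y",
        EncodingCompound("I-2245", "I", "reference", 2245.0, native_scale=5.0),
        EncodingCompound("I-2220", "I", "coding", 2220.0, native_scale=5.0),
        allocation_fraction=0.3,
    )
    pair_z = CompoundPair(
        "Z",
        EncodingCompound("III-1140", "III", "reference", 1140.0, native_scale=50.0),
        EncodingCompound("III-1105", "III", "coding", 1105.0, native_scale=50.0),
        allocation_fraction=0.1,
    )
    return CodeScheme(pairs=(pair_x, pair_y, pair_z))


def enumerate_codes(scheme: CodeScheme) -> list[Code]:
    """All ``n_levels**3`` codes in ascending code-number order."""
    if scheme.n_levels < 1:
        raise ConfigurationError("n_levels must be >= 1")
    return [Code(x, y, z) for x, y, z in product(range(scheme.n_levels), repeat=3)]


def code_to_sequence(code: Code, scheme: CodeScheme) -> str:
    """Substitute the alphabet symbols for digits x, y, z into the template."""
    for name, digit in (("x", code.x), ("y", code.y), ("z", code.z)):
        if digit >= scheme.n_levels:
            raise ConfigurationError(
                f"code digit {name}={digit} >= n_levels={scheme.n_levels}"
            )
    return scheme.template.format(
        X=scheme.alphabet[code.x], Y=scheme.alphabet[code.y], Z=scheme.alphabet[code.z]
    )


def _template_layout(template: str) -> list[str]:
    """Per-position layout: literal char, or 'X'/'Y'/'Z' for a variable slot."""
    layout: list[str] = []
    i = 0
    while i < len(template):
        if template[i] == "{" and i + 2 < len(template) and template[i + 2] == "}":
            layout.append(template[i + 1])
            i += 3
        else:
            layout.append(template[i])
            i += 1
    return layout


def sequence_to_code(sequence: str, scheme: CodeScheme) -> Code:
    """Exact inverse of :func:`code_to_sequence`; errors name the bad position."""
    layout = _template_layout(scheme.template)
    if len(sequence) != len(layout):
        raise SequenceParseError(
            f"sequence {sequence!r} has length {len(sequence)}, template needs {len(layout)}"
        )
    digits: dict[str, int] = {}
    for pos, (symbol, slot) in enumerate(zip(sequence, layout), start=1):
        if slot in ("X", "Y", "Z"):
            try:
                digits[slot] = scheme.alphabet.index(symbol)
            except ValueError:
                raise SequenceParseError(
                    f"position {pos}: symbol {symbol!r} not in alphabet {scheme.alphabet}"
                ) from None
        elif symbol != slot:
            raise SequenceParseError(
                f"position {pos}: expected template residue {slot!r}, got {symbol!r}"
            )
    return Code(digits["X"], digits["Y"], digits["Z"])


# --- amino-group allocation arithmetic -------------------------------------

def allocation_remainder(prior_fractions: list[float] | tuple[float, ...]) -> float:
    """Fraction of amino groups still available after the given allocations."""
    total = 0.0
    for f in prior_fractions:
        if not 0 <= f <= 1:
            raise InfeasiblePlanError(f"allocation fraction {f} outside [0, 1]")
        total += f
        if total > 1 + 1e-12:
            raise InfeasiblePlanError(f"allocation fractions sum to {total} > 1")
    return 1.0 - total


@dataclass(frozen=True)
class AllocationPlan:
    """Total per-region fractions and the stepwise Dde-deprotection schedule.

    ``stepwise_deprotection[k]`` is the fraction of *remaining* amino groups
    deprotected at step k, i.e. ``fractions[k] / (1 - sum(fractions[:k]))``.
    """

    fractions: tuple[float, ...]
    stepwise_deprotection: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        allocation_remainder(self.fractions)  # validates
        if not self.stepwise_deprotection:
            object.__setattr__(
                self, "stepwise_deprotection", _stepwise(self.fractions)
            )


def _stepwise(fractions: tuple[float, ...]) -> tuple[float, ...]:
    steps = []
    consumed = 0.0
    for f in fractions:
        remaining = 1.0 - consumed
        if f == 0:
            steps.append(0.0)
        elif remaining <= 0:
            raise InfeasiblePlanError("no amino groups remain for a nonzero allocation")
        else:
            steps.append(f / remaining)
        consumed += f
    return tuple(steps)


def design_allocation(total_fractions: list[float] | tuple[float, ...]) -> AllocationPlan:
    """Turn target per-region fractions into a sequential deprotection schedule."""
    return AllocationPlan(fractions=tuple(float(f) for f in total_fractions))


def simulate_sequential_deprotection(plan: AllocationPlan) -> tuple[float, ...]:
    """Forward-run the stepwise schedule; returns realized per-region fractions."""
    remaining = 1.0
    realized = []
    for step in plan.stepwise_deprotection:
        used = remaining * step
        realized.append(used)
        remaining -= used
    return tuple(realized)


# --- serialization ---------------------------------------------------------

def scheme_to_dict(scheme: CodeScheme) -> dict:
    return {
        "n_levels": scheme.n_levels,
        "level_ratios": list(scheme.level_ratios),
        "alphabet": list(scheme.alphabet),
        "template": scheme.template,
        "polystyrene_peak": scheme.polystyrene_peak,
        "polystyrene_fwhm": scheme.polystyrene_fwhm,
        "pairs": [
            {
                "region_label": p.region_label,
                "allocation_fraction": p.allocation_fraction,
                "reference": vars(p.reference).copy(),
                "coding": vars(p.coding).copy(),
            }
            for p in scheme.pairs
        ],
    }


def scheme_from_dict(data: dict) -> CodeScheme:
    pairs = tuple(
        CompoundPair(
            region_label=p["region_label"],
            reference=EncodingCompound(**p["reference"]),
            coding=EncodingCompound(**p["coding"]),
            allocation_fraction=p["allocation_fraction"],
        )
        for p in data["pairs"]
    )
    return CodeScheme(
        pairs=pairs,  # type: ignore[arg-type]
        n_levels=data["n_levels"],
        level_ratios=tuple(data["level_ratios"]),
        alphabet=tuple(data["alphabet"]),
        template=data["template"],
        polystyrene_peak=data["polystyrene_peak"],
        polystyrene_fwhm=data["polystyrene_fwhm"],
    )


def save_scheme(scheme: CodeScheme, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scheme_to_dict(scheme), sort_keys=False))


def load_scheme(path: str | Path) -> CodeScheme:
    return scheme_from_dict(yaml.safe_load(Path(path).read_text()))
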