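"""Chemical-survivability assay analysis.

An encoding compound passes a reagent condition when the ratio of its
marker peak to the bead's native polystyrene band (an internal standard
immune to global intensity fluctuations) is unchanged between the before-
and after-treatment spectra, within a relative tolerance ``delta``
(default 15%; the published account is qualitative — "unchanged").

The five representative reagent conditions of peptide-library synthesis
are tested in decreasing severity order with an early exit: a failure at
any condition settles the outcome as ``not_pass`` and the remaining, milder
conditions are left untested.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .decode import DEFAULT_WINDOW, quantify_peak
from .errors import IncompletePanelError, InvalidBaselineError, LowSignalError
from .spectrum import Spectrum

__all__ = [
    "SurvivabilityRecord",
    "DEFAULT_SEVERITY_ORDER",
    "reagent_conditions",
    "compound_survivability_table",
    "compound_ratio",
    "assess_condition",
    "panel_outcome",
    "run_panel",
    "record_to_frame",
]

#: Condition names in decreasing severity: the two harshest reagents
#: (Fmoc-deprotection base, global-deprotection acid) first.
DEFAULT_SEVERITY_ORDER = ("piperidine", "tfa", "imidazole_nh2oh", "activation", "dmso_buffer")

DEFAULT_DELTA = 0.15


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("ramancode.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def reagent_conditions() -> pd.DataFrame:
    """The 5-condition reagent panel (index, name, property, chemicals, purpose)."""
    return _load_table("reagent_conditions.tsv")


def compound_survivability_table() -> pd.DataFrame:
    """Reported pass/not-pass outcomes of the 20 named candidate compounds."""
    table = _load_table("compound_survivability.tsv")
    table["first_failed"] = table["first_failed"].fillna("")
    return table


def compound_ratio(
    spectrum: Spectrum,
    compound_peak: float,
    polystyrene_peak: float = 1001.0,
    window: float = DEFAULT_WINDOW,
    min_polystyrene: float = 5.0,
) -> float:
    """Compound-peak / polystyrene-peak height ratio (brightness invariant)."""
    h_ps = quantify_peak(spectrum, polystyrene_peak, window)
    if h_ps < min_polystyrene:
        raise LowSignalError(
            f"polystyrene internal standard at {polystyrene_peak} cm^-1 is "
            f"{h_ps:.3g} a.u., below floor {min_polystyrene} — invalid measurement"
        )
    return quantify_peak(spectrum, compound_peak, window) / h_ps


def assess_condition(
    before: Spectrum,
    after: Spectrum,
    compound_peak: float,
    polystyrene_peak: float = 1001.0,
    delta: float = DEFAULT_DELTA,
    window: float = DEFAULT_WINDOW,
) -> tuple[bool, float, float]:
    """Pass/fail of one condition; returns (passed, R_before, R_after).

    Pass iff ``|R_after - R_before| / R_before <= delta`` (inclusive).
    """
    if not np.array_equal(before.wavenumbers, after.wavenumbers):
        raise InvalidBaselineError("before/after spectra are on different grids")
    r_before = compound_ratio(before, compound_peak, polystyrene_peak, window)
    r_after = compound_ratio(after, compound_peak, polystyrene_peak, window)
    if r_before == 0:
        raise InvalidBaselineError(
            "before-treatment compound/polystyrene ratio is 0; relative change undefined"
        )
    passed = abs(r_after - r_before) / r_before <= delta
    return passed, r_before, r_after


@dataclass
class SurvivabilityRecord:
    """Outcome of the ordered condition panel for one compound.

    ``verdicts``/``ratios`` contain only the conditions actually tested:
    everything after the first failure is absent by the early-exit rule.
    """

    compound: str
    verdicts: dict[str, bool]
    ratios: dict[str, tuple[float, float]]
    outcome: str  # "pass" | "not_pass"
    first_failed: str | None


def panel_outcome(verdicts_in_severity_order: list[bool]) -> tuple[str, int | None, int]:
    """Early-exit evaluation of an ordered verdict list.

    Returns (outcome, index of first failure or None, number tested).
    """
    for i, passed in enumerate(verdicts_in_severity_order):
        if not passed:
            return "not_pass", i, i + 1
    return "pass", None, len(verdicts_in_severity_order)


def run_panel(
    compound: str,
    measurements: dict[str, tuple[Spectrum, Spectrum]],
    compound_peak: float,
    polystyrene_peak: float = 1001.0,
    delta: float = DEFAULT_DELTA,
    severity_order: tuple[str, ...] = DEFAULT_SEVERITY_ORDER,
    window: float = DEFAULT_WINDOW,
) -> SurvivabilityRecord:
    """Evaluate the condition panel in severity order with early exit.

    *measurements* maps condition name to a (before, after) spectrum pair.
    A condition missing before any failure is an :class:`IncompletePanelError`;
    conditions after the first failure need not (and per the early-exit rule
    should not) be measured.
    """
    verdicts: dict[str, bool] = {}
    ratios: dict[str, tuple[float, float]] = {}
    for condition in severity_order:
        if condition not in measurements:
            raise IncompletePanelError(
                f"{compound}: condition {condition!r} missing before any failure; "
                f"panel order is {severity_order}"
            )
        passed, r_before, r_after = assess_condition(
            *measurements[condition],
            compound_peak=compound_peak,
            polystyrene_peak=polystyrene_peak,
            delta=delta,
            window=window,
        )
        verdicts[condition] = passed
        ratios[condition] = (r_before, r_after)
        if not passed:
            return SurvivabilityRecord(compound, verdicts, ratios, "not_pass", condition)
    return SurvivabilityRecord(compound, verdicts, ratios, "pass", None)


def record_to_frame(record: SurvivabilityRecord) -> pd.DataFrame:
    """One row per tested condition, in tested order."""
    rows = []
    for condition, passed in record.verdicts.items():
        r_before, r_after = record.ratios[condition]
        rows.append(
            {
                "compound": record.compound,
                "condition": condition,
                "R_before": r_before,
                "R_after": r_after,
                "relative_change": abs(r_after - r_before) / r_before,
                "verdict": "pass" if passed else "fail",
            }
        )
    return pd.DataFrame(rows)


def treatment_stability(
    codes,
    cfg,
    calibration,
    reagents: tuple[str, ...] = ("piperidine", "tfa"),
    degradation_factor: float = 0.0,
    preprocess_params=None,
    rng=None,
) -> pd.DataFrame:
    """Code-assignment stability under simulated reagent treatments.

    For each code, simulate a bead, apply a treatment degrading every
    encoding-compound peak by *degradation_factor* (0 = fully survivable
    chemistry, the published outcome for the piperidine/TFA stress test of
    the complete code set), and decode before and after.  Returns one row
    per (code, reagent) with the decoded assignments and whether they match.
    """
    from .decode import decode_bead
    from .simulate import simulate_spectrum, simulate_treatment

    rows = []
    for code in codes:
        before = simulate_spectrum(code, cfg, rng=rng, noise=rng is not None)
        decoded_before = decode_bead(before, cfg.scheme, calibration, preprocess_params)
        for reagent in reagents:
            after = before
            for pair in cfg.scheme.pairs:
                for compound in (pair.reference, pair.coding):
                    after = simulate_treatment(
                        after, compound.peak_center, degradation_factor, cfg, rng=None
                    )
            decoded_after = decode_bead(after, cfg.scheme, calibration, preprocess_params)
            rows.append(
                {
                    "code": code.code_number,
                    "reagent": reagent,
                    "before": decoded_before.code.code_number,
                    "after": decoded_after.code.code_number,
                    "unchanged": decoded_before.code == decoded_after.code,
                }
            )
    return pd.DataFrame(rows)
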