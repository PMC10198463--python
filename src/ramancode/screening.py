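"""Positional statistics over decoded positive beads.

After a screen, every positive bead contributes one decoded code; tallying
the level of each code region across positives gives a 3 x n_levels count
matrix (the occurrence table of the three variable residues).  A region
whose counts concentrate on a single level is a *conserved* position; the
modal sequence is the most frequent full code, ties broken deterministically
toward the lower code number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decode import DecodedBead
from .errors import EmptyScreenError, GridMismatchError
from .spectrum import Spectrum

__all__ = [
    "PositionalCounts",
    "ScreenSummary",
    "positional_counts",
    "summarize_screen",
    "spectra_average_by_code",
    "plot_counts",
]

REGIONS = ("X", "Y", "Z")


@dataclass
class PositionalCounts:
    """Level-occurrence counts per code region (rows X, Y, Z)."""

    counts: pd.DataFrame  # index X/Y/Z, columns 0..n_levels-1
    total: int

    def conserved_positions(self) -> list[str]:
        """Regions where exactly one level occurs among the positives."""
        return [
            region
            for region in self.counts.index
            if int((self.counts.loc[region] > 0).sum()) == 1
        ]


@dataclass
class ScreenSummary:
    counts: PositionalCounts
    per_sequence: pd.DataFrame  # code_number, sequence, count (desc)
    modal_sequence: str
    modal_code_number: int
    modal_count: int
    modal_tied: bool
    conserved_positions: list[str]
    n_undecodable: int = 0


def positional_counts(decoded: list[DecodedBead], n_levels: int = 10) -> PositionalCounts:
    """Tally decoded level occurrences per region; rows sum to the bead count."""
    if not decoded:
        raise EmptyScreenError("no decoded beads to tally")
    matrix = np.zeros((3, n_levels), dtype=int)
    for bead in decoded:
        for row, digit in enumerate((bead.code.x, bead.code.y, bead.code.z)):
            matrix[row, digit] += 1
    frame = pd.DataFrame(matrix, index=list(REGIONS), columns=list(range(n_levels)))
    return PositionalCounts(counts=frame, total=len(decoded))


def summarize_screen(
    decoded: list[DecodedBead], n_levels: int = 10, n_undecodable: int = 0
) -> ScreenSummary:
    """Per-sequence tally, modal sequence, and conserved positions."""
    counts = positional_counts(decoded, n_levels)
    tally: dict[int, list] = {}
    for bead in decoded:
        entry = tally.setdefault(bead.code.code_number, [bead.sequence, 0])
        entry[1] += 1
    frame = (
        pd.DataFrame(
            [
                {"code_number": number, "sequence": seq, "count": n}
                for number, (seq, n) in tally.items()
            ]
        )
        .sort_values(["count", "code_number"], ascending=[False, True])
        .reset_index(drop=True)
    )
    top = frame.iloc[0]
    tied = bool((frame["count"] == top["count"]).sum() > 1)
    return ScreenSummary(
        counts=counts,
        per_sequence=frame,
        modal_sequence=str(top["sequence"]),
        modal_code_number=int(top["code_number"]),
        modal_count=int(top["count"]),
        modal_tied=tied,
        conserved_positions=counts.conserved_positions(),
        n_undecodable=n_undecodable,
    )


def spectra_average_by_code(
    grouped: list[tuple[int, Spectrum]]
) -> dict[int, Spectrum]:
    """Pointwise mean spectrum per code (replicate beads of one code collapse
    to a single curve).  All spectra of a code must share one grid."""
    if not grouped:
        raise EmptyScreenError("no spectra to average")
    by_code: dict[int, list[Spectrum]] = {}
    for code_number, spectrum in grouped:
        by_code.setdefault(code_number, []).append(spectrum)
    out: dict[int, Spectrum] = {}
    for code_number, members in by_code.items():
        grid = members[0].wavenumbers
        for s in members[1:]:
            if s.wavenumbers.shape != grid.shape or not np.array_equal(s.wavenumbers, grid):
                raise GridMismatchError(
                    f"code {code_number}: spectra are on different wavenumber grids"
                )
        mean = np.mean([s.intensities for s in members], axis=0)
        out[code_number] = Spectrum(
            grid.copy(), mean, {"code": code_number, "n_averaged": len(members)}
        )
    return out


def plot_counts(counts: PositionalCounts, path=None, ax=None):
    """Heatmap of the 3 x n_levels occurrence matrix (lazy matplotlib import)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    im = ax.imshow(counts.counts.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(counts.counts.index)), counts.counts.index)
    ax.set_xticks(range(counts.counts.shape[1]))
    ax.set_xlabel("level")
    ax.set_ylabel("code region")
    for (i, j), value in np.ndenumerate(counts.counts.to_numpy()):
        if value:
            ax.text(j, i, str(value), ha="center", va="center", color="white", fontsize=8)
    ax.figure.colorbar(im, ax=ax, label="occurrences")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
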