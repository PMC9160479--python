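"""Flow-scatter gating: FSC/SSC events -> 16-population (A-P) percentage profiles.

Nano-sized particles measured on a 4-decade logarithmic flow cytometer are
binned on a 4x4 grid in (log10 FSC, log10 SSC) space.  The sixteen cells are
lettered A-P row-major with rows ordered by *descending* SSC decade and
columns by ascending FSC decade, so "A" is the lowest-FSC / highest-SSC cell
and "M" is the lowest-FSC / lowest-SSC cell (the smallest, least dense
particles).  Per-population event counts are corrected by subtracting a
paired instrument blank (PBS) acquired at the same flow rate and duration,
clamped at zero, and expressed as percentages of the corrected total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "POPULATION_LETTERS",
    "GateGrid",
    "PopulationProfile",
    "default_grid",
    "assign_population",
    "population_counts",
    "blank_correct",
    "population_percentages",
    "profile_from_events",
]

#: Row-major letters: row 0 = highest SSC decade, column 0 = lowest FSC decade.
POPULATION_LETTERS: tuple[str, ...] = tuple("ABCDEFGHIJKLMNOP")

OUT_OF_RANGE = "out_of_range"


def _letter_index(letter: str) -> int:
    return POPULATION_LETTERS.index(letter)


@dataclass(frozen=True)
class GateGrid:
    """4x4 log-scale gate.

    Parameters
    ----------
    fsc_edges, ssc_edges:
        Five strictly increasing bin boundaries each, in log10 intensity
        units, forming four bins per axis.  Cells are half-open
        ``[low, high)`` except the top edge, which is closed.
    """

    fsc_edges: tuple[float, ...]
    ssc_edges: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, edges in (("fsc_edges", self.fsc_edges), ("ssc_edges", self.ssc_edges)):
            edges = tuple(float(e) for e in edges)
            object.__setattr__(self, name, edges)
            if len(edges) != 5:
                raise ValueError(f"{name} must have exactly 5 boundaries, got {len(edges)}")
            if not all(b > a for a, b in zip(edges, edges[1:])):
                raise ValueError(f"{name} must be strictly increasing: {edges}")

    def cell_bounds(self, letter: str) -> tuple[tuple[float, float], tuple[float, float]]:
        """(log10 FSC interval, log10 SSC interval) of a lettered cell."""
        idx = _letter_index(letter)
        row, col = divmod(idx, 4)  # row 0 = top SSC decade
        fsc_lo, fsc_hi = self.fsc_edges[col], self.fsc_edges[col + 1]
        ssc_bin = 3 - row  # bottom SSC bin is index 0 on the axis
        ssc_lo, ssc_hi = self.ssc_edges[ssc_bin], self.ssc_edges[ssc_bin + 1]
        return (fsc_lo, fsc_hi), (ssc_lo, ssc_hi)


def default_grid() -> GateGrid:
    """One gate per decade over the 4-decade instrument range (log10 0..4)."""
    edges = (0.0, 1.0, 2.0, 3.0, 4.0)
    return GateGrid(fsc_edges=edges, ssc_edges=edges)


@dataclass
class PopulationProfile:
    """Percentages of the 16 corrected populations (keyed A..P)."""

    percentages: dict[str, float]
    total_corrected_events: int
    degenerate: bool = field(default=False)

    def as_series(self) -> pd.Series:
        return pd.Series(self.percentages, index=list(POPULATION_LETTERS), dtype=float)


def _bin_axis(log_values: np.ndarray, edges: tuple[float, ...]) -> np.ndarray:
    """Half-open [low, high) bins, top edge closed; -1 marks out-of-range."""
    idx = np.searchsorted(np.asarray(edges), log_values, side="right") - 1
    idx = np.where(np.isclose(log_values, edges[-1]), 3, idx)
    idx = np.where((log_values < edges[0]) | (log_values > edges[-1]), -1, idx)
    return idx.astype(int)


def assign_population(fsc: float, ssc: float, grid: GateGrid) -> str:
    """Letter (A..P) of the gate containing one event, or ``"out_of_range"``."""
    if fsc <= 0 or ssc <= 0:
        raise ValueError(f"scatter intensities must be positive, got fsc={fsc}, ssc={ssc}")
    fcol = _bin_axis(np.asarray([np.log10(fsc)]), grid.fsc_edges)[0]
    sbin = _bin_axis(np.asarray([np.log10(ssc)]), grid.ssc_edges)[0]
    if fcol < 0 or sbin < 0:
        return OUT_OF_RANGE
    row = 3 - sbin
    return POPULATION_LETTERS[row * 4 + fcol]


def population_counts(events: pd.DataFrame, grid: GateGrid) -> tuple[pd.Series, int]:
    """Events per gate plus the out-of-range tally.

    ``events`` needs ``fsc`` and ``ssc`` columns of positive intensities;
    an empty table yields all-zero counts.
    """
    counts = pd.Series(0, index=list(POPULATION_LETTERS), dtype=int)
    if len(events) == 0:
        return counts, 0
    fsc = np.asarray(events["fsc"], dtype=float)
    ssc = np.asarray(events["ssc"], dtype=float)
    if np.any(fsc <= 0) or np.any(ssc <= 0):
        raise ValueError("scatter intensities must be positive")
    fcol = _bin_axis(np.log10(fsc), grid.fsc_edges)
    sbin = _bin_axis(np.log10(ssc), grid.ssc_edges)
    inside = (fcol >= 0) & (sbin >= 0)
    cell = (3 - sbin[inside]) * 4 + fcol[inside]
    binned = np.bincount(cell, minlength=16)
    counts.iloc[:] = binned
    return counts, int((~inside).sum())


def blank_correct(sample_counts: pd.Series, blank_counts: pd.Series) -> pd.Series:
    """Per-population blank subtraction, clamped at zero.

    Both acquisitions are assumed to share flow rate and duration, so raw
    counts are directly comparable.
    """
    s = np.asarray(sample_counts, dtype=float)
    b = np.asarray(blank_counts, dtype=float)
    if s.shape != (16,) or b.shape != (16,):
        raise ValueError(f"expected two 16-vectors, got shapes {s.shape} and {b.shape}")
    if np.any(s < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    corrected = np.maximum(s - b, 0.0)
    return pd.Series(corrected, index=list(POPULATION_LETTERS))


def population_percentages(corrected_counts: pd.Series) -> PopulationProfile:
    """Composition of the 16 corrected gates, summing to 100.

    All-zero input yields the degenerate all-zero profile (flagged), which
    downstream assembly treats as a failed acquisition.
    """
    c = np.asarray(corrected_counts, dtype=float)
    if c.shape != (16,):
        raise ValueError(f"expected a 16-vector, got shape {c.shape}")
    if np.any(c < 0):
        raise ValueError("corrected counts must be non-negative")
    total = c.sum()
    if total == 0:
        pct = np.zeros(16)
        return PopulationProfile(dict(zip(POPULATION_LETTERS, pct)), 0, degenerate=True)
    pct = 100.0 * c / total
    return PopulationProfile(dict(zip(POPULATION_LETTERS, pct)), int(round(total)))


def profile_from_events(
    sample: pd.DataFrame, blank: pd.DataFrame, grid: GateGrid
) -> PopulationProfile:
    """Full chain: gate sample and blank, subtract, convert to percentages."""
    sample_counts, _ = population_counts(sample, grid)
    blank_counts, _ = population_counts(blank, grid)
    return population_percentages(blank_correct(sample_counts, blank_counts))
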