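"""Raw assay readouts -> analysis-ready quantities.

Endpoint antibody titers are interpolated from ELISA dilution series
(log-linear crossing of the OD450 = 0.2 cutoff), group readouts are turned
into fold changes against the antigen-alone group or background-subtracted
concentrations, and per-substance feature blocks are aligned into the
matrices consumed by the latent-variable integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ENDPOINTS",
    "BLOCK_NAMES",
    "DilutionSeries",
    "FeatureBlock",
    "TiterResult",
    "titer_from_od",
    "fold_change",
    "background_subtract",
    "assemble_blocks",
    "scale_columns",
]

#: Canonical in-vivo adjuvanticity endpoints: fold-change IgG titers against
#: the antigen-alone group, and background-subtracted IgE / T-cell cytokines.
ENDPOINTS: tuple[str, ...] = (
    "totalIgG_fc",
    "igg1_fc",
    "igg2c_fc",
    "ige_delta",
    "il13_delta",
    "ifng_delta",
)

BLOCK_NAMES: tuple[str, ...] = ("human_cytokine", "mouse_cytokine", "particle")

DEFAULT_CUTOFF = 0.2


@dataclass(frozen=True)
class DilutionSeries:
    """One ELISA dilution curve: reciprocal dilutions vs OD450 readings."""

    dilutions: np.ndarray
    od_values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dilutions, dtype=float)
        od = np.asarray(self.od_values, dtype=float)
        object.__setattr__(self, "dilutions", d)
        object.__setattr__(self, "od_values", od)
        if d.ndim != 1 or od.ndim != 1 or len(d) != len(od):
            raise ValueError("dilutions and od_values must be 1-D of equal length")
        if len(d) < 2:
            raise ValueError("a dilution series needs at least two points")
        if np.any(d <= 0):
            raise ValueError("reciprocal dilutions must be positive")
        if np.any(np.diff(d) <= 0):
            raise ValueError("dilutions must be strictly increasing")


@dataclass(frozen=True)
class TiterResult:
    titer: float
    censored: str | None = None  # None | "low" | "high"

    def __float__(self) -> float:
        return float(self.titer)


def titer_from_od(series: DilutionSeries, cutoff: float = DEFAULT_CUTOFF) -> TiterResult:
    """Endpoint titer: the dilution at which the curve crosses ``cutoff``.

    The curve is taken piecewise linear in (log10 dilution, OD) between the
    measured points.  A series that starts below the cutoff is censored low
    (titer = smallest dilution); one that ends above it is censored high
    (titer = largest dilution).  Non-monotone series with several crossings
    use the first crossing from the low-dilution end, with a warning.
    """
    d, od = series.dilutions, series.od_values
    if od[0] < cutoff:
        return TiterResult(titer=float(d[0]), censored="low")
    if od[-1] > cutoff:
        return TiterResult(titer=float(d[-1]), censored="high")
    crossings = [
        i
        for i in range(len(d) - 1)
        if (od[i] >= cutoff > od[i + 1]) or (od[i] <= cutoff < od[i + 1])
    ]
    # an exactly-at-cutoff point is its own crossing
    exact = np.flatnonzero(od == cutoff)
    if len(exact) and (not crossings or exact[0] <= crossings[0]):
        return TiterResult(titer=float(d[exact[0]]))
    if len(crossings) > 1:
        warnings.warn(
            "dilution series crosses the cutoff more than once; "
            "using the first crossing from the low-dilution end",
            stacklevel=2,
        )
    i = crossings[0]
    logd = np.log10(d)
    frac = (od[i] - cutoff) / (od[i] - od[i + 1])
    log_titer = logd[i] + frac * (logd[i + 1] - logd[i])
    return TiterResult(titer=float(10.0**log_titer))


def fold_change(group_values, reference_values) -> float:
    """Ratio of group mean to reference (antigen-alone) group mean."""
    g = np.asarray(group_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    if g.size == 0 or r.size == 0:
        raise ValueError("both groups must be non-empty")
    ref_mean = r.mean()
    if ref_mean <= 0:
        raise ValueError(f"reference mean must be positive, got {ref_mean}")
    return float(g.mean() / ref_mean)


def background_subtract(values, background_values) -> float:
    """mean(values) - mean(background), floored at zero.

    Concentrations below background are reported as 0 rather than negative:
    the downstream blocks assume non-negative concentrations.
    """
    v = np.asarray(values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    if v.size == 0 or b.size == 0:
        raise ValueError("both inputs must be non-empty")
    if np.any(v < 0) or np.any(b < 0):
        raise ValueError("raw concentrations must be non-negative (check upstream units)")
    return float(max(v.mean() - b.mean(), 0.0))


@dataclass
class FeatureBlock:
    """Substances x features matrix for one data block."""

    name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.name not in BLOCK_NAMES:
            raise ValueError(f"unknown block name {self.name!r}; expected one of {BLOCK_NAMES}")
        self.validate()

    @property
    def substance_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def validate(self, atol: float = 1e-6) -> None:
        df = self.data
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(f"block {self.name!r} contains NaN in columns {bad}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate substance ids in block {self.name!r}: {dups}")
        values = df.to_numpy(dtype=float)
        if self.name == "particle":
            sums = values.sum(axis=1)
            off = np.flatnonzero(np.abs(sums - 100.0) > atol)
            if len(off):
                ids = [df.index[i] for i in off[:5]]
                raise ValueError(
                    f"particle rows must sum to 100 +- {atol}; offenders include {ids} "
                    f"(sums {sums[off[:5]].round(4).tolist()})"
                )
        elif np.any(values < 0):
            raise ValueError(f"cytokine block {self.name!r} has negative concentrations")


def assemble_blocks(
    raw_blocks: dict[str, pd.DataFrame], outcome_table: pd.DataFrame
) -> tuple[dict[str, FeatureBlock], pd.DataFrame]:
    """Align blocks and outcomes on a canonical (sorted) substance order.

    Every substance must be present in every input; offenders are named.
    """
    expected = set(BLOCK_NAMES)
    if set(raw_blocks) != expected:
        raise ValueError(f"expected blocks {sorted(expected)}, got {sorted(raw_blocks)}")
    all_ids = set(outcome_table.index)
    for df in raw_blocks.values():
        all_ids |= set(df.index)
    canonical = sorted(all_ids)
    missing_msgs = []
    for name, df in list(raw_blocks.items()) + [("outcomes", outcome_table)]:
        missing = sorted(all_ids - set(df.index))
        if missing:
            missing_msgs.append(f"{name}: {missing}")
    if missing_msgs:
        raise ValueError("substances missing from some tables -- " + "; ".join(missing_msgs))
    outcomes = outcome_table.loc[canonical].astype(float)
    if list(outcomes.columns) != list(ENDPOINTS):
        missing_cols = [c for c in ENDPOINTS if c not in outcomes.columns]
        if missing_cols:
            raise ValueError(f"outcome table lacks endpoints {missing_cols}")
        outcomes = outcomes[list(ENDPOINTS)]
    if outcomes.isna().any().any():
        raise ValueError("outcome table contains NaN")
    if not np.all(np.isfinite(outcomes.to_numpy())):
        raise ValueError("outcome table contains non-finite values")
    blocks = {
        name: FeatureBlock(name=name, data=raw_blocks[name].loc[canonical].astype(float))
        for name in BLOCK_NAMES
    }
    return blocks, outcomes


@dataclass
class ScaledMatrix:
    data: pd.DataFrame
    dropped: list[str] = field(default_factory=list)
    center: pd.Series | None = None
    scale: pd.Series | None = None


def scale_columns(matrix: pd.DataFrame | np.ndarray) -> ScaledMatrix:
    """Standardize columns to mean 0, sample SD 1 (n-1 denominator).

    Zero-variance columns carry no information for correlation-based
    analyses; they are dropped with a warning and reported in the result.
    """
    df = pd.DataFrame(matrix).astype(float)
    if len(df) < 2:
        raise ValueError("need at least 2 rows to standardize")
    sd = df.std(ddof=1)
    dropped = sd.index[sd == 0].tolist()
    if len(dropped) == len(df.columns):
        raise ValueError("all columns have zero variance")
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
        df = df.drop(columns=dropped)
        sd = sd.drop(index=dropped)
    mean = df.mean()
    scaled = (df - mean) / sd
    return ScaledMatrix(data=scaled, dropped=dropped, center=mean, scale=sd)
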