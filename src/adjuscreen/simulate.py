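"""Synthetic immunoprofiling cohorts with planted latent structure.

The generator emulates the statistical skeleton the integration methods
assume: an 80-substance cohort (73 library extracts + 7 potent control
adjuvants) profiled on three blocks -- human cytokines, mouse cytokines and
a 16-population nanoparticle scatter composition -- plus six in-vivo
adjuvanticity endpoints.

Two independent standard-normal latent factors drive the data:

* ``z_pos`` loads positively on a handful of informative cytokines in each
  species block and raises every outcome endpoint;
* ``z_neg`` raises the log-abundance of one designated particle population
  while *lowering* the outcomes, making that population an independent
  negative screening parameter.

Cytokine concentrations are log-normal (non-negative, right-skewed);
particle profiles are softmax-closed compositions summing to 100; outcomes
are exponentiated linear predictors so fold changes stay positive.  Control
substances are drawn from the same model with a +1 SD shift on ``z_pos``.
All randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gating import POPULATION_LETTERS, GateGrid
from .preprocess import ENDPOINTS, DilutionSeries, FeatureBlock

__all__ = [
    "HUMAN_CYTOKINES",
    "MOUSE_CYTOKINES",
    "SimConfig",
    "PlantedSignal",
    "generate_cohort",
    "generate_event_table",
    "generate_dilution_series",
]

HUMAN_CYTOKINES: tuple[str, ...] = (
    "hIL-1b", "hIL-2", "hIL-4", "hIL-5", "hIL-6", "hIL-7", "hIL-8", "hIL-10",
    "hIL-12p70", "hIL-13", "hIL-17", "hG-CSF", "hGM-CSF", "hIFN-g", "hMCP-1",
    "hMIP-1b", "hTNF-a", "hIFN-a",
)

MOUSE_CYTOKINES: tuple[str, ...] = (
    "mIL-1a", "mIL-1b", "mIL-2", "mIL-3", "mIL-4", "mIL-5", "mIL-6", "mIL-9",
    "mIL-10", "mIL-12p40", "mIL-12p70", "mIL-13", "mIL-17A", "mEotaxin",
    "mG-CSF", "mGM-CSF", "mIFN-g", "mKC", "mMCP-1", "mMIP-1a", "mMIP-1b",
    "mRANTES", "mTNF-a",
)

# Default planted positive signatures: the chemokine/growth-factor panel the
# screen is meant to rediscover (G-CSF, GM-CSF, MIP-1b, IL-8/KC-family, MCP-1
# analogues; RANTES on the mouse side).
_DEFAULT_POS_HUMAN = ("hG-CSF", "hGM-CSF", "hMIP-1b", "hIL-8", "hMCP-1")
_DEFAULT_POS_MOUSE = ("mRANTES", "mMIP-1b", "mMCP-1", "mIL-5", "mG-CSF")

#: Index of population M (lowest FSC, lowest SSC) in the A..P layout.
_DEFAULT_NEG_POPULATION = POPULATION_LETTERS.index("M")  # == 12

#: ELISA endpoint-titer cutoff absorbance (OD450).
DEFAULT_CUTOFF_OD = 0.2

# Baseline particle log-abundances: populations J, K, N and H are the
# typical majors in scatter profiles of this kind.
_PARTICLE_BASELINE = {"J": 1.5, "K": 1.5, "N": 1.5, "H": 1.5, "M": 0.5}


def _default_outcome_link() -> dict[str, tuple[float, float]]:
    # (w_pos, w_neg) per endpoint on the log scale: the positive factor is
    # the primary driver, the negative factor a secondary antagonist.
    return {endpoint: (1.0, 0.5) for endpoint in ENDPOINTS}


@dataclass
class SimConfig:
    """Knobs of the cohort generator (defaults = the study-shaped cohort)."""

    n_extracts: int = 73
    n_controls: int = 7
    n_human: int = 18
    n_mouse: int = 23
    n_particle: int = 16
    informative_pos_human: tuple[int, ...] = tuple(
        HUMAN_CYTOKINES.index(c) for c in _DEFAULT_POS_HUMAN
    )
    informative_pos_mouse: tuple[int, ...] = tuple(
        MOUSE_CYTOKINES.index(c) for c in _DEFAULT_POS_MOUSE
    )
    informative_neg: int = _DEFAULT_NEG_POPULATION
    effect_pos: float = 1.0
    effect_neg: float = 1.0
    noise_sd: float = 0.5
    control_shift: float = 1.0
    outcome_link: dict[str, tuple[float, float]] = field(default_factory=_default_outcome_link)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_extracts < 2 or self.n_controls < 2:
            raise ValueError("n_extracts and n_controls must each be >= 2")
        if min(self.n_human, self.n_mouse, self.n_particle) < 2:
            raise ValueError("every block needs at least 2 features")
        if self.effect_pos <= 0 or self.effect_neg <= 0:
            raise ValueError("effect sizes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.informative_neg < self.n_particle):
            raise ValueError(
                f"informative_neg must lie in 0..{self.n_particle - 1}, got {self.informative_neg}"
            )
        for name, idx, limit in (
            ("informative_pos_human", self.informative_pos_human, self.n_human),
            ("informative_pos_mouse", self.informative_pos_mouse, self.n_mouse),
        ):
            if any(not (0 <= i < limit) for i in idx):
                raise ValueError(f"{name} indices must lie in 0..{limit - 1}, got {idx}")
        missing = [e for e in ENDPOINTS if e not in self.outcome_link]
        if missing:
            raise ValueError(f"outcome_link lacks endpoints {missing}")

    @property
    def n_substances(self) -> int:
        return self.n_extracts + self.n_controls


@dataclass
class PlantedSignal:
    """Ground truth stored alongside every generated cohort."""

    z_pos: pd.Series
    z_neg: pd.Series
    informative_human: list[str]
    informative_mouse: list[str]
    informative_particle: str
    true_outcome_means: pd.DataFrame  # noise-free exp(linear predictor)

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"z_pos": self.z_pos, "z_neg": self.z_neg})
        return df.join(self.true_outcome_means.add_prefix("mean_"))


def _feature_names(config: SimConfig) -> dict[str, list[str]]:
    human = list(HUMAN_CYTOKINES[: config.n_human])
    human += [f"hX{i}" for i in range(len(human), config.n_human)]
    mouse = list(MOUSE_CYTOKINES[: config.n_mouse])
    mouse += [f"mX{i}" for i in range(len(mouse), config.n_mouse)]
    if config.n_particle == 16:
        particle = list(POPULATION_LETTERS)
    else:
        particle = [f"P{i}" for i in range(config.n_particle)]
    return {"human_cytokine": human, "mouse_cytokine": mouse, "particle": particle}


def generate_cohort(
    config: SimConfig | None = None,
) -> tuple[dict[str, FeatureBlock], pd.DataFrame, PlantedSignal]:
    """Draw one cohort: three feature blocks, outcome table, ground truth."""
    config = config if config is not None else SimConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_substances
    ids = [f"extract_{i + 1:02d}" for i in range(config.n_extracts)] + [
        f"control_{i + 1}" for i in range(config.n_controls)
    ]
    names = _feature_names(config)

    z_pos = rng.standard_normal(n)
    z_pos[config.n_extracts:] += config.control_shift  # potent controls
    z_neg = rng.standard_normal(n)

    def cytokine_block(n_feat: int, informative: tuple[int, ...]) -> np.ndarray:
        log_conc = config.noise_sd * rng.standard_normal((n, n_feat))
        log_conc[:, list(informative)] += config.effect_pos * z_pos[:, None]
        return np.exp(log_conc)

    human = cytokine_block(config.n_human, config.informative_pos_human)
    mouse = cytokine_block(config.n_mouse, config.informative_pos_mouse)

    baseline = np.zeros(config.n_particle)
    for letter, value in _PARTICLE_BASELINE.items():
        j = names["particle"].index(letter) if letter in names["particle"] else -1
        if 0 <= j < config.n_particle:
            baseline[j] = value
    log_abund = baseline[None, :] + config.noise_sd * rng.standard_normal((n, config.n_particle))
    log_abund[:, config.informative_neg] += config.effect_neg * z_neg
    expo = np.exp(log_abund - log_abund.max(axis=1, keepdims=True))
    particle = 100.0 * expo / expo.sum(axis=1, keepdims=True)
    # exact compositional closure despite floating point
    particle[:, -1] = 100.0 - particle[:, :-1].sum(axis=1)

    linpred = {
        e: config.outcome_link[e][0] * z_pos - config.outcome_link[e][1] * z_neg
        for e in ENDPOINTS
    }
    outcomes = pd.DataFrame(
        {
            e: np.exp(linpred[e] + config.noise_sd * rng.standard_normal(n))
            for e in ENDPOINTS
        },
        index=ids,
    )
    truth = PlantedSignal(
        z_pos=pd.Series(z_pos, index=ids),
        z_neg=pd.Series(z_neg, index=ids),
        informative_human=[names["human_cytokine"][i] for i in config.informative_pos_human],
        informative_mouse=[names["mouse_cytokine"][i] for i in config.informative_pos_mouse],
        informative_particle=names["particle"][config.informative_neg],
        true_outcome_means=pd.DataFrame(
            {e: np.exp(linpred[e]) for e in ENDPOINTS}, index=ids
        ),
    )
    blocks = {
        "human_cytokine": FeatureBlock(
            "human_cytokine", pd.DataFrame(human, index=ids, columns=names["human_cytokine"])
        ),
        "mouse_cytokine": FeatureBlock(
            "mouse_cytokine", pd.DataFrame(mouse, index=ids, columns=names["mouse_cytokine"])
        ),
        "particle": FeatureBlock(
            "particle", pd.DataFrame(particle, index=ids, columns=names["particle"])
        ),
    }
    return blocks, outcomes, truth


def generate_event_table(
    grid: GateGrid,
    population_probs,
    n_events: int,
    blank_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw scatter events for one sample plus its paired instrument blank.

    Sample events are multinomial over the 16 gates, placed uniformly (in
    log10 units) inside their assigned cell so re-gating recovers the drawn
    counts exactly; the blank holds Poisson(``blank_rate``) events per gate.
    The drawn per-gate counts are attached as ``table.attrs["true_counts"]``.
    """
    probs = np.asarray(population_probs, dtype=float)
    if probs.shape != (16,):
        raise ValueError(f"population_probs must have length 16, got shape {probs.shape}")
    if np.any(probs < 0):
        raise ValueError("population_probs must be non-negative")
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError(f"population_probs must sum to 1, got {probs.sum()}")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if blank_rate < 0:
        raise ValueError("blank_rate must be non-negative")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, probs / probs.sum())

    def events_for(cell_counts: np.ndarray) -> pd.DataFrame:
        fsc, ssc = [], []
        for idx, c in enumerate(cell_counts):
            if c == 0:
                continue
            letter = POPULATION_LETTERS[idx]
            (flo, fhi), (slo, shi) = grid.cell_bounds(letter)
            # strictly interior draws: the half-open cell convention can
            # never push a generated event into a neighbouring gate
            fsc.append(10.0 ** rng.uniform(flo, fhi, size=c))
            ssc.append(10.0 ** rng.uniform(slo, shi, size=c))
        if not fsc:
            return pd.DataFrame({"fsc": [], "ssc": []})
        return pd.DataFrame({"fsc": np.concatenate(fsc), "ssc": np.concatenate(ssc)})

    sample = events_for(counts)
    sample.attrs["true_counts"] = pd.Series(counts, index=list(POPULATION_LETTERS))
    blank_counts = rng.poisson(blank_rate, size=16)
    blank = events_for(blank_counts)
    blank.attrs["true_counts"] = pd.Series(blank_counts, index=list(POPULATION_LETTERS))
    return sample, blank


def generate_dilution_series(
    true_titer: float,
    dilution_start: float = 100.0,
    dilution_factor: float = 4.0,
    n_points: int = 8,
    od_max: float = 3.5,
    od_floor: float = 0.02,
    seed: int = 0,
) -> DilutionSeries:
    """A monotone ELISA curve whose log-linear cutoff crossing is ``true_titer``.

    ODs decrease with dilution; between the pair of points bracketing the
    true titer the curve is constructed so that linear interpolation in
    (log10 dilution, OD) crosses OD = 0.2 exactly at ``true_titer``.  A titer
    outside the dilution range yields a flagged (attrs) all-high or all-low
    series for censoring tests.
    """
    if dilution_start <= 0 or dilution_factor <= 1 or n_points < 2:
        raise ValueError("need dilution_start > 0, dilution_factor > 1, n_points >= 2")
    if not od_floor < DEFAULT_CUTOFF_OD < od_max:
        raise ValueError("od_floor < 0.2 < od_max required")
    rng = np.random.default_rng(seed)
    dilutions = dilution_start * dilution_factor ** np.arange(n_points)
    cutoff = DEFAULT_CUTOFF_OD

    def descending(k: int, low: float, high: float) -> np.ndarray:
        if k == 0:
            return np.array([])
        vals = rng.uniform(low, high, size=k)
        return np.sort(vals)[::-1]

    if true_titer < dilutions[0] or true_titer > dilutions[-1]:
        flag = "low" if true_titer < dilutions[0] else "high"
        if flag == "low":
            od = descending(n_points, od_floor, cutoff * 0.9)
        else:
            od = descending(n_points, cutoff * 1.2, od_max)
        series = DilutionSeries(dilutions=dilutions, od_values=od)
        object.__setattr__(series, "censored_construction", flag)
        return series

    logd = np.log10(dilutions)
    logt = np.log10(true_titer)
    i = int(np.searchsorted(logd, logt, side="right") - 1)
    od = np.empty(n_points)
    if np.isclose(logt, logd[i]) or i == n_points - 1:
        # titer falls on a measured point: pin it to the cutoff exactly
        i = i if np.isclose(logt, logd[i]) else n_points - 1
        od[i] = cutoff
        od[:i] = descending(i, cutoff + 0.15, od_max)
        od[i + 1:] = descending(n_points - i - 1, od_floor, cutoff - 0.05)
    else:
        alpha = (logt - logd[i]) / (logd[i + 1] - logd[i])  # in (0, 1)
        u_cap = (cutoff - od_floor) * alpha / (1.0 - alpha) if alpha < 1 else np.inf
        u = min(rng.uniform(0.1, 0.6), 0.95 * u_cap, (od_max - cutoff) * 0.5)
        od[i] = cutoff + u
        od[i + 1] = cutoff - u * (1.0 - alpha) / alpha
        od[:i] = descending(i, od[i] + 0.05, od_max)
        od[i + 2:] = descending(n_points - i - 2, od_floor, max(od[i + 1] - 0.005, od_floor * 1.01))
    return DilutionSeries(dilutions=dilutions, od_values=od)
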