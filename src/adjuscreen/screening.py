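"""Threshold screening, separation statistics and PCA discrimination.

The headline procedure: screen substances on an in-vitro parameter at its
cohort-mean threshold (positive parameters pass above, negative parameters
pass below), optionally as a two-step screen (negative particle-population
step first, then the positive cytokine step among survivors), and quantify
how well the screened group separates from the rest on an in-vivo outcome
with an unpaired pooled-variance t-test.  A PCA-based variant splits
component-1 scores at their mean and orients the component so the side
enriched for the designated positive parameters is the screened group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .multiblock import LatentModel, block_splsda, dichotomize, pca
from .preprocess import scale_columns

__all__ = [
    "ScreeningResult",
    "threshold_screen",
    "two_step_screen",
    "separation_test",
    "correlate",
    "pca_discriminate",
    "screening_report",
]


@dataclass
class ScreeningResult:
    """A screened / non-screened partition with its separation statistics."""

    mask: np.ndarray
    thresholds: dict[str, tuple[float, str]] = field(default_factory=dict)
    n_screened: int = 0
    n_not_screened: int = 0
    screened_mean: float = float("nan")
    not_screened_mean: float = float("nan")
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    degrees_of_freedom: int = 0
    step_survivors: list[int] | None = None


def threshold_screen(
    values, threshold: float | str = "auto", direction: str = "positive"
) -> tuple[np.ndarray, float]:
    """Mask of substances passing one threshold rule.

    ``threshold="auto"`` uses the arithmetic mean over all substances
    (extracts and controls jointly).  Positive screens pass values >=
    threshold; negative screens pass values strictly below it, so a
    substance sitting exactly at a negative threshold is rejected.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 substances to screen")
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"threshold must be a number or 'auto', got {threshold!r}")
        if len(np.unique(v)) < 2:
            raise ValueError("auto-mean threshold is degenerate for constant values")
        thr = float(v.mean())
    else:
        thr = float(threshold)
    mask = v >= thr if direction == "positive" else v < thr
    return mask, thr


def two_step_screen(
    neg_values,
    pos_values,
    neg_threshold: float | str = "auto",
    pos_threshold: float | str = "auto",
) -> tuple[np.ndarray, dict]:
    """Negative screen first, then the positive screen among survivors.

    The final mask is the logical AND of the two rules; auto thresholds are
    computed over all substances jointly (not survivors only).  Step-wise
    survivor counts are returned alongside the thresholds used.
    """
    neg_values = np.asarray(neg_values, dtype=float)
    pos_values = np.asarray(pos_values, dtype=float)
    if neg_values.shape != pos_values.shape:
        raise ValueError("negative and positive parameter vectors must be aligned")
    neg_mask, neg_thr = threshold_screen(neg_values, neg_threshold, "negative")
    pos_mask, pos_thr = threshold_screen(pos_values, pos_threshold, "positive")
    mask = neg_mask & pos_mask
    info = {
        "neg_threshold": neg_thr,
        "pos_threshold": pos_thr,
        "step_survivors": [int(neg_mask.sum()), int(mask.sum())],
    }
    return mask, info


def separation_test(outcome_values, mask, welch: bool = False) -> ScreeningResult:
    """Two-sample t-test between screened and non-screened outcome values.

    Pooled-variance Student's t by default (two-tailed); ``welch=True``
    switches to the unequal-variance fallback.
    """
    v = np.asarray(outcome_values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if v.shape != mask.shape:
        raise ValueError("outcome values and mask must be aligned")
    a, b = v[mask], v[~mask]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"both groups need >= 2 members for the t-test (got {len(a)} vs {len(b)}); "
            "for unequal, tiny groups consider welch=True after enlarging the screen"
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = len(a) + len(b) - 2 if not welch else res.df
    return ScreeningResult(
        mask=mask,
        n_screened=len(a),
        n_not_screened=len(b),
        screened_mean=float(a.mean()),
        not_screened_mean=float(b.mean()),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        degrees_of_freedom=int(round(df)),
    )


def correlate(parameter_values, outcome_values) -> tuple[float, float]:
    """Pearson correlation with its t-based two-tailed p-value."""
    x = np.asarray(parameter_values, dtype=float)
    y = np.asarray(outcome_values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pca_discriminate(
    parameter_matrix: pd.DataFrame,
    outcome_fold_changes,
    positive_parameter_names: list[str],
) -> tuple[ScreeningResult, np.ndarray]:
    """Screen by splitting PCA component-1 scores at their mean.

    The parameter matrix is standardized; component 1 is oriented so the
    score side whose substances have the higher mean of the designated
    positive parameters is labeled "screened".  The split is then scored by
    ``separation_test`` on the outcome.
    """
    df = pd.DataFrame(parameter_matrix)
    if df.shape[0] < 3 or df.shape[1] < 2:
        raise ValueError("need at least 3 substances and 2 parameters")
    missing = [c for c in positive_parameter_names if c not in df.columns]
    if missing:
        raise ValueError(f"positive parameters not in matrix: {missing}")
    scaled = scale_columns(df)
    model = pca(scaled.data, scale=False, n_components=min(2, df.shape[1]))
    comp1 = model.scores[:, 0]
    thr = float(comp1.mean())  # 0 under centering; kept explicit for robustness
    side = comp1 > thr
    if side.all() or not side.any():
        raise ValueError("all substances fall on one side of component 1")
    pos_cols = [c for c in positive_parameter_names if c in scaled.data.columns]
    if not pos_cols:
        raise ValueError("all designated positive parameters were zero-variance")
    pos_mean = scaled.data[pos_cols].mean(axis=1).to_numpy()
    screened = side if pos_mean[side].mean() >= pos_mean[~side].mean() else ~side
    result = separation_test(outcome_fold_changes, screened)
    result.thresholds = {"component_1": (thr, "positive")}
    return result, comp1


def screening_report(
    blocks: dict[str, object],
    outcomes: pd.DataFrame,
    models: dict[str, LatentModel] | None = None,
    keepX: int = 10,
    negative_block: str = "particle",
) -> dict[str, dict]:
    """Per-endpoint screening summary tying feature selection to screens.

    For each outcome endpoint: dichotomize at the cohort mean, fit (or
    reuse) a one-component discriminant model at ``keepX`` per block, list
    selected parameters with their dominant class and outcome correlation,
    then run the single-step positive screen, the two-step screen (negative
    particle step first, when one is selected) and PCA discrimination on
    the selected parameters.  Endpoints with no positive-direction selected
    parameter are flagged not-applicable rather than screened.
    """
    scaled = {name: scale_columns(pd.DataFrame(block)).data for name, block in blocks.items()}
    report: dict[str, dict] = {}
    for endpoint in outcomes.columns:
        y = outcomes[endpoint].to_numpy(dtype=float)
        section: dict = {"endpoint": endpoint}
        labels = dichotomize(y)
        if models is not None and endpoint in models:
            model = models[endpoint]
        else:
            model = block_splsda(scaled, labels, keepX=keepX, n_comp=1)
        rows = []
        for b in model.block_names:
            for feat in model.selected_features[b][0]:
                r, p = correlate(pd.DataFrame(blocks[b])[feat].to_numpy(dtype=float), y)
                rows.append(
                    {
                        "block": b,
                        "parameter": feat,
                        "dominant_class": model.dominant_class[b][0][feat],
                        "pearson_r": r,
                        "p_value": p,
                    }
                )
        params = pd.DataFrame(rows)
        section["selected_parameters"] = params
        positive = params[(params["dominant_class"] == "high")]
        negative = params[
            (params["dominant_class"] == "low") & (params["block"] == negative_block)
        ]
        if positive.empty:
            section["screening"] = "not_applicable"
            section["reason"] = "no positive-direction parameter selected"
            report[endpoint] = section
            continue
        best_pos = positive.sort_values("pearson_r", ascending=False).iloc[0]
        pos_vals = pd.DataFrame(blocks[best_pos["block"]])[best_pos["parameter"]].to_numpy(
            dtype=float
        )
        mask_pos, thr_pos = threshold_screen(pos_vals, "auto", "positive")
        one_step = separation_test(y, mask_pos)
        one_step.thresholds = {str(best_pos["parameter"]): (thr_pos, "positive")}
        section["single_step"] = one_step
        if not negative.empty:
            best_neg = negative.sort_values("pearson_r").iloc[0]
            neg_vals = pd.DataFrame(blocks[negative_block])[best_neg["parameter"]].to_numpy(
                dtype=float
            )
            mask2, info = two_step_screen(neg_vals, pos_vals)
            two_step = separation_test(y, mask2)
            two_step.thresholds = {
                str(best_neg["parameter"]): (info["neg_threshold"], "negative"),
                str(best_pos["parameter"]): (info["pos_threshold"], "positive"),
            }
            two_step.step_survivors = info["step_survivors"]
            section["two_step"] = two_step
        param_matrix = pd.concat(
            [
                pd.DataFrame(blocks[b])[model.selected_features[b][0]]
                for b in model.block_names
                if model.selected_features[b][0]
            ],
            axis=1,
        )
        pca_result, comp1 = pca_discriminate(
            param_matrix, y, positive["parameter"].tolist()
        )
        section["pca"] = pca_result
        section["pca_scores"] = comp1
        report[endpoint] = section
    return report
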