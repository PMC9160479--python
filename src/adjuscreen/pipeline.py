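"""End-to-end orchestration: simulate/load -> preprocess -> integrate -> screen.

``run_pipeline`` drives the full analysis from a single config mapping and
writes every artifact (block TSVs, outcome TSV, model bundles, screening
report, manifest) into one output directory.  Each stage logs one line with
row/feature counts; a stage failure leaves partial outputs plus a FAILED
marker and re-raises with a stage-tagged message.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .multiblock import LatentModel, block_splsda, dichotomize, rcca, block_spls
from .preprocess import ENDPOINTS, assemble_blocks, scale_columns
from .screening import screening_report
from .simulate import SimConfig, generate_cohort

log = logging.getLogger("adjuscreen")

__all__ = ["run_pipeline", "PipelineError", "write_model_bundle"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sim_config_from(cfg: dict) -> SimConfig:
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown simulate options: {sorted(unknown)}")
    return SimConfig(**cfg)


def write_model_bundle(model: LatentModel, out_dir: Path, prefix: str) -> None:
    """Serialize a fitted latent model as a TSV bundle."""
    for b in model.block_names:
        w = pd.DataFrame(
            model.weights[b],
            index=model.feature_names[b],
            columns=[f"comp{h + 1}" for h in range(model.weights[b].shape[1])],
        )
        aio.write_table(w, out_dir / f"{prefix}_weights_{b}.tsv", index_label="feature")
    rows = []
    for b in model.block_names:
        for h, feats in enumerate(model.selected_features[b]):
            for f in feats:
                row = {"block": b, "component": h + 1, "feature": f}
                if model.dominant_class is not None:
                    row["dominant_class"] = model.dominant_class[b][h][f]
                rows.append(row)
    sel = pd.DataFrame(rows)
    sel.to_csv(out_dir / f"{prefix}_selected.tsv", sep="\t", index=False)


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> Path:
    """Execute the configured stages and return the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = aio.RunManifest(seed=seed, hyperparameters=dict(config))
    stage = "setup"
    try:
        # ---- inputs: simulate or load --------------------------------
        if "simulate" in config:
            stage = "simulate"
            sim_cfg = dict(config["simulate"])
            if seed is not None:
                sim_cfg["seed"] = seed
            blocks, outcomes, truth = generate_cohort(_sim_config_from(sim_cfg))
            aio.write_table(truth.as_frame(), out / "truth.tsv")
            log.info("simulate: %d substances", len(outcomes))
        elif "inputs" in config:
            stage = "load"
            paths = config["inputs"]
            raw = {
                name: aio.read_table(paths[name])
                for name in ("human_cytokine", "mouse_cytokine", "particle")
            }
            outcome_table = aio.read_table(paths["outcomes"])
            for p in paths.values():
                manifest.record_input(p)
            blocks, outcomes = assemble_blocks(raw, outcome_table)
            log.info("load: %d substances", len(outcomes))
        else:
            raise ValueError("config needs a 'simulate' or 'inputs' section")
        for name, block in blocks.items():
            aio.write_block(block, out / f"{name}.tsv")
        aio.write_table(outcomes, out / "outcomes.tsv")

        # ---- preprocess: standardize blocks --------------------------
        stage = "preprocess"
        scaled = {name: scale_columns(block.data).data for name, block in blocks.items()}
        for name, df in scaled.items():
            log.info("preprocess: %s %d x %d", name, *df.shape)

        # ---- integrate -----------------------------------------------
        integrate = config.get("integrate", {"method": "diablo"})
        method = integrate.get("method", "diablo")
        keepX = int(integrate.get("keepX", 10))
        n_comp = int(integrate.get("n_comp", 1))
        endpoint = integrate.get("endpoint", ENDPOINTS[0])
        stage = f"integrate:{method}"
        y = outcomes[endpoint].to_numpy(dtype=float)
        models: dict[str, LatentModel] = {}
        if method == "rcca":
            lam1 = float(integrate.get("lambda1", 0.1))
            lam2 = float(integrate.get("lambda2", 0.1))
            for name, df in scaled.items():
                model = rcca(df, scale_columns(outcomes).data, lam1, lam2)
                rho = pd.DataFrame(
                    {"canonical_correlation": model.canonical_correlations}
                )
                aio.write_table(rho, out / f"rcca_rho_{name}.tsv", index_label="dimension")
            log.info("rcca: fitted 3 block-outcome models")
        elif method == "spls":
            model = block_spls(scaled, scale_columns(outcomes[[endpoint]]).data, keepX, n_comp)
            write_model_bundle(model, out, "spls")
            log.info("spls: selected %s features per block", keepX)
        elif method == "diablo":
            for ep in outcomes.columns:
                labels = dichotomize(outcomes[ep].to_numpy(dtype=float))
                models[ep] = block_splsda(scaled, labels, keepX, n_comp)
            write_model_bundle(models[endpoint], out, f"diablo_{endpoint}")
            log.info("diablo: fitted %d endpoint models", len(models))
        else:
            raise ValueError(f"unknown integration method {method!r}")

        # ---- screen --------------------------------------------------
        if method == "diablo" and config.get("screen", True):
            stage = "screen"
            raw_blocks = {name: block.data for name, block in blocks.items()}
            report = screening_report(raw_blocks, outcomes, models=models, keepX=keepX)
            lines = []
            stats_rows = []
            mask_table = pd.DataFrame(index=outcomes.index)
            for ep, section in report.items():
                lines.append(f"== {ep} ==")
                if section.get("screening") == "not_applicable":
                    lines.append(f"  screening not applicable: {section['reason']}")
                    continue
                for key in ("single_step", "two_step", "pca"):
                    if key not in section:
                        continue
                    res = section[key]
                    mask_table[f"{ep}:{key}"] = res.mask
                    stats_rows.append(
                        {
                            "endpoint": ep,
                            "screen": key,
                            "n_screened": res.n_screened,
                            "t": res.t_statistic,
                            "p": res.p_value,
                        }
                    )
                    lines.append(
                        f"  {key}: {res.n_screened} screened, t={res.t_statistic:.3f}, "
                        f"p={res.p_value:.4g}"
                    )
            (out / "report.txt").write_text("\n".join(lines) + "\n")
            aio.write_table(mask_table, out / "screen_masks.tsv")
            pd.DataFrame(stats_rows).to_csv(out / "screen_stats.tsv", sep="\t", index=False)
            log.info("screen: %d endpoint sections", len(report))

        manifest.write(out / "manifest.yaml")
        return out
    except Exception as err:
        (out / "FAILED").write_text(f"[{stage}] {err}\n")
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, str(err)) from err
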