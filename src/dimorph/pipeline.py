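"""End-to-end orchestration: simulate -> gene stats -> regression ->
traits -> G estimation -> response predictions.

Each stage writes plain-text artifacts into the output directory plus a
``manifest.json`` recording package and library versions, the seed, the
full configuration and its hash, per-file checksums and the method tags
of the estimators used, so a rerun with the same configuration is
bit-identical for every seeded stage.  A stage failure raises with the
stage name; artifacts written so far are left in place.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genewise import ExpressionDataset, gene_summaries
from .gestimate import SexedGModel, summarize_over_replicates
from .gmatrix import MatrixModification, write_g_csv
from .io import config_hash, file_sha256, read_table, read_tissue_table, write_table
from .regression import DimorphismRegression, RegressionSpec
from .response import (
    SelectionGradient,
    modification_ratio_table,
    predict_response,
)
from .simulate import make_scenario, simulate_panel
from .traits import DEFAULT_TRAIT_SPEC, assemble_trait_set

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("dimorph")


@dataclass
class PipelineConfig:
    """Stage toggles, thresholds and file paths for one pipeline run."""

    out_dir: str = "dimorph_out"
    scenario: str | None = "table2_like"  # None -> read expr_path instead
    expr_path: str | None = None
    tissue_path: str | None = None
    stages: tuple[str, ...] = (
        "simulate",
        "gene_stats",
        "regress",
        "build_traits",
        "estimate_g",
        "predict_response",
    )
    screen_alpha: float = 0.01
    bias_cutoff: float = 1.0
    transform_offset: float = 0.01
    regression_subset: str = "all"
    n_boot: int = 1000
    n_g_samples: int = 1000
    trait_spec: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_SPEC))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.screen_alpha, self.bias_cutoff, self.transform_offset) <= 0:
            raise ValueError("thresholds must be positive")


class StageError(RuntimeError):
    pass


def _hashable_config(cfg: PipelineConfig) -> dict:
    """Configuration dict without filesystem paths, so the hash identifies
    the analysis, not where it ran."""
    out = asdict(cfg)
    for key in ("out_dir", "expr_path", "tissue_path"):
        out.pop(key, None)
    return out


def _meta(cfg: PipelineConfig) -> dict:
    return {"seed": cfg.seed, "config_hash": config_hash(_hashable_config(cfg))}


def run_pipeline(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "dimorph",
        "version": __version__,
        "libs": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": config_hash(_hashable_config(cfg)),
        "stages": {},
        "method_notes": [
            "G estimation: MANOVA moment estimator + PSD projection + AICc rank "
            "selection (stand-in for reduced-rank REML)",
            "G uncertainty: balanced-design Wishart parametric resampling "
            "(stand-in for REML-MVN)",
        ],
    }
    meta = _meta(cfg)
    dataset = truth = None
    state: dict = {}
    for stage in cfg.stages:
        log.info("stage %s", stage)
        try:
            if stage == "simulate":
                if cfg.scenario is None:
                    raise StageError("simulate stage needs a scenario")
                scen = make_scenario(cfg.scenario, seed=cfg.seed)
                dataset, truth = simulate_panel(scen)
                dataset.to_tsv(out / "expr.tsv")
                write_table(truth.genes, out / "truth_genes.tsv", meta)
                files = ["expr.tsv", "truth_genes.tsv"]
            elif stage == "gene_stats":
                if dataset is None:
                    if cfg.expr_path is None:
                        raise StageError("no expression data: simulate or set expr_path")
                    dataset = ExpressionDataset.from_tsv(cfg.expr_path)
                tissue = (
                    read_tissue_table(cfg.tissue_path) if cfg.tissue_path else None
                )
                summary, lm = gene_summaries(
                    dataset, tissue_table=tissue, alpha=cfg.screen_alpha
                )
                state["summary"], state["lm"] = summary, lm
                write_table(summary, out / "gene_summary.tsv", meta)
                write_table(lm.to_frame(), out / "line_means.tsv", meta)
                files = ["gene_summary.tsv", "line_means.tsv"]
            elif stage == "regress":
                summary, lm = _need(state, "summary", "lm", stage="regress")
                retained = summary[summary["retained"]]
                preds = RegressionSpec().predictors
                if retained["tau"].isna().all():  # no tissue table supplied
                    preds = tuple(p for p in preds if p != "tau")
                reg = DimorphismRegression(
                    retained,
                    lm,
                    RegressionSpec(preds, cfg.regression_subset),
                )
                res = reg.fit(n_boot=cfg.n_boot, seed=cfg.seed)
                write_table(res.table, out / "table1_like.tsv", meta)
                (out / "regression_summary.txt").write_text(res.summary() + "\n")
                files = ["table1_like.tsv", "regression_summary.txt"]
            elif stage == "build_traits":
                summary, lm = _need(state, "summary", "lm", stage="build_traits")
                retained = summary[summary["retained"]]
                table = assemble_trait_set(
                    lm, retained["bias_class"], spec=cfg.trait_spec
                )
                state["traits"] = table
                write_table(table.line_scores, out / "trait_scores.tsv", meta)
                files = ["trait_scores.tsv"]
                for cls, load in table.loadings.items():
                    name = f"loadings_{cls}.tsv"
                    load_out = load.copy()
                    load_out["center"] = table.centers[cls]
                    write_table(load_out, out / name, meta)
                    files.append(name)
            elif stage == "estimate_g":
                (table,) = _need(state, "traits", stage="estimate_g")
                model = SexedGModel.from_traits(table, dataset)
                est = model.fit()
                state["g_est"] = est
                write_g_csv(est.g, out / "g_matrix.csv", meta)
                write_table(est.aicc, out / "g_rank_aicc.tsv", meta)
                (out / "g_summary.txt").write_text(est.summary() + "\n")
                if cfg.n_g_samples > 0:
                    state["g_samples"] = est.sample(cfg.n_g_samples, seed=cfg.seed)
                files = ["g_matrix.csv", "g_matrix.csv.json", "g_rank_aicc.tsv",
                         "g_summary.txt"]
            elif stage == "predict_response":
                (est,) = _need(state, "g_est", stage="predict_response")
                g = est.g
                shared = g.shared_traits
                if not shared:
                    raise StageError("no shared traits: cannot form gradients")
                grads = []
                for t in shared:
                    grads.append(SelectionGradient.antagonistic(g, [t]))
                    grads.append(SelectionGradient.concordant(g, [t]))
                grads.append(SelectionGradient.antagonistic(g, shared))
                grads.append(SelectionGradient.concordant(g, shared))
                samples = state.get("g_samples")
                rows = []
                for grad in grads:
                    resp = predict_response(g, grad)
                    row = {"gradient": grad.label, "scheme": grad.scheme,
                           **resp.as_row()}
                    if samples is not None:
                        for key, fn in (
                            ("e", lambda gg: predict_response(gg, grad).e),
                            ("R", lambda gg: predict_response(gg, grad).r),
                            ("delta_norm",
                             lambda gg: predict_response(gg, grad).delta_norm),
                        ):
                            q = summarize_over_replicates(samples, fn)
                            row[f"{key}_median"] = q["median"]
                            row[f"{key}_q2.5"] = q["q2.5"]
                            row[f"{key}_q97.5"] = q["q97.5"]
                    rows.append(row)
                write_table(pd.DataFrame(rows), out / "table3_like.tsv", meta,
                            index=False)
                ratios = modification_ratio_table(
                    g, grads, [m for m in MatrixModification if m.value != "none"]
                )
                write_table(ratios, out / "table4_like.tsv", meta, index=False)
                files = ["table3_like.tsv", "table4_like.tsv"]
            else:
                raise StageError(f"unknown stage {stage!r}")
        except StageError:
            raise
        except Exception as err:
            raise StageError(f"stage {stage!r} failed: {err}") from err
        manifest["stages"][stage] = {
            "files": {f: file_sha256(out / f) for f in files if (out / f).exists()}
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _need(state: dict, *keys: str, stage: str):
    missing = [k for k in keys if k not in state]
    if missing:
        raise StageError(
            f"stage {stage!r} needs earlier stage outputs {missing}; "
            "enable the producing stages"
        )
    return tuple(state[k] for k in keys)
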