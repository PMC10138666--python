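"""End-to-end orchestration: study on disk -> crosstalk report.

Stages run in method order — LoF masking (and optional re-normalization),
pathway decomposition, metabolite production, circuit activity, paired
differential production, GP + SHAP relevance, shared-gene Fisher control —
each writing its table under the output directory, with a JSON manifest of
file hashes, parameters and per-stage seeds for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import crosstalk_enrichment as ct
from . import differential_stats as ds
from . import gp_relevance as gp
from . import flux_propagation as mc
from . import preprocess as pp
from . import signaling_circuits as sc
from .pathway_model import save_subpathways
from .synthetic_data import SyntheticStudy, load_study, make_study, write_study

logger = logging.getLogger(__name__)

_STAGE_SEEDS = {"preprocess": 1, "decompose": 2, "produce": 3, "signal": 4,
                "diff": 5, "relevance": 6, "crosstalk": 7}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage parameters with the analysis defaults, plus file locations."""

    study_dir: str
    out_dir: str
    normalize: bool = False          # inputs are already on the [0,1] scale
    trunc_quantile: float = 0.99
    min_damaging: int = 3
    lof_factor: float = 0.001
    tol: float = 1e-6
    max_iter: int = 1000
    init_value: float = 1.0
    rate_rule: str = "min"
    alpha: float = 0.05
    cv_k: int = 5
    cv_reps: int = 100
    n_inducing: int = 50
    gp_opt_iter: int = 200
    r2_threshold: float = 0.5
    top_k: int = 1
    explain_frac: float = 0.2        # held-out share used for SHAP
    seed: int = 0
    function_map: str | None = None
    hallmark_map: str | None = None

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
        doc.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if not Path(self.study_dir).is_dir():
            raise ValueError(f"study_dir does not exist: {self.study_dir}")
        for name, lo, hi, v in [("trunc_quantile", 0, 1, self.trunc_quantile),
                                ("lof_factor", 0, 1, self.lof_factor),
                                ("r2_threshold", -1, 1, self.r2_threshold),
                                ("alpha", 0, 1, self.alpha),
                                ("explain_frac", 0, 1, self.explain_frac)]:
            if not lo < v < hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        for path in (self.function_map, self.hallmark_map):
            if path is not None and not Path(path).is_file():
                raise ValueError(f"mapping table does not exist: {path}")


def _stage_seed(master: int, stage: str) -> int:
    return int(np.random.default_rng((master, _STAGE_SEEDS[stage])).integers(2 ** 31))


def simulate_study(out_dir: str | Path, seed: int = 0, **params) -> SyntheticStudy:
    """Materialize a default synthetic study on disk, ready for run_pipeline."""
    study = make_study(seed=seed, **params)
    write_study(study, out_dir)
    return study


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to out_dir)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = load_study(config.study_dir)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name, fn, *paths):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            for p in paths:
                if Path(p).exists():
                    Path(p).rename(str(p) + ".partial")
            raise PipelineError(name, str(exc)) from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs", name, timings[name])
        for p in paths:
            artifacts[Path(p).name] = Path(p)
        return result

    # -- preprocess ---------------------------------------------------------
    expr_path = out / "expression_masked.tsv"

    def _preprocess():
        expr = study.expression
        if config.normalize:
            expr = pp.normalize_expression(expr, config.trunc_quantile)
        expr = pp.lof_mask(expr, study.variant_table,
                           min_damaging=config.min_damaging,
                           factor=config.lof_factor)
        expr.to_csv(expr_path, sep="\t", index_label="gene")
        return expr

    expr = stage("preprocess", _preprocess, expr_path)

    # -- decompose ----------------------------------------------------------
    subs_path = out / "subpathways.json"

    def _decompose():
        subs = [s for s in study.subpathways if s.valid]
        save_subpathways(subs, subs_path)
        return subs

    subs = stage("decompose", _decompose, subs_path)

    # -- produce ------------------------------------------------------------
    prod_path = out / "production.tsv"

    def _produce():
        prod = mc.production_matrix(subs, expr, init_value=config.init_value,
                                    tol=config.tol, max_iter=config.max_iter,
                                    rate_rule=config.rate_rule)
        prod.to_csv(prod_path, sep="\t", index_label="metabolite")
        return prod

    prod = stage("produce", _produce, prod_path)

    # -- signal -------------------------------------------------------------
    act_path = out / "circuit_activity.tsv"

    def _signal():
        act = sc.activity_matrix(study.circuits, expr, tol=config.tol,
                                 max_iter=config.max_iter)
        act.to_csv(act_path, sep="\t", index_label="circuit")
        return act

    act = stage("signal", _signal, act_path)

    # -- differential production -------------------------------------------
    diff_path = out / "differential.tsv"

    def _diff():
        table = ds.differential_production(prod, study.pairing, alpha=config.alpha)
        table.to_csv(diff_path, sep="\t")
        return table

    diff = stage("diff", _diff, diff_path)

    # -- GP relevance -------------------------------------------------------
    cv_path = out / "cv_report.tsv"
    rel_path = out / "relevance.tsv"
    hyper_path = out / "gp_hyperparameters.json"

    def _relevance():
        tumor = study.tumor_samples
        X = prod[tumor].T.to_numpy()
        Y = act[tumor].T.to_numpy()
        mets = list(prod.index)
        circuits = list(act.index)
        gp_seed = _stage_seed(config.seed, "relevance")
        cfg = gp.GPConfig(n_inducing=config.n_inducing,
                          max_opt_iter=config.gp_opt_iter, seed=gp_seed,
                          clip_range=(0.0, 1.0))
        cv = gp.repeated_kfold_cv(X, Y, k=config.cv_k, reps=config.cv_reps,
                                  config=cfg, task_names=circuits)
        cv.table.to_csv(cv_path, sep="\t", index=False)
        rng = np.random.default_rng(gp_seed)
        n = X.shape[0]
        n_test = max(1, int(round(config.explain_frac * n)))
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        model = gp.fit_mtgp(X[train_idx], Y[train_idx], cfg)
        with open(hyper_path, "w") as fh:
            json.dump(model.hyperparameters, fh, indent=1, sort_keys=True)
        shap_by_task = {}
        p = X.shape[1]
        for j, circ in enumerate(circuits):
            if p <= gp.EXACT_SHAP_MAX_FEATURES:
                attr = np.vstack([gp.exact_shap_oracle(model, X[i], X[train_idx],
                                                       task=j)
                                  for i in test_idx])
            else:
                attr = gp.kernel_shap(model, X[train_idx], X[test_idx],
                                      task=j, seed=gp_seed + j)
            shap_by_task[circ] = attr
        rel = gp.relevance_ranking(cv, shap_by_task, mets,
                                   r2_threshold=config.r2_threshold)
        rel.to_csv(rel_path, sep="\t", index=False)
        return rel

    rel = stage("relevance", _relevance, cv_path, rel_path, hyper_path)

    # -- crosstalk ----------------------------------------------------------
    crosstalk_path = out / "crosstalk.json"

    def _crosstalk():
        sub_by_product = {s.product: s for s in subs}
        circ_by_name = {c.name: c for c in study.circuits}
        overlap = {}
        for _, row in rel.iterrows():
            pair = (row["metabolite"], row["circuit"])
            overlap[pair] = len(ct.shared_genes(circ_by_name[pair[1]],
                                                sub_by_product[pair[0]]))
        table = ct.build_contingency(rel, overlap,
                                     r2_threshold=config.r2_threshold,
                                     top_k=config.top_k)
        pval = ct.fisher_exact(table, alternative="greater")
        doc = {"contingency": {"a": table.a, "b": table.b,
                               "c": table.c, "d": table.d},
               "fisher_p": pval,
               "top_k": config.top_k}
        if config.function_map or config.hallmark_map:
            empty = pd.DataFrame(columns=["circuit", "term"])
            fmap = (pd.read_csv(config.function_map, sep="\t")
                    if config.function_map else empty)
            hmap = (pd.read_csv(config.hallmark_map, sep="\t")
                    if config.hallmark_map else empty)
            doc["annotation"] = ct.annotate_circuits(rel, fmap, hmap)
        with open(crosstalk_path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
        return doc

    crosstalk = stage("crosstalk", _crosstalk, crosstalk_path)

    manifest = {
        "parameters": dataclasses.asdict(config),
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in _STAGE_SEEDS},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "artifacts": {name: _sha256(path) for name, path in sorted(artifacts.items())},
        "n_significant_dpms": int(diff["significant"].sum()),
        "fisher_p": crosstalk["fisher_p"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
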