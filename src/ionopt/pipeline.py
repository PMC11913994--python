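"""End-to-end workflow orchestration.

Stage order mirrors the optimization campaign: two-level screening of all
seven source/collision-cell factors, central-composite response-surface
optimization of the retained factors, Monte-Carlo design-space mapping and
setpoint selection, collision-energy cross-check on the D-optimal design,
and the final sensitivity evaluation (calibration curves, LOQ comparison,
pre/post improvement).  Each stage is a pure function of (inputs, config,
seed); the manifest records seeds, config hash and output hashes so a
rerun with the same manifest reproduces the report bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import ce as ce_mod
from . import simulate, space
from .design import design_to_csv
from .errors import ConfigurationError
from .rsm import fit_ols, models_to_json, refine_model
from .terms import linear_terms, quadratic_terms

__all__ = [
    "DEFAULT_CONFIG",
    "RunManifest",
    "select_screening_factors",
    "run_pipeline",
]

DEFAULT_CONFIG = {
    "seed": 42,
    "screening": {"alpha": 0.05, "min_analytes": 2, "transform": "log"},
    "optimization": {"alpha": 0.05, "transform": "log"},
    "design_space": {
        "threshold": 0.01,
        "min_fraction_of_max": 0.7,
        "n_samples": 2000,
        "weights": space.DEFAULT_WEIGHTS,
    },
    "ce": {"alpha": 0.05, "tolerance_ev": 2.0},
    "sensitivity": {"weighting": "1/x"},
    "noise_cv": 0.04,
}

_REQUIRED_SECTIONS = ("screening", "optimization", "design_space", "ce", "sensitivity")


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    stages: list = field(default_factory=list)
    version: str = "0.1.0"

    def record(self, stage: str, seed: int, outputs: dict, elapsed_s: float):
        self.stages.append(
            {
                "stage": stage,
                "seed": int(seed),
                "outputs": {k: str(v) for k, v in outputs.items()},
                "hashes": {
                    k: _file_hash(v) for k, v in outputs.items() if Path(v).is_file()
                },
                "elapsed_s": round(elapsed_s, 3),
            }
        )

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "stages": self.stages,
                },
                fh,
                indent=2,
            )


def _file_hash(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage_seeds(root_seed: int, n: int = 8) -> list:
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def validate_config(config: dict) -> dict:
    if "seed" not in config:
        raise ConfigurationError("config must set a root seed")
    merged = {**DEFAULT_CONFIG, **config}
    for section in _REQUIRED_SECTIONS:
        if section not in config:
            raise ConfigurationError(f"config missing required section {section!r}")
        merged[section] = {**DEFAULT_CONFIG[section], **(config[section] or {})}
    return merged


# ---------------------------------------------------------------------------
# Screening factor selection
# ---------------------------------------------------------------------------


def select_screening_factors(
    design,
    responses,
    alpha: float = 0.05,
    min_analytes: int = 2,
    transform: str = "log",
):
    """Factors carried forward from the screening stage.

    Per analyte a main-effects model is fitted on replicate-level data and
    a factor is flagged when its confidence interval at the
    Bonferroni-adjusted level (family-wise alpha over the factor family)
    excludes zero.  A factor advances when it is flagged for at least
    ``min_analytes`` of the analytes — a majority-style rule that keeps the
    family-wise false-selection rate across the inert factors low while
    active factors (flagged with huge margins) always pass.

    Returns ``(selected factor names, per-analyte flag DataFrame)``.
    """
    names = design.factor_names
    adj_alpha = alpha / len(names)
    # two-level effects are estimated on the factorial points only; the
    # center points measure curvature, which would otherwise inflate the
    # residual of the purely linear screening model
    import dataclasses

    fact_rows = [r for r in design.rows if r.point_type == "factorial"]
    fact_design = dataclasses.replace(design, rows=fact_rows)
    fact_ids = {r.run_id for r in fact_rows}
    fact_resp = dataclasses.replace(
        responses,
        design=fact_design,
        data=responses.data[responses.data["run_id"].isin(fact_ids)],
    )
    flags = {}
    for analyte in fact_resp.analytes:
        model = fit_ols(
            fact_design,
            fact_resp,
            linear_terms(names),
            transform=transform,
            analyte=analyte,
            alpha=adj_alpha,
        )
        sig = {
            t.name: bool(abs(b) > hw)
            for t, b, hw in zip(model.terms, model.coefficients, model.ci95)
            if t.kind == "linear"
        }
        flags[analyte] = sig
    table = pd.DataFrame(flags).T  # analytes x factors
    counts = table.sum(axis=0)
    selected = [n for n in names if counts.get(n, 0) >= min_analytes]
    return selected, table


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: dict, outdir, surfaces=None) -> dict:
    """Execute the full synthetic campaign and write artifacts + report.

    ``config`` is a dict (or a path to a YAML file) with a root ``seed``
    and the per-stage sections of :data:`DEFAULT_CONFIG`.  Returns the
    report dict; artifacts, the manifest and ``report.json`` are written
    under ``outdir``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(seed=int(config["seed"]), config_hash=cfg_hash)
    seeds = _stage_seeds(int(config["seed"]))
    noise = float(config.get("noise_cv", 0.04))
    gen = lambda s: simulate.GeneratorConfig(seed=s, noise_cv=noise)
    report: dict = {"seed": int(config["seed"])}

    # -- stage 1: screening -------------------------------------------------
    t0 = time.perf_counter()
    scr_cfg = config["screening"]
    design, resp = simulate.generate_regime("screening", seeds[0], gen(seeds[0]))
    selected, flag_table = select_screening_factors(
        design,
        resp,
        alpha=scr_cfg["alpha"],
        min_analytes=scr_cfg["min_analytes"],
        transform=scr_cfg["transform"],
    )
    paths = {
        "design": outdir / "screening_design.csv",
        "responses": outdir / "screening_responses.csv",
        "flags": outdir / "screening_flags.csv",
    }
    design_to_csv(design, paths["design"])
    resp.to_csv(paths["responses"])
    flag_table.to_csv(paths["flags"])
    report["screening"] = {
        "selected_factors": selected,
        "n_runs": design.n_runs(),
        "resolution": str(design.alias.resolution),
    }
    manifest.record("screening", seeds[0], paths, time.perf_counter() - t0)

    # -- stage 2: CCD optimization ------------------------------------------
    t0 = time.perf_counter()
    opt_cfg = config["optimization"]
    ccd, ccd_resp = simulate.generate_regime("ccd", seeds[1], gen(seeds[1]))
    models = {}
    for analyte in ccd_resp.analytes:
        full = fit_ols(
            ccd,
            ccd_resp,
            quadratic_terms(ccd.factor_names),
            transform=opt_cfg["transform"],
            analyte=analyte,
        )
        models[analyte] = refine_model(full, ccd, ccd_resp, alpha=opt_cfg["alpha"])
    paths = {
        "design": outdir / "ccd_design.csv",
        "responses": outdir / "ccd_responses.csv",
        "models": outdir / "models.json",
    }
    design_to_csv(ccd, paths["design"])
    ccd_resp.to_csv(paths["responses"])
    models_to_json(list(models.values()), paths["models"])
    report["optimization"] = {
        a: {
            "r2": m.r2,
            "q2": m.q2,
            "reproducibility": m.reproducibility,
            "lof_p": m.lof_p,
            "terms": m.term_names,
        }
        for a, m in models.items()
    }
    manifest.record("optimization", seeds[1], paths, time.perf_counter() - t0)

    # -- stage 3: design space ----------------------------------------------
    t0 = time.perf_counter()
    ds_cfg = config["design_space"]
    specs = space.specs_from_models(
        models,
        weights=ds_cfg["weights"],
        min_fraction_of_max=ds_cfg["min_fraction_of_max"],
    )
    dsmap = space.map_design_space(
        models,
        specs,
        threshold=ds_cfg["threshold"],
        n_samples=int(ds_cfg["n_samples"]),
        seed=seeds[2],
    )
    paths = {"map": outdir / "design_space.csv", "optimum": outdir / "optimum.json"}
    dsmap.to_frame().to_csv(paths["map"], index=False)
    idx = int(
        np.argmin(
            np.abs(
                dsmap.grid
                - np.array([dsmap.optimum[k] for k in dsmap.factor_names])
            ).sum(axis=1)
        )
    )
    report["design_space"] = {
        "optimum": dsmap.optimum,
        "pfail_at_optimum": float(dsmap.pfail[idx]),
        "no_design_space": dsmap.no_design_space,
    }
    with open(paths["optimum"], "w") as fh:
        json.dump(report["design_space"], fh, indent=2)
    manifest.record("design_space", seeds[2], paths, time.perf_counter() - t0)

    # -- stage 4: CE cross-check --------------------------------------------
    t0 = time.perf_counter()
    ce_cfg = config["ce"]
    dopt, dopt_resp = simulate.generate_regime("doptimal", seeds[3], gen(seeds[3]))
    ce_models = ce_mod.fit_ce_cid_models(dopt, dopt_resp, alpha=ce_cfg["alpha"])
    scan_df = simulate.generate_ofat_scan(
        seeds[4], cid_kpa=report["design_space"]["optimum"].get("CID", 222.0),
        config=gen(seeds[4]),
    )
    scans = ce_mod.ofat_scans(scan_df)
    ce_report = ce_mod.compare_ce_optima(
        ce_models, scans, tolerance_ev=ce_cfg["tolerance_ev"]
    )
    paths = {
        "design": outdir / "doptimal_design.csv",
        "responses": outdir / "doptimal_responses.csv",
        "scan": outdir / "ofat_scan.csv",
        "comparison": outdir / "ce_comparison.csv",
    }
    design_to_csv(dopt, paths["design"])
    dopt_resp.to_csv(paths["responses"])
    scan_df.to_csv(paths["scan"], index=False)
    ce_report.to_csv(paths["comparison"])
    report["ce"] = {
        "cid_retained": {a: ce_mod.cid_retained(m) for a, m in ce_models.items()},
        "n_inside": int(ce_report["inside"].sum()),
        "max_deviation_ev": float(ce_report["deviation_ev"].max()),
    }
    manifest.record("ce", seeds[3], paths, time.perf_counter() - t0)

    # -- stage 5: sensitivity evaluation ------------------------------------
    t0 = time.perf_counter()
    pre = simulate.generate_calibration("pre", gen(seeds[5]))
    post = simulate.generate_calibration("post", gen(seeds[6]))
    pre_res = {a: cal.evaluate_series(s) for a, s in pre.items()}
    post_res = {a: cal.evaluate_series(s) for a, s in post.items()}
    comparison = cal.compare_methods(pre_res, post_res)
    imp_pre, imp_post = simulate.generate_improvement(gen(seeds[7]))
    gains = cal.improvement_metrics(imp_pre, imp_post)
    paths = {
        "comparison": outdir / "loq_comparison.csv",
        "gains": outdir / "improvement.csv",
    }
    comparison.table.to_csv(paths["comparison"])
    gains.to_csv(paths["gains"])
    report["sensitivity"] = {
        "n_loq_improved": comparison.n_loq_improved,
        "n_snr_improved": comparison.n_snr_improved,
        "n_analytes": len(comparison.table),
        "height_gain_pct_range": [
            float(gains["height_gain_pct"].min()),
            float(gains["height_gain_pct"].max()),
        ],
        "auc_gain_pct_range": [
            float(gains["auc_gain_pct"].min()),
            float(gains["auc_gain_pct"].max()),
        ],
    }
    manifest.record("sensitivity", seeds[5], paths, time.perf_counter() - t0)

    # -- report ---------------------------------------------------------------
    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    manifest.to_json(outdir / "manifest.json")
    return report
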