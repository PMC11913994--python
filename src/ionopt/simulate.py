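"""Synthetic triple-quadrupole instrument.

Seeded generator of every input the optimization pipeline consumes:
screening / central-composite / D-optimal response tables, one-factor
collision-energy scans, calibration dilution series and pre/post
improvement runs.  Ground truth is a log-quadratic response surface per
analyte,

    H(x) = H0 * exp(f(x)),    f quadratic in coded factor settings,

so factor effects act multiplicatively (consistent with reporting gains as
percentages), with lognormal replicate noise of fixed coefficient of
variation (default 4%).  The committed coefficient table encodes the
effect structure recovered by the study stages: CID and IntT carry
negative quadratic curvature (interior optima); IntV is monotonically
harmful with its optimum at the 2 kV lower bound; the CID x IntT
interaction is positive only for LTB4-d4 and 9-HODE-d4 and IntT x IntV
only for LXA4-d5; heating/drying gas, heating block and desolvation line
are inert (coefficients well below the noise floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationSeries, load_table3
from .design import DesignMatrix, generate_ccd, generate_d_optimal, generate_ffd
from .errors import ConfigurationError, SchemaError
from .factors import Factor, ccd_factors, ce_factors, screening_factors
from .rsm import ResponseTable
from .terms import Term, quadratic_terms

__all__ = [
    "GeneratorConfig",
    "GroundTruthSurface",
    "default_surfaces",
    "ce_surfaces",
    "measure",
    "generate_regime",
    "generate_calibration",
    "generate_improvement",
    "ANALYTES",
    "STANDARD_CONDITIONS",
    "OPTIMIZED_CONDITIONS",
]

ANALYTES = ["PGE2-d4", "LXA4-d5", "LTB4-d4", "9-HODE-d4", "5-HETE-d8"]

#: baseline ESI-source settings the optimization is compared against
STANDARD_CONDITIONS = {"IntV": 3.0, "IntT": 300.0, "CID": 270.0}
#: settings selected by the design-space stage
OPTIMIZED_CONDITIONS = {"IntV": 2.0, "IntT": 380.0, "CID": 222.0}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_replicates: int = 2
    noise_cv: float = 0.04

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")


@dataclass
class GroundTruthSurface:
    """Log-quadratic ground-truth response surface for one analyte.

    ``coeffs`` maps term names over reference-frame factors (e.g. "CID",
    "IntT^2", "CID*IntT") to coefficients; each factor is coded through its
    own reference :class:`Factor` frame in ``frames`` so the surface can be
    evaluated at any natural-unit setting regardless of which design frame
    produced it.
    """

    analyte: str
    h0: float
    coeffs: dict
    frames: dict
    width: float = 3.0  # AUC = height * width (fixed per-analyte peak shape)

    def __post_init__(self):
        for name in self.coeffs:
            for f in Term.parse(name).factors:
                if f not in self.frames:
                    raise SchemaError(
                        f"{self.analyte}: coefficient {name!r} references "
                        f"factor {f!r} without a reference frame"
                    )

    def log_response(self, natural: dict) -> np.ndarray:
        """f(x) at natural-unit settings (missing factors sit at center)."""
        coded = {}
        n = 1
        for fname, frame in self.frames.items():
            if fname in natural:
                vals = np.atleast_1d(np.asarray(natural[fname], dtype=float))
                coded[fname] = frame.code(vals)
                n = max(n, vals.size)
            else:
                coded[fname] = np.zeros(1)
        out = np.zeros(n)
        for name, b in self.coeffs.items():
            t = Term.parse(name)
            if t.kind == "intercept":
                out = out + b
            elif t.kind == "linear":
                out = out + b * coded[t.factors[0]]
            elif t.kind == "quadratic":
                out = out + b * coded[t.factors[0]] ** 2
            else:
                out = out + b * coded[t.factors[0]] * coded[t.factors[1]]
        return out

    def height(self, natural: dict) -> np.ndarray:
        return self.h0 * np.exp(self.log_response(natural))


def _read_data(name: str) -> pd.DataFrame:
    with resources.files("ionopt.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def default_surfaces(noise_cv: float = 0.04) -> list:
    """The committed five-analyte ground-truth surfaces.

    Validates the structural invariants the screening and optimization
    stages rely on: negative CID/IntT curvature (interior optima) and inert
    coefficients below half the replicate noise CV.
    """
    table = _read_data("ground_truth.csv")
    opt_frames = {f.name: f for f in ccd_factors()}
    scr_frames = {f.name: f for f in screening_factors() if f.name in ("HG", "DG", "HB", "DL")}
    surfaces = []
    for _, r in table.iterrows():
        if not (r["b_cc"] < 0 and r["b_tt"] < 0):
            raise ConfigurationError(
                f"{r['analyte']}: CID/IntT curvature must be negative"
            )
        inert = {k: r[f"inert_{k}"] for k in ("HG", "DG", "HB", "DL")}
        if any(abs(v) >= noise_cv / 2 for v in inert.values()):
            raise ConfigurationError(
                f"{r['analyte']}: inert coefficients must stay below noise/2"
            )
        coeffs = {
            "CID": r["b_c"],
            "IntT": r["b_t"],
            "IntV": r["b_v"],
            "CID^2": r["b_cc"],
            "IntT^2": r["b_tt"],
            "IntV^2": r["b_vv"],
            "CID*IntT": r["b_ct"],
            "IntT*IntV": r["b_tv"],
            **inert,
        }
        coeffs = {k: float(v) for k, v in coeffs.items() if v != 0.0 or k in
                  ("CID", "IntT", "IntV", "CID^2", "IntT^2", "IntV^2")}
        surfaces.append(
            GroundTruthSurface(
                analyte=r["analyte"],
                h0=float(r["h0"]),
                coeffs=coeffs,
                frames={**opt_frames, **scr_frames},
                width=float(r["width"]),
            )
        )
    return surfaces


def ce_surfaces() -> list:
    """Ground-truth fragmentation surfaces over collision energy and CID.

    Collision energy dominates (sharp quadratic with a whole-eV optimum);
    CID carries a small linear effect only for LXA4-d5 and 5-HETE-d8.
    """
    table = _read_data("ce_truth.csv")
    frames = {f.name: f for f in ce_factors()}
    out = []
    for _, r in table.iterrows():
        coeffs = {
            "CE": float(r["b_ce"]),
            "CE^2": float(r["b_cece"]),
        }
        if r["b_cid"] != 0.0:
            coeffs["CID"] = float(r["b_cid"])
        if r["b_cidcid"] != 0.0:
            coeffs["CID^2"] = float(r["b_cidcid"])
        out.append(
            GroundTruthSurface(
                analyte=r["analyte"],
                h0=float(r["h0"]),
                coeffs=coeffs,
                frames=frames,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------


def measure(
    design: DesignMatrix,
    surfaces: Sequence[GroundTruthSurface],
    config: GeneratorConfig,
) -> ResponseTable:
    """Simulated replicate measurements of a design on ground-truth surfaces.

    Per run, replicate and analyte the observed height is
    ``H(x) * exp(eps)`` with ``eps ~ Normal(0, noise_cv)``; AUC is height
    times the analyte's fixed peak-width factor (with slightly smaller
    replicate noise of its own).  Fully deterministic for a fixed seed.
    """
    for f in design.factor_names:
        if not all(f in s.frames for s in surfaces):
            raise SchemaError(f"design factor {f!r} unknown to ground truth")
    rng = np.random.default_rng(config.seed)
    recs = []
    for row in design.rows:
        natural = dict(zip(design.factor_names, row.natural))
        for surf in surfaces:
            mu = float(surf.height(natural)[0])
            for rep in range(1, config.n_replicates + 1):
                h = mu * np.exp(rng.normal(0.0, config.noise_cv))
                a = h * surf.width * np.exp(rng.normal(0.0, config.noise_cv / 2))
                recs.append(
                    {
                        "run_id": row.run_id,
                        "replicate": rep,
                        "analyte": surf.analyte,
                        "height": h,
                        "auc": a,
                    }
                )
    return ResponseTable(design=design, data=pd.DataFrame(recs))


def generate_regime(regime: str, seed: int, config: Optional[GeneratorConfig] = None):
    """One-call generation of (design, responses) for a named study stage.

    Regimes: ``screening`` (two-level fractional factorial over all seven
    factors), ``ccd`` (central composite on CID/IntT/IntV), ``doptimal``
    (multilevel CE x CID design), ``ofat`` (CE scan at fixed CID 222 kPa).
    """
    config = config or GeneratorConfig(seed=seed)
    config.seed = seed
    if regime == "screening":
        design, _ = generate_ffd(
            screening_factors(), p=3, n_center=3, n_replicates=config.n_replicates
        )
        return design, measure(design, default_surfaces(config.noise_cv), config)
    if regime == "ccd":
        design = generate_ccd(
            ccd_factors(), alpha=1.35, n_center=3, n_replicates=config.n_replicates
        )
        return design, measure(design, default_surfaces(config.noise_cv), config)
    if regime == "doptimal":
        factors = ce_factors()
        ce_grid = np.arange(12.0, 28.1, 2.0)
        cid_grid = np.arange(190.0, 250.1, 10.0)
        cand = np.array(
            [
                [factors[0].code(ce), factors[1].code(cid)]
                for ce in ce_grid
                for cid in cid_grid
            ]
        )
        design = generate_d_optimal(
            factors,
            cand,
            quadratic_terms([f.name for f in factors]),
            n_runs=14,
            seed=seed,
            n_replicates=config.n_replicates,
        )
        return design, measure(design, ce_surfaces(), config)
    if regime == "ofat":
        return generate_ofat_scan(seed, config=config)
    raise ConfigurationError(f"unknown regime {regime!r}")


def generate_ofat_scan(
    seed: int,
    cid_kpa: float = 222.0,
    ce_grid: Optional[np.ndarray] = None,
    config: Optional[GeneratorConfig] = None,
) -> pd.DataFrame:
    """Duplicate CE scan at fixed CID: one row per analyte/CE/replicate."""
    config = config or GeneratorConfig(seed=seed)
    rng = np.random.default_rng(seed)
    if ce_grid is None:
        ce_grid = np.arange(12.0, 28.1, 2.0)
    recs = []
    for surf in ce_surfaces():
        for ce in ce_grid:
            mu = float(surf.height({"CE": ce, "CID": cid_kpa})[0])
            for rep in range(1, config.n_replicates + 1):
                recs.append(
                    {
                        "analyte": surf.analyte,
                        "ce_ev": ce,
                        "cid_kpa": cid_kpa,
                        "replicate": rep,
                        "response": mu * np.exp(rng.normal(0.0, config.noise_cv)),
                    }
                )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Calibration series (14-analyte panel)
# ---------------------------------------------------------------------------

#: ten 2-fold dilution levels, 31.25 pg on column down to 0.061 pg
CAL_LEVELS = 31.25 / 2 ** np.arange(10)

_BASE_NOISE = 40.0  # pre-optimization baseline-noise SD, detector counts
_LOSS_SCALE = 1.127  # low-end loss scale relative to the level below the LOQ
_LOSS_POWER = 4


def _nearest_level(printed: float) -> float:
    return float(CAL_LEVELS[np.argmin(np.abs(np.log(CAL_LEVELS / printed)))])


def _panel_parameters() -> pd.DataFrame:
    """Per-analyte generator parameters inverted from the reference table.

    Slopes and baseline-noise SDs reproduce the printed S/N at the
    pre-optimization LOQ under both methods; post/pre height gain factors
    are spread over 1.70-2.10; a sharp low-end recovery loss
    (x_eff = x^5/(x^4 + l^4)) is switched on whenever S/N alone would not
    gate the printed LOQ, making those LOQs accuracy-limited.
    """
    t3 = load_table3()
    n = len(t3)
    gains = 1.70 + 0.40 * np.arange(n) / max(n - 1, 1)
    recs = []
    for i, r in t3.iterrows():
        pre_loq = _nearest_level(r["loq_pre_pg"])
        post_loq = _nearest_level(r["loq_post_pg"])
        slope_pre = r["snr_pre"] * _BASE_NOISE / pre_loq
        slope_post = gains[i] * slope_pre
        noise_post = slope_post * pre_loq / r["snr_post"]
        rec = {
            "analyte": r["analyte"],
            "pre_loq": pre_loq,
            "post_loq": post_loq,
            "slope_pre": slope_pre,
            "slope_post": slope_post,
            "noise_pre": _BASE_NOISE,
            "noise_post": noise_post,
            "gain": gains[i],
        }
        for method, slope, noise, loq in (
            ("pre", slope_pre, _BASE_NOISE, pre_loq),
            ("post", slope_post, noise_post, post_loq),
        ):
            fail_level = loq / 2.0
            if fail_level >= CAL_LEVELS[-1] and slope * fail_level / noise >= 5.0:
                rec[f"loss_{method}"] = _LOSS_SCALE * fail_level
            else:
                rec[f"loss_{method}"] = 0.0
        recs.append(rec)
    return pd.DataFrame(recs)


def generate_calibration(
    settings: str,
    config: GeneratorConfig,
    analytes: Optional[Sequence[str]] = None,
) -> dict:
    """Simulated dilution series for the panel under pre or post settings.

    Returns a dict analyte -> :class:`CalibrationSeries` with duplicate
    injections, multiplicative replicate noise (CV ``noise_cv``) and the
    constant baseline-noise SD that defines S/N.
    """
    if settings not in ("pre", "post"):
        raise ConfigurationError("settings must be 'pre' or 'post'")
    params = _panel_parameters()
    if analytes is not None:
        unknown = set(analytes) - set(params["analyte"])
        if unknown:
            raise ConfigurationError(f"unknown analytes: {sorted(unknown)}")
        params = params[params["analyte"].isin(analytes)]
    rng = np.random.default_rng(config.seed)
    out = {}
    for _, p in params.iterrows():
        slope = p[f"slope_{settings}"]
        noise = p[f"noise_{settings}"]
        loss = p[f"loss_{settings}"]
        x = CAL_LEVELS
        if loss > 0:
            x_eff = x * x**_LOSS_POWER / (x**_LOSS_POWER + loss**_LOSS_POWER)
        else:
            x_eff = x
        eps = rng.normal(0.0, config.noise_cv, size=(x.size, config.n_replicates))
        heights = slope * x_eff[:, None] * np.exp(eps)
        aucs = heights * 3.0 * np.exp(
            rng.normal(0.0, config.noise_cv / 2, size=heights.shape)
        )
        out[p["analyte"]] = CalibrationSeries(
            analyte=p["analyte"],
            levels=x.copy(),
            heights=heights,
            noise_sd=np.full(x.size, noise),
            aucs=aucs,
            method=settings,
        )
    return out


# ---------------------------------------------------------------------------
# Pre/post improvement runs (deuterated standards, n = 3)
# ---------------------------------------------------------------------------

_HEIGHT_GAINS = dict(zip(ANALYTES, [1.72, 2.08, 1.95, 1.80, 2.02]))
_AUC_GAINS = dict(zip(ANALYTES, [1.33, 1.60, 1.48, 1.38, 1.55]))


def generate_improvement(config: GeneratorConfig, n_replicates: int = 3):
    """Triplicate runs of the five standards under baseline and optimized
    settings, with per-analyte height gains inside 70-110% and AUC gains
    inside 33-60%.  Returns ``(pre, post)`` DataFrames for
    :func:`ionopt.calibration.improvement_metrics`."""
    rng = np.random.default_rng(config.seed)
    surfaces = default_surfaces(config.noise_cv)
    pre_recs, post_recs = [], []
    for surf in surfaces:
        h_pre = float(surf.height(STANDARD_CONDITIONS)[0])
        gh, ga = _HEIGHT_GAINS[surf.analyte], _AUC_GAINS[surf.analyte]
        for rep in range(1, n_replicates + 1):
            e1, e2 = rng.normal(0.0, config.noise_cv, 2)
            pre_recs.append(
                {
                    "analyte": surf.analyte,
                    "replicate": rep,
                    "height": h_pre * np.exp(e1),
                    "auc": h_pre * surf.width * np.exp(e2),
                }
            )
            e3, e4 = rng.normal(0.0, config.noise_cv, 2)
            post_recs.append(
                {
                    "analyte": surf.analyte,
                    "replicate": rep,
                    "height": h_pre * gh * np.exp(e3),
                    "auc": h_pre * surf.width * ga * np.exp(e4),
                }
            )
    return pd.DataFrame(pre_recs), pd.DataFrame(post_recs)
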