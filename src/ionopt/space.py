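"""Monte-Carlo design space over fitted response-surface models.

The design space is the region of instrument settings where the
probability that any analyte's response falls below its acceptance target
stays under a risk threshold (default 1%).  Failure probabilities are
estimated by seeded Monte-Carlo simulation propagating two disturbance
sources: setpoint jitter (the instrument not sitting exactly at the
nominal setting) and model residual noise (resampled from each model's
residual SD).  The operating point is then chosen inside the design space
by maximizing a weighted log-margin score, with abundance-critical
analytes (prostaglandins, lipoxins) weighted above HETEs/HODEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidValueError
from .factors import round_to_step
from .rsm import QuadraticModel

__all__ = [
    "ResponseSpec",
    "DisturbanceSpec",
    "DesignSpaceMap",
    "DEFAULT_WEIGHTS",
    "default_grid",
    "default_disturbance",
    "specs_from_models",
    "pfail_at",
    "map_design_space",
    "select_optimum",
]

#: default analyte weights: prostaglandins and lipoxins prioritized over
#: leukotrienes, HODEs and HETEs (low-abundance mediators matter most)
DEFAULT_WEIGHTS = {
    "PGE2-d4": 2.0,
    "LXA4-d5": 2.0,
    "LTB4-d4": 1.5,
    "9-HODE-d4": 1.0,
    "5-HETE-d8": 1.0,
}

#: natural-unit reporting resolution of the selected optimum
_REPORT_STEP = {"CID": 1.0, "IntT": 1.0, "IntV": 0.1}


@dataclass(frozen=True)
class ResponseSpec:
    analyte: str
    min_acceptable: float  # response units (detector counts)
    weight: float = 1.0

    def __post_init__(self):
        if self.min_acceptable <= 0 and self.min_acceptable != 0.0:
            raise InvalidValueError("min_acceptable must be >= 0")
        if self.weight <= 0:
            raise InvalidValueError("weight must be > 0")


@dataclass
class DisturbanceSpec:
    """Setpoint jitter SDs (natural units, per factor) and whether model
    residual noise is resampled onto predictions."""

    jitter_sd: dict = field(default_factory=dict)
    resample_residual: bool = True

    def __post_init__(self):
        if any(v < 0 for v in self.jitter_sd.values()):
            raise InvalidValueError("jitter SDs must be >= 0")


@dataclass
class DesignSpaceMap:
    axes: dict  # factor -> natural-unit grid values
    grid: np.ndarray  # (G, k) natural settings
    pfail: np.ndarray  # (G,)
    objective: np.ndarray  # (G,) weighted log-margin score
    threshold: float
    optimum: dict  # factor -> natural setting
    n_samples: int
    seed: int
    no_design_space: bool = False

    @property
    def factor_names(self) -> list:
        return list(self.axes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.grid, columns=self.factor_names)
        df["pfail"] = self.pfail
        df["objective"] = self.objective
        return df


def default_grid() -> dict:
    """CID x IntT x IntV evaluation grid in natural units."""
    return {
        "CID": np.arange(120.0, 270.1, 2.0),
        "IntT": np.arange(282.0, 400.1, 2.0),
        "IntV": np.array([1.8, 2.0, 2.5, 3.0]),
    }


def default_disturbance(models: dict) -> DisturbanceSpec:
    """Setpoint jitter of 2% of each factor's [low, high] range."""
    model = next(iter(models.values()))
    jitter = {f.name: 0.02 * (f.high - f.low) for f in model.factors}
    return DisturbanceSpec(jitter_sd=jitter, resample_residual=True)


# ---------------------------------------------------------------------------
# Vectorized model evaluation
# ---------------------------------------------------------------------------


def _log_mean(model: QuadraticModel, coded: dict) -> np.ndarray:
    """Linear predictor (log response for log models) on broadcastable
    coded-factor arrays."""
    out = 0.0
    for term, b in zip(model.terms, model.coefficients):
        if term.kind == "intercept":
            out = out + b
        elif term.kind == "linear":
            out = out + b * coded[term.factors[0]]
        elif term.kind == "quadratic":
            out = out + b * coded[term.factors[0]] ** 2
        else:
            out = out + b * coded[term.factors[0]] * coded[term.factors[1]]
    return out


def _predict_mean_natural(model: QuadraticModel, natural: dict) -> np.ndarray:
    frames = {f.name: f for f in model.factors}
    coded = {k: frames[k].code(np.asarray(v, dtype=float)) for k, v in natural.items()
             if k in frames}
    mu = _log_mean(model, coded)
    return np.exp(mu) if model.response_transform == "log" else mu


def specs_from_models(
    models: dict,
    grid: Optional[dict] = None,
    weights: Optional[dict] = None,
    min_fraction_of_max: float = 0.7,
) -> list:
    """Acceptance targets: a fraction (default 70%) of each analyte's own
    model-predicted maximum over the evaluation grid."""
    grid = grid or default_grid()
    weights = weights or DEFAULT_WEIGHTS
    mesh = _mesh(grid)
    specs = []
    for analyte, model in models.items():
        pred = _predict_mean_natural(model, mesh)
        specs.append(
            ResponseSpec(
                analyte=analyte,
                min_acceptable=float(min_fraction_of_max * np.max(pred)),
                weight=float(weights.get(analyte, 1.0)),
            )
        )
    return specs


def _mesh(grid: dict) -> dict:
    arrays = np.meshgrid(*grid.values(), indexing="ij")
    return {k: a.ravel() for k, a in zip(grid, arrays)}


# ---------------------------------------------------------------------------
# Failure probability
# ---------------------------------------------------------------------------


def _pfail_grid(
    models: dict,
    grid_natural: dict,
    specs: Sequence[ResponseSpec],
    disturbance: DisturbanceSpec,
    n_samples: int,
    seed: int,
    chunk: int = 2000,
) -> np.ndarray:
    """Failure probability at each of G natural-unit settings.

    Common random numbers across grid points: one (S,) jitter draw per
    factor and one (S,) residual draw per analyte are shared by all grid
    points, which leaves each point's estimate unbiased while making the
    map smooth in the settings.
    """
    for spec in specs:
        if spec.analyte not in models:
            raise ConfigurationError(f"no model for spec analyte {spec.analyte!r}")
    names = list(grid_natural)
    G = len(next(iter(grid_natural.values())))
    rng = np.random.default_rng(seed)
    jitter = {
        k: rng.normal(0.0, disturbance.jitter_sd.get(k, 0.0), n_samples)
        for k in names
    }
    resid = {}
    for spec in specs:
        m = models[spec.analyte]
        sd = m.residual_sd if disturbance.resample_residual else 0.0
        resid[spec.analyte] = rng.normal(0.0, sd, n_samples)

    frames = {f.name: f for m in models.values() for f in m.factors}
    pfail = np.empty(G)
    for start in range(0, G, chunk):
        sl = slice(start, min(start + chunk, G))
        coded = {}
        for k in names:
            nat = grid_natural[k][sl, None] + jitter[k][None, :]
            if frames[k].hard_min is not None or frames[k].hard_max is not None:
                nat = np.clip(
                    nat,
                    frames[k].hard_min if frames[k].hard_min is not None else -np.inf,
                    frames[k].hard_max if frames[k].hard_max is not None else np.inf,
                )
            coded[k] = frames[k].code(nat)
        fail_any = np.zeros((sl.stop - sl.start, n_samples), dtype=bool)
        for spec in specs:
            if spec.min_acceptable <= 0:
                continue
            m = models[spec.analyte]
            mu = _log_mean(m, coded) + resid[spec.analyte][None, :]
            if m.response_transform == "log":
                fail_any |= mu < np.log(spec.min_acceptable)
            else:
                fail_any |= mu < spec.min_acceptable
        pfail[sl] = fail_any.mean(axis=1)
    return pfail


def pfail_at(
    models: dict,
    setpoint: dict,
    specs: Sequence[ResponseSpec],
    disturbance: Optional[DisturbanceSpec] = None,
    n_samples: int = 20000,
    seed: int = 0,
) -> float:
    """Monte-Carlo probability that any analyte misses its target at one
    natural-unit setpoint."""
    disturbance = disturbance if disturbance is not None else DisturbanceSpec()
    grid = {k: np.array([float(v)]) for k, v in setpoint.items()}
    return float(
        _pfail_grid(models, grid, specs, disturbance, n_samples, seed)[0]
    )


# ---------------------------------------------------------------------------
# Mapping and optimum selection
# ---------------------------------------------------------------------------


def map_design_space(
    models: dict,
    specs: Sequence[ResponseSpec],
    grid: Optional[dict] = None,
    disturbance: Optional[DisturbanceSpec] = None,
    threshold: float = 0.01,
    n_samples: int = 20000,
    seed: int = 0,
) -> DesignSpaceMap:
    """Failure-probability map over the settings grid plus selected optimum."""
    grid = grid or default_grid()
    disturbance = disturbance if disturbance is not None else default_disturbance(models)
    mesh = _mesh(grid)
    names = list(mesh)
    G = len(next(iter(mesh.values())))
    pfail = _pfail_grid(models, mesh, specs, disturbance, n_samples, seed)

    # weighted log-margin score (deterministic predictions, no jitter)
    objective = np.zeros(G)
    for spec in specs:
        m = models[spec.analyte]
        pred = _predict_mean_natural(m, mesh)
        if spec.min_acceptable > 0:
            objective += spec.weight * np.log(pred / spec.min_acceptable)
        else:
            objective += spec.weight * np.log(pred)

    dsmap = DesignSpaceMap(
        axes={k: np.asarray(v, dtype=float) for k, v in grid.items()},
        grid=np.column_stack([mesh[k] for k in names]),
        pfail=pfail,
        objective=objective,
        threshold=threshold,
        optimum={},
        n_samples=n_samples,
        seed=seed,
    )
    dsmap.optimum, dsmap.no_design_space = _select(dsmap)
    return dsmap


def _tie_rank(names, point):
    # gentler settings first: lowest IntV, then lowest IntT
    key = []
    for pref in ("IntV", "IntT"):
        if pref in names:
            key.append(point[names.index(pref)])
    return tuple(key)


def _select(dsmap: DesignSpaceMap):
    names = dsmap.factor_names
    feasible = dsmap.pfail <= dsmap.threshold
    no_space = not feasible.any()
    score = dsmap.objective.copy()
    if not no_space:
        score[~feasible] = -np.inf
    best = np.max(score)
    ties = np.nonzero(score >= best - 1e-12)[0]
    best_i = min(ties, key=lambda i: _tie_rank(names, dsmap.grid[i]))
    opt = {}
    for j, name in enumerate(names):
        v = dsmap.grid[best_i, j]
        step = _REPORT_STEP.get(name)
        opt[name] = round_to_step(v, step) if step else float(v)
    return opt, no_space


def select_optimum(dsmap: DesignSpaceMap) -> dict:
    """Grid point maximizing the weighted log-margin score among settings
    with pfail <= threshold (ties broken toward lowest IntV then IntT)."""
    opt, _ = _select(dsmap)
    return opt
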