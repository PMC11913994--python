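"""Response-surface modelling on coded factors.

Quadratic models of (optionally log-transformed) detector response are fit
per analyte by ordinary least squares on replicate-level data, then pruned
by backward elimination using 95% confidence intervals (a term is removable
when its CI covers zero and no retained higher-order term contains it).
Diagnostics follow the response-surface conventions used by DoE software:

* R^2        - corrected coefficient of determination,
* Q^2        - PRESS-based leave-one-out predictability,
* reproducibility - 1 - MS_pure_error / MS_total,
* lack-of-fit F test splitting residual SS into lack-of-fit and pure error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix
from .errors import (
    AliasedTermsError,
    InvalidValueError,
    NotComputableError,
    SchemaError,
)
from .factors import Factor
from .terms import Term, build_matrix, quadratic_terms

__all__ = [
    "ResponseTable",
    "QuadraticModel",
    "build_model_matrix",
    "fit_ols",
    "refine_model",
    "lack_of_fit",
    "q2_press",
    "reproducibility",
    "predict",
    "predict_natural",
    "surface_grid",
    "models_to_json",
    "models_from_json",
]


# ---------------------------------------------------------------------------
# Response container
# ---------------------------------------------------------------------------


@dataclass
class ResponseTable:
    """Replicate-level responses for one design.

    ``data`` has columns run_id, replicate, analyte, height (and optionally
    auc); responses are strictly positive detector counts.
    """

    design: DesignMatrix
    data: pd.DataFrame

    def __post_init__(self):
        required = {"run_id", "replicate", "analyte", "height"}
        if not required <= set(self.data.columns):
            raise SchemaError(f"response table needs columns {sorted(required)}")
        metrics = [c for c in ("height", "auc") if c in self.data.columns]
        if (self.data[metrics] <= 0).any().any():
            raise InvalidValueError("responses must be strictly positive")

    @property
    def analytes(self) -> list:
        return sorted(self.data["analyte"].unique())

    def for_analyte(self, analyte: str, metric: str = "height"):
        """Aligned (coded rows, responses, run_ids) at replicate level."""
        sub = self.data[self.data["analyte"] == analyte]
        if sub.empty:
            raise SchemaError(f"no responses for analyte {analyte!r}")
        by_run = {r.run_id: r for r in self.design.rows}
        coded, y, run_ids = [], [], []
        for _, rec in sub.sort_values(["run_id", "replicate"]).iterrows():
            rid = int(rec["run_id"])
            if rid not in by_run:
                raise SchemaError(f"response references unknown run_id {rid}")
            coded.append(by_run[rid].coded)
            y.append(float(rec[metric]))
            run_ids.append(rid)
        return np.array(coded), np.array(y), np.array(run_ids)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, design: DesignMatrix) -> "ResponseTable":
        return cls(design=design, data=pd.read_csv(path))


# ---------------------------------------------------------------------------
# Fitted model container
# ---------------------------------------------------------------------------


@dataclass
class QuadraticModel:
    analyte: str
    terms: list
    coefficients: np.ndarray
    ci95: np.ndarray  # half-widths
    cov: np.ndarray
    residual_sd: float
    df_resid: int
    r2: float
    q2: Optional[float]
    reproducibility: Optional[float]
    lof_p: Optional[float]
    response_transform: str  # identity | log
    factors: list  # Factor frame the model was fitted in
    # fitted data kept for diagnostics / refinement
    _X: Optional[np.ndarray] = field(default=None, repr=False)
    _y: Optional[np.ndarray] = field(default=None, repr=False)
    _settings_key: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def factor_names(self) -> list:
        return [f.name for f in self.factors]

    @property
    def term_names(self) -> list:
        return [t.name for t in self.terms]

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.term_names.index(name)])

    def significant_terms(self) -> list:
        """Terms whose 95% CI excludes zero (intercept always reported)."""
        out = []
        for t, b, hw in zip(self.terms, self.coefficients, self.ci95):
            if t.kind == "intercept" or abs(b) > hw:
                out.append(t)
        return out


def build_model_matrix(design: DesignMatrix, terms: Sequence[Term]) -> np.ndarray:
    """Model matrix at design-run level (one row per run, coded units)."""
    return build_matrix(design.coded_array(), design.factor_names, terms)


def _expanded_inputs(design, responses, analyte, metric):
    """Replicate-level (coded, y, settings-keys) for an analyte."""
    if isinstance(responses, ResponseTable):
        coded, y, run_ids = responses.for_analyte(analyte, metric=metric)
        by_run = {r.run_id: r for r in design.rows}
        keys = np.array(
            [hash(tuple(by_run[rid].natural.tolist())) for rid in run_ids]
        )
        return coded, y, keys
    # plain array aligned with replicate-expanded design rows
    y = np.asarray(responses, dtype=float)
    coded, keys = [], []
    for row in design.rows:
        for _ in range(row.n_replicates):
            coded.append(row.coded)
            keys.append(hash(tuple(row.natural.tolist())))
    coded = np.array(coded)
    if len(y) != len(coded):
        raise SchemaError(
            f"{len(y)} responses but design expands to {len(coded)} observations"
        )
    return coded, y, np.array(keys)


def _diagnose_rank_deficiency(X, terms, alias):
    """Name the confounded terms behind a rank-deficient model matrix."""
    _, s, Vt = np.linalg.svd(X)
    tol = max(X.shape) * np.finfo(float).eps * s[0]
    null = Vt[s.size - np.sum(s <= tol):] if np.sum(s <= tol) else Vt[X.shape[1]:]
    involved = set()
    for v in null:
        for j in np.nonzero(np.abs(v) > 1e-8)[0]:
            involved.add(terms[j].name)
    if alias is not None:
        extra = set()
        for name in involved:
            t = Term.parse(name)
            if t.kind in ("linear", "interaction"):
                for al in alias.aliases_of(t.factors):
                    extra.add("*".join(al) if len(al) > 1 else al[0])
        involved |= extra
    return involved


def fit_ols(
    design: DesignMatrix,
    responses,
    terms: Optional[Sequence[Term]] = None,
    transform: str = "identity",
    analyte: str = "",
    metric: str = "height",
    alpha: float = 0.05,
) -> QuadraticModel:
    """Least-squares fit of a term list to replicate-level responses.

    ``responses`` is either a :class:`ResponseTable` (with ``analyte``
    naming the series) or an array aligned with the replicate-expanded
    design rows.  ``transform='log'`` fits the model on log responses,
    appropriate when effects act multiplicatively.
    """
    if terms is None:
        terms = quadratic_terms(design.factor_names)
    terms = list(terms)
    coded, y, keys = _expanded_inputs(design, responses, analyte, metric)
    if transform == "log":
        if np.any(y <= 0):
            raise InvalidValueError("log transform requires positive responses")
        y = np.log(y)
    elif transform != "identity":
        raise InvalidValueError(f"unknown transform {transform!r}")

    X = build_matrix(coded, design.factor_names, terms)
    n, m = X.shape
    if n < m:
        raise AliasedTermsError(
            [t.name for t in terms], f"only {n} observations for {m} terms"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < m:
        raise AliasedTermsError(_diagnose_rank_deficiency(X, terms, design.alias))

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = n - m
    ss_res = float(resid @ resid)
    sigma2 = ss_res / df if df > 0 else 0.0
    cov = XtX_inv * sigma2
    tcrit = stats.t.ppf(1 - alpha / 2, df) if df > 0 else np.inf
    ci95 = tcrit * np.sqrt(np.diag(cov))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    model = QuadraticModel(
        analyte=analyte,
        terms=terms,
        coefficients=beta,
        ci95=ci95,
        cov=cov,
        residual_sd=float(np.sqrt(sigma2)),
        df_resid=df,
        r2=r2,
        q2=None,
        reproducibility=None,
        lof_p=None,
        response_transform=transform,
        factors=list(design.factors),
        _X=X,
        _y=y,
        _settings_key=keys,
    )
    try:
        model.q2 = q2_press(model)
    except NotComputableError:
        model.q2 = None
    try:
        model.reproducibility = reproducibility(model)
    except NotComputableError:
        model.reproducibility = None
    try:
        _, model.lof_p = lack_of_fit(model)
    except NotComputableError:
        model.lof_p = None
    return model


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def _require_fit_data(model: QuadraticModel):
    if model._X is None or model._y is None:
        raise NotComputableError("model was deserialized without its fit data")
    return model._X, model._y


def q2_press(model: QuadraticModel) -> float:
    """PRESS-based leave-one-out predictability Q^2 = 1 - PRESS/SS_tot."""
    X, y = _require_fit_data(model)
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    h = np.diag(H)
    if np.any(h >= 1 - 1e-10):
        raise NotComputableError("saturated fit: leverage 1 observation")
    resid = y - X @ (np.linalg.lstsq(X, y, rcond=None)[0])
    press = float(np.sum((resid / (1 - h)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise NotComputableError("zero total variation")
    return 1.0 - press / ss_tot


def _pure_error(model: QuadraticModel):
    X, y = _require_fit_data(model)
    keys = model._settings_key
    if keys is None:
        raise NotComputableError("no replicate structure recorded")
    ss_pe, df_pe = 0.0, 0
    for key in np.unique(keys):
        grp = y[keys == key]
        if grp.size > 1:
            ss_pe += float(np.sum((grp - grp.mean()) ** 2))
            df_pe += grp.size - 1
    return ss_pe, df_pe


def lack_of_fit(model: QuadraticModel):
    """Lack-of-fit F test: residual SS split into lack-of-fit vs pure error.

    Pure error pools replicate injections and repeated (e.g. center-point)
    settings.  Returns ``(F, p)``; a model that only misses through
    replicate noise gives p close to 1.
    """
    X, y = _require_fit_data(model)
    ss_pe, df_pe = _pure_error(model)
    if df_pe < 1:
        raise NotComputableError("no replicated settings: pure-error df = 0")
    resid = y - X @ model.coefficients
    ss_res = float(resid @ resid)
    n_distinct = len(np.unique(model._settings_key))
    df_lof = n_distinct - X.shape[1]
    if df_lof < 1:
        raise NotComputableError("residual df does not exceed pure-error df")
    ss_lof = max(ss_res - ss_pe, 0.0)
    ms_pe = ss_pe / df_pe
    ms_lof = ss_lof / df_lof
    if ms_pe == 0:
        if ms_lof <= 1e-12 * max(1.0, abs(float(y.mean()))):
            return 0.0, 1.0
        return np.inf, 0.0
    F = ms_lof / ms_pe
    p = float(stats.f.sf(F, df_lof, df_pe))
    return float(F), p


def reproducibility(model: QuadraticModel) -> float:
    """Replicate consistency, 1 - MS_pure_error / MS_total (MS convention)."""
    X, y = _require_fit_data(model)
    ss_pe, df_pe = _pure_error(model)
    if df_pe < 1:
        raise NotComputableError("no replicated settings: pure-error df = 0")
    n = y.size
    ms_tot = float(np.sum((y - y.mean()) ** 2)) / (n - 1)
    if ms_tot <= 0:
        raise NotComputableError("zero total variation")
    return 1.0 - (ss_pe / df_pe) / ms_tot


# ---------------------------------------------------------------------------
# Backward refinement
# ---------------------------------------------------------------------------


def _protected_factors(terms: Sequence[Term]) -> set:
    out = set()
    for t in terms:
        if t.kind in ("quadratic", "interaction"):
            out.update(t.factors)
    return out


def refine_model(
    model: QuadraticModel,
    design: DesignMatrix,
    responses,
    alpha: float = 0.05,
    metric: str = "height",
    family_adjust: bool = True,
) -> QuadraticModel:
    """Backward elimination by CI significance with effect-heredity protection.

    Iteratively removes the least significant removable term (its CI covers
    zero, it is not the intercept, and - for main effects - no retained
    quadratic/interaction term contains its factor), refitting after each
    removal.  Idempotent: refining a refined model changes nothing.

    With ``family_adjust`` (default) the retention test at each step uses a
    Bonferroni-adjusted level ``alpha / m`` over the ``m`` candidate terms
    currently in the model, controlling the family-wise rate of spuriously
    retained terms; without it each term is tested at ``alpha``, which with
    ~7-9 inert candidates retains at least one noise term in roughly a
    quarter of runs.  The returned model carries conventional
    ``1 - alpha`` confidence intervals either way.
    """
    terms = list(model.terms)
    while True:
        m_cand = max(1, sum(1 for t in terms if t.kind != "intercept"))
        test_alpha = alpha / m_cand if family_adjust else alpha
        fitted = fit_ols(
            design,
            responses,
            terms,
            transform=model.response_transform,
            analyte=model.analyte,
            metric=metric,
            alpha=test_alpha,
        )
        protected = _protected_factors(fitted.terms)
        candidates = []
        for j, t in enumerate(fitted.terms):
            if t.kind == "intercept":
                continue
            if t.kind == "linear" and t.factors[0] in protected:
                continue
            b, hw = fitted.coefficients[j], fitted.ci95[j]
            if abs(b) <= hw:  # CI covers zero at the retention level
                se = np.sqrt(fitted.cov[j, j])
                tval = abs(b) / se if se > 0 else 0.0
                p = 2 * stats.t.sf(tval, fitted.df_resid)
                candidates.append((p, j))
        if not candidates:
            if test_alpha != alpha:
                fitted = fit_ols(
                    design,
                    responses,
                    terms,
                    transform=model.response_transform,
                    analyte=model.analyte,
                    metric=metric,
                    alpha=alpha,
                )
            return fitted
        _, worst = max(candidates)
        terms = [t for k, t in enumerate(fitted.terms) if k != worst]


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict(
    model: QuadraticModel,
    coded_point,
    extrapolation_box: float = 1.5,
):
    """Predicted mean response and its standard error at a coded point.

    For log-transformed models the mean is back-transformed (exp of the
    linear predictor) and the SE mapped through the delta method.  Points
    outside the +/- ``extrapolation_box`` coded cube trigger an
    extrapolation warning but still evaluate.
    """
    pt = np.atleast_2d(np.asarray(coded_point, dtype=float))
    if np.any(np.abs(pt) > extrapolation_box):
        warnings.warn(
            "prediction point outside the coded extrapolation box",
            stacklevel=2,
        )
    x = build_matrix(pt, model.factor_names, model.terms)
    mu = x @ model.coefficients
    se = np.sqrt(np.einsum("ij,jk,ik->i", x, model.cov, x))
    if model.response_transform == "log":
        mean = np.exp(mu)
        se = mean * se
    else:
        mean = mu
    if mean.size == 1:
        return float(mean[0]), float(se[0])
    return mean, se


def predict_natural(model: QuadraticModel, natural_point, **kw):
    """Predict at a natural-unit point using the model's factor frame."""
    nat = np.asarray(natural_point, dtype=float)
    coded = np.array(
        [f.code(v) for f, v in zip(model.factors, np.atleast_2d(nat).T)]
    ).T
    return predict(model, coded, **kw)


def surface_grid(
    model: QuadraticModel,
    factor_x: str,
    factor_y: str,
    fixed: Optional[dict] = None,
    n: int = 41,
    span: float = 1.35,
) -> pd.DataFrame:
    """Long-format prediction grid for contour rendering of a response surface."""
    names = model.factor_names
    fixed = dict(fixed or {})
    gx = np.linspace(-span, span, n)
    gy = np.linspace(-span, span, n)
    recs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cx in gx:
            for cy in gy:
                pt = np.zeros(len(names))
                for k, v in fixed.items():
                    pt[names.index(k)] = v
                pt[names.index(factor_x)] = cx
                pt[names.index(factor_y)] = cy
                mean, _ = predict(model, pt)
                rec = {factor_x: cx, factor_y: cy, "predicted": mean}
                recs.append(rec)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------


def _model_payload(m: QuadraticModel) -> dict:
    return {
        "analyte": m.analyte,
        "terms": [t.name for t in m.terms],
        "coefficients": m.coefficients.tolist(),
        "ci95": m.ci95.tolist(),
        "cov": m.cov.tolist(),
        "residual_sd": m.residual_sd,
        "df_resid": m.df_resid,
        "r2": m.r2,
        "q2": m.q2,
        "reproducibility": m.reproducibility,
        "lof_p": m.lof_p,
        "response_transform": m.response_transform,
        "factors": [
            {
                "name": f.name,
                "unit": f.unit,
                "low": f.low,
                "high": f.high,
                "rounding_step": f.rounding_step,
                "hard_min": f.hard_min,
                "hard_max": f.hard_max,
            }
            for f in m.factors
        ],
    }


def models_to_json(models: Sequence[QuadraticModel], path) -> None:
    payload = {m.analyte: _model_payload(m) for m in models}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def models_from_json(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for analyte, p in payload.items():
        out[analyte] = QuadraticModel(
            analyte=analyte,
            terms=[Term.parse(t) for t in p["terms"]],
            coefficients=np.array(p["coefficients"]),
            ci95=np.array(p["ci95"]),
            cov=np.array(p["cov"]),
            residual_sd=p["residual_sd"],
            df_resid=p["df_resid"],
            r2=p["r2"],
            q2=p.get("q2"),
            reproducibility=p.get("reproducibility"),
            lof_p=p.get("lof_p"),
            response_transform=p["response_transform"],
            factors=[
                Factor(
                    name=f["name"],
                    unit=f["unit"],
                    low=f["low"],
                    high=f["high"],
                    rounding_step=f["rounding_step"],
                    hard_min=f.get("hard_min"),
                    hard_max=f.get("hard_max"),
                )
                for f in p["factors"]
            ],
        )
    return out
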