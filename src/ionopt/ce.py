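"""Collision-energy tuning: CE x CID response models on the multilevel
D-optimal design, and the one-factor-at-a-time (OFAT) CE scan used to
validate them.

Fragment-ion intensity responds sharply to collision energy (a 2 eV step
off the optimum already costs ~10% of peak height), while collision-gas
pressure has at most a minor effect once CE dominates — the comparison
between the model-predicted optimal CE region and the scan argmax is the
check that the response-surface route and the exhaustive scan agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .errors import ConfigurationError, DegenerateScanError, InvalidValueError
from .rsm import QuadraticModel, ResponseTable, fit_ols, predict_natural, refine_model
from .terms import quadratic_terms

__all__ = [
    "CEScan",
    "fit_ce_cid_models",
    "cid_retained",
    "ofat_scan",
    "ofat_scans",
    "predicted_ce_region",
    "compare_ce_optima",
]


@dataclass
class CEScan:
    """Normalized one-factor CE scan at fixed CID for one analyte."""

    analyte: str
    ce_values: np.ndarray  # eV, strictly increasing
    cid: float  # kPa
    normalized_response: np.ndarray  # percent of maximum (max = 100)

    def __post_init__(self):
        self.ce_values = np.asarray(self.ce_values, dtype=float)
        self.normalized_response = np.asarray(self.normalized_response, dtype=float)
        if np.any(np.diff(self.ce_values) <= 0):
            raise InvalidValueError("CE grid must be strictly increasing")
        if not np.isclose(self.normalized_response.max(), 100.0):
            raise InvalidValueError("normalized response must peak at 100")

    def argmax_ce(self):
        """CE at the scan maximum; ties resolve to the lowest CE and are
        flagged."""
        best = self.normalized_response.max()
        ties = np.nonzero(np.isclose(self.normalized_response, best))[0]
        return float(self.ce_values[ties[0]]), len(ties) > 1


def fit_ce_cid_models(
    design: DesignMatrix,
    responses: ResponseTable,
    transform: str = "log",
    alpha: float = 0.05,
) -> dict:
    """Refined quadratic CE x CID model per analyte.

    Whether CID survives refinement can be read from each returned model's
    terms (see :func:`cid_retained`).
    """
    models = {}
    for analyte in responses.analytes:
        full = fit_ols(
            design,
            responses,
            quadratic_terms(design.factor_names),
            transform=transform,
            analyte=analyte,
        )
        models[analyte] = refine_model(full, design, responses, alpha=alpha)
    return models


def cid_retained(model: QuadraticModel) -> bool:
    """True if any CID term survived model refinement."""
    return any("CID" in t.factors for t in model.terms)


def ofat_scan(responses: pd.DataFrame, analyte: Optional[str] = None) -> CEScan:
    """Build a normalized CE scan from duplicate responses at fixed CID.

    ``responses`` has columns analyte, ce_ev, cid_kpa, replicate, response.
    Replicates are averaged per CE step and the scan normalized to its
    maximum (100%).
    """
    df = responses
    if analyte is not None:
        df = df[df["analyte"] == analyte]
    if df.empty:
        raise ConfigurationError(f"no scan rows for analyte {analyte!r}")
    names = df["analyte"].unique()
    if len(names) != 1:
        raise ConfigurationError("ofat_scan expects a single analyte; use ofat_scans")
    cids = df["cid_kpa"].unique()
    if len(cids) != 1:
        raise InvalidValueError("OFAT scan must be at a single fixed CID")
    mean = df.groupby("ce_ev")["response"].mean().sort_index()
    top = mean.max()
    if top <= 0:
        raise DegenerateScanError(f"{names[0]}: all-zero scan responses")
    return CEScan(
        analyte=str(names[0]),
        ce_values=mean.index.to_numpy(dtype=float),
        cid=float(cids[0]),
        normalized_response=100.0 * mean.to_numpy() / top,
    )


def ofat_scans(responses: pd.DataFrame) -> dict:
    return {a: ofat_scan(responses, a) for a in sorted(responses["analyte"].unique())}


def predicted_ce_region(
    model: QuadraticModel,
    cid: float,
    ce_grid: Optional[np.ndarray] = None,
    rel_threshold: float = 0.95,
):
    """Model-predicted optimal CE point and region at fixed CID.

    The region is the CE interval where predicted response is at least
    ``rel_threshold`` (default 95%) of the model maximum over the grid.
    Returns ``(ce_opt, (ce_lo, ce_hi))``.
    """
    if ce_grid is None:
        ce_grid = np.arange(12.0, 28.01, 0.5)
    pred = np.array(
        [predict_natural(model, [ce, cid])[0] for ce in ce_grid]
    )
    top = pred.max()
    inside = ce_grid[pred >= rel_threshold * top]
    return float(ce_grid[np.argmax(pred)]), (float(inside.min()), float(inside.max()))


def compare_ce_optima(
    models: dict,
    scans: dict,
    tolerance_ev: float = 2.0,
    rel_threshold: float = 0.95,
) -> pd.DataFrame:
    """Per-analyte agreement between model-predicted and scanned CE optima.

    Reports the predicted optimal region, the scan argmax (ties flagged,
    lower CE reported), an inside/outside-the-region verdict and the
    absolute deviation between predicted and scanned optimum in eV.
    """
    missing = set(models) ^ set(scans)
    if missing:
        raise ConfigurationError(f"analyte mismatch between models and scans: {sorted(missing)}")
    recs = []
    for analyte in sorted(models):
        scan = scans[analyte]
        ce_opt, (lo, hi) = predicted_ce_region(
            models[analyte], scan.cid, rel_threshold=rel_threshold
        )
        scan_opt, tie = scan.argmax_ce()
        deviation = abs(scan_opt - ce_opt)
        recs.append(
            {
                "analyte": analyte,
                "model_ce_opt": ce_opt,
                "region_lo": lo,
                "region_hi": hi,
                "scan_ce_opt": scan_opt,
                "tie": tie,
                "inside": lo - 1e-9 <= scan_opt <= hi + 1e-9,
                "deviation_ev": deviation,
                "within_tolerance": deviation <= tolerance_ev + 1e-9,
            }
        )
    return pd.DataFrame(recs).set_index("analyte")
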