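import numpy as np
import pytest

import ionopt as io
from ionopt.rsm import fit_ols, refine_model
from ionopt.terms import quadratic_terms


@pytest.fixture(scope="session")
def ccd_design():
    return io.generate_ccd(io.ccd_factors(), alpha=1.35, n_center=3)


@pytest.fixture(scope="session")
def ffd_design():
    design, alias = io.generate_ffd(io.screening_factors(), p=3, n_center=3)
    return design, alias


def fit_refined_models(seed: int) -> dict:
    """Synthetic CCD responses at default noise -> refined per-analyte models."""
    design, resp = io.generate_regime("ccd", seed)
    models = {}
    for analyte in resp.analytes:
        full = fit_ols(
            design,
            resp,
            quadratic_terms(design.factor_names),
            transform="log",
            analyte=analyte,
        )
        models[analyte] = refine_model(full, design, resp)
    return models


@pytest.fixture(scope="session")
def refined_models_seed42():
    return fit_refined_models(42)


@pytest.fixture(scope="session")
def noise_free_models():
    """Models fitted to noiseless synthetic CCD data (exact recovery)."""
    design = io.generate_ccd(io.ccd_factors(), alpha=1.35, n_center=3)
    resp = io.measure(
        design, io.default_surfaces(), io.GeneratorConfig(seed=0, noise_cv=0.0)
    )
    models = {}
    for analyte in resp.analytes:
        models[analyte] = fit_ols(
            design,
            resp,
            quadratic_terms(design.factor_names),
            transform="log",
            analyte=analyte,
        )
    return models
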