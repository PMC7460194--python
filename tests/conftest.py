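"""Shared fixtures: small graphs, a ground-truthed panel, and one short fit."""

import warnings

import numpy as np
import pytest

import stvcpanel as sp

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture
def path3():
    """3-node path graph 0-1-2."""
    return sp.graph_from_edges(["a", "b", "c"], [(0, 1), (1, 2)])


@pytest.fixture(scope="session")
def study_panel():
    """Default-scale 10x10, T=10 panel with 3 covariates and its truth."""
    cfg = sp.GeneratorConfig(n_se=2, n_ex=1, n_time_invariant=0, seed=42)
    panel, truth = sp.generate_panel(cfg)
    graph = sp.make_lattice_graph(cfg.rows, cfg.cols)
    return panel, truth, graph


@pytest.fixture(scope="session")
def stvc_fit(study_panel):
    """A short but usable STVC (model 5) fit on the study panel."""
    panel, truth, graph = study_panel
    pp = sp.preprocess(panel)
    design = sp.build_model(sp.ModelSpec.for_model(5, pp), pp, graph)
    fit = sp.fit_gibbs(design, sp.McmcConfig(chains=2, iterations=1000, burn_in=500, seed=11))
    return fit, pp, truth, graph


def make_intercept_fit(y, draws_beta0, draws_sigma2, area_axis=True):
    """Hand-built intercept-only PosteriorFit over a complete log-scale panel.

    ``y`` is I x T; draws are 1-D arrays (single chain). Used to probe the
    evaluation criteria at posteriors with known closed forms.
    """
    y = np.asarray(y, dtype=float)
    I, T = y.shape
    panel = sp.PanelData(
        area_ids=tuple(f"a{i}" for i in range(I)),
        years=tuple(range(2000, 2000 + T)),
        y=y,
        X=np.zeros((I, T, 1)),
        covariate_names=("X1",),
        block_labels=("SE",),
        log_response=True,
    )
    graph = (
        sp.make_lattice_graph(1, I) if area_axis else sp.make_lattice_graph(I, 1)
    )
    graph = sp.AreaGraph(area_ids=panel.area_ids, neighbors=graph.neighbors)
    spec = sp.ModelSpec(
        model_id=1,
        include_global_slopes=False,
        include_si=False,
        include_ti=False,
        sc_covariates=(),
        tc_covariates=(),
    )
    design = sp.build_model(spec, panel, graph)
    import pandas as pd

    draws = {
        "beta0": np.asarray(draws_beta0, dtype=float)[None, :],
        "sigma2:obs": np.asarray(draws_sigma2, dtype=float)[None, :],
    }
    return sp.PosteriorFit(
        design=design, draws=draws, mcmc_config=sp.McmcConfig(), diagnostics=pd.DataFrame()
    )
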