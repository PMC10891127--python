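import numpy as np
import pandas as pd
import pytest

import clonalsig as cs


@pytest.fixture
def tiny_multiregion():
    """3 patients x 3 regions, 4 genes, values chosen for hand computation."""
    genes = ["gA", "gB", "gC", "gD"]
    samples = [f"P{p}_{r}" for p in range(3) for r in ("sup", "lat", "inf")]
    values = np.array(
        [
            [1, 2, 3, 4, 4, 4, 0, 2, 4],   # per-patient SDs: 1, 0, 2 -> median 1
            [5, 5, 5, 5, 5, 5, 5, 5, 5],   # constant everywhere
            [0, 0, 0, 9, 9, 9, 3, 3, 3],   # regions identical within patients
            [2, 4, 6, 1, 1, 7, 0, 5, 10],  # generic
        ],
        dtype=float,
    )
    expr = cs.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "log2")
    sm = cs.SampleMap(
        pd.DataFrame(
            {
                "patient_id": [f"P{p}" for p in range(3) for _ in range(3)],
                "region": ["sup", "lat", "inf"] * 3,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return cs.MultiRegionCohort(expr, sm)


@pytest.fixture
def sim_cfg():
    return cs.SimulationConfig(n_genes=400, seed=11)


@pytest.fixture
def sim_cohorts(sim_cfg):
    mr, truth = cs.simulate_multiregion(sim_cfg)
    surv = cs.simulate_survival_cohort(sim_cfg, truth, n_samples=250)
    return mr, surv, truth


def make_survival(n, beta, rng, censor_scale=None):
    """Single-covariate survival draw with true log-hazard beta."""
    x = rng.standard_normal(n)
    t = rng.exponential(np.exp(-beta * x))
    if censor_scale is None:
        return x, t, np.ones(n, dtype=int)
    c = rng.exponential(censor_scale, n)
    return x, np.minimum(t, c), (t <= c).astype(int)


@pytest.fixture
def truth_signature():
    """Build a Signature straight from generator ground truth."""

    def _make(truth):
        genes = truth.prognostic_genes
        coef = truth.beta[genes]
        return cs.Signature(
            genes=genes,
            coefficients=coef.rename("coefficient"),
            penalized_coefficients=coef.rename("penalized"),
            provenance={"input": len(genes), "lasso": len(genes)},
            lam=float("nan"),
        )

    return _make
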