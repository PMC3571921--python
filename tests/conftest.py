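import numpy as np
import pytest

import kinfba
from kinfba.adjust import AdjustedFluxes
from kinfba.estimation import WSLSProblem, solve_wsls


@pytest.fixture(scope="session")
def network():
    return kinfba.load_fixture("ecoli_central")


@pytest.fixture(scope="session")
def kinetic_model():
    return kinfba.build_simplified_model()


@pytest.fixture(scope="session")
def fitted():
    params, halfwidths = kinfba.load_fitted_parameters()
    return params, halfwidths


@pytest.fixture(scope="session")
def small_noiseless_study(network, kinetic_model):
    """Five-condition noise-free chemostat study with hidden truth."""
    return kinfba.generate_study(network, kinetic_model, n_train=4,
                                 n_test=1, noise_cv=0.0, seed=2)


@pytest.fixture(scope="session")
def small_noiseless_problem(kinetic_model, small_noiseless_study):
    study = small_noiseless_study
    ds = study.train
    adj = AdjustedFluxes(
        v={cid: dict(study.truth.fluxes[cid]) for cid in ds.condition_ids},
        distance={cid: 0.0 for cid in ds.condition_ids})
    weights = kinfba.compute_weights(ds, 0.05)
    return WSLSProblem(kinetic_model, ds, weights, adj)


@pytest.fixture(scope="session")
def small_noiseless_fit(small_noiseless_problem):
    return solve_wsls(small_noiseless_problem, n_starts=1, seed=0,
                      max_sweeps=3)


@pytest.fixture(scope="session")
def noisy_study(network, kinetic_model):
    """Headline-scale study: 20 training + 5 test conditions, 5% noise."""
    return kinfba.generate_study(network, kinetic_model, n_train=20,
                                 n_test=5, noise_cv=0.05, seed=11)


@pytest.fixture(scope="session")
def noisy_fit(network, kinetic_model, noisy_study):
    ds = noisy_study.train
    adj = kinfba.adjust_dataset(network, ds)
    weights = kinfba.compute_weights(ds, 0.05)
    problem = WSLSProblem(kinetic_model, ds, weights, adj)
    result = solve_wsls(problem, n_starts=1, seed=0, max_sweeps=2)
    return problem, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_pgm_only_problem(kcat=10.0, keq=0.5):
    """Single-reaction estimation problem built forward from known
    parameters: fluxes and concentrations exactly satisfy the rate law."""
    from kinfba.estimation import WSLSProblem
    from kinfba.omics import ConditionRecord, Measurement, OmicsDataset
    from kinfba.rate_laws import KineticModel, ParameterSpec

    full = kinfba.build_simplified_model()
    law = full.rate_laws["PGM"]
    km = KineticModel(
        rate_laws={"PGM": law},
        specs={"kcat_PGM": ParameterSpec("kcat_PGM", "kcat",
                                         "mmol/mg protein/hr"),
               "Keq_PGM": ParameterSpec("Keq_PGM", "Keq", "dimensionless",
                                        keq_reference=keq)})
    theta = {"kcat_PGM": kcat, "Keq_PGM": keq}
    records, vmap = [], {}
    for i, (c3, ratio, e) in enumerate(
            [(2.0, 0.3, 0.5), (1.0, 0.45, 1.2), (4.0, 0.2, 0.25)]):
        c = {"3pg": c3, "2pg": ratio * c3, "atp": 2.0, "adp": 0.5,
             "amp": 0.05}
        v = e * law.f(c, theta)
        cid = f"t{i}"
        records.append(ConditionRecord(
            cid, 0.2, None, fluxes={"PGM": v},
            metabolites={m: Measurement(c[m], 0.0)
                         for m in ("3pg", "2pg", "adp", "amp")},
            enzymes={"PGM": Measurement(e, 0.0)}))
        vmap[cid] = {"PGM": v}
    ds = OmicsDataset(records, ["3pg", "2pg", "adp", "amp"], ["PGM"])
    adj = AdjustedFluxes(v=vmap, distance={c: 0.0 for c in vmap})
    weights = kinfba.compute_weights(ds, 0.05)
    return WSLSProblem(km, ds, weights, adj), theta


@pytest.fixture()
def pgm_only_problem():
    return make_pgm_only_problem()
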