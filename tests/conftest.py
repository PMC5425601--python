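import numpy as np
import pytest

import groupmediate as gm


@pytest.fixture(scope="session")
def catalog():
    return gm.population_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_dataset(catalog):
    """A modest two-group dataset from the homogeneous null population."""
    return gm.generate_dataset(catalog["I-0"], 60, 60, seed=101)


@pytest.fixture()
def medium_dataset(catalog):
    return gm.generate_dataset(catalog["II-0"], 150, 150, seed=202)


def make_dummy_dataset(n=8, seed=0):
    r = np.random.default_rng(seed)
    x = r.normal(size=n)
    m = 0.3 * x + r.normal(size=n)
    y = 0.3 * m + r.normal(size=n)
    group = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2), dtype=object)
    return gm.MediationDataset(x=x, m=m, y=y, group=group)


def make_single_fit(a1, a2, a3, b, c_prime, se_a3=0.1, se_b=0.1,
                    reference="G1", focal="G2"):
    """Construct a SingleGroupFit with prescribed coefficients and a diagonal
    coefficient covariance — for unit-testing estimand algebra and tests that
    consume printed coefficients."""
    data = make_dummy_dataset()
    names = ("intercept_m", "a1", "a2", "a3", "intercept_y", "b", "c_prime")
    ses = {"a1": 0.1, "a2": 0.1, "a3": se_a3, "b": se_b,
           "intercept_m": 0.1, "intercept_y": 0.1, "c_prime": 0.1}
    vcov = np.diag([ses[n] ** 2 for n in names])
    return gm.SingleGroupFit(
        coding=gm.GroupCoding(reference=reference, focal=focal),
        n=data.n_total,
        params={"intercept_m": 0.0, "a1": a1, "a2": a2, "a3": a3,
                "intercept_y": 0.0, "b": b, "c_prime": c_prime},
        psi_m=1.0,
        psi_y=1.0,
        param_names=names,
        vcov=vcov,
        neg2loglik=0.0,
        data_fingerprint=data.fingerprint(),
        data=data,
    )


def make_multi_fit(a1, b1, a2, b2, se_a1=0.1, se_b1=0.1, se_a2=0.1, se_b2=0.1,
                   labels=("G1", "G2")):
    """Construct a MultiGroupFit with prescribed paths and standard errors."""
    data = make_dummy_dataset()
    l1, l2 = labels
    params = {
        l1: {"intercept_m": 0.0, "a": a1, "psi_m": 1.0,
             "intercept_y": 0.0, "b": b1, "cprime": 0.0, "psi_y": 1.0},
        l2: {"intercept_m": 0.0, "a": a2, "psi_m": 1.0,
             "intercept_y": 0.0, "b": b2, "cprime": 0.0, "psi_y": 1.0},
    }
    def vc(se_a, se_b):
        v = np.zeros((5, 5))
        v[0, 0] = v[2, 2] = v[4, 4] = 0.01
        v[1, 1] = se_a ** 2
        v[3, 3] = se_b ** 2
        return v
    return gm.MultiGroupFit(
        order=labels,
        n_per_group={l1: 4, l2: 4},
        params=params,
        vcov_by_group={l1: vc(se_a1, se_b1), l2: vc(se_a2, se_b2)},
        neg2loglik=0.0,
        constraints=frozenset(),
        n_free_params=12,
        data_fingerprint=data.fingerprint(),
        data=data,
    )
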