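import numpy as np
import pytest

import scfaphase as sp
from scfaphase.cluster import JSDTyper
from scfaphase.cohort import SCFA_COLUMNS


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort at the default study conditions (12 subjects, 730 d)."""
    return sp.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def composition_typer(default_cohort):
    return JSDTyper().fit(default_cohort.order_table())


@pytest.fixture(scope="session")
def scfa_typer(default_cohort):
    return JSDTyper().fit(default_cohort.scfa[SCFA_COLUMNS])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def brute_force_kmedoids(D: np.ndarray, k: int):
    """Exhaustive k-medoid search: globally optimal medoid set and cost."""
    from itertools import combinations

    n = D.shape[0]
    best_cost, best = np.inf, None
    for medoids in combinations(range(n), k):
        cost = D[:, medoids].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, medoids
    return np.array(best), float(best_cost)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """BH step-up from the definition: q_i = min_{p_j >= p_i} p_j * m / rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = ranked * m / (np.arange(m) + 1)
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@pytest.fixture(scope="session")
def latent_phase_fn():
    """Map (truth, day) to the latent SCFA phase 1/2/3."""

    def fn(truth, day):
        if day < truth.T1:
            return 1
        return 2 if day < truth.wean_day else 3

    return fn
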