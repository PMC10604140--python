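"""Shared fixtures: the default model components and one intact-knee
gait simulation reused across test modules."""

import numpy as np
import pytest

import kneesim as ks


@pytest.fixture(scope="session")
def geometry():
    return ks.default_geometry()


@pytest.fixture(scope="session")
def body():
    return ks.BodyParams()


@pytest.fixture(scope="session")
def contact():
    return ks.ContactParams()


@pytest.fixture(scope="session")
def ligaments(geometry):
    return ks.default_ligament_set(geometry)


@pytest.fixture(scope="session")
def muscles():
    return ks.default_muscle_set()


@pytest.fixture(scope="session")
def gait_clean():
    """Deterministic template stride (no jitter), 100 samples."""
    return ks.generate_gait_cycle(ks.GaitGenParams(noise_sd=0.0, seed=0), 100)


@pytest.fixture(scope="session")
def intact_result(geometry, ligaments, muscles, gait_clean, body, contact):
    """Second-cycle result of the default intact knee."""
    return ks.simulate_gait(geometry, ligaments, muscles, gait_clean, body,
                            contact, condition="IntactKnee")


def brute_force_minmax_stress(demand, levers_m, pcsas, tol=1e-10):
    """Solver-independent oracle for the Min/Max optimum stress.

    Bisection on the common stress sigma; feasibility of a sigma is
    decided by enumerating every extreme force combination
    F_i in {0, pcsa_i * sigma} (dense for the <=3-muscle problems it is
    used on) and checking whether the demanded moment lies within the
    achievable moment interval.
    """
    levers = np.asarray(levers_m, float)
    pcsas = np.asarray(pcsas, float)
    n = len(levers)

    def feasible(sigma):
        moments = []
        for mask in range(2 ** n):
            forces = np.array([(mask >> i) & 1 for i in range(n)]) * pcsas * sigma
            moments.append(float(levers @ forces))
        return min(moments) - tol <= demand <= max(moments) + tol

    if demand == 0.0:
        return 0.0
    hi = 1.0
    while not feasible(hi):
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("oracle: problem appears infeasible")
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return hi
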