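"""Shared fixtures: default phantom, truth reconstruction, and the 20-seed study."""

import numpy as np
import pytest

from cinealign.benchmark import misalignment_study, summarize_study
from cinealign.config import RunConfig
from cinealign.phantom import PhantomSpec, make_phantom
from cinealign.reconstruction import ReconstructionParams, reconstruct


@pytest.fixture(scope="session")
def phantom():
    """Default analytic phantom: (truth surface, truth slice records)."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def truth_reconstruction(phantom):
    """Surface reconstructed from the phantom's exact (unperturbed) contours."""
    _, records = phantom
    return reconstruct(records, ReconstructionParams())


@pytest.fixture(scope="session")
def study():
    """The 20-seed misalignment-recovery study under the default conditions.

    Shared by the acceptance tests and the reconstruction ordering checks so
    the expensive simulations run once per session.
    """
    rows = misalignment_study(base_seed=1, n_runs=20, config=RunConfig())
    return rows, summarize_study(rows)


def enumerate_min_cut(n_tets, arcs, capacities, source_tets, sink_tets):
    """Brute-force minimum s-t cut by enumerating all tet labelings.

    Independent oracle for the max-flow solver: source tets fixed interior,
    sink tets fixed exterior, free tets take every combination.
    """
    import itertools

    source_tets = set(int(t) for t in np.atleast_1d(source_tets))
    sink_tets = set(int(t) for t in np.atleast_1d(sink_tets))
    free = [t for t in range(n_tets) if t not in source_tets and t not in sink_tets]
    best = np.inf
    for bits in itertools.product([False, True], repeat=len(free)):
        labels = np.zeros(n_tets, dtype=bool)
        labels[list(source_tets)] = True
        for t, b in zip(free, bits):
            labels[t] = b
        cost = capacities[labels[arcs[:, 0]] != labels[arcs[:, 1]]].sum()
        best = min(best, float(cost))
    return best
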