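"""Shared fixtures: sampled series and oracle values reused across tests.

The expensive Monte Carlo runs are session-scoped so that the estimator
unit tests, the invariant tests and the acceptance suite all draw on the
same trajectories.
"""

import numpy as np
import pytest

from alchemkit import (
    CouplingState,
    EDSParams,
    SamplerConfig,
    ThermoContext,
    as_system,
    clash_toy,
    eds_well_pair,
    generate_fixtures,
    harmonic_lambda_pair,
    metropolis_sample,
    quadrature_free_energy,
    sample_eds_reference,
)
from alchemkit.eds_search import initial_offset_estimate, run_search
from alchemkit.io_cli import unbiased_state_a_series
from alchemkit.model_systems import FixedStateSystem

CLASH_BOX = [(-1.5, 1.5)]


@pytest.fixture(scope="session")
def ctx():
    return ThermoContext()


@pytest.fixture(scope="session")
def harmonic_system():
    return as_system(harmonic_lambda_pair())


@pytest.fixture(scope="session")
def clash_system():
    return as_system(clash_toy())


@pytest.fixture(scope="session")
def clash_corners(clash_system, ctx):
    """Deterministic-quadrature free energies of the four corner states."""
    return {
        c: quadrature_free_energy(clash_system, CouplingState(*c), CLASH_BOX, ctx)
        for c in ((0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0))
    }


@pytest.fixture(scope="session")
def harmonic_bar_series(harmonic_system, ctx):
    """Five cross-evaluated windows of the stiffening harmonic well."""
    lams = np.linspace(0.0, 1.0, 5)
    out = []
    for k, l in enumerate(lams):
        neigh = []
        if k > 0:
            neigh.append(CouplingState(lams[k - 1], 0.0))
        if k + 1 < len(lams):
            neigh.append(CouplingState(lams[k + 1], 0.0))
        out.append(
            metropolis_sample(
                harmonic_system,
                CouplingState(l, 0.0),
                SamplerConfig(30000, 0.2, seed=100 + k),
                ctx,
                neighbor_states=neigh,
            )
        )
    return out


@pytest.fixture(scope="session")
def harmonic_probe_series(harmonic_system, ctx):
    """Nine windows with dense on-the-fly probe records for extended TI.

    The simulated points are drawn from the probe grid itself so that the
    lam_P = lam_S coincidences are exact floating-point identities.
    """
    probes = np.linspace(0.0, 1.0, 101)
    lams = probes[[0, 12, 25, 37, 50, 63, 75, 88, 100]]
    return [
        metropolis_sample(
            harmonic_system,
            CouplingState(l, 0.0),
            SamplerConfig(40000, 0.2, seed=200 + k, record_stride=5),
            ctx,
            probe_lams=probes,
        )
        for k, l in enumerate(lams)
    ]


@pytest.fixture(scope="session")
def well_pair():
    return eds_well_pair()


@pytest.fixture(scope="session")
def well_search(well_pair, ctx):
    """Automated (E, s) search on the overlap-friendly well pair."""
    a, b, _ = well_pair
    probe = unbiased_state_a_series(a, b, SamplerConfig(5000, 0.1, seed=42), ctx)
    e0 = initial_offset_estimate(probe)
    return run_search(
        [a, b],
        init=EDSParams.two_state(0.002, e0),
        n_rounds=200,
        steps_per_round=2000,
        seed=7,
        ctx=ctx,
    )


@pytest.fixture(scope="session")
def well_production(well_pair, well_search, ctx):
    """Long reference-state run with the searched parameters."""
    a, b, _ = well_pair
    return sample_eds_reference(
        [a, b], well_search.current_params, SamplerConfig(200000, 0.1, seed=99), ctx
    )


@pytest.fixture(scope="session")
def clash_search(clash_system, ctx):
    """The same search on the strongly clashing diagonal state pair."""
    e_a = FixedStateSystem(clash_system, CouplingState(0.0, 0.0))
    e_b = FixedStateSystem(clash_system, CouplingState(1.0, 1.0))
    probe = unbiased_state_a_series(e_a, e_b, SamplerConfig(5000, 0.1, seed=42), ctx)
    e0 = initial_offset_estimate(probe)
    return run_search(
        [e_a, e_b],
        init=EDSParams.two_state(0.002, e0),
        n_rounds=200,
        steps_per_round=2000,
        seed=7,
        ctx=ctx,
    )


@pytest.fixture(scope="session")
def clash_diag_series(clash_system, ctx):
    """Cross-evaluated windows along the diagonal path lam = kap."""
    ts = [0.0, 0.1, 0.2, 0.3, 0.4, 0.45, 0.5, 0.55, 0.6, 0.7, 0.8, 0.9, 1.0]
    out = []
    for k, t in enumerate(ts):
        neigh = []
        if k > 0:
            neigh.append(CouplingState(ts[k - 1], ts[k - 1]))
        if k + 1 < len(ts):
            neigh.append(CouplingState(ts[k + 1], ts[k + 1]))
        out.append(
            metropolis_sample(
                clash_system,
                CouplingState(t, t),
                SamplerConfig(30000, 0.1, seed=300 + k),
                ctx,
                neighbor_states=neigh,
            )
        )
    return out


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return generate_fixtures(seed=7, outdir=out)
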