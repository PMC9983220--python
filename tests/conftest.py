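"""Shared fixtures: small analytic circuits and scaled-down ensembles.

Ensemble fixtures are session-scoped and deliberately smaller than the
10,000 x 100 production runs (sampling error of a fraction at this scale
is ~1 pp, well inside every tolerance asserted on them) so the whole
suite stays within a CI budget.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from emtcircuits.circuits import Edge, HillParams, KineticParameterSet, RegulatoryNetwork
from emtcircuits.ensemble import run_ensemble


@pytest.fixture(scope="session")
def isolated_node():
    net = RegulatoryNetwork("iso", ["X"], [])
    params = KineticParameterSet({"X": 10.0}, {"X": 0.1}, {})
    return net, params


@pytest.fixture(scope="session")
def toggle():
    """Symmetric two-node toggle switch: bistable with one saddle."""
    net = RegulatoryNetwork(
        "toggle", ["A", "B"], [Edge("A", "B", "inhibition"), Edge("B", "A", "inhibition")]
    )
    params = KineticParameterSet(
        {"A": 50.0, "B": 50.0},
        {"A": 0.5, "B": 0.5},
        {("A", "B"): HillParams(0.02, 30.0, 4), ("B", "A"): HillParams(0.02, 30.0, 4)},
    )
    return net, params


@pytest.fixture(scope="session")
def grhl2_ensemble():
    """Scaled-down control ensemble of the GRHL2-ELF3 circuit."""
    from emtcircuits.circuits import load_fixture

    net, _ = load_fixture("core_emt_elf3_grhl2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_ensemble(net, n_sets=4000, n_inits=50, seed=7)


@pytest.fixture(scope="session")
def elf3_diagrams():
    """Classified bifurcation diagrams of the core and ELF3 circuits."""
    from emtcircuits.bifurcation import classify_phenotypes, sweep_bifurcation
    from emtcircuits.circuits import load_fixture

    out = {}
    for name in ("core_emt", "core_emt_elf3"):
        net, params = load_fixture(name)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            diag = sweep_bifurcation(
                net, params, control="I_ext", range_=(1e3, 3e5), n_points=60,
                readout="ZEB", n_starts=24, seed=5, t_max=4000.0,
            )
        classify_phenotypes(diag)
        out[name] = (net, params, diag)
    return out
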