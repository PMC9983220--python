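"""Bifurcation sweeps, phenotype phases, windows and sensitivity."""

import warnings

import numpy as np
import pytest

from emtcircuits.circuits import (
    CircuitError,
    Edge,
    HillParams,
    KineticParameterSet,
    RegulatoryNetwork,
    load_fixture,
)
from emtcircuits.bifurcation import (
    Branch,
    BifurcationDiagram,
    classify_phenotypes,
    hybrid_window,
    phase_diagram,
    sensitivity_analysis,
    sweep_bifurcation,
)


class TestSweep:
    def test_isolated_node_linear_branch(self, isolated_node):
        net, params = isolated_node
        diag = sweep_bifurcation(
            net, params, control="g:X", range_=(1.0, 100.0), n_points=12,
            readout="X", log=False, n_starts=4, seed=0,
        )
        assert len(diag.branches) == 1
        b = diag.branches[0]
        assert b.stability == "stable"
        assert np.allclose(b.readout, np.asarray(b.control) / 0.1, rtol=1e-6)

    def test_cascade_has_three_stable_branches(self, elf3_diagrams):
        _, _, diag = elf3_diagrams["core_emt_elf3"]
        stable = diag.stable_branches()
        assert len(stable) == 3
        labels = {b.label for b in stable}
        assert labels == {"E", "H", "M"}
        med = {b.label: b.median_readout() for b in stable}
        assert med["E"] < med["H"] < med["M"]

    def test_hybrid_branch_contiguous(self, elf3_diagrams):
        _, _, diag = elf3_diagrams["core_emt_elf3"]
        h = next(b for b in diag.stable_branches() if b.label == "H")
        grid = diag.grid
        covered = [c for c in grid if h.c_min <= c <= h.c_max]
        assert len(covered) == len(h.control)  # no gaps inside the window

    def test_fold_points_stable_under_grid_refinement(self):
        net, params = load_fixture("core_emt")
        folds = {}
        for n_points in (50, 100):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                diag = sweep_bifurcation(net, params, range_=(1e3, 3e5), n_points=n_points,
                                         n_starts=24, seed=5, t_max=4000.0, include_unstable=False)
            classify_phenotypes(diag)
            e = max((b for b in diag.stable_branches() if b.label == "E"), key=lambda b: b.c_max)
            folds[n_points] = e.c_max
        coarse_step = 3e5 / 1e3
        step = folds[50] * (coarse_step ** (1 / 49) - 1)  # one coarse log-grid step
        assert abs(folds[100] - folds[50]) <= step * 1.05

    def test_unknown_control_rejected(self, isolated_node):
        net, params = isolated_node
        with pytest.raises(KeyError):
            sweep_bifurcation(net, params, control="g:missing", range_=(1, 10), n_points=3,
                              readout="X")


class TestClassification:
    def _fake_diagram(self, branch_specs):
        branches = [
            Branch(list(c), list(r), [np.array([v]) for v in r], stability=s)
            for c, r, s in branch_specs
        ]
        grid = np.unique(np.concatenate([b.control for b in branches]))
        return BifurcationDiagram("I_ext", grid, branches, "ZEB", ("ZEB",))

    def test_more_than_three_coexisting_is_error(self):
        diag = self._fake_diagram(
            [((1, 2), (10 * 3 ** i, 10 * 3 ** i), "stable") for i in range(4)]
        )
        with pytest.raises(CircuitError, match="three"):
            classify_phenotypes(diag)

    def test_monotone_lone_branch_spans_e_to_m(self):
        diag = self._fake_diagram([((1, 2, 3), (10.0, 100.0, 1000.0), "stable")])
        mapping = classify_phenotypes(diag)
        assert mapping == {0: "E/M"}

    def test_labels_invariant_under_control_rescaling(self, elf3_diagrams):
        _, _, diag = elf3_diagrams["core_emt_elf3"]
        rescaled = BifurcationDiagram(
            diag.control_name, diag.grid * 1e-3,
            [Branch([c * 1e-3 for c in b.control], list(b.readout), list(b.states), b.stability)
             for b in diag.branches],
            diag.readout, diag.nodes,
        )
        mapping = classify_phenotypes(rescaled)
        original = {i: b.label for i, b in enumerate(diag.branches) if b.stability == "stable"}
        assert {i: l for i, l in mapping.items()} == original


class TestHybridWindow:
    def test_no_intermediate_branch_gives_zero(self, isolated_node):
        net, params = isolated_node
        diag = sweep_bifurcation(net, params, control="g:X", range_=(1.0, 100.0),
                                 n_points=8, readout="X", log=False, n_starts=4)
        classify_phenotypes(diag)
        assert hybrid_window(diag) == 0.0

    def test_refined_window_within_grid_resolution_of_dense_scan(self):
        """Sweep + bisection refinement agrees with a brute-force dense
        steady-state scan of the hybrid branch extent."""
        net, params = load_fixture("core_emt_elf3")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coarse = sweep_bifurcation(net, params, range_=(1e3, 3e5), n_points=50,
                                       n_starts=24, seed=5, t_max=4000.0, include_unstable=False)
            classify_phenotypes(coarse)
            w_refined = hybrid_window(coarse, net, params, refine=True, t_max=4000.0)
            dense = sweep_bifurcation(net, params, range_=(1e3, 3e5), n_points=150,
                                      n_starts=24, seed=5, t_max=4000.0, include_unstable=False)
            classify_phenotypes(dense)
            w_dense = hybrid_window(dense)
        dense_step = 0.05  # 150-point log grid: ~4% spacing
        assert abs(w_refined - w_dense) / w_dense < 2.5 * dense_step


class TestPhaseDiagram:
    def test_single_cell_equals_pointwise_classification(self):
        net, params = load_fixture("core_emt_elf3")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pd_ = phase_diagram(net, params, "I_ext", "lambda:ELF3->ZEB",
                                x_grid=[1.3e4], y_grid=[0.42], n_starts=24, seed=1, t_max=4000.0)
            point = sweep_bifurcation(net, params, control="I_ext", range_=np.array([1.3e4]),
                                      n_starts=24, seed=1, t_max=4000.0, include_unstable=False)
        mapping = classify_phenotypes(point)
        direct = frozenset(l for l in mapping.values() if l in ("E", "H", "M"))
        assert pd_.labels.shape == (1, 1)
        assert len(pd_.labels[0, 0]) == len(point.stable_branches()) == 2
        # without sweep context a coexisting pair is ordered low/high,
        # exactly what point-wise classification produces
        assert pd_.labels[0, 0] == direct

    def test_wt1_snail_activation_expands_mesenchymal_region(self):
        """Strengthening WT1->SNAIL activation grows {M} and shrinks {E}."""
        net, params = load_fixture("core_emt_elf3_wt1")
        x_grid = np.geomspace(3e3, 1.2e5, 28)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pd_ = phase_diagram(net, params, "I_ext", "lambda:WT1->SNAIL",
                                x_grid=x_grid, y_grid=[1.5, 4.0], n_starts=28, seed=2, t_max=4000.0)
        def only(row, phase):
            return sum(1 for lbl in pd_.labels[row] if lbl == frozenset({phase}))
        assert only(1, "M") > only(0, "M")
        assert only(1, "E") < only(0, "E")

    def test_elf3_zeb_inhibition_expands_epithelial_region(self):
        """Stronger ELF3-mediated ZEB repression (smaller fold-change)
        grows {E} and shrinks {M}."""
        net, params = load_fixture("core_emt_elf3")
        x_grid = np.geomspace(3e3, 1.2e5, 28)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pd_ = phase_diagram(net, params, "I_ext", "lambda:ELF3->ZEB",
                                x_grid=x_grid, y_grid=[0.6, 0.3], n_starts=28, seed=2, t_max=4000.0)
        def cells(row, phase):
            return sum(1 for lbl in pd_.labels[row] if phase in lbl)
        assert sum(1 for lbl in pd_.labels[1] if lbl == frozenset({"E"})) > \
               sum(1 for lbl in pd_.labels[0] if lbl == frozenset({"E"}))
        assert cells(1, "M") < cells(0, "M")

    def test_deterministic_repeatability(self):
        net, params = load_fixture("core_emt_elf3")
        kw = dict(x_grid=np.geomspace(1e3, 1e5, 6), y_grid=[0.3, 0.6],
                  n_starts=10, seed=4, t_max=3000.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = phase_diagram(net, params, "I_ext", "lambda:ELF3->ZEB", **kw)
            b = phase_diagram(net, params, "I_ext", "lambda:ELF3->ZEB", **kw)
        assert a.to_frame().equals(b.to_frame())


class TestSensitivity:
    def test_disconnected_node_has_zero_effect(self):
        """Perturbing the kinetics of a node outside the circuit leaves
        the hybrid window untouched."""
        net, params = load_fixture("core_emt_elf3")
        aug = RegulatoryNetwork(net.name + "+orphan", (*net.nodes, "ORPHAN"), net.edges,
                                signal=net.signal)
        p = params.copy()
        p.production["ORPHAN"] = 25.0
        p.degradation["ORPHAN"] = 0.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = sensitivity_analysis(
                aug, p, range_=(1e3, 3e5), n_points=50, n_starts=24, seed=5, t_max=4000.0,
                parameters=["g:ORPHAN", "k:ORPHAN"], refine=True,
            )
        assert rep.attrs["baseline_window"] > 0
        assert np.allclose(rep["percent_change"], 0.0, atol=1e-6)

    def test_perturbation_reversibility(self):
        _, params = load_fixture("core_emt_elf3")
        name = "lambda:ELF3->ZEB"
        v = params.get(name)
        restored = params.set(name, v * 1.1).set(name, v)
        assert restored.get(name) == pytest.approx(v)
        assert restored.hill == params.hill
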