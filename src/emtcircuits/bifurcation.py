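"""Bifurcation diagrams, phase diagrams and parameter sensitivity.

The control parameter (the external EMT-inducing signal ``I_ext`` or any
named kinetic parameter) is swept over a grid; at each grid value the
steady states are found by multi-start integration plus saddle polishing,
and states at adjacent grid values are linked into branches by
nearest-neighbour matching on the readout level.  Phenotypes are assigned
by *branch ordering* (lowest stable readout branch = epithelial, highest
= mesenchymal, intermediate = hybrid E/M), never by absolute thresholds,
so diagrams are invariant to rescaling the readout.

The hybrid-E/M window is the length of the control interval on which the
hybrid branch is stable; its endpoints are sharpened past the grid by
bisection on branch disappearance (a saddle-node fold).  The sensitivity
analysis perturbs each kinetic parameter by ±10% and reports the percent
change of this window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .circuits import (
    CircuitError,
    ConfigurationError,
    KineticParameterSet,
    RegulatoryNetwork,
    build_rhs,
)
from . import dynamics
from .dynamics import (
    CONVERGED,
    DEDUP_RTOL,
    STEADY_TOL_FACTOR,
    compile_system,
    steady_state_batch,
    _classify_stability,
    _dedupe,
    _polish,
    _same_state,
    _sampling_caps,
)

__all__ = [
    "Branch",
    "BifurcationDiagram",
    "PhaseDiagram",
    "sweep_bifurcation",
    "classify_phenotypes",
    "hybrid_window",
    "phase_diagram",
    "sensitivity_analysis",
]

# Relative readout change between adjacent grid points above which two
# states are considered to lie on different branches.  Branches of this
# model class sit a factor >= 2.5 apart while along-branch steps near a
# fold reach ~40% on practical grids, hence the 0.45 default.
JUMP_TOL = 0.45
PHENOTYPES = ("E", "H", "M")


@dataclass
class Branch:
    """A continuous run of steady states across adjacent control values."""

    control: list[float] = field(default_factory=list)
    readout: list[float] = field(default_factory=list)
    states: list[np.ndarray] = field(default_factory=list)
    stability: str = "stable"
    label: str | None = None

    @property
    def c_min(self) -> float:
        return self.control[0]

    @property
    def c_max(self) -> float:
        return self.control[-1]

    def median_readout(self) -> float:
        return float(np.median(self.readout))


@dataclass
class BifurcationDiagram:
    control_name: str
    grid: np.ndarray
    branches: list[Branch]
    readout: str
    nodes: tuple[str, ...]
    network_name: str = ""

    def stable_branches(self) -> list[Branch]:
        return [b for b in self.branches if b.stability == "stable"]

    def max_coexisting_stable(self) -> int:
        best = 0
        for c in self.grid:
            n = sum(1 for b in self.stable_branches() if _contains(b, c))
            best = max(best, n)
        return best

    def phases_at(self, value: float) -> frozenset[str]:
        """Set of phenotype labels of stable branches covering ``value``
        (requires :func:`classify_phenotypes` to have run)."""
        labels = {b.label for b in self.stable_branches() if _contains(b, value) and b.label}
        return frozenset(labels)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.branches):
            for c, r in zip(b.control, b.readout):
                rows.append((i, b.label, b.stability, c, r))
        return pd.DataFrame(rows, columns=["branch", "label", "stability", self.control_name, self.readout])


def _contains(branch: Branch, value: float, rtol: float = 1e-9) -> bool:
    lo, hi = branch.c_min, branch.c_max
    pad = rtol * max(abs(lo), abs(hi), 1.0)
    return lo - pad <= value <= hi + pad


# ---------------------------------------------------------------------------
# Sweeping
# ---------------------------------------------------------------------------


def _control_grid(rng: Sequence[float] | np.ndarray, n_points: int | None, log: bool) -> np.ndarray:
    arr = np.asarray(rng, dtype=float)
    if arr.size != 2:
        return arr
    lo, hi = float(arr[0]), float(arr[1])
    n = n_points or 60
    if log:
        lo_ = max(lo, 1e-9 * max(hi, 1.0))
        return np.geomspace(lo_, hi, n)
    return np.linspace(lo, hi, n)


def _states_along_grid(
    network: RegulatoryNetwork,
    params: KineticParameterSet,
    control: str,
    grid: np.ndarray,
    I_ext: float,
    n_starts: int,
    seed: int,
    include_unstable: bool,
    dt: float,
    t_max: float,
):
    """Steady states at every grid value, via one batched kernel call."""
    if control == "I_ext":
        if network.signal is None:
            raise ConfigurationError("network has no external signal node; cannot sweep I_ext")
        plist = [params] * grid.size
        sig = grid.astype(float)
    else:
        params.get(control)  # raises KeyError for unknown names
        plist = [params.set(control, v) for v in grid]
        sig = np.full(grid.size, float(I_ext))

    cs = compile_system(network, plist, I_ext=sig)
    rng = np.random.default_rng(seed)
    caps = _sampling_caps(network, params)
    lo = np.ones_like(caps)
    hi = np.maximum(caps, 2.0)
    x0_base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n_starts, caps.size)))
    x0 = np.tile(x0_base, (grid.size, 1))
    model_of = np.repeat(np.arange(grid.size), n_starts)
    xf, status = steady_state_batch(cs, x0, model_of, dt=dt, t_max=t_max)

    per_grid: list[list[tuple[np.ndarray, str]]] = []
    for i, c in enumerate(grid):
        sel = (model_of == i) & (status == CONVERGED)
        rhs = build_rhs(network, plist[i], external_signal=sig[i])
        reps, _counts = _dedupe(xf[sel])
        found: list[tuple[np.ndarray, str]] = []
        for r in reps:
            r = _polish(rhs, r)
            found.append((np.clip(r, 0.0, None), _classify_stability(rhs, r)))
        if include_unstable and len(found) >= 2:
            attractors = [s for s, st in found if st == "stable"]
            mids = [0.5 * (a + b) for ia, a in enumerate(attractors) for b in attractors[ia + 1 :]]
            mids += [np.sqrt(np.maximum(a, 1e-9) * np.maximum(b, 1e-9))
                     for ia, a in enumerate(attractors) for b in attractors[ia + 1 :]]
            gmax = float(max(plist[i].production.values()))
            for m in mids:
                root = _polish(rhs, m, require_success=True)
                if root is None or np.any(root < -1e-9):
                    continue
                root = np.clip(root, 0.0, None)
                if float(np.max(np.abs(rhs(root)))) > 10 * STEADY_TOL_FACTOR * gmax:
                    continue
                if any(_same_state(root, s) for s, _ in found):
                    continue
                found.append((root, _classify_stability(rhs, root)))
        per_grid.append(found)
    return per_grid


def _predict_readout(branch: Branch, c_new: float) -> float:
    """Expected readout of ``branch`` at the next control value, by
    log-linear extrapolation of its last two points (branches steepen
    near folds, so comparing against the raw last value fragments them)."""
    if len(branch.readout) < 2:
        return branch.readout[-1]
    r1, r0 = branch.readout[-1], branch.readout[-2]
    c1, c0 = branch.control[-1], branch.control[-2]
    if min(r1, r0) <= 0 or min(c1, c0, c_new) <= 0 or c1 == c0:
        slope = (r1 - r0) / ((c1 - c0) or 1.0)
        pred = r1 + slope * (c_new - c1)
    else:
        slope = (np.log(r1) - np.log(r0)) / (np.log(c1) - np.log(c0))
        pred = float(np.exp(np.log(r1) + slope * (np.log(c_new) - np.log(c1))))
    # the prediction may steepen but never jump branches: one grid step
    # changes a branch's level by at most ~2x in this model class
    lo, hi = sorted((r1 / 2.0, r1 * 2.0))
    return float(np.clip(pred, lo, hi))


def _link_branches(grid: np.ndarray, per_grid, readout_idx: int, jump_tol: float) -> list[Branch]:
    open_branches: list[Branch] = []
    closed: list[Branch] = []
    for c, states in zip(grid, per_grid):
        entries = [(s, st, float(s[readout_idx])) for s, st in states]
        unmatched = list(range(len(entries)))
        next_open: list[Branch] = []
        # match each open branch to the nearest same-stability state within tolerance
        for b in sorted(open_branches, key=Branch.median_readout):
            best, best_d = None, np.inf
            pred = _predict_readout(b, float(c))
            for j in unmatched:
                s, st, r = entries[j]
                if st != b.stability:
                    continue
                d = abs(r - pred) / max(abs(pred), abs(r), 1e-9)
                if d < best_d:
                    best, best_d = j, d
            # a single continuing branch with a single same-stability
            # candidate is linked unconditionally: continuity is forced,
            # and relative-jump tolerances misfire on steep lone ramps
            forced = len(open_branches) == 1 and sum(
                1 for j in unmatched if entries[j][1] == b.stability
            ) == 1
            if best is not None and (best_d < jump_tol or forced):
                s, st, r = entries[best]
                b.control.append(float(c))
                b.readout.append(r)
                b.states.append(s)
                unmatched.remove(best)
                next_open.append(b)
            else:
                closed.append(b)
        for j in unmatched:
            s, st, r = entries[j]
            next_open.append(Branch([float(c)], [r], [s], st))
        open_branches = next_open
    closed.extend(open_branches)
    return [b for b in closed if b.control]


def _merge_collinear(branches: list[Branch], jump_tol: float) -> list[Branch]:
    """Join branch segments split by a grid gap when their facing endpoints
    align in readout (same stability, non-overlapping control ranges)."""
    branches = sorted(branches, key=lambda b: b.c_min)
    merged = True
    while merged:
        merged = False
        for i, a in enumerate(branches):
            for j, b in enumerate(branches):
                if i == j or a.stability != b.stability or a.c_max >= b.c_min:
                    continue
                pred = _predict_readout(a, b.control[0])
                d = abs(b.readout[0] - pred) / max(abs(pred), abs(b.readout[0]), 1e-9)
                if d < jump_tol:
                    a.control += b.control
                    a.readout += b.readout
                    a.states += b.states
                    branches.pop(j)
                    merged = True
                    break
            if merged:
                break
    return branches


def sweep_bifurcation(
    network: RegulatoryNetwork,
    params: KineticParameterSet,
    control: str = "I_ext",
    range_: Sequence[float] | np.ndarray = (1e3, 3e5),
    n_points: int | None = None,
    readout: str = "ZEB",
    I_ext: float = 0.0,
    n_starts: int = 32,
    seed: int = 0,
    log: bool = True,
    include_unstable: bool = True,
    jump_tol: float = JUMP_TOL,
    dt: float = dynamics.DEFAULT_DT,
    t_max: float = dynamics.DEFAULT_T_MAX,
) -> BifurcationDiagram:
    """Sweep ``control`` and link steady states into branches.

    ``control`` is ``"I_ext"`` or a flat parameter name such as
    ``"lambda:ELF3->ZEB"``.  ``range_`` is either a (lo, hi) pair (grid
    spacing set by ``n_points``/``log``) or an explicit grid.  An empty
    steady-state set at a grid value leaves a branch gap (warned, not
    fatal); gap-split segments that align are re-joined.
    """
    nodes = network.dynamic_nodes
    if readout not in nodes:
        raise ConfigurationError(f"readout node {readout!r} not in network {network.name!r}")
    grid = _control_grid(range_, n_points, log)
    per_grid = _states_along_grid(
        network, params, control, grid, I_ext, n_starts, seed, include_unstable, dt, t_max
    )
    if any(len(s) == 0 for s in per_grid):
        gaps = [float(c) for c, s in zip(grid, per_grid) if not s]
        warnings.warn(f"no steady state found at {control}={gaps}; branch gap recorded")
    ridx = nodes.index(readout)
    branches = _link_branches(grid, per_grid, ridx, jump_tol)
    branches = _merge_collinear(branches, jump_tol)
    return BifurcationDiagram(control, grid, branches, readout, nodes, network.name)


# ---------------------------------------------------------------------------
# Phenotype classification on a diagram
# ---------------------------------------------------------------------------


def classify_phenotypes(diagram: BifurcationDiagram) -> dict[int, str]:
    """Label stable branches E / H / M by readout ordering.

    With two or three stable branches the lowest is epithelial and the
    highest mesenchymal (ordering by median readout, which is what branch
    identity preserves along the sweep).  A lone monotone branch is
    labelled point-wise by its position within its own range.  More than
    three coexisting stable states is outside the E/H/M vocabulary and is
    an error.
    """
    stable = diagram.stable_branches()
    if not stable:
        raise CircuitError("diagram has no stable branch")
    if diagram.max_coexisting_stable() > 3:
        raise CircuitError("more than three coexisting stable states: outside the E/H/M phenotype vocabulary")

    mapping: dict[int, str] = {}
    order = sorted(stable, key=Branch.median_readout)
    if len(order) == 1:
        # a lone branch has no ordering partner: label by its own span
        # ("E/M" marks a monotone rising branch, resolved point-wise by
        # position where a single-phase call is needed, e.g. phase diagrams)
        b = order[0]
        span = max(b.readout) - min(b.readout)
        if span <= 1e-9 * max(abs(max(b.readout)), 1.0):
            b.label = "E"
        else:
            b.label = "E/M" if b.readout[-1] > b.readout[0] else "M/E"
        mapping[diagram.branches.index(b)] = b.label
        return mapping
    if len(order) == 2:
        labels = ["E", "M"]
    elif len(order) == 3:
        labels = ["E", "H", "M"]
    else:
        # more global segments than phenotypes: cluster by readout level
        med = np.array([b.median_readout() for b in order])
        logmed = np.log10(np.maximum(med, 1e-12))
        cuts = np.argsort(np.diff(logmed))[-2:]
        group = np.zeros(len(order), dtype=int)
        for c in sorted(cuts):
            group[c + 1 :] += 1
        labels = [PHENOTYPES[gr] for gr in group]
    for b, lbl in zip(order, labels):
        b.label = lbl
        mapping[diagram.branches.index(b)] = lbl
    return mapping


# ---------------------------------------------------------------------------
# Hybrid window and fold refinement
# ---------------------------------------------------------------------------


def _branch_persists(network, params, control, c_value, I_ext, state, readout_idx, dt, t_max) -> tuple[bool, np.ndarray]:
    """Continuation test: integrate from ``state`` at the new control value
    and check the attractor stays on the same branch (readout within the
    jump tolerance) and is stable."""
    if control == "I_ext":
        p, sig = params, float(c_value)
    else:
        p, sig = params.set(control, float(c_value)), float(I_ext)
    cs = compile_system(network, p, I_ext=sig)
    xf, status = steady_state_batch(cs, state[None, :], dt=dt, t_max=t_max)
    if status[0] != CONVERGED:
        return False, state
    new = xf[0]
    r_old, r_new = state[readout_idx], new[readout_idx]
    same = abs(r_new - r_old) / max(abs(r_old), abs(r_new), 1e-9) < JUMP_TOL
    if not same:
        return False, state
    rhs = build_rhs(network, p, external_signal=sig)
    return _classify_stability(rhs, new) == "stable", new


def _refine_fold(network, params, control, c_in, c_out, state, readout_idx, I_ext, dt, t_max, n_iter=12):
    """Bisect between a control value where the branch exists (``c_in``)
    and one where it has disappeared (``c_out``)."""
    s = state
    for _ in range(n_iter):
        c_mid = np.sqrt(c_in * c_out) if min(c_in, c_out) > 0 else 0.5 * (c_in + c_out)
        ok, s_new = _branch_persists(network, params, control, c_mid, I_ext, s, readout_idx, dt, t_max)
        if ok:
            c_in, s = c_mid, s_new
        else:
            c_out = c_mid
    return c_in


def hybrid_window(
    diagram: BifurcationDiagram,
    network: RegulatoryNetwork | None = None,
    params: KineticParameterSet | None = None,
    refine: bool = False,
    I_ext: float = 0.0,
    dt: float = dynamics.DEFAULT_DT,
    t_max: float = dynamics.DEFAULT_T_MAX,
) -> float:
    """Length of the control interval on which the hybrid branch is stable.

    Returns 0 when no intermediate stable branch exists.  With
    ``refine=True`` (requires the network/params used for the sweep) the
    window endpoints are sharpened past the grid by bisection on branch
    disappearance.
    """
    if not any(b.label for b in diagram.branches):
        classify_phenotypes(diagram)
    hybrids = [b for b in diagram.stable_branches() if b.label == "H"]
    if not hybrids:
        return 0.0
    lo = min(b.c_min for b in hybrids)
    hi = max(b.c_max for b in hybrids)
    if refine:
        if network is None or params is None:
            raise ValueError("refine=True needs the network and parameter set")
        ridx = diagram.nodes.index(diagram.readout)
        grid = diagram.grid
        b_lo = min(hybrids, key=lambda b: b.c_min)
        b_hi = max(hybrids, key=lambda b: b.c_max)
        i_lo = int(np.searchsorted(grid, lo))
        i_hi = int(np.searchsorted(grid, hi))
        c_below = grid[i_lo - 1] if i_lo > 0 else lo
        c_above = grid[i_hi + 1] if i_hi + 1 < grid.size else hi
        if c_below < lo:
            lo = _refine_fold(network, params, diagram.control_name, lo, c_below, b_lo.states[0], ridx, I_ext, dt, t_max)
        if c_above > hi:
            hi = _refine_fold(network, params, diagram.control_name, hi, c_above, b_hi.states[-1], ridx, I_ext, dt, t_max)
    return float(hi - lo)


# ---------------------------------------------------------------------------
# Phase diagrams
# ---------------------------------------------------------------------------


@dataclass
class PhaseDiagram:
    """Phenotype-combination labels over a rectangular two-parameter grid.

    ``labels[iy, ix]`` is the frozenset of coexisting stable phenotypes at
    ``(x_grid[ix], y_grid[iy])``.
    """

    param_x: str
    param_y: str
    x_grid: np.ndarray
    y_grid: np.ndarray
    labels: np.ndarray  # object array of frozensets

    def area(self, phase: frozenset[str] | set[str] | str) -> int:
        """Number of grid cells whose label equals ``phase`` exactly."""
        want = frozenset([phase]) if isinstance(phase, str) else frozenset(phase)
        return int(sum(1 for lbl in self.labels.flat if lbl == want))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iy, y in enumerate(self.y_grid):
            for ix, x in enumerate(self.x_grid):
                rows.append((x, y, "{" + ",".join(sorted(self.labels[iy, ix])) + "}"))
        return pd.DataFrame(rows, columns=[self.param_x, self.param_y, "phase"])


def phase_diagram(
    network: RegulatoryNetwork,
    params: KineticParameterSet,
    param_x: str,
    param_y: str,
    x_grid: Sequence[float] | np.ndarray,
    y_grid: Sequence[float] | np.ndarray,
    readout: str = "ZEB",
    I_ext: float = 0.0,
    n_starts: int = 24,
    seed: int = 0,
    dt: float = dynamics.DEFAULT_DT,
    t_max: float = dynamics.DEFAULT_T_MAX,
) -> PhaseDiagram:
    """Two-parameter phase diagram; each row is a classified x-sweep.

    The x axis (commonly ``I_ext``) is swept as a bifurcation diagram for
    every y value so that phenotype labels come from branch ordering.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    y_grid = np.asarray(y_grid, dtype=float)
    labels = np.empty((y_grid.size, x_grid.size), dtype=object)
    for iy, y in enumerate(y_grid):
        p_row = params.set(param_y, y) if param_y != "I_ext" else params
        row_I = I_ext if param_y != "I_ext" else y
        diag = sweep_bifurcation(
            network, p_row, control=param_x, range_=x_grid, readout=readout, I_ext=row_I,
            n_starts=n_starts, seed=seed, include_unstable=False, dt=dt, t_max=t_max,
        )
        classify_phenotypes(diag)
        for ix, x in enumerate(x_grid):
            phases = diag.phases_at(x)
            if not phases:  # gap: fall back to nearest labelled grid point
                phases = frozenset({"E"})
                for b in diag.stable_branches():
                    if b.label in PHENOTYPES:
                        phases = frozenset({b.label})
                        break
            # a lone monotone branch carries a positional E/M split
            if phases & {"E/M", "M/E"}:
                b = diag.stable_branches()[0]
                j = int(np.argmin(np.abs(np.array(b.control) - x)))
                lo, hi = min(b.readout), max(b.readout)
                pos = (b.readout[j] - lo) / max(hi - lo, 1e-12)
                phases = frozenset({"E" if pos < 1 / 3 else ("H" if pos < 2 / 3 else "M")})
            labels[iy, ix] = phases
    return PhaseDiagram(param_x, param_y, x_grid, y_grid, labels)


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------


def sensitivity_analysis(
    network: RegulatoryNetwork,
    params: KineticParameterSet,
    control: str = "I_ext",
    range_: Sequence[float] | np.ndarray = (1e3, 3e5),
    n_points: int | None = None,
    readout: str = "ZEB",
    perturbation: float = 0.10,
    parameters: Sequence[str] | None = None,
    flag_threshold: float = 10.0,
    n_starts: int = 24,
    seed: int = 0,
    refine: bool = True,
    dt: float = dynamics.DEFAULT_DT,
    t_max: float = dynamics.DEFAULT_T_MAX,
) -> pd.DataFrame:
    """Percent change of the hybrid-E/M window under ±``perturbation``.

    Every continuous kinetic parameter (g, k, fold-changes and thresholds;
    Hill coefficients are integers and excluded) is perturbed one by one
    in both directions and the hybrid window recomputed.  Columns:
    parameter, direction, window, percent_change, flagged.  A zero
    baseline window yields NaN percent changes (reported, not raised).
    """

    def window_for(p: KineticParameterSet) -> float:
        diag = sweep_bifurcation(
            network, p, control=control, range_=range_, n_points=n_points, readout=readout,
            n_starts=n_starts, seed=seed, include_unstable=False, dt=dt, t_max=t_max,
        )
        classify_phenotypes(diag)
        return hybrid_window(diag, network, p, refine=refine, dt=dt, t_max=t_max)

    baseline = window_for(params)
    if parameters is None:
        parameters = [
            name
            for name in params.parameter_names()
            if not name.startswith("n:")
        ]
    rows = []
    for name in parameters:
        base_value = params.get(name)
        for direction, factor in (("+10%", 1 + perturbation), ("-10%", 1 - perturbation)):
            w = window_for(params.set(name, base_value * factor))
            pct = 100.0 * (w - baseline) / baseline if baseline > 0 else np.nan
            rows.append((name, direction, w, pct, bool(abs(pct) > flag_threshold) if baseline > 0 else True))
    df = pd.DataFrame(rows, columns=["parameter", "direction", "window", "percent_change", "flagged"])
    df.attrs["baseline_window"] = baseline
    return df
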