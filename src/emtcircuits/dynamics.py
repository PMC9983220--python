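"""Time integration and steady-state detection for shifted-Hill circuits.

Two execution paths are provided and cross-checked in the test suite:

* :func:`integrate` — a single recorded trajectory, forward Euler by
  default (the convention in this modelling lineage) or an adaptive
  scipy integrator.
* a batched Euler kernel (:func:`steady_state_batch`) that advances many
  (parameter set, initial condition) pairs at once and is the workhorse
  behind multi-start steady-state finding, bifurcation sweeps and the
  random-parameter ensemble.  It is JIT-compiled with numba when
  available, with a vectorised numpy fallback.

Steady states found by integration are attractors; saddle-type (unstable)
states lying between them are recovered by root polishing and classified
by the eigenvalues of a finite-difference Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .circuits import (
    ACTIVATION,
    CircuitError,
    ConfigurationError,
    KineticParameterSet,
    RegulatoryNetwork,
    build_rhs,
)

__all__ = [
    "Trajectory",
    "SteadyState",
    "IntegrationError",
    "integrate",
    "find_steady_states",
    "epithelial_initial_condition",
    "compare_circuits_temporal",
    "compile_system",
    "steady_state_batch",
]

# Numerical defaults (rationale in docs/methods.md):
#   steady-state residual tolerance = STEADY_TOL_FACTOR * max production rate
#   duplicate steady states merged below DEDUP_RTOL relative L-inf distance
#   divergence ceiling = CEILING_FACTOR * g_max / k_min
STEADY_TOL_FACTOR = 1e-6
DEDUP_RTOL = 0.01
CEILING_FACTOR = 1e6
DEFAULT_DT = 0.1
DEFAULT_T_MAX = 2000.0

# Status codes returned by the batch kernel.
RUNNING, CONVERGED, DIVERGED = 0, 1, 2


class IntegrationError(CircuitError):
    """Raised when a trajectory diverges past the configured ceiling."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """A recorded time course: ``states[i]`` is the state at ``times[i]``."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_nodes), molecules
    nodes: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.nodes))
        df.insert(0, "time", self.times)
        return df

    def final(self, node: str | None = None):
        if node is None:
            return self.states[-1]
        return float(self.states[-1, self.nodes.index(node)])

    @property
    def converged(self) -> bool:
        return bool(self.metadata.get("converged", False))


@dataclass
class SteadyState:
    """A fixed point of the circuit with its stability classification."""

    levels: np.ndarray
    nodes: tuple[str, ...]
    stability: str  # "stable" | "unstable"
    residual: float
    basin_starts: int = 0  # number of initial conditions that reached it

    def level(self, node: str) -> float:
        return float(self.levels[self.nodes.index(node)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.nodes, self.levels)}

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


# ---------------------------------------------------------------------------
# Single-trajectory integration
# ---------------------------------------------------------------------------


def _initial_vector(initial, nodes: Sequence[str]) -> np.ndarray:
    if isinstance(initial, Mapping):
        missing = [n for n in nodes if n not in initial]
        if missing:
            raise ConfigurationError(f"initial condition missing nodes {missing}")
        x0 = np.array([float(initial[n]) for n in nodes])
    else:
        x0 = np.asarray(initial, dtype=float)
        if x0.shape != (len(nodes),):
            raise ConfigurationError(f"initial condition has shape {x0.shape}, expected ({len(nodes)},)")
    if np.any(x0 < 0) or not np.all(np.isfinite(x0)):
        raise ConfigurationError("initial levels must be finite and non-negative")
    return x0


def integrate(
    network: RegulatoryNetwork,
    params: KineticParameterSet,
    initial,
    I_ext: float = 0.0,
    t_end: float = 200.0,
    dt: float = DEFAULT_DT,
    method: str = "euler",
    record_every: int = 10,
) -> Trajectory:
    """Integrate the circuit ODEs and record the trajectory.

    ``method`` is ``"euler"`` (forward Euler, the lineage default) or
    ``"adaptive"`` (scipy ``solve_ivp`` LSODA).  The final state carries a
    convergence flag (max |dX/dt| below the steady-state tolerance) in
    ``metadata``.  A level exceeding the divergence ceiling raises
    :class:`IntegrationError` naming the offending node.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    rhs = build_rhs(network, params, I_ext)
    nodes = rhs.nodes
    x = _initial_vector(initial, nodes)
    g_max = max(float(rhs.production.max()), 1e-12)
    ceiling = CEILING_FACTOR * g_max / float(rhs.degradation.min())

    if method == "euler":
        n_steps = int(round(t_end / dt))
        times = [0.0]
        states = [x.copy()]
        for step in range(1, n_steps + 1):
            x = x + dt * rhs(x)
            np.maximum(x, 0.0, out=x)  # Euler clamp: levels stay non-negative
            if np.any(x > ceiling):
                bad = nodes[int(np.argmax(x))]
                raise IntegrationError(f"level of {bad!r} exceeded divergence ceiling {ceiling:.3g}")
            if step % record_every == 0 or step == n_steps:
                times.append(step * dt)
                states.append(x.copy())
        traj = Trajectory(np.array(times), np.array(states), nodes)
    elif method == "adaptive":
        t_eval = np.linspace(0.0, t_end, max(2, int(round(t_end / (dt * record_every))) + 1))
        sol = scipy_solve_ivp(rhs, x, t_end, t_eval)
        if np.any(sol.y > ceiling):
            bad = nodes[int(np.argmax(sol.y.max(axis=1)))]
            raise IntegrationError(f"level of {bad!r} exceeded divergence ceiling {ceiling:.3g}")
        traj = Trajectory(sol.t, np.clip(sol.y.T, 0.0, None), nodes)
    else:
        raise ValueError(f"unknown method {method!r}")

    residual = float(np.max(np.abs(rhs(traj.states[-1]))))
    traj.metadata.update(
        network=network.name,
        provenance=params.provenance,
        I_ext=float(I_ext),
        method=method,
        residual=residual,
        converged=residual < STEADY_TOL_FACTOR * g_max,
    )
    return traj


def scipy_solve_ivp(rhs: Callable, x0: np.ndarray, t_end: float, t_eval: np.ndarray):
    from scipy.integrate import solve_ivp

    sol = solve_ivp(lambda t, y: rhs(np.clip(y, 0.0, None)), (0.0, t_end), x0, t_eval=t_eval, method="LSODA", rtol=1e-8, atol=1e-9)
    if not sol.success:  # pragma: no cover - defensive
        raise IntegrationError(sol.message)
    return sol


# ---------------------------------------------------------------------------
# Batched Euler kernel
# ---------------------------------------------------------------------------


@dataclass
class CompiledSystem:
    """Array form of one or many parameterisations of a single topology.

    ``g``/``k`` have shape (n_models, n_nodes); ``lam``/``a0``/``nh`` have
    shape (n_models, n_edges) in edge order; ``esrc`` is -1 where the edge
    source is the external signal node, whose per-model level is ``sig``.
    """

    nodes: tuple[str, ...]
    esrc: np.ndarray
    etgt: np.ndarray
    g: np.ndarray
    k: np.ndarray
    lam: np.ndarray
    a0: np.ndarray
    nh: np.ndarray
    sig: np.ndarray

    @property
    def n_models(self) -> int:
        return self.g.shape[0]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def compile_system(
    network: RegulatoryNetwork,
    params: KineticParameterSet | Sequence[KineticParameterSet],
    I_ext: float | np.ndarray = 0.0,
) -> CompiledSystem:
    """Pack one or many kinetic parameter sets into kernel-ready arrays."""
    plist = [params] if isinstance(params, KineticParameterSet) else list(params)
    nodes = network.dynamic_nodes
    index = {n: i for i, n in enumerate(nodes)}
    edges = network.edges
    for p in plist:
        from .circuits import _check_coverage

        _check_coverage(network, p)
    esrc = np.array([-1 if e.source == network.signal else index[e.source] for e in edges], dtype=np.int64)
    etgt = np.array([index[e.target] for e in edges], dtype=np.int64)
    g = np.array([[p.production[n] for n in nodes] for p in plist], dtype=float)
    k = np.array([[p.degradation[n] for n in nodes] for p in plist], dtype=float)
    lam = np.array([[p.hill[e.key].fold_change for e in edges] for p in plist], dtype=float)
    a0 = np.array([[p.hill[e.key].threshold for e in edges] for p in plist], dtype=float)
    nh = np.array([[p.hill[e.key].coefficient for e in edges] for p in plist], dtype=np.int64)
    sig = np.broadcast_to(np.asarray(I_ext, dtype=float), (len(plist),)).copy()
    return CompiledSystem(nodes, esrc, etgt, g, k, lam, a0, nh, sig)


def _euler_batch_numpy(x, model_of, cs: CompiledSystem, dt, check_every, max_steps, tol, ceiling):
    """Vectorised fallback kernel; same contract as the numba version."""
    x = x.copy()
    n_traj = x.shape[0]
    status = np.zeros(n_traj, dtype=np.int8)
    active = np.arange(n_traj)
    steps_done = 0
    while active.size and steps_done < max_steps:
        n_sub = min(check_every, max_steps - steps_done)
        xa = x[active]
        m = model_of[active]
        g, k = cs.g[m], cs.k[m]
        lam, a0, nh, sig = cs.lam[m], cs.a0[m], cs.nh[m], cs.sig[m]
        for _ in range(n_sub):
            prod = g.copy()
            for e in range(cs.esrc.size):
                s = cs.esrc[e]
                level = sig if s < 0 else xa[:, s]
                ratio = (level / a0[:, e]) ** nh[:, e]
                prod[:, cs.etgt[e]] *= lam[:, e] + (1.0 - lam[:, e]) / (1.0 + ratio)
            xa += dt * (prod - k * xa)
            np.maximum(xa, 0.0, out=xa)
        steps_done += n_sub
        x[active] = xa
        rate = np.abs(prod - k * xa).max(axis=1)
        conv = rate < tol[m]
        div = xa.max(axis=1) > ceiling[m]
        status[active[conv]] = CONVERGED
        status[active[div & ~conv]] = DIVERGED
        active = active[~(conv | div)]
    return x, status


def _make_numba_kernel():  # pragma: no cover - exercised indirectly
    try:
        import numba
    except ImportError:
        return None

    @numba.njit(cache=False, fastmath=True)
    def kernel(x, model_of, esrc, etgt, g, k, lam, a0, nh, sig, dt, check_every, max_steps, tol, ceiling):
        n_traj, n_nodes = x.shape
        n_edges = esrc.size
        status = np.zeros(n_traj, dtype=np.int8)
        prod = np.empty(n_nodes)
        for t in range(n_traj):
            m = model_of[t]
            steps = 0
            while steps < max_steps:
                stop = min(steps + check_every, max_steps)
                while steps < stop:
                    for j in range(n_nodes):
                        prod[j] = g[m, j]
                    for e in range(n_edges):
                        s = esrc[e]
                        level = sig[m] if s < 0 else x[t, s]
                        r = level / a0[m, e]
                        p = r
                        for _ in range(nh[m, e] - 1):
                            p *= r
                        prod[etgt[e]] *= lam[m, e] + (1.0 - lam[m, e]) / (1.0 + p)
                    for j in range(n_nodes):
                        xn = x[t, j] + dt * (prod[j] - k[m, j] * x[t, j])
                        x[t, j] = xn if xn > 0.0 else 0.0
                    steps += 1
                # residual and divergence check at chunk boundary
                worst = 0.0
                top = 0.0
                for j in range(n_nodes):
                    prod[j] = g[m, j]
                for e in range(n_edges):
                    s = esrc[e]
                    level = sig[m] if s < 0 else x[t, s]
                    r = level / a0[m, e]
                    p = r
                    for _ in range(nh[m, e] - 1):
                        p *= r
                    prod[etgt[e]] *= lam[m, e] + (1.0 - lam[m, e]) / (1.0 + p)
                for j in range(n_nodes):
                    rate = prod[j] - k[m, j] * x[t, j]
                    if abs(rate) > worst:
                        worst = abs(rate)
                    if x[t, j] > top:
                        top = x[t, j]
                if worst < tol[m]:
                    status[t] = 1
                    break
                if top > ceiling[m]:
                    status[t] = 2
                    break
        return x, status

    return kernel


_NUMBA_KERNEL = _make_numba_kernel()


def steady_state_batch(
    cs: CompiledSystem,
    x0: np.ndarray,
    model_of: np.ndarray | None = None,
    dt: float = DEFAULT_DT,
    t_max: float = DEFAULT_T_MAX,
    check_every: int = 100,
    tol_factor: float = STEADY_TOL_FACTOR,
    use_numba: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance every trajectory to steady state (or give up at ``t_max``).

    Returns final states (n_traj, n_nodes) and an int8 status per
    trajectory (0 not converged, 1 converged, 2 diverged).
    """
    x0 = np.ascontiguousarray(x0, dtype=float)
    n_traj = x0.shape[0]
    if model_of is None:
        model_of = np.zeros(n_traj, dtype=np.int64)
    model_of = np.ascontiguousarray(model_of, dtype=np.int64)
    tol = tol_factor * cs.g.max(axis=1)
    ceiling = CEILING_FACTOR * cs.g.max(axis=1) / cs.k.min(axis=1)
    max_steps = int(round(t_max / dt))
    if use_numba is None:
        use_numba = _NUMBA_KERNEL is not None
    if use_numba and _NUMBA_KERNEL is not None:
        return _NUMBA_KERNEL(
            x0.copy(), model_of, cs.esrc, cs.etgt, cs.g, cs.k, cs.lam, cs.a0, cs.nh, cs.sig,
            float(dt), int(check_every), max_steps, tol, ceiling,
        )
    return _euler_batch_numpy(x0, model_of, cs, float(dt), int(check_every), max_steps, tol, ceiling)


# ---------------------------------------------------------------------------
# Multi-start steady-state finding
# ---------------------------------------------------------------------------


def _sampling_caps(network: RegulatoryNetwork, params: KineticParameterSet) -> np.ndarray:
    """Per-node upper bound for initial-condition sampling: the maximum
    attainable level g/k scaled by the product of incoming activation
    fold-changes (every activator saturated, no repression)."""
    caps = []
    for n in network.dynamic_nodes:
        boost = 1.0
        for e in network.incoming(n):
            lam = params.hill[e.key].fold_change
            if lam > 1.0:
                boost *= lam
        caps.append(max(params.production[n], 1e-6) / params.degradation[n] * boost)
    return np.array(caps)


def _dedupe(states: np.ndarray, rtol: float = DEDUP_RTOL):
    """Greedy clustering by relative L-inf distance; returns representatives
    (cluster means) and per-cluster member counts."""
    reps: list[np.ndarray] = []
    members: list[list[np.ndarray]] = []
    for s in states:
        placed = False
        for i, r in enumerate(reps):
            scale = np.maximum(np.maximum(np.abs(r), np.abs(s)), 1e-9)
            if np.max(np.abs(r - s) / scale) < rtol:
                members[i].append(s)
                reps[i] = np.mean(members[i], axis=0)
                placed = True
                break
        if not placed:
            reps.append(s.copy())
            members.append([s])
    counts = np.array([len(m) for m in members], dtype=int)
    return reps, counts


def finite_difference_jacobian(rhs: Callable, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    n = x.size
    jac = np.empty((n, n))
    f0 = rhs(x)
    for j in range(n):
        h = rel_step * max(abs(x[j]), 1.0)
        xp = x.copy()
        xp[j] += h
        jac[:, j] = (rhs(xp) - f0) / h
    return jac


def _classify_stability(rhs: Callable, x: np.ndarray) -> str:
    eig = np.linalg.eigvals(finite_difference_jacobian(rhs, x))
    return "stable" if np.all(eig.real < 0) else "unstable"


def find_steady_states(
    network: RegulatoryNetwork,
    params: KineticParameterSet,
    I_ext: float = 0.0,
    n_starts: int = 100,
    seed: int = 0,
    dt: float = DEFAULT_DT,
    t_max: float = DEFAULT_T_MAX,
    include_unstable: bool = True,
    use_numba: bool | None = None,
) -> list[SteadyState]:
    """Locate the circuit's steady states by multi-start integration.

    Initial conditions are log-uniform between 1 and each node's
    unregulated maximum; converged endpoints are deduplicated (relative
    L-inf < 1%) and classified via Jacobian eigenvalues.  Saddle states
    between attractor pairs are recovered by Newton root polishing from
    pairwise midpoints (they shape the unstable branches of bifurcation
    diagrams).  An empty list is returned (with a warning in the caller's
    hands) when no start converges.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    rhs = build_rhs(network, params, I_ext)
    nodes = rhs.nodes
    caps = _sampling_caps(network, params)
    lo = np.ones_like(caps)
    hi = np.maximum(caps, 2.0)
    x0 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n_starts, caps.size)))

    cs = compile_system(network, params, I_ext)
    xf, status = steady_state_batch(cs, x0, dt=dt, t_max=t_max, use_numba=use_numba)
    converged = xf[status == CONVERGED]
    out: list[SteadyState] = []
    reps, counts = _dedupe(converged)
    for r, c in zip(reps, counts):
        r = _polish(rhs, r)
        out.append(SteadyState(r, nodes, _classify_stability(rhs, r), float(np.max(np.abs(rhs(r)))), int(c)))

    if include_unstable and len(out) >= 2:
        attractors = [s.levels for s in out]
        seeds = [0.5 * (a + b) for i, a in enumerate(attractors) for b in attractors[i + 1 :]]
        # geometric midpoints help when attractor levels differ by orders of magnitude
        seeds += [np.sqrt(np.maximum(a, 1e-9) * np.maximum(b, 1e-9))
                  for i, a in enumerate(attractors) for b in attractors[i + 1 :]]
        for s0 in seeds:
            root = _polish(rhs, s0, require_success=True)
            if root is None:
                continue
            if np.any(root < -1e-9):
                continue
            root = np.clip(root, 0.0, None)
            if float(np.max(np.abs(rhs(root)))) > STEADY_TOL_FACTOR * float(rhs.production.max()) * 10:
                continue
            if any(_same_state(root, s.levels) for s in out):
                continue
            out.append(
                SteadyState(root, nodes, _classify_stability(rhs, root), float(np.max(np.abs(rhs(root)))), 0)
            )
    out.sort(key=lambda s: tuple(s.levels))
    return out


def _same_state(a: np.ndarray, b: np.ndarray, rtol: float = DEDUP_RTOL) -> bool:
    scale = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-9)
    return bool(np.max(np.abs(a - b) / scale) < rtol)


def _polish(rhs: Callable, x: np.ndarray, require_success: bool = False):
    """Newton-polish a near-fixed-point; acceptance is by residual, not by
    fsolve's progress flag (which trips near marginally stable saddles)."""
    g_max = float(getattr(rhs, "production", np.ones(1)).max())
    tol = 1e-7 * max(1.0, g_max)
    sol = np.asarray(x, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # hybrd progress chatter
        for _ in range(3):  # hybrd can stall on symmetric saddles; restart helps
            sol = optimize.fsolve(rhs, sol, xtol=1e-10)
            if np.max(np.abs(rhs(sol))) < tol:
                return sol
        res = optimize.root(rhs, sol, method="lm")
    if np.max(np.abs(rhs(res.x))) < tol:
        return res.x
    return None if require_success else x


# ---------------------------------------------------------------------------
# Temporal comparison across circuit variants
# ---------------------------------------------------------------------------


def epithelial_initial_condition(
    network: RegulatoryNetwork,
    params: KineticParameterSet,
    readout: str = "ZEB",
    n_starts: int = 60,
    seed: int = 0,
) -> np.ndarray:
    """The stable state at zero external signal with the lowest readout
    level — the model's resting epithelial phenotype."""
    states = [s for s in find_steady_states(network, params, I_ext=0.0, n_starts=n_starts, seed=seed) if s.stable]
    if not states:
        raise CircuitError(f"no stable state at I_ext=0 for network {network.name!r}")
    return min(states, key=lambda s: s.level(readout)).levels


def compare_circuits_temporal(
    circuits: Mapping[str, tuple[RegulatoryNetwork, KineticParameterSet]],
    I_ext: float,
    readout: str = "ZEB",
    initial: str = "epithelial",
    t_end: float = 400.0,
    dt: float = DEFAULT_DT,
    seed: int = 0,
) -> tuple[dict[str, Trajectory], list[str]]:
    """Integrate each circuit from its epithelial resting state under the
    same external signal; returns the trajectories and the circuit names
    ordered by terminal readout level (ascending)."""
    trajectories: dict[str, Trajectory] = {}
    for label, (network, params) in circuits.items():
        if readout not in network.dynamic_nodes:
            raise ConfigurationError(f"readout node {readout!r} absent from circuit {label!r}")
        if initial == "epithelial":
            x0 = epithelial_initial_condition(network, params, readout=readout, seed=seed)
        else:
            x0 = initial
        trajectories[label] = integrate(network, params, x0, I_ext=I_ext, t_end=t_end, dt=dt)
    ordering = sorted(trajectories, key=lambda lbl: trajectories[lbl].final(readout))
    return trajectories, ordering
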