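"""Random-parameter ensemble simulation of a circuit topology.

For a fixed network the kinetic parameters are sampled from broad
pre-defined ranges (the convention of the random-circuit-perturbation
lineage): production 1–100, degradation 0.1–1, fold-change 1–100
(reciprocal for inhibition), integer Hill coefficient 1–6, and edge
thresholds by the half-functional rule — uniform in [0.02, 1.98] times
the median unregulated level of the regulator.  Each parameter set is
integrated from many random initial conditions (forward Euler), the
distinct steady states are collected, log2-transformed and z-normalised,
and the solution matrix is summarised by PCA and classified into
epithelial/mesenchymal phenotypes at the minimum of the bimodal
EMT-score (z(ZEB) − z(miR-200)) distribution.

In-silico over/down-expression multiplies/divides the target's sampled
production rate by a fold, re-normalises against the control statistics,
and compares phenotype fractions across replicates with a Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.optimize import brentq

from .circuits import (
    ACTIVATION,
    CircuitError,
    ConfigurationError,
    HillParams,
    KineticParameterSet,
    RegulatoryNetwork,
)
from .dynamics import CONVERGED, CompiledSystem, steady_state_batch

__all__ = [
    "SamplingRanges",
    "ParameterSample",
    "EnsembleResult",
    "PerturbationExperiment",
    "sample_parameters",
    "run_ensemble",
    "pca_summary",
    "bimodal_threshold",
    "call_phenotypes",
    "perturb",
    "er_network_experiment",
]

_LOG_FLOOR = 1e-12  # levels are strictly positive in this model class; guard anyway


@dataclass(frozen=True)
class SamplingRanges:
    """Sampling ranges of the random ensemble (lineage defaults).

    ``threshold_rule`` selects how the half-functional anchor level of a
    regulator is estimated: ``"regulated-median"`` (default, the lineage
    convention) takes the median of g/k times the Hill multipliers of the
    node's own incoming links, each evaluated at its half-functional
    point; ``"unregulated-median"`` uses the bare median of g/k.
    """

    production: tuple[float, float] = (1.0, 100.0)
    degradation: tuple[float, float] = (0.1, 1.0)
    fold_change: tuple[float, float] = (1.0, 100.0)
    hill_coefficient: tuple[int, int] = (1, 6)
    threshold_spread: tuple[float, float] = (0.02, 1.98)
    threshold_rule: str = "regulated-median"

    def __post_init__(self) -> None:
        for lo, hi in (self.production, self.degradation, self.fold_change, self.threshold_spread):
            if not lo < hi:
                raise ValueError("range lower bound must be below upper bound")
        if self.hill_coefficient[0] < 1:
            raise ValueError("Hill coefficients must be >= 1")
        if self.threshold_rule not in ("regulated-median", "unregulated-median"):
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")

    def median_unregulated_level(self) -> float:
        """Median of g/k with g, k uniform on the declared ranges — the
        anchor of the half-functional threshold rule."""
        g0, g1 = self.production
        k0, k1 = self.degradation

        def cdf(m: float) -> float:
            # P(g/k <= m) for independent uniforms, by integrating over k
            ks = np.linspace(k0, k1, 2001)
            p = np.clip((m * ks - g0) / (g1 - g0), 0.0, 1.0)
            return float(np.trapezoid(p, ks) / (k1 - k0))

        return brentq(lambda m: cdf(m) - 0.5, g0 / k1, g1 / k0)

    def _hill_multiplier_draws(self, activation: bool, n_mc: int, rng: np.random.Generator) -> np.ndarray:
        """Draws of the shifted-Hill multiplier of one link evaluated at the
        regulator's half-functional level.  Because the link threshold is
        spread x M(source) while the regulator sits at M(source), the
        level/threshold ratio is 1/spread — independent of the source —
        making the multiplier distribution universal per sign."""
        lam = rng.uniform(*self.fold_change, size=n_mc)
        if not activation:
            lam = 1.0 / lam
        n = rng.integers(self.hill_coefficient[0], self.hill_coefficient[1] + 1, size=n_mc)
        spread = rng.uniform(*self.threshold_spread, size=n_mc)
        ratio = spread ** (-n.astype(float))
        return lam + (1.0 - lam) / (1.0 + ratio)

    def node_medians(self, network: RegulatoryNetwork, n_mc: int = 200_000) -> dict[str, float]:
        """Half-functional anchor level per node under ``threshold_rule``."""
        base = self.median_unregulated_level()
        if self.threshold_rule == "unregulated-median":
            return {n: base for n in network.dynamic_nodes}
        rng = np.random.default_rng(np.random.SeedSequence(180_451))  # fixed: a convention, not a model input
        g = rng.uniform(*self.production, size=n_mc)
        k = rng.uniform(*self.degradation, size=n_mc)
        out: dict[str, float] = {}
        for node in network.dynamic_nodes:
            level = g / k
            for e in network.incoming(node):
                level = level * self._hill_multiplier_draws(e.sign == ACTIVATION, n_mc, rng)
            out[node] = float(np.median(level))
        return out


DEFAULT_RANGES = SamplingRanges()


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------


@dataclass
class ParameterSample:
    """Array-backed collection of sampled kinetic parameter sets.

    Behaves like a sequence of :class:`KineticParameterSet` (for API and
    round-trip use) while keeping the kernel-ready arrays.
    """

    network: RegulatoryNetwork
    g: np.ndarray  # (n_sets, n_nodes)
    k: np.ndarray
    lam: np.ndarray  # (n_sets, n_edges)
    a0: np.ndarray
    nh: np.ndarray
    seed: int
    ranges: SamplingRanges = DEFAULT_RANGES

    def __len__(self) -> int:
        return self.g.shape[0]

    def __getitem__(self, i: int) -> KineticParameterSet:
        nodes = self.network.dynamic_nodes
        edges = self.network.edges
        return KineticParameterSet(
            {n: float(self.g[i, j]) for j, n in enumerate(nodes)},
            {n: float(self.k[i, j]) for j, n in enumerate(nodes)},
            {e.key: HillParams(float(self.lam[i, j]), float(self.a0[i, j]), int(self.nh[i, j])) for j, e in enumerate(edges)},
            provenance=f"sampled(seed={self.seed}, index={i})",
        )

    def compile(self, I_ext: float = 0.0) -> CompiledSystem:
        nodes = self.network.dynamic_nodes
        index = {n: i for i, n in enumerate(nodes)}
        esrc = np.array(
            [-1 if e.source == self.network.signal else index[e.source] for e in self.network.edges], dtype=np.int64
        )
        etgt = np.array([index[e.target] for e in self.network.edges], dtype=np.int64)
        sig = np.full(len(self), float(I_ext))
        return CompiledSystem(nodes, esrc, etgt, self.g, self.k, self.lam, self.a0, self.nh, sig)

    def scaled_production(self, target: str, factor: float) -> "ParameterSample":
        """Copy with the target node's production rates scaled (OE/DE)."""
        nodes = self.network.dynamic_nodes
        if target not in nodes:
            raise ConfigurationError(f"target {target!r} not in network {self.network.name!r}")
        g = self.g.copy()
        g[:, nodes.index(target)] *= factor
        return ParameterSample(self.network, g, self.k, self.lam, self.a0, self.nh, self.seed, self.ranges)


def sample_parameters(
    network: RegulatoryNetwork,
    ranges: SamplingRanges = DEFAULT_RANGES,
    n_sets: int = 10_000,
    seed: int = 0,
) -> ParameterSample:
    """Draw ``n_sets`` kinetic parameter sets for the topology.

    Activation fold-changes are uniform on the declared range; inhibition
    fold-changes are the reciprocal of such a draw (multipliers in
    [1/hi, 1]).  Thresholds follow the half-functional rule.  Reproducible
    given the seed.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = network.dynamic_nodes
    edges = network.edges
    n, m = len(nodes), len(edges)
    g = rng.uniform(*ranges.production, size=(n_sets, n))
    k = rng.uniform(*ranges.degradation, size=(n_sets, n))
    raw_fc = rng.uniform(*ranges.fold_change, size=(n_sets, m))
    is_act = np.array([e.sign == ACTIVATION for e in edges])
    lam = np.where(is_act[None, :], raw_fc, 1.0 / raw_fc)
    nh = rng.integers(ranges.hill_coefficient[0], ranges.hill_coefficient[1] + 1, size=(n_sets, m))
    medians = ranges.node_medians(network)
    source_median = np.array([medians[e.source] for e in edges])
    spread = rng.uniform(*ranges.threshold_spread, size=(n_sets, m))
    a0 = spread * source_median[None, :]
    return ParameterSample(network, g, k, lam, a0, nh.astype(np.int64), seed, ranges)


# ---------------------------------------------------------------------------
# Ensemble simulation
# ---------------------------------------------------------------------------


@dataclass
class EnsembleResult:
    """Distinct steady states across all sampled parameter sets.

    ``raw`` holds molecule levels (solutions × nodes); ``z`` holds
    log2-transformed levels z-scored with ``norm_mean``/``norm_sd`` —
    the statistics of the run itself for a control ensemble, or of the
    paired control run for a perturbation ensemble.
    """

    network_name: str
    raw: pd.DataFrame
    z: pd.DataFrame
    set_index: np.ndarray
    multistability: np.ndarray  # states per parameter set, aligned with rows
    norm_mean: pd.Series
    norm_sd: pd.Series
    seed: int
    n_sets: int
    n_inits: int
    converged_fraction: float
    replicate: int = 0

    @property
    def n_solutions(self) -> int:
        return len(self.raw)

    @property
    def set_weights(self) -> np.ndarray:
        """Per-solution weight 1/(states of its parameter set), so each
        sampled set — one *cell* of the ensemble — counts once in
        phenotype fractions regardless of its multistability."""
        return 1.0 / self.multistability

    def renormalised(self, mean: pd.Series, sd: pd.Series) -> "EnsembleResult":
        """Re-express the z matrix in another run's normalisation frame."""
        log2 = np.log2(np.maximum(self.raw.to_numpy(), _LOG_FLOOR))
        z = pd.DataFrame((log2 - mean.to_numpy()) / sd.to_numpy(), columns=self.raw.columns)
        return EnsembleResult(
            self.network_name, self.raw, z, self.set_index, self.multistability,
            mean, sd, self.seed, self.n_sets, self.n_inits, self.converged_fraction, self.replicate,
        )


def _initial_conditions(sample: ParameterSample, n_inits: int, rng: np.random.Generator) -> np.ndarray:
    """Log-uniform between 1 and each node's unregulated maximum scaled by
    the largest incoming activation fold-change, per parameter set."""
    network = sample.network
    nodes = network.dynamic_nodes
    boost = np.ones((len(sample), len(nodes)))
    for j, e in enumerate(network.edges):
        if e.source == network.signal:
            continue
        t = nodes.index(e.target)
        boost[:, t] = np.maximum(boost[:, t], sample.lam[:, j])
    caps = np.maximum(sample.g / sample.k * boost, 2.0)
    log_caps = np.log(caps)
    n_traj = len(sample) * n_inits
    u = rng.uniform(size=(n_traj, len(nodes)))
    model_of = np.repeat(np.arange(len(sample)), n_inits)
    return np.exp(u * log_caps[model_of]), model_of


def run_ensemble(
    network: RegulatoryNetwork,
    ranges: SamplingRanges = DEFAULT_RANGES,
    n_sets: int = 10_000,
    n_inits: int = 100,
    seed: int = 0,
    dt: float = 0.1,
    t_max: float = 1000.0,
    sample: ParameterSample | None = None,
    norm_stats: tuple[pd.Series, pd.Series] | None = None,
    replicate: int = 0,
    use_numba: bool | None = None,
) -> EnsembleResult:
    """Simulate the ensemble and collect distinct steady states.

    ``sample`` overrides fresh sampling (used by OE/DE perturbations);
    ``norm_stats`` imposes a control run's log2 mean/sd for the z matrix.
    Non-converged trajectories are excluded and reported via
    ``converged_fraction``.
    """
    if sample is None:
        sample = sample_parameters(network, ranges, n_sets, seed)
    else:
        n_sets = len(sample)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9173]))
    x0, model_of = _initial_conditions(sample, n_inits, rng)
    cs = sample.compile()
    xf, status = steady_state_batch(cs, x0, model_of, dt=dt, t_max=t_max, use_numba=use_numba)
    ok = status == CONVERGED
    converged_fraction = float(ok.mean())

    nodes = network.dynamic_nodes
    # distinct states per parameter set: bucket on log2 levels rounded to
    # 0.01 (≈0.7% relative), a tolerance matched to the dedup rule of the
    # deterministic path
    log2 = np.log2(np.maximum(xf[ok], _LOG_FLOOR))
    frame = pd.DataFrame(np.round(log2, 2), columns=[f"b_{n}" for n in nodes])
    frame["set"] = model_of[ok]
    keep = ~frame.duplicated()
    raw = pd.DataFrame(xf[ok][keep.to_numpy()], columns=list(nodes))
    set_index = model_of[ok][keep.to_numpy()]
    counts = pd.Series(set_index).value_counts()
    multistability = counts.reindex(set_index).to_numpy()

    log2_kept = np.log2(np.maximum(raw.to_numpy(), _LOG_FLOOR))
    if norm_stats is None:
        mean = pd.Series(log2_kept.mean(axis=0), index=raw.columns)
        sd = pd.Series(log2_kept.std(axis=0, ddof=0), index=raw.columns).replace(0.0, 1.0)
    else:
        mean, sd = norm_stats
    z = pd.DataFrame((log2_kept - mean.to_numpy()) / sd.to_numpy(), columns=raw.columns)
    return EnsembleResult(
        network.name, raw, z, set_index, multistability, mean, sd,
        seed, n_sets, n_inits, converged_fraction, replicate,
    )


# ---------------------------------------------------------------------------
# PCA summary
# ---------------------------------------------------------------------------


@dataclass
class PCASummary:
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # components × nodes
    coordinates: pd.DataFrame  # solutions × components
    dropped: tuple[str, ...] = ()


def pca_summary(result: EnsembleResult, n_components: int | None = None) -> PCASummary:
    """PCA of the z-normalised solution matrix (constant columns dropped)."""
    from sklearn.decomposition import PCA

    if result.n_solutions < 2:
        raise CircuitError("PCA needs at least two solutions")
    z = result.z
    variances = z.var(axis=0, ddof=0)
    dropped = tuple(variances.index[variances < 1e-12])
    if dropped:
        import warnings

        warnings.warn(f"dropping constant columns {dropped} before PCA")
        z = z.drop(columns=list(dropped))
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PCASummary(
        pca.explained_variance_ratio_,
        pd.DataFrame(pca.components_, index=comp_names, columns=z.columns),
        pd.DataFrame(coords, columns=comp_names),
        dropped,
    )


# ---------------------------------------------------------------------------
# Phenotype calling
# ---------------------------------------------------------------------------


def bimodal_threshold(values: np.ndarray, bw_method: str | float = "scott", n_grid: int = 512):
    """KDE local minimum between the two dominant modes of ``values``.

    Raises :class:`CircuitError` when the density has fewer than two
    modes (the bimodal classification scheme is then inapplicable).
    """
    values = np.asarray(values, dtype=float)
    kde = sstats.gaussian_kde(values, bw_method=bw_method)
    pad = 0.5 * values.std()
    grid = np.linspace(values.min() - pad, values.max() + pad, n_grid)
    dens = kde(grid)
    interior = np.arange(1, n_grid - 1)
    maxima = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    if len(maxima) < 2:
        raise CircuitError("distribution is unimodal; bimodal threshold undefined")
    top2 = sorted(sorted(maxima, key=lambda i: dens[i], reverse=True)[:2])
    lo, hi = top2
    between = np.arange(lo, hi + 1)
    cut = between[np.argmin(dens[between])]
    return float(grid[cut]), (float(grid[lo]), float(grid[hi]))


def _score(z: pd.DataFrame, plus: Sequence[str], minus: Sequence[str] = ()) -> pd.Series:
    missing = [n for n in (*plus, *minus) if n not in z.columns]
    if missing:
        raise ConfigurationError(f"score needs nodes {missing} absent from the ensemble")
    s = sum((z[n] for n in plus), pd.Series(0.0, index=z.index))
    for n in minus:
        s = s - z[n]
    return s


def call_phenotypes(
    result: EnsembleResult,
    scheme: str = "emt_bimodal",
    thresholds: Mapping[str, float] | None = None,
    hybrid_band: float = 0.25,
) -> pd.DataFrame:
    """Per-solution phenotype labels with the scores that produced them.

    ``emt_bimodal`` (the default): epithelial vs mesenchymal at the KDE
    minimum of the bimodal EMT score (z(ZEB) − z(miR200)); ELF3-high/low
    at the KDE minimum of z(ELF3) when ELF3 is in the circuit.

    ``emt_tertile``: three-way E/H/M by EMT-score tertiles.  This scheme
    is a convenience extra, not part of the published classification.

    ``er_pairs``: joint EMT (Epi/Hyb/Mes; hybrid = within ``hybrid_band``
    of the intermode distance around the midpoint of the two dominant
    EMT-score modes) and tamoxifen-resistance labels (resistant = high
    z(ERa36) − z(ERa66), thresholded at its bimodal KDE minimum).

    Precomputed ``thresholds`` (e.g. from a control run) override the KDE
    estimates; the thresholds used are recorded in ``df.attrs``.
    """
    z = result.z
    thresholds = dict(thresholds or {})
    out = pd.DataFrame(index=z.index)
    out["emt_score"] = _score(z, ["ZEB"], ["miR200"])

    used: dict[str, float] = {}

    def thr(name: str, series: pd.Series) -> float:
        if name in thresholds:
            used[name] = float(thresholds[name])
        else:
            used[name], _modes = bimodal_threshold(series.to_numpy())
        return used[name]

    if scheme == "emt_bimodal":
        t = thr("emt_score", out["emt_score"])
        out["phenotype"] = np.where(out["emt_score"] < t, "E", "M")
        if "GRHL2" in z.columns:
            out["epithelial_score"] = _score(z, ["GRHL2", "miR200"])
        if {"SNAIL", "SLUG"} <= set(z.columns):
            out["mesenchymal_score"] = _score(z, ["ZEB", "SNAIL", "SLUG"])
        if "ELF3" in z.columns:
            te = thr("ELF3", z["ELF3"])
            out["elf3_status"] = np.where(z["ELF3"] > te, "ELF3-high", "ELF3-low")
    elif scheme == "emt_tertile":
        q1, q2 = out["emt_score"].quantile([1 / 3, 2 / 3])
        used["emt_q1"], used["emt_q2"] = float(q1), float(q2)
        out["phenotype"] = np.where(out["emt_score"] < q1, "E", np.where(out["emt_score"] < q2, "H", "M"))
    elif scheme == "er_pairs":
        if "emt_modes" in thresholds and "emt_intermode" in thresholds:
            mid = float(thresholds["emt_modes"])
            d = float(thresholds["emt_intermode"])
            used["emt_modes"], used["emt_intermode"] = mid, d
        else:
            _t, (m1, m2) = bimodal_threshold(out["emt_score"].to_numpy())
            mid, d = 0.5 * (m1 + m2), m2 - m1
            used["emt_modes"], used["emt_intermode"] = mid, d
        lo, hi = mid - hybrid_band * d, mid + hybrid_band * d
        out["emt_call"] = np.where(out["emt_score"] < lo, "Epi", np.where(out["emt_score"] > hi, "Mes", "Hyb"))
        out["resistance_score"] = _score(z, ["ERa36"], ["ERa66"])
        tr = thr("resistance_score", out["resistance_score"])
        out["resistance_call"] = np.where(out["resistance_score"] > tr, "Res", "Sen")
        out["phenotype"] = out["emt_call"] + "-" + out["resistance_call"]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    out.attrs["thresholds"] = used
    out.attrs["scheme"] = scheme
    return out


def phenotype_fractions(
    calls: pd.DataFrame,
    labels: Sequence[str] | None = None,
    weights: np.ndarray | None = None,
) -> pd.Series:
    """Fraction of each phenotype label; ``weights`` (typically
    ``EnsembleResult.set_weights``) make fractions per parameter set
    rather than per solution row."""
    if weights is None:
        frac = calls["phenotype"].value_counts(normalize=True)
    else:
        w = pd.Series(np.asarray(weights, dtype=float), index=calls.index)
        frac = w.groupby(calls["phenotype"]).sum() / w.sum()
        frac = frac.sort_values(ascending=False)
    if labels is not None:
        frac = frac.reindex(labels, fill_value=0.0)
    frac.name = "fraction"
    return frac


# ---------------------------------------------------------------------------
# In-silico perturbation experiments
# ---------------------------------------------------------------------------


@dataclass
class PerturbationExperiment:
    """Phenotype fractions of an OE/DE experiment versus paired controls."""

    target: str
    mode: str  # "OE" | "DE"
    fold: float
    control_fractions: pd.DataFrame  # replicates × labels
    perturbed_fractions: pd.DataFrame
    p_values: pd.Series  # Welch t-test per label, perturbed vs control
    scheme: str = "emt_bimodal"

    @property
    def replicates(self) -> int:
        return len(self.control_fractions)

    def mean_fraction(self, label: str, perturbed: bool = True) -> float:
        df = self.perturbed_fractions if perturbed else self.control_fractions
        return float(df[label].mean())


def _replicate_seed(master: int, replicate: int) -> int:
    return int(np.random.SeedSequence([master, replicate]).generate_state(1)[0] % (2**31 - 1))


def perturb(
    network: RegulatoryNetwork,
    target: str,
    mode: str = "OE",
    fold: float = 20.0,
    ranges: SamplingRanges = DEFAULT_RANGES,
    n_sets: int = 10_000,
    n_inits: int = 100,
    n_replicates: int = 3,
    seed: int = 0,
    scheme: str = "emt_bimodal",
    controls: Sequence[EnsembleResult] | None = None,
    dt: float = 0.1,
    t_max: float = 1000.0,
    use_numba: bool | None = None,
) -> PerturbationExperiment:
    """Over/down-express ``target`` by ``fold`` across replicate ensembles.

    Each replicate draws fresh parameters from a seed derived from the
    master seed; the perturbed run reuses the replicate's control
    parameters with the target's production rate scaled, is z-normalised
    with the control statistics and classified at the control thresholds.
    Per-label Welch t-tests compare fractions across replicates.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1 (use mode='DE' for downregulation)")
    if mode not in ("OE", "DE"):
        raise ValueError("mode must be 'OE' or 'DE'")
    if target not in network.dynamic_nodes:
        raise ConfigurationError(f"target {target!r} not in network {network.name!r}")
    factor = float(fold) if mode == "OE" else 1.0 / float(fold)

    ctrl_rows, pert_rows = [], []
    for r in range(n_replicates):
        seed_r = _replicate_seed(seed, r)
        if controls is not None:
            control = controls[r]
            sample = sample_parameters(network, ranges, control.n_sets, control.seed)
        else:
            sample = sample_parameters(network, ranges, n_sets, seed_r)
            control = run_ensemble(
                network, ranges, n_inits=n_inits, seed=seed_r, sample=sample,
                dt=dt, t_max=t_max, replicate=r, use_numba=use_numba,
            )
        ctrl_calls = call_phenotypes(control, scheme=scheme)
        thresholds = ctrl_calls.attrs["thresholds"]
        pert = run_ensemble(
            network, ranges, n_inits=n_inits, seed=seed_r,
            sample=sample.scaled_production(target, factor),
            norm_stats=(control.norm_mean, control.norm_sd),
            dt=dt, t_max=t_max, replicate=r, use_numba=use_numba,
        )
        pert_calls = call_phenotypes(pert, scheme=scheme, thresholds=thresholds)
        ctrl_rows.append(phenotype_fractions(ctrl_calls, weights=control.set_weights))
        pert_rows.append(phenotype_fractions(pert_calls, weights=pert.set_weights))

    labels = sorted(set().union(*(r.index for r in ctrl_rows + pert_rows)))
    ctrl_df = pd.DataFrame([r.reindex(labels, fill_value=0.0) for r in ctrl_rows]).reset_index(drop=True)
    pert_df = pd.DataFrame([r.reindex(labels, fill_value=0.0) for r in pert_rows]).reset_index(drop=True)
    pvals = {}
    for lbl in labels:
        a, b = pert_df[lbl], ctrl_df[lbl]
        if np.allclose(a, b):
            pvals[lbl] = 1.0
        else:
            pvals[lbl] = float(sstats.ttest_ind(a, b, equal_var=False).pvalue)
    return PerturbationExperiment(target, mode, float(fold), ctrl_df, pert_df, pd.Series(pvals), scheme)


ER_LABELS = ("Epi-Res", "Epi-Sen", "Hyb-Res", "Hyb-Sen", "Mes-Res", "Mes-Sen")


def er_network_experiment(
    fold: float = 20.0,
    n_sets: int = 10_000,
    n_inits: int = 100,
    n_replicates: int = 3,
    seed: int = 0,
    dt: float = 0.1,
    t_max: float = 1000.0,
    use_numba: bool | None = None,
) -> pd.DataFrame:
    """ELF3 up/down-regulation in the ER+ breast-cancer circuit.

    Returns mean phenotype-pair fractions (labels × conditions
    control/OE/DE) with per-label OE/DE p-values in ``df.attrs``.
    """
    from .circuits import load_fixture

    network, _params = load_fixture("er_breast")
    kw = dict(
        ranges=DEFAULT_RANGES, n_sets=n_sets, n_inits=n_inits, n_replicates=n_replicates,
        seed=seed, scheme="er_pairs", dt=dt, t_max=t_max, use_numba=use_numba,
    )
    oe = perturb(network, "ELF3", mode="OE", fold=fold, **kw)
    de = perturb(network, "ELF3", mode="DE", fold=fold, **kw)
    labels = [l for l in ER_LABELS if l in oe.control_fractions.columns or l in de.perturbed_fractions.columns]
    table = pd.DataFrame(
        {
            "control": oe.control_fractions.reindex(columns=labels, fill_value=0.0).mean(),
            "ELF3-OE": oe.perturbed_fractions.reindex(columns=labels, fill_value=0.0).mean(),
            "ELF3-DE": de.perturbed_fractions.reindex(columns=labels, fill_value=0.0).mean(),
        }
    )
    table.attrs["p_values"] = {"ELF3-OE": oe.p_values.to_dict(), "ELF3-DE": de.p_values.to_dict()}
    return table
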