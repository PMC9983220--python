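# Methods

## Model class

Every species X (transcription factor, mRNA or microRNA) in a circuit
follows a chemical rate equation

    dX/dt = g_X · ∏_i H^S(A_i; A0_i, n_i, λ_i) − k_X · X

with basal production `g_X` (molecules per time unit), first-order
degradation `k_X` (1/time), and one shifted Hill function per incoming
regulation,

    H^S(A; A0, n, λ) = λ + (1 − λ) / (1 + (A/A0)^n).

`H^S` equals 1 in the absence of the regulator and saturates at the
fold-change λ (λ > 1 activation, λ < 1 inhibition). Multiple regulators
act multiplicatively on production. MicroRNA-mediated interactions (the
miR-200/ZEB mutual silencing) carry a `microRNA` mechanism tag but use
the same functional form by default; the tag exists so a dedicated
translational-repression form can be substituted without touching
topology declarations. The external EMT-inducing signal `Iext` is a
constant-level pseudo-node — it regulates its targets but carries no
equation — which is what makes it usable as a bifurcation parameter.
Units are molecules and inverse time throughout, on scales where a
saturating stimulus is of order 10^5 molecules; there is no unit
conversion layer.

## Circuits and provenance of the kinetic values

Five topologies ship as fixtures:

* `core_emt` — miR-200/ZEB toggle with ZEB self-activation, driven by
  SNAIL (itself driven by `Iext`), with the peripheral EMT-TFs SLUG
  (activated by SNAIL, mutually repressive with miR-200) and KLF4
  (repressed by SNAIL, repressing SLUG).
* `core_emt_elf3` — adds ELF3: self-activating, repressed by SNAIL and
  SLUG, repressing ZEB.
* `core_emt_elf3_wt1` — adds WT1: self-inhibitory, activating SNAIL,
  repressing SLUG.
* `core_emt_elf3_grhl2` — the ensemble topology: the ELF3 circuit
  without the external signal, plus GRHL2 in mutual inhibition with ZEB
  and activating ELF3.
* `er_breast` — ER+ breast-cancer context: miR-200/ZEB/SLUG/ELF3 plus
  the estrogen-receptor isoforms ERα66 (mutually repressive with ELF3,
  repressed by ZEB, repressing ERα36) and ERα36 (promoting ZEB).

The interaction signs follow the experimental literature summarised in
the circuit's source publications. The *numerical* kinetic values of the
deterministic fixtures are a reconstruction, not published constants:
they were calibrated once so that the circuits realise the documented
phenomenology — an epithelial → hybrid E/M → mesenchymal cascade of ZEB
against `Iext` with two overlapping bistable windows, a hybrid window
that shrinks by ≈35% when ELF3 is removed, an epithelial state that
survives to higher `Iext` with ELF3 than without, lower stable ZEB with
ELF3 everywhere, and full EMT at `Iext` = 100,000 molecules — and were
then frozen into the YAML fixtures (provenance tag
`reconstructed-calibrated`). Quantities that depend on fine properties
of the original, unpublished parameter set (notably the uniform ±10%
robustness of the hybrid window) should not be expected to transfer; see
Limitations.

## Deterministic numerics

* Default integrator: forward Euler with dt = 0.1 (the lineage
  convention); an adaptive LSODA path is available and the two are
  cross-checked in the tests. Euler steps clamp states at 0, which is
  exact in the limit dt → 0 because production is bounded and
  degradation is proportional to the level.
* Steady-state tolerance: max-norm of dX/dt below 10⁻⁶ × max(g).
* Duplicate steady states merged below 1% relative L∞ distance.
* Initial conditions for multi-start searches: log-uniform between 1
  and each node's maximum attainable level, g/k times the product of
  incoming activation fold-changes. (A single-fold-change cap misses
  the mesenchymal basin when self-activation and upstream activation
  combine.)
* Divergence ceiling 10⁶ × g_max/k_min; unreachable for intact Hill
  kinetics but guards pathological inputs.
* Saddle points between attractors are recovered by Newton polishing
  (scipy hybrd with restarts, Levenberg–Marquardt fallback) seeded at
  arithmetic and geometric midpoints of attractor pairs; a root is
  accepted by residual, not by the solver's progress flag, which trips
  on symmetric saddles. Stability is classified by the eigenvalues of a
  forward-difference Jacobian.

## Bifurcation analysis

Diagrams are built by a grid sweep (log-spaced control grid by default)
with the multi-start steady-state finder at every grid value, then
nearest-neighbour linking of states at adjacent grid values into
branches. Matching compares each candidate against a log-linear
extrapolation of the branch's last two points, with the prediction
capped at 2× per grid step; a relative mismatch above 0.45 starts a new
branch. The published-lineage branches sit ≥2.5× apart in readout while
along-branch steps steepen to ~40% just before a fold, which is why a
plain last-value comparison at a 20% tolerance fragments branches and
the extrapolated 0.45 rule is the default. Gap-split segments that
align under the same extrapolation rule are re-joined.

Phenotypes are assigned by branch ordering, never absolute thresholds:
with three stable branches the lowest median readout is epithelial (E),
the middle hybrid (H), the highest mesenchymal (M); two branches give
{E, M}; a lone monotone branch is labelled positionally. More than three
coexisting stable states is an error (outside the E/H/M vocabulary).

The hybrid window is the control-interval length on which an H-labelled
branch is stable. Its endpoints can be refined past the grid by
bisection on branch disappearance: integrate from the last branch state
at the trial control value and test whether the attractor stays within
the jump tolerance of the branch and remains stable.

Phase diagrams over two parameters are stacks of classified sweeps
along the x axis (commonly `Iext`), so cell labels inherit the
branch-ordering semantics; cells where the sweep left a gap fall back
to the nearest labelled branch. The sensitivity analysis perturbs every
continuous kinetic parameter (g, k, fold-changes, thresholds — Hill
coefficients are integers and excluded) by ±10% one at a time and
reports the percent change of the refined hybrid window.

## Random-parameter ensemble

Parameter sets are sampled from the established ranges of the
random-circuit-perturbation lineage: production uniform 1–100,
degradation uniform 0.1–1, fold-change uniform 1–100 (used as its
reciprocal for inhibitions), Hill coefficient integer-uniform 1–6.
Edge thresholds follow the half-functional rule: uniform in
[0.02, 1.98] × M(source), where M(source) is the median level of the
regulator *including its own regulation*. Because each incoming link of
the regulator is itself anchored at its source's median, the Hill
multiplier of a link evaluated at the half-functional point has a
universal distribution per sign, and M reduces to the median of
g/k × ∏(multiplier draws) — computed once by Monte Carlo with a fixed
internal seed. The simpler unregulated rule (M = median g/k for every
node) is available as `threshold_rule="unregulated-median"`; it starves
heavily repressed regulators (miR-200's outgoing thresholds become
unreachably high) and skews the ensemble mesenchymal.

Each parameter set is integrated from `n_inits` log-uniform initial
conditions by the batched Euler kernel (numba-compiled when available;
a vectorised numpy fallback is bit-compatible and cross-checked in the
tests). Non-converged trajectories are excluded and reported as a
converged fraction (>99.9% at the defaults). Distinct steady states per
set are collected by bucketing log2 levels at 0.01.

Steady states are log2-transformed and z-normalised per node; a
perturbation run is normalised with its paired control's statistics.
Phenotype calling uses the minimum of a Gaussian KDE (Scott bandwidth)
between the two dominant modes of the bimodal score distribution:
EMT score = z(ZEB) − z(miR200) for E vs M, z(ELF3) for ELF3-high/low.
A unimodal distribution raises an error rather than inventing a cut.
Phenotype *fractions* are per parameter set — each set is one cell of
the in-silico population, and a set with k coexisting states contributes
1/k per state — while the PCA and correlation analyses operate on the
full solution matrix. An optional tertile-based three-way E/H/M scheme
exists for exploration; it is not part of the published classification.

Overexpression (OE) multiplies the target's sampled production rates by
the fold; downexpression (DE) divides. Experiments run three replicates
by default, each with a fresh seed derived from the master seed and its
own paired control, and per-label fractions are compared by a two-tailed
Welch t-test. The ER+ scheme (`er_pairs`) crosses a three-way EMT call
(hybrid = within 0.25 of the intermode distance around the midpoint of
the two dominant EMT-score modes) with a resistance call thresholded on
z(ERα36) − z(ERα66) (high = tamoxifen-resistant).

## Transcriptomic scoring

* 76GS-style: per-gene weights are Pearson correlations with an
  epithelial anchor gene (CDH1 by default; explicit weights may be
  supplied instead), and the score is the weighted sum of row-centred
  expression. Higher = more epithelial; no predefined range.
* KS: per sample, the signed supremum distance between the empirical
  CDFs of the mesenchymal and epithelial signature genes, positive when
  the mesenchymal program dominates; bounded in [−1, 1], antisymmetric
  under signature swap. Ties are handled by right-continuous empirical
  CDFs; genes missing in a sample are dropped from that sample.
* ssGSEA-like: rank-weighted running-sum enrichment of one signature
  per sample (average ranks on ties). It is monotone in the signature
  genes' ranks and is used for synthetic-data testing; it does not claim
  numerical parity with any external enrichment tool.

Gene signatures are caller-supplied inputs; the package ships none.

## Synthetic data

`generate_cohort` plants the structure the scorers assume: an epithelial
and a mesenchymal gene block with a label-driven mean shift
(`effect_size`, in noise-SD units), a shared continuous latent factor
anti-correlating the blocks beyond the labels, Gaussian noise on the
log-expression scale, and background genes. `generate_timecourse`
plants piecewise-linear EMT induction with an optional MET recovery
(ELF3-like genes fall then recover; ZEB-like genes mirror them). Both
are seed-deterministic and return ground truth.

What the generators do *not* emulate: count-distribution noise,
batch/platform effects, gene–gene correlation beyond one latent axis,
or realistic signature sizes and overlaps. A green scorer test therefore
establishes correct mechanics (weighting, ranking, CDF handling,
orientation) and sane discrimination behaviour — not performance on any
real cohort.

## Known limitations

* The deterministic kinetic values are reconstructed, and fine-grained
  properties of the original parameter set do not all transfer: the
  hybrid window of the reconstruction is fragile under ±10% changes to
  several core ZEB parameters (fold positions sit on shallow response
  flanks and amplify perturbations), and the ensemble's PC1 explained
  variance (~61%) exceeds the reported value for the original topology.
* Hybrid E/M states are first-class in the bifurcation analysis but the
  default ensemble classification is binary E/M.
* No stochastic (Gillespie) simulation, delays, or spatial structure;
  topology is always declared, never inferred from data.
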