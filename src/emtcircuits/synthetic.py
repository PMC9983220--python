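"""Synthetic expression data with the structure the scoring stage assumes.

Real cohorts used in EMT scoring show two anti-correlated gene programs —
an epithelial block (CDH1, GRHL2, miR-200s, ...) and a mesenchymal block
(VIM, ZEB1, SNAI1/2, ...) — with samples distributed bimodally between
them, and EMT time courses show monotone induction with an optional
recovery (MET) phase.  The generators below plant exactly that structure
on a log-expression scale with Gaussian noise, returning ground-truth
labels/trends so scorer behaviour can be tested without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "TimeCourseSpec", "generate_cohort", "generate_timecourse"]

# canonical leading gene names keep fixtures realistic and give the 76GS
# scorer its CDH1 anchor
_EPI_SEED_GENES = ("CDH1", "GRHL2", "OVOL2", "EPCAM", "ELF3", "KLF4")
_MES_SEED_GENES = ("VIM", "ZEB1", "SNAI1", "SNAI2", "TWIST1", "FN1")


@dataclass(frozen=True)
class CohortSpec:
    """A two-phenotype bulk cohort on log-expression scale.

    ``effect_size`` is the epithelial-vs-mesenchymal mean shift of each
    block gene in units of ``noise_sd``; ``block_correlation`` sets the
    shared-latent-factor variance fraction that anti-correlates the two
    blocks beyond the label-driven shift.
    """

    n_samples: int = 200
    n_genes: int = 400
    n_epi_genes: int = 40
    n_mes_genes: int = 40
    effect_size: float = 3.0
    noise_sd: float = 1.0
    block_correlation: float = 0.4
    fraction_epithelial: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_epithelial <= 1.0:
            raise ValueError("fraction_epithelial must be in [0, 1]")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in [0, 1)")
        if min(self.n_samples, self.n_genes, self.n_epi_genes, self.n_mes_genes) < 1:
            raise ValueError("sizes must be positive")
        if self.n_epi_genes + self.n_mes_genes > self.n_genes:
            raise ValueError("signature blocks larger than the gene panel")


def _block_names(prefix: str, seeds: Sequence[str], n: int) -> list[str]:
    names = list(seeds[:n])
    names += [f"{prefix}{i:03d}" for i in range(1, n - len(names) + 1)]
    return names


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Draw a labelled cohort; returns (matrix, labels, signatures).

    ``matrix`` is genes × samples; ``labels`` maps sample id to "E"/"M";
    ``signatures`` holds the planted epithelial/mesenchymal gene lists.
    The spec (including the seed) is recorded in ``matrix.attrs``.
    """
    rng = np.random.default_rng(spec.seed)
    n_e = int(round(spec.fraction_epithelial * spec.n_samples))
    label = np.array(["E"] * n_e + ["M"] * (spec.n_samples - n_e))
    rng.shuffle(label)
    sign = np.where(label == "M", 1.0, -1.0)  # mesenchymal samples sit high in the M block

    epi_genes = _block_names("EPI", _EPI_SEED_GENES, spec.n_epi_genes)
    mes_genes = _block_names("MES", _MES_SEED_GENES, spec.n_mes_genes)
    n_bg = spec.n_genes - spec.n_epi_genes - spec.n_mes_genes
    bg_genes = [f"BG{i:04d}" for i in range(1, n_bg + 1)]

    latent = rng.standard_normal(spec.n_samples)  # continuous EMT axis within labels
    rho = spec.block_correlation
    shared = np.sqrt(rho) * latent
    resid = np.sqrt(1.0 - rho)

    half = 0.5 * spec.effect_size * spec.noise_sd
    rows = []
    for _ in epi_genes:
        rows.append(-half * sign - spec.noise_sd * shared + spec.noise_sd * resid * rng.standard_normal(spec.n_samples))
    for _ in mes_genes:
        rows.append(half * sign + spec.noise_sd * shared + spec.noise_sd * resid * rng.standard_normal(spec.n_samples))
    for _ in bg_genes:
        rows.append(spec.noise_sd * rng.standard_normal(spec.n_samples))

    samples = [f"S{i:04d}" for i in range(1, spec.n_samples + 1)]
    matrix = pd.DataFrame(np.array(rows), index=epi_genes + mes_genes + bg_genes, columns=samples)
    matrix.attrs["spec"] = spec
    labels = pd.Series(label, index=samples, name="phenotype")
    return matrix, labels, {"epithelial": epi_genes, "mesenchymal": mes_genes}


@dataclass(frozen=True)
class TimeCourseSpec:
    """An EMT-induction time course with an optional MET recovery phase.

    Between ``induction_window`` bounds the planted genes ramp linearly to
    ±``amplitude`` (ELF3-like genes fall on EMT, ZEB-like genes rise);
    during ``recovery_window`` they ramp back.  Windows must lie inside
    the time grid; an empty recovery window gives a monotone EMT course.
    """

    times: tuple[float, ...] = tuple(float(t) for t in range(0, 21, 2))
    induction_window: tuple[float, float] = (2.0, 10.0)
    recovery_window: tuple[float, float] = (14.0, 20.0)
    elf3_like: tuple[str, ...] = ("ELF3", "CDH1", "GRHL2", "miR200")
    zeb_like: tuple[str, ...] = ("ZEB1", "VIM", "SNAI1", "SNAI2")
    n_background: int = 30
    amplitude: float = 2.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        t0, t1 = min(self.times), max(self.times)
        for w in (self.induction_window, self.recovery_window):
            if w and not (t0 <= w[0] <= w[1] <= t1):
                raise ValueError(f"window {w} outside the time grid [{t0}, {t1}]")


def _ramp(t: np.ndarray, window: tuple[float, float], start: float, stop: float) -> np.ndarray:
    a, b = window
    if b <= a:
        return np.where(t >= a, float(stop), float(start))
    frac = np.clip((t - a) / (b - a), 0.0, 1.0)
    return start + (stop - start) * frac


def generate_timecourse(spec: TimeCourseSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the time course; returns (matrix, annotations).

    ``matrix`` is genes × time points (columns labelled ``t=<time>``);
    ``annotations`` records each planted gene's trend direction.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times, dtype=float)
    recovery = spec.recovery_window and spec.recovery_window[1] > spec.recovery_window[0]

    def mean_profile(direction: str) -> np.ndarray:
        peak = spec.amplitude if direction == "up_down" else -spec.amplitude
        prof = _ramp(t, spec.induction_window, 0.0, peak)
        if recovery:
            prof = np.where(t < spec.recovery_window[0], prof, _ramp(t, spec.recovery_window, peak, 0.0))
        return prof

    rows, names, meta = [], [], []
    for gene in spec.zeb_like:
        rows.append(mean_profile("up_down") + spec.noise_sd * rng.standard_normal(t.size))
        names.append(gene)
        meta.append((gene, "up_down"))
    for gene in spec.elf3_like:
        rows.append(mean_profile("down_up") + spec.noise_sd * rng.standard_normal(t.size))
        names.append(gene)
        meta.append((gene, "down_up"))
    for i in range(1, spec.n_background + 1):
        rows.append(spec.noise_sd * rng.standard_normal(t.size))
        names.append(f"BG{i:04d}")
        meta.append((f"BG{i:04d}", "flat"))

    cols = [f"t={tt:g}" for tt in t]
    matrix = pd.DataFrame(np.array(rows), index=names, columns=cols)
    matrix.attrs["spec"] = spec
    annotations = pd.DataFrame(meta, columns=["gene", "trend"]).set_index("gene")
    return matrix, annotations
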