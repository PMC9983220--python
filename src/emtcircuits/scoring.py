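"""Transcriptomic EMT scoring: 76GS-style, KS, and ssGSEA-like scores.

All scorers take a genes × samples expression matrix (``pandas.DataFrame``
with unique gene and sample identifiers) and gene signatures supplied by
the caller; none of them ships a hard-coded gene list.

* 76GS-style: weighted sum of centred expression over an epithelial gene
  list, each gene weighted by its correlation with an epithelial anchor
  gene (CDH1 by default).  Higher = more epithelial; unbounded.
* KS: signed supremum distance between the per-sample CDFs of the
  mesenchymal and epithelial signature genes, in [-1, 1]; positive =
  mesenchymal.
* ssGSEA-like: rank-based weighted running-sum enrichment of one
  signature per sample.  A pragmatic single-sample enrichment, not a
  parity implementation of any external tool.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circuits import CircuitError

__all__ = ["score_76gs", "score_ks", "score_ssgsea_like"]


class ScoringError(CircuitError):
    pass


def _present(matrix: pd.DataFrame, genes: Sequence[str], minimum: int, what: str) -> list[str]:
    found = [g for g in genes if g in matrix.index]
    if len(found) < minimum:
        raise ScoringError(f"{what}: only {len(found)} signature genes present (need >= {minimum})")
    return found


def score_76gs(
    matrix: pd.DataFrame,
    signature: Sequence[str],
    anchor: str = "CDH1",
    weights: Mapping[str, float] | None = None,
) -> pd.Series:
    """Weighted epithelial score per sample (higher = more epithelial).

    Weights default to each signature gene's Pearson correlation with the
    anchor gene across samples; genes with no variance get weight 0.  The
    score is the weighted sum of row-centred expression, so it has no
    predefined range and is invariant to per-gene offsets.
    """
    genes = _present(matrix, signature, 1, "76GS")
    sub = matrix.loc[genes].astype(float)
    if weights is None:
        if anchor not in matrix.index:
            raise ScoringError(f"anchor gene {anchor!r} absent and no weights supplied")
        anchor_expr = matrix.loc[anchor].astype(float)
        w = sub.T.corrwith(anchor_expr).fillna(0.0)
    else:
        w = pd.Series({g: float(weights.get(g, 0.0)) for g in genes})
    centred = sub.sub(sub.mean(axis=1), axis=0)
    score = centred.mul(w, axis=0).sum(axis=0)
    score.name = "score_76gs"
    return score


def _signed_ks(epi_vals: np.ndarray, mes_vals: np.ndarray) -> float:
    """sup|F_E - F_M| signed positive when mesenchymal genes dominate
    (their CDF lies to the right)."""
    grid = np.sort(np.concatenate([epi_vals, mes_vals]))
    f_e = np.searchsorted(np.sort(epi_vals), grid, side="right") / epi_vals.size
    f_m = np.searchsorted(np.sort(mes_vals), grid, side="right") / mes_vals.size
    d_plus = float(np.max(f_e - f_m))  # M shifted high -> F_M below F_E
    d_minus = float(np.max(f_m - f_e))
    return d_plus if d_plus >= d_minus else -d_minus


def score_ks(
    matrix: pd.DataFrame,
    epi_signature: Sequence[str],
    mes_signature: Sequence[str],
) -> pd.Series:
    """Signed KS score per sample in [-1, 1]; positive = mesenchymal.

    Genes with missing values in a sample are dropped from that sample's
    comparison.  Needs at least two genes of each signature in the matrix.
    """
    epi = _present(matrix, epi_signature, 2, "KS epithelial signature")
    mes = _present(matrix, mes_signature, 2, "KS mesenchymal signature")
    out = {}
    for sample in matrix.columns:
        ev = matrix.loc[epi, sample].dropna().to_numpy(dtype=float)
        mv = matrix.loc[mes, sample].dropna().to_numpy(dtype=float)
        if ev.size < 2 or mv.size < 2:
            raise ScoringError(f"sample {sample!r}: fewer than two non-missing genes in a signature")
        out[sample] = _signed_ks(ev, mv)
    score = pd.Series(out, name="score_ks")
    return score


def score_ssgsea_like(matrix: pd.DataFrame, signature: Sequence[str], exponent: float = 1.0) -> pd.Series:
    """Rank-weighted running-sum enrichment of ``signature`` per sample.

    Genes are ranked by expression (average ranks on ties; missing values
    dropped per sample); the hit increment at a gene is its rank weight
    ``rank**exponent``, the miss increment is uniform, and the score is
    the integrated difference of the two running sums, scaled by the
    number of ranked genes.  Monotone in the signature genes' ranks.
    """
    genes = _present(matrix, signature, 2, "enrichment signature")
    sig = set(genes)
    out = {}
    for sample in matrix.columns:
        col = matrix[sample].dropna().astype(float)
        n = col.size
        ranks = col.rank(method="average")  # 1 = lowest expression
        order = col.sort_values(ascending=False).index
        in_sig = np.array([g in sig for g in order])
        w = ranks.loc[order].to_numpy() ** exponent
        hit = np.where(in_sig, w, 0.0)
        denom_hit = hit.sum()
        if denom_hit == 0:
            raise ScoringError(f"sample {sample!r}: no signature gene ranked")
        p_hit = np.cumsum(hit) / denom_hit
        miss = np.where(~in_sig, 1.0, 0.0)
        p_miss = np.cumsum(miss) / max(miss.sum(), 1.0)
        out[sample] = float(np.sum(p_hit - p_miss) / n)
    score = pd.Series(out, name="score_ssgsea_like")
    return score
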