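"""Mitonuclear coadaptation vs decoupling of codon-usage landscapes.

A species' mitochondrial and nuclear compartments co-encode the OXPHOS
machinery, so their synonymous codon preferences may be coordinated
(coadapted) or evolve independently (decoupled).  We quantify concordance per
species over a shared codon set three ways:

* Pearson r and Spearman rho between the two RSCU vectors;
* a normalized mutual information |M| in [0, 1]: both vectors are
  discretized into equal-frequency bins by rank, plug-in mutual information
  is computed from the joint histogram, and normalized by the smaller
  marginal entropy (identical vectors attain exactly 1);
* a threshold classification on r: coadapted (r >= 0.7), decoupled
  (r < 0.2), intermediate otherwise.

The default shared set is the 59 degenerate standard-code sense codons
(excluding ATG, TGG and stops), so both compartments are compared on codons
that are synonymous choices in both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import RSCUProfile
from .genetic_code import load_genetic_code

__all__ = [
    "CoadaptationResult",
    "CoadaptationThresholds",
    "shared_codon_set",
    "compartment_correlation",
    "normalized_mutual_information",
    "classify_coadaptation",
    "coadaptation_table",
    "InsufficientOverlapError",
]


class InsufficientOverlapError(ValueError):
    """Fewer than the minimum shared codons with defined RSCU in both vectors."""


@dataclass(frozen=True)
class CoadaptationThresholds:
    r_coadapt: float = 0.7   # the conventional "high r" coadaptation bound
    r_decouple: float = 0.2  # our operationalization of "near 0"


@dataclass
class CoadaptationResult:
    species_id: str
    r_pearson: float
    rho_spearman: float
    m_norm: float
    n_codons_used: int
    class_label: str
    thresholds: CoadaptationThresholds = CoadaptationThresholds()


def shared_codon_set(mode: str = "paper_compat_59") -> list[str]:
    """Codon set over which the compartments are compared.

    ``paper_compat_59``: the 59 degenerate standard-code sense codons
    (sense minus ATG, TGG and stops).
    """
    code = load_genetic_code(1)
    if mode == "paper_compat_59":
        return sorted(c for c in code.degenerate_codons)
    raise ValueError(f"unknown shared codon set mode {mode!r}")


def _paired_vectors(
    rscu_mito: RSCUProfile | dict,
    rscu_nuc: RSCUProfile | dict,
    codon_set: list[str] | None,
    min_overlap: int = 10,
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    mito = rscu_mito.rscu if isinstance(rscu_mito, RSCUProfile) else rscu_mito
    nuc = rscu_nuc.rscu if isinstance(rscu_nuc, RSCUProfile) else rscu_nuc
    codons = codon_set if codon_set is not None else shared_codon_set()
    pairs = [(c, mito[c], nuc[c]) for c in codons if c in mito and c in nuc]
    dropped = len(codons) - len(pairs)
    if len(pairs) < min_overlap:
        raise InsufficientOverlapError(
            f"only {len(pairs)} shared codons with defined RSCU (< {min_overlap})"
        )
    labels = [p[0] for p in pairs]
    x = np.array([p[1] for p in pairs], dtype=float)
    y = np.array([p[2] for p in pairs], dtype=float)
    return x, y, labels, dropped


def compartment_correlation(
    rscu_mito: RSCUProfile | dict,
    rscu_nuc: RSCUProfile | dict,
    codon_set: list[str] | None = None,
) -> tuple[float, float]:
    """Pearson r and Spearman rho between compartment RSCU vectors.

    Codons whose family is unobserved in either compartment are
    pairwise-dropped; fewer than 10 shared codons raises
    :class:`InsufficientOverlapError`.
    """
    x, y, _, _ = _paired_vectors(rscu_mito, rscu_nuc, codon_set)
    r = stats.pearsonr(x, y).statistic
    rho = stats.spearmanr(x, y).statistic
    return float(r), float(rho)


def _rank_bins(values: np.ndarray, labels: list[str], bins: int) -> np.ndarray:
    """Equal-frequency binning by rank; ties broken by codon label order."""
    order = sorted(range(len(values)), key=lambda i: (values[i], labels[i]))
    out = np.empty(len(values), dtype=int)
    n = len(values)
    for rank, i in enumerate(order):
        out[i] = rank * bins // n
    return out


def normalized_mutual_information(
    rscu_mito: RSCUProfile | dict,
    rscu_nuc: RSCUProfile | dict,
    *,
    bins: int = 4,
    codon_set: list[str] | None = None,
) -> float:
    """Normalized mutual information |M| in [0, 1] between compartments.

    Each vector is discretized into ``bins`` equal-frequency bins over the
    shared codons (rank binning, ties broken by codon label so the statistic
    is deterministic), plug-in MI is computed from the joint bin histogram,
    and the result is normalized by the smaller marginal entropy.  Identical
    vectors give exactly 1.0; a degenerate vector (all values equal, zero
    entropy) gives 0.0.  Invariant to strictly monotone transforms of either
    vector.
    """
    x, y, labels, _ = _paired_vectors(rscu_mito, rscu_nuc, codon_set)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0  # degenerate binning: a constant vector carries no information
    bx = _rank_bins(x, labels, bins)
    by = _rank_bins(y, labels, bins)
    n = len(bx)
    joint = np.zeros((bins, bins))
    for i, j in zip(bx, by):
        joint[i, j] += 1
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    hx, hy = entropy(px), entropy(py)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum())
    h_min = min(hx, hy)
    if h_min == 0:
        return 0.0
    # clip tiny negative / >1 excursions from floating point
    return float(min(max(mi / h_min, 0.0), 1.0))


def classify_coadaptation(
    r: float,
    m_norm: float | None = None,
    thresholds: CoadaptationThresholds = CoadaptationThresholds(),
) -> str:
    """Threshold rule on Pearson r: coadapted / intermediate / decoupled.

    ``m_norm`` is reported alongside but does not enter the default rule.
    """
    if math.isnan(r):
        raise ValueError("r is undefined")
    if r >= thresholds.r_coadapt:
        return "coadapted"
    if r < thresholds.r_decouple:
        return "decoupled"
    return "intermediate"


def coadaptation_table(
    profiles: dict[str, tuple[RSCUProfile, RSCUProfile]],
    *,
    codon_set: list[str] | None = None,
    bins: int = 4,
    thresholds: CoadaptationThresholds = CoadaptationThresholds(),
) -> pd.DataFrame:
    """Per-species coadaptation summary from (mito, nuclear) RSCU profiles."""
    rows = []
    codons = codon_set if codon_set is not None else shared_codon_set()
    for species_id in sorted(profiles):
        mito, nuc = profiles[species_id]
        r, rho = compartment_correlation(mito, nuc, codons)
        m = normalized_mutual_information(mito, nuc, bins=bins, codon_set=codons)
        x, y, labels, _ = _paired_vectors(mito, nuc, codons)
        rows.append(
            {
                "species_id": species_id,
                "r_pearson": r,
                "rho_spearman": rho,
                "m_norm": m,
                "n_codons_used": len(labels),
                "class": classify_coadaptation(r, m, thresholds),
            }
        )
    return pd.DataFrame(rows)
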