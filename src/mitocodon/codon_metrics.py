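"""Per-unit codon-usage statistics.

The statistics here are the classical single-sequence measures of synonymous
codon-usage bias:

* **RSCU** — relative synonymous codon usage, the observed count of a codon
  divided by its expected count under equal use within its amino-acid family:
  ``RSCU_ij = X_ij * n_i / sum_j X_ij``.  RSCU = 1 means no bias; values >= 1.5
  are conventionally flagged as strong preference.
* **ENC** — Wright's (1990) effective number of codons, built from per-family
  codon homozygosity and averaged within degeneracy classes; 20 means one
  codon per amino acid under the standard code, 61 (the sense-codon count)
  means uniform synonymous use.  Degeneracy classes are derived from the
  active genetic code, so table 5 (with its 8-fold Ser family and 62 sense
  codons) is handled self-consistently.
* **CAI** — codon adaptation index, the geometric mean of relative
  adaptiveness weights ``w`` (codon frequency over the most frequent synonym
  in a reference set).
* Positional GC (GC1/GC2/GC3, GC12 = (GC1+GC2)/2, and GC3s restricted to
  synonymously variable codons) and coding-strand AT/GC skews.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

from .genetic_code import GeneticCode
from .sequence_io import CodingSequence

__all__ = [
    "CodonCountTable",
    "RSCUProfile",
    "GeneMetrics",
    "AdaptivenessWeights",
    "EncResult",
    "SkewPair",
    "PositionalGC",
    "count_codons",
    "merge_counts",
    "compute_rscu",
    "compute_enc",
    "positional_gc",
    "compute_skews",
    "reference_weights",
    "compute_cai",
    "gene_metrics",
    "STRONG_PREFERENCE_RSCU",
]

#: Conventional RSCU threshold above which a codon is called strongly preferred.
STRONG_PREFERENCE_RSCU = 1.5


@dataclass
class CodonCountTable:
    """Integer codon counts for one analysis unit (gene or concatenation).

    Stop-codon counts are tracked separately and never enter downstream
    metrics; codons containing N are tallied as ambiguous.
    """

    unit_id: str
    counts: dict[str, int]
    code: GeneticCode
    stop_counts: dict[str, int] = field(default_factory=dict)
    ambiguous: int = 0

    def __post_init__(self) -> None:
        for codon, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            if self.code.is_stop(codon):
                raise ValueError(f"stop codon {codon} in sense counts")

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def nucleotide_counts(self) -> Counter:
        c: Counter = Counter()
        for codon, n in {**self.counts, **self.stop_counts}.items():
            for base in codon:
                c[base] += n
        return c


def count_codons(cds: CodingSequence, *, unit_id: str | None = None) -> CodonCountTable:
    """Frame-0 triplet counts.  Codons containing N are excluded and tallied."""
    if len(cds.sequence) % 3 != 0:
        raise ValueError(
            f"{cds.gene}: length {len(cds.sequence)} is not a multiple of 3"
        )
    sense: dict[str, int] = {}
    stops: dict[str, int] = {}
    ambiguous = 0
    for codon in cds.codons:
        if "N" in codon:
            ambiguous += 1
        elif cds.code.is_stop(codon):
            stops[codon] = stops.get(codon, 0) + 1
        else:
            sense[codon] = sense.get(codon, 0) + 1
    return CodonCountTable(
        unit_id=unit_id or f"{cds.species_id}/{cds.compartment}/{cds.gene}",
        counts=sense,
        code=cds.code,
        stop_counts=stops,
        ambiguous=ambiguous,
    )


def merge_counts(tables: list[CodonCountTable], unit_id: str) -> CodonCountTable:
    """Sum codon counts over units sharing a genetic code (e.g. pooled 13 PCGs)."""
    if not tables:
        raise ValueError("no tables to merge")
    code = tables[0].code
    if any(t.code.table_id != code.table_id for t in tables):
        raise ValueError("cannot merge counts under different genetic codes")
    sense: Counter = Counter()
    stops: Counter = Counter()
    ambiguous = 0
    for t in tables:
        sense.update(t.counts)
        stops.update(t.stop_counts)
        ambiguous += t.ambiguous
    return CodonCountTable(unit_id, dict(sense), code, dict(stops), ambiguous)


# ---------------------------------------------------------------------------
# RSCU

@dataclass
class RSCUProfile:
    """RSCU values per codon; codons of unobserved families are *missing*
    (absent from the mapping), not zero."""

    unit_id: str
    rscu: dict[str, float]
    family_sizes: dict[str, int]
    code: GeneticCode

    def strongly_preferred(self, threshold: float = STRONG_PREFERENCE_RSCU) -> list[str]:
        return sorted(c for c, v in self.rscu.items() if v >= threshold)


def compute_rscu(counts: CodonCountTable) -> RSCUProfile:
    """RSCU_ij = X_ij * n_i / sum_j X_ij for every observed family."""
    rscu: dict[str, float] = {}
    fam_sizes: dict[str, int] = {}
    for aa, codons in counts.code.families.items():
        fam_sizes[aa] = len(codons)
        total = sum(counts.get(c) for c in codons)
        if total == 0:
            continue  # unobserved family -> missing
        n_i = len(codons)
        for c in codons:
            rscu[c] = counts.get(c) * n_i / total
    return RSCUProfile(counts.unit_id, rscu, fam_sizes, counts.code)


# ---------------------------------------------------------------------------
# ENC (Wright 1990)

class EncResult(NamedTuple):
    value: float
    low_confidence: bool
    imputed_classes: tuple[int, ...]
    floored_families: tuple[str, ...]
    capped: bool


def compute_enc(counts: CodonCountTable, *, details: bool = False):
    """Wright's effective number of codons, with code-aware degeneracy classes.

    Per observed family (n >= 2 codons) the codon homozygosity is
    ``F = (n * sum(p^2) - 1) / (n - 1)``; families with ``F <= 0`` are floored
    at ``1/k``.  F is averaged within each degeneracy class of the active
    code, and ``ENC = n_singleton_families + sum_k N_k / Fbar_k``.  A class
    with no observed family is imputed as the mean of the two adjacent class
    averages when both exist, else skipped with a low-confidence flag.  The
    result is capped at the code's sense-codon count.
    """
    code = counts.code
    class_families: dict[int, int] = {}  # degeneracy -> n families in code
    for aa, codons in code.families.items():
        class_families[len(codons)] = class_families.get(len(codons), 0) + 1

    f_by_class: dict[int, list[float]] = {}
    floored: list[str] = []
    any_degenerate = False
    for aa, codons in code.families.items():
        k = len(codons)
        if k < 2:
            continue
        n = sum(counts.get(c) for c in codons)
        if n < 2:
            continue
        any_degenerate = True
        sum_p2 = sum((counts.get(c) / n) ** 2 for c in codons)
        f_hat = (n * sum_p2 - 1) / (n - 1)
        if f_hat <= 0:
            f_hat = 1.0 / k
            floored.append(aa)
        f_by_class.setdefault(k, []).append(f_hat)

    if not any_degenerate:
        raise ValueError("ENC undefined: no degenerate family with >= 2 codons observed")

    degeneracies = sorted(k for k in class_families if k >= 2)
    class_means: dict[int, float] = {
        k: sum(v) / len(v) for k, v in f_by_class.items()
    }

    imputed: list[int] = []
    low_confidence = False
    enc = float(class_families.get(1, 0))
    for i, k in enumerate(degeneracies):
        fbar = class_means.get(k)
        if fbar is None:
            lower = class_means.get(degeneracies[i - 1]) if i > 0 else None
            upper = class_means.get(degeneracies[i + 1]) if i + 1 < len(degeneracies) else None
            if lower is not None and upper is not None:
                fbar = (lower + upper) / 2
                imputed.append(k)
            else:
                low_confidence = True
                continue
        enc += class_families[k] / fbar

    capped = enc > code.enc_max
    if capped:
        enc = float(code.enc_max)
    result = EncResult(enc, low_confidence, tuple(imputed), tuple(floored), capped)
    return result if details else result.value


# ---------------------------------------------------------------------------
# positional GC and skews

class PositionalGC(NamedTuple):
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float  # NaN when no degenerate codon observed


def positional_gc(cds: CodingSequence, *, exclude_aas: tuple[str, ...] = ()) -> PositionalGC:
    """GC fraction per codon position (over non-N bases) plus GC12 and GC3s.

    GC3s counts third-position G/C only over synonymously variable codons:
    stop codons and single-codon families of the active code are excluded,
    as are families of any amino acid listed in ``exclude_aas`` (e.g.
    ``("M", "W")`` for the CodonW-style variant).
    """
    gc = [0, 0, 0]
    tot = [0, 0, 0]
    gc3s_num = gc3s_den = 0
    for codon in cds.codons:
        for pos, base in enumerate(codon):
            if base == "N":
                continue
            tot[pos] += 1
            if base in "GC":
                gc[pos] += 1
        if "N" in codon or cds.code.is_stop(codon):
            continue
        aa = cds.code.translate_codon(codon)
        if cds.code.family_size(codon) >= 2 and aa not in exclude_aas:
            gc3s_den += 1
            if codon[2] in "GC":
                gc3s_num += 1
    if not all(tot):
        raise ValueError("no counted positions; cannot compute positional GC")
    gc1, gc2, gc3 = (g / t for g, t in zip(gc, tot))
    gc3s = gc3s_num / gc3s_den if gc3s_den else math.nan
    return PositionalGC(gc1, gc2, gc3, (gc1 + gc2) / 2, gc3s)


class SkewPair(NamedTuple):
    at_skew: float  # (A - T) / (A + T); NaN when A + T == 0
    gc_skew: float  # (G - C) / (G + C); NaN when G + C == 0


def compute_skews(source) -> SkewPair:
    """Coding-strand AT and GC skews from a sequence or a count table.

    Positive AT skew means A-enrichment over T; positive GC skew means
    G-enrichment over C.  An undefined skew (empty base pair) is NaN.
    """
    if isinstance(source, CodingSequence):
        bases = Counter(source.sequence)
    elif isinstance(source, CodonCountTable):
        bases = source.nucleotide_counts()
    elif isinstance(source, str):
        bases = Counter(source)
    else:
        raise TypeError(f"cannot compute skews from {type(source).__name__}")
    a, t, g, c = (bases.get(b, 0) for b in "ATGC")
    at = (a - t) / (a + t) if a + t else math.nan
    gc = (g - c) / (g + c) if g + c else math.nan
    return SkewPair(at, gc)


# ---------------------------------------------------------------------------
# CAI (Sharp & Li)

@dataclass
class AdaptivenessWeights:
    """Relative adaptiveness w per codon: frequency over the most frequent
    synonym in the reference set; within every family max w = 1."""

    weights: dict[str, float]
    reference_desc: str
    code: GeneticCode


def reference_weights(
    pooled: CodonCountTable,
    *,
    pseudo_count: float = 0.5,
    reference_desc: str | None = None,
) -> AdaptivenessWeights:
    """Relative adaptiveness from a reference count table (e.g. the pooled
    13 mitochondrial PCGs of the species itself).

    Zero counts within an observed family are replaced by ``pseudo_count``
    before the ratio-to-max, so unused codons get a small positive weight.
    Single-codon families get w = 1 but are excluded from CAI.  Families with
    no reference observation have undefined weights.
    """
    if pooled.total_codons == 0:
        raise ValueError("empty reference set")
    weights: dict[str, float] = {}
    for aa, codons in pooled.code.families.items():
        if len(codons) == 1:
            weights[codons[0]] = 1.0
            continue
        xs = {c: pooled.get(c) for c in codons}
        x_max = max(xs.values())
        if x_max == 0:
            continue  # unobserved family -> undefined
        for c, x in xs.items():
            weights[c] = (x if x > 0 else pseudo_count) / x_max
    return AdaptivenessWeights(
        weights,
        reference_desc or f"pooled:{pooled.unit_id}",
        pooled.code,
    )


def compute_cai(gene_counts: CodonCountTable, weights: AdaptivenessWeights) -> float:
    """Geometric-mean CAI over the gene's degenerate-family codons.

    ``CAI = exp((1/L) * sum(ln w))``, excluding stop codons, single-codon
    families, and codons without a defined reference weight.  Returns NaN if
    no eligible codon remains.
    """
    log_sum = 0.0
    length = 0
    code = gene_counts.code
    for codon, n in gene_counts.counts.items():
        if code.family_size(codon) < 2:
            continue
        w = weights.weights.get(codon)
        if w is None:
            continue
        log_sum += n * math.log(w)
        length += n
    if length == 0:
        return math.nan
    return math.exp(log_sum / length)


# ---------------------------------------------------------------------------
# convenience bundle

@dataclass
class GeneMetrics:
    """Per-unit summary used by the pipeline's tidy metric tables."""

    unit_id: str
    enc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float
    at_skew: float
    gc_skew: float
    gc_content: float
    at_content: float
    cai: float = math.nan
    n_codons: int = 0


def gene_metrics(
    cds: CodingSequence,
    *,
    weights: AdaptivenessWeights | None = None,
    unit_id: str | None = None,
) -> GeneMetrics:
    """Compute the full per-unit metric row for one CDS."""
    counts = count_codons(cds, unit_id=unit_id)
    pos = positional_gc(cds)
    skews = compute_skews(cds)
    bases = Counter(cds.sequence)
    acgt = sum(bases.get(b, 0) for b in "ACGT")
    gc_content = (bases.get("G", 0) + bases.get("C", 0)) / acgt if acgt else math.nan
    try:
        enc = compute_enc(counts)
    except ValueError:
        enc = math.nan
    cai = compute_cai(counts, weights) if weights is not None else math.nan
    return GeneMetrics(
        unit_id=counts.unit_id,
        enc=enc,
        gc1=pos.gc1,
        gc2=pos.gc2,
        gc3=pos.gc3,
        gc12=pos.gc12,
        gc3s=pos.gc3s,
        at_skew=skews.at_skew,
        gc_skew=skews.gc_skew,
        gc_content=gc_content,
        at_content=1 - gc_content if acgt else math.nan,
        cai=cai,
        n_codons=counts.total_codons,
    )
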