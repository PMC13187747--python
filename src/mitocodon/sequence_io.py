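"""Reading, quality control and concatenation of coding sequences.

Mitochondrial CDSs come from GenBank flat files (feature table, with
``/transl_table`` honoured and minus-strand features reverse-complemented into
coding orientation); nuclear CDS sets come from FASTA.  QC mirrors standard
mitogenome curation: internal stops, frameshifts and ambiguous sequences are
dropped, and trailing incomplete stop codons (the T/TA overhangs completed by
polyadenylation in invertebrate mitogenomes) are trimmed rather than rejected.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .genetic_code import GeneticCode, load_genetic_code

__all__ = [
    "CodingSequence",
    "QCPolicy",
    "SpeciesRecord",
    "RejectionLog",
    "CANONICAL_MITO_GENES",
    "read_genbank_cds",
    "read_fasta_cds",
    "qc_filter",
    "concatenate",
    "reverse_complement",
    "normalize_gene_name",
]

#: The 13 canonical mitochondrial protein-coding genes, in conventional order.
CANONICAL_MITO_GENES: tuple[str, ...] = (
    "ATP6", "ATP8", "COX1", "COX2", "COX3", "COB",
    "NAD1", "NAD2", "NAD3", "NAD4", "NAD4L", "NAD5", "NAD6",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CodingSequence:
    """One quality-controllable CDS in coding orientation."""

    species_id: str
    compartment: str  # "mito" | "nuclear"
    gene: str
    sequence: str
    code: GeneticCode

    def __post_init__(self) -> None:
        if self.compartment not in ("mito", "nuclear"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if not set(self.sequence) <= set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"sequence contains non-ACGTN symbols: {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codons(self) -> list[str]:
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


@dataclass(frozen=True)
class QCPolicy:
    """Filtering thresholds applied by :func:`qc_filter`.

    Defaults follow common mitogenome curation practice: drop CDSs with more
    than 1% ambiguous (N) sites, nuclear CDSs shorter than 150 nt, reject
    internal stops and frameshifts, and require 100 codons before a gene
    enters ENC analyses.
    """

    max_ambiguous_fraction: float = 0.01
    min_nuclear_length: int = 150
    min_codons_for_enc: int = 100
    reject_internal_stops: bool = True
    reject_frameshift: bool = True

    def __post_init__(self) -> None:
        if self.max_ambiguous_fraction <= 0:
            raise ValueError("max_ambiguous_fraction must be > 0")
        if self.min_nuclear_length <= 0 or self.min_codons_for_enc <= 0:
            raise ValueError("length thresholds must be > 0")


@dataclass
class SpeciesRecord:
    """All retained CDSs of one species, grouped by compartment."""

    species_id: str
    order_label: str
    mito_genes: list[CodingSequence] = field(default_factory=list)
    nuclear_genes: list[CodingSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.order_label:
            raise ValueError("order_label must be non-empty")

    def genes(self, compartment: str) -> list[CodingSequence]:
        return self.mito_genes if compartment == "mito" else self.nuclear_genes

    def concatenated(self, compartment: str) -> CodingSequence:
        return concatenate(self.genes(compartment), self.species_id, compartment)


@dataclass
class RejectionLog:
    """Per-CDS QC outcomes: rejections and trims, exportable as TSV."""

    entries: list[dict] = field(default_factory=list)

    def add(self, cds_id: str, rule: str, detail: str = "") -> None:
        self.entries.append({"id": cds_id, "rule": rule, "detail": detail})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["id", "rule", "detail"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene-name normalization

_GENE_SYNONYMS = {
    "COB": "COB", "CYTB": "COB", "CYB": "COB", "CYTOCHROMEB": "COB",
    "COX1": "COX1", "COI": "COX1", "CO1": "COX1", "COXI": "COX1",
    "COX2": "COX2", "COII": "COX2", "CO2": "COX2", "COXII": "COX2",
    "COX3": "COX3", "COIII": "COX3", "CO3": "COX3", "COXIII": "COX3",
    "ATP6": "ATP6", "ATPASE6": "ATP6", "ATP8": "ATP8", "ATPASE8": "ATP8",
    "NAD1": "NAD1", "ND1": "NAD1", "NADH1": "NAD1",
    "NAD2": "NAD2", "ND2": "NAD2", "NADH2": "NAD2",
    "NAD3": "NAD3", "ND3": "NAD3", "NADH3": "NAD3",
    "NAD4": "NAD4", "ND4": "NAD4", "NADH4": "NAD4",
    "NAD4L": "NAD4L", "ND4L": "NAD4L", "NADH4L": "NAD4L",
    "NAD5": "NAD5", "ND5": "NAD5", "NADH5": "NAD5",
    "NAD6": "NAD6", "ND6": "NAD6", "NADH6": "NAD6",
}

_PRODUCT_PATTERNS = [
    (re.compile(r"CYTOCHROME\s*C?\s*OXIDASE\s*(?:SUBUNIT)?\s*(I{1,3}|[123])"),
     lambda m: "COX" + str("I II III 1 2 3".split().index(m.group(1)) % 3 + 1)),
    (re.compile(r"CYTOCHROME\s*B"), lambda m: "COB"),
    (re.compile(r"NADH\s*DEHYDROGENASE\s*(?:SUBUNIT)?\s*(4L|[1-6])"),
     lambda m: "NAD" + m.group(1)),
    (re.compile(r"ATP\s*SYNTHASE\s*(?:F0\s*)?(?:SUBUNIT)?\s*([68])"),
     lambda m: "ATP" + m.group(1)),
]


def normalize_gene_name(raw: str) -> str:
    """Map a gene/product qualifier to one of the 13 canonical mito labels.

    Unrecognized names are returned cleaned-but-unmapped; callers keep such
    CDSs but exclude them from 13-PCG summaries.
    """
    token = re.sub(r"[^A-Z0-9]", "", raw.upper())
    if token in _GENE_SYNONYMS:
        return _GENE_SYNONYMS[token]
    spaced = raw.upper()
    for pattern, build in _PRODUCT_PATTERNS:
        m = pattern.search(spaced)
        if m:
            name = build(m)
            return _GENE_SYNONYMS.get(name, name)
    return token or raw


# ---------------------------------------------------------------------------
# readers

class FormatError(ValueError):
    """Input file failed to parse."""


class CoordinateError(ValueError):
    """A CDS feature's coordinates exceed the record's sequence."""


def read_genbank_cds(
    source,
    *,
    compartment: str = "mito",
    default_table: int = 5,
    species_id: str | None = None,
) -> list[CodingSequence]:
    """Extract CDS features from a GenBank flat file.

    Minus-strand features are reverse-complemented into coding orientation.
    ``/transl_table`` qualifiers always win; ``default_table`` (table 5,
    invertebrate mitochondrial) applies when absent.  Gene labels are
    normalized to the canonical 13-gene names where a synonym is recognized.

    ``source`` may be a path or a text string containing the record.
    """
    if isinstance(source, str) and "\nORIGIN" in source or (
        isinstance(source, str) and source.lstrip().startswith("LOCUS")
    ):
        handle = io.StringIO(source)
    else:
        handle = open(source)
    try:
        try:
            records = list(SeqIO.parse(handle, "genbank"))
        except Exception as exc:
            raise FormatError(f"could not parse GenBank input: {exc}") from exc
    finally:
        handle.close()
    if not records:
        raise FormatError("no GenBank records found")

    out: list[CodingSequence] = []
    for rec in records:
        sp = species_id or rec.annotations.get("organism") or rec.id
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if int(feat.location.end) > len(rec.seq):
                raise CoordinateError(
                    f"CDS {feat.location} exceeds sequence length {len(rec.seq)}"
                )
            seq = str(feat.extract(rec.seq)).upper().replace("U", "T")
            quals = feat.qualifiers
            raw_name = (quals.get("gene") or quals.get("product") or ["unknown"])[0]
            table = int(quals.get("transl_table", [default_table])[0])
            out.append(
                CodingSequence(
                    species_id=sp,
                    compartment=compartment,
                    gene=normalize_gene_name(raw_name),
                    sequence=re.sub(r"[^ACGTN]", "N", seq),
                    code=load_genetic_code(table),
                )
            )
    return out


def read_fasta_cds(
    source,
    *,
    compartment: str = "nuclear",
    default_table: int = 1,
    header_pattern: str = r"(?P<species>[^|]+)\|(?P<gene>\S+)",
    species_id: str | None = None,
) -> list[CodingSequence]:
    """Read CDSs from FASTA, one :class:`CodingSequence` per entry.

    Species and gene are parsed from the header with ``header_pattern``
    (named groups ``species`` and ``gene``); a header not matching the
    pattern falls back to its first whitespace token as the gene label.
    Lowercase input is uppercased and U is normalized to T.  Duplicate ids
    are suffixed ``.2``, ``.3``, ... with a warning.
    """
    if isinstance(source, str) and source.lstrip().startswith(">"):
        handle = io.StringIO(source)
    else:
        handle = open(source)
    pattern = re.compile(header_pattern)
    out: list[CodingSequence] = []
    seen: dict[str, int] = {}
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            header = rec.description or rec.id
            m = pattern.match(header)
            if m and "gene" in m.groupdict():
                gene = m.group("gene")
                sp = species_id or (m.groupdict().get("species") or rec.id)
            else:
                gene = header.split()[0]
                sp = species_id or "unknown"
            if gene in seen:
                seen[gene] += 1
                warnings.warn(f"duplicate CDS id {gene!r}; suffixing", stacklevel=2)
                gene = f"{gene}.{seen[gene]}"
            else:
                seen[gene] = 1
            seq = str(rec.seq).upper().replace("U", "T")
            out.append(
                CodingSequence(
                    species_id=sp,
                    compartment=compartment,
                    gene=gene,
                    sequence=re.sub(r"[^ACGTN]", "N", seq),
                    code=load_genetic_code(default_table),
                )
            )
    finally:
        handle.close()
    return out


# ---------------------------------------------------------------------------
# QC

def _trim_trailing_partial_stop(cds: CodingSequence) -> tuple[CodingSequence, bool]:
    """Trim a 1-2 nt incomplete stop overhang on mito genes (T or TA)."""
    overhang = len(cds.sequence) % 3
    if cds.compartment != "mito" or overhang == 0:
        return cds, False
    tail = cds.sequence[-overhang:]
    if tail in ("T", "TA"):
        return replace(cds, sequence=cds.sequence[:-overhang]), True
    return cds, False


def qc_filter(
    cds_list: Iterable[CodingSequence],
    policy: QCPolicy = QCPolicy(),
) -> tuple[list[CodingSequence], RejectionLog]:
    """Apply QC rules; returns (retained, log).  Filtering is total: no raise.

    Rules, in order: trailing incomplete stop codons are trimmed (logged, not
    rejected); then frameshift (length not divisible by 3), ambiguous-site
    fraction, nuclear minimum length, and internal stop codons reject.
    A complete terminal stop codon is retained in the sequence but ignored by
    the internal-stop test.
    """
    retained: list[CodingSequence] = []
    log = RejectionLog()
    for cds in cds_list:
        cid = f"{cds.species_id}/{cds.compartment}/{cds.gene}"
        cds, trimmed = _trim_trailing_partial_stop(cds)
        if trimmed:
            log.add(cid, "trimmed_partial_stop", "1-2 nt overhang removed")
        if policy.reject_frameshift and len(cds.sequence) % 3 != 0:
            log.add(cid, "frameshift", f"length {len(cds.sequence)} not multiple of 3")
            continue
        if len(cds.sequence) == 0:
            log.add(cid, "empty", "zero-length sequence")
            continue
        n_frac = cds.sequence.count("N") / len(cds.sequence)
        if n_frac > policy.max_ambiguous_fraction:
            log.add(cid, "ambiguous", f"N fraction {n_frac:.4f}")
            continue
        if cds.compartment == "nuclear" and len(cds.sequence) < policy.min_nuclear_length:
            log.add(cid, "min_length", f"{len(cds.sequence)} nt < {policy.min_nuclear_length}")
            continue
        if policy.reject_internal_stops:
            codons = cds.codons
            internal = codons[:-1] if codons and cds.code.is_stop(codons[-1]) else codons
            if any(cds.code.is_stop(c) for c in internal if "N" not in c):
                log.add(cid, "internal_stop", "stop codon before the final position")
                continue
        retained.append(cds)
    return retained, log


# ---------------------------------------------------------------------------
# concatenation

def _gene_sort_key(compartment: str):
    canon = {g: i for i, g in enumerate(CANONICAL_MITO_GENES)}
    if compartment == "mito":
        return lambda c: (canon.get(c.gene, len(canon)), c.gene)
    return lambda c: c.gene


def concatenate(
    records: Sequence[CodingSequence],
    species_id: str,
    compartment: str,
) -> CodingSequence:
    """In-order concatenation of one species'/compartment's CDSs.

    Gene order is deterministic: canonical 13-gene order for mito,
    lexicographic for nuclear.  Terminal stop codons are removed from each
    part so the concatenation is a clean codon sequence.
    """
    records = list(records)
    if not records:
        raise ValueError("nothing to concatenate")
    for cds in records:
        if cds.species_id != species_id or cds.compartment != compartment:
            raise ValueError(
                f"mixed species/compartment: {cds.species_id}/{cds.compartment} "
                f"vs {species_id}/{compartment}"
            )
        if len(cds.sequence) % 3 != 0:
            raise ValueError(f"{cds.gene}: length not a multiple of 3")
    ordered = sorted(records, key=_gene_sort_key(compartment))
    parts = []
    for cds in ordered:
        codons = cds.codons
        if codons and cds.code.is_stop(codons[-1]):
            codons = codons[:-1]
        parts.append("".join(codons))
    return CodingSequence(
        species_id=species_id,
        compartment=compartment,
        gene="concatenated",
        sequence="".join(parts),
        code=records[0].code,
    )
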