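"""NCBI genetic-code tables and synonymous-family structure.

Codon-usage statistics (RSCU families, ENC degeneracy classes, CAI weight
families, GC3s degeneracy) all depend on the genetic code in force.  Animal
mitogenomes are typically translated with NCBI table 5 (invertebrate
mitochondrial: TGA=Trp, ATA=Met, AGA/AGG=Ser), which changes the family
structure relative to the standard code — table 5 has 62 sense codons, an
8-fold serine family, and no single-codon families.  Everything downstream
therefore carries a :class:`GeneticCode` rather than assuming the standard
code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "UnsupportedCodeError",
    "load_genetic_code",
    "ALL_CODONS",
    "SUPPORTED_TABLES",
]

NUCLEOTIDES = "TCAG"
#: All 64 codons in TCAG ordering (the conventional codon-table layout).
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)

#: NCBI translation tables registered by default.  The registry is extensible:
#: any table known to Biopython can be added via :func:`register_table`.
SUPPORTED_TABLES: tuple[int, ...] = (1, 2, 5, 9, 13, 14)

STOP = "*"


class UnsupportedCodeError(KeyError):
    """Raised when a translation-table id is not in the registry."""


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table.

    Attributes
    ----------
    table_id:
        NCBI translation-table number (1 = standard, 5 = invertebrate mito).
    codon_to_aa:
        Mapping of every codon to a one-letter amino acid, or ``"*"`` for stop.
    start_codons:
        Codons annotated as initiation codons for this table.
    """

    table_id: int
    codon_to_aa: dict[str, str] = field(repr=False)
    start_codons: frozenset[str] = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("codon_to_aa must cover exactly the 64 codons")

    # -- derived structure ------------------------------------------------

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != STOP)

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous families: amino acid -> codons, in TCAG codon order."""
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = self.codon_to_aa[codon]
            if aa != STOP:
                fams.setdefault(aa, []).append(codon)
        return {aa: tuple(cods) for aa, cods in fams.items()}

    def family_of(self, codon: str) -> tuple[str, ...]:
        aa = self.codon_to_aa[codon]
        if aa == STOP:
            raise ValueError(f"{codon} is a stop codon under table {self.table_id}")
        return self.families[aa]

    def family_size(self, codon: str) -> int:
        return len(self.family_of(codon))

    @property
    def degenerate_codons(self) -> tuple[str, ...]:
        """Sense codons whose family has >= 2 synonyms."""
        return tuple(c for c in self.sense_codons if self.family_size(c) >= 2)

    @property
    def enc_max(self) -> int:
        """Upper cap for the effective number of codons: the sense-codon count
        (61 for the standard code, 62 for table 5)."""
        return len(self.sense_codons)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == STOP

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[codon]


_REGISTRY: dict[int, GeneticCode] = {}


def register_table(table_id: int) -> GeneticCode:
    """Add an NCBI table to the registry from Biopython's definitions."""
    try:
        bio = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:  # pragma: no cover - defensive
        raise UnsupportedCodeError(f"NCBI table {table_id} unknown") from exc
    mapping = {c: bio.forward_table.get(c, STOP) for c in ALL_CODONS}
    code = GeneticCode(
        table_id=table_id,
        codon_to_aa=mapping,
        start_codons=frozenset(bio.start_codons),
    )
    _REGISTRY[table_id] = code
    return code


@lru_cache(maxsize=None)
def load_genetic_code(table_id: int) -> GeneticCode:
    """Return the :class:`GeneticCode` for an NCBI translation-table id.

    Raises
    ------
    UnsupportedCodeError
        If ``table_id`` is not registered (default registry: tables
        1, 2, 5, 9, 13, 14).
    """
    if table_id in _REGISTRY:
        return _REGISTRY[table_id]
    if table_id in SUPPORTED_TABLES:
        return register_table(table_id)
    raise UnsupportedCodeError(
        f"translation table {table_id} not supported "
        f"(registered: {sorted(set(_REGISTRY) | set(SUPPORTED_TABLES))})"
    )
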