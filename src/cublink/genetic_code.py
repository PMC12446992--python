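"""Genetic-code bookkeeping: codon order, synonymous families, degeneracy classes.

Every downstream index (RSCU, ENC, SCUO, CAI, RCDI) is defined over synonymous
codon families, so this module is the single source of truth for which codons
encode which amino acid and how large each family is.  The table itself comes
from Biopython's standard code (NCBI translation table 1); for CDS-internal
codons the bacterial table (11) makes identical assignments, so one table
serves both organisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.Data import CodonTable

BASES = "ACGT"

#: All 64 codons in fixed alphabetical order; every count vector in the
#: package is indexed by this order.
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

CODON_INDEX: Mapping[str, int] = {c: i for i, c in enumerate(CODONS)}


@dataclass
class GeneticCode:
    """A genetic code with synonymous families and degeneracy classes.

    Attributes
    ----------
    name:
        Human-readable name of the source table.
    codon_to_aa:
        Mapping of the 61 sense codons to one-letter amino acids.
    stop_codons:
        The 3 stop codons.
    families:
        amino acid -> alphabetically sorted tuple of its synonymous codons.
    degeneracy:
        amino acid -> family size k in {1, 2, 3, 4, 6}.
    """

    name: str
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    families: dict[str, tuple[str, ...]] = field(init=False)
    degeneracy: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        fams: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            fams.setdefault(aa, []).append(codon)
        self.families = {aa: tuple(sorted(cs)) for aa, cs in sorted(fams.items())}
        self.degeneracy = {aa: len(cs) for aa, cs in self.families.items()}
        if len(self.codon_to_aa) != 61 or len(self.stop_codons) != 3:
            raise ValueError(
                f"expected 61 sense codons and 3 stops, got "
                f"{len(self.codon_to_aa)} and {len(self.stop_codons)}"
            )

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard genetic code (NCBI table 1)."""
        table = CodonTable.unambiguous_dna_by_id[1]
        sense = {c: aa for c, aa in table.forward_table.items() if set(c) <= set(BASES)}
        return cls(
            name="standard",
            codon_to_aa=dict(sorted(sense.items())),
            stop_codons=frozenset(table.stop_codons),
        )

    # -- derived codon sets ------------------------------------------------

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    @property
    def informative_codons(self) -> tuple[str, ...]:
        """Sense codons in families of size >= 2 (59 for the standard code).

        Met (ATG) and Trp (TGG) carry no synonymous choice and are excluded
        from all bias indices.
        """
        return tuple(
            c for c in self.sense_codons if self.degeneracy[self.codon_to_aa[c]] >= 2
        )

    @property
    def multi_families(self) -> dict[str, tuple[str, ...]]:
        """Families with at least two synonymous codons."""
        return {aa: cs for aa, cs in self.families.items() if len(cs) >= 2}

    @property
    def fourfold_families(self) -> dict[str, tuple[str, ...]]:
        """Strictly fourfold-degenerate families (Ala, Gly, Pro, Thr, Val).

        The fourfold boxes inside sixfold families (Leu, Ser, Arg) are NOT
        included: their usage also reflects the choice between boxes.
        """
        return {aa: cs for aa, cs in self.families.items() if len(cs) == 4}

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]


STANDARD_CODE = GeneticCode.standard()
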