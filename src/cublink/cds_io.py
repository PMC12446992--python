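"""CDS input: FASTA reading, quality control, codon counting, base composition.

QC enforces the minimal structural requirements for codon-level analysis:
length divisible by 3, no internal stop codon, no ambiguous base (in strict
mode), and a minimum number of codons.  A terminal stop codon is tolerated
and excluded from all counts; CDS dumps are inconsistent about including it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import BASES, CODON_INDEX, CODONS, GeneticCode, STANDARD_CODE

DEFAULT_MIN_CODONS = 30


@dataclass(frozen=True)
class CodingSequence:
    """One coding sequence; ``id`` is the FASTA header token before whitespace."""

    id: str
    seq: str

    @property
    def length_nt(self) -> int:
        return len(self.seq)

    def codons(self) -> list[str]:
        """Frame-0 codons, terminal stop (if any) excluded."""
        cods = [self.seq[i : i + 3] for i in range(0, len(self.seq) - len(self.seq) % 3, 3)]
        if cods and cods[-1] in STANDARD_CODE.stop_codons:
            cods = cods[:-1]
        return cods


@dataclass
class QCRecord:
    id: str
    status: str  # "pass" | "fail"
    reason: str  # "" when passing


@dataclass
class QCReport:
    records: list[QCRecord]

    @property
    def n_pass(self) -> int:
        return sum(r.status == "pass" for r in self.records)

    @property
    def n_fail(self) -> int:
        return sum(r.status == "fail" for r in self.records)

    def removals_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            if r.status == "fail":
                out[r.reason] = out.get(r.reason, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.id, r.status, r.reason) for r in self.records],
            columns=["id", "status", "reason"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class InputError(ValueError):
    """Fatal problem with an input file (unreadable, empty, duplicate ids)."""


def _check_sequence(
    seq: str, code: GeneticCode, min_codons: int, strict: bool
) -> str:
    """Return the failure reason for one sequence, or '' if it passes."""
    if len(seq) % 3 != 0:
        return "not a codon multiple"
    n_codons = len(seq) // 3
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    if strict and any(set(c) - set(BASES) for c in codons):
        return "ambiguous base"
    if any(c in code.stop_codons for c in codons):
        return "internal stop"
    if len(codons) < min_codons:
        return "too short"
    return ""


def qc_sequences(
    seqs: Iterable[CodingSequence],
    code: GeneticCode = STANDARD_CODE,
    min_codons: int = DEFAULT_MIN_CODONS,
    strict: bool = True,
) -> tuple[list[CodingSequence], QCReport]:
    """Filter sequences by the QC rules; order of retained sequences preserved."""
    kept: list[CodingSequence] = []
    records: list[QCRecord] = []
    seen: set[str] = set()
    for s in seqs:
        if not s.id:
            raise InputError("sequence with empty id")
        if s.id in seen:
            raise InputError(f"duplicate sequence id: {s.id!r}")
        seen.add(s.id)
        reason = _check_sequence(s.seq.upper(), code, min_codons, strict)
        if reason:
            records.append(QCRecord(s.id, "fail", reason))
        else:
            kept.append(CodingSequence(s.id, s.seq.upper()))
            records.append(QCRecord(s.id, "pass", ""))
    return kept, QCReport(records)


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read a (wrapped or unwrapped) multi-record FASTA file."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    seqs = [
        CodingSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise InputError(f"empty or non-FASTA file: {path}")
    return seqs


def read_and_qc(
    fasta_path: str | Path,
    code: GeneticCode = STANDARD_CODE,
    min_codons: int = DEFAULT_MIN_CODONS,
    strict: bool = True,
) -> tuple[list[CodingSequence], QCReport]:
    """Read a CDS FASTA and apply QC; see :func:`qc_sequences` for the rules."""
    return qc_sequences(read_fasta(fasta_path), code, min_codons, strict)


def write_fasta(seqs: Sequence[CodingSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# codon counting
# ---------------------------------------------------------------------------


@dataclass
class CodonCountTable:
    """Per-gene occurrence counts of all 64 codons (terminal stops excluded).

    ``counts[i, j]`` is the number of times codon ``CODONS[j]`` occurs in
    frame 0 of gene ``gene_ids[i]``.
    """

    gene_ids: tuple[str, ...]
    counts: np.ndarray  # (n_genes, 64) int64
    code: GeneticCode

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.gene_ids), 64):
            raise ValueError("counts must be genes x 64")
        if (self.counts < 0).any():
            raise ValueError("negative codon count")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.counts[self.gene_ids.index(gene_id)]

    def pooled(self) -> np.ndarray:
        """Summed counts over all genes (organism-level usage)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.gene_ids), columns=list(CODONS))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, code: GeneticCode = STANDARD_CODE) -> "CodonCountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index), df[list(CODONS)].to_numpy(), code)


def count_codons(
    seqs: Sequence[CodingSequence], code: GeneticCode = STANDARD_CODE
) -> CodonCountTable:
    """Count frame-0 codons per gene; codons with non-ACGT bases are skipped."""
    counts = np.zeros((len(seqs), 64), dtype=np.int64)
    for i, s in enumerate(seqs):
        idx = [CODON_INDEX[c] for c in s.codons() if c in CODON_INDEX]
        if idx:
            counts[i] = np.bincount(idx, minlength=64)
    return CodonCountTable(tuple(s.id for s in seqs), counts, code)


# ---------------------------------------------------------------------------
# base composition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaseComposition:
    """Positional G+C fractions and third-position base counts for one gene.

    ``a3 .. t3`` count third-position bases over all complete codons;
    ``a3_ff .. t3_ff`` restrict to codons of strictly fourfold-degenerate
    families, where the third base is fully synonymous (the PR2 default).
    """

    gc: float
    gc1: float
    gc2: float
    gc3: float
    a3: int
    c3: int
    g3: int
    t3: int
    a3_ff: int
    c3_ff: int
    g3_ff: int
    t3_ff: int
    n_codons: int


def base_composition(
    seq: CodingSequence | str, code: GeneticCode = STANDARD_CODE
) -> BaseComposition:
    """Positional composition over the gene's codons (terminal stop excluded)."""
    cs = seq if isinstance(seq, CodingSequence) else CodingSequence("_", seq.upper())
    codons = [c for c in cs.codons() if set(c) <= set(BASES)]
    if not codons:
        raise ValueError(f"no complete unambiguous codons in {cs.id!r}")
    pos_gc = [0, 0, 0]
    third = {b: 0 for b in BASES}
    third_ff = {b: 0 for b in BASES}
    fourfold = {c for cs4 in code.fourfold_families.values() for c in cs4}
    for codon in codons:
        for k, base in enumerate(codon):
            pos_gc[k] += base in "GC"
        third[codon[2]] += 1
        if codon in fourfold:
            third_ff[codon[2]] += 1
    n = len(codons)
    return BaseComposition(
        gc=sum(pos_gc) / (3 * n),
        gc1=pos_gc[0] / n,
        gc2=pos_gc[1] / n,
        gc3=pos_gc[2] / n,
        a3=third["A"],
        c3=third["C"],
        g3=third["G"],
        t3=third["T"],
        a3_ff=third_ff["A"],
        c3_ff=third_ff["C"],
        g3_ff=third_ff["G"],
        t3_ff=third_ff["T"],
        n_codons=n,
    )
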