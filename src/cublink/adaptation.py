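"""Host-adaptation indices: CAI, RCDI, and the organism-level similarity SiD.

All three compare codon usage against a host reference built from the host's
pooled CDS counts:

* CAI — geometric mean of relative-adaptiveness weights w_c (codon count over
  its family maximum in the reference); 1 means fully host-preferred usage.
* RCDI — count-weighted mean ratio of the gene's within-family codon
  frequencies to the host's; 1 means identical usage, larger means
  deoptimized relative to the host.
* SiD — (1 - cosine similarity) / 2 between two organism-level usage
  vectors; 0 = identical direction, 0.5 = orthogonal.

Zero reference counts get a 0.5 pseudocount so weights and frequencies stay
strictly positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cds_io import CodonCountTable
from .genetic_code import CODON_INDEX, GeneticCode, STANDARD_CODE
from .indices import genome_rscu

PSEUDOCOUNT = 0.5


def _informative_index(code: GeneticCode) -> list[int]:
    return [CODON_INDEX[c] for c in code.informative_codons]


@dataclass
class ReferenceWeights:
    """CAI relative-adaptiveness weights, one per sense codon (NaN for stops)."""

    w: np.ndarray  # (64,)
    code: GeneticCode
    source: str = "host"
    pseudocounted: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"codon": c, "amino_acid": self.code.codon_to_aa[c], "w": float(self.w[CODON_INDEX[c]])}
            for c in self.code.sense_codons
        ]
        return pd.DataFrame(rows)


@dataclass
class HostCodonFrequencies:
    """Within-family relative codon frequencies of the host (NaN for stops)."""

    cif: np.ndarray  # (64,)
    code: GeneticCode
    source: str = "host"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "amino_acid": self.code.codon_to_aa[c],
                "cif": float(self.cif[CODON_INDEX[c]]),
            }
            for c in self.code.sense_codons
        ]
        return pd.DataFrame(rows)


def cai_weights(
    host_counts: np.ndarray | CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    pseudocount: float = PSEUDOCOUNT,
) -> ReferenceWeights:
    """Relative adaptiveness w_c = x_c / max(x over family) from pooled host
    counts; zero counts are replaced by ``pseudocount`` first, so every w is
    strictly positive and the family maximum is exactly 1."""
    if isinstance(host_counts, CodonCountTable):
        host_counts = host_counts.pooled()
    x = np.asarray(host_counts, dtype=float).copy()
    if x.sum() <= 0:
        raise ValueError("empty host reference: all codon counts are zero")
    used_pseudo = False
    w = np.full(64, np.nan)
    for codons in code.families.values():
        idx = [CODON_INDEX[c] for c in codons]
        fam = x[idx]
        if (fam == 0).any():
            used_pseudo = True
            fam = np.where(fam == 0, pseudocount, fam)
        w[idx] = fam / fam.max()
    return ReferenceWeights(w, code, pseudocounted=used_pseudo)


def cai(
    gene_counts: np.ndarray,
    weights: ReferenceWeights,
) -> float:
    """Codon adaptation index of one gene: exp((1/L) * sum x_c ln w_c) over
    informative codons (Met, Trp, stops excluded).  NaN when the gene has no
    informative codon."""
    x = np.asarray(gene_counts, dtype=float)
    idx = _informative_index(weights.code)
    xi = x[idx]
    L = xi.sum()
    if L == 0:
        return float("nan")
    logw = np.log(weights.w[idx])
    return float(math.exp(np.dot(xi, logw) / L))


def host_frequencies(
    host_counts: np.ndarray | CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    pseudocount: float = PSEUDOCOUNT,
) -> HostCodonFrequencies:
    """Within-family relative frequencies CiF of the host, pseudocounted so
    every frequency is strictly positive."""
    if isinstance(host_counts, CodonCountTable):
        host_counts = host_counts.pooled()
    x = np.asarray(host_counts, dtype=float).copy()
    if x.sum() <= 0:
        raise ValueError("empty host reference: all codon counts are zero")
    cif = np.full(64, np.nan)
    for codons in code.families.values():
        idx = [CODON_INDEX[c] for c in codons]
        fam = np.where(x[idx] == 0, pseudocount, x[idx])
        cif[idx] = fam / fam.sum()
    return HostCodonFrequencies(cif, code)


def rcdi(gene_counts: np.ndarray, host: HostCodonFrequencies) -> float:
    """Relative codon deoptimization index of one gene.

    RCDI = (1/N) * sum_c (CiF_gene(c) / CiF_host(c)) * x_c over informative
    codons, where CiF_gene is the codon's within-family relative frequency in
    the gene and N the gene's informative codon total.  1 means the gene's
    within-family usage equals the host's.  NaN for an empty gene.
    """
    x = np.asarray(gene_counts, dtype=float)
    code = host.code
    total = 0.0
    n = 0.0
    for codons in code.multi_families.values():
        idx = [CODON_INDEX[c] for c in codons]
        fam = x[idx]
        fam_n = fam.sum()
        if fam_n == 0:
            continue
        cif_gene = fam / fam_n
        total += float(np.sum(cif_gene / host.cif[idx] * fam))
        n += fam_n
    if n == 0:
        return float("nan")
    return total / n


def sid(query_usage: np.ndarray, host_usage: np.ndarray) -> float:
    """Similarity index between two organism-level codon-usage vectors.

    SiD = (1 - R) / 2 with R the cosine similarity
    sum a_i b_i / sqrt(sum a_i^2 * sum b_i^2).  Entries undefined (NaN) in
    either vector are dropped pairwise.  0 = identical direction; 0.5 =
    orthogonal (maximal dissimilarity for nonnegative vectors).
    """
    a = np.asarray(query_usage, dtype=float)
    b = np.asarray(host_usage, dtype=float)
    if a.shape != b.shape:
        raise ValueError("usage vectors must share the same codon set")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if (a < 0).any() or (b < 0).any():
        raise ValueError("usage vectors must be nonnegative")
    na, nb = np.sqrt(np.sum(a**2)), np.sqrt(np.sum(b**2))
    if na == 0 or nb == 0:
        raise ValueError("all-zero usage vector")
    r = float(np.dot(a, b) / (na * nb))
    return (1 - r) / 2


def organism_usage(
    table: CodonCountTable, basis: str = "rscu"
) -> np.ndarray:
    """Organism-level usage vector over the informative codons, for SiD.

    ``basis='rscu'`` (default) uses pooled-count RSCU; ``basis='frequency'``
    uses raw codon frequencies among informative codons.
    """
    code = table.code
    idx = _informative_index(code)
    if basis == "rscu":
        return genome_rscu(table).values[idx]
    if basis == "frequency":
        pooled = table.pooled().astype(float)[idx]
        return pooled / pooled.sum()
    raise ValueError(f"unknown basis {basis!r} (expected 'rscu' or 'frequency')")


def adaptation_table(
    query_table: CodonCountTable,
    host_table: CodonCountTable,
) -> pd.DataFrame:
    """Per-gene CAI and RCDI of every query gene against the host reference."""
    weights = cai_weights(host_table)
    freqs = host_frequencies(host_table)
    rows = [
        {"gene_id": g, "cai": cai(x, weights), "rcdi": rcdi(x, freqs)}
        for g, x in zip(query_table.gene_ids, query_table.counts)
    ]
    return pd.DataFrame(rows).set_index("gene_id")
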