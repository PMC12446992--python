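"""Per-gene codon-usage-bias indices: RSCU, ENC, SCUO, PR2, and summaries.

Definitions
-----------
RSCU_c = x_c / ((1/k) * sum of counts over the codon's family), i.e. the
observed count over the expected count under uniform synonymous usage; values
of 1 mean no bias and family sums equal the family size k.

ENC (effective number of codons, Wright's Nc) is built from per-family
homozygosity F = (n * sum p_i^2 - 1) / (n - 1), averaged within degeneracy
classes; 20 means one codon per amino acid, 61 means uniform usage.

SCUO is the information-theoretic orderliness (1 - H/Hmax) per family,
weighted by family usage; 0 = uniform, 1 = single codon per family.

PR2 places a gene at (G3/(G3+C3), A3/(A3+T3)) over third positions of
fourfold-degenerate codons; (0.5, 0.5) means no strand/selection asymmetry.

Undefined values (empty families, zero denominators) are carried as NaN plus
explicit ``defined`` flags, never silently as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cds_io import BaseComposition, CodingSequence, CodonCountTable, base_composition, count_codons
from .genetic_code import CODON_INDEX, CODONS, GeneticCode, STANDARD_CODE

# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------


@dataclass
class RscuVector:
    """RSCU over the 64-codon order; NaN where the codon's family is unobserved
    or the codon is a stop.  ``informative_mask`` excludes single-codon
    families (Met, Trp) and stops."""

    values: np.ndarray  # (64,), NaN = undefined
    code: GeneticCode

    @property
    def informative_mask(self) -> np.ndarray:
        mask = np.zeros(64, dtype=bool)
        for c in self.code.informative_codons:
            mask[CODON_INDEX[c]] = True
        return mask

    def informative(self, codon_order: Sequence[str]) -> np.ndarray:
        """Values in a given informative-codon order (NaN kept for undefined)."""
        return np.array([self.values[CODON_INDEX[c]] for c in codon_order])

    def as_dict(self, include_undefined: bool = False) -> dict[str, float]:
        out = {}
        for c in self.code.sense_codons:
            v = self.values[CODON_INDEX[c]]
            if include_undefined or np.isfinite(v):
                out[c] = float(v)
        return out


def rscu(counts: np.ndarray, code: GeneticCode = STANDARD_CODE) -> RscuVector:
    """RSCU of one gene's (or a pooled) 64-codon count vector.

    Families with zero total count yield NaN entries (flagged undefined,
    never zero-filled).  Single-codon families get RSCU 1 when observed.
    """
    counts = np.asarray(counts)
    values = np.full(64, np.nan)
    for codons in code.families.values():
        idx = [CODON_INDEX[c] for c in codons]
        total = counts[idx].sum()
        if total > 0:
            values[idx] = counts[idx] * len(idx) / total
    return RscuVector(values, code)


def genome_rscu(table: CodonCountTable) -> RscuVector:
    """Organism-level RSCU from pooled counts over all genes."""
    return rscu(table.pooled(), table.code)


def genome_rscu_table(
    tables: dict[str, CodonCountTable], code: GeneticCode = STANDARD_CODE
) -> pd.DataFrame:
    """Side-by-side organism-level RSCU (amino acid, codon, one column per
    organism) in fixed family/codon order, the conventional layout for
    comparing preferred codons across species."""
    vecs = {name: genome_rscu(t) for name, t in tables.items()}
    rows = []
    for aa, codons in code.families.items():
        for c in codons:
            rows.append(
                {"amino_acid": aa, "codon": c}
                | {name: float(v.values[CODON_INDEX[c]]) for name, v in vecs.items()}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ENC
# ---------------------------------------------------------------------------


@dataclass
class EncValue:
    enc: float  # NaN when undefined
    family_means: dict[int, float]  # degeneracy class k -> mean homozygosity
    imputed_classes: tuple[int, ...]

    @property
    def defined(self) -> bool:
        return math.isfinite(self.enc)


def enc(counts: np.ndarray, code: GeneticCode = STANDARD_CODE) -> EncValue:
    """Wright's effective number of codons for one gene.

    Per family with n >= 2 codon occurrences, homozygosity
    F = (n * sum p_i^2 - 1) / (n - 1); F values <= 0 (possible at small n)
    are excluded.  Class means Fk are averaged over families of equal
    degeneracy; a missing k=3 class (Ile absent) is imputed as (F2 + F4) / 2.
    Nc = n_single + sum_k N_k / Fk, capped at 61.  Sixfold families count as
    single 6-fold classes.  If any class other than k=3 has no usable F the
    ENC is undefined (NaN).
    """
    counts = np.asarray(counts, dtype=float)
    f_by_class: dict[int, list[float]] = {}
    class_sizes: dict[int, int] = {}
    n_single = 0
    for codons in code.families.values():
        k = len(codons)
        if k == 1:
            n_single += 1
            continue
        class_sizes[k] = class_sizes.get(k, 0) + 1
        x = counts[[CODON_INDEX[c] for c in codons]]
        n = x.sum()
        if n < 2:
            continue
        p = x / n
        f = (n * np.sum(p**2) - 1) / (n - 1)
        if f > 0:
            f_by_class.setdefault(k, []).append(float(f))
    means = {k: float(np.mean(v)) for k, v in f_by_class.items()}
    imputed: tuple[int, ...] = ()
    if 3 in class_sizes and 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2
        imputed = (3,)
    if any(k not in means for k in class_sizes):
        return EncValue(float("nan"), means, imputed)
    nc = n_single + sum(nk / means[k] for k, nk in class_sizes.items())
    return EncValue(min(nc, 61.0), means, imputed)


def enc_expected_curve(gc3: float | np.ndarray) -> float | np.ndarray:
    """Expected ENC under mutation pressure alone at third-position G+C
    fraction ``gc3``: 2 + s + 29 / (s^2 + (1-s)^2)."""
    s = np.asarray(gc3, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("gc3 must be in [0, 1]")
    out = 2 + s + 29.0 / (s**2 + (1 - s) ** 2)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# SCUO
# ---------------------------------------------------------------------------


@dataclass
class ScuoValue:
    scuo: float  # NaN when no multi-codon family observed
    per_aa_orderliness: dict[str, float]

    @property
    def defined(self) -> bool:
        return math.isfinite(self.scuo)


def scuo(counts: np.ndarray, code: GeneticCode = STANDARD_CODE) -> ScuoValue:
    """Synonymous codon usage orderliness of one gene.

    For each amino acid with k >= 2 and n > 0: H = -sum p_i log2 p_i,
    O = (log2 k - H) / log2 k; SCUO is the usage-weighted mean of O.
    """
    counts = np.asarray(counts, dtype=float)
    per_aa: dict[str, float] = {}
    weights: dict[str, float] = {}
    for aa, codons in code.multi_families.items():
        x = counts[[CODON_INDEX[c] for c in codons]]
        n = x.sum()
        if n == 0:
            continue
        p = x[x > 0] / n
        h = float(-np.sum(p * np.log2(p)))
        hmax = math.log2(len(codons))
        per_aa[aa] = (hmax - h) / hmax
        weights[aa] = n
    if not per_aa:
        return ScuoValue(float("nan"), {})
    total = sum(weights.values())
    value = sum(weights[aa] / total * per_aa[aa] for aa in per_aa)
    return ScuoValue(float(value), per_aa)


# ---------------------------------------------------------------------------
# PR2
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pr2Point:
    x: float  # G3 / (G3 + C3); NaN when denominator is 0
    y: float  # A3 / (A3 + T3); NaN when denominator is 0
    quadrant: str  # top-left / top-right / bottom-left / bottom-right /
    #                boundary / undefined

    @property
    def defined(self) -> bool:
        return math.isfinite(self.x) and math.isfinite(self.y)


def _quadrant(x: float, y: float) -> str:
    if not (math.isfinite(x) and math.isfinite(y)):
        return "undefined"
    if x == 0.5 or y == 0.5:
        return "boundary"
    horiz = "right" if x > 0.5 else "left"
    vert = "top" if y > 0.5 else "bottom"
    return f"{vert}-{horiz}"


def pr2_point(comp: BaseComposition, fourfold_only: bool = True) -> Pr2Point:
    """PR2 plane coordinates for one gene.

    By default third positions are restricted to strictly fourfold-degenerate
    families, where the base choice is fully synonymous; ``fourfold_only=False``
    uses all third positions.  Exact 0.5 on either axis is labelled
    ``boundary`` and excluded from the four quadrant counts.
    """
    if fourfold_only:
        a, c, g, t = comp.a3_ff, comp.c3_ff, comp.g3_ff, comp.t3_ff
    else:
        a, c, g, t = comp.a3, comp.c3, comp.g3, comp.t3
    x = g / (g + c) if (g + c) > 0 else float("nan")
    y = a / (a + t) if (a + t) > 0 else float("nan")
    return Pr2Point(x, y, _quadrant(x, y))


# ---------------------------------------------------------------------------
# per-gene index table + summaries
# ---------------------------------------------------------------------------

INDEX_COLUMNS = ["gc", "gc1", "gc2", "gc3", "enc", "scuo", "pr2_x", "pr2_y"]


def gene_index_table(
    seqs: Sequence[CodingSequence],
    code: GeneticCode = STANDARD_CODE,
    pr2_fourfold_only: bool = True,
) -> pd.DataFrame:
    """Per-gene index table (one row per gene, NaN = undefined).

    Columns: n_codons, gc, gc1, gc2, gc3, enc, scuo, pr2_x, pr2_y,
    pr2_quadrant.  CAI/RCDI require a host reference and are added by
    :mod:`cublink.adaptation`.
    """
    table = count_codons(seqs, code)
    rows = []
    for seq, counts in zip(seqs, table.counts):
        comp = base_composition(seq, code)
        p = pr2_point(comp, pr2_fourfold_only)
        rows.append(
            {
                "gene_id": seq.id,
                "n_codons": comp.n_codons,
                "gc": comp.gc,
                "gc1": comp.gc1,
                "gc2": comp.gc2,
                "gc3": comp.gc3,
                "enc": enc(counts, code).enc,
                "scuo": scuo(counts, code).scuo,
                "pr2_x": p.x,
                "pr2_y": p.y,
                "pr2_quadrant": p.quadrant,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def pr2_quadrant_counts(df: pd.DataFrame) -> pd.Series:
    """Counts of genes per PR2 quadrant (boundary/undefined listed separately)."""
    order = ["top-left", "top-right", "bottom-left", "bottom-right", "boundary", "undefined"]
    counts = df["pr2_quadrant"].value_counts()
    return counts.reindex(order, fill_value=0)


def index_summary_and_correlations(
    df: pd.DataFrame, columns: Iterable[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Min/max/mean/median per index plus pairwise Pearson r and two-sided p.

    Correlations use genes where both indices are defined; pairs with fewer
    than 3 complete observations are flagged undefined (NaN).
    Returns (summary, r_matrix, p_matrix).
    """
    cols = [c for c in (columns or INDEX_COLUMNS) if c in df.columns]
    summary = df[cols].agg(["min", "max", "mean", "median", "count"]).T
    summary["n_undefined"] = len(df) - summary["count"].astype(int)
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        col = df[a].dropna()
        if len(col) >= 3 and col.nunique() >= 2:
            r.loc[a, a], p.loc[a, a] = 1.0, 0.0
        for b in cols[i + 1 :]:
            pair = df[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                continue
            res = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return summary, r, p
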