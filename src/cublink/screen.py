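"""Cross-species RSCU similarity screen.

Identifies query-organism genes whose per-gene RSCU vector is significantly
positively correlated with the partner organism's codon usage.  The default
("profile") mode correlates each query gene against the partner's
organism-level RSCU vector, yielding one test per query gene; "best-gene"
mode correlates against every partner gene and reports the best match.

Selection follows the conventional screen: Pearson r >= r_min (default 0.5)
and two-sided p < p_max (default 0.05) from t = r * sqrt((n-2)/(1-r^2)) with
n - 2 degrees of freedom, with NO multiple-testing correction by default
(Benjamini-Hochberg available via ``fdr='bh'``).

A caveat documented in docs/methods.md: RSCU entries within a synonymous
family are linearly constrained (they sum to the family size), so the
nominal t reference overstates the effective degrees of freedom and the
null p-values are somewhat anticonservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cds_io import CodonCountTable
from .genetic_code import GeneticCode, STANDARD_CODE
from .indices import genome_rscu, rscu

#: Fixed informative-codon order shared by every RSCU matrix (59 codons).
CODON_ORDER: tuple[str, ...] = STANDARD_CODE.informative_codons

DEFAULT_R_MIN = 0.5
DEFAULT_P_MAX = 0.05
MIN_CODONS_USED = 10


@dataclass
class RscuMatrix:
    """Genes x informative-codons RSCU matrix; NaN marks undefined entries
    (absent families), which are pairwise-deleted in correlations, never
    zero-filled."""

    gene_ids: tuple[str, ...]
    values: np.ndarray  # (n_genes, 59) float, NaN = undefined
    codon_order: tuple[str, ...] = CODON_ORDER
    excluded: list[tuple[str, float]] = field(default_factory=list)
    # (gene_id, undefined fraction) for genes dropped at build time

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.codon_order)):
            raise ValueError("values must be genes x len(codon_order)")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.codon_order)
        )


def build_rscu_matrix(
    table: CodonCountTable,
    max_undefined_fraction: float = 0.5,
) -> RscuMatrix:
    """Per-gene RSCU matrix over the fixed informative-codon order.

    Genes whose undefined fraction (codons of unobserved families) exceeds
    ``max_undefined_fraction`` are excluded and reported in ``excluded``.
    """
    if len(table) == 0:
        raise ValueError("empty codon count table")
    code = table.code
    rows, ids, excluded = [], [], []
    for gene_id, counts in zip(table.gene_ids, table.counts):
        vec = rscu(counts, code).informative(CODON_ORDER)
        frac_undef = float(np.mean(~np.isfinite(vec)))
        if frac_undef > max_undefined_fraction:
            excluded.append((gene_id, frac_undef))
        else:
            ids.append(gene_id)
            rows.append(vec)
    if not rows:
        raise ValueError("all genes excluded by max_undefined_fraction")
    return RscuMatrix(tuple(ids), np.array(rows), CODON_ORDER, excluded)


def organism_profile(table: CodonCountTable) -> np.ndarray:
    """Organism-level RSCU vector (pooled counts) in the fixed codon order."""
    return genome_rscu(table).informative(CODON_ORDER)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r and two-sided t-based p; returns (r, p, n)."""
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        return float("nan"), float("nan"), n
    xm, ym = x[mask], y[mask]
    xc, yc = xm - xm.mean(), ym - ym.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        return float("nan"), float("nan"), n
    r = float(np.clip(np.dot(xc, yc) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * float(stats.t.sf(abs(t), n - 2))
    return r, p, n


def screen_genes(
    query: RscuMatrix,
    partner: np.ndarray | RscuMatrix,
    mode: str = "profile",
    r_min: float = DEFAULT_R_MIN,
    p_max: float = DEFAULT_P_MAX,
    fdr: str | None = None,
    min_codons_used: int = MIN_CODONS_USED,
) -> pd.DataFrame:
    """Screen query genes for codon-usage similarity to the partner organism.

    Parameters
    ----------
    query:
        RSCU matrix of the screened organism.
    partner:
        Organism-level RSCU vector (mode='profile') or the partner's
        RSCU matrix (mode='best-gene').
    fdr:
        ``None`` (default, matching the conventional screen) or ``'bh'`` for
        Benjamini-Hochberg adjustment of the selection p-values.

    Returns
    -------
    DataFrame with columns gene_id, r, p, n_codons_used, selected (plus
    partner_id and p_adj where applicable), sorted by descending r with ties
    broken by gene id.  Genes with fewer than ``min_codons_used`` shared
    defined codons are flagged untestable (NaN r/p, never selected).
    """
    if mode not in ("profile", "best-gene"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    if mode == "profile":
        if isinstance(partner, RscuMatrix):
            raise ValueError(
                "profile mode needs an organism-level RSCU vector; "
                "use organism_profile() on the partner's counts"
            )
        profile = np.asarray(partner, dtype=float)
        if profile.shape != (len(query.codon_order),):
            raise ValueError("partner profile length must match codon_order")
        for gene_id, vec in zip(query.gene_ids, query.values):
            r, p, n = _pearson_with_p(vec, profile)
            rows.append({"gene_id": gene_id, "r": r, "p": p, "n_codons_used": n})
    else:
        if not isinstance(partner, RscuMatrix):
            raise ValueError("best-gene mode needs the partner RscuMatrix")
        if partner.codon_order != query.codon_order:
            raise ValueError("codon_order differs between organisms")
        for gene_id, vec in zip(query.gene_ids, query.values):
            best = (float("nan"), float("nan"), 0, "")
            for pid, pvec in zip(partner.gene_ids, partner.values):
                r, p, n = _pearson_with_p(vec, pvec)
                if np.isfinite(r) and (not np.isfinite(best[0]) or r > best[0]):
                    best = (r, p, n, pid)
            rows.append(
                {
                    "gene_id": gene_id,
                    "r": best[0],
                    "p": best[1],
                    "n_codons_used": best[2],
                    "partner_id": best[3],
                }
            )
    df = pd.DataFrame(rows)
    testable = df["n_codons_used"] >= min_codons_used
    df.loc[~testable, ["r", "p"]] = np.nan
    p_for_selection = df["p"].copy()
    if fdr == "bh":
        mask = df["p"].notna()
        adj = np.full(len(df), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
        df["p_adj"] = adj
        p_for_selection = df["p_adj"]
    elif fdr is not None:
        raise ValueError(f"unknown fdr method {fdr!r}")
    df["selected"] = (df["r"] >= r_min) & (p_for_selection < p_max) & testable
    df = df.sort_values(
        ["r", "gene_id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return df


def screen_summary(df: pd.DataFrame) -> dict:
    return {
        "n_genes": int(len(df)),
        "n_testable": int(df["r"].notna().sum()),
        "n_selected": int(df["selected"].sum()),
        "selected_fraction": float(df["selected"].mean()),
    }
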