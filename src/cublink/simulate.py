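"""Synthetic-data generation with known ground truth.

This module fabricates every input the pipeline consumes:

* two CDS collections whose per-amino-acid codon distributions follow
  controllable codon models, with a planted subset of query genes whose
  usage is mixed toward the partner organism's model at strength lambda
  (so "similarity" is continuous and recovery curves are meaningful);
* negative-binomial count matrices for the four-group, three-replicate
  study design, with genes planted on integer expression profiles;
* differential-expression call tables - either fabricated directly with
  exact planted overlaps (for testing the merge step), or derived from the
  simulated counts by two deliberately simple test recipes (a z-type test
  on log2 CPM and an exact rank test) so the merge sees realistic,
  partially overlapping inputs;
* Ct tables for 2^-ddCt with known true fold changes.

All randomness flows through one seeded generator per call; identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cds_io import CodingSequence
from .expression import DEFAULT_GROUPS
from .genetic_code import GeneticCode, STANDARD_CODE

# Average amino-acid composition of well-annotated proteomes (UniProt-style
# background); used to draw protein sequences.
AA_BACKGROUND = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}

STOP_CODON = "TAA"


# ---------------------------------------------------------------------------
# codon models
# ---------------------------------------------------------------------------


@dataclass
class CodonModel:
    """Per-amino-acid synonymous codon probabilities plus per-gene jitter.

    ``jitter`` is the Dirichlet concentration scale used when drawing a
    gene-specific deviation of the family probabilities: the gene's
    probabilities are Dirichlet(jitter * p + 0.05) distributed, so larger
    values mean genes hew closer to the organism model.
    """

    probs: dict[str, np.ndarray]  # aa -> probabilities over code.families[aa]
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)
    jitter: float = 60.0

    def __post_init__(self) -> None:
        for aa, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (len(self.code.families[aa]),) or (p < 0).any():
                raise ValueError(f"bad probability vector for {aa}")
            self.probs[aa] = p / p.sum()

    @classmethod
    def uniform(cls, code: GeneticCode = STANDARD_CODE, jitter: float = 60.0) -> "CodonModel":
        return cls(
            {aa: np.ones(len(cs)) / len(cs) for aa, cs in code.families.items()},
            code,
            jitter,
        )

    @classmethod
    def gc3_tilted(
        cls,
        beta: float,
        code: GeneticCode = STANDARD_CODE,
        concentration: float | None = None,
        seed: int | None = None,
        jitter: float = 60.0,
    ) -> "CodonModel":
        """Model with third-position G/C weighted by exp(beta), optionally
        multiplied by a seeded Dirichlet(concentration) family preference.

        beta < 0 emulates an A/T-ending-preferring organism, beta > 0 a
        G/C-leaning one; the Dirichlet factor adds family-specific structure
        beyond the GC tilt (real organisms prefer specific codons, not just
        an ending class).
        """
        rng = np.random.default_rng(seed)
        probs = {}
        for aa, codons in code.families.items():
            w = np.exp([beta * (c[2] in "GC") for c in codons])
            if concentration is not None:
                w = w * rng.dirichlet(np.full(len(codons), concentration))
            probs[aa] = w / w.sum()
        return cls(probs, code, jitter)

    def mixed_with(self, other: "CodonModel", lam: float) -> "CodonModel":
        """(1 - lam) * self + lam * other, family by family."""
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        probs = {
            aa: (1 - lam) * p + lam * other.probs[aa] for aa, p in self.probs.items()
        }
        return CodonModel(probs, self.code, self.jitter)


def plant_like_model(jitter: float = 60.0) -> CodonModel:
    """Default query-organism model: moderate A/T-ending preference with
    family-specific structure (seeded, fixed)."""
    return CodonModel.gc3_tilted(-0.5, concentration=8.0, seed=101, jitter=jitter)


def bacterium_like_model(jitter: float = 60.0) -> CodonModel:
    """Default partner-organism model: mild G/C lean with its own
    family-specific structure (seeded, fixed)."""
    return CodonModel.gc3_tilted(0.3, concentration=8.0, seed=202, jitter=jitter)


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class SimTruth:
    """Ground truth of one synthetic dataset."""

    seed: int
    lam: float = 0.0
    planted_similar: tuple[str, ...] = ()
    planted_profiles: dict[str, tuple[str, ...]] = field(default_factory=dict)
    planted_degs: dict[str, dict[str, tuple[str, ...]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=list)


# ---------------------------------------------------------------------------
# CDS generation
# ---------------------------------------------------------------------------


def generate_cds_set(
    model: CodonModel,
    n_genes: int,
    partner_model: CodonModel | None = None,
    n_planted: int = 0,
    lam: float = 0.0,
    median_codons: int = 300,
    length_sigma: float = 0.35,
    min_codons: int = 60,
    id_prefix: str = "GENE",
    seed: int = 0,
) -> tuple[list[CodingSequence], SimTruth]:
    """Generate a CDS collection with an optional planted similar subset.

    Every gene starts with ATG, ends with a stop, contains no internal stop
    and no ambiguous base, so the output passes strict QC with zero
    removals.  Lengths are log-normal (median ``median_codons`` codons).
    For the ``n_planted`` randomly chosen genes, codons are drawn from
    (1 - lam) * model + lam * partner_model; all genes get per-gene
    Dirichlet jitter around their model.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if n_planted > n_genes:
        raise ValueError("n_planted exceeds n_genes")
    if n_planted > 0 and partner_model is None:
        raise ValueError("planting requires a partner model")
    rng = np.random.default_rng(seed)
    code = model.code
    aas = sorted(AA_BACKGROUND)
    aa_p = np.array([AA_BACKGROUND[a] for a in aas])
    aa_p = aa_p / aa_p.sum()

    planted_idx = set(
        rng.choice(n_genes, size=n_planted, replace=False).tolist() if n_planted else []
    )
    mixed = model.mixed_with(partner_model, lam) if partner_model is not None else model

    width = max(5, len(str(n_genes)))
    seqs: list[CodingSequence] = []
    planted_ids: list[str] = []
    for i in range(n_genes):
        gene_model = mixed if i in planted_idx else model
        length = int(np.rint(np.exp(rng.normal(np.log(median_codons), length_sigma))))
        length = max(min_codons, length)
        aa_seq = rng.choice(aas, size=length - 1, p=aa_p)
        codons = np.empty(length - 1, dtype=object)
        for aa in np.unique(aa_seq):
            fam = code.families[aa]
            pos = np.flatnonzero(aa_seq == aa)
            p = gene_model.probs[aa]
            if len(fam) > 1:
                p = rng.dirichlet(gene_model.jitter * p + 0.05)
            codons[pos] = rng.choice(fam, size=len(pos), p=p)
        gene_id = f"{id_prefix}{i + 1:0{width}d}"
        seqs.append(CodingSequence(gene_id, "ATG" + "".join(codons) + STOP_CODON))
        if i in planted_idx:
            planted_ids.append(gene_id)
    truth = SimTruth(seed=seed, lam=lam, planted_similar=tuple(sorted(planted_ids)))
    return seqs, truth


# ---------------------------------------------------------------------------
# count matrices and DEG tables
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCounts:
    counts: pd.DataFrame  # genes x samples, integer
    groups: pd.Series  # sample -> group label
    deg_tables: dict[str, dict[str, pd.DataFrame]]  # contrast -> method -> table
    truth: SimTruth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def _ztest_table(
    logc: pd.DataFrame, group_samples: list[str], control_samples: list[str]
) -> pd.DataFrame:
    """Welch t-type test on log2(CPM + 1) per gene."""
    a = logc[group_samples].to_numpy()
    b = logc[control_samples].to_numpy()
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    return pd.DataFrame(
        {
            "gene_id": logc.index,
            "log2fc": lfc,
            "p": p,
            "p_adj": multipletests(p, method="fdr_bh")[1],
        }
    )


def _rank_table(
    logc: pd.DataFrame, group_samples: list[str], control_samples: list[str]
) -> pd.DataFrame:
    """Exact Mann-Whitney rank test per gene (conservative at few replicates)."""
    a = logc[group_samples].to_numpy()
    b = logc[control_samples].to_numpy()
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="exact")
    lfc = a.mean(axis=1) - b.mean(axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    return pd.DataFrame(
        {
            "gene_id": logc.index,
            "log2fc": lfc,
            "p": p,
            "p_adj": multipletests(p, method="fdr_bh")[1],
        }
    )


def simulate_counts(
    n_genes: int,
    planted: Mapping[tuple[int, ...], int] | None = None,
    effect: float = 2.0,
    dispersion: float = 0.1,
    baseline_mean: float = 100.0,
    groups: Sequence[str] = DEFAULT_GROUPS,
    n_reps: int = 3,
    seed: int = 0,
) -> SimulatedCounts:
    """Simulate the four-group count matrix with planted profile genes.

    ``planted`` maps an integer pattern over the ordered groups (first entry
    0) to the number of genes planted on it; a planted gene's group mean is
    mu_g * 2^(effect * pattern_t).  Counts are negative binomial with
    var = mu + dispersion * mu^2 and per-gene log-normal baselines around
    ``baseline_mean``.  For every non-baseline group two DEG tables
    (vs. the first group) are derived with the z-type and rank recipes.
    """
    if dispersion <= 0 or baseline_mean <= 0:
        raise ValueError("dispersion and baseline_mean must be positive")
    if n_reps < 2:
        raise ValueError("need >= 2 replicates per group for DEG fabrication")
    planted = dict(planted or {})
    T = len(groups)
    for pattern in planted:
        if len(pattern) != T or pattern[0] != 0:
            raise ValueError(f"pattern {pattern} must have length {T} and start at 0")
    n_planted_total = sum(planted.values())
    if n_planted_total > n_genes:
        raise ValueError("more planted genes than genes")

    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    order = rng.permutation(n_genes)

    patterns = np.zeros((n_genes, T))
    planted_map: dict[str, tuple[str, ...]] = {}
    start = 0
    for pattern, count in planted.items():
        idx = order[start : start + count]
        patterns[idx] = np.asarray(pattern, dtype=float)
        planted_map[",".join(map(str, pattern))] = tuple(
            sorted(gene_ids[i] for i in idx)
        )
        start += count

    mu0 = baseline_mean * np.exp(rng.normal(0.0, 0.6, size=n_genes))
    sample_ids = [f"{g}_r{r + 1}" for g in groups for r in range(n_reps)]
    group_of = pd.Series(
        [g for g in groups for _ in range(n_reps)], index=sample_ids, name="group"
    )
    mat = np.zeros((n_genes, len(sample_ids)), dtype=np.int64)
    for j, sample in enumerate(sample_ids):
        t = list(groups).index(group_of[sample])
        mu = mu0 * 2.0 ** (effect * patterns[:, t])
        mat[:, j] = _nb_draw(rng, mu, dispersion)
    counts = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)

    logc = np.log2(counts / counts.sum(axis=0) * 1e6 + 1)
    control_samples = [s for s in sample_ids if group_of[s] == groups[0]]
    deg_tables: dict[str, dict[str, pd.DataFrame]] = {}
    true_degs: dict[str, dict[str, tuple[str, ...]]] = {}
    for t, g in enumerate(groups[1:], start=1):
        gsamples = [s for s in sample_ids if group_of[s] == g]
        deg_tables[g] = {
            "ztest": _ztest_table(logc, gsamples, control_samples),
            "rank": _rank_table(logc, gsamples, control_samples),
        }
        true_degs[g] = {
            "up": tuple(sorted(np.array(gene_ids)[patterns[:, t] > 0])),
            "down": tuple(sorted(np.array(gene_ids)[patterns[:, t] < 0])),
        }
    truth = SimTruth(
        seed=seed, planted_profiles=planted_map, planted_degs=true_degs
    )
    return SimulatedCounts(counts, group_of, deg_tables, truth)


def simulate_deg_tables(
    n_genes: int = 1000,
    n_common_up: int = 25,
    n_common_down: int = 25,
    n_only_a: int = 10,
    n_only_b: int = 10,
    n_conflict: int = 0,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Fabricate two DEG tables with exact planted call structure.

    The first ``n_common_up`` genes are called up by both methods, the next
    ``n_common_down`` down by both, then blocks called by only one method,
    then genes called in opposite directions, and the rest not significant.
    Used to test the merge step against exact expected counts.
    """
    total = n_common_up + n_common_down + 2 * n_only_a + 2 * n_only_b + n_conflict
    if total > n_genes:
        raise ValueError("planted blocks exceed n_genes")
    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_genes)))
    gene_ids = [f"D{i + 1:0{width}d}" for i in range(n_genes)]

    def sig_p(n: int) -> np.ndarray:
        return rng.uniform(1e-8, alpha / 10, size=n)

    def ns_p(n: int) -> np.ndarray:
        return rng.uniform(2 * alpha, 1.0, size=n)

    def sig_lfc(n: int, sign: int) -> np.ndarray:
        return sign * rng.uniform(lfc_min, lfc_min + 2.0, size=n)

    def ns_lfc(n: int) -> np.ndarray:
        return rng.uniform(-lfc_min, lfc_min, size=n) * 0.5

    frames = []
    for which in ("a", "b"):
        p_adj = ns_p(n_genes)
        lfc = ns_lfc(n_genes)
        i = 0

        def fill(n: int, sign: int | None) -> None:
            nonlocal i
            if sign is None:
                p_adj[i : i + n] = ns_p(n)
                lfc[i : i + n] = ns_lfc(n)
            else:
                p_adj[i : i + n] = sig_p(n)
                lfc[i : i + n] = sig_lfc(n, sign)
            i += n

        fill(n_common_up, +1)
        fill(n_common_down, -1)
        fill(n_only_a, +1 if which == "a" else None)
        fill(n_only_a, -1 if which == "a" else None)
        fill(n_only_b, +1 if which == "b" else None)
        fill(n_only_b, -1 if which == "b" else None)
        fill(n_conflict, +1 if which == "a" else -1)
        frames.append(
            pd.DataFrame(
                {"gene_id": gene_ids, "log2fc": lfc, "p": p_adj, "p_adj": p_adj}
            )
        )
    k = n_common_up + n_common_down
    truth = SimTruth(
        seed=seed,
        planted_degs={
            "contrast": {
                "common_up": tuple(gene_ids[:n_common_up]),
                "common_down": tuple(gene_ids[n_common_up : k]),
                "conflict": tuple(
                    gene_ids[k + 2 * n_only_a + 2 * n_only_b : k + 2 * n_only_a + 2 * n_only_b + n_conflict]
                ),
            }
        },
    )
    return frames[0], frames[1], truth


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


def simulate_ct_table(
    fold_truth: Mapping[str, Mapping[str, float]],
    groups: Sequence[str] = DEFAULT_GROUPS,
    control_group: str = "Control",
    n_reps: int = 3,
    reference_gene: str = "GAPDH",
    reference_ct: float = 18.0,
    base_dct: float = 6.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table whose 2^-ddCt folds match ``fold_truth[gene][group]``.

    The control group's true fold is fixed at 1.  With ``noise_sd`` 0 the
    recovered folds are exact, which is how worked examples are generated.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        for r in range(n_reps):
            sample = f"{g}_r{r + 1}"
            ref = reference_ct + rng.normal(0.0, noise_sd)
            rows.append({"sample": sample, "group": g, "gene": reference_gene, "ct": ref})
            for gene, per_group in fold_truth.items():
                fold = 1.0 if g == control_group else float(per_group.get(g, 1.0))
                dct = base_dct - np.log2(fold) + rng.normal(0.0, noise_sd)
                rows.append(
                    {"sample": sample, "group": g, "gene": gene, "ct": ref + dct}
                )
    return pd.DataFrame(rows)
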