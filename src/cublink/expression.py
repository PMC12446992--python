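"""Expression-response stage: DEG-set merging, model-profile clustering with
an exact permutation null, and 2^-ddCt relative quantification.

The study design behind this module is four ordered treatment groups
(Control, Bacterium, Calcium, Calcium+Bacterium) with replicated RNA-seq
counts.  Differential-expression fitting itself is out of scope: two
independent DE tools produce tabular calls, and this module owns the
threshold semantics and the intersection ("common genes") step.

Profile clustering follows the short-series model-profile approach: all
integer templates of length T starting at 0 with bounded per-step change are
enumerated, a well-spread subset of m is chosen greedily by correlation
distance, every gene is assigned to its best-correlated profile, and profile
sizes are tested against the exact T! permutation null of each gene's
response vector (T=4 gives 24 permutations, so the null is enumerated, not
sampled).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_GROUPS = ("Control", "LZ04", "CaCl2", "CaCl2+LZ04")
DEFAULT_ALPHA = 0.05
DEFAULT_LFC_MIN = 1.0


# ---------------------------------------------------------------------------
# DEG tables and merging
# ---------------------------------------------------------------------------


def call_directions(
    deg: pd.DataFrame, alpha: float = DEFAULT_ALPHA, lfc_min: float = DEFAULT_LFC_MIN
) -> pd.DataFrame:
    """Add a ``direction`` column (up / down / ns) to a DEG table.

    up: log2fc > 0, p_adj < alpha and |log2fc| >= lfc_min; down symmetric.
    The fold-change rule interprets "fold change > 1" on the log2 scale
    (|log2FC| >= 1 by default), since a raw-fold threshold of 1 would be
    vacuous.
    """
    required = {"gene_id", "log2fc", "p_adj"}
    missing = required - set(deg.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    out = deg.copy()
    sig = (out["p_adj"] < alpha) & (out["log2fc"].abs() >= lfc_min)
    out["direction"] = "ns"
    out.loc[sig & (out["log2fc"] > 0), "direction"] = "up"
    out.loc[sig & (out["log2fc"] < 0), "direction"] = "down"
    return out


@dataclass
class MergedDegs:
    """Intersection of two methods' DEG calls for one contrast."""

    common_up: tuple[str, ...]
    common_down: tuple[str, ...]
    conflicts: tuple[str, ...]  # called in opposite directions by the two methods

    @property
    def n_up(self) -> int:
        return len(self.common_up)

    @property
    def n_down(self) -> int:
        return len(self.common_down)


def merge_degs(
    a: pd.DataFrame,
    b: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> MergedDegs:
    """Merge two methods' DEG calls: common up = up(a) & up(b), common down
    symmetric; genes called in opposite directions are excluded and reported.

    Symmetric in its arguments.  Raises if the two gene universes do not
    overlap at all.
    """
    da = call_directions(a, alpha, lfc_min)
    db = call_directions(b, alpha, lfc_min)
    if not (set(da["gene_id"]) & set(db["gene_id"])):
        raise ValueError("DEG tables share no genes")
    dir_a = dict(zip(da["gene_id"], da["direction"]))
    dir_b = dict(zip(db["gene_id"], db["direction"]))
    up = {g for g, d in dir_a.items() if d == "up" and dir_b.get(g) == "up"}
    down = {g for g, d in dir_a.items() if d == "down" and dir_b.get(g) == "down"}
    conflict = {
        g
        for g, d in dir_a.items()
        if d in ("up", "down")
        and dir_b.get(g) in ("up", "down")
        and dir_b[g] != d
    }
    return MergedDegs(tuple(sorted(up)), tuple(sorted(down)), tuple(sorted(conflict)))


# ---------------------------------------------------------------------------
# model profiles
# ---------------------------------------------------------------------------


@dataclass
class ProfileModel:
    """One integer model profile over the ordered groups (pattern[0] = 0)."""

    profile_id: int
    pattern: tuple[int, ...]
    n_assigned: int = 0
    expected: float = float("nan")  # expected assigned count under the null
    p_value: float = float("nan")  # Bonferroni-adjusted
    significant: bool = False
    assigned_genes: tuple[str, ...] = field(default_factory=tuple)


def candidate_profiles(T: int, c: int) -> list[tuple[int, ...]]:
    """All integer profiles of length T starting at 0 with per-step change in
    [-c, c]; there are (2c+1)**(T-1) of them."""
    if T < 3 or c < 1:
        raise ValueError("need T >= 3 and c >= 1")
    out = []
    for steps in itertools.product(range(-c, c + 1), repeat=T - 1):
        pat = [0]
        for s in steps:
            pat.append(pat[-1] + s)
        out.append(tuple(pat))
    return sorted(out)


def _pattern_corr(p: Sequence[int | float], q: Sequence[int | float]) -> float:
    """Pearson r between two patterns; 0 if either is flat (so distance 1)."""
    a = np.asarray(p, dtype=float)
    b = np.asarray(q, dtype=float)
    ac, bc = a - a.mean(), b - b.mean()
    denom = math.sqrt(float(np.sum(ac**2) * np.sum(bc**2)))
    if denom == 0:
        return 0.0
    return float(np.dot(ac, bc) / denom)


def stem_profiles(T: int = 4, c: int = 2, m: int = 50) -> list[ProfileModel]:
    """Select m well-spread model profiles from the (2c+1)**(T-1) candidates.

    Greedy max-min-distance selection with d = 1 - Pearson r between
    patterns: start from the candidate farthest from the flat profile,
    then repeatedly add the candidate maximizing its minimum distance to the
    profiles already chosen.  All ties break lexicographically on the
    pattern, so the selection is fully deterministic.  The flat (all-zero)
    profile is never a selection candidate; it serves only as the reference
    level.  Profile ids follow selection order.
    """
    flat = (0,) * T
    pool = [p for p in candidate_profiles(T, c) if p != flat]
    if m > len(pool):
        raise ValueError(f"m={m} exceeds the {len(pool)} non-flat candidates")
    dist = {
        (p, q): 1.0 - _pattern_corr(p, q)
        for p in pool
        for q in pool
    }
    # distance to flat is 1 for every candidate (r undefined -> 0), so the
    # first pick is decided purely by the lexicographic tie-break
    chosen = [min(pool)]
    remaining = [p for p in pool if p != chosen[0]]
    while len(chosen) < m:
        # max-min-distance; at equal distance the negated tuple makes max()
        # favor the lexicographically smaller pattern
        best = max(
            remaining,
            key=lambda p: (min(dist[(p, q)] for q in chosen), tuple(-x for x in p)),
        )
        chosen.append(best)
        remaining.remove(best)
    return [ProfileModel(i, pat) for i, pat in enumerate(chosen)]


def rescue_profile_id(
    profiles: Sequence[ProfileModel], reference: tuple[int, ...] | None = None
) -> int:
    """Id of the selected profile matching the rescue shape (0, 0, +k, 0):
    elevated under stress, restored to baseline by the bacterium.

    Exact shape matches win; otherwise the selected profile with the highest
    Pearson correlation to (0, 0, 1, 0) is reported (ties -> lower id).
    """
    T = len(profiles[0].pattern)
    ref = reference or tuple(1 if i == T - 2 else 0 for i in range(T))
    exact = [
        p.profile_id
        for p in profiles
        if all(
            (x == 0) if ref[i] == 0 else (x > 0) and x == p.pattern[T - 2]
            for i, x in enumerate(p.pattern)
        )
        and any(x > 0 for x in p.pattern)
    ]
    if exact:
        return min(exact)
    best = max(profiles, key=lambda p: (_pattern_corr(p.pattern, ref), -p.profile_id))
    return best.profile_id


# ---------------------------------------------------------------------------
# assignment and exact permutation significance
# ---------------------------------------------------------------------------


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and L2-normalize; returns (standardized, nonconstant mask)."""
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xc, axis=1)
    ok = norm > 0
    out = np.zeros_like(xc)
    out[ok] = xc[ok] / norm[ok, None]
    return out, ok


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts scaled to per-sample totals of one million.

    ``library_sizes`` overrides the per-sample totals; pass the full
    matrix's totals when normalizing a gene subset, otherwise a shared
    planted signal is absorbed into the scaling.
    """
    totals = counts.sum(axis=0) if library_sizes is None else library_sizes.loc[counts.columns]
    if (totals == 0).any():
        raise ValueError("sample with zero total count")
    return counts / totals * 1e6


def group_response_vectors(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    group_order: Sequence[str] = DEFAULT_GROUPS,
    baseline: str = "Control",
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene response vector v_t = s_t - s_baseline, with s_t the group
    mean of log2(CPM + 1)."""
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    if baseline not in set(groups):
        raise ValueError(f"baseline group {baseline!r} absent from group map")
    missing = [g for g in group_order if g not in set(groups)]
    if missing:
        raise ValueError(f"groups with no samples: {missing}")
    logc = np.log2(cpm(counts, library_sizes) + 1)
    means = pd.DataFrame(
        {g: logc[groups.index[groups == g]].mean(axis=1) for g in group_order}
    )
    return means.sub(means[baseline], axis=0)


def assign_profiles(
    v: np.ndarray, patterns: np.ndarray
) -> np.ndarray:
    """Assign each response vector to the best-correlated pattern.

    Returns the pattern index per row, or -1 for zero-variance vectors.
    Ties take the lowest index (argmax keeps the first maximum).
    """
    vs, ok = _standardize_rows(np.asarray(v, dtype=float))
    ps, _ = _standardize_rows(np.asarray(patterns, dtype=float))
    r = vs @ ps.T
    idx = np.argmax(np.round(r, 12), axis=1)  # round so exact ties break by id
    idx[~ok] = -1
    return idx


def assign_and_test_profiles(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    profiles: Sequence[ProfileModel],
    group_order: Sequence[str] = DEFAULT_GROUPS,
    baseline: str = "Control",
    alpha: float = DEFAULT_ALPHA,
    library_sizes: pd.Series | None = None,
) -> tuple[list[ProfileModel], pd.Series]:
    """Assign genes to model profiles and test profile sizes exactly.

    Each gene's response vector v (group means of log2(CPM+1) relative to the
    baseline group) is assigned to the selected profile with maximal Pearson
    correlation; constant genes stay unassigned.  The null assignment
    distribution is computed by exact enumeration of all T! permutations of
    each gene's v; per profile, the p-value is the upper-tail binomial
    probability of observing at least the assigned count given the
    permutation-expected proportion, Bonferroni-corrected by the number of
    profiles.

    Returns the profiles enriched with counts/p-values and a gene -> profile
    id Series (-1 = unassigned).
    """
    v = group_response_vectors(counts, groups, group_order, baseline, library_sizes)
    T = len(group_order)
    patterns = np.array([p.pattern for p in profiles], dtype=float)
    if patterns.shape[1] != T:
        raise ValueError("profile length does not match number of groups")
    m = len(profiles)

    varr = v.to_numpy()
    assignment = assign_profiles(varr, patterns)
    assigned_mask = assignment >= 0
    n_assigned = int(assigned_mask.sum())

    # exact permutation null: every permutation of each assignable gene's v
    perms = np.array(list(itertools.permutations(range(T))))  # (T!, T)
    va = varr[assigned_mask]
    perm_counts = np.zeros(m, dtype=float)
    for perm in perms:
        idx = assign_profiles(va[:, perm], patterns)
        perm_counts += np.bincount(idx[idx >= 0], minlength=m)
    expected_prop = perm_counts / (len(perms) * max(n_assigned, 1))

    gene_ids = np.asarray(v.index)
    out: list[ProfileModel] = []
    for j, prof in enumerate(profiles):
        obs = int(np.sum(assignment == j))
        p_exp = float(expected_prop[j])
        if n_assigned == 0:
            p_adj = float("nan")
        else:
            p_raw = float(stats.binom.sf(obs - 1, n_assigned, p_exp)) if p_exp > 0 else (
                0.0 if obs > 0 else 1.0
            )
            p_adj = min(1.0, p_raw * m)
        out.append(
            ProfileModel(
                profile_id=prof.profile_id,
                pattern=prof.pattern,
                n_assigned=obs,
                expected=p_exp * n_assigned,
                p_value=p_adj,
                significant=bool(p_adj < alpha) if math.isfinite(p_adj) else False,
                assigned_genes=tuple(gene_ids[assignment == j]),
            )
        )
    return out, pd.Series(assignment, index=v.index, name="profile_id")


def profile_report(profiles: Sequence[ProfileModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "profile_id": p.profile_id,
                "pattern": ",".join(str(x) for x in p.pattern),
                "n_assigned": p.n_assigned,
                "expected": p.expected,
                "p_adj": p.p_value,
                "significant": p.significant,
            }
            for p in profiles
        ]
    )


# ---------------------------------------------------------------------------
# 2^-ddCt
# ---------------------------------------------------------------------------


def ddct_fold_change(
    ct: pd.DataFrame,
    control_group: str = "Control",
    reference_gene: str = "GAPDH",
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct`` holds one row per (sample, gene) with columns sample, group, gene,
    ct.  Per sample, dCt = Ct_target - Ct_reference; ddCt subtracts the
    control-group mean dCt of the same target; fold = 2^-ddCt, so the
    control-group geometric mean fold is 1 by construction.  Samples missing
    the reference gene are dropped with a warning.
    """
    required = {"sample", "group", "gene", "ct"}
    if missing := required - set(ct.columns):
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    targets = ct[ct["gene"] != reference_gene].copy()
    no_ref = sorted(set(targets["sample"]) - set(ref.index))
    if no_ref:
        warnings.warn(f"samples without reference Ct dropped: {no_ref}")
        targets = targets[~targets["sample"].isin(no_ref)]
    if targets.empty:
        raise ValueError("no target measurements with reference Ct")
    targets["dct"] = targets["ct"].to_numpy() - ref.loc[targets["sample"]].to_numpy()
    control = targets[targets["group"] == control_group]
    if control.empty:
        raise ValueError(f"no samples in control group {control_group!r}")
    control_mean = control.groupby("gene")["dct"].mean()
    absent = sorted(set(targets["gene"]) - set(control_mean.index))
    if absent:
        raise ValueError(f"targets with no control-group measurement: {absent}")
    targets["ddct"] = targets["dct"] - control_mean.loc[targets["gene"]].to_numpy()
    targets["fold"] = 2.0 ** (-targets["ddct"])
    return targets[["sample", "group", "gene", "ct", "dct", "ddct", "fold"]].reset_index(
        drop=True
    )
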