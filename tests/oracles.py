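"""Independent brute-force oracle implementations for the index formulas.

Everything here is written as plain dict-and-loop arithmetic, deliberately
sharing no code with the package: the genetic code is rebuilt directly from
Biopython's table, counts are dicts keyed by codon strings, and each formula
follows its definition one term at a time.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
AA_OF: dict[str, str] = dict(_TABLE.forward_table)
STOPS = set(_TABLE.stop_codons)
SYN: dict[str, list[str]] = {}
for _c, _a in sorted(AA_OF.items()):
    SYN.setdefault(_a, []).append(_c)
ALL_CODONS = sorted(AA_OF) + sorted(STOPS)
FOURFOLD_AAS = [a for a, cs in SYN.items() if len(cs) == 4]
INFORMATIVE = [c for c in sorted(AA_OF) if len(SYN[AA_OF[c]]) >= 2]


def sliding_codons(seq: str) -> list[str]:
    """Frame-0 codon list with a terminal stop removed."""
    out = []
    i = 0
    while i + 3 <= len(seq):
        out.append(seq[i : i + 3])
        i += 3
    if out and out[-1] in STOPS:
        out.pop()
    return out


def count_codons(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in sliding_codons(seq):
        if set(c) <= set("ACGT"):
            counts[c] = counts.get(c, 0) + 1
    return counts


def rscu(counts: dict[str, int]) -> dict[str, float]:
    """RSCU per sense codon; families with zero usage are simply absent."""
    out: dict[str, float] = {}
    for aa, codons in SYN.items():
        n = sum(counts.get(c, 0) for c in codons)
        if n == 0:
            continue
        for c in codons:
            out[c] = counts.get(c, 0) / (n / len(codons))
    return out


def enc(counts: dict[str, int]) -> float | None:
    f_per_class: dict[int, list[float]] = {}
    n_classes: dict[int, int] = {}
    for aa, codons in SYN.items():
        k = len(codons)
        if k == 1:
            continue
        n_classes[k] = n_classes.get(k, 0) + 1
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        s = sum((counts.get(c, 0) / n) ** 2 for c in codons)
        f = (n * s - 1) / (n - 1)
        if f > 0:
            f_per_class.setdefault(k, []).append(f)
    fbar = {k: sum(v) / len(v) for k, v in f_per_class.items()}
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    if any(k not in fbar for k in n_classes):
        return None
    nc = 2 + sum(n_classes[k] / fbar[k] for k in n_classes)
    return min(nc, 61.0)


def scuo(counts: dict[str, int]) -> float | None:
    num = 0.0
    total = 0
    for aa, codons in SYN.items():
        k = len(codons)
        if k < 2:
            continue
        n = sum(counts.get(c, 0) for c in codons)
        if n == 0:
            continue
        h = 0.0
        for c in codons:
            p = counts.get(c, 0) / n
            if p > 0:
                h -= p * math.log2(p)
        num += n * (math.log2(k) - h) / math.log2(k)
        total += n
    return num / total if total else None


def cai_weights(host_counts: dict[str, int], pseudo: float = 0.5) -> dict[str, float]:
    w = {}
    for aa, codons in SYN.items():
        fam = {c: (host_counts.get(c, 0) or pseudo) for c in codons}
        top = max(fam.values())
        for c in codons:
            w[c] = fam[c] / top
    return w


def cai(counts: dict[str, int], w: dict[str, float]) -> float | None:
    logs = 0.0
    n = 0
    for c in INFORMATIVE:
        x = counts.get(c, 0)
        if x:
            logs += x * math.log(w[c])
            n += x
    return math.exp(logs / n) if n else None


def host_cif(host_counts: dict[str, int], pseudo: float = 0.5) -> dict[str, float]:
    cif = {}
    for aa, codons in SYN.items():
        fam = {c: (host_counts.get(c, 0) or pseudo) for c in codons}
        tot = sum(fam.values())
        for c in codons:
            cif[c] = fam[c] / tot
    return cif


def rcdi(counts: dict[str, int], cif: dict[str, float]) -> float | None:
    total = 0.0
    n = 0
    for aa, codons in SYN.items():
        if len(codons) < 2:
            continue
        fam_n = sum(counts.get(c, 0) for c in codons)
        if fam_n == 0:
            continue
        for c in codons:
            x = counts.get(c, 0)
            total += (x / fam_n) / cif[c] * x
        n += fam_n
    return total / n if n else None


def sid(a: list[float], b: list[float]) -> float:
    num = sum(x * y for x, y in zip(a, b))
    r = num / math.sqrt(sum(x * x for x in a) * sum(y * y for y in b))
    return (1 - r) / 2


def pr2(seq: str) -> tuple[float | None, float | None]:
    third = {"A": 0, "C": 0, "G": 0, "T": 0}
    for c in sliding_codons(seq):
        if AA_OF.get(c) in FOURFOLD_AAS:
            third[c[2]] += 1
    x = third["G"] / (third["G"] + third["C"]) if third["G"] + third["C"] else None
    y = third["A"] / (third["A"] + third["T"]) if third["A"] + third["T"] else None
    return x, y


def gc_by_position(seq: str) -> tuple[float, float, float, float]:
    cods = [c for c in sliding_codons(seq) if set(c) <= set("ACGT")]
    n = len(cods)
    gck = [sum(c[k] in "GC" for c in cods) / n for k in range(3)]
    return sum(gck) / 3, gck[0], gck[1], gck[2]


def pearson(x, y) -> tuple[float, float]:
    """Pearson r via the covariance formula and its two-sided t-based p."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x - x.mean(), y - y.mean()
    r = float(np.sum(sx * sy) / math.sqrt(np.sum(sx**2) * np.sum(sy**2)))
    if abs(r) >= 1:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * float(stats.t.sf(abs(t), n - 2))


def random_gene(rng: np.random.Generator, n_codons: int = 300) -> str:
    """A random valid CDS (start codon, sense codons, terminal stop)."""
    sense = sorted(AA_OF)
    body = "".join(rng.choice(sense) for _ in range(n_codons - 1))
    return "ATG" + body + "TAA"


# ---------------------------------------------------------------------------
# profile machinery oracles
# ---------------------------------------------------------------------------


def greedy_profiles(T: int, c: int, m: int) -> list[tuple[int, ...]]:
    """Second, independent implementation of the greedy profile selection."""

    def corr(p, q):
        mp, mq = sum(p) / len(p), sum(q) / len(q)
        num = sum((a - mp) * (b - mq) for a, b in zip(p, q))
        dp = math.sqrt(sum((a - mp) ** 2 for a in p))
        dq = math.sqrt(sum((b - mq) ** 2 for b in q))
        if dp == 0 or dq == 0:
            return 0.0
        return num / (dp / 1 * dq)

    cands = []
    for steps in itertools.product(range(-c, c + 1), repeat=T - 1):
        pat = (0,)
        for s in steps:
            pat = pat + (pat[-1] + s,)
        if any(pat):
            cands.append(pat)
    cands.sort()
    chosen = [cands[0]]  # all are at distance 1 from flat; lexicographic tie
    rest = cands[1:]
    while len(chosen) < m:
        scored = sorted(
            rest, key=lambda p: (-min(1 - corr(p, q) for q in chosen), p)
        )
        chosen.append(scored[0])
        rest.remove(scored[0])
    return chosen


def assign_gene(v, patterns) -> int:
    """Best-correlated pattern index for one response vector (-1 if flat)."""
    vm = sum(v) / len(v)
    dv = math.sqrt(sum((a - vm) ** 2 for a in v))
    if dv == 0:
        return -1
    best, best_r = -1, -2.0
    for j, p in enumerate(patterns):
        pm = sum(p) / len(p)
        dp = math.sqrt(sum((a - pm) ** 2 for a in p))
        r = sum((a - vm) * (b - pm) for a, b in zip(v, p)) / (dv * dp)
        if round(r, 12) > round(best_r, 12):
            best, best_r = j, r
    return best


def exact_permutation_expectation(vectors, patterns) -> list[float]:
    """Expected assignment proportion per pattern by full T! enumeration."""
    m = len(patterns)
    totals = [0.0] * m
    n = 0
    for v in vectors:
        if len(set(v)) == 1:
            continue
        n += 1
        for perm in itertools.permutations(v):
            j = assign_gene(perm, patterns)
            if j >= 0:
                totals[j] += 1
    nperm = math.factorial(len(patterns[0]))
    return [t / (n * nperm) for t in totals] if n else totals
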