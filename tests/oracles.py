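"""Independent brute-force reference implementations used only by tests.

Everything here is written as a direct, unoptimized transcription of the
defining formulas — separate from the package's code paths — so tests can
compare the two routes.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import product


# -- global alignment ------------------------------------------------------

def nw_best_score(a: str, b: str) -> int:
    """Optimal global alignment score: match +1, mismatch 0, gap -1."""
    n, m = len(a), len(b)
    prev = [-j for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [-i] + [0] * m
        for j in range(1, m + 1):
            diag = prev[j - 1] + (1 if a[i - 1] == b[j - 1] else 0)
            cur[j] = max(diag, prev[j] - 1, cur[j - 1] - 1)
        prev = cur
    return prev[m]


def nw_max_matches(a: str, b: str) -> int:
    """Maximum identities over all optimal-score global alignments."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    # DP over (score, matches) with lexicographic max
    prev = [(-j, 0) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(-i, 0)] + [(NEG, 0)] * m
        for j in range(1, m + 1):
            eq = 1 if a[i - 1] == b[j - 1] else 0
            cands = [
                (prev[j - 1][0] + eq, prev[j - 1][1] + eq),
                (prev[j][0] - 1, prev[j][1]),
                (cur[j - 1][0] - 1, cur[j - 1][1]),
            ]
            cur[j] = max(cands)
        prev = cur
    return prev[m][1]


def greedy_reduce_bruteforce(records, cutoff, identity_fn):
    """All-pairs reimplementation of the greedy clustering contract."""
    order = sorted(range(len(records)), key=lambda i: (-len(records[i].sequence), i))
    reps = []
    clusters = {}
    for idx in order:
        rec = records[idx]
        for rep in reps:
            if identity_fn(rep.sequence, rec.sequence) >= cutoff:
                clusters[rep.id].append(rec.id)
                break
        else:
            reps.append(rec)
            clusters[rec.id] = []
    return reps, clusters


# -- pseudo amino acid composition ----------------------------------------

def pseaac_bruteforce(seq: str, lam: int, w: float, scales) -> list[float]:
    """Direct transcription of the Type-I PseAAC formulas.

    ``scales`` are raw residue->value dicts; standard conversion is done
    here with explicit loops.
    """
    aas = "ACDEFGHIKLMNPQRSTVWY"
    normed = []
    for scale in scales:
        vals = [scale[aa] for aa in aas]
        mean = sum(vals) / 20
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20)
        normed.append({aa: (scale[aa] - mean) / sd for aa in aas})

    def coupling(r1, r2):
        return sum((s[r1] - s[r2]) ** 2 for s in normed) / len(normed)

    L = len(seq)
    thetas = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(L - k):
            total += coupling(seq[i], seq[i + k])
        thetas.append(total / (L - k))
    freqs = [seq.count(aa) / L for aa in aas]
    denom = sum(freqs) + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


# -- ROC -------------------------------------------------------------------

def auc_pairwise(pos, neg) -> Fraction:
    """Exhaustive pairwise Mann-Whitney count, ties half-credited."""
    num = Fraction(0)
    for p in pos:
        for q in neg:
            if p > q:
                num += 1
            elif p == q:
                num += Fraction(1, 2)
    return num / (len(pos) * len(neg))


def best_threshold_bruteforce(pos, neg):
    """Scan every candidate threshold and both orientations; return the
    maximum accuracy (threshold/orientation tie-breaks not compared)."""
    values = sorted(set(list(pos) + list(neg)))
    mids = [(u + v) / 2 for u, v in zip(values, values[1:])]
    candidates = [float("-inf")] + mids + [float("inf")]
    n = len(pos) + len(neg)
    best = 0.0
    for t in candidates:
        acc_g = (sum(1 for p in pos if p > t) + sum(1 for q in neg if q <= t)) / n
        acc_l = (sum(1 for p in pos if p < t) + sum(1 for q in neg if q >= t)) / n
        best = max(best, acc_g, acc_l)
    return best


# -- confusion-matrix metrics ---------------------------------------------

def metrics_formulas(tp, tn, fp, fn):
    """Literal evaluation of the four printed metric formulas."""
    acc = (tp + tn) / (tp + tn + fp + fn)
    rad = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(rad) if rad else 0.0
    sn = tp / (tp + fn) if tp + fn else float("nan")
    sp = tn / (tn + fp) if tn + fp else float("nan")
    return acc, mcc, sn, sp


# -- Dempster-Shafer combination ------------------------------------------

def dempster_combine(masses):
    """Combine mass functions over frame {'A', 'B'} by Dempster's rule.

    ``masses``: list of dicts over focal sets 'A', 'B', 'AB' (the frame).
    Enumerated over all focal-set intersections; normalized by 1-conflict.
    """
    sets = {"A": {"A"}, "B": {"B"}, "AB": {"A", "B"}}
    combined = {"A": 0.0, "B": 0.0, "AB": 0.0}
    conflict = 0.0
    for combo in product(*[list(m.items()) for m in masses]):
        inter = {"A", "B"}
        weight = 1.0
        for focal, mass in combo:
            inter &= sets[focal]
            weight *= mass
        if not inter:
            conflict += weight
        elif inter == {"A", "B"}:
            combined["AB"] += weight
        elif inter == {"A"}:
            combined["A"] += weight
        else:
            combined["B"] += weight
    norm = 1.0 - conflict
    return {k: v / norm for k, v in combined.items()}


# -- pH grid scan ----------------------------------------------------------

def pi_grid_scan(charge_fn, step=1e-4):
    """Brute-force pH grid scan: pH in [0, 14] with the smallest |charge|."""
    best_ph, best_abs = 0.0, float("inf")
    n = int(14.0 / step)
    for i in range(n + 1):
        ph = i * step
        c = abs(charge_fn(ph))
        if c < best_abs:
            best_ph, best_abs = ph, c
    return best_ph
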