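"""Independent brute-force reference implementations used by the tests.

Deliberately naive: tuple products, word enumerations, per-window rescans
and quadratic substring comparisons.  They share no code with the package
paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


# -- core ------------------------------------------------------------------

def brute_min_support(lists):
    """Minimal interval covering one (start, end) per list, by tuple product."""
    if any(not lst for lst in lists):
        return None
    best = None
    for combo in itertools.product(*lists):
        start = min(s for s, _ in combo)
        end = max(e for _, e in combo)
        key = (end - start, start)
        if best is None or key < best:
            best = key
    return (best[1], best[1] + best[0])


def brute_feature_coverage(instances, seq_ids):
    return len({s for s, _, _ in instances}) / len(seq_ids)


def brute_module_coverage(feature_instances, seq_ids):
    """feature_instances: dict feature -> list of (seq, start, end)."""
    n = 0
    for sid in seq_ids:
        if all(any(s == sid for s, _, _ in lst)
               for lst in feature_instances.values()):
            n += 1
    return n / len(seq_ids)


def brute_overlap(sup1, sup2):
    """sup1/sup2: dict seq -> (start, end)."""
    total = 0
    for sid in sup1:
        if sid in sup2:
            a, b = sup1[sid], sup2[sid]
            total += max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return total


# -- pwm -------------------------------------------------------------------

def word_score(weights, word):
    return sum(weights["ACGT".index(b), j] for j, b in enumerate(word))


def brute_max_score(weights):
    L = weights.shape[1]
    return max(word_score(weights, "".join(w))
               for w in itertools.product("ACGT", repeat=L))


def brute_scan(weights, min_score, max_score, residues, threshold):
    """Per-window rescan on both strands; returns {(start, strand)}."""
    L = weights.shape[1]
    span = max_score - min_score
    hits = set()
    for strand, seq in (("+", residues), ("-", rc(residues))):
        for i in range(len(seq) - L + 1):
            w = seq[i:i + L]
            if "N" in w:
                continue
            norm = (word_score(weights, w) - min_score) / span
            if norm >= threshold - 1e-9:
                start = i if strand == "+" else len(seq) - i - L
                hits.add((start, strand))
    return hits


def brute_norm_scores(weights, min_score, max_score, residues):
    """All attained normalized window scores, both strands."""
    L = weights.shape[1]
    span = max_score - min_score
    out = []
    for seq in (residues, rc(residues)):
        for i in range(len(seq) - L + 1):
            w = seq[i:i + L]
            if "N" in w:
                continue
            out.append((word_score(weights, w) - min_score) / span)
    return out


def brute_optimal_threshold(weights, min_score, max_score, pos_seqs, neg_seqs,
                            c_pos_min=0.75, c_neg_max=0.5, f_ratio_min=2.0):
    """Exhaustive search over every attained score; returns (t, ratio) or None."""
    pos_scores = [brute_norm_scores(weights, min_score, max_score, s)
                  for s in pos_seqs]
    neg_scores = [brute_norm_scores(weights, min_score, max_score, s)
                  for s in neg_seqs]
    attained = sorted({x for lst in pos_scores + neg_scores for x in lst})
    pos_bp = sum(len(s) for s in pos_seqs)
    neg_bp = sum(len(s) for s in neg_seqs)
    best = None
    for t in attained:
        c_pos = sum(any(x >= t - 1e-9 for x in lst) for lst in pos_scores) / len(pos_seqs)
        c_neg = sum(any(x >= t - 1e-9 for x in lst) for lst in neg_scores) / len(neg_seqs)
        f_pos = sum(sum(x >= t - 1e-9 for x in lst) for lst in pos_scores) / pos_bp
        f_neg = sum(sum(x >= t - 1e-9 for x in lst) for lst in neg_scores) / neg_bp
        if f_neg > 0:
            f_ratio = f_pos / f_neg
        else:
            f_ratio = math.inf if f_pos > 0 else 0.0
        if not (c_pos >= c_pos_min and c_neg <= c_neg_max and f_ratio >= f_ratio_min):
            continue
        c_eff = c_neg if c_neg > 0 else 1.0 / (2 * len(neg_seqs))
        ratio = c_pos / c_eff
        if best is None or ratio > best[1] + 1e-12 or (
                abs(ratio - best[1]) <= 1e-12 and t > best[0]):
            best = (t, ratio)
    return best


# -- detectors -------------------------------------------------------------

def brute_composition_regions(residues, low, high, w):
    """Classify every window, then merge touching same-class windows."""
    out = {"at_rich": [], "gc_rich": []}
    n = len(residues)
    for i in range(n - w + 1):
        win = residues[i:i + w]
        gc = sum(b in "GC" for b in win) / w
        if gc < low:
            out["at_rich"].append((i, i + w))
        elif gc > high:
            out["gc_rich"].append((i, i + w))
    merged = {}
    for cls, ivs in out.items():
        acc = []
        for s, e in ivs:
            if acc and s <= acc[-1][1]:
                acc[-1] = (acc[-1][0], max(acc[-1][1], e))
            else:
                acc.append((s, e))
        merged[cls] = acc
    return merged


def brute_poly_a(residues, k, mm):
    return [(i, i + k) for i in range(len(residues) - k + 1)
            if sum(b != "A" for b in residues[i:i + k]) <= mm]


def brute_repeats(residues, min_arm, max_spacer):
    """All maximal direct/inverted repeats by quadratic extension scans."""
    s = residues
    n = len(s)
    found = set()

    def ok(a, b):
        return a == b and a != "N"

    # direct: for each offset d, maximal runs of s[i] == s[i+d]
    for d in range(1, n):
        i = 0
        while i + d < n:
            if ok(s[i], s[i + d]):
                j = i
                while j + d < n and ok(s[j], s[j + d]):
                    j += 1
                L0 = j - i
                L = min(L0, d)
                if L >= min_arm:
                    a, b = i, i + d
                    spacer = b - (a + L)
                    if 0 <= spacer <= max_spacer:
                        found.add(("direct", (a, a + L), (b, b + L)))
                i = j + 1
            else:
                i += 1
    # inverted: maximal anti-diagonal runs of s[i] == COMP[s[j]]
    r = rc(s)
    for d in range(-(n - 1), n):
        # match s[i] with r[i + d]
        i = max(0, -d)
        while i < n and i + d < n:
            if i + d >= 0 and ok(s[i], r[i + d]):
                j = i
                while j < n and j + d < n and ok(s[j], r[j + d]):
                    j += 1
                L0 = j - i
                i0, p0 = i, i + d
                jf = n - p0 - L0
                a, b = min(i0, jf), max(i0, jf)
                L = min(L0, (b + L0 - a) // 2)
                if L >= min_arm:
                    arm1 = (a, a + L)
                    arm2 = (b + L0 - L, b + L0)
                    spacer = arm2[0] - arm1[1]
                    if 0 <= spacer <= max_spacer:
                        found.add(("inverted", arm1, arm2))
                i = j + 1
            else:
                i += 1
    return found


# -- search ----------------------------------------------------------------

def brute_select_k(supports, fitness, keys, k):
    """Exhaustive K-subset minimization of summed pairwise overlap.

    supports: list of dict seq -> (start, end); tie-break: higher summed
    fitness, then lexicographic keys.
    """
    m = len(supports)
    best = None
    best_idx = None
    for combo in itertools.combinations(range(m), k):
        total = sum(brute_overlap(supports[a], supports[b])
                    for a, b in itertools.combinations(combo, 2))
        key = (total, -sum(fitness[i] for i in combo),
               tuple(sorted(keys[i] for i in combo)))
        if best is None or key < best:
            best = key
            best_idx = combo
    return set(best_idx)


def brute_binom_tail(n_hit, n, p):
    return sum(math.comb(n, k) * p ** k * (1 - p) ** (n - k)
               for k in range(n_hit, n + 1))
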