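"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the definition of the quantity, with no code
shared with the package, so that agreement is an actual cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

GAS_CONSTANT = 0.0019872

_CANONICAL = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def enumerate_structures(seq: str, min_hairpin: int = 3):
    """All nested structures (as frozensets of (i, j) pairs) of a sequence."""
    n = len(seq)

    def pairable(i, j):
        return j - i > min_hairpin and (seq[i], seq[j]) in _CANONICAL

    memo = {}

    def spans(i, j):
        if (i, j) in memo:
            return memo[(i, j)]
        if j < i:
            return [frozenset()]
        out = []
        # base j unpaired
        out.extend(spans(i, j - 1))
        # base j paired with k
        for k in range(i, j):
            if pairable(k, j):
                for left in spans(i, k - 1):
                    for inner in spans(k + 1, j - 1):
                        out.append(left | inner | {(k, j)})
        memo[(i, j)] = out
        return out

    return spans(0, n - 1)


def structure_energy(pairs, pair_energies, stack_energy):
    """Energy = sum of pair energies + stacking bonus per directly stacked pair."""
    e = 0.0
    pairset = set(pairs)
    for (i, j) in pairs:
        e += pair_energies[(i, j)]
        if (i + 1, j - 1) in pairset:
            e += stack_energy
    return e


def boltzmann_bpp(seq: str, params) -> np.ndarray:
    """Base-pair probabilities by exhaustive enumeration + Boltzmann weighting."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    rt = GAS_CONSTANT * params.temperature
    elookup = {}
    for (x, y), e in params.pair_energies.items():
        elookup[(x, y)] = e
        elookup[(y, x)] = e
    structures = enumerate_structures(seq, params.min_hairpin)
    P = np.zeros((n, n))
    Ztot = 0.0
    for pairs in structures:
        pe = {(i, j): elookup[(seq[i], seq[j])] for (i, j) in pairs}
        w = math.exp(-structure_energy(pairs, pe, params.stack_energy) / rt)
        Ztot += w
        for (i, j) in pairs:
            P[i, j] += w
    return P / Ztot


def naive_d_max(A: np.ndarray, B: np.ndarray, d_min_span: int) -> float:
    """d_max by direct scan over every subinterval (cubic, definitional)."""
    n = A.shape[0]
    best = 0.0
    for a in range(n):
        for b in range(a + d_min_span - 1, n):
            tot = 0.0
            for i in range(a, b + 1):
                for j in range(i + 1, b + 1):
                    tot += (A[i, j] - B[i, j]) ** 2
            best = max(best, math.sqrt(tot) / (b - a + 1))
    return best


def shannon_entropy(chars) -> float:
    """Plain (unweighted) Shannon entropy in bits of a symbol sequence."""
    chars = [c for c in chars if c not in ("-", "N")]
    if not chars:
        return float("nan")
    n = len(chars)
    h = 0.0
    for c in set(chars):
        p = chars.count(c) / n
        h -= p * math.log2(p)
    return h


def mh_chi2_textbook(tables) -> float:
    """Continuity-corrected Mantel-Haenszel chi-square, written from the
    textbook formula with independent variable naming."""
    num = 0.0
    expect = 0.0
    var = 0.0
    for (a, b, c, d) in tables:
        t = a + b + c + d
        if t < 2:
            continue
        num += a
        row1, col1 = a + b, a + c
        row2, col2 = c + d, b + d
        expect += row1 * col1 / t
        var += row1 * row2 * col1 * col2 / (t * t * (t - 1))
    return (abs(num - expect) - 0.5) ** 2 / var


def wright_enc(codon_counts, families) -> float:
    """Classic effective number of codons from codon homozygosity.

    F-hat per family = (n * sum p_i^2 - 1) / (n - 1); class averages are
    weighted by family codon counts; missing 3-fold class interpolated.
    """
    class_f = {}
    for k in (2, 3, 4, 6):
        fams = [f for f in families if len(f) == k]
        num = 0.0
        den = 0
        for fam in fams:
            counts = [codon_counts.get(c, 0) for c in fam]
            n = sum(counts)
            if n < 2:
                continue
            shom = sum((c / n) ** 2 for c in counts)
            f_hat = (n * shom - 1) / (n - 1)
            num += n * f_hat
            den += n
        if den > 0:
            class_f[k] = num / den
    if 3 not in class_f and 2 in class_f and 4 in class_f:
        class_f[3] = (class_f[2] + class_f[4]) / 2
    enc = 2.0
    for k, mult in ((2, 9.0), (3, 1.0), (4, 5.0), (6, 3.0)):
        f = class_f.get(k, 1.0 / k)
        f = max(f, 1e-12)
        enc += mult / f
    return min(61.0, max(20.0, enc))
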