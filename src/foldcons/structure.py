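"""Base-pair probabilities and mutation structural-disruption scores.

The engine computes equilibrium base-pair probabilities over the ensemble of
nested secondary structures by an exact inside--outside dynamic program
(McCaskill-style).  The energy model is deliberately lightweight: each
canonical pair (AU/AT, GC, GU/GT) contributes a fixed stabilising energy and
every directly stacked pair adds a stacking bonus.  Hairpin loops must
enclose at least ``min_hairpin`` unpaired bases; no other loop penalties are
applied.  The statistics built on top (``d_max``, site sensitivity) depend on
*differences* between probability matrices of wild-type and mutant sequences,
not on absolute folding accuracy.

Coordinates are 0-based internally; ``BasePairMatrix.P[i, j]`` with ``i < j``
is the probability that bases i and j pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FoldParams",
    "BasePairMatrix",
    "SensitivityResult",
    "partition_bpp",
    "local_window",
    "d_max",
    "site_sensitivity",
    "calibrate_sensitivity_cutoff",
]

#: gas constant in kcal/(mol*K)
GAS_CONSTANT = 0.0019872

_ALPHABET = set("ACGTU")

# canonical pairs, DNA alphabet (U is mapped to T on input)
_DEFAULT_PAIR_ENERGIES = {
    ("G", "C"): -2.1,
    ("A", "T"): -1.3,
    ("G", "T"): -0.9,
}


@dataclass
class FoldParams:
    """Parameters of the folding engine and the locality of d_max.

    temperature : kelvin (Boltzmann weights use RT = 0.0019872 * T kcal/mol).
    min_hairpin : minimum number of unpaired bases enclosed by a hairpin.
    flank : nucleotides of local context folded on each side of a site.
    d_min_span : shortest subinterval length scanned when maximising d_max.
    pair_energies / stack_energy : kcal/mol, negative = stabilising.
    """

    temperature: float = 310.15
    min_hairpin: int = 3
    flank: int = 200
    d_min_span: int = 10
    pair_energies: dict = field(default_factory=lambda: dict(_DEFAULT_PAIR_ENERGIES))
    stack_energy: float = -1.1
    sensitivity_cutoff: float = 0.1

    def __post_init__(self) -> None:
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if self.flank < self.d_min_span:
            raise ValueError("flank must be >= d_min_span")

    @property
    def rt(self) -> float:
        return GAS_CONSTANT * self.temperature

    def pair_weight_matrix(self, seq: str) -> np.ndarray:
        """Boltzmann weight of pairing base i with base j (0 if non-canonical)."""
        n = len(seq)
        w = {}
        for (x, y), e in self.pair_energies.items():
            bw = float(np.exp(-e / self.rt))
            w[x + y] = bw
            w[y + x] = bw
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + self.min_hairpin + 1, n):
                W[i, j] = w.get(seq[i] + seq[j], 0.0)
        return W


@dataclass
class BasePairMatrix:
    """Upper-triangular matrix of base-pair probabilities for one sequence."""

    n: int
    P: np.ndarray  # (n, n), P[i, j] defined for i < j, zeros elsewhere

    def total_pairing(self) -> np.ndarray:
        """Per-base probability of being paired with anything."""
        return self.P.sum(axis=0) + self.P.sum(axis=1)


@dataclass
class SensitivityResult:
    cds_pos: int  # 1-based position in the reference CDS
    ref_nt: str
    d_max_per_mutant: dict  # mutant nucleotide -> d_max
    sensitivity: float  # mean of the three d_max values
    sensitive: bool


def _normalize_seq(sequence: str) -> str:
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def _inside(W: np.ndarray, sigma: float, invs: float):
    """Inside pass.  Returns (Z, Zb, ZeM, Ztot).

    Z[i, j]  : partition function of span [i, j] (any structure).
    Zb[i, j] : partition function of span [i, j] given i pairs j.
    ZeM[i, k]: Z[i, k-1] for k >= i (empty span = 1), 0 for k < i; used for
               the "j pairs k" decomposition and reused by the outside pass.
    All quantities carry a 1/s factor per nucleotide to keep float64 in range.
    """
    n = W.shape[0]
    Z = np.zeros((n, n))
    Zb = np.zeros((n, n))
    ZeM = np.zeros((n, n + 1))
    ZeM[0, 0] = 1.0
    for j in range(n):
        # Zb[:, j]: i pairs j, interior [i+1, j-1]
        if j >= 1:
            interior = ZeM[1 : j + 1, j].copy()  # Z[i+1, j-1] for i = 0..j-1
            # empty interior spans (j-1 < i+1) are 1 in ZeM by construction
            inner_b = np.zeros(j)
            inner_b[: j - 1] = Zb[1:j, j - 1]  # Zb[i+1, j-1] for i+1 <= j-1
            Zb[:j, j] = W[:j, j] * (interior + (sigma - 1.0) * inner_b)
        # Z[:, j] = unpaired-j term + sum_k Z[i, k-1] * Zb[k, j]
        unpaired = np.zeros(j + 1)
        if j >= 1:
            unpaired[:j] = Z[:j, j - 1] * invs
        unpaired[j] = invs  # span [j, j]: Z[j, j-1] (empty) * 1/s
        pair_term = ZeM[: j + 1, : j + 1] @ Zb[: j + 1, j]
        Z[: j + 1, j] = unpaired + pair_term
        # extend ZeM with column k = j+1 (holds Z[i, j])
        ZeM[: j + 1, j + 1] = Z[: j + 1, j]
        if j + 1 < n:
            ZeM[j + 1, j + 1] = 1.0  # empty span [j+1, j]
    return Z, Zb, ZeM, Z[0, n - 1]


def _outside(W: np.ndarray, sigma: float, invs: float, Zb: np.ndarray, ZeM: np.ndarray):
    """Outside pass: Ob[i, j] such that P[i, j] = Zb[i, j] * Ob[i, j] / Ztot."""
    n = W.shape[0]
    Oz = np.zeros((n, n))
    Ob = np.zeros((n, n))
    for j in range(n - 1, -1, -1):
        col = np.zeros(n)
        if j == n - 1:
            col[0] = 1.0  # root span [0, n-1]
        if j + 1 < n:
            col += Oz[:, j + 1] * invs  # base j+1 unpaired in enclosing span
            # Z[i, j] as left factor of "k=j+1 pairs j'" in Z[i, j']
            col += Oz[:, j + 1 :] @ Zb[j + 1, j + 1 :]
            # Z[i, j] as interior of pair (i-1, j+1)
            col[1:] += W[: n - 1, j + 1] * Ob[: n - 1, j + 1]
        Oz[:, j] = col
        # Ob[k, j]: Zb[k, j] used in Z[i, j] for i <= k, and in the stack term
        t = ZeM[:, :n].T @ Oz[:, j]  # t[k] = sum_i Z[i, k-1] * Oz[i, j]
        if j + 1 < n:
            t[1:] += W[: n - 1, j + 1] * (sigma - 1.0) * Ob[: n - 1, j + 1]
        Ob[:, j] = t
    return Ob


def partition_bpp(sequence: str, params: FoldParams | None = None) -> BasePairMatrix:
    """Exact base-pair probability matrix over the nested-structure ensemble.

    Returns an all-zero matrix (with a warning) for sequences too short to
    form any hairpin.
    """
    params = params or FoldParams()
    seq = _normalize_seq(sequence)
    n = len(seq)
    if n < params.min_hairpin + 2:
        warnings.warn(f"sequence of length {n} too short to fold; empty matrix")
        return BasePairMatrix(n=n, P=np.zeros((n, n)))
    W0 = params.pair_weight_matrix(seq)
    sigma = float(np.exp(-params.stack_energy / params.rt))
    # per-nucleotide rescaling keeps the partition function inside float64
    # range; the scale cancels exactly in the probability ratio.
    emin = min(params.pair_energies.values())
    s = max(1.0, float(np.exp(-emin / (4.0 * params.rt))))
    for _attempt in range(200):
        invs = 1.0 / s
        W = W0 * invs * invs
        Z, Zb, ZeM, Ztot = _inside(W, sigma, invs)
        if not np.isfinite(Ztot) or not np.all(np.isfinite(Z)):
            s *= 4.0
            continue
        if Ztot == 0.0:
            s *= 0.25
            continue
        Ob = _outside(W, sigma, invs, Zb, ZeM)
        if not np.all(np.isfinite(Ob)):
            s *= 4.0
            continue
        P = Zb * Ob / Ztot
        if np.all(np.isfinite(P)):
            np.clip(P, 0.0, 1.0, out=P)
            return BasePairMatrix(n=n, P=np.triu(P))
        s *= 4.0
    raise FloatingPointError("partition function could not be stabilised")


def local_window(sequence: str, cds_pos: int, flank: int) -> tuple[str, int]:
    """Subsequence of +/- ``flank`` nt around 1-based position ``cds_pos``.

    Returns ``(window, offset)`` with ``offset`` such that window index k
    (0-based) corresponds to CDS position ``offset + k + 1``.  The window of
    a mutant and its wild type are always the same interval.
    """
    n = len(sequence)
    if not 1 <= cds_pos <= n:
        raise ValueError(f"cds_pos {cds_pos} outside sequence of length {n}")
    lo = max(1, cds_pos - flank)
    hi = min(n, cds_pos + flank)
    return sequence[lo - 1 : hi], lo - 1


def d_max(P_wt: BasePairMatrix | np.ndarray, P_mut: BasePairMatrix | np.ndarray,
          d_min_span: int = 10) -> float:
    """Maximum local structural distance between two base-pair matrices.

    Over every subinterval [a, b] with b-a+1 >= d_min_span, the Euclidean
    norm of the probability differences restricted to pairs inside the
    interval is divided by the interval length; d_max is the maximum.
    Computed with 2-D prefix sums, O(n^2) over all intervals.
    """
    A = P_wt.P if isinstance(P_wt, BasePairMatrix) else np.asarray(P_wt, dtype=float)
    B = P_mut.P if isinstance(P_mut, BasePairMatrix) else np.asarray(P_mut, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"matrix shapes differ: {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < d_min_span:
        return 0.0
    D2 = np.triu((A - B) ** 2, k=1)
    C = np.zeros((n + 1, n + 1))
    C[1:, 1:] = D2.cumsum(axis=0).cumsum(axis=1)
    # T[a, b] = sum of D2 over rows a..b, cols a..b (upper triangle only)
    diag = np.diagonal(C).copy()
    T = diag[1:][None, :] - C[:n, 1:] - C[1:, :n].T + diag[:n][:, None]
    lengths = np.arange(n)[None, :] - np.arange(n)[:, None] + 1
    valid = lengths >= d_min_span
    if not valid.any():
        return 0.0
    with np.errstate(invalid="ignore"):
        scores = np.sqrt(np.maximum(T, 0.0)) / lengths
    return float(scores[valid].max())


_MUTANTS = {
    "A": ("C", "G", "T"),
    "C": ("A", "G", "T"),
    "G": ("A", "C", "T"),
    "T": ("A", "C", "G"),
}


def site_sensitivity(sequence: str, cds_pos: int,
                     params: FoldParams | None = None) -> SensitivityResult:
    """Structural sensitivity of one site: mean d_max over its 3 mutations.

    The local window around the site is folded once for the wild type and
    once per single-nucleotide mutant; a site is called sensitive when the
    mean d_max strictly exceeds ``params.sensitivity_cutoff``.
    """
    params = params or FoldParams()
    seq = _normalize_seq(sequence)
    window, offset = local_window(seq, cds_pos, params.flank)
    k = cds_pos - offset - 1  # 0-based index of the site within the window
    ref = window[k]
    P_wt = partition_bpp(window, params)
    per_mut = {}
    for mut in _MUTANTS[ref]:
        mut_window = window[:k] + mut + window[k + 1 :]
        P_mut = partition_bpp(mut_window, params)
        per_mut[mut] = d_max(P_wt, P_mut, params.d_min_span)
    sens = float(np.mean(list(per_mut.values())))
    return SensitivityResult(
        cds_pos=cds_pos,
        ref_nt=ref,
        d_max_per_mutant=per_mut,
        sensitivity=sens,
        sensitive=sens > params.sensitivity_cutoff,
    )


def calibrate_sensitivity_cutoff(sensitivities, target_fraction: float) -> float:
    """Cutoff giving a target sensitive-site fraction (upper quantile).

    Offered as an alternative to the absolute default cutoff when matching a
    desired genome-wide fraction of sensitive sites.
    """
    arr = np.asarray(list(sensitivities), dtype=float)
    if arr.size == 0:
        raise ValueError("no sensitivity values supplied")
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    return float(np.quantile(arr, 1.0 - target_fraction))
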