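"""Pairwise nucleotide alignment and evolutionary distance.

Self-contained dynamic-programming global (Needleman–Wunsch) and local
(Smith–Waterman) alignment with linear gap penalties, plus the Kimura
two-parameter (K2P) distance between the two rows of an alignment.  This is
the numerical core used by every other module: monomer extraction anchors on
local alignments, domain decomposition scores reference subsequences against
monomers, and insertion dating converts an LTR-pair alignment into a K2P
distance.

The DP fills score matrices with vectorized numpy rows.  With a linear gap
penalty the within-row (horizontal) dependency unrolls into a running
maximum, so each row costs a handful of O(m) array operations:

    H[i, j] = max_{k <= j} ( C[k] + (j - k) * gap )      with
    C[j]    = max( H[i-1, j-1] + s(a_i, b_j), H[i-1, j] + gap )

Traceback is deterministic: diagonal is preferred over up over left, so two
runs on the same inputs produce byte-identical alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seq import clean, decode, encode, is_transition

GAP = "-"

__all__ = [
    "ScoringScheme",
    "Alignment",
    "K2PResult",
    "K2PDomainError",
    "DEFAULT_SCORING",
    "global_align",
    "local_align",
    "k2p_distance",
    "k2p_from_pq",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/gap scores for the linear-gap DP.

    ``N`` scores as a mismatch against every base, including another ``N``,
    so ambiguous sequence can never create a spurious match.
    """

    match: int = 1
    mismatch: int = -1
    gap: int = -2

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.mismatch > 0:
            raise ValueError("mismatch score must be <= 0")
        if self.gap > 0:
            raise ValueError("gap penalty must be <= 0")


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class Alignment:
    """A gapped pairwise alignment with 0-based half-open input coordinates."""

    aligned_a: str
    aligned_b: str
    score: int
    start_a: int
    end_a: int
    start_b: int
    end_b: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")

    def __len__(self) -> int:
        return len(self.aligned_a)

    @property
    def n_identical(self) -> int:
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != GAP and x != "N"
        )

    @property
    def identity(self) -> float:
        """Percent identical columns over all alignment columns (0..100)."""
        if len(self.aligned_a) == 0:
            return 0.0
        return 100.0 * self.n_identical / len(self.aligned_a)


class K2PDomainError(ValueError):
    """K2P distance undefined: saturation (log of a non-positive argument)
    or no comparable sites."""


@dataclass(frozen=True)
class K2PResult:
    P: float  # proportion of transition-differing sites
    Q: float  # proportion of transversion-differing sites
    kappa: float  # substitutions per site
    n_sites: int  # ungapped, unambiguous comparable columns


def _substitution_row(a_code: int, b_codes: np.ndarray, s: ScoringScheme) -> np.ndarray:
    """Score of base ``a_code`` against each base of ``b`` (N never matches)."""
    if a_code == 4:  # N
        return np.full(b_codes.shape, s.mismatch, dtype=np.int64)
    row = np.where((b_codes == a_code) & (b_codes != 4), s.match, s.mismatch)
    return row.astype(np.int64)


def _fill_global(a: np.ndarray, b: np.ndarray, s: ScoringScheme) -> np.ndarray:
    n, m = len(a), len(b)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    H[0, :] = s.gap * np.arange(m + 1)
    H[:, 0] = s.gap * np.arange(n + 1)
    if m == 0 or n == 0:
        return H
    offsets = s.gap * np.arange(1, m + 1)
    for i in range(1, n + 1):
        sub = _substitution_row(a[i - 1], b, s)
        cand = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + s.gap)
        run = np.empty(m + 1, dtype=np.int64)
        run[0] = H[i, 0]
        run[1:] = cand - offsets
        np.maximum.accumulate(run, out=run)
        H[i, 1:] = run[1:] + offsets
    return H


def _fill_local(a: np.ndarray, b: np.ndarray, s: ScoringScheme) -> np.ndarray:
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    if m == 0 or n == 0:
        return H
    offsets = s.gap * np.arange(1, m + 1)
    for i in range(1, n + 1):
        sub = _substitution_row(a[i - 1], b, s)
        cand = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + s.gap)
        np.maximum(cand, 0, out=cand)
        run = np.empty(m + 1, dtype=np.int64)
        run[0] = 0
        run[1:] = cand - offsets
        np.maximum.accumulate(run, out=run)
        H[i, 1:] = np.maximum(run[1:] + offsets, 0)
    return H


def _traceback(
    H: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    s: ScoringScheme,
    i: int,
    j: int,
    *,
    local: bool,
) -> tuple[str, str, int, int]:
    """Walk back from (i, j); returns aligned rows and the (i0, j0) origin.

    Tie-break order is fixed: diagonal, then up (gap in b), then left.
    """
    rows_a: list[str] = []
    rows_b: list[str] = []
    sa = decode(a)
    sb = decode(b)
    while True:
        if local and H[i, j] == 0:
            break
        if not local and i == 0 and j == 0:
            break
        if i > 0 and j > 0:
            diag_ok = a[i - 1] == b[j - 1] and a[i - 1] != 4
            sub = s.match if diag_ok else s.mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                rows_a.append(sa[i - 1])
                rows_b.append(sb[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + s.gap:
            rows_a.append(sa[i - 1])
            rows_b.append(GAP)
            i -= 1
            continue
        rows_a.append(GAP)
        rows_b.append(sb[j - 1])
        j -= 1
    return "".join(reversed(rows_a)), "".join(reversed(rows_b)), i, j


def global_align(a: str, b: str, s: ScoringScheme = DEFAULT_SCORING) -> Alignment:
    """Optimal end-to-end alignment of *a* and *b* under scheme *s*.

    Empty inputs are legal: aligning "" to a non-empty string yields an
    all-gap row with the corresponding gap penalty.
    """
    a = clean(a, name="a")
    b = clean(b, name="b")
    ea, eb = encode(a), encode(b)
    H = _fill_global(ea, eb, s)
    aligned_a, aligned_b, i0, j0 = _traceback(
        H, ea, eb, s, len(ea), len(eb), local=False
    )
    assert (i0, j0) == (0, 0)
    return Alignment(
        aligned_a,
        aligned_b,
        int(H[len(ea), len(eb)]),
        0,
        len(a),
        0,
        len(b),
    )


def local_align(a: str, b: str, s: ScoringScheme = DEFAULT_SCORING) -> Alignment:
    """Maximal-scoring local alignment (score >= 0).

    When no pair of substrings scores positively the empty alignment with
    score 0 and empty coordinate intervals is returned.  Among equal-scoring
    cells the first in row-major order is chosen, so results are stable.
    """
    a = clean(a, name="a")
    b = clean(b, name="b")
    ea, eb = encode(a), encode(b)
    H = _fill_local(ea, eb, s)
    best = int(H.max()) if H.size else 0
    if best <= 0:
        return Alignment("", "", 0, 0, 0, 0, 0)
    flat = int(np.argmax(H))  # first maximum in row-major order
    i, j = divmod(flat, H.shape[1])
    aligned_a, aligned_b, i0, j0 = _traceback(H, ea, eb, s, i, j, local=True)
    return Alignment(aligned_a, aligned_b, best, i0, i, j0, j)


def k2p_from_pq(P: float, Q: float) -> float:
    """Kimura two-parameter distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise K2PDomainError(
            f"K2P distance undefined for P={P:.4g}, Q={Q:.4g} (saturated)"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(aln: Alignment) -> K2PResult:
    """K2P distance between the two rows of *aln* with pairwise deletion.

    Columns containing a gap or an ``N`` in either row are excluded.  Raises
    :class:`K2PDomainError` when no comparable column remains or when the
    observed P, Q saturate the model.
    """
    transitions = 0
    transversions = 0
    n_sites = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x in (GAP, "N") or y in (GAP, "N"):
            continue
        n_sites += 1
        if x == y:
            continue
        cx = "ACGT".index(x)
        cy = "ACGT".index(y)
        if is_transition(cx, cy):
            transitions += 1
        else:
            transversions += 1
    if n_sites == 0:
        raise K2PDomainError("no ungapped unambiguous columns to compare")
    P = transitions / n_sites
    Q = transversions / n_sites
    kappa = k2p_from_pq(P, Q)
    return K2PResult(P=P, Q=Q, kappa=kappa, n_sites=n_sites)
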