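"""Nested-insertion discovery and LTR-pair dating.

Full-length LTR retrotransposons carry two LTRs that are identical at
insertion time and diverge neutrally afterwards, so the K2P distance kappa
between the 5' and 3' LTR converts to an insertion age T = kappa / (2 r)
with r the substitution rate per site per year.  The default
r = 6.5e-9 /site/year reproduces the reference kappa -> age conversions
(0.00699 -> 0.54 My, 0.05319 -> 4.09 My, 0.0122 -> 0.94 My,
0.0103 -> 0.79 My) to two decimal My.

Candidate insertions are the gaps between tandem-array islands; each gap
is screened for a target-site duplication (the longest 3-20 nt exact
duplication flanking the gap) and an LTR pair (the best terminal-proximal
local self-match between the gap's first and last thirds).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import alignkit
from ._seq import revcomp
from .arrayfinder import Island

__all__ = [
    "NestedInsertion",
    "InsertionAge",
    "DEFAULT_RATE",
    "age_from_kappa",
    "find_insertions",
    "estimate_age",
]

DEFAULT_RATE = 6.5e-9  # substitutions / site / year
MIN_ELEMENT_LEN = 1000
MIN_LTR_HIT = 100
MIN_LTR_IDENTITY = 80.0


@dataclass
class NestedInsertion:
    """A candidate element between two islands, with TSD and LTR evidence."""

    interval: tuple[int, int]  # genomic, element proper
    tsd: str
    ltr5_interval: tuple[int, int] | None  # genomic
    ltr3_interval: tuple[int, int] | None
    strand: str = "?"

    @property
    def has_ltr_pair(self) -> bool:
        return self.ltr5_interval is not None and self.ltr3_interval is not None


@dataclass
class InsertionAge:
    insertion_ref: NestedInsertion
    kappa: float
    P: float
    Q: float
    n_sites: int
    r: float
    T: float  # years

    @property
    def T_my(self) -> float:
        """Age in million years, rounded to the reported 2 decimals."""
        return round(self.T / 1e6, 2)


def age_from_kappa(kappa: float, r: float = DEFAULT_RATE) -> float:
    """Insertion age in years from an LTR-pair K2P distance: T = kappa/(2r)."""
    if r <= 0:
        raise ValueError("substitution rate r must be positive")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    return kappa / (2.0 * r)


def _find_tsd(
    genome: str,
    gap: tuple[int, int],
    max_len: int = 20,
    max_shift: int = 12,
) -> tuple[str, tuple[int, int]]:
    """Longest exact duplication (3..max_len nt) flanking *gap*.

    The duplication is a left-flank suffix equal to a right-flank prefix.
    Because k-mer-derived gap boundaries can be off by a few bases when a
    mutation sits near the junction, boundaries are allowed to shrink
    inward by up to ``max_shift`` bases (smallest total shift wins);
    returns the TSD string and the refined gap interval ('' and the
    original interval when none is found).
    """
    s, e = gap
    # candidates are scored as length minus a per-base shift penalty, so a
    # boundary correction is only accepted when it buys a decisively longer
    # duplication than anything at the nominal boundary
    best: tuple[float, int, str, tuple[int, int]] | None = None
    for dl in range(0, max_shift + 1):
        for dr in range(0, max_shift + 1):
            s2, e2 = s + dl, e - dr
            if e2 - s2 < 1:
                continue
            for L in range(max_len, 2, -1):
                if s2 - L < 0 or e2 + L > len(genome):
                    continue
                if genome[s2 - L : s2] == genome[e2 : e2 + L]:
                    score = L - 0.6 * (dl + dr)
                    cand = (score, -(dl + dr), genome[s2 - L : s2], (s2, e2))
                    if best is None or cand[:2] > best[:2]:
                        best = cand
                    break
    if best is None:
        return "", gap
    return best[2], best[3]


def _refine_gap(
    genome: str, gap: tuple[int, int], unit_ref: str, pad: int = 40
) -> tuple[int, int]:
    """Snap coverage-derived gap boundaries onto the array/element junctions.

    Seed-and-chain boundaries can fall short of the true junction by up to
    a seed length per nearby mutation.  Locally aligning the doubled repeat
    unit against a window across each boundary locates where array-like
    sequence really ends (left) and resumes (right).
    """
    g0, g1 = gap
    # strict scoring: extending an alignment into non-array sequence has a
    # strongly negative drift, so hits stop within a base or two of the
    # junction, while genuine array sequence still scores ~+0.8/base
    strict = alignkit.ScoringScheme(1, -3, -5)
    # left boundary: array sequence ends at the junction
    w0 = max(0, g0 - pad)
    window = genome[w0 : min(g0 + 2 * pad, g1)]
    aln = alignkit.local_align(window, unit_ref, strict)
    if len(aln) >= 15:
        g0 = max(g0, w0 + aln.end_a)
    # right boundary: array sequence resumes at the junction
    w0 = max(g0, g1 - 2 * pad)
    window = genome[w0 : g1 + pad]
    aln = alignkit.local_align(window, unit_ref, strict)
    if len(aln) >= 15:
        g1 = min(g1, w0 + aln.start_a)
    if g1 <= g0:
        return gap
    return g0, g1


def _find_ltr_pair(
    gap_seq: str,
    terminal_tolerance: int = 50,
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Best local self-match between the first and last thirds of a gap.

    Both hits must be terminal-proximal (within ``terminal_tolerance`` of
    the respective gap end), at least ``MIN_LTR_HIT`` nt and
    ``MIN_LTR_IDENTITY`` percent identical; returns intervals within the
    gap, or None.
    """
    n = len(gap_seq)
    third = n // 3
    if third < MIN_LTR_HIT:
        return None
    head = gap_seq[:third]
    tail = gap_seq[n - third :]
    aln = alignkit.local_align(head, tail)
    if len(aln) == 0 or aln.identity < MIN_LTR_IDENTITY:
        return None
    if (aln.end_a - aln.start_a) < MIN_LTR_HIT:
        return None
    if aln.start_a > terminal_tolerance or (third - aln.end_b) > terminal_tolerance:
        return None
    ltr5 = (aln.start_a, aln.end_a)
    ltr3 = (n - third + aln.start_b, n - third + aln.end_b)
    return ltr5, ltr3


def _orientation(seq_a: str, seq_b: str) -> str:
    """Relative orientation of two candidate element sequences.

    Returns '+' when the forward-forward local alignment outscores
    forward-reverse, '-' otherwise.
    """
    fwd = alignkit.local_align(seq_a, seq_b).score
    rev = alignkit.local_align(seq_a, revcomp(seq_b)).score
    return "+" if fwd >= rev else "-"


def find_insertions(
    genome: str,
    islands: list[Island],
    unit: str | None = None,
    element_ref: str | None = None,
    min_element_len: int = MIN_ELEMENT_LEN,
    max_tsd_len: int = 20,
) -> list[NestedInsertion]:
    """Candidate nested insertions in the gaps between consecutive islands.

    Each inter-island gap of at least ``min_element_len`` is screened for a
    flanking TSD and an LTR pair.  When the reference repeat *unit* is
    given, gap boundaries are first refined onto the array/element
    junctions.  Candidate strand is assigned against ``element_ref`` when
    given; otherwise candidates are oriented relative to the first
    candidate (which is reported as '+').
    """
    islands = sorted(islands, key=lambda i: i.interval)
    out: list[NestedInsertion] = []
    for left, right in zip(islands, islands[1:]):
        g0, g1 = left.interval[1], right.interval[0]
        if g1 - g0 < min_element_len:
            continue
        if unit is not None:
            unit_ref = unit + unit
            if left.array_ref.strand == "-":
                unit_ref = revcomp(unit_ref)
            g0, g1 = _refine_gap(genome, (g0, g1), unit_ref)
        tsd, (g0, g1) = _find_tsd(genome, (g0, g1), max_len=max_tsd_len)
        gap_seq = genome[g0:g1]
        pair = _find_ltr_pair(gap_seq)
        if pair is None:
            ltr5 = ltr3 = None
        else:
            (a0, a1), (b0, b1) = pair
            ltr5 = (g0 + a0, g0 + a1)
            ltr3 = (g0 + b0, g0 + b1)
        out.append(
            NestedInsertion(
                interval=(g0, g1), tsd=tsd, ltr5_interval=ltr5, ltr3_interval=ltr3
            )
        )
    if element_ref is not None:
        for ins in out:
            ins.strand = _orientation(
                element_ref, genome[ins.interval[0] : ins.interval[1]]
            )
    elif out:
        first_seq = genome[out[0].interval[0] : out[0].interval[1]]
        out[0].strand = "+"
        for ins in out[1:]:
            ins.strand = _orientation(
                first_seq, genome[ins.interval[0] : ins.interval[1]]
            )
    return out


def estimate_age(
    ins: NestedInsertion,
    genome: str,
    r: float = DEFAULT_RATE,
) -> InsertionAge:
    """Date an insertion from the K2P distance of its LTR pair.

    The two LTRs are globally aligned, kappa computed with pairwise
    deletion, and T = kappa / (2 r).  Raises when the candidate lacks an
    LTR pair or when kappa is undefined (saturation).
    """
    if r <= 0:
        raise ValueError("substitution rate r must be positive")
    if not ins.has_ltr_pair:
        raise ValueError("insertion candidate has no LTR pair to date")
    s5, e5 = ins.ltr5_interval
    s3, e3 = ins.ltr3_interval
    aln = alignkit.global_align(genome[s5:e5], genome[s3:e3])
    k2p = alignkit.k2p_distance(aln)
    T = age_from_kappa(k2p.kappa, r)
    return InsertionAge(
        insertion_ref=ins,
        kappa=k2p.kappa,
        P=k2p.P,
        Q=k2p.Q,
        n_sites=k2p.n_sites,
        r=r,
        T=T,
    )
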