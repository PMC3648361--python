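"""Detection and decomposition of tandem arrays homologous to a repeat unit.

Given a genome and a reference repeat unit, this module finds tandem arrays
on either strand by exact k-mer seeding and collinear chaining, segments
each array into uninterrupted islands, cuts islands into phase-normalized
monomers at recurrences of the unit-start anchor, and measures internal
sequence periodicity by lagged self-match autocorrelation.

All coordinates are 0-based half-open on the forward strand; GFF3 output
(see :mod:`retrotandem.io`) converts to 1-based closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import alignkit
from ._seq import clean, encode, revcomp

log = logging.getLogger(__name__)

__all__ = [
    "ArrayHit",
    "Island",
    "Monomer",
    "PeriodicityReport",
    "find_arrays",
    "segment_islands",
    "extract_monomers",
    "find_periodicity",
]

DEFAULT_KMER = 13


@dataclass
class ArrayHit:
    """A chained homology hit covering a candidate tandem array."""

    target_id: str
    interval: tuple[int, int]
    strand: str  # "+" or "-"
    n_monomer_equivalents: float
    mean_identity: float
    match_mask: np.ndarray = field(repr=False)  # bool, over interval


@dataclass
class Island:
    """An uninterrupted run of matching sequence within an array."""

    array_ref: ArrayHit
    interval: tuple[int, int]
    n_full_monomers: int = 0


@dataclass
class Monomer:
    """One extracted repeat unit, phase-normalized to the reference start."""

    id: str
    island_ref: Island
    interval: tuple[int, int]
    strand: str
    sequence: str
    full_length: bool

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class PeriodicityReport:
    period: int | None
    n_copies: float
    secondary_period: int | None


# ---------------------------------------------------------------------------
# array detection
# ---------------------------------------------------------------------------


def _kmer_positions(seq: str, kmers: set[str], k: int) -> np.ndarray:
    """Boolean per-base mask of positions covered by any matching k-mer."""
    mask = np.zeros(len(seq), dtype=bool)
    for i in range(len(seq) - k + 1):
        if seq[i : i + k] in kmers:
            mask[i : i + k] = True
    return mask


def _unit_kmers(unit: str, k: int) -> set[str]:
    # the doubled unit also yields the k-mers spanning the tandem junction
    doubled = unit + unit[: k - 1]
    return {doubled[i : i + k] for i in range(len(unit))}


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array, as half-open intervals."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(
    runs: list[tuple[int, int]], max_gap: int
) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe < max_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def _chain_identity(
    seq: str, span: tuple[int, int], unit: str, strand: str, n_windows: int = 5
) -> float:
    """Mean percent identity of sampled unit-length windows vs the unit.

    Windows start at arbitrary phase, so each is locally aligned against the
    doubled unit, which contains every rotation of the unit.
    """
    s, e = span
    ulen = len(unit)
    ref = unit + unit
    if strand == "-":
        seq_span = revcomp(seq[s:e])
    else:
        seq_span = seq[s:e]
    span_len = len(seq_span)
    n = min(n_windows, max(1, span_len // ulen))
    idents = []
    for i in range(n):
        w0 = (span_len - ulen) * i // max(1, n - 1) if n > 1 else 0
        w0 = max(0, min(w0, span_len - ulen))
        window = seq_span[w0 : w0 + ulen]
        if not window:
            continue
        aln = alignkit.local_align(window, ref)
        if len(aln) == 0:
            idents.append(0.0)
        else:
            idents.append(aln.identity)
    return float(np.mean(idents)) if idents else 0.0


def find_arrays(
    genome: dict[str, str],
    unit: str,
    min_identity: float = 80.0,
    min_monomers: int = 2,
    k: int = DEFAULT_KMER,
    chain_gap: int | None = None,
) -> list[ArrayHit]:
    """Find tandem arrays homologous to *unit* on both strands.

    Exact k-mer seeds against the unit (doubled, so junction-spanning
    k-mers count) mark matching bases; runs of matching sequence closer
    than ``chain_gap`` (default: one unit length) are chained; chains
    covering at least ``min_monomers`` unit-equivalents and
    ``min_identity`` percent mean identity are reported.  Pass a larger
    ``chain_gap`` to keep an array interrupted by nested insertions as a
    single hit, then split it with :func:`segment_islands`.
    """
    unit = clean(unit, name="unit")
    if len(unit) < 50:
        raise ValueError("reference unit must be at least 50 nt")
    fwd = _unit_kmers(unit, k)
    rev = _unit_kmers(revcomp(unit), k)
    if chain_gap is None:
        chain_gap = len(unit)
    hits: list[ArrayHit] = []
    for name, seq in genome.items():
        seq = clean(seq, name=name)
        fwd_mask = _kmer_positions(seq, fwd, k)
        rev_mask = _kmer_positions(seq, rev, k)
        both = fwd_mask | rev_mask
        for s, e in _merge_runs(_runs(both), max_gap=chain_gap):
            # unit-equivalents from island-level matched span: sub-unit gaps
            # (divergence) count as matching, unit-scale gaps (insertions) don't
            inner = _merge_runs(_runs(both[s:e]), max_gap=len(unit))
            n_equiv = sum(b - a for a, b in inner) / len(unit)
            if n_equiv < min_monomers:
                continue
            strand = "+" if fwd_mask[s:e].sum() >= rev_mask[s:e].sum() else "-"
            ident = _chain_identity(seq, (s, e), unit, strand)
            if ident < min_identity:
                continue
            hits.append(
                ArrayHit(
                    target_id=name,
                    interval=(s, e),
                    strand=strand,
                    n_monomer_equivalents=n_equiv,
                    mean_identity=ident,
                    match_mask=both[s:e].copy(),
                )
            )
    return hits


def segment_islands(
    hit: ArrayHit,
    match_mask: np.ndarray | None = None,
    gap_min: int | None = None,
    unit_length: int | None = None,
) -> list[Island]:
    """Split an array hit into islands at long non-matching gaps.

    Maximal matching runs separated by at least ``gap_min`` non-matching
    bases (default: one unit length, approximated by the hit's span per
    monomer equivalent when ``unit_length`` is not given) become distinct
    islands.
    """
    if match_mask is None:
        match_mask = hit.match_mask
    s0 = hit.interval[0]
    if gap_min is None:
        if unit_length is None:
            unit_length = int(
                (hit.interval[1] - hit.interval[0])
                / max(hit.n_monomer_equivalents, 1.0)
            )
        gap_min = unit_length
    merged = _merge_runs(_runs(np.asarray(match_mask, dtype=bool)), max_gap=gap_min)
    return [Island(hit, (s0 + s, s0 + e)) for s, e in merged]


# ---------------------------------------------------------------------------
# monomer extraction
# ---------------------------------------------------------------------------


def _anchor_scores(seq: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Match count of *anchor* at every offset of *seq* (vectorized)."""
    n, m = len(seq), len(anchor)
    if n < m:
        return np.zeros(0, dtype=np.int32)
    scores = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        scores += (seq[j : n - m + 1 + j] == anchor[j]).astype(np.int32)
    return scores


def extract_monomers(
    island: Island,
    unit: str,
    genome_seq: str,
    flen_frac: float = 0.9,
    anchor_len: int = 32,
    anchor_min_frac: float = 0.7,
) -> list[Monomer]:
    """Partition an island into monomers at recurrences of the unit start.

    The phase anchor is the first ``anchor_len`` bases of the reference
    unit; positions matching it at >= ``anchor_min_frac`` identity, kept as
    local maxima at least half a unit apart, become monomer start cuts.
    Segments between cuts are monomers; a segment is flagged full-length
    when it starts at a cut and spans at least ``flen_frac`` of the unit.
    Edge segments before the first cut are retained as partials.
    """
    unit = clean(unit, name="unit")
    s0, e0 = island.interval
    strand = island.array_ref.strand
    island_seq = genome_seq[s0:e0]
    if strand == "-":
        island_seq = revcomp(island_seq)
    if len(island_seq) < len(unit):
        log.warning(
            "island %s shorter than one unit (%d < %d); no monomers",
            island.interval,
            len(island_seq),
            len(unit),
        )
        return []
    anchor = encode(unit[:anchor_len])
    scores = _anchor_scores(encode(island_seq), anchor)
    thresh = anchor_min_frac * len(anchor)
    min_sep = max(2 * len(anchor), len(unit) // 2)
    cuts: list[int] = []
    order = np.argsort(scores, kind="stable")[::-1]
    taken = np.zeros(len(scores), dtype=bool)
    for pos in order:
        if scores[pos] < thresh:
            break
        if taken[max(0, pos - min_sep) : pos + min_sep].any():
            continue
        taken[pos] = True
        cuts.append(int(pos))
    cuts.sort()
    if not cuts:
        log.warning("no phase anchor found in island %s", island.interval)
        return []

    monomers: list[Monomer] = []
    bounds = []
    if cuts[0] >= 20:  # leading segment (an edge-clipped or partial monomer)
        bounds.append((0, cuts[0]))
    for a, b in zip(cuts, cuts[1:]):
        bounds.append((a, b))
    bounds.append((cuts[-1], len(island_seq)))

    n_full = 0
    for a, b in bounds:
        if b - a < 10:
            continue
        full = (b - a) >= flen_frac * len(unit)
        if full:
            n_full += 1
        if strand == "+":
            g_iv = (s0 + a, s0 + b)
        else:
            g_iv = (e0 - b, e0 - a)
        monomers.append(
            Monomer(
                id=f"{island.array_ref.target_id}:{g_iv[0]}-{g_iv[1]}({strand})",
                island_ref=island,
                interval=g_iv,
                strand=strand,
                sequence=island_seq[a:b],
                full_length=full,
            )
        )
    island.n_full_monomers = n_full
    if strand == "-":
        monomers.reverse()  # report in forward-genome coordinate order
    return monomers


# ---------------------------------------------------------------------------
# periodicity
# ---------------------------------------------------------------------------


def find_periodicity(
    seq: str,
    kmin: int = 2,
    kmax: int = 100,
    threshold: float = 0.6,
    margin: float = 0.15,
) -> PeriodicityReport:
    """Dominant internal period of *seq* by lagged self-match autocorrelation.

    For each lag in [kmin, kmax] the fraction of positions i with
    seq[i] == seq[i+lag] is computed.  The period is the smallest lag whose
    autocorrelation lies within ``margin`` of the maximum (so a fundamental
    beats its own harmonics); a 2x harmonic scoring within ``margin`` of
    the period's own score is reported as ``secondary_period`` — the
    signature of composite higher-order repeats.  Returns period ``None``
    when the best autocorrelation is below ``threshold``.
    """
    seq = clean(seq)
    if kmin < 2:
        raise ValueError("kmin must be >= 2")
    if len(seq) < 2 * kmin:
        raise ValueError("region must be at least 2*kmin long")
    arr = encode(seq)
    kmax = min(kmax, len(seq) - 1)
    lags = np.arange(kmin, kmax + 1)
    ac = np.array(
        [float(np.mean(arr[:-lag] == arr[lag:])) for lag in lags]
    )
    best = float(ac.max())
    if best < threshold:
        return PeriodicityReport(period=None, n_copies=0.0, secondary_period=None)
    # smallest lag within margin of the maximum = the fundamental
    within = np.nonzero(ac >= best - margin)[0]
    period = int(lags[within[0]])
    period_score = float(ac[within[0]])
    secondary = None
    lag2 = 2 * period
    if kmin <= lag2 <= kmax:
        score2 = float(ac[lag2 - kmin])
        if score2 >= period_score - margin:
            secondary = lag2
    n_copies = len(seq) / period
    return PeriodicityReport(
        period=period, n_copies=n_copies, secondary_period=secondary
    )
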