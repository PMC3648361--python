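"""Monomer architecture, consensus building, diagnostic SNPs and haplotypes.

A monomer of a retrotransposon-derived tandem repeat decomposes into a
start sequence (S), one to several tandem internal-repeat copies (IR) and
an end variant (E_A or E_B, inherited from one of two parent alleles).
This module annotates that architecture by local alignment of domain
references, builds anchor-projected (star-alignment) consensus profiles,
selects diagnostic SNP columns that separate two monomer groups (loci),
and tabulates per-region haplotypes — including position-specific calls
for multi-copy IR regions (IR.c1, IR.c2, ...).

Star alignment to an anchor is used instead of a progressive MSA: the
monomers handled here are >= 95% identical, where anchor projection is
adequate and, unlike heuristic MSA, deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alignkit
from ._seq import clean
from .arrayfinder import Monomer

__all__ = [
    "DomainAnnotation",
    "ConsensusProfile",
    "HaplotypeCall",
    "DiagnosticPanel",
    "build_consensus",
    "decompose_monomer",
    "mask_low_complexity",
    "select_diagnostic_snps",
    "call_haplotypes",
]

IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass
class DomainAnnotation:
    """A monomer's domain architecture, e.g. ``S-IR×3-E_A``."""

    monomer_ref: str | None
    architecture: str
    domains: list[tuple[str, tuple[int, int]]]
    partial: bool

    @property
    def ir_count(self) -> int:
        return sum(1 for lab, _ in self.domains if lab == "IR")


@dataclass
class ConsensusProfile:
    """Anchor-projected alignment profile of a set of monomer sequences.

    ``matrix`` holds one row per input sequence over all anchor columns
    ('-' where a sequence has no base); ``kept_columns`` are the anchor
    columns retained in the consensus (gap in <= 50% of sequences);
    ``coords`` gives each cell's ungapped coordinate in its own sequence
    (-1 at gaps), which lets a consensus column be mapped back onto any
    monomer.
    """

    sequence: str
    depth: np.ndarray
    kept_columns: np.ndarray
    matrix: np.ndarray = field(repr=False)  # (n_seqs, n_anchor_cols) of chars
    coords: np.ndarray = field(repr=False)  # (n_seqs, n_anchor_cols) int

    @property
    def column_map(self) -> np.ndarray:
        """Consensus column -> anchor column index."""
        return self.kept_columns

    def column_bases(self, consensus_col: int) -> np.ndarray:
        return self.matrix[:, self.kept_columns[consensus_col]]

    def column_coords(self, consensus_col: int) -> np.ndarray:
        return self.coords[:, self.kept_columns[consensus_col]]


@dataclass
class HaplotypeCall:
    monomer_ref: str
    region_label: str
    haplotype: str
    complete: bool


@dataclass
class DiagnosticPanel:
    """Consensus columns whose group-major alleles separate two groups."""

    region_label: str
    columns: list[int]
    group_major_alleles: list[tuple[str, str]]
    concordance: list[float]

    def __len__(self) -> int:
        return len(self.columns)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def build_consensus(
    monomer_sequences: list[str], anchor: str | None = None
) -> ConsensusProfile:
    """Star-align sequences to an anchor and take per-column majorities.

    When no anchor is given the longest input (first among ties) is used.
    Per column the majority base wins; ties among top bases are encoded as
    IUPAC ambiguity; columns that are gap in more than half the sequences
    are dropped from the consensus string but remain addressable through
    ``matrix``/``coords``.
    """
    if not monomer_sequences:
        raise ValueError("need at least one sequence")
    seqs = [clean(s) for s in monomer_sequences]
    if anchor is None:
        anchor = max(seqs, key=len)
    else:
        anchor = clean(anchor, name="anchor")
    n, m = len(seqs), len(anchor)
    matrix = np.full((n, m), "-", dtype="<U1")
    coords = np.full((n, m), -1, dtype=np.int64)
    for r, seq in enumerate(seqs):
        if seq == anchor:  # common fast path
            matrix[r, :] = list(seq)
            coords[r, :] = np.arange(m)
            continue
        aln = alignkit.global_align(seq, anchor)
        ai = 0  # ungapped position in seq
        bj = 0  # ungapped position in anchor
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if y != alignkit.GAP:
                if x != alignkit.GAP:
                    matrix[r, bj] = x
                    coords[r, bj] = ai
                bj += 1
            if x != alignkit.GAP:
                ai += 1

    kept: list[int] = []
    cons: list[str] = []
    depth: list[int] = []
    for j in range(m):
        col = matrix[:, j]
        gaps = int(np.sum(col == "-"))
        if gaps * 2 > n:
            continue
        bases, counts = np.unique(col[col != "-"], return_counts=True)
        top = counts.max()
        tied = frozenset(str(b) for b, c in zip(bases, counts) if c == top)
        cons.append(IUPAC[frozenset("".join(tied) or "N")])
        depth.append(n - gaps)
        kept.append(j)
    return ConsensusProfile(
        sequence="".join(cons),
        depth=np.array(depth, dtype=np.int64),
        kept_columns=np.array(kept, dtype=np.int64),
        matrix=matrix,
        coords=coords,
    )


# ---------------------------------------------------------------------------
# domain decomposition
# ---------------------------------------------------------------------------


def _domain_hits(
    ref: str,
    monomer: str,
    scoring: alignkit.ScoringScheme,
    identity_min: float,
    min_cover: float,
    max_hits: int = 8,
) -> list[tuple[int, tuple[int, int]]]:
    """Non-overlapping local hits of *ref* in *monomer*: (score, interval).

    Repeated masking finds each tandem copy in turn; a hit qualifies when
    it covers at least ``min_cover`` of the reference at ``identity_min``
    percent identity.
    """
    hits: list[tuple[int, tuple[int, int]]] = []
    work = monomer
    for _ in range(max_hits):
        aln = alignkit.local_align(ref, work, scoring)
        if len(aln) == 0:
            break
        if aln.identity < identity_min or (aln.end_a - aln.start_a) < min_cover * len(
            ref
        ):
            break
        hits.append((aln.score, (aln.start_b, aln.end_b)))
        work = work[: aln.start_b] + "N" * (aln.end_b - aln.start_b) + work[aln.end_b :]
    return hits


def decompose_monomer(
    m: Monomer | str,
    refs: dict[str, str],
    scoring: alignkit.ScoringScheme = alignkit.DEFAULT_SCORING,
    identity_min: float = 70.0,
    min_cover: float = 0.5,
    e_tie_margin: float = 0.05,
) -> DomainAnnotation:
    """Annotate a monomer's S / IR×k / E architecture.

    Each reference in *refs* (keys among S, IR, E, E_A, E_B) is locally
    aligned against the monomer; non-overlapping hits above threshold are
    greedily selected by score.  The end domain is assigned to whichever of
    E_A/E_B scores higher; scores within ``e_tie_margin`` of each other
    yield the non-committal label ``E_?`` so recombinants are not
    overcalled.
    """
    if isinstance(m, Monomer):
        seq, ref_id = m.sequence, m.id
    else:
        seq, ref_id = clean(m), None
    if not refs:
        raise ValueError("refs must be non-empty")

    candidates: list[tuple[int, str, tuple[int, int]]] = []
    e_best: dict[str, tuple[int, tuple[int, int]]] = {}
    for label, ref in refs.items():
        multi = label == "IR"
        found = _domain_hits(
            clean(ref, name=label), seq, scoring, identity_min, min_cover,
            max_hits=8 if multi else 1,
        )
        if label in ("E", "E_A", "E_B"):
            if found:
                e_best[label] = found[0]
            continue
        for score, iv in found:
            candidates.append((score, label, iv))

    if e_best:
        sa = e_best.get("E_A", (0, None))[0]
        sb = e_best.get("E_B", (0, None))[0]
        if "E_A" in e_best or "E_B" in e_best:
            hi = max(sa, sb)
            if sa and sb and abs(sa - sb) <= e_tie_margin * hi:
                label = "E_?"
                iv = e_best["E_A"][1] if sa >= sb else e_best["E_B"][1]
                candidates.append((hi, label, iv))
            elif sa >= sb and "E_A" in e_best:
                candidates.append((sa, "E_A", e_best["E_A"][1]))
            else:
                candidates.append((sb, "E_B", e_best["E_B"][1]))
        if "E" in e_best:
            score, iv = e_best["E"]
            candidates.append((score, "E", iv))

    # greedy non-overlapping selection by score
    selected: list[tuple[str, tuple[int, int]]] = []
    for score, label, iv in sorted(candidates, key=lambda t: (-t[0], t[2])):
        s, e = iv
        overlap = any(
            min(e, e2) - max(s, s2) > 0.2 * min(e - s, e2 - s2)
            for _, (s2, e2) in selected
        )
        if not overlap:
            selected.append((label, iv))
    selected.sort(key=lambda t: t[1])

    k = sum(1 for lab, _ in selected if lab == "IR")
    has_s = any(lab == "S" for lab, _ in selected)
    e_label = next((lab for lab, _ in selected if lab.startswith("E")), None)
    parts: list[str] = []
    if has_s:
        parts.append("S")
    if k:
        parts.append(f"IR×{k}")
    if e_label:
        parts.append(e_label)
    architecture = "-".join(parts) if parts else "?"
    partial = not (has_s and e_label and k >= 1)
    return DomainAnnotation(
        monomer_ref=ref_id,
        architecture=architecture,
        domains=selected,
        partial=partial,
    )


# ---------------------------------------------------------------------------
# low-complexity masking
# ---------------------------------------------------------------------------


def mask_low_complexity(
    seq: str, base: str = "A", min_len: int = 10, min_frac: float = 0.8
) -> list[tuple[int, int]]:
    """Maximal base-rich windows, e.g. the polymorphic A-rich IR tails.

    Windows of length >= ``min_len`` with at least ``min_frac`` of *base*
    are reported (merged and greedily extended while the fraction holds).
    Downstream SNP selection should exclude these intervals.
    """
    if min_len < 4:
        raise ValueError("min_len must be >= 4")
    seq = clean(seq)
    n = len(seq)
    if n < min_len:
        return []
    hit = np.array([c == base for c in seq], dtype=np.int64)
    csum = np.concatenate(([0], np.cumsum(hit)))
    windows = [
        (i, i + min_len)
        for i in range(n - min_len + 1)
        if csum[i + min_len] - csum[i] >= min_frac * min_len
    ]
    if not windows:
        return []
    merged: list[list[int]] = [list(windows[0])]
    for s, e in windows[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    def frac(s: int, e: int) -> float:
        return (csum[e] - csum[s]) / (e - s)

    out: list[tuple[int, int]] = []
    for s, e in merged:
        while e < n and frac(s, e + 1) >= min_frac:
            e += 1
        while s > 0 and frac(s - 1, e) >= min_frac:
            s -= 1
        out.append((s, e))
    # extension can re-join neighbours
    final = [out[0]]
    for s, e in out[1:]:
        if s <= final[-1][1]:
            final[-1] = (final[-1][0], max(final[-1][1], e))
        else:
            final.append((s, e))
    return final


# ---------------------------------------------------------------------------
# diagnostic SNPs and haplotypes
# ---------------------------------------------------------------------------


def select_diagnostic_snps(
    profile: ConsensusProfile,
    group_labels: list[str],
    concordance_min: float = 0.7,
    region_label: str = "S",
    masked_columns: set[int] | None = None,
) -> DiagnosticPanel:
    """Consensus columns whose group-major alleles differ between two groups.

    A column qualifies when each group's majority symbol is a real base
    (not a gap), reaches within-group frequency >= ``concordance_min``, and
    the two majorities differ.  ``masked_columns`` (consensus indices, e.g.
    from :func:`mask_low_complexity`) are excluded.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != profile.matrix.shape[0]:
        raise ValueError("one group label per profiled sequence required")
    uniq = sorted(set(group_labels))
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    g1 = labels == uniq[0]
    g2 = labels == uniq[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each group needs at least 2 members")
    masked_columns = masked_columns or set()

    columns: list[int] = []
    majors: list[tuple[str, str]] = []
    concord: list[float] = []
    for c in range(len(profile.sequence)):
        if c in masked_columns:
            continue
        col = profile.column_bases(c)
        picks = []
        for g in (g1, g2):
            bases, counts = np.unique(col[g], return_counts=True)
            i = int(np.argmax(counts))
            picks.append((str(bases[i]), counts[i] / int(g.sum())))
        (b1, f1), (b2, f2) = picks
        if b1 == "-" or b2 == "-" or b1 == b2:
            continue
        if f1 >= concordance_min and f2 >= concordance_min:
            columns.append(c)
            majors.append((b1, b2))
            concord.append(float(min(f1, f2)))
    return DiagnosticPanel(region_label, columns, majors, concord)


def call_haplotypes(
    profile: ConsensusProfile,
    panel: DiagnosticPanel,
    monomer_ids: list[str] | None = None,
) -> tuple[list[HaplotypeCall], pd.DataFrame]:
    """Concatenate each monomer's bases at panel columns into a haplotype.

    Returns the per-monomer calls and a frequency table (haplotype, count,
    percent) over complete calls; monomers missing a panel base (gap or
    ambiguity) are flagged ``complete=False`` and tabulated separately
    under percent ``NaN``.
    """
    if not panel.columns:
        raise ValueError("panel is empty")
    n = profile.matrix.shape[0]
    if monomer_ids is None:
        monomer_ids = [f"m{i}" for i in range(n)]
    calls: list[HaplotypeCall] = []
    for i in range(n):
        hap = "".join(str(profile.column_bases(c)[i]) for c in panel.columns)
        complete = all(ch in "ACGT" for ch in hap)
        calls.append(HaplotypeCall(monomer_ids[i], panel.region_label, hap, complete))
    rows = []
    complete_calls = [c for c in calls if c.complete]
    counts = pd.Series([c.haplotype for c in complete_calls]).value_counts()
    total = len(complete_calls)
    for hap, cnt in counts.items():
        rows.append(
            {
                "region": panel.region_label,
                "haplotype": hap,
                "count": int(cnt),
                "percent": 100.0 * cnt / total,
                "complete": True,
            }
        )
    incomplete = [c for c in calls if not c.complete]
    if incomplete:
        inc_counts = pd.Series([c.haplotype for c in incomplete]).value_counts()
        for hap, cnt in inc_counts.items():
            rows.append(
                {
                    "region": panel.region_label,
                    "haplotype": hap,
                    "count": int(cnt),
                    "percent": float("nan"),
                    "complete": False,
                }
            )
    table = pd.DataFrame(
        rows, columns=["region", "haplotype", "count", "percent", "complete"]
    )
    return calls, table
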