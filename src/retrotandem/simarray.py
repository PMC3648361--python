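"""Forward simulator of retrotransposon-derived tandem-repeat arrays.

The model: a tandem repeat is born when sequential intrastrand deletions
splice part of an element's LTR to part of its UTR (an LTR-UTR~LTR
structure); the resulting seed monomer is then amplified by non-allelic gene
conversion (modelled as tandem block duplications), diverges neutrally,
acquires locus-specific SNP haplotypes, variable internal-repeat copy
number, donor-allele conversion tracts from a second parent allele, and
nested retrotransposon insertions with target-site duplications and
independently diverging LTR pairs.

The simulator emits the final genomic sequence together with a
machine-readable truth record (:class:`ArrayTruth`), so every downstream
detector in this package can be scored by parameter recovery.  All
randomness flows through one ``numpy`` generator seeded from
:class:`SimConfig`, drawn in a fixed order, so identical configurations
yield byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import clean, revcomp

__all__ = [
    "ParentModel",
    "SimConfig",
    "HaplotypePanelSpec",
    "TractTruth",
    "InsertionTruth",
    "ArrayTruth",
    "SimResult",
    "make_parent_pair",
    "default_seed_monomer",
    "splice_seed",
    "grow_array",
    "replay_events",
    "mutate",
    "inject_variation",
    "inject_haplotypes",
    "parent_diagnostic_sites",
    "assemble",
    "insert_nested_te",
    "simulate",
]

# Canonical toy-parent layout (0-based half-open, total 7000 nt).
PARENT_LEN = 7000
LTR5 = (0, 600)
UTR = (600, 1400)
INTERNAL = (1400, 6400)
LTR3 = (6400, 7000)
TATA_OFFSET = 20
# The seed monomer spans the LTR tail through the UTR head: an S start
# sequence, one internal repeat (IR) and an end sequence (E), mirroring the
# ~402 + ~100 + ~185 nt layout of the repeat this models.
SEED_SPAN = (198, 885)
S_REF = (198, 600)
IR_REF = (600, 700)
E_REF = (700, 885)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class ParentModel:
    """A parent retrotransposon: sequence, landmark intervals, domain refs."""

    allele_label: str  # "A" or "B"
    sequence: str
    ltr5: tuple[int, int]
    utr: tuple[int, int]
    internal: tuple[int, int]
    ltr3: tuple[int, int]
    domain_refs: dict[str, tuple[int, int]]
    tata_offset: int = TATA_OFFSET

    def __post_init__(self) -> None:
        if self.allele_label not in ("A", "B"):
            raise ValueError("allele_label must be 'A' or 'B'")
        spans = [self.ltr5, self.utr, self.internal, self.ltr3]
        prev_end = 0
        for s, e in spans:
            if not (prev_end <= s < e <= len(self.sequence)):
                raise ValueError("parent intervals must be ordered and in range")
            prev_end = e

    def domain_sequence(self, label: str) -> str:
        s, e = self.domain_refs[label]
        return self.sequence[s:e]


@dataclass(frozen=True)
class HaplotypePanelSpec:
    """Diagnostic-SNP injection: per-group alleles at fixed S-region sites.

    ``group_alleles`` maps a group (locus) label to the allele string its
    major haplotype carries at the panel sites; ``major_fraction`` is the
    fraction of monomers carrying the major haplotype unperturbed, the rest
    differ from it at one random panel site.
    """

    group_alleles: dict[str, str]
    major_fraction: float = 0.76
    n_sites: int | None = None

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.group_alleles.values()}
        if len(lengths) != 1:
            raise ValueError("all group allele strings must share one length")
        if not 0.0 <= self.major_fraction <= 1.0:
            raise ValueError("major_fraction must lie in [0, 1]")

    @property
    def size(self) -> int:
        return len(next(iter(self.group_alleles.values())))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of one simulation run.

    ``ir_copy_distribution`` defaults to the observed locus-II copy-number
    mixture (1:2/90, 2:22/90, 3:60/90, 4:6/90); ``donor_tract_prob``
    defaults to the observed ~68% recombinant-monomer fraction; tract
    lengths are shifted-geometric with a 71 bp floor and 150 bp mean,
    matching the 71 bp minimal / ~200 bp maximal converted region.
    """

    seed: int = 0
    mu: float = 6.5e-9  # substitutions / site / year
    tstv: float = 2.0  # transition/transversion ratio (math.inf allowed)
    n_expansion_events: int = 0  # 0 = grow until n_monomers_target
    tract_len_mean: float = 150.0
    tract_len_min: int = 71
    n_monomers_target: int = 30
    ir_copy_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 2 / 90, 2: 22 / 90, 3: 60 / 90, 4: 6 / 90}
    )
    donor_tract_prob: float = 0.68
    nested_insertions: tuple[tuple[float, int, int], ...] = ()  # (age, len, tsd)
    nested_share_template: bool = False  # same element inserted repeatedly
    array_age_years: float = 0.0
    parent_divergence: float = 0.08
    flank_len: int = 1000
    nested_ltr_len: int = 1000
    snp_panel: HaplotypePanelSpec | None = None
    locus_label: str = "II"

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.n_monomers_target < 0 or self.n_expansion_events < 0:
            raise ValueError("counts must be >= 0")
        probs = list(self.ir_copy_distribution.values())
        if probs and (min(probs) < 0 or abs(sum(probs) - 1.0) > 1e-9):
            raise ValueError("ir_copy_distribution must be a probability vector")
        if not 0.0 <= self.donor_tract_prob <= 1.0:
            raise ValueError("donor_tract_prob must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        # YAML 1.1 reads exponents like 2.0e6 as strings; coerce numerics
        for key in ("mu", "tstv", "tract_len_mean", "donor_tract_prob",
                    "array_age_years", "parent_divergence"):
            if key in d:
                d[key] = float(d[key])
        for key in ("seed", "n_expansion_events", "tract_len_min",
                    "n_monomers_target", "flank_len", "nested_ltr_len"):
            if key in d:
                d[key] = int(d[key])
        if "ir_copy_distribution" in d:
            d["ir_copy_distribution"] = {
                int(k): float(v) for k, v in d["ir_copy_distribution"].items()
            }
        if "nested_insertions" in d:
            d["nested_insertions"] = tuple(
                (float(a), int(l), int(t)) for a, l, t in d["nested_insertions"]
            )
        if d.get("snp_panel") is not None:
            d["snp_panel"] = HaplotypePanelSpec(**d["snp_panel"])
        return cls(**d)


@dataclass
class TractTruth:
    monomer_index: int
    donor: str  # "A" or "B"
    start: int  # monomer-local, 0-based half-open
    end: int


@dataclass
class InsertionTruth:
    start: int  # genomic, element proper (TSD copies flank it)
    end: int
    tsd: str
    ltr5: tuple[int, int]  # genomic
    ltr3: tuple[int, int]
    kappa_expected: float
    age_years: float
    strand: str


@dataclass
class ArrayTruth:
    """Ground truth emitted alongside the simulated sequence."""

    monomer_intervals: list[tuple[int, int]] = field(default_factory=list)
    monomer_haplotypes: list[str] = field(default_factory=list)
    domain_maps: list[list[tuple[str, tuple[int, int]]]] = field(default_factory=list)
    tracts: list[TractTruth] = field(default_factory=list)
    insertions: list[InsertionTruth] = field(default_factory=list)
    island_boundaries: list[tuple[int, int]] = field(default_factory=list)
    monomer_seqs: list[str] = field(default_factory=list)
    events: list[tuple[int, int, int]] = field(default_factory=list)
    panel_sites: list[int] = field(default_factory=list)  # monomer-local

    def to_dict(self) -> dict:
        return {
            "monomer_intervals": [list(t) for t in self.monomer_intervals],
            "monomer_haplotypes": self.monomer_haplotypes,
            "domain_maps": [
                [[lab, list(iv)] for lab, iv in dm] for dm in self.domain_maps
            ],
            "tracts": [vars(t) for t in self.tracts],
            "insertions": [
                {**vars(i), "ltr5": list(i.ltr5), "ltr3": list(i.ltr3)}
                for i in self.insertions
            ],
            "island_boundaries": [list(t) for t in self.island_boundaries],
            "monomer_seqs": self.monomer_seqs,
            "events": [list(e) for e in self.events],
            "panel_sites": self.panel_sites,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayTruth":
        t = cls()
        t.monomer_intervals = [tuple(x) for x in d["monomer_intervals"]]
        t.monomer_haplotypes = list(d["monomer_haplotypes"])
        t.domain_maps = [
            [(lab, tuple(iv)) for lab, iv in dm] for dm in d["domain_maps"]
        ]
        t.tracts = [TractTruth(**x) for x in d["tracts"]]
        t.insertions = [
            InsertionTruth(
                **{**x, "ltr5": tuple(x["ltr5"]), "ltr3": tuple(x["ltr3"])}
            )
            for x in d["insertions"]
        ]
        t.island_boundaries = [tuple(x) for x in d["island_boundaries"]]
        t.monomer_seqs = list(d["monomer_seqs"])
        t.events = [tuple(e) for e in d["events"]]
        t.panel_sites = list(d.get("panel_sites", []))
        return t

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "ArrayTruth":
        return cls.from_dict(json.loads(s))


@dataclass
class SimResult:
    sequence: str
    truth: ArrayTruth
    parent_a: ParentModel
    parent_b: ParentModel
    unit: str  # the seed monomer, i.e. the reference repeat unit
    config: SimConfig


# ---------------------------------------------------------------------------
# parents and seed
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_parent_pair(
    rng: np.random.Generator,
    divergence: float = 0.08,
    tstv: float = 2.0,
) -> tuple[ParentModel, ParentModel]:
    """Build a B parent (the repeat's source allele) and a diverged A allele.

    Both parents share the canonical toy layout; the A allele differs by
    substitutions only (real end variants also differ in length — see the
    methods note), and each parent's two LTRs are identical, as at
    insertion time.
    """
    body = _random_seq(rng, LTR3[0])
    seq_b = body + body[LTR5[0] : LTR5[1]]  # ltr3 := copy of ltr5
    refs = {"S": S_REF, "IR": IR_REF, "E": E_REF}
    parent_b = ParentModel("B", seq_b, LTR5, UTR, INTERNAL, LTR3, refs)

    mutated = _mutate_string(seq_b, divergence, tstv, rng)
    # restore the LTR identity invariant for the A allele as well
    seq_a = mutated[: LTR3[0]] + mutated[LTR5[0] : LTR5[1]]
    parent_a = ParentModel("A", seq_a, LTR5, UTR, INTERNAL, LTR3, refs)
    return parent_a, parent_b


def splice_seed(
    parent: ParentModel, deletions: list[tuple[int, int]]
) -> tuple[str, list[tuple[int, int]]]:
    """Excise the given spans from the parent; returns (seed, retained spans).

    Models sequential illegitimate recombination: each deletion removes a
    contiguous internal span, leaving part of the LTR joined to part of the
    UTR.  Rejects deletion sets that would remove an entire LTR or the
    entire UTR, since no repeat unit would remain.
    """
    n = len(parent.sequence)
    dels = sorted(tuple(d) for d in deletions)
    prev_end = 0
    for s, e in dels:
        if not (0 <= s < e <= n):
            raise ValueError(f"deletion ({s}, {e}) out of range")
        if s < prev_end:
            raise ValueError("deletions must be non-overlapping")
        prev_end = e

    def covered(region: tuple[int, int]) -> bool:
        rs, re_ = region
        pos = rs
        for s, e in dels:
            if s <= pos < e:
                pos = e
            if pos >= re_:
                return True
        return pos >= re_

    if covered(parent.utr):
        raise ValueError("deletions remove the entire UTR; no repeat unit remains")
    if covered(parent.ltr5) and covered(parent.ltr3):
        raise ValueError("deletions remove both LTRs; no repeat unit remains")

    retained: list[tuple[int, int]] = []
    pos = 0
    for s, e in dels:
        if pos < s:
            retained.append((pos, s))
        pos = e
    if pos < n:
        retained.append((pos, n))
    seed = "".join(parent.sequence[s:e] for s, e in retained)
    return seed, retained


def default_seed_monomer(
    parent: ParentModel,
) -> tuple[str, list[tuple[str, tuple[int, int]]]]:
    """The canonical seed repeat unit and its monomer-local domain map.

    The unit spans the LTR tail (S), one internal repeat (IR) and the UTR
    head (E); in the full LTR-UTR~LTR genesis the next unit starts at the
    homologous position of the downstream LTR.
    """
    s0, _ = SEED_SPAN
    monomer = parent.sequence[SEED_SPAN[0] : SEED_SPAN[1]]
    domain_map = [
        ("S", (S_REF[0] - s0, S_REF[1] - s0)),
        ("IR", (IR_REF[0] - s0, IR_REF[1] - s0)),
        ("E", (E_REF[0] - s0, E_REF[1] - s0)),
    ]
    return monomer, domain_map


# ---------------------------------------------------------------------------
# growth and mutation
# ---------------------------------------------------------------------------


def grow_array(
    seed: str,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    seed_domains: list[tuple[str, tuple[int, int]]] | None = None,
) -> tuple[list[str], ArrayTruth]:
    """Expand one seed monomer into a tandem array by block duplications.

    Each expansion event copies a contiguous block of monomers (block length
    geometric, mean 2, capped) and inserts the copy adjacent to the source —
    the footprint a conversion-mediated duplication leaves.  Events are
    logged as (source index, block length, insert position) and replaying
    the log reconstructs the array exactly.
    """
    if not seed:
        raise ValueError("seed monomer must be non-empty")
    seed = clean(seed, name="seed")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    monomers = [seed]
    events: list[tuple[int, int, int]] = []
    target = cfg.n_monomers_target
    n_events = cfg.n_expansion_events

    def one_event() -> None:
        src = int(rng.integers(0, len(monomers)))
        block = int(rng.geometric(0.5))  # mean 2
        block = min(block, len(monomers) - src)
        if target > 0:
            block = min(block, target - len(monomers))
        block = max(block, 1)
        insert_at = src + block
        monomers[insert_at:insert_at] = monomers[src : src + block]
        events.append((src, block, insert_at))

    if target > 0:
        while len(monomers) < target:
            one_event()
    else:
        for _ in range(n_events):
            one_event()

    truth = ArrayTruth()
    truth.events = events
    if seed_domains is not None:
        truth.domain_maps = [list(seed_domains) for _ in monomers]
    truth.monomer_haplotypes = ["" for _ in monomers]
    return monomers, truth


def replay_events(seed: str, events: list[tuple[int, int, int]]) -> list[str]:
    """Reconstruct the monomer list from the seed and the event log."""
    monomers = [seed]
    for src, block, insert_at in events:
        monomers[insert_at:insert_at] = monomers[src : src + block]
    return monomers


def _mutate_string(
    seq: str, p: float, tstv: float, rng: np.random.Generator
) -> str:
    """Apply Poisson(p) substitution hits per site with the K2P kernel.

    Multiple hits per site are modelled, so the K2P-corrected distance
    between a sequence and its mutated copy is an unbiased estimate of p.
    """
    if p <= 0.0 or not seq:
        return seq
    chars = list(seq)
    n_hits = rng.poisson(p, len(chars))
    if math.isinf(tstv):
        p_transition = 1.0
    else:
        p_transition = tstv / (tstv + 1.0)
    for i in np.nonzero(n_hits)[0]:
        if chars[i] == "N":
            continue
        for _ in range(int(n_hits[i])):
            if rng.random() < p_transition:
                chars[i] = _TRANSITION[chars[i]]
            else:
                chars[i] = _TRANSVERSIONS[chars[i]][int(rng.integers(0, 2))]
    return "".join(chars)


def mutate(
    seq: str,
    years: float,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> str:
    """Neutral per-site substitution over *years* at rate ``cfg.mu``.

    Substitution probability per site is ``mu * years`` (multiple hits are
    not modelled; at the rates simulated here mu*years << 1).  Transitions
    are favored by ``cfg.tstv``; two diverging copies of a common ancestor
    are expected to differ by kappa ~ 2*mu*years.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = cfg.mu * years
    if p > 0.75:
        raise ValueError("mu*years too large; substitution model saturated")
    return _mutate_string(clean(seq), p, cfg.tstv, rng)


# ---------------------------------------------------------------------------
# haplotype / IR / tract injection
# ---------------------------------------------------------------------------


def _local_to_parent(
    pos: int, domain_map: list[tuple[str, tuple[int, int]]]
) -> int:
    """Map a monomer-local coordinate to its homologous parent coordinate.

    Repeated IR copies all map onto the single parental IR.
    """
    s0 = SEED_SPAN[0]
    for label, (ds, de) in domain_map:
        if ds <= pos < de:
            if label == "S":
                return S_REF[0] + (pos - ds)
            if label.startswith("IR"):
                return IR_REF[0] + (pos - ds) % (IR_REF[1] - IR_REF[0])
            return E_REF[0] + (pos - ds)
    # off the annotated domains (should not happen for canonical monomers)
    return min(max(s0 + pos, 0), PARENT_LEN - 1)


def inject_variation(
    monomers: list[str],
    truth: ArrayTruth,
    parent_a: ParentModel,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], ArrayTruth]:
    """Draw per-monomer IR copy number and donor conversion tracts.

    IR copy number k is drawn from ``cfg.ir_copy_distribution`` and the
    monomer's IR span is tiled k times (domain map updated).  With
    probability ``cfg.donor_tract_prob`` a tract of shifted-geometric length
    (floor ``tract_len_min``, mean ``tract_len_mean``) anchored over the end
    domain replaces the homologous span with parent-A alleles; tract
    coordinates are recorded in the truth.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not truth.domain_maps:
        raise ValueError("truth has no domain maps; grow with seed_domains")
    ks = sorted(cfg.ir_copy_distribution)
    probs = [cfg.ir_copy_distribution[k] for k in ks]
    out: list[str] = []
    for idx, seq in enumerate(monomers):
        dm = truth.domain_maps[idx]
        labels = [lab for lab, _ in dm]
        ir_i = labels.index("IR")
        ir_s, ir_e = dm[ir_i][1]
        ir_len = ir_e - ir_s
        k = int(rng.choice(ks, p=probs)) if ks else 1
        if k != 1:
            seq = seq[:ir_e] + seq[ir_s:ir_e] * (k - 1) + seq[ir_e:]
        shift = ir_len * (k - 1)
        new_dm: list[tuple[str, tuple[int, int]]] = []
        for lab, (ds, de) in dm:
            if lab == "IR":
                for c in range(k):
                    new_dm.append(("IR", (ir_s + c * ir_len, ir_s + (c + 1) * ir_len)))
            elif ds >= ir_e:
                new_dm.append((lab, (ds + shift, de + shift)))
            else:
                new_dm.append((lab, (ds, de)))
        dm = new_dm

        if rng.random() < cfg.donor_tract_prob:
            e_span = next(iv for lab, iv in dm if lab.startswith("E"))
            mean_extra = max(cfg.tract_len_mean - cfg.tract_len_min, 1.0)
            length = cfg.tract_len_min + int(rng.geometric(1.0 / mean_extra)) - 1
            start = int(rng.integers(max(0, e_span[0] - 30), e_span[0] + 10))
            end = min(len(seq), start + length)
            converted = [
                parent_a.sequence[_local_to_parent(p, dm)] for p in range(start, end)
            ]
            seq = seq[:start] + "".join(converted) + seq[end:]
            truth.tracts.append(TractTruth(idx, "A", start, end))
        out.append(seq)
        truth.domain_maps[idx] = dm
    return out, truth


def parent_diagnostic_sites(
    domain_map: list[tuple[str, tuple[int, int]]],
    parent_a: ParentModel,
    parent_b: ParentModel,
) -> tuple[list[int], str, str]:
    """Monomer-local sites where the two parent alleles differ.

    Returns (sites, alleleA string, alleleB string) ordered by site; this is
    the ground-truth diagnostic panel for conversion-tract inference.
    """
    sites: list[int] = []
    aa: list[str] = []
    bb: list[str] = []
    end = max(de for _, (_, de) in domain_map)
    for pos in range(end):
        pp = _local_to_parent(pos, domain_map)
        ba = parent_a.sequence[pp]
        bc = parent_b.sequence[pp]
        if ba != bc:
            sites.append(pos)
            aa.append(ba)
            bb.append(bc)
    return sites, "".join(aa), "".join(bb)


def inject_haplotypes(
    monomers: list[str],
    truth: ArrayTruth,
    panel: HaplotypePanelSpec,
    group_label: str,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[list[str], ArrayTruth]:
    """Write group-specific alleles at fixed S-region panel sites.

    Sites are evenly spaced inside the S domain (identical across groups).
    A ``major_fraction`` share of monomers carries the group's major
    haplotype; the rest differ from it at one random panel site, flipped to
    a base used by no group at that site.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    alleles = panel.group_alleles[group_label]
    n = len(alleles)
    s_span = next(iv for lab, iv in truth.domain_maps[0] if lab == "S")
    s_len = s_span[1] - s_span[0]
    sites = [s_span[0] + (i + 1) * s_len // (n + 1) for i in range(n)]
    truth.panel_sites = sites
    out: list[str] = []
    for idx, seq in enumerate(monomers):
        hap = list(alleles)
        if rng.random() >= panel.major_fraction:
            j = int(rng.integers(0, n))
            used = {v[j] for v in panel.group_alleles.values()}
            free = [b for b in "ACGT" if b not in used]
            hap[j] = free[int(rng.integers(0, len(free)))] if free else hap[j]
        chars = list(seq)
        for site, base in zip(sites, hap):
            chars[site] = base
        out.append("".join(chars))
        truth.monomer_haplotypes[idx] = "".join(hap)
    return out, truth


# ---------------------------------------------------------------------------
# assembly and nested insertions
# ---------------------------------------------------------------------------


def assemble(
    monomers: list[str],
    truth: ArrayTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[str, ArrayTruth]:
    """Concatenate monomers between random flanks; set genomic coordinates."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    left = _random_seq(rng, cfg.flank_len)
    right = _random_seq(rng, cfg.flank_len)
    pos = len(left)
    intervals: list[tuple[int, int]] = []
    for m in monomers:
        intervals.append((pos, pos + len(m)))
        pos += len(m)
    truth.monomer_intervals = intervals
    truth.monomer_seqs = list(monomers)
    truth.island_boundaries = [(len(left), pos)]
    sequence = left + "".join(monomers) + right
    return sequence, truth


def _shift(x: int, at: int, by: int) -> int:
    return x + by if x > at else x


def _shift_iv(iv: tuple[int, int], at: int, by: int) -> tuple[int, int]:
    return (_shift(iv[0], at, by), _shift(iv[1], at, by))


def insert_nested_te(
    sequence: str,
    truth: ArrayTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[str, ArrayTruth]:
    """Insert the configured nested elements into the array.

    Each element is LTR-internal-LTR; the two LTRs are copies of one
    template mutated independently for ``age`` years (expected pair
    divergence kappa = 2*mu*age).  ``tsd_length`` bases at the insertion
    point are duplicated so the element is flanked by a target-site
    duplication.  Insertion points are drawn inside monomers (never inside
    a previously inserted element); an island containing an insertion is
    split in two.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    templates: dict[int, tuple[str, str]] = {}  # elem_len -> (ltr, internal)
    for age, elem_len, tsd_len in cfg.nested_insertions:
        if not 0 <= tsd_len <= 20:
            raise ValueError("tsd_length must lie in [0, 20]")
        ltr_len = min(cfg.nested_ltr_len, max(100, (elem_len - 100) // 2))
        if 2 * ltr_len + 1 > elem_len:
            raise ValueError("element too short for its LTR pair")
        if cfg.nested_share_template and elem_len in templates:
            ltr, inner = templates[elem_len]
        else:
            ltr = _random_seq(rng, ltr_len)
            inner = _random_seq(rng, elem_len - 2 * ltr_len)
            templates[elem_len] = (ltr, inner)
        p_sub = cfg.mu * age
        ltr_a = _mutate_string(ltr, p_sub, cfg.tstv, rng)
        ltr_b = _mutate_string(ltr, p_sub, cfg.tstv, rng)
        element = ltr_a + inner + ltr_b
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            element = revcomp(element)
        # choose an insertion point inside a monomer, far enough from its end
        # and not inside a monomer already interrupted by an earlier element
        candidates = [
            (s, e)
            for s, e in truth.monomer_intervals
            if e - s > tsd_len + 2
            and not any(s < ins.end and ins.start < e for ins in truth.insertions)
        ]
        if not candidates:
            raise ValueError("no insertion position available inside the array span")
        ms, me = candidates[int(rng.integers(0, len(candidates)))]
        p = int(rng.integers(ms + 1, me - tsd_len))
        tsd = sequence[p : p + tsd_len]
        sequence = sequence[: p + tsd_len] + element + sequence[p:]
        shift_by = tsd_len + len(element)

        truth.monomer_intervals = [
            _shift_iv(iv, p, shift_by) for iv in truth.monomer_intervals
        ]
        truth.insertions = [
            replace(
                ins,
                start=_shift(ins.start, p, shift_by),
                end=_shift(ins.end, p, shift_by),
                ltr5=_shift_iv(ins.ltr5, p, shift_by),
                ltr3=_shift_iv(ins.ltr3, p, shift_by),
            )
            for ins in truth.insertions
        ]
        new_islands: list[tuple[int, int]] = []
        for s, e in truth.island_boundaries:
            if s <= p < e:
                new_islands.append((s, p + tsd_len))
                new_islands.append((p + tsd_len + len(element), e + shift_by))
            else:
                new_islands.append(_shift_iv((s, e), p, shift_by))
        truth.island_boundaries = new_islands

        elem_start = p + tsd_len
        truth.insertions.append(
            InsertionTruth(
                start=elem_start,
                end=elem_start + len(element),
                tsd=tsd,
                ltr5=(elem_start, elem_start + ltr_len),
                ltr3=(elem_start + len(element) - ltr_len, elem_start + len(element)),
                kappa_expected=2.0 * cfg.mu * age,
                age_years=age,
                strand=strand,
            )
        )
    return sequence, truth


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def simulate(
    cfg: SimConfig,
    parents: tuple[ParentModel, ParentModel] | None = None,
) -> SimResult:
    """Run the full genesis/growth model and emit sequence plus truth.

    Stages, in fixed RNG order: build parents, splice the seed monomer, grow
    the array by block duplications, diverge each monomer for
    ``array_age_years``, draw IR copy numbers and donor tracts, inject the
    haplotype panel (if configured), assemble between random flanks, and
    place nested insertions.
    """
    rng = np.random.default_rng(cfg.seed)
    if parents is None:
        parent_a, parent_b = make_parent_pair(rng, cfg.parent_divergence, cfg.tstv)
    else:
        parent_a, parent_b = parents
    unit, seed_domains = default_seed_monomer(parent_b)
    monomers, truth = grow_array(unit, cfg, rng, seed_domains=seed_domains)
    if cfg.array_age_years > 0:
        monomers = [mutate(m, cfg.array_age_years, cfg, rng) for m in monomers]
    monomers, truth = inject_variation(monomers, truth, parent_a, cfg, rng)
    if cfg.snp_panel is not None:
        monomers, truth = inject_haplotypes(
            monomers, truth, cfg.snp_panel, cfg.locus_label, rng
        )
    sequence, truth = assemble(monomers, truth, cfg, rng)
    sequence, truth = insert_nested_te(sequence, truth, cfg, rng)
    return SimResult(sequence, truth, parent_a, parent_b, unit, cfg)
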