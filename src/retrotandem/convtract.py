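"""Parent-allele assignment and gene-conversion tract inference.

A monomer derived from parent allele B may carry a segment of parent-A
sequence introduced by gene conversion.  At sites where the two parent
alleles differ (diagnostic sites), each monomer base is called A, B, other
or masked; maximal runs of donor-allele calls become conversion tracts
with two coordinate bounds: the *minimal* tract spans the first to last
supporting site, while the *maximal* tract extends up to — but excludes —
the nearest flanking sites still carrying the background allele (a
converted region cannot include a site that retained the background
base).  The true tract always lies between the two bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .arrayfinder import Monomer

__all__ = [
    "ParentDiagnostics",
    "SiteAssignment",
    "ConversionTract",
    "assign_parent_sites",
    "infer_tracts",
    "summarize_recombinants",
]


@dataclass(frozen=True)
class ParentDiagnostics:
    """Sites (monomer-frame coordinates) where parent alleles A and B differ."""

    sites: tuple[int, ...]
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if not (len(self.sites) == len(self.allele_a) == len(self.allele_b)):
            raise ValueError("sites and allele strings must have equal length")
        if any(a == b for a, b in zip(self.allele_a, self.allele_b)):
            raise ValueError("alleles must differ at every diagnostic site")
        if any(x >= y for x, y in zip(self.sites, self.sites[1:])):
            raise ValueError("sites must be strictly increasing")


@dataclass(frozen=True)
class SiteAssignment:
    site: int
    observed: str
    call: str  # "A" | "B" | "other" | "masked"


@dataclass(frozen=True)
class ConversionTract:
    monomer_ref: str | None
    donor: str
    minimal: tuple[int, int]  # first..last supporting site, half-open
    maximal: tuple[int, int]  # bounded by flanking background sites, exclusive
    n_supporting_sites: int

    def __post_init__(self) -> None:
        if not (
            self.maximal[0] <= self.minimal[0]
            and self.minimal[1] <= self.maximal[1]
        ):
            raise ValueError("minimal bound must lie within maximal bound")


def assign_parent_sites(
    monomer: Monomer | str,
    panel: ParentDiagnostics,
    masked_intervals: list[tuple[int, int]] | None = None,
) -> list[SiteAssignment]:
    """Call each diagnostic site of a monomer to parent A, B, other or masked.

    The monomer is assumed to be in the same coordinate frame as the panel
    (phase-normalized against the background parent).  Sites beyond the
    monomer end and sites inside ``masked_intervals`` (e.g. A-rich runs)
    are reported as masked; masked sites never enter tract logic.
    """
    seq = monomer.sequence if isinstance(monomer, Monomer) else monomer
    masked_intervals = masked_intervals or []
    out: list[SiteAssignment] = []
    for i, site in enumerate(panel.sites):
        if site >= len(seq) or any(s <= site < e for s, e in masked_intervals):
            out.append(SiteAssignment(site, "", "masked"))
            continue
        obs = seq[site]
        if obs == panel.allele_a[i]:
            call = "A"
        elif obs == panel.allele_b[i]:
            call = "B"
        else:
            call = "other"
        out.append(SiteAssignment(site, obs, call))
    return out


def infer_tracts(
    assignments: list[SiteAssignment],
    background: str = "B",
    min_sites: int = 2,
    max_gap_sites: int = 0,
    monomer_ref: str | None = None,
    monomer_length: int | None = None,
) -> list[ConversionTract]:
    """Maximal donor-allele runs over the assignment vector.

    A run of donor calls (the non-background parent) with at least
    ``min_sites`` supporting sites, allowing up to ``max_gap_sites``
    interior non-donor calls, becomes a tract.  The minimal bound spans the
    first to last supporting site (half-open); the maximal bound extends to
    the nearest flanking background-called site on each side, excluding
    that site itself, or to the monomer edge when there is none.
    """
    donor = "A" if background == "B" else "B"
    usable = [a for a in assignments if a.call != "masked"]
    usable.sort(key=lambda a: a.site)
    if monomer_length is None:
        monomer_length = (usable[-1].site + 1) if usable else 0

    # group donor sites into runs allowing max_gap_sites interior non-donor
    runs: list[list[int]] = []  # indices into usable
    current: list[int] = []
    gap = 0
    for idx, a in enumerate(usable):
        if a.call == donor:
            current.append(idx)
            gap = 0
        elif current:
            gap += 1
            if gap > max_gap_sites:
                runs.append(current)
                current = []
                gap = 0
    if current:
        runs.append(current)

    tracts: list[ConversionTract] = []
    for run in runs:
        if len(run) < min_sites:
            continue
        first = usable[run[0]].site
        last = usable[run[-1]].site
        # nearest flanking background-called sites
        left = None
        for idx in range(run[0] - 1, -1, -1):
            if usable[idx].call == background:
                left = usable[idx].site
                break
        right = None
        for idx in range(run[-1] + 1, len(usable)):
            if usable[idx].call == background:
                right = usable[idx].site
                break
        max_start = 0 if left is None else left + 1
        max_end = monomer_length if right is None else right
        tracts.append(
            ConversionTract(
                monomer_ref=monomer_ref,
                donor=donor,
                minimal=(first, last + 1),
                maximal=(max_start, max_end),
                n_supporting_sites=len(run),
            )
        )
    return tracts


def summarize_recombinants(
    tracts: list[ConversionTract],
    monomer_ids: list[str],
) -> pd.DataFrame:
    """Per-donor recombinant summary over a set of monomers.

    One row per donor allele: number of tracts, number and fraction of
    monomers carrying at least one tract of that donor, and minimal /
    maximal tract-length statistics.  A monomer with two tracts counts once
    in the monomer-level fraction, twice in the tract-level statistics.
    """
    n_monomers = len(monomer_ids)
    rows = []
    for donor in sorted({t.donor for t in tracts}) or []:
        dt = [t for t in tracts if t.donor == donor]
        carriers = {t.monomer_ref for t in dt}
        min_lens = [t.minimal[1] - t.minimal[0] for t in dt]
        max_lens = [t.maximal[1] - t.maximal[0] for t in dt]
        rows.append(
            {
                "donor": donor,
                "n_tracts": len(dt),
                "n_monomers_with_tract": len(carriers),
                "fraction_recombinant": len(carriers) / n_monomers
                if n_monomers
                else 0.0,
                "minimal_len_mean": float(pd.Series(min_lens).mean()),
                "minimal_len_max": max(min_lens),
                "maximal_len_mean": float(pd.Series(max_lens).mean()),
                "maximal_len_max": max(max_lens),
            }
        )
    if not rows:
        rows.append(
            {
                "donor": "A",
                "n_tracts": 0,
                "n_monomers_with_tract": 0,
                "fraction_recombinant": 0.0,
                "minimal_len_mean": float("nan"),
                "minimal_len_max": 0,
                "maximal_len_mean": float("nan"),
                "maximal_len_max": 0,
            }
        )
    return pd.DataFrame(rows)
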