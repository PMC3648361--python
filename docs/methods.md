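# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `retrotandem` package.

## Alignment core (`alignkit`)

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment are
implemented with linear gap penalties and a fixed traceback tie-break
(diagonal over up over left), so all outputs are bit-reproducible. Input
is uppercase-normalized and restricted to {A,C,G,T,N}; `N` scores as a
mismatch against everything, including another `N`, so ambiguity can
never manufacture similarity. Defaults are match +1, mismatch −1, gap −2
per base. Linear (rather than affine) gaps were chosen because no stage
of this pipeline aligns across structurally different sequences where
long gaps should be cheap; every consumer aligns near-identical
homologs. The DP rows are vectorized: with linear gaps the horizontal
dependency unrolls into a running maximum, so a 1000×1000 problem costs
a few milliseconds.

The K2P distance is computed with pairwise deletion: columns containing
a gap or `N` in either row are dropped; P and Q are the transition and
transversion proportions over the remaining columns and
κ = −½·ln(1−2P−Q) − ¼·ln(1−2Q). Saturated inputs (non-positive log
arguments) and empty comparisons raise a domain error rather than
returning a number.

## Forward simulator (`simarray`)

The simulator emulates, stage by stage, how a retrotransposon-derived
tandem repeat locus arises and diversifies:

1. **Parents.** A 7 kb toy element (600 nt LTRs flanking an 800 nt UTR
   and a 5 kb internal region, both LTRs identical at time 0) is drawn
   at random; a second allele ("A") is produced by substituting 8% of
   sites. Both alleles have equal length — the real end variants also
   differ by an indel, which the simulator does not model; every
   diagnostic-site mechanism downstream works on substitutions only.
2. **Seed.** `splice_seed` excises arbitrary internal spans (sequential
   illegitimate recombination); the canonical seed monomer spans the LTR
   tail through the UTR head and carries an S (402 nt) + IR (100 nt) +
   E (185 nt) domain map, giving a 687 nt unit — matching the scale of
   the repeats this models (~700–900 nt monomers).
3. **Growth.** `grow_array` duplicates contiguous monomer blocks (block
   length geometric with mean 2, capped) until the target copy number is
   reached, logging every event. Monomer-scale blocks reflect
   double-strand-break-repair gene conversion with tract lengths of
   roughly 1–2 kb.
4. **Divergence.** Each monomer is mutated independently for
   `array_age_years` at rate `mu` (default 6.5×10⁻⁹/site/year, the rate
   back-calculated from the reference κ→age conversions). Hits per site
   are Poisson with a Kimura-type kernel (transition:transversion ratio
   `tstv`, default 2), so K2P-corrected distances are unbiased
   estimates of the simulated divergence.
5. **Architecture and tracts.** IR copy number per monomer is drawn from
   the observed locus-II mixture (1:2/90, 2:22/90, 3:60/90, 4:6/90 —
   configurable). With probability `donor_tract_prob` (default 0.68, the
   observed recombinant-monomer fraction) a donor tract replaces the
   homologous span around the end domain with parent-A alleles. Tract
   length is a shifted geometric: floor 71 bp (the minimal converted
   region supported by diagnostic sites) and mean 150 bp, consistent
   with a 71 bp–~200 bp minimal/maximal bracket.
6. **Haplotypes.** An optional panel spec writes group-specific alleles
   at seven evenly spaced S-region sites; a configurable major-haplotype
   fraction (default 76%) carries the group haplotype unperturbed, the
   remainder differ at one random panel site.
7. **Assembly and nested insertions.** Monomers are concatenated between
   random 1 kb flanks. Each configured nested element (LTR–internal–LTR;
   LTRs are copies of one template mutated independently for the
   element's age, expected κ = 2·mu·age) is inserted at a random
   intra-monomer position with an exact target-site duplication;
   insertions split the island record in two. Optionally all insertions
   share one element template, which reproduces the observed case of one
   element inserted twice in opposite orientation.

A single `numpy` generator seeded from `SimConfig.seed` drives every
draw in the order above, so identical configurations produce
byte-identical FASTA and truth JSON. The emitted `ArrayTruth` records
monomer intervals and sequences, domain maps, tract and insertion
coordinates, island boundaries, the duplication event log and the panel
sites.

**What the simulator does not emulate:** indel mutation (alignment
columns are never shifted by drift), length differences between end
variants, transcription/splicing, CENH3/chromatin context, assembly
gaps, and selection or homogenization gradients along the array.
Recovery results on simulated data therefore certify the inference
machinery under substitution-type variation, not performance on real
assemblies with indels and segmental structure.

## Array detection (`arrayfinder`)

`find_arrays` seeds with exact 13-mers from the doubled repeat unit
(doubling covers junction-spanning words) on both strands, marks covered
bases, and chains covered runs separated by less than `chain_gap`
(default: one unit length; pass a larger value to hold an
insertion-interrupted array together as one hit, then split it with
`segment_islands`). Monomer equivalents are the island-level matched
span divided by the unit length; mean identity is measured by locally
aligning up to five sampled unit-length windows against the doubled
unit. At 5% divergence the expected fraction of positions covered by at
least one clean 13-mer is still high enough that arrays chain into
single runs; below ~80% identity detection degrades, which matches the
80% default identity floor.

`extract_monomers` cuts an island at recurrences of the unit-start
anchor (first 32 nt of the unit, ≥70% identity, local maxima at least
half a unit apart). Segments of length ≥ `flen_frac`×unit (default 0.9
— "full length" is a free parameter, deliberately configurable) are
flagged full-length; the flag is length-based, so a full monomer whose
first few bases are clipped by coverage erosion at an island edge still
counts. Monomers on the minus strand are reported phase-normalized
(reverse-complemented) with forward-strand coordinates.

`find_periodicity` scores each lag in [kmin, kmax] by the fraction of
self-matching positions. The reported period is the *smallest* lag
within a margin (default 0.15) of the maximum — this makes an 18 nt
fundamental beat its own 36 nt harmonic even when alternating-copy SNPs
make the harmonic score higher — and a 2× harmonic within the margin is
reported as the secondary (composite) period. Below an absolute
autocorrelation threshold of 0.6 no period is called.

## Monomer structure (`monostruct`)

Consensus profiles are star alignments: every sequence is globally
aligned to an anchor (the longest sequence, or the reference unit) and
projected onto anchor columns. For monomer sets that are ≥95% identical
this is equivalent to a progressive MSA at a fraction of the cost and,
unlike heuristic MSA, deterministic. Majority bases win per column, ties
become IUPAC ambiguity codes, and columns that are gaps in more than
half the rows are dropped from the consensus but remain addressable.

`decompose_monomer` locally aligns each domain reference against the
monomer (the IR reference repeatedly, masking previous hits) and
greedily selects non-overlapping hits by score; the end domain goes to
whichever of E_A/E_B scores higher, with scores within 5% of each other
yielding `E_?` so recombinant ends are not overcalled. Hits must cover
half the reference at ≥70% identity.

Diagnostic SNP columns require both groups' majority alleles to be real
bases, to differ, and to reach within-group frequency ≥
`concordance_min` (default 0.7 — low enough to tolerate the minor-
haplotype diversity seen in real loci, high enough to keep panels
discriminative). Groups are ordered lexicographically, so swapping
group labels permutes the reported allele pairs but never the selected
columns. A-rich low-complexity runs (windows ≥10 nt at ≥80% A) are
masked before SNP selection, mirroring the exclusion of the polymorphic
A-rich IR tails.

## Conversion tracts (`convtract`)

Sites where the parent alleles differ are typed per monomer as A, B,
`other` or `masked`. Runs of ≥ `min_sites` donor calls (default 2 — a
single discordant site is indistinguishable from a point mutation),
allowing ≤ `max_gap_sites` interior non-donor calls (default 0), become
tracts. The minimal bound spans the supporting sites; the maximal bound
extends to, and excludes, the nearest flanking background-called site
on each side (a converted region cannot contain a site that still
carries the background allele) or the monomer edge. On noise-free
simulations the truth tract always satisfies minimal ⊆ truth ⊆ maximal.

## Insertion dating (`tedate`)

Inter-island gaps of at least 1 kb are screened. Gap boundaries derived
from k-mer coverage can fall short of the true array/element junction by
up to a seed length per nearby mutation, so when the repeat unit is
supplied the boundaries are first snapped to the junctions by strict
local alignment (match +1, mismatch −3, gap −5: extension into
non-array sequence has strongly negative drift). The TSD is the longest
3–20 nt exact left-flank-suffix/right-flank-prefix duplication, allowing
the boundary to shrink inward by up to 12 nt with a 0.6/nt penalty so a
shift is accepted only when it buys a decisively longer duplication. The
LTR pair is the best terminal-proximal local self-match between the
gap's first and last thirds (≥100 nt at ≥80% identity). Ages are
T = κ/(2r) with r = 6.5×10⁻⁹/site/year by default, displayed to two
decimal My. Orientation is assigned against a supplied element
reference, or relative to the first candidate when two or more
candidates are homologous to each other.

Limitations: candidates without a detectable LTR pair are reported
undated; heavily eroded junctions (more than ~2 seed lengths of
coverage loss) can still displace the TSD by a few bases; and elements
nested within other elements are not resolved recursively.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on simulated loci
of 10–100 monomers (7–90 kb) — ample to exercise every code path while
keeping the whole suite under a minute of compute. Recovery statistics
use 20 replicates (monomer counts), 200 monomers (IR copy number),
50–100 replicates per age point (dating), 187 monomers across two loci
(haplotypes), and 100 donor-tract monomers (bracketing); binomial
recovery checks use 95% confidence intervals at the simulated
proportions. Genome-scale figures from real assemblies (total monomer
censuses, per-locus haplotype tables) are outside the desk-scale scope:
they require the original assembly, and the machinery that would produce
them is exactly what the recovery tests certify.
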