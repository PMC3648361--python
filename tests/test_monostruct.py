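"""Consensus, domain decomposition, masking, diagnostic SNPs, haplotypes."""

from __future__ import annotations

import numpy as np
import pytest

from retrotandem import monostruct as ms
from retrotandem import simarray as sa
from tests.conftest import years_for_divergence


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestBuildConsensus:
    def test_idempotent_on_identical_copies(self):
        rng = np.random.default_rng(3)
        seq = _random_seq(rng, 120)
        for n in (1, 2, 5):
            prof = ms.build_consensus([seq] * n)
            assert prof.sequence == seq
            assert (prof.depth == n).all()

    def test_majority_wins(self):
        prof = ms.build_consensus(["AAT", "AAT", "AGT"])
        assert prof.sequence == "AAT"

    def test_tie_becomes_iupac(self):
        prof = ms.build_consensus(["AAT", "AGT"])
        assert prof.sequence == "ART"  # A/G tie -> R

    def test_majority_gap_column_dropped(self):
        # the deleted base is gap in 2 of 3 rows: dropped from consensus
        prof = ms.build_consensus(["ACGTACGT", "ACGACGT", "ACGACGT"])
        assert prof.sequence == "ACGACGT"
        assert len(prof.kept_columns) == 7

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ms.build_consensus([])

    def test_coords_map_back_to_sequences(self):
        seqs = ["ACGTACGT", "ACGACGT", "ACGTACTT"]
        prof = ms.build_consensus(seqs, anchor=seqs[0])
        for c in range(len(prof.sequence)):
            bases = prof.column_bases(c)
            coords = prof.column_coords(c)
            for r in range(len(seqs)):
                if bases[r] != "-":
                    assert seqs[r][coords[r]] == bases[r]


@pytest.fixture(scope="module")
def refs():
    rng = np.random.default_rng(9)
    return {
        "S": _random_seq(rng, 402),
        "IR": _random_seq(rng, 100),
        "E_A": _random_seq(rng, 150),
        "E_B": _random_seq(rng, 185),
    }


class TestDecomposeMonomer:

    def test_three_ir_architecture(self, refs):
        mono = refs["S"] + refs["IR"] * 3 + refs["E_A"]
        ann = ms.decompose_monomer(mono, refs)
        assert ann.architecture == "S-IR×3-E_A"
        assert ann.ir_count == 3
        assert not ann.partial

    def test_single_ir_e_b(self, refs):
        mono = refs["S"] + refs["IR"] + refs["E_B"]
        ann = ms.decompose_monomer(mono, refs)
        assert ann.architecture == "S-IR×1-E_B"
        assert not ann.partial

    def test_missing_s_is_partial(self, refs):
        mono = refs["IR"] * 2 + refs["E_B"]
        ann = ms.decompose_monomer(mono, refs)
        assert ann.architecture == "IR×2-E_B"
        assert ann.partial

    def test_unannotatable_monomer(self, refs):
        rng = np.random.default_rng(10)
        ann = ms.decompose_monomer(_random_seq(rng, 600), refs)
        assert ann.architecture == "?"
        assert ann.partial

    def test_e_tie_gives_uncommitted_label(self, refs):
        mono = refs["S"] + refs["IR"] + refs["E_A"]
        # offering the same sequence as both end variants forces a tie
        tied = dict(refs, E_B=refs["E_A"])
        ann = ms.decompose_monomer(mono, tied)
        assert ann.architecture.endswith("E_?")

    def test_ir_copy_number_recovery_rate(self):
        # <=2% pairwise divergence, 200 monomers: k exact in >=95%
        good = tot = 0
        for seed in (70, 71, 72, 73):
            cfg = sa.SimConfig(seed=seed, n_monomers_target=50,
                               array_age_years=years_for_divergence(0.02))
            res = sa.simulate(cfg)
            refs = {
                "S": res.parent_b.domain_sequence("S"),
                "IR": res.parent_b.domain_sequence("IR"),
                "E_A": res.parent_a.domain_sequence("E"),
                "E_B": res.parent_b.domain_sequence("E"),
            }
            for i, seq in enumerate(res.truth.monomer_seqs):
                k_true = sum(
                    1 for lab, _ in res.truth.domain_maps[i] if lab == "IR"
                )
                ann = ms.decompose_monomer(seq, refs)
                tot += 1
                good += ann.ir_count == k_true
        assert tot == 200
        assert good / tot >= 0.95


class TestMaskLowComplexity:
    def test_pure_run_fully_masked(self):
        assert ms.mask_low_complexity("A" * 10, "A", 10, 0.8) == [(0, 10)]

    def test_mixed_sequence_unmasked(self):
        assert ms.mask_low_complexity("ACGTACGTAC", "A", 10, 0.8) == []

    @pytest.mark.parametrize("tail_len", [38, 25])
    def test_a_rich_tail_masked(self, tail_len):
        # A-rich terminal runs at 85% A, as at the two loci's IR tails
        rng = np.random.default_rng(tail_len)
        tail = list("A" * tail_len)
        n_other = round(0.15 * tail_len)
        for pos in rng.choice(tail_len, n_other, replace=False):
            tail[pos] = "G"
        seq = _random_seq(rng, 80) + "".join(tail)
        masked = ms.mask_low_complexity(seq, "A", 10, 0.8)
        assert masked, "tail should be masked"
        s, e = masked[-1]
        assert e >= len(seq) - 2
        assert (e - s) >= 0.6 * tail_len

    def test_min_len_validation(self):
        with pytest.raises(ValueError):
            ms.mask_low_complexity("AAAA", "A", 3, 0.8)


def _two_locus_profiles(n1=20, n2=20, major_fraction=1.0, seed=50):
    """S-region profile of two simulated loci sharing one parent pair."""
    parents = sa.make_parent_pair(np.random.default_rng(123))
    panel = sa.HaplotypePanelSpec(
        group_alleles={"I": "ACGGAGT", "II": "GTCACTC"},
        major_fraction=major_fraction,
    )
    common = dict(array_age_years=years_for_divergence(0.02),
                  snp_panel=panel, donor_tract_prob=0.0,
                  ir_copy_distribution={1: 1.0})
    r1 = sa.simulate(sa.SimConfig(seed=seed, n_monomers_target=n1,
                                  locus_label="I", **common), parents=parents)
    r2 = sa.simulate(sa.SimConfig(seed=seed + 1, n_monomers_target=n2,
                                  locus_label="II", **common), parents=parents)
    s1 = [m[:402] for m in r1.truth.monomer_seqs]
    s2 = [m[:402] for m in r2.truth.monomer_seqs]
    prof = ms.build_consensus(s1 + s2, anchor=r1.unit[:402])
    labels = ["I"] * n1 + ["II"] * n2
    return prof, labels, r1, r2


class TestDiagnosticSnps:
    def test_injected_panel_recovered_exactly(self):
        prof, labels, r1, _ = _two_locus_profiles()
        panel = ms.select_diagnostic_snps(prof, labels, 0.7)
        assert panel.columns == r1.truth.panel_sites
        assert [a for a, _ in panel.group_major_alleles] == list("ACGGAGT")
        assert [b for _, b in panel.group_major_alleles] == list("GTCACTC")

    def test_identical_groups_give_empty_panel(self):
        rng = np.random.default_rng(4)
        seqs = [_random_seq(rng, 100)] * 8
        prof = ms.build_consensus(seqs)
        panel = ms.select_diagnostic_snps(prof, ["x"] * 4 + ["y"] * 4)
        assert panel.columns == []

    def test_group_label_swap_selects_same_columns(self):
        prof, labels, _, _ = _two_locus_profiles()
        p1 = ms.select_diagnostic_snps(prof, labels, 0.7)
        swapped = ["II" if l == "I" else "I" for l in labels]
        p2 = ms.select_diagnostic_snps(prof, swapped, 0.7)
        assert p1.columns == p2.columns
        assert [(b, a) for a, b in p1.group_major_alleles] == p2.group_major_alleles

    def test_masked_columns_excluded(self):
        prof, labels, r1, _ = _two_locus_profiles()
        skip = {r1.truth.panel_sites[0]}
        panel = ms.select_diagnostic_snps(prof, labels, 0.7,
                                          masked_columns=skip)
        assert panel.columns == r1.truth.panel_sites[1:]

    def test_small_group_rejected(self):
        rng = np.random.default_rng(5)
        prof = ms.build_consensus([_random_seq(rng, 50) for _ in range(4)])
        with pytest.raises(ValueError):
            ms.select_diagnostic_snps(prof, ["x", "y", "y", "y"])


class TestCallHaplotypes:
    def test_uniform_monomers_single_haplotype(self):
        prof, labels, _, _ = _two_locus_profiles()
        panel = ms.select_diagnostic_snps(prof, labels, 0.7)
        prof1 = ms.build_consensus(
            [  # locus I rows only
                "".join(prof.matrix[i]) for i in range(20)
            ]
        )
        calls, table = ms.call_haplotypes(prof1, panel)
        complete = table[table.complete]
        assert len(complete) == 1
        assert complete.iloc[0]["haplotype"] == "ACGGAGT"
        assert complete.iloc[0]["percent"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        prof, labels, _, _ = _two_locus_profiles(major_fraction=0.7, seed=60)
        panel = ms.select_diagnostic_snps(prof, labels, 0.6)
        _, table = ms.call_haplotypes(prof, panel)
        complete = table[table.complete]
        assert complete["percent"].sum() == pytest.approx(100.0)

    def test_mixture_fraction_recovered_within_ci(self):
        # locus I at n=97 carrying the major haplotype at 76%
        prof, labels, r1, _ = _two_locus_profiles(
            n1=97, n2=90, major_fraction=0.76, seed=70
        )
        panel = ms.select_diagnostic_snps(prof, labels, 0.7)
        calls, _ = ms.call_haplotypes(prof, panel)
        haps = [c.haplotype for c in calls[:97] if c.complete]
        frac = haps.count("ACGGAGT") / 97
        half_width = 1.96 * np.sqrt(0.76 * 0.24 / 97)
        assert abs(frac - 0.76) <= half_width

    def test_empty_panel_rejected(self):
        prof = ms.build_consensus(["ACGT"] * 4)
        with pytest.raises(ValueError):
            ms.call_haplotypes(prof, ms.DiagnosticPanel("S", [], [], []))
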