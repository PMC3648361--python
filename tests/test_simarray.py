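"""Simulator correctness: bookkeeping identities, determinism, calibration."""

from __future__ import annotations

import math

import numpy as np
import pytest

from retrotandem import alignkit as ak
from retrotandem import simarray as sa
from tests.conftest import years_for_divergence


@pytest.fixture(scope="module")
def parents():
    return sa.make_parent_pair(np.random.default_rng(77))


class TestSpliceSeed:
    def test_retained_span_concatenation(self, parents):
        _, pb = parents
        deletions = [(885, 6400), (6450, 6598)]
        seed, retained = sa.splice_seed(pb, deletions)
        assert seed == "".join(pb.sequence[s:e] for s, e in retained)
        assert len(seed) == len(pb.sequence) - sum(e - s for s, e in deletions)

    def test_no_deletions_is_identity(self, parents):
        _, pb = parents
        seed, retained = sa.splice_seed(pb, [])
        assert seed == pb.sequence
        assert retained == [(0, len(pb.sequence))]

    def test_rejects_whole_utr_removal(self, parents):
        _, pb = parents
        with pytest.raises(ValueError):
            sa.splice_seed(pb, [(pb.utr[0] - 10, pb.utr[1] + 10)])

    def test_rejects_overlapping_deletions(self, parents):
        _, pb = parents
        with pytest.raises(ValueError):
            sa.splice_seed(pb, [(100, 300), (200, 400)])

    def test_parent_ltrs_identical_at_time_zero(self, parents):
        for p in parents:
            assert (
                p.sequence[p.ltr5[0] : p.ltr5[1]]
                == p.sequence[p.ltr3[0] : p.ltr3[1]]
            )


class TestGrowArray:
    def test_mu_zero_gives_identical_copies(self):
        cfg = sa.SimConfig(seed=4, n_monomers_target=10)
        monomers, _ = sa.grow_array("ACGTTGCA" * 20, cfg)
        assert len(monomers) == 10
        assert len(set(monomers)) == 1

    def test_event_log_replay_reconstructs_array(self):
        cfg = sa.SimConfig(seed=9, n_monomers_target=37)
        seed = "ACGTTGCATT" * 10
        monomers, truth = sa.grow_array(seed, cfg)
        assert sa.replay_events(seed, truth.events) == monomers

    def test_deterministic_under_fixed_seed(self):
        cfg = sa.SimConfig(seed=5, n_monomers_target=25)
        m1, t1 = sa.grow_array("ACGT" * 30, cfg)
        m2, t2 = sa.grow_array("ACGT" * 30, cfg)
        assert m1 == m2 and t1.events == t2.events


class TestMutate:
    def test_zero_years_unchanged(self):
        cfg = sa.SimConfig(seed=0)
        assert sa.mutate("ACGTACGT", 0.0, cfg) == "ACGTACGT"

    def test_divergence_matches_closed_form(self):
        # 200 replicates at length 10 kb: mean K2P distance to the ancestor
        # must sit within 3 SE of mu*years
        rng = np.random.default_rng(8)
        cfg = sa.SimConfig(seed=0, mu=6.5e-9)
        anc = "".join(rng.choice(list("ACGT"), 10_000))
        years = 1e6
        kappas = []
        for _ in range(200):
            der = sa.mutate(anc, years, cfg, rng)
            aln = ak.Alignment(anc, der, 0, 0, len(anc), 0, len(der))
            kappas.append(ak.k2p_distance(aln).kappa)
        mean = np.mean(kappas)
        se = np.std(kappas, ddof=1) / math.sqrt(len(kappas))
        assert abs(mean - 6.5e-3) < 3 * se

    def test_infinite_tstv_yields_no_transversions(self):
        rng = np.random.default_rng(1)
        cfg = sa.SimConfig(seed=0, mu=1e-2, tstv=math.inf)
        anc = "".join(rng.choice(list("ACGT"), 5000))
        der = sa.mutate(anc, 1.0, cfg, rng)
        aln = ak.Alignment(anc, der, 0, 0, len(anc), 0, len(der))
        res = ak.k2p_distance(aln)
        assert res.Q == 0.0
        assert res.P > 0.0


class TestInjectVariation:
    def _grown(self, seed_val, n, parents):
        pa, pb = parents
        unit, domains = sa.default_seed_monomer(pb)
        cfg = sa.SimConfig(seed=seed_val, n_monomers_target=n)
        rng = np.random.default_rng(seed_val)
        monomers, truth = sa.grow_array(unit, cfg, rng, seed_domains=domains)
        return monomers, truth, rng

    def test_no_donor_prob_no_tracts(self, parents):
        monomers, truth, rng = self._grown(2, 15, parents)
        cfg = sa.SimConfig(seed=2, donor_tract_prob=0.0)
        _, truth = sa.inject_variation(monomers, truth, parents[0], cfg, rng)
        assert truth.tracts == []

    def test_fixed_ir_copy_number(self, parents):
        monomers, truth, rng = self._grown(3, 15, parents)
        cfg = sa.SimConfig(seed=3, donor_tract_prob=0.0,
                           ir_copy_distribution={3: 1.0})
        monomers, truth = sa.inject_variation(monomers, truth, parents[0], cfg, rng)
        for dm, seq in zip(truth.domain_maps, monomers):
            assert sum(1 for lab, _ in dm if lab == "IR") == 3
            # domain intervals tile the monomer in order
            assert dm[0][1][0] == 0 and dm[-1][1][1] == len(seq)

    def test_tract_replaces_donor_alleles(self, parents):
        pa, pb = parents
        monomers, truth, rng = self._grown(4, 30, parents)
        cfg = sa.SimConfig(seed=4, donor_tract_prob=1.0)
        monomers, truth = sa.inject_variation(monomers, truth, pa, cfg, rng)
        assert len(truth.tracts) == 30
        for t in truth.tracts:
            seq = monomers[t.monomer_index]
            dm = truth.domain_maps[t.monomer_index]
            for pos in range(t.start, t.end):
                assert seq[pos] == pa.sequence[sa._local_to_parent(pos, dm)]

    def test_diagnostic_sites_cover_injected_tract(self, parents):
        # a tract spanning known diagnostic sites is fully donor-typed
        pa, pb = parents
        monomers, truth, rng = self._grown(6, 10, parents)
        cfg = sa.SimConfig(seed=6, donor_tract_prob=1.0)
        monomers, truth = sa.inject_variation(monomers, truth, pa, cfg, rng)
        t = truth.tracts[0]
        dm = truth.domain_maps[t.monomer_index]
        sites, allele_a, _ = sa.parent_diagnostic_sites(dm, pa, pb)
        covered = [i for i, s in enumerate(sites) if t.start <= s < t.end]
        assert covered, "default tract should span at least one diagnostic site"
        seq = monomers[t.monomer_index]
        for i in covered:
            assert seq[sites[i]] == allele_a[i]


class TestNestedInsertions:
    def test_age_zero_gives_identical_ltrs(self):
        cfg = sa.SimConfig(seed=10, n_monomers_target=8,
                           nested_insertions=((0.0, 3000, 5),))
        res = sa.simulate(cfg)
        ins = res.truth.insertions[0]
        l5 = res.sequence[ins.ltr5[0] : ins.ltr5[1]]
        l3 = res.sequence[ins.ltr3[0] : ins.ltr3[1]]
        if ins.strand == "-":
            l5, l3 = sa.revcomp(l3), sa.revcomp(l5)
        assert l5 == l3
        assert ins.kappa_expected == 0.0

    def test_tsd_duplicated_exactly(self):
        cfg = sa.SimConfig(seed=11, n_monomers_target=8,
                           nested_insertions=((1e6, 3000, 5),))
        res = sa.simulate(cfg)
        ins = res.truth.insertions[0]
        assert len(ins.tsd) == 5
        assert res.sequence[ins.start - 5 : ins.start] == ins.tsd
        assert res.sequence[ins.end : ins.end + 5] == ins.tsd

    def test_kappa_calibration_at_reference_age(self):
        # age 0.94 My at mu=6.5e-9 -> expected kappa 0.01222
        mu = 6.5e-9
        age = 0.94e6
        assert 2 * mu * age == pytest.approx(0.01222)
        rng = np.random.default_rng(12)
        cfg = sa.SimConfig(seed=0, mu=mu)
        kappas = []
        for _ in range(50):
            ltr = "".join(rng.choice(list("ACGT"), 1000))
            a = sa.mutate(ltr, age, cfg, rng)
            b = sa.mutate(ltr, age, cfg, rng)
            kappas.append(ak.k2p_distance(ak.global_align(a, b)).kappa)
        mean = np.mean(kappas)
        se = np.std(kappas, ddof=1) / math.sqrt(len(kappas))
        assert abs(mean - 0.01222) < 3 * se


class TestSimulatePipeline:
    def test_truth_intervals_match_emitted_sequence(self, small_locus):
        res = small_locus
        t = res.truth
        interrupted = [
            (s, e)
            for s, e in t.monomer_intervals
            if any(s < ins.end and ins.start < e for ins in t.insertions)
        ]
        for (s, e), mseq in zip(t.monomer_intervals, t.monomer_seqs):
            if (s, e) in interrupted:
                continue
            assert res.sequence[s:e] == mseq

    def test_length_conservation(self, small_locus):
        res = small_locus
        t = res.truth
        expected = (
            2 * res.config.flank_len
            + sum(len(m) for m in t.monomer_seqs)
            + sum(i.end - i.start + len(i.tsd) for i in t.insertions)
        )
        assert len(res.sequence) == expected

    def test_byte_identical_under_fixed_config(self):
        cfg = sa.SimConfig(seed=21, n_monomers_target=10,
                           array_age_years=years_for_divergence(0.03),
                           nested_insertions=((0.5e6, 2500, 4),))
        r1, r2 = sa.simulate(cfg), sa.simulate(cfg)
        assert r1.sequence == r2.sequence
        assert r1.truth.to_json() == r2.truth.to_json()

    def test_divergence_grows_linearly_with_age(self):
        # pairwise monomer K2P distance ~ 2*mu*years: regression slope
        # within 10% over 20 replicates
        import itertools

        mu = 6.5e-9
        ages = [0.5e6, 1e6, 2e6, 4e6]
        xs, ys = [], []
        for i, age in enumerate(ages):
            for rep in range(5):
                cfg = sa.SimConfig(
                    seed=1000 + 10 * i + rep, n_monomers_target=16,
                    array_age_years=age, donor_tract_prob=0.0,
                    ir_copy_distribution={1: 1.0},
                )
                res = sa.simulate(cfg)
                kappas = [
                    ak.k2p_distance(
                        ak.Alignment(a, b, 0, 0, len(a), 0, len(b))
                    ).kappa
                    for a, b in itertools.combinations(res.truth.monomer_seqs, 2)
                ]
                xs.append(age)
                ys.append(float(np.mean(kappas)))
        slope = np.polyfit(xs, ys, 1)[0]
        assert slope == pytest.approx(2 * mu, rel=0.10)

    def test_truth_roundtrips_through_json(self, small_locus):
        t = small_locus.truth
        assert sa.ArrayTruth.from_json(t.to_json()).to_json() == t.to_json()
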