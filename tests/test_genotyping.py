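from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from packped.genotypes import AlleleFrequencyTable, ErrorModel
from packped.genotyping import (STATUS_HET, STATUS_HOM, STATUS_MISSING,
                                call_consensus, cluster_samples, consensus_table,
                                match_genotypes, reliability_score, screen_sample)
from packped.popstats import consensus_from_array
from packped.simulate import SimulationConfig, simulate_noninvasive_samples, simulate_population


def reps_frame(rows):
    """rows: (locus, replicate, a1, a2)"""
    return pd.DataFrame([{"sample_id": "s", "locus": l, "replicate": r,
                          "allele1": a1, "allele2": a2} for l, r, a1, a2 in rows])


def locus_reps(pairs, locus="L1"):
    return reps_frame([(locus, r, a, b) for r, (a, b) in enumerate(pairs)])


class TestScreening:
    @pytest.mark.parametrize("n_amplified,keep", [(5, True), (4, False), (18, True)])
    def test_five_locus_rule_boundary(self, n_amplified, keep):
        rows = []
        for i in range(18):
            a = 1 if i < n_amplified else 0
            rows.append((f"L{i:02d}", 0, a, a))
            rows.append((f"L{i:02d}", 1, a, a))
        assert screen_sample(reps_frame(rows)) is keep

    def test_only_first_two_pcrs_count(self):
        rows = [(f"L{i:02d}", 2, 1, 1) for i in range(18)]  # later replicate
        rows += [(f"L{i:02d}", 0, 1 if i < 3 else 0, 1 if i < 3 else 0) for i in range(18)]
        assert screen_sample(reps_frame(rows)) is False

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            screen_sample(reps_frame([]))


class TestConsensusRules:
    def test_heterozygote_confirmed_by_two_pcrs(self):
        g = call_consensus(locus_reps([(1, 2), (1, 2)]))
        assert g.status[0] == STATUS_HET
        assert tuple(g.alleles[0]) == (1, 2)

    def test_homozygote_needs_three_pcrs(self):
        g = call_consensus(locus_reps([(1, 1), (1, 1), (1, 1)]))
        assert g.status[0] == STATUS_HOM
        g2 = call_consensus(locus_reps([(1, 1), (1, 1)]))
        assert g2.status[0] == STATUS_MISSING

    def test_replicated_second_allele_vetoes_homozygote(self):
        g = call_consensus(locus_reps([(1, 1), (1, 1), (1, 1), (1, 2), (1, 2)]))
        # the het pair (1,2) is itself confirmed by 2 PCRs
        assert g.status[0] == STATUS_HET

    def test_consensus_against_exhaustive_rule_enumeration(self):
        """All replicate patterns at 3 alleles, 2-4 PCRs, vs a direct
        restatement of the calling rules."""
        observable = [(0, 0), (1, 1), (2, 2), (3, 3), (1, 2), (1, 3), (2, 3)]

        def reference_call(pairs):
            amped = [p for p in pairs if p != (0, 0)]
            hets = {}
            singles = {}
            presence = {}
            for (a, b) in amped:
                for al in {a, b}:
                    presence[al] = presence.get(al, 0) + 1
                if a == b:
                    singles[a] = singles.get(a, 0) + 1
                else:
                    hets[(a, b)] = hets.get((a, b), 0) + 1
            confirmed = [p for p, c in hets.items() if c >= 2]
            if len(confirmed) == 1:
                return (STATUS_HET, confirmed[0])
            if len(confirmed) > 1:
                return (STATUS_MISSING, (0, 0))
            for a in sorted(singles):
                if singles[a] >= 3 and not any(
                        al != a and c >= 2 for al, c in presence.items()):
                    return (STATUS_HOM, (a, a))
            return (STATUS_MISSING, (0, 0))

        for n in (2, 3, 4):
            for pattern in product(observable, repeat=n):
                got = call_consensus(locus_reps(list(pattern)))
                want_status, want_pair = reference_call(pattern)
                assert got.status[0] == want_status, pattern
                if want_status != STATUS_MISSING:
                    assert tuple(got.alleles[0]) == want_pair, pattern

    @given(st.lists(st.sampled_from([(1, 2), (1, 1), (2, 2), (1, 3), (0, 0)]),
                    min_size=0, max_size=4))
    @settings(max_examples=60, deadline=None)
    def test_adding_replicates_never_demotes_confirmed_het(self, extra):
        base = [(1, 2), (1, 2)]
        g0 = call_consensus(locus_reps(base))
        assert g0.status[0] == STATUS_HET
        g1 = call_consensus(locus_reps(base + extra))
        # monotone: the confirmed het stays confirmed unless a *different*
        # het pair also reaches confirmation (conflict) — with these extras
        # only (1,3)x2 could conflict
        if extra.count((1, 3)) < 2:
            assert g1.status[0] == STATUS_HET
            assert tuple(g1.alleles[0]) == (1, 2)


def consensus_of(pairs):
    return consensus_from_array(np.array(pairs))


class TestMatching:
    def test_identical_full_genotypes_match(self):
        g = consensus_of([(i + 1, i + 2) for i in range(18)])
        assert match_genotypes(g, g) == "same-individual"

    def test_single_dropout_pattern_matches(self):
        a = [(102, 102)] + [(i + 1, i + 2) for i in range(17)]
        b = [(102, 106)] + [(i + 1, i + 2) for i in range(17)]
        assert match_genotypes(consensus_of(a), consensus_of(b)) == "same-individual"

    def test_two_dropout_mismatches_differ(self):
        a = [(1, 1), (5, 5)] + [(i + 1, i + 2) for i in range(16)]
        b = [(1, 2), (5, 6)] + [(i + 1, i + 2) for i in range(16)]
        assert match_genotypes(consensus_of(a), consensus_of(b)) == "different"

    def test_incompatible_locus_differs(self):
        a = [(1, 2)] + [(i + 1, i + 2) for i in range(17)]
        b = [(3, 4)] + [(i + 1, i + 2) for i in range(17)]
        assert match_genotypes(consensus_of(a), consensus_of(b)) == "different"

    def test_too_few_shared_loci_indeterminate(self):
        a = consensus_of([(1, 2)] * 5 + [(0, 0)] * 13)
        b = consensus_of([(1, 2)] * 18)
        assert match_genotypes(a, b) == "indeterminate"

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = consensus_of(np.sort(rng.integers(1, 4, (18, 2)), axis=1))
        b = consensus_of(np.sort(rng.integers(1, 4, (18, 2)), axis=1))
        assert match_genotypes(a, b) == match_genotypes(b, a)

    def test_dropout_relation_not_transitive_but_clustering_deterministic(self):
        # a matches b (1 dropout), b matches c (1 dropout at another locus),
        # but a and c mismatch at 2 loci -> not transitive
        base = [(i + 1, i + 2) for i in range(16)]
        a = consensus_of([(1, 1), (5, 6)] + base)
        b = consensus_of([(1, 2), (5, 6)] + base)
        c = consensus_of([(1, 2), (5, 5)] + base)
        a.sample_id, b.sample_id, c.sample_id = "a", "b", "c"
        assert match_genotypes(a, b) == "same-individual"
        assert match_genotypes(b, c) == "same-individual"
        assert match_genotypes(a, c) == "different"
        # equal-rank samples: id ascending order fixes the partition
        import itertools
        results = set()
        for perm in itertools.permutations([a, b, c]):
            cat = cluster_samples(list(perm))
            results.add(tuple(sorted(tuple(sorted(map(str, e.sample_ids)))
                                     for e in cat.entries)))
        assert len(results) == 1


class TestClustering:
    def test_identical_samples_collapse(self):
        gs = []
        for i in range(6):
            g = consensus_of([(j + 1, j + 2) for j in range(18)])
            g.sample_id = i
            gs.append(g)
        cat = cluster_samples(gs)
        assert len(cat) == 1
        assert len(cat.entries[0].sample_ids) == 6

    def test_error_free_simulation_recovers_every_individual(self, small_pop, no_error):
        reps = simulate_noninvasive_samples(small_pop, no_error)
        cat = cluster_samples(consensus_table(reps))
        assert len(cat) == reps.individual_id.nunique()

    def test_noisy_simulation_catalog_size_close_to_truth(self, small_pop):
        reps = simulate_noninvasive_samples(
            small_pop, ErrorModel(0.01, 0.01, 0.05),
            rng=np.random.default_rng(77))
        cat = cluster_samples(consensus_table(reps))
        truth = reps.individual_id.nunique()
        assert abs(len(cat) - truth) / truth < 0.02


class TestReliability:
    def test_error_free_confirmed_genotype_scores_one(self, uniform4):
        reps = locus_reps([(1, 2), (1, 2)], locus="L01")
        g = call_consensus(reps, loci=["L01"])
        score, ok = reliability_score(g, reps, uniform4, ErrorModel(0, 0, 0))
        assert score == pytest.approx(1.0)
        assert ok

    def test_homozygote_score_matches_hand_enumeration(self):
        """(a,a) in 3 PCRs, dropout d, p(a)=0.5, two alleles: Bayes over the
        three genotypes {aa, ab, bb}."""
        d = 0.01
        freqs = AlleleFrequencyTable([{1: 0.5, 2: 0.5}])
        reps = locus_reps([(1, 1)] * 3, locus="L01")
        g = call_consensus(reps, loci=["L01"])
        assert g.status[0] == STATUS_HOM
        score, _ = reliability_score(g, reps, freqs, ErrorModel(d, 0.0, 0.0))
        # hand enumeration: per PCR P((1,1)|aa) = (1-d)^2 + 2d(1-d)... both
        # fates keep allele 1 or one drops; P((1,1)|ab) = (1-d)d (allele 2
        # drops, allele 1 kept); P((1,1)|bb) = 0
        p_aa = ((1 - d) ** 2 + 2 * d * (1 - d)) ** 3 * 0.25
        p_ab = ((1 - d) * d) ** 3 * 0.5
        expected = p_aa / (p_aa + p_ab)
        assert score == pytest.approx(expected, rel=1e-12)

    def test_score_decreasing_in_dropout_for_homozygotes(self, uniform4):
        reps = locus_reps([(1, 1)] * 3, locus="L01")
        g = call_consensus(reps, loci=["L01"])
        scores = [reliability_score(g, reps, uniform4, ErrorModel(d, 0.0, 0.0))[0]
                  for d in (0.0, 0.01, 0.05, 0.2)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_unknown_allele_raises(self, uniform4):
        reps = locus_reps([(9, 9)] * 3, locus="L01")
        g = call_consensus(reps, loci=["L01"])
        with pytest.raises(KeyError):
            reliability_score(g, reps, uniform4, ErrorModel(0.01, 0.0, 0.0))

    def test_single_detection_noise_free_all_reliable(self, small_pop, no_error):
        reps = simulate_noninvasive_samples(small_pop, no_error)
        one_sample = reps[reps.sample_id == reps.sample_id.iloc[0]]
        g = call_consensus(one_sample, loci=small_pop.freqs.loci)
        score, ok = reliability_score(g, one_sample, small_pop.freqs, no_error)
        assert ok and score == pytest.approx(1.0)
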