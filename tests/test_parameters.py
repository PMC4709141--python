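"""Parameter estimation: counting, tiered aggregation, normalization,
Viterbi training, and bootstrap uncertainties."""

from collections import Counter

import numpy as np
import pytest

from vdjhmm.annotation import Annotation, naive_sequence
from vdjhmm.parameters import (
    MUTATION_P_MAX,
    MUTATION_P_MIN,
    CountTables,
    ParameterSet,
    bootstrap_uncertainty,
    build_parameter_set,
    count_events,
    tiered_counts,
    viterbi_train,
)
from vdjhmm.simulate import SimulatorConfig, simulate_sample


def _make_annotation(germline, rid="q", v="IGHV1-2*01", d="IGHD2-2*01",
                     j="IGHJ4*01", v_3p=0, vd="", mutated=()):
    naive = naive_sequence(germline, v, d, j, 0, v_3p, 0, 0, 0, 0, vd, "")
    return Annotation(
        query_ids=(rid,), v_allele=v, d_allele=d, j_allele=j,
        v_5p_del=0, v_3p_del=v_3p, d_5p_del=0, d_3p_del=0,
        j_5p_del=0, j_3p_del=0, vd_insertion=vd, dj_insertion="",
        naive_seq=naive, mutated_positions=(tuple(mutated),),
    )


class TestCountEvents:
    def test_deletion_lengths_tallied(self, germline):
        anns = [
            _make_annotation(germline, "a", v_3p=1),
            _make_annotation(germline, "b", v_3p=3),
        ]
        counts = count_events(anns, germline)
        assert counts.deletions[("IGHV1-2*01", "v_3p")] == Counter({1: 1, 3: 1})
        assert counts.allele_counts["IGHV1-2*01"] == 2

    def test_insertion_lengths_and_bases_tallied(self, germline):
        counts = count_events(
            [_make_annotation(germline, vd="GGA")], germline
        )
        assert counts.insertion_lengths["vd"] == Counter({3: 1})
        assert counts.insertion_bases["vd"] == Counter({"G": 2, "A": 1})

    def test_mutations_tallied_at_covered_positions(self, germline):
        anns = [
            _make_annotation(germline, rid=f"r{i}",
                             mutated=(7,) if i < 4 else ())
            for i in range(10)
        ]
        counts = count_events(anns, germline)
        # read position 7 maps to germline position 7 (no 5' deletion)
        assert counts.mutation["IGHV1-2*01"][7] == [4, 10]

    def test_unknown_allele_rejected(self, germline):
        ann = _make_annotation(germline)
        ann.v_allele = "IGHV5-99*01"
        with pytest.raises(KeyError, match="IGHV5-99"):
            count_events([ann], germline)


class TestTieredAggregation:
    def _counts(self, germline, obs: dict) -> CountTables:
        counts = CountTables()
        for allele, n in obs.items():
            counts.allele_counts[allele] = n
            dtype = {"V": "v_3p", "D": "d_3p", "J": "j_3p"}[
                germline[allele].segment
            ]
            counts.deletions[(allele, dtype)][1] = n
        return counts

    def test_well_observed_allele_stays_at_allele_tier(self, germline):
        counts = self._counts(germline, {"IGHV1-2*01": 25})
        agg, tier = tiered_counts(counts, germline, "IGHV1-2*01", min_obs=20)
        assert tier == "allele"
        assert agg.n_obs == 25
        assert agg.deletions["v_3p"] == Counter({1: 25})

    def test_sparse_allele_pools_allelic_variants(self, germline):
        counts = self._counts(germline, {"IGHV1-2*01": 3, "IGHV1-2*02": 30})
        agg, tier = tiered_counts(counts, germline, "IGHV1-2*01", min_obs=20)
        assert tier == "gene"
        assert agg.n_obs == 33
        assert agg.deletions["v_3p"] == Counter({1: 33})

    def test_sparse_family_falls_through_to_segment(self, germline):
        counts = self._counts(germline, {"IGHV1-2*01": 2, "IGHV1-18*01": 3,
                                         "IGHV3-23*01": 40})
        agg, tier = tiered_counts(counts, germline, "IGHV1-2*01", min_obs=20)
        assert tier == "segment"
        assert agg.n_obs == 45

    def test_tier_is_monotone_in_min_obs(self, germline):
        counts = self._counts(
            germline, {"IGHV1-2*01": 5, "IGHV1-2*02": 10, "IGHV1-18*01": 30}
        )
        order = {t: i for i, t in enumerate(("allele", "gene", "family",
                                             "segment"))}
        last = -1
        for min_obs in (1, 5, 10, 16, 40, 50, 100):
            _, tier = tiered_counts(counts, germline, "IGHV1-2*01", min_obs)
            assert order[tier] >= last
            last = order[tier]


class TestBuildParameterSet:
    def test_usage_deletion_and_insertion_normalization(self, germline):
        anns = (
            [_make_annotation(germline, f"a{i}", v_3p=0, vd="GG")
             for i in range(5)]
            + [_make_annotation(germline, f"b{i}", v_3p=2, vd="GG")
               for i in range(15)]
            + [_make_annotation(germline, f"c{i}", v="IGHV3-23*01", vd="GGGGG")
               for i in range(10)]
        )
        params = build_parameter_set(count_events(anns, germline), germline,
                                     min_obs=20)
        assert params.q_g["V"]["IGHV1-2*01"] == pytest.approx(20 / 30)
        assert params.q_g["V"]["IGHV3-23*01"] == pytest.approx(10 / 30)
        dist = params.deletion_dists[("IGHV1-2*01", "v_3p")]
        assert dist == pytest.approx({0: 0.25, 2: 0.75})
        # lengths {2}x20 and {5}x10 -> mean 3.0
        assert params.insertion_mean_len["vd"] == pytest.approx(3.0)
        params.validate()

    def test_mutation_probabilities_clamped(self, germline):
        anns = [
            _make_annotation(germline, f"r{i}", mutated=(0,))
            for i in range(30)
        ]
        params = build_parameter_set(count_events(anns, germline), germline)
        # position 0 mutated in every read -> clamped at the ceiling
        assert params.mutation_freq["IGHV1-2*01"][0] == MUTATION_P_MAX
        # position 1 never mutated -> clamped at the floor
        assert params.mutation_freq["IGHV1-2*01"][1] == MUTATION_P_MIN

    def test_empty_counts_rejected(self, germline):
        with pytest.raises(ValueError, match="segment"):
            build_parameter_set(CountTables(), germline)

    def test_round_trip_through_csv_directory(self, germline, tmp_path):
        anns = [_make_annotation(germline, f"r{i}", v_3p=i % 3, vd="AG")
                for i in range(25)]
        params = build_parameter_set(count_events(anns, germline), germline)
        params.save(tmp_path / "pdir")
        back = ParameterSet.load(tmp_path / "pdir")
        assert back.q_g == params.q_g
        assert back.deletion_dists == params.deletion_dists
        assert back.insertion_mean_len == pytest.approx(
            params.insertion_mean_len
        )
        assert back.mutation_freq == params.mutation_freq
        assert back.tiers == params.tiers


class TestViterbiTrain:
    def test_empty_read_set_rejected(self, germline):
        with pytest.raises(ValueError, match="empty"):
            viterbi_train([], germline)

    def test_zero_mutation_training_recovers_sample_usage(
        self, germline, true_params
    ):
        _, reads, truth = simulate_sample(
            true_params, germline,
            SimulatorConfig(n_events=150, leaves_per_event=1,
                            mutation_multiplier=0.0), rng=21,
        )
        params, per_round = viterbi_train(reads, germline, rounds=1)
        # empirical usage of the sample itself
        usage = Counter(t.v_allele for t in truth)
        for allele, n in usage.items():
            assert params.q_g["V"][allele] == pytest.approx(
                n / len(truth), abs=0.02
            )
        assert len(per_round) == 2

    def test_second_round_changes_little(self, germline, true_params):
        _, reads, _ = simulate_sample(
            true_params, germline,
            SimulatorConfig(n_events=200, leaves_per_event=5), rng=22,
        )
        params2, per_round = viterbi_train(reads, germline, rounds=2)
        params1 = build_parameter_set(
            count_events(per_round[1], germline), germline
        )

        def tv(d1, d2):
            keys = set(d1) | set(d2)
            return 0.5 * sum(abs(d1.get(k, 0) - d2.get(k, 0)) for k in keys)

        counts1 = count_events(per_round[1], germline)
        dists, weights = [], []
        for key in params1.deletion_dists:
            dists.append(
                tv(params1.deletion_dists[key], params2.deletion_dists[key])
            )
            weights.append(counts1.allele_counts.get(key[0], 0))
        weighted_mean = np.average(dists, weights=weights)
        assert weighted_mean < 0.05
        assert max(dists) < 0.15  # individual sparse tables may jitter more


class TestBootstrap:
    def test_identical_subsets_have_zero_uncertainty(
        self, germline, true_params
    ):
        _, reads, _ = simulate_sample(
            true_params, germline,
            SimulatorConfig(n_events=10, leaves_per_event=1,
                            mutation_multiplier=0.0), rng=30,
        )
        # two copies of the same reads, round-robin split -> identical halves
        doubled = []
        for rid, seq in reads:
            doubled.append((rid + "-1", seq))
            doubled.append((rid + "-2", seq))
        out = bootstrap_uncertainty(doubled, germline, n_subsets=2, rounds=0)
        for mean, unc in out.values():
            assert unc == pytest.approx(0.0, abs=1e-12)

    def test_uncertainty_is_twice_the_subset_std(self, germline, true_params):
        _, reads, _ = simulate_sample(
            true_params, germline,
            SimulatorConfig(n_events=40, leaves_per_event=1,
                            mutation_multiplier=0.0), rng=31,
        )
        out = bootstrap_uncertainty(reads, germline, n_subsets=2, rounds=0)
        # recompute one parameter by hand from the two halves
        from vdjhmm.sw import sw_match

        halves = [reads[0::2], reads[1::2]]
        q_vals = []
        for half in halves:
            anns = [sw_match(s, germline, query_id=r).provisional
                    for r, s in half]
            params = build_parameter_set(count_events(anns, germline), germline)
            q_vals.append(params.q_g["V"]["IGHV1-18*01"])
        key = ("q", "IGHV1-18*01")
        assert out[key][0] == pytest.approx(np.mean(q_vals))
        assert out[key][1] == pytest.approx(2 * np.std(q_vals, ddof=1))

    def test_fewer_reads_than_subsets_rejected(self, germline):
        with pytest.raises(ValueError, match="subsets"):
            bootstrap_uncertainty([("r", "ACGT")], germline, n_subsets=10)
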