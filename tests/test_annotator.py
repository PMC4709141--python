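"""Per-allele HMM construction and factorized annotation inference."""

import pytest

from vdjhmm.annotation import naive_sequence
from vdjhmm.annotator import (
    AnnotatorConfig,
    annotate,
    annotate_batch,
    build_allele_hmm,
)
from vdjhmm.germline import GermlineAllele, GermlineSet
from vdjhmm.parameters import ParameterSet
from vdjhmm.simulate import SimulatorConfig, simulate_sample
from vdjhmm.sw import AnnotationFailure


def _uniform_params(germline, mutation_p=0.001, ins_range=5):
    """Flat hand-built parameters for constructed-fixture tests."""
    q_g = {
        seg: {a: 1.0 / len(germline.segment_alleles(seg))
              for a in germline.segment_alleles(seg)}
        for seg in ("V", "D", "J")
    }
    deletion_dists = {}
    mutation_freq = {}
    for seg, (d5, d3) in (
        ("V", ("v_5p", "v_3p")), ("D", ("d_5p", "d_3p")), ("J", ("j_5p", "j_3p"))
    ):
        for a in germline.segment_alleles(seg):
            n = len(germline.seq(a))
            support = min(4, max(1, (n - 1) // 2))
            flat = {i: 1.0 / support for i in range(support)}
            deletion_dists[(a, d5)] = dict(flat)
            deletion_dists[(a, d3)] = dict(flat)
            mutation_freq[a] = {i: mutation_p for i in range(n)}
    ins_len = {i: 1.0 / ins_range for i in range(ins_range)}
    mean_len = sum(l * p for l, p in ins_len.items())
    params = ParameterSet(
        q_g=q_g,
        deletion_dists=deletion_dists,
        insertion_length_dists={"vd": dict(ins_len), "dj": dict(ins_len)},
        insertion_mean_len={"vd": mean_len, "dj": mean_len},
        insertion_base_freqs={
            b: {x: 0.25 for x in "ACGT"} for b in ("vd", "dj")
        },
        mutation_freq=mutation_freq,
        overall_mutation_mean=mutation_p,
    )
    params.validate()
    return params


@pytest.fixture(scope="module")
def fixed_germline():
    """Hand-picked genes whose junction-adjacent bases are distinctive."""
    alleles = {
        "IGHV7-1*01": GermlineAllele("IGHV7-1*01", "V", "ATGGCCGATTCACT"),
        "IGHD7-7*01": GermlineAllele("IGHD7-7*01", "D", "GGGTACGG"),
        "IGHJ7*01": GermlineAllele("IGHJ7*01", "J", "CCTTAAGACC"),
    }
    return GermlineSet(alleles)


class TestBuildAlleleHMM:
    def test_emissions_follow_p_over_3_rule(self, fixed_germline):
        params = _uniform_params(fixed_germline)
        params.mutation_freq["IGHV7-1*01"][3] = 0.3
        am = build_allele_hmm(fixed_germline["IGHV7-1*01"], params)
        # germline base at position 3 is G
        em = am.model.state("g3").emissions
        assert em == pytest.approx({"G": 0.7, "A": 0.1, "C": 0.1, "T": 0.1})

    def test_zero_mutation_gives_point_emission(self, fixed_germline):
        params = _uniform_params(fixed_germline)
        params.mutation_freq["IGHV7-1*01"][0] = 0.0
        am = build_allele_hmm(fixed_germline["IGHV7-1*01"], params)
        em = am.model.state("g0").emissions  # germline A
        assert em == pytest.approx({"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0})

    def test_exit_probabilities_reproduce_deletion_table(self):
        gs = GermlineSet(
            {
                "IGHV8-1*01": GermlineAllele("IGHV8-1*01", "V", "ACGTACGTAC"),
                "IGHD8-1*01": GermlineAllele("IGHD8-1*01", "D", "ACGT"),
                "IGHJ8*01": GermlineAllele("IGHJ8*01", "J", "ACGT"),
            }
        )
        params = _uniform_params(gs)
        params.deletion_dists[("IGHV8-1*01", "v_3p")] = {0: 0.75, 2: 0.25}
        am = build_allele_hmm(gs["IGHV8-1*01"], params)
        # conditional (hazard) form: given arrival at state 7 the path exits
        # with 0.25; state 8 cannot exit; state 9 always exits
        assert am.model.state("g7").transitions["END"] == pytest.approx(0.25)
        assert "END" not in am.model.state("g8").transitions
        assert am.model.state("g9").transitions["END"] == pytest.approx(1.0)
        # unconditional exit mass telescopes back to the table
        survive_7 = 1.0 - 0.25
        assert survive_7 * 1.0 * 1.0 == pytest.approx(0.75)

    def test_entry_probabilities_encode_5p_deletions(self, fixed_germline):
        params = _uniform_params(fixed_germline)
        params.deletion_dists[("IGHV7-1*01", "v_5p")] = {0: 0.6, 2: 0.4}
        am = build_allele_hmm(fixed_germline["IGHV7-1*01"], params)
        assert am.model.initial_transitions == pytest.approx(
            {"g0": 0.6, "g2": 0.4}
        )

    def test_insert_states_only_on_d_and_j_models(self, fixed_germline):
        params = _uniform_params(fixed_germline)
        v = build_allele_hmm(fixed_germline["IGHV7-1*01"], params)
        d = build_allele_hmm(fixed_germline["IGHD7-7*01"], params)
        j = build_allele_hmm(fixed_germline["IGHJ7*01"], params)
        assert not any(s.name.startswith("i") for s in v.model.states)
        for model, boundary in ((d, "vd"), (j, "dj")):
            names = {s.name for s in model.model.states}
            assert {"iA", "iC", "iG", "iT"} <= names
            assert model.insert_boundary == boundary

    def test_insert_geometry_matches_mean_positive_length(self, fixed_germline):
        params = _uniform_params(fixed_germline, ins_range=5)
        am = build_allele_hmm(fixed_germline["IGHD7-7*01"], params)
        # uniform lengths 0..4: P(>0) = 0.8, mean positive length 2.5
        stay = sum(
            p for t, p in am.model.state("iA").transitions.items()
            if t.startswith("i")
        )
        assert stay == pytest.approx(1 - 1 / 2.5)
        p_ins = sum(
            p for t, p in am.model.initial_transitions.items()
            if t.startswith("i")
        )
        assert p_ins == pytest.approx(0.8)


class TestAnnotate:
    def test_zero_mutation_identifiable_event_recovered_exactly(
        self, fixed_germline
    ):
        params = _uniform_params(fixed_germline)
        # junction bases chosen to differ from the adjacent germline bases,
        # so no boundary slide can re-explain the read
        v, d, j = "IGHV7-1*01", "IGHD7-7*01", "IGHJ7*01"
        read = naive_sequence(
            fixed_germline, v, d, j, 0, 1, 1, 0, 0, 0, "CC", "TT"
        )
        ann = annotate(
            [("q", read)], fixed_germline, params,
            config=AnnotatorConfig(mode="both", exhaustive_kbounds=True),
        )
        assert (ann.v_allele, ann.d_allele, ann.j_allele) == (v, d, j)
        assert (ann.v_3p_del, ann.d_5p_del) == (1, 1)
        assert (ann.vd_insertion, ann.dj_insertion) == ("CC", "TT")
        assert ann.naive_seq == read
        assert ann.mutated_positions == ((),)
        assert ann.viterbi_log_prob <= ann.forward_log_prob + 1e-12

    def test_multi_hmm_k1_equals_single_sequence_mode(
        self, germline, true_params
    ):
        _, reads, _ = simulate_sample(
            true_params, germline,
            SimulatorConfig(n_events=5, leaves_per_event=1), rng=40,
        )
        config = AnnotatorConfig(mode="both")
        for rid, seq in reads:
            single = annotate([(rid, seq)], germline, true_params,
                              config=config)
            multi = annotate([(rid, seq)], germline, true_params,
                             config=config)
            assert single == multi

    def test_n_region_majority_vote_across_clonal_reads(self, fixed_germline):
        params = _uniform_params(fixed_germline, mutation_p=0.05)
        v, d, j = "IGHV7-1*01", "IGHD7-7*01", "IGHJ7*01"
        naive = naive_sequence(
            fixed_germline, v, d, j, 0, 0, 0, 0, 0, 0, "CCCC", ""
        )
        # the VD insert occupies read positions 14..17; mutate one base of
        # one read inside the N-region
        pos = 15
        mutated = naive[:pos] + "T" + naive[pos + 1:]
        reads = [(f"r{i}", naive) for i in range(4)] + [("r4", mutated)]
        ann = annotate(
            reads, fixed_germline, params,
            config=AnnotatorConfig(mode="viterbi", exhaustive_kbounds=True),
        )
        assert ann.vd_insertion == "CCCC"  # four unmutated votes win
        assert ann.naive_seq == naive
        assert ann.mutated_positions[4] == (pos,)

    def test_viterbi_log_prob_bounded_by_forward(self, germline, true_params):
        _, reads, _ = simulate_sample(
            true_params, germline,
            SimulatorConfig(n_events=10, leaves_per_event=1), rng=41,
        )
        for rid, seq in reads:
            ann = annotate([(rid, seq)], germline, true_params,
                           config=AnnotatorConfig(mode="both", extra_fuzz=15))
            assert ann.viterbi_log_prob <= ann.forward_log_prob + 1e-9

    def test_length_bookkeeping_holds_for_all_outputs(
        self, germline, true_params
    ):
        _, reads, _ = simulate_sample(
            true_params, germline,
            SimulatorConfig(n_events=20, leaves_per_event=1), rng=42,
        )
        anns, failures = annotate_batch(reads, germline, true_params)
        assert not failures
        for ann in anns:
            ann.check_lengths(germline)  # raises on violation
            assert len(ann.naive_seq) == len(dict(reads)[ann.query_ids[0]])

    def test_empty_candidates_recorded_as_failure(self, fixed_germline):
        params = _uniform_params(fixed_germline)
        params.q_g["D"]["IGHD7-7*01"] = 0.0
        read = naive_sequence(
            fixed_germline, "IGHV7-1*01", "IGHD7-7*01", "IGHJ7*01",
            0, 0, 0, 0, 0, 0, "", "",
        )
        with pytest.raises(AnnotationFailure, match="candidate"):
            annotate([("q", read)], fixed_germline, params,
                     config=AnnotatorConfig(exhaustive_kbounds=True))


class TestAnnotateBatch:
    def test_groupings_produce_one_annotation_per_family(
        self, germline, true_params
    ):
        _, reads, truth = simulate_sample(
            true_params, germline,
            SimulatorConfig(n_events=20, leaves_per_event=5), rng=43,
        )
        groups = [list(t.query_ids) for t in truth]
        anns, failures = annotate_batch(
            reads, germline, true_params, groupings=groups
        )
        assert not failures
        assert len(anns) == 20
        assert all(a.k == 5 for a in anns)

    def test_batch_is_deterministic(self, germline, true_params, tmp_path):
        from vdjhmm.annotation import write_annotations

        _, reads, _ = simulate_sample(
            true_params, germline,
            SimulatorConfig(n_events=10, leaves_per_event=2), rng=44,
        )
        out = []
        for name in ("a.csv", "b.csv"):
            anns, _ = annotate_batch(reads, germline, true_params)
            path = tmp_path / name
            write_annotations(anns, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_failed_reads_listed_not_dropped(self, germline, true_params):
        reads = [("ok", None), ("junk", "TTTTTTTTTT")]
        _, sim_reads, _ = simulate_sample(
            true_params, germline,
            SimulatorConfig(n_events=1, leaves_per_event=1), rng=45,
        )
        reads[0] = ("ok", sim_reads[0][1])
        anns, failures = annotate_batch(reads, germline, true_params)
        assert len(anns) == 1 and anns[0].query_ids == ("ok",)
        assert len(failures) == 1 and failures[0][0] == "junk"
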