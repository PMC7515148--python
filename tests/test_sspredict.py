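import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpseq import sspredict, synthetic_data
from idpseq.seqio import SequenceRecord
from idpseq.sspredict import PredictorSpec, SSTrack


def spec_list(n):
    return [PredictorSpec(f"p{i}", i, "external_track") for i in range(1, n + 1)]


def make_tracks(votes_per_track):
    return [SSTrack(id="x", labels=v) for v in votes_per_track]


class TestPropensityPredictor:
    def test_window1_argmax_forced(self):
        scale = {aa: (0.0, 0.0, 1.0) for aa in "ACDEFGHIKLMNPQRSTVWY"}
        scale["A"] = (5.0, 0.0, 0.0)
        rec = SequenceRecord(id="x", sequence="AAAA")
        assert sspredict.predict_propensity(rec, scale, window=1).labels == "HHHH"

    def test_window3_means_hand_computed(self):
        # crafted scale: window means at position 2 of "AKA" are
        # H: (2+0+2)/3 = 4/3, E: (0+5+0)/3 = 5/3, C: (1+1+1)/3 = 1 -> E wins
        scale = {aa: (0.0, 0.0, 0.0) for aa in "ACDEFGHIKLMNPQRSTVWY"}
        scale["A"] = (2.0, 0.0, 1.0)
        scale["K"] = (0.0, 5.0, 1.0)
        rec = SequenceRecord(id="x", sequence="AKA")
        track = sspredict.predict_propensity(rec, scale, window=3)
        assert track.labels[1] == "E"

    def test_all_equal_propensities_fall_back_to_coil(self):
        scale = {aa: (1.0, 1.0, 1.0) for aa in "ACDEFGHIKLMNPQRSTVWY"}
        rec = SequenceRecord(id="x", sequence="MKVLA")
        assert sspredict.predict_propensity(rec, scale, window=3).labels == "CCCCC"

    def test_even_window_rejected(self):
        rec = SequenceRecord(id="x", sequence="MKVLA")
        with pytest.raises(ValueError, match="odd"):
            sspredict.predict_propensity(rec, window=4)


class TestGOR:
    def test_sign_forced_by_construction(self):
        # 'A' occurs only in H states, 'K' only in E, 'V' only in C
        corpus = [
            (SequenceRecord(id="1", sequence="AAKKVV"), SSTrack(id="1", labels="HHEECC")),
            (SequenceRecord(id="2", sequence="AKV"), SSTrack(id="2", labels="HEC")),
        ]
        model = sspredict.train_gor(corpus, window=1, pseudocount=0.5)
        a = "ACDEFGHIKLMNPQRSTVWY".index("A")
        assert model.info[0, 0, a] > 0  # I(H; A, 0)
        assert model.info[1, 0, a] < 0  # I(E; A, 0)

    def test_counts_match_bruteforce_tallies(self):
        corpus = [
            (SequenceRecord(id="1", sequence="AKVAK"), SSTrack(id="1", labels="HHECC")),
            (SequenceRecord(id="2", sequence="KKAV"), SSTrack(id="2", labels="EEHC")),
        ]
        window, pc = 3, 1.0
        half = window // 2
        counts = np.zeros((3, window, 20))
        totals = np.zeros(3)
        for rec, trk in corpus:
            for i, lab in enumerate(trk.labels):
                s = "HEC".index(lab)
                totals[s] += 1
                for d in range(-half, half + 1):
                    if 0 <= i + d < len(rec.sequence):
                        a = "ACDEFGHIKLMNPQRSTVWY".index(rec.sequence[i + d])
                        counts[s, d + half, a] += 1
        not_counts = counts.sum(axis=0) - counts
        not_totals = totals.sum() - totals
        expected = (
            np.log((counts + pc) / (not_counts + pc))
            - np.log((totals + pc) / (not_totals + pc))[:, None, None]
        )
        model = sspredict.train_gor(corpus, window=window, pseudocount=pc)
        np.testing.assert_allclose(model.info, expected, atol=1e-12)

    def test_large_pseudocount_flattens_information(self):
        corpus = [
            (SequenceRecord(id="1", sequence="AAKKVV"), SSTrack(id="1", labels="HHEECC")),
        ]
        model = sspredict.train_gor(corpus, window=1, pseudocount=1e12)
        assert np.abs(model.info).max() < 1e-6

    def test_missing_class_rejected(self):
        corpus = [(SequenceRecord(id="1", sequence="AAAA"), SSTrack(id="1", labels="HHHH"))]
        with pytest.raises(ValueError, match="larger"):
            sspredict.train_gor(corpus)

    def test_predict_single_residue_is_argmax_of_information(self):
        corpus = [
            (SequenceRecord(id="1", sequence="AAKKVV"), SSTrack(id="1", labels="HHEECC")),
        ]
        model = sspredict.train_gor(corpus, window=1, pseudocount=0.1)
        rec = SequenceRecord(id="x", sequence="A")
        a = "ACDEFGHIKLMNPQRSTVWY".index("A")
        expected = "HEC"[int(np.argmax(model.info[:, 0, a]))]
        assert sspredict.predict_gor(model, rec).labels == expected

    def test_predict_matches_hand_summed_scores(self):
        corpus = [
            (SequenceRecord(id="1", sequence="AKVAKVAKV"), SSTrack(id="1", labels="HHHEEECCC")),
            (SequenceRecord(id="2", sequence="VAKVAK"), SSTrack(id="2", labels="CHEHCE")),
        ]
        model = sspredict.train_gor(corpus, window=3)
        seq = "AKVAK"
        labels = []
        for i in range(len(seq)):
            scores = np.zeros(3)
            for d in (-1, 0, 1):
                if 0 <= i + d < len(seq):
                    a = "ACDEFGHIKLMNPQRSTVWY".index(seq[i + d])
                    scores += model.info[:, d + 1, a]
            # tie rule C > H > E
            best = 2
            if scores[0] > scores[2] and scores[0] >= scores[1]:
                best = 0
            elif scores[1] > scores[2] and scores[1] > scores[0]:
                best = 1
            labels.append("HEC"[best])
        rec = SequenceRecord(id="x", sequence=seq)
        assert sspredict.predict_gor(model, rec).labels == "".join(labels)

    def test_helix_rich_generator_recovered(self, gor_model, emission_model):
        # sequences emitted from an (almost) all-H path should predict mostly H
        rng = np.random.default_rng(7)
        emission = np.array(emission_model.emission)
        seq = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[rng.choice(20, p=emission[0])] for _ in range(100)
        )
        track = sspredict.predict_gor(gor_model, SequenceRecord(id="h", sequence=seq))
        assert track.labels.count("H") / len(track) >= 0.8

    def test_serialization_roundtrip(self, gor_model, tmp_path):
        p = tmp_path / "gor.tsv"
        gor_model.to_tsv(p)
        loaded = sspredict.GORModel.from_tsv(p)
        assert loaded.window == gor_model.window
        np.testing.assert_allclose(loaded.info, gor_model.info)


class TestConsensus:
    def test_strict_majority(self):
        tracks = make_tracks(["H", "H", "E", "C", "C", "C"])
        assert sspredict.consensus(tracks, spec_list(6)).labels == "C"

    def test_tie_resolved_by_highest_priority_tied_voter(self):
        # 2-2-2 three-way tie: priority-1 predictor voted H
        tracks = make_tracks(["H", "H", "E", "E", "C", "C"])
        assert sspredict.consensus(tracks, spec_list(6)).labels == "H"
        # 3-3 tie where priority 1 voted for a non-tied label cannot happen
        # with two tied labels out of three states and six voters; check the
        # E/C tie with the top predictor among the tied voters
        tracks = make_tracks(["E", "E", "E", "C", "C", "C"])
        assert sspredict.consensus(tracks, spec_list(6)).labels == "E"

    def test_single_track_identity(self):
        track = SSTrack(id="x", labels="HECCH")
        assert sspredict.consensus([track], spec_list(1)).labels == track.labels

    def test_identical_tracks_identity(self):
        track = SSTrack(id="x", labels="HECCH")
        for k in (2, 3, 5):
            out = sspredict.consensus([track] * k, spec_list(k))
            assert out.labels == track.labels

    def test_priority_permutation_covariance(self):
        rng = np.random.default_rng(5)
        labels = ["HECH", "CECH", "HHEC", "CCCC", "EEEE"]
        tracks = make_tracks(labels)
        specs = spec_list(5)
        baseline = sspredict.consensus(tracks, specs).labels
        for _ in range(20):
            order = rng.permutation(5)
            assert sspredict.consensus(
                [tracks[i] for i in order], [specs[i] for i in order]
            ).labels == baseline

    def test_strict_majority_immune_to_priorities(self):
        rng = np.random.default_rng(6)
        tracks = make_tracks(["H", "H", "H", "E", "C"])
        for _ in range(100):
            prios = rng.permutation(5) + 1
            specs = [PredictorSpec(f"p{i}", int(p), "external_track")
                     for i, p in enumerate(prios)]
            assert sspredict.consensus(tracks, specs).labels == "H"

    def test_length_mismatch_names_track(self):
        tracks = [SSTrack(id="good", labels="HE"), SSTrack(id="bad", labels="H")]
        with pytest.raises(ValueError, match="bad"):
            sspredict.consensus(tracks, spec_list(2))

    def test_noncontiguous_priorities_rejected(self):
        tracks = make_tracks(["H", "E"])
        specs = [PredictorSpec("a", 1, "external_track"),
                 PredictorSpec("b", 3, "external_track")]
        with pytest.raises(ValueError, match="contiguous"):
            sspredict.consensus(tracks, specs)

    def test_majority_of_reference_copies_beats_adversary(self):
        reference = SSTrack(id="r", labels="HEHEC")
        adversary = SSTrack(id="a", labels="CCCCC")
        for m in (2, 3, 4):
            cons = sspredict.consensus([reference] * m + [adversary], spec_list(m + 1))
            assert sspredict.q3(cons, reference) == 1.0


class TestContentAndQ3:
    def test_content_direct_count(self):
        content = sspredict.ss_content(SSTrack(id="x", labels="HHEC"))
        assert content.helix_frac == 0.5
        assert content.sheet_frac == 0.25
        assert content.coil_frac == 0.25
        assert content.structured_frac == 0.75

    def test_all_coil_unstructured(self):
        assert sspredict.ss_content(SSTrack(id="x", labels="CCCC")).structured_frac == 0.0

    def test_random_track_matches_counting_oracle(self):
        rng = np.random.default_rng(11)
        labels = "".join(rng.choice(list("HEC"), size=1000))
        content = sspredict.ss_content(SSTrack(id="x", labels=labels))
        assert content.helix_frac == labels.count("H") / 1000
        assert content.sheet_frac == labels.count("E") / 1000

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="HEC", min_size=1, max_size=300))
    def test_fractions_sum_to_one(self, labels):
        content = sspredict.ss_content(SSTrack(id="x", labels=labels))
        assert abs(content.helix_frac + content.sheet_frac + content.coil_frac - 1) < 1e-9

    def test_q3_identical_and_partial(self):
        t = SSTrack(id="x", labels="HEC")
        assert sspredict.q3(t, t) == 1.0
        assert sspredict.q3(SSTrack(id="x", labels="HHH"), t) == pytest.approx(1 / 3)

    def test_q3_batch_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        values = []
        expected = []
        for _ in range(10):
            a = "".join(rng.choice(list("HEC"), size=60))
            b = "".join(rng.choice(list("HEC"), size=60))
            values.append(sspredict.q3(SSTrack(id="a", labels=a), SSTrack(id="b", labels=b)))
            expected.append(sum(x == y for x, y in zip(a, b)) / 60)
        assert np.mean(values) == pytest.approx(np.mean(expected))

    def test_q3_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            sspredict.q3(SSTrack(id="a", labels="H"), SSTrack(id="b", labels="HE"))


class TestExternalTracks:
    def test_eight_state_reduction(self, tmp_path):
        p = tmp_path / "ext.tsv"
        labels = ["G", "H", "I", "E", "B", "T", "S", "C", "-"]
        p.write_text(
            "id\tposition\tlabel\n"
            + "".join(f"x\t{i + 1}\t{lab}\n" for i, lab in enumerate(labels))
        )
        track = sspredict.read_external_track(p)[0]
        assert track.labels == "HHHEECCCC"

    def test_three_state_passthrough_and_case(self, tmp_path):
        p = tmp_path / "ext.tsv"
        p.write_text("id\tposition\tlabel\nx\t1\th\nx\t2\tE\nx\t3\tc\n")
        assert sspredict.read_external_track(p)[0].labels == "HEC"

    def test_unknown_label_named(self, tmp_path):
        p = tmp_path / "ext.tsv"
        p.write_text("id\tposition\tlabel\nx\t1\tQ\n")
        with pytest.raises(ValueError, match="'Q'"):
            sspredict.read_external_track(p)

    def test_gapped_positions_rejected(self, tmp_path):
        p = tmp_path / "ext.tsv"
        p.write_text("id\tposition\tlabel\nx\t1\tH\nx\t3\tE\n")
        with pytest.raises(ValueError, match="gap"):
            sspredict.read_external_track(p)
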