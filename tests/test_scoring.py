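"""Fragment-frequency indexing and NP-likeness scoring."""

import math

import pytest

from nplikeness.errors import ModelFormatError, TrainingError, UndefinedScoreError
from nplikeness.records import SignatureFileRecord
from nplikeness.scoring import (
    FrequencyIndex,
    ScorerModel,
    build_index,
    fragment_score,
    load_model,
    plot_score_density,
    save_model,
    score_molecules,
    top_fragments,
    train,
)
from nplikeness.signatures import reencode, sign_batch

S = SignatureFileRecord


class TestBuildIndex:
    def test_document_frequency_not_term_frequency(self):
        idx = build_index([S("U1", "A"), S("U1", "A"), S("U1", "B"), S("U2", "A")])
        assert idx.counts == {"A": 2, "B": 1}
        assert idx.total_molecules == 2

    def test_single_record(self):
        idx = build_index([S("U", "sig")])
        assert idx.counts == {"sig": 1} and idx.total_molecules == 1

    def test_empty_raises(self):
        with pytest.raises(TrainingError):
            build_index([])

    def test_counts_bounded_by_total(self, np_corpus):
        idx = build_index(sign_batch(np_corpus[:30], 2))
        assert all(1 <= c <= idx.total_molecules for c in idx.counts.values())


def make_model(np_counts, np_total, sm_counts, sm_total, alpha=0.0):
    return ScorerModel(
        FrequencyIndex(dict(np_counts), np_total),
        FrequencyIndex(dict(sm_counts), sm_total),
        height=2,
        alpha=alpha,
    )


class TestFragmentScore:
    def test_hand_computed_log_ratio(self):
        model = make_model({"s": 2}, 10, {"s": 1}, 10, alpha=0.0)
        assert fragment_score("s", model).value == pytest.approx(math.log(2), abs=1e-12)

    def test_identical_indexes_score_zero(self):
        model = make_model({"s": 3}, 10, {"s": 3}, 10, alpha=0.0)
        assert fragment_score("s", model).value == 0.0

    def test_unseen_fragment_zero_with_smoothing(self):
        model = make_model({}, 10, {}, 10, alpha=1.0)
        assert fragment_score("novel", model).value == 0.0

    def test_alpha_zero_undefined_on_missing(self):
        model = make_model({"s": 1}, 10, {}, 10, alpha=0.0)
        with pytest.raises(UndefinedScoreError):
            fragment_score("s", model)

    def test_antisymmetric_under_corpus_swap(self):
        model = make_model({"s": 5, "t": 1}, 20, {"s": 2, "t": 9}, 40, alpha=1.0)
        for sig in ("s", "t", "unseen"):
            assert fragment_score(sig, model.swapped()).value == -fragment_score(sig, model).value


class TestScoreMolecules:
    def test_normalised_mean_of_fragments(self):
        # three signatures scoring {ln 2, ln 2, 0}
        model = make_model({"a": 2, "b": 1}, 10, {"a": 1, "b": 1}, 10, alpha=0.0)
        query = [S("m", "a"), S("m", "a"), S("m", "b")]
        (result,) = score_molecules(query, model)
        assert result.n_atoms == 3
        assert result.np_likeness == pytest.approx(2 * math.log(2) / 3, abs=1e-12)
        assert result.raw_sum == pytest.approx(result.np_likeness * 3, abs=1e-12)

    def test_disjoint_double_same_score(self):
        model = make_model({"a": 2, "b": 3}, 10, {"a": 1, "b": 1}, 10, alpha=0.0)
        single = score_molecules([S("m", "a"), S("m", "b")], model)[0]
        double = score_molecules([S("m", "a"), S("m", "b")] * 2, model)[0]
        assert double.np_likeness == pytest.approx(single.np_likeness, abs=1e-15)
        assert double.n_atoms == 2 * single.n_atoms

    def test_first_appearance_order(self):
        model = make_model({"a": 1}, 2, {"a": 1}, 2, alpha=1.0)
        results = score_molecules([S("x", "a"), S("y", "a"), S("x", "a")], model)
        assert [r.uuid for r in results] == ["x", "y"]
        assert [r.n_atoms for r in results] == [2, 1]

    def test_normalisation_bound(self, np_corpus, sm_corpus):
        """|score| never exceeds the largest |fragment contribution|."""
        model = train(sign_batch(np_corpus[:40], 2), sign_batch(sm_corpus[:40], 2))
        query = sign_batch(np_corpus[40:60] + sm_corpus[40:60], 2)
        by_uuid: dict[str, list[float]] = {}
        for recd in query:
            by_uuid.setdefault(recd.uuid, []).append(
                fragment_score(recd.signature, model).value
            )
        for result in score_molecules(query, model):
            assert abs(result.np_likeness) <= max(
                abs(v) for v in by_uuid[result.uuid]
            ) + 1e-12


class TestPersistence:
    def test_roundtrip_equality(self, np_corpus, sm_corpus, tmp_path):
        model = train(sign_batch(np_corpus[:20], 2), sign_batch(sm_corpus[:20], 2),
                      alpha=0.5)
        path = tmp_path / "model.npl"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.np_index.counts == model.np_index.counts
        assert loaded.sm_index.counts == model.sm_index.counts
        assert loaded.np_index.total_molecules == model.np_index.total_molecules
        assert loaded.sm_index.total_molecules == model.sm_index.total_molecules
        assert loaded.height == model.height and loaded.alpha == model.alpha

    def test_loaded_model_scores_identically(self, np_corpus, sm_corpus, tmp_path):
        model = train(sign_batch(np_corpus[:30], 2), sign_batch(sm_corpus[:30], 2))
        path = tmp_path / "model.npl"
        save_model(model, path)
        loaded = load_model(path)
        query = sign_batch(np_corpus[30:60], 2)
        for a, b in zip(score_molecules(query, model), score_molecules(query, loaded)):
            assert a == b

    def test_version_mismatch(self, tmp_path):
        path = tmp_path / "bad.npl"
        path.write_text("nplikeness-model\tv99\n")
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_not_a_model_file(self, tmp_path):
        path = tmp_path / "junk.npl"
        path.write_text("hello\n")
        with pytest.raises(ModelFormatError):
            load_model(path)


class TestTopFragments:
    def test_direction_and_ties(self):
        model = make_model({"a": 7, "b": 1}, 10, {"a": 3, "b": 7}, 10, alpha=1.0)
        (top,) = top_fragments(model, 1, "np_like")
        assert top[0] == "a"
        (bottom,) = top_fragments(model, 1, "synthetic_like")
        assert bottom[0] == "b"

    def test_k_exceeding_vocabulary(self):
        model = make_model({"a": 1}, 2, {"b": 1}, 2, alpha=1.0)
        assert len(top_fragments(model, 100)) == 2

    def test_decoded_top_fragment_reencodes(self, np_corpus, sm_corpus):
        model = train(sign_batch(np_corpus[:20], 2), sign_batch(sm_corpus[:20], 2))
        for sig, _score, decoded in top_fragments(model, 5, decode=True):
            assert reencode(decoded) == sig

    def test_bad_direction(self):
        model = make_model({"a": 1}, 1, {"a": 1}, 1, alpha=1.0)
        with pytest.raises(ValueError):
            top_fragments(model, 1, "sideways")


class TestDensityPlot:
    def test_two_named_sets_written_as_pdf(self, tmp_path):
        path = tmp_path / "density.pdf"
        out = plot_score_density(
            {"natural": [0.5, 0.7, 1.1, 0.2], "synthetic": [-1.0, -0.4, -0.9]},
            path,
        )
        assert out.exists() and out.stat().st_size > 0
        assert path.read_bytes()[:5] == b"%PDF-"

    def test_degenerate_identical_scores(self, tmp_path):
        path = tmp_path / "spike.pdf"
        plot_score_density({"constant": [0.25] * 10}, path)
        assert path.stat().st_size > 0

    def test_no_sets_raises(self, tmp_path):
        with pytest.raises(ValueError):
            plot_score_density({}, tmp_path / "x.pdf")
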