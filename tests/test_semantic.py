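import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluencylab.semantic import (
    AngleSequence,
    EmbeddingLexicon,
    InsufficientDataError,
    angle_between,
    build_chain,
    estimate_persistence_length,
    semantic_relatedness,
    turning_angles,
)
from tests.conftest import constant_angle_embedding


class TestEmbeddingIO:
    def test_no_header(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("a 1.0 0.0\nb 0.0 1.0\nc 1.0 1.0\n")
        emb = EmbeddingLexicon.load(p)
        assert len(emb) == 3 and emb.dim == 2

    def test_header(self, tmp_path):
        p = tmp_path / "e.txt"
        rows = [" ".join(["w%d" % i] + ["0.1"] * 50) for i in range(2)]
        p.write_text("2 50\n" + "\n".join(rows) + "\n")
        emb = EmbeddingLexicon.load(p)
        assert emb.dim == 50

    def test_inconsistent_dim_raises(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("a 1.0 0.0\nb 0.5\n")
        with pytest.raises(ValueError):
            EmbeddingLexicon.load(p)

    def test_zero_vector_skipped(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("a 1.0 0.0\nz 0.0 0.0\n")
        emb = EmbeddingLexicon.load(p)
        assert "z" not in emb and "a" in emb

    def test_duplicate_keeps_first(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("a 1.0 0.0\na 0.0 1.0\n")
        emb = EmbeddingLexicon.load(p)
        assert emb.get("a")[0] == 1.0

    def test_save_roundtrip(self, tmp_path, toy_emb):
        out = tmp_path / "e.txt"
        toy_emb.save(out)
        back = EmbeddingLexicon.load(out)
        assert back.words() == toy_emb.words()
        np.testing.assert_allclose(back.get("northeast"),
                                   toy_emb.get("northeast"), atol=1e-6)


class TestTurningAngles:
    def test_identical_vectors_zero(self, toy_emb):
        angles, _ = turning_angles(["east", "east"], toy_emb)
        assert angles.angles_deg == [0.0]

    def test_orthogonal_ninety(self, toy_emb):
        angles, _ = turning_angles(["east", "north"], toy_emb)
        assert angles.angles_deg[0] == pytest.approx(90.0)

    def test_paper_worked_pair(self, emb_lex):
        angles, _ = turning_angles(["four", "five"], emb_lex)
        assert angles.angles_deg[0] == pytest.approx(17.82, abs=0.5)

    def test_oov_dropped(self, toy_emb):
        angles, oov = turning_angles(["east", "zzz", "west"], toy_emb)
        assert oov == ["zzz"]
        assert angles.angles_deg[0] == pytest.approx(180.0)

    def test_insufficient(self, toy_emb):
        with pytest.raises(InsufficientDataError):
            turning_angles(["east", "zzz"], toy_emb)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, scale):
        u = np.array([1.0, 2.0, -1.0])
        v = np.array([0.5, -1.0, 3.0])
        assert angle_between(u, v) == pytest.approx(
            angle_between(scale * u, v), abs=1e-9
        )

    @given(
        st.lists(
            st.tuples(st.floats(-5, 5), st.floats(-5, 5)).filter(
                lambda t: abs(t[0]) + abs(t[1]) > 1e-3
            ),
            min_size=2,
            max_size=8,
        )
    )
    def test_angle_bounds(self, coords):
        vecs = {f"w{i}": np.array(c) for i, c in enumerate(coords)}
        emb = EmbeddingLexicon(vecs)
        angles, _ = turning_angles(sorted(vecs), emb)
        assert all(0.0 <= a <= 180.0 for a in angles.angles_deg)


class TestChain:
    def test_straight(self):
        chain = build_chain(AngleSequence([0.0, 0.0]))
        np.testing.assert_allclose(
            chain.vertices, [[0, 0], [1, 0], [2, 0], [3, 0]], atol=1e-12
        )

    def test_single_right_angle(self):
        chain = build_chain(AngleSequence([90.0]))
        np.testing.assert_allclose(
            chain.vertices, [[0, 0], [1, 0], [1, 1]], atol=1e-12
        )

    def test_vertex_count(self):
        chain = build_chain(AngleSequence([10.0, 20.0, 30.0]))
        assert chain.vertices.shape == (5, 2)

    def test_segment_lengths_unit(self):
        chain = build_chain(AngleSequence([33.0, 140.0, 7.0]), sign_rule="random",
                            seed=3)
        steps = np.diff(chain.vertices, axis=0)
        np.testing.assert_allclose(np.linalg.norm(steps, axis=1), 1.0)

    def test_alternating_straighter_than_same_sign(self):
        angles = AngleSequence([90.0] * 4)
        same = build_chain(angles, sign_rule="positive")
        alt = build_chain(angles, sign_rule="alternating")
        d_same = np.linalg.norm(same.vertices[-1] - same.vertices[0])
        d_alt = np.linalg.norm(alt.vertices[-1] - alt.vertices[0])
        assert d_alt > d_same

    def test_straightness_limit(self):
        n = 7
        chain = build_chain(AngleSequence([0.0] * (n - 1)))
        assert np.linalg.norm(chain.vertices[-1] - chain.vertices[0]) == (
            pytest.approx(n)
        )


class TestPersistence:
    def test_straight_chain_infinite(self):
        est = estimate_persistence_length(AngleSequence([0.0, 0.0, 0.0]))
        assert est.is_infinite

    def test_closed_form_unit_lp(self):
        theta = math.degrees(math.acos(math.exp(-1.0)))
        est = estimate_persistence_length(AngleSequence([theta] * 5))
        assert est.lp_segments == pytest.approx(1.0, rel=1e-9)

    def test_insufficient(self):
        with pytest.raises(InsufficientDataError):
            estimate_persistence_length(AngleSequence([10.0, 20.0]))

    def test_anticorrelated_angles_zero(self):
        est = estimate_persistence_length(AngleSequence([150.0] * 4))
        assert est.lp_segments == 0.0

    def test_lag_fit_matches_adjacent_on_constant(self):
        angles = AngleSequence([40.0] * 20)
        a = estimate_persistence_length(angles, "adjacent_cosine")
        b = estimate_persistence_length(angles, "lag_decay_fit")
        assert b.lp_segments == pytest.approx(a.lp_segments, rel=1e-6)

    def test_simulation_recovery_lp5(self):
        # oracle: median over simulated worm-like chains with known truth
        from fluencylab.synth import simulate_wlc_angles

        rng = np.random.default_rng(42)
        ests = []
        for _ in range(500):
            angles = simulate_wlc_angles(5.0, 50, rng=rng)
            ests.append(estimate_persistence_length(angles).lp_segments)
        assert np.median(ests) == pytest.approx(5.0, rel=0.10)

    def test_unknown_estimator(self):
        with pytest.raises(ValueError):
            estimate_persistence_length(AngleSequence([1.0] * 4), "bogus")


class TestSemanticRelatedness:
    def test_identical_words_sr_one(self, toy_emb):
        idx = semantic_relatedness(["east"] * 4, toy_emb)
        assert idx.sr == 1.0
        assert idx.lp.is_infinite

    def test_orthogonal_sr_zero(self):
        words, emb = constant_angle_embedding(90.0, 4)
        assert semantic_relatedness(words, emb).sr == pytest.approx(0.0, abs=1e-12)

    def test_constant_angle_closed_form(self):
        words, emb = constant_angle_embedding(58.0, 6)
        idx = semantic_relatedness(words, emb)
        assert idx.sr == pytest.approx(math.cos(math.radians(58.0)), abs=1e-12)

    def test_sr_equals_exp_minus_inv_lp(self):
        words, emb = constant_angle_embedding(47.0, 6)
        idx = semantic_relatedness(words, emb)
        assert idx.sr == pytest.approx(math.exp(-1.0 / idx.lp.lp_segments))

    def test_min_words(self, toy_emb):
        with pytest.raises(InsufficientDataError):
            semantic_relatedness(["east", "north", "west"], toy_emb)

    @settings(max_examples=30, deadline=None)
    @given(
        st.tuples(st.floats(1.0, 89.0), st.floats(1.0, 89.0)).filter(
            lambda t: abs(t[0] - t[1]) > 0.5
        )
    )
    def test_monotone_decreasing_in_angle(self, pair):
        lo, hi = sorted(pair)
        w1, e1 = constant_angle_embedding(lo, 5)
        w2, e2 = constant_angle_embedding(hi, 5)
        assert semantic_relatedness(w1, e1).sr > semantic_relatedness(w2, e2).sr

    def test_sr_independent_of_dimension(self):
        # same cosines realized in 2-d and in 5-d give the same SR
        words, emb2 = constant_angle_embedding(30.0, 5)
        vecs5 = {w: np.concatenate([emb2.get(w), np.zeros(3)]) for w in words}
        idx2 = semantic_relatedness(words, emb2)
        idx5 = semantic_relatedness(words, EmbeddingLexicon(vecs5))
        assert idx5.sr == pytest.approx(idx2.sr, abs=1e-12)
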