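"""Henikoff weighting, profile construction, adaptive mixing, quality features."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from bindprof.profiles import (
    TemplateHit, adaptive_profile, build_profile, collect_templates,
    henikoff_weights, js_divergence, mutant_profile_score,
    mutant_profile_score_multi, profile_quality_features, select_adaptive,
    substitution_matrix,
)
from bindprof.structmodel import AA_INDEX, AA_ORDER


class _StubHit:
    """Minimal hit carrying only a similarity value (selection tests)."""

    def __init__(self, sim, hid="h"):
        self.sim = sim
        self.template_id = hid
        self.aligned_sequence = "A"

    def score(self, metric):
        return self.sim


def _seq_hit(seq, hid="h", d=None, f=None):
    n = len(seq)
    d = np.where(np.array(list(seq)) == "-", np.nan,
                 np.zeros(n)) if d is None else np.asarray(d, float)
    f = np.where(np.isnan(d), np.nan, 1.0) if f is None else np.asarray(f, float)
    return TemplateHit(hid, None, seq, d, f)


class TestHenikoffWeights:
    def test_identical_sequences_share_weight(self):
        w = henikoff_weights(["ACD"] * 5)
        np.testing.assert_allclose(w, 0.2)

    def test_single_column_worked_example(self):
        # column {A, A, B}: raw 1/(2*2), 1/(2*2), 1/(2*1) -> (.25, .25, .5)
        np.testing.assert_allclose(henikoff_weights(["A", "A", "B"]),
                                   [0.25, 0.25, 0.5])

    def test_matches_per_column_oracle(self, rng):
        for _ in range(30):
            n, L = int(rng.integers(2, 8)), int(rng.integers(1, 10))
            msa = ["".join(rng.choice(list("ACDE-"), L)) for _ in range(n)]
            if all(set(s) == {"-"} for s in msa):
                continue
            raw = np.zeros(n)
            for col in range(L):
                column = [s[col] for s in msa]
                types = {c for c in column if c != "-"}
                for i, c in enumerate(column):
                    if c != "-":
                        raw[i] += 1.0 / (len(types) * column.count(c))
            expected = raw / raw.sum() if raw.sum() else np.full(n, 1 / n)
            np.testing.assert_allclose(henikoff_weights(msa), expected,
                                       atol=1e-12)


class TestBuildProfile:
    def test_single_sequence_gives_substitution_row(self):
        prof = build_profile([_seq_hit("L")])
        M = substitution_matrix()
        np.testing.assert_allclose(prof.F[0], M[:, AA_INDEX["L"]], atol=1e-12)

    def test_uniform_frequencies_give_column_means(self):
        hits = [_seq_hit(aa, hid=f"h{aa}") for aa in AA_ORDER]
        prof = build_profile(hits)
        M = substitution_matrix()
        np.testing.assert_allclose(prof.F[0], M.mean(axis=1), atol=1e-12)

    def test_matches_matrix_product_oracle(self, rng):
        hits = [_seq_hit("".join(rng.choice(list(AA_ORDER), 6)), hid=f"h{i}")
                for i in range(3)]
        prof = build_profile(hits)
        M = substitution_matrix()
        for p in range(6):
            for A in range(20):
                expected = sum(prof.g[p, a] * M[A, a] for a in range(20))
                assert abs(prof.F[p, A] - expected) < 1e-12

    def test_g_rows_are_distributions(self, hits_all):
        prof = build_profile(hits_all)
        covered = prof.n_seq > 0
        np.testing.assert_allclose(prof.g[covered].sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_duplicating_every_hit_leaves_profile_unchanged(self, rng):
        hits = [_seq_hit("".join(rng.choice(list(AA_ORDER), 5)), hid=f"h{i}")
                for i in range(4)]
        doubled = hits + [_seq_hit(h.aligned_sequence, hid=h.template_id + "b")
                          for h in hits]
        p1, p2 = build_profile(hits), build_profile(doubled)
        np.testing.assert_allclose(p1.g, p2.g, atol=1e-12)
        np.testing.assert_allclose(p1.F, p2.F, atol=1e-12)

    def test_empty_hits_rejected(self):
        with pytest.raises(ValueError):
            build_profile([])

    def test_all_gap_profile_rejected(self):
        with pytest.raises(ValueError, match="all-gap"):
            build_profile([_seq_hit("--"), _seq_hit("--", hid="h2")])


class TestMutantProfileScore:
    def test_identity_mutation_scores_zero(self):
        prof = build_profile([_seq_hit("LK")])
        assert mutant_profile_score(prof, 0, "L", "L") == 0.0

    def test_antisymmetric_under_swap(self, rng):
        hits = [_seq_hit("".join(rng.choice(list(AA_ORDER), 4)), hid=f"h{i}")
                for i in range(5)]
        prof = build_profile(hits)
        s1 = mutant_profile_score(prof, 2, "L", "D")
        s2 = mutant_profile_score(prof, 2, "D", "L")
        assert s1 == pytest.approx(-s2, abs=1e-12)

    def test_single_sequence_profile_equals_blosum_difference(self):
        prof = build_profile([_seq_hit("L")])
        M = substitution_matrix()
        expected = M[AA_INDEX["L"], AA_INDEX["L"]] - M[AA_INDEX["D"], AA_INDEX["L"]]
        assert mutant_profile_score(prof, 0, "L", "D") == pytest.approx(expected)
        assert expected == 8.0   # published BLOSUM62 entries: L/L=4, D/L=-4

    def test_multi_site_additivity(self, rng):
        hits = [_seq_hit("".join(rng.choice(list(AA_ORDER), 4)), hid=f"h{i}")
                for i in range(5)]
        prof = build_profile(hits)
        total = mutant_profile_score_multi(prof, [(0, "A", "W"), (3, "K", "E")])
        parts = (mutant_profile_score(prof, 0, "A", "W")
                 + mutant_profile_score(prof, 3, "K", "E"))
        assert total == pytest.approx(parts, abs=1e-12)

    def test_uncovered_site_falls_back_to_substitution_matrix(self):
        prof = build_profile([_seq_hit("L-")])
        M = substitution_matrix()
        expected = M[AA_INDEX["K"], AA_INDEX["K"]] - M[AA_INDEX["K"], AA_INDEX["E"]]
        assert mutant_profile_score(prof, 1, "K", "E") == pytest.approx(expected)

    def test_out_of_range_site_rejected(self):
        prof = build_profile([_seq_hit("L")])
        with pytest.raises(ValueError):
            mutant_profile_score(prof, 5, "L", "D")


class TestAdaptiveProfile:
    def test_worked_example_selects_four(self):
        hits = [_StubHit(s, f"h{i}") for i, s in
                enumerate([0.30, 0.26, 0.24, 0.22, 0.18])]
        chosen = select_adaptive(hits, strict=0.25, loose=0.19, n=2)
        assert [h.sim for h in chosen] == [0.30, 0.26, 0.24, 0.22]

    def test_all_above_strict_ignores_n(self):
        hits = [_StubHit(s, f"h{i}") for i, s in enumerate([0.9, 0.8, 0.7])]
        assert len(select_adaptive(hits, 0.25, 0.19, n=0)) == 3

    def test_n_zero_keeps_only_strict_set(self):
        hits = [_StubHit(s, f"h{i}") for i, s in enumerate([0.30, 0.22, 0.20])]
        assert [h.sim for h in select_adaptive(hits, 0.25, 0.19, 0)] == [0.30]

    def test_no_usable_templates(self):
        hits = [_StubHit(0.1)]
        with pytest.raises(ValueError, match="no usable templates"):
            select_adaptive(hits, 0.25, 0.19, 5)

    def test_set_algebra_on_random_similarity_lists(self, rng):
        for _ in range(200):
            sims = np.sort(rng.uniform(0, 1, rng.integers(1, 30)))[::-1]
            hits = [_StubHit(float(s), f"h{i}") for i, s in enumerate(sims)]
            strict, loose = 0.25, 0.19
            n = int(rng.integers(0, 10))
            strict_set = {h.template_id for h in hits if h.sim >= strict}
            loose_set = {h.template_id for h in hits if h.sim >= loose}
            try:
                chosen = {h.template_id
                          for h in select_adaptive(hits, strict, loose, n)}
            except ValueError:
                assert not loose_set
                continue
            assert strict_set <= chosen <= loose_set

    def test_profile_built_from_selection(self, hits_all, query_iface):
        prof = adaptive_profile(hits_all, 0.25, 0.19, 10,
                                positions=query_iface.positions())
        assert len(prof.positions) == query_iface.L_Q


class TestCollectTemplates:
    def test_exact_copy_scores_one(self, query_iface, toy_dimer):
        hits = collect_templates(query_iface, [("copy", toy_dimer)])
        assert len(hits) == 1
        assert hits[0].similarity.iscore == pytest.approx(1.0, abs=1e-9)

    def test_impossible_cutoff_gives_empty_list(self, query_iface, toy_dimer):
        assert collect_templates(query_iface, [("copy", toy_dimer)],
                                 cutoff=1.1) == []

    def test_duplicate_sequences_removed(self, query_iface, family):
        # two structurally identical templates with identical sequences
        t0 = family.templates[0]
        hits = collect_templates(query_iface, [t0, (t0[0] + "b", t0[1])])
        assert len(hits) == 1


class TestQualityFeatures:
    def test_js_identical_distributions(self):
        p = np.full(20, 0.05)
        assert js_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_js_disjoint_support_is_one_bit(self):
        assert js_divergence(np.eye(20)[0], np.eye(20)[1]) == pytest.approx(1.0)

    def test_js_matches_kl_term_oracle(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(20))
            q = rng.dirichlet(np.ones(20))
            m = 0.5 * (p + q)
            expected = 0.5 * sum(pi * np.log2(pi / mi)
                                 for pi, mi in zip(p, m) if pi > 0) \
                + 0.5 * sum(qi * np.log2(qi / mi)
                            for qi, mi in zip(q, m) if qi > 0)
            assert abs(js_divergence(p, q) - expected) < 1e-12

    def test_zscore_zero_when_all_sites_identical(self):
        hits = [_seq_hit("LL", hid=f"h{i}") for i in range(3)]
        prof = build_profile(hits)
        q = profile_quality_features(hits, prof, 0)
        assert q.js_zscore == 0.0

    def test_site_features_match_manual_computation(self):
        hits = [
            _seq_hit("LK", d=[0.5, 1.5], f=[1.0, 0.5]),
            _seq_hit("L-", hid="h2", d=[1.0, np.nan], f=[0.8, np.nan]),
        ]
        prof = build_profile(hits)
        q = profile_quality_features(hits, prof, 0)
        assert q.mean_rmsd_at_site == pytest.approx(0.75)
        assert q.mean_preserved_contacts == pytest.approx(0.9)
        assert q.n_seq_at_site == 2

    def test_uncovered_site_sentinels(self):
        hits = [_seq_hit("L-")]
        prof = build_profile(hits)
        q = profile_quality_features(hits, prof, 1)
        assert q.n_seq_at_site == 0
        assert q.mean_rmsd_at_site < 0
        assert q.js_divergence == 1.0


class TestGenerativeRecovery:
    def test_profile_ranks_recover_log_pi(self, query_iface, family, hits_all):
        """Profiles built from 50 templates drawn from a known π rank
        amino acids consistently with log π at well-covered positions."""
        hits = [h for h in hits_all if h.score("iscore") >= 0.19]
        prof = build_profile(hits, positions=query_iface.positions())
        rhos = [spearmanr(prof.F[p], np.log(family.pi[p])).statistic
                for p in range(len(prof.positions)) if prof.n_seq[p] >= 15]
        assert len(rhos) >= 10
        assert np.mean(rhos) >= 0.8
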