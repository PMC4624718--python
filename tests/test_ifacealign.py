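"""Interface superposition, correspondence search and similarity scores."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from bindprof.fixtures import FixtureSpec, make_template_family, make_toy_dimer
from bindprof.ifacealign import (
    CHEMICAL_CLASSES, InterfaceAlignment, align_interfaces, chemical_class,
    contact_overlap, d0, i_score, itm_score, kabsch_superpose, pc_score,
)
from bindprof.structmodel import AA_ORDER, extract_interface


def _random_alignment(rng, n_pairs, with_f=True):
    return InterfaceAlignment(
        pairs=[(("A", i), ("A", i)) for i in range(n_pairs)],
        d=rng.uniform(0.0, 8.0, n_pairs),
        f=rng.uniform(0.0, 1.0, n_pairs) if with_f else np.ones(n_pairs),
        I=rng.integers(0, 2, n_pairs).astype(float),
        rotation=np.eye(3), translation=np.zeros(3), rmsd=0.0,
        f_c=float(rng.uniform(0.0, 1.0)),
    )


class TestKabsch:
    def test_identity(self, rng):
        A = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(A, A)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0.0, atol=1e-10)
        assert rmsd < 1e-10

    def test_recovers_random_rigid_motion(self, rng):
        A = rng.normal(size=(12, 3))
        R_true = Rotation.random(random_state=5).as_matrix()
        B = (A - A.mean(0)) @ R_true + A.mean(0) + np.array([3.0, -2.0, 7.0])
        R, t, rmsd = kabsch_superpose(A, B)
        assert rmsd < 1e-6
        np.testing.assert_allclose(B @ R.T + t, A, atol=1e-6)
        assert abs(np.linalg.det(R) - 1.0) < 1e-9

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_matches_quaternion_minimization_oracle(self, rng):
        A = rng.normal(size=(15, 3)) * 4.0
        B = A + rng.normal(0.0, 0.5, size=A.shape)
        _, _, rmsd = kabsch_superpose(A, B)

        def cost(params):
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            diff = A - (B @ rot.T + params[3:])
            return np.sqrt((diff ** 2).sum() / len(A))

        # several starts to keep the oracle off local optima
        results = []
        for v in (np.zeros(3), np.array([0.1, -0.2, 0.3]), np.array([1.0, 1.0, -1.0])):
            res = minimize(cost, np.concatenate([v, np.zeros(3)]),
                           method="Nelder-Mead",
                           options={"xatol": 1e-9, "fatol": 1e-12,
                                    "maxiter": 20000})
            results.append(res.fun)
        assert abs(rmsd - min(results)) < 1e-4


class TestD0:
    def test_floor_below_16_residues(self):
        for L in (1, 5, 15):
            assert d0(L) == 0.5

    def test_direct_evaluation(self):
        assert d0(142) == pytest.approx(1.24 * np.cbrt(127.0) - 1.8, rel=1e-12)

    def test_monotone_nondecreasing(self):
        vals = [d0(L) for L in range(1, 501)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestScoreFormulas:
    def test_brute_force_oracles(self, rng):
        """All three score formulas agree with independent summation."""
        for _ in range(100):
            n = int(rng.integers(1, 40))
            L_Q = int(rng.integers(n, n + 30))
            aln = _random_alignment(rng, n)
            scale = max(0.5, 1.24 * np.cbrt(L_Q - 15.0) - 1.8)
            itm_ref = sum(1.0 / (1.0 + (di / scale) ** 2) for di in aln.d) / L_Q
            isc_ref = sum(fi / (1.0 + (di / scale) ** 2)
                          for di, fi in zip(aln.d, aln.f)) / L_Q
            pc_ref = aln.f_c * sum(
                1.0 / (1.0 + 0.25 * (1.0 - Ii) + (di / 4.0) ** 2)
                for di, Ii in zip(aln.d, aln.I)) / L_Q
            assert abs(itm_score(aln, L_Q) - itm_ref) < 1e-10
            assert abs(i_score(aln, L_Q) - isc_ref) < 1e-10
            assert abs(pc_score(aln, L_Q) - pc_ref) < 1e-10
            assert i_score(aln, L_Q) <= itm_score(aln, L_Q) + 1e-12

    def test_single_pair_at_d0_gives_half(self):
        aln = InterfaceAlignment(pairs=[(("A", 0), ("A", 0))],
                                 d=np.array([d0(1)]), f=np.ones(1),
                                 I=np.ones(1), rotation=np.eye(3),
                                 translation=np.zeros(3), rmsd=0.0, f_c=1.0)
        assert itm_score(aln, 1) == pytest.approx(0.5, abs=1e-12)

    def test_chemistry_mismatch_term(self):
        aln = InterfaceAlignment(pairs=[(("A", 0), ("A", 0))],
                                 d=np.zeros(1), f=np.ones(1),
                                 I=np.zeros(1), rotation=np.eye(3),
                                 translation=np.zeros(3), rmsd=0.0, f_c=1.0)
        assert pc_score(aln, 1) == pytest.approx(0.8, abs=1e-12)

    def test_zero_interface_length_rejected(self, rng):
        aln = _random_alignment(rng, 3)
        for fn in (itm_score, i_score):
            with pytest.raises(ValueError):
                fn(aln, 0)


class TestContactOverlap:
    def test_printed_example(self):
        # query residue has b=2 contacts, template a=4, overlapped c=2
        q, t = ("A", 0), ("A", 0)
        q_partners = {q: {("B", 1), ("B", 2)}}
        t_partners = {t: {("B", 1), ("B", 2), ("B", 3), ("B", 4)}}
        pair_map = {q: t, ("B", 1): ("B", 1), ("B", 2): ("B", 2)}
        f = contact_overlap((q, t), q_partners, t_partners, pair_map)
        assert f == pytest.approx((2 / 4 + 2 / 2) / 2)

    def test_zero_when_either_side_has_no_contacts(self):
        assert contact_overlap((("A", 0), ("A", 0)), {}, {("A", 0): {("B", 1)}},
                               {}) == 0.0

    def test_randomized_maps_match_enumeration_oracle(self, rng):
        for _ in range(50):
            nq, nt = 8, 8
            q_res = [("A", i) for i in range(nq)]
            t_res = [("A", i) for i in range(nt)]
            partners_q = {r: {("B", int(j)) for j in
                              rng.choice(6, rng.integers(0, 5), replace=False)}
                          for r in q_res}
            partners_t = {r: {("B", int(j)) for j in
                              rng.choice(6, rng.integers(0, 5), replace=False)}
                          for r in t_res}
            perm = rng.permutation(6)
            pair_map = {("A", i): ("A", i) for i in range(nq)}
            pair_map.update({("B", i): ("B", int(perm[i])) for i in range(6)})
            pair = (("A", 0), ("A", 0))
            got = contact_overlap(pair, partners_q, partners_t, pair_map)
            a = len(partners_t[("A", 0)])
            b = len(partners_q[("A", 0)])
            c = sum(1 for p in partners_q[("A", 0)]
                    if pair_map[p] in partners_t[("A", 0)])
            expected = 0.0 if a == 0 or b == 0 else 0.5 * (c / a + c / b)
            assert got == pytest.approx(expected, abs=1e-12)


class TestChemicalClasses:
    def test_partition_of_the_twenty_amino_acids(self):
        seen = {}
        for name, members in CHEMICAL_CLASSES.items():
            for aa in members:
                assert aa not in seen
                seen[aa] = name
        assert sorted(seen) == sorted(AA_ORDER)

    @pytest.mark.parametrize("aa,cls", [
        ("K", "pos"), ("R", "pos"), ("E", "neg"), ("N", "donor_acceptor"),
        ("F", "aromatic"), ("G", "hydrophobic"), ("H", "his_tyr"),
        ("Y", "his_tyr"),
    ])
    def test_examples(self, aa, cls):
        assert chemical_class(aa) == cls

    def test_nonstandard_rejected(self):
        with pytest.raises(ValueError):
            chemical_class("X")


class TestAlignInterfaces:
    def test_self_alignment_is_perfect(self, query_iface):
        rep = align_interfaces(query_iface, query_iface)
        assert rep.itm == pytest.approx(1.0, abs=1e-9)
        assert rep.iscore == pytest.approx(1.0, abs=1e-9)
        assert rep.pcscore == pytest.approx(1.0, abs=1e-9)
        assert rep.alignment.N_a == query_iface.L_Q

    def test_rigid_motion_invariance(self, toy_dimer):
        from bindprof.fixtures import _copy_complex
        moved = _copy_complex(toy_dimer, "moved")
        R = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).as_matrix()
        for ch in moved.chains:
            for res in ch.residues:
                for a in res.atoms:
                    a.coord = R @ a.coord + np.array([5.0, -3.0, 11.0])
        q = extract_interface(toy_dimer, classify=False)
        t = extract_interface(moved, classify=False)
        rep = align_interfaces(q, t)
        assert rep.itm == pytest.approx(1.0, abs=1e-6)
        assert rep.iscore == pytest.approx(1.0, abs=1e-6)

    def test_score_consistent_with_formula_and_beats_random(self, query_iface,
                                                            family, rng):
        # noisy template: returned metric equals Eq-style re-summation on
        # the returned correspondence, and beats random correspondences
        tm = extract_interface(family.templates[30][1], classify=False)
        rep = align_interfaces(query_iface, tm, metric="itm")
        L_Q = query_iface.L_Q
        scale = d0(L_Q)
        ref = sum(1.0 / (1.0 + (di / scale) ** 2)
                  for di in rep.alignment.d) / L_Q
        assert abs(rep.itm - ref) < 1e-10

        q_refs = query_iface.positions()
        t_refs = tm.positions()
        q_ca = {r: query_iface.complex.residue(r).ca for r in q_refs}
        t_ca = {r: tm.complex.residue(r).ca for r in t_refs}
        n = rep.alignment.N_a
        for _ in range(50):
            qs = [q_refs[i] for i in rng.choice(len(q_refs), n, replace=False)]
            ts = [t_refs[i] for i in rng.choice(len(t_refs), n, replace=False)]
            A = np.array([q_ca[r] for r in qs])
            B = np.array([t_ca[r] for r in ts])
            R, t, _ = kabsch_superpose(A, B)
            dists = np.linalg.norm(A - (B @ R.T + t), axis=1)
            random_score = np.sum(1.0 / (1.0 + (dists / scale) ** 2)) / L_Q
            assert rep.itm >= random_score - 1e-9

    def test_iscore_bounded_by_itm(self, query_iface, family):
        for tid, tmpl in family.templates[::10]:
            tm = extract_interface(tmpl, classify=False)
            rep = align_interfaces(query_iface, tm)
            assert rep.iscore <= rep.itm + 1e-12

    def test_noise_degrades_median_itm(self, rng):
        medians = []
        for sigma in (0.0, 0.5, 1.0, 2.0, 4.0):
            scores = []
            for seed in range(10):
                spec = FixtureSpec(seed=100 + seed, n_templates=2,
                                   noise_sigma=sigma, interface_length=10,
                                   flank=2)
                dimer = make_toy_dimer(spec)
                q = extract_interface(dimer, classify=False)
                fam = make_template_family(dimer, spec)
                # the ramp puts the last template exactly at sigma
                t = extract_interface(fam.templates[-1][1], classify=False)
                scores.append(align_interfaces(q, t, metric="itm").itm)
            medians.append(np.median(scores))
        assert all(b <= a + 1e-9 for a, b in zip(medians, medians[1:]))
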