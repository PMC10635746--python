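"""Dempster-Shafer combination: worked examples, algebraic laws, and
equivalence with a set-based brute-force enumerator."""

import numpy as np
import pytest
from _oracles import dempster_bruteforce

import mldstnet as m
from mldstnet.errors import ContractError, TotalConflictError

M1 = m.MassFunction(0.8, 0.1, 0.1)
M2 = m.MassFunction(0.6, 0.3, 0.1)


class TestProbsToMass:
    def test_identity_mapping(self):
        mass = m.probs_to_mass((0.7, 0.2, 0.1))
        assert mass.as_array() == pytest.approx([0.7, 0.2, 0.1])

    def test_renormalizes_drifted_triple(self):
        mass = m.probs_to_mass((0.5, 0.5, 0.2))
        assert mass.as_array() == pytest.approx([0.5 / 1.2, 0.5 / 1.2, 0.2 / 1.2])

    def test_degenerate_certainty(self):
        assert m.probs_to_mass((1, 0, 0)).as_array() == pytest.approx([1, 0, 0])

    def test_negative_entries_rejected(self):
        with pytest.raises(ContractError):
            m.probs_to_mass((-0.1, 0.6, 0.5))


class TestConflict:
    def test_full_agreement_no_conflict(self):
        one = m.MassFunction(1, 0, 0)
        assert m.conflict(one, one) == pytest.approx(0.0)

    def test_disjoint_singleton_worked_example(self):
        """k = 1 - (0.48 + 0.03 + 0.01) = 0.48 over the 6 off-diagonal products."""
        assert m.conflict(M1, M2, m.DISJOINT_SINGLETON) == pytest.approx(0.48)

    def test_classical_worked_example(self):
        """Only benign x malignant cross terms conflict: 0.8*0.3 + 0.1*0.6."""
        assert m.conflict(M1, M2, m.CLASSICAL_DS) == pytest.approx(0.30)


class TestCombine:
    def test_disjoint_singleton_worked_example(self):
        r = m.combine(M1, M2, m.DISJOINT_SINGLETON)
        assert r.mass.as_array() == pytest.approx([0.9231, 0.0577, 0.0192], abs=5e-5)
        assert r.k == pytest.approx(0.48)
        assert r.K == pytest.approx(1 / 0.52)
        assert r.decided == "benign"

    def test_classical_worked_example(self):
        r = m.combine(M1, M2, m.CLASSICAL_DS)
        assert r.mass.as_array() == pytest.approx([0.8857, 0.1000, 0.0143], abs=5e-5)
        assert r.k == pytest.approx(0.30)

    def test_vacuous_mass_is_identity_in_classical_frame(self):
        vac = m.MassFunction(0, 0, 1)
        r = m.combine(M1, vac, m.CLASSICAL_DS)
        assert r.mass.as_array() == pytest.approx(M1.as_array(), abs=1e-12)
        assert r.k == pytest.approx(0.0)

    def test_total_conflict_raises_with_argmax_classes(self):
        with pytest.raises(TotalConflictError) as exc:
            m.combine(m.MassFunction(1, 0, 0), m.MassFunction(0, 1, 0))
        assert exc.value.argmax1 == "benign"
        assert exc.value.argmax2 == "malignant"

    @pytest.mark.parametrize("frame", [m.DISJOINT_SINGLETON, m.CLASSICAL_DS])
    def test_oracle_equivalence_1000_random_pairs(self, frame):
        """Implementation matches set-based enumeration within 1e-12."""
        rng = np.random.default_rng(2718)
        for _ in range(1000):
            m1 = m.MassFunction.from_array(rng.dirichlet(np.ones(3)))
            m2 = m.MassFunction.from_array(rng.dirichlet(np.ones(3)))
            expected = dempster_bruteforce(m1.as_array(), m2.as_array(), frame.variant)
            assert expected is not None
            r = m.combine(m1, m2, frame)
            assert np.allclose(r.mass.as_array(), expected[0], atol=1e-12)
            assert r.k == pytest.approx(expected[1], abs=1e-12)

    @pytest.mark.parametrize("frame", [m.DISJOINT_SINGLETON, m.CLASSICAL_DS])
    def test_commutativity(self, frame):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m1 = m.MassFunction.from_array(rng.dirichlet(np.ones(3)))
            m2 = m.MassFunction.from_array(rng.dirichlet(np.ones(3)))
            a = m.combine(m1, m2, frame)
            b = m.combine(m2, m1, frame)
            assert np.allclose(a.mass.as_array(), b.mass.as_array(), atol=1e-12)
            assert a.k == pytest.approx(b.k, abs=1e-12)

    @pytest.mark.parametrize("frame", [m.DISJOINT_SINGLETON, m.CLASSICAL_DS])
    def test_normalization_when_k_below_one(self, frame):
        rng = np.random.default_rng(6)
        for _ in range(50):
            m1 = m.MassFunction.from_array(rng.dirichlet(np.ones(3)))
            m2 = m.MassFunction.from_array(rng.dirichlet(np.ones(3)))
            r = m.combine(m1, m2, frame)
            assert r.mass.as_array().sum() == pytest.approx(1.0, abs=1e-12)

    def test_monotone_agreement(self):
        """If both sources put their maximum on the same class, so does the
        fusion.  In the disjoint frame this holds for all three elements; in
        the classical frame it holds for the two singleton classes (shared
        maximum on the Theta element can legitimately migrate to a class,
        since Theta intersects everything)."""
        rng = np.random.default_rng(8)
        checked = 0
        while checked < 100:
            m1 = m.MassFunction.from_array(rng.dirichlet(np.ones(3)))
            m2 = m.MassFunction.from_array(rng.dirichlet(np.ones(3)))
            a1, a2 = np.argmax(m1.as_array()), np.argmax(m2.as_array())
            if a1 != a2:
                continue
            r = m.combine(m1, m2, m.DISJOINT_SINGLETON)
            assert np.argmax(r.mass.as_array()) == a1
            if a1 < 2:  # shared maximum on a singleton class
                r = m.combine(m1, m2, m.CLASSICAL_DS)
                assert np.argmax(r.mass.as_array()) == a1
            checked += 1


class TestCombineMany:
    def test_single_mass_is_itself(self):
        r = m.combine_many([M1])
        assert r.mass == M1
        assert r.k == 0.0

    def test_fold_order_invariance_classical(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            ms = [m.MassFunction.from_array(rng.dirichlet(np.ones(3))) for _ in range(3)]
            left = m.combine_many(ms, m.CLASSICAL_DS)
            right = m.combine(
                ms[0], m.combine(ms[1], ms[2], m.CLASSICAL_DS).mass, m.CLASSICAL_DS
            )
            assert np.allclose(left.mass.as_array(), right.mass.as_array(), atol=1e-12)

    def test_vacuous_list_stays_vacuous(self):
        vac = m.MassFunction(0, 0, 1)
        r = m.combine_many([vac] * 4, m.CLASSICAL_DS)
        assert r.mass.as_array() == pytest.approx([0, 0, 1], abs=1e-12)


class TestFuseSources:
    def test_agreeing_confident_sources(self):
        p = np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]])
        decided, results = m.fuse_sources(p, p)
        assert list(decided) == ["benign", "malignant", "ignorant"]
        assert all(not r.conflict_flag for r in results)

    def test_empty_inputs(self):
        decided, results = m.fuse_sources(np.empty((0, 3)), np.empty((0, 3)))
        assert decided.size == 0 and results == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            m.fuse_sources(np.ones((2, 3)) / 3, np.ones((3, 3)) / 3)

    def test_total_conflict_falls_back_to_confident_source(self):
        p1 = np.array([[1.0, 0.0, 0.0]])
        p2 = np.array([[0.0, 1.0, 0.0]])
        decided, results = m.fuse_sources(p1, p2)
        assert results[0].conflict_flag
        assert decided[0] in ("benign", "malignant")

    def test_fusion_beats_both_sources_on_independent_errors(self):
        """Simulation oracle: with independent errors, DS fusion of a 0.92 and
        a 0.95 source is more accurate than either."""
        labels, p1, p2 = m.simulate_source_pair(
            m.SimulatedSourceSpec(
                n_samples=10000, accuracy_source1=0.92, accuracy_source2=0.95,
                error_correlation=0.0, seed=3,
            )
        )
        acc1 = np.mean([m.CLASSES[i] for i in np.argmax(p1, 1)] == labels)
        acc2 = np.mean([m.CLASSES[i] for i in np.argmax(p2, 1)] == labels)
        decided, _ = m.fuse_sources(p1, p2)
        fused = np.mean(decided == labels)
        assert fused > max(acc1, acc2)
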