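import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetramap._util import DataError, DomainError
from tetramap.tetrapoint import (JointCountTable, PairPhase, SegType,
                                 candidate_phases, classify_segregation,
                                 estimate_double_reduction, estimate_two_point,
                                 joint_gamete_distribution, pairwise_linkage,
                                 preferential_pairing_check)

PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def table(n11, n10, n01, n00):
    c = np.zeros((5, 5), dtype=int)
    c[1, 1], c[1, 0], c[0, 1], c[0, 0] = n11, n10, n01, n00
    return JointCountTable(c)


def mc_gamete_oracle(alleles, r, n_draws, seed=0):
    """Vectorized Monte-Carlo meiosis, independent of the exact engine.

    alleles: (4, 2) binary matrix. Simulates pairing choice, chromatid
    choice per bivalent and a recombination event with probability r.
    Returns the empirical (3, 3) gamete dosage-class table.
    """
    rng = np.random.default_rng(seed)
    pairing = rng.integers(3, size=n_draws)
    out = np.zeros((3, 3))
    pair_arr = np.array(PAIRINGS)  # (3, 2, 2)
    chosen = pair_arr[pairing]     # (n, 2, 2)
    g1 = np.zeros(n_draws, dtype=int)
    g2 = np.zeros(n_draws, dtype=int)
    for b in range(2):
        pick = rng.integers(2, size=n_draws)
        x = chosen[np.arange(n_draws), b, pick]
        rec = rng.random(n_draws) < r
        y = np.where(rec, chosen[np.arange(n_draws), b, 1 - pick], x)
        g1 += np.asarray(alleles)[x, 0]
        g2 += np.asarray(alleles)[y, 1]
    np.add.at(out, (g1, g2), 1)
    return out / n_draws


class TestClassifySegregation:
    def test_simplex_nulliplex(self):
        seg = classify_segregation(1, 0)
        assert seg.label == "1x0" and seg.informative

    def test_non_segregating_uninformative(self):
        assert not classify_segregation(0, 0).informative
        assert not classify_segregation(4, 4).informative
        assert not classify_segregation(0, 4).informative

    def test_simplex_simplex_bridges(self):
        seg = classify_segregation(1, 1)
        assert seg.label == "1x1" and seg.informative
        phases = candidate_phases(seg, seg)
        assert all(p.maternal and p.paternal for p in phases)

    @given(st.integers(0, 4), st.integers(0, 4))
    def test_label_format(self, m, p):
        assert classify_segregation(m, p).label == f"{m}x{p}"

    @pytest.mark.parametrize("m,p", [(-1, 0), (5, 0), (0, 9)])
    def test_domain_error(self, m, p):
        with pytest.raises(DomainError):
            classify_segregation(m, p)


class TestJointGameteDistribution:
    @pytest.mark.parametrize("d1,d2", [(1, 1), (1, 2), (2, 2), (1, 3), (0, 1)])
    @pytest.mark.parametrize("phase", ["coupling", "repulsion", None])
    @pytest.mark.parametrize("r", [0.0, 0.1, 0.25, 0.5])
    def test_sums_to_one(self, d1, d2, phase, r):
        if phase is not None and (d1 in (0, 4) or d2 in (0, 4)):
            pytest.skip("phase undefined")
        t = joint_gamete_distribution(d1, d2, phase, r)
        assert abs(t.sum() - 1.0) < 1e-12

    def test_coupling_r0_no_single_transmission(self):
        t = joint_gamete_distribution(1, 1, "coupling", 0.0)
        assert t[1, 0] == 0.0 and t[0, 1] == 0.0

    @pytest.mark.parametrize("r", [0.0, 0.07, 0.33, 0.5])
    @pytest.mark.parametrize("phase", ["coupling", "repulsion"])
    def test_first_second_symmetry(self, r, phase):
        t = joint_gamete_distribution(1, 1, phase, r)
        assert t[1, 0] == pytest.approx(t[0, 1], abs=1e-15)

    def test_repulsion_r0_both_transmitted_matches_mc(self):
        # Monte-Carlo meiosis oracle: homologues carrying the two markers
        # can enter different bivalents, so the both-transmitted class
        # keeps mass even at r = 0
        alleles = np.zeros((4, 2), dtype=int)
        alleles[0, 0] = 1
        alleles[1, 1] = 1
        n = 1_000_000
        mc = mc_gamete_oracle(alleles, 0.0, n)
        t = joint_gamete_distribution(1, 1, "repulsion", 0.0)
        assert t[1, 1] > 0
        se = np.sqrt(t[1, 1] * (1 - t[1, 1]) / n)
        assert abs(mc[1, 1] - t[1, 1]) <= 3 * se
        assert t[1, 1] == pytest.approx(1 / 6, abs=1e-12)

    @pytest.mark.parametrize("d1,d2,phase,r", [
        (1, 1, "coupling", 0.13), (1, 1, "repulsion", 0.21),
        (2, 1, "coupling", 0.05), (2, 2, "repulsion", 0.37),
    ])
    def test_engine_matches_mc(self, d1, d2, phase, r):
        from tetramap.tetrapoint import _allele_config
        a = _allele_config(d1, d2, phase)
        t = joint_gamete_distribution(d1, d2, phase, r)
        mc = mc_gamete_oracle(a, r, 400_000, seed=d1 * 10 + d2)
        assert np.abs(mc - t).max() < 4 * np.sqrt(0.25 / 400_000) + 1e-3

    def test_r_domain(self):
        with pytest.raises(DomainError):
            joint_gamete_distribution(1, 1, "coupling", 0.6)


class TestEstimateTwoPoint:
    def test_closed_form_simplex_coupling(self):
        # closed form (n10 + n01) / n for maternal coupling simplex pairs
        res = estimate_two_point(table(48, 2, 2, 48), SegType(1, 0), SegType(1, 0))
        assert res.r == pytest.approx(0.04, abs=1e-4)
        assert res.phase.maternal == "coupling"
        # grid-search verification of the same likelihood
        grid = np.arange(0.0, 0.5 + 1e-9, 1e-4)
        probs = [joint_gamete_distribution(1, 1, "coupling", r) for r in grid]
        ll = [48 * np.log(p[1, 1]) + 4 * np.log(max(p[1, 0], 1e-300))
              + 48 * np.log(p[0, 0]) for p in probs]
        assert grid[int(np.argmax(ll))] == pytest.approx(res.r, abs=1e-3)

    def test_perfect_coupling(self):
        res = estimate_two_point(table(50, 0, 0, 50), SegType(1, 0), SegType(1, 0))
        assert res.r == pytest.approx(0.0, abs=1e-6)
        assert res.lod > 0

    def test_independence(self):
        res = estimate_two_point(table(25, 25, 25, 25), SegType(1, 0),
                                 SegType(1, 0))
        assert res.r == pytest.approx(0.5, abs=1e-6)
        assert res.lod == pytest.approx(0.0, abs=1e-9)

    def test_no_data_error(self):
        with pytest.raises(DataError):
            estimate_two_point(JointCountTable(np.zeros((5, 5), int)),
                               SegType(1, 0), SegType(1, 0))

    def test_impossible_class_error(self):
        c = np.zeros((5, 5), dtype=int)
        c[1, 1] = 10
        c[4, 4] = 3  # impossible for 1x0 markers
        with pytest.raises(DataError, match="impossible"):
            estimate_two_point(JointCountTable(c), SegType(1, 0), SegType(1, 0))

    def test_no_informative_parent_error(self):
        with pytest.raises(DataError, match="informative"):
            estimate_two_point(table(1, 1, 1, 1), SegType(1, 0), SegType(0, 1))

    def test_mle_matches_dense_grid(self, rng):
        # 20 random tables; full sweep lives in the acceptance suite
        for _ in range(20):
            counts = np.zeros((5, 5), dtype=int)
            counts[:2, :2] = rng.integers(0, 60, size=(2, 2))
            if counts.sum() == 0:
                continue
            t = JointCountTable(counts)
            res = estimate_two_point(t, SegType(1, 0), SegType(1, 0))
            grid = np.arange(0.0, 0.5 + 1e-9, 1e-4)
            best_ll, best_r = -np.inf, None
            for ph in candidate_phases(SegType(1, 0), SegType(1, 0)):
                probs = joint_gamete_distribution(1, 1, ph.maternal, grid)
                ll = sum(counts[i, j]
                         * np.log(np.clip(probs[:, i, j], 1e-300, None))
                         for i in range(2) for j in range(2))
                k = int(np.argmax(ll))
                if ll[k] > best_ll:
                    best_ll, best_r = ll[k], grid[k]
            assert abs(res.r - best_r) <= 1e-3

    def test_monotone_in_recombinant_fraction(self):
        # coupling-type tables: r_hat non-decreasing in the recombinant share
        prev = -1.0
        for k in range(0, 51, 5):
            res = estimate_two_point(table(50 - k // 2, k // 2, k - k // 2,
                                           50 - (k - k // 2)),
                                     SegType(1, 0), SegType(1, 0))
            assert res.r >= prev - 1e-9
            prev = res.r


class TestDoubleReduction:
    def test_no_signal(self):
        d = np.array([0] * 100 + [1] * 100)
        est = estimate_double_reduction(d, SegType(1, 0))
        assert est.alpha == 0.0 and est.ci_low == 0.0

    def test_forward_simulation_value(self):
        # E[n2] = n * alpha / 4, so 5 of 200 -> alpha = 0.10
        d = np.array([0] * 97 + [1] * 98 + [2] * 5)
        est = estimate_double_reduction(d, SegType(0, 1))
        assert est.alpha == pytest.approx(0.10)
        assert est.ci_low < 0.10 < est.ci_high

    def test_wrong_segtype(self):
        with pytest.raises(DomainError):
            estimate_double_reduction(np.array([0, 1]), SegType(1, 1))

    def test_parameter_recovery(self):
        # recovery vs simdata truth at alpha = 0.045 (telomeric loci)
        from tetramap.simdata import SimConfig, simulate_f1, simulate_parents
        alpha = 0.045
        cfg = SimConfig(n_chromosomes=4, n_markers_per_chrom=2, n_offspring=187,
                        seed=9, quadrivalent_rate=1.0,
                        double_reduction_rate=alpha, seg_mix={"1x0": 1.0})
        mother, father = simulate_parents(cfg)
        L = cfg.chrom_length_bp
        for c in range(4):
            mother.positions[c][:] = [1, L - 1]
            father.positions[c][:] = mother.positions[c]
        n2 = n = 0
        for rep in range(10):
            cfg_r = SimConfig(**{**cfg.to_dict(), "seed": 900 + rep})
            matrix, _ = simulate_f1(mother, father, cfg_r)
            for i in range(matrix.n_markers):
                est = estimate_double_reduction(matrix.data[i], SegType(1, 0))
                n2 += est.n_dosage2
                n += est.n
        pooled = 4 * n2 / n
        assert 0.03 <= pooled <= 0.06


class TestPreferentialPairing:
    def test_uniform(self):
        res = preferential_pairing_check([100, 100, 100])
        assert res.chi2 == 0.0 and res.p_value == pytest.approx(1.0)

    def test_strong_preference(self):
        res = preferential_pairing_check([200, 50, 50])
        assert res.chi2 == pytest.approx(150.0)
        assert res.p_value < 1e-30

    def test_underpowered_flag(self):
        assert preferential_pairing_check([5, 5, 5]).underpowered

    def test_type_one_error_rate(self, rng):
        # uniform-pairing simulation: ~5% rejections at alpha = 0.05
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            counts = rng.multinomial(150, [1 / 3] * 3)
            if preferential_pairing_check(counts).p_value < 0.05:
                rejections += 1
        assert abs(rejections / n_rep - 0.05) < 0.025


class TestPairwiseLinkage:
    def test_matches_single_pair_estimates(self, small_cross):
        _, _, _, matrix, _ = small_cross
        sub = matrix.subset(marker_idx=np.arange(6))
        pw = pairwise_linkage(sub, r_step=0.001, error_floor=1e-4)
        assert len(pw) == 15
        for row in pw.itertuples():
            i = sub.marker_index()[row.marker1]
            j = sub.marker_index()[row.marker2]
            t = JointCountTable.from_dosages(sub.data[i], sub.data[j])
            res = estimate_two_point(t, SegType(1, 0), SegType(1, 0),
                                     error_floor=1e-4)
            assert row.r == pytest.approx(res.r, abs=2e-3)
            assert row.lod == pytest.approx(res.lod, abs=0.02)

    def test_uninformative_pairs_omitted(self):
        from tetramap.dosage import DosageMatrix
        m = DosageMatrix(markers=["a", "b"], individuals=["i1", "i2"],
                         maternal=[1, 0], paternal=[0, 1],
                         data=np.array([[0, 1], [1, 0]], dtype=np.int8))
        assert len(pairwise_linkage(m)) == 0


class TestProbabilityInvariants:
    @given(st.floats(0.0, 0.5), st.sampled_from(["coupling", "repulsion"]),
           st.integers(1, 3), st.integers(1, 3))
    @settings(max_examples=60, deadline=None)
    def test_distribution_normalized(self, r, phase, d1, d2):
        t = joint_gamete_distribution(d1, d2, phase, r)
        assert abs(t.sum() - 1.0) < 1e-12
        assert (t >= -1e-15).all()
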