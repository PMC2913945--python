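"""Peeling likelihoods, LOD/HLOD, NPL sharing, and LOD <-> p conversions."""

import numpy as np
import pytest
from conftest import brute_force_loglik, drop_marker_genotypes, random_small_pedigree

from pedlink import linkage as L
from pedlink.models import recessive_model
from pedlink.pedigree import Individual, Pedigree


def _phase_known_pedigree(n_kids, recombinant_kids=0):
    """Grandparents fix the phase of an affected double-heterozygote
    father; each non-recombinant child contributes log10(2) at theta 0."""
    mem = [
        Individual("f", "gf", None, None, "male"),
        Individual("f", "gm", None, None, "female"),
        Individual("f", "dad", "gf", "gm", "male"),
        Individual("f", "mom", None, None, "female"),
    ]
    for k in range(n_kids):
        mem.append(Individual("f", f"k{k}", "dad", "mom", "male"))
    ped = Pedigree("f", mem)
    # gf 1/1 affected, gm 2/2 unaffected, dad 1/2 affected, mom 2/2 unaffected
    codes = [1, 3, 2, 3]
    aff = [1, 0, 1, 0]
    for k in range(n_kids):
        if k < recombinant_kids:
            codes.append(3)  # affected but carrying marker 2/2: recombinant
        else:
            codes.append(2)
        aff.append(1)
    pw = np.where(
        np.array(aff)[:, None], np.array([0.0, 1.0, 1.0]), np.array([1.0, 0.0, 0.0])
    )
    return ped, np.array(codes), pw


class TestHaldane:
    def test_ten_cm(self):
        assert L.haldane_theta(10.0) == pytest.approx(0.0906, abs=1e-4)

    def test_inverse(self):
        for d in (1.0, 10.0, 50.0):
            assert L.haldane_cm(L.haldane_theta(d)) == pytest.approx(d)


class TestPeeling:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        parent_idx = random_small_pedigree(rng)
        codes = drop_marker_genotypes(parent_idx, rng)
        pw = rng.random((len(parent_idx), 3))
        plan = L.PeelingPlan(parent_idx)
        u = L.build_unary(plan, codes, pw, 0.1, 0.4)
        for theta in (0.0, 0.1, 0.5):
            a = L.peel_loglik(plan, u[None], theta)[0]
            b = brute_force_loglik(parent_idx, u, theta)
            assert a == pytest.approx(b, rel=1e-9)

    def test_no_data_gives_zero_lod(self):
        parent_idx = (None, None, (0, 1), (0, 1))
        plan = L.PeelingPlan(parent_idx)
        codes = np.zeros(4, dtype=int)
        pw = np.ones((4, 3))
        u = L.build_unary(plan, codes, pw, 0.05, 0.5)
        ll0 = L.peel_loglik(plan, u[None], 0.0)[0]
        ll5 = L.peel_loglik(plan, u[None], 0.5)[0]
        assert ll0 == pytest.approx(ll5, abs=1e-12)

    def test_lod_zero_at_theta_half(self):
        rng = np.random.default_rng(3)
        parent_idx = random_small_pedigree(rng)
        codes = drop_marker_genotypes(parent_idx, rng)
        pw = rng.random((len(parent_idx), 3))
        plan = L.PeelingPlan(parent_idx)
        u = L.build_unary(plan, codes, pw, 0.05, 0.5)
        lods = L.lod_curves([plan], [u], L.THETA_GRID)
        assert lods[0, L.THETA_GRID.index(0.5)] == pytest.approx(0.0, abs=1e-12)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(8)
        parent_idx = random_small_pedigree(rng)
        codes = drop_marker_genotypes(parent_idx, rng, freq1=0.3)
        pw = rng.random((len(parent_idx), 3))
        plan = L.PeelingPlan(parent_idx)
        swapped = codes.copy()
        swapped[codes == 1] = 3
        swapped[codes == 3] = 1
        for theta in (0.0, 0.2):
            a = L.peel_loglik(
                plan, L.build_unary(plan, codes, pw, 0.05, 0.3)[None], theta
            )[0]
            b = L.peel_loglik(
                plan, L.build_unary(plan, swapped, pw, 0.05, 0.7)[None], theta
            )[0]
            assert a == pytest.approx(b, rel=1e-12)

    def test_penetrance_scale_invariance(self):
        rng = np.random.default_rng(9)
        parent_idx = random_small_pedigree(rng)
        codes = drop_marker_genotypes(parent_idx, rng)
        pw = rng.random((len(parent_idx), 3))
        plan = L.PeelingPlan(parent_idx)
        u1 = L.build_unary(plan, codes, pw, 0.05, 0.5)
        u2 = L.build_unary(plan, codes, pw * 37.5, 0.05, 0.5)
        l1 = L.lod_curves([plan], [u1], L.THETA_GRID)
        l2 = L.lod_curves([plan], [u2], L.THETA_GRID)
        np.testing.assert_allclose(l1, l2, rtol=1e-9, atol=1e-9)

    def test_mendelian_inconsistency_raises(self):
        # parents 1/1 x 1/1 with a 2/2 child is impossible at any theta
        parent_idx = (None, None, (0, 1))
        plan = L.PeelingPlan(parent_idx)
        codes = np.array([1, 1, 3])
        pw = np.ones((3, 3))
        u = L.build_unary(plan, codes, pw, 0.05, 0.5)
        with pytest.raises(L.ImpossibleDataError):
            L.lod_curves([plan], [u], L.THETA_GRID, ["famX"])


class TestLodCurves:
    def test_phase_known_meioses_closed_form(self):
        for n in (1, 3, 5):
            ped, codes, pw = _phase_known_pedigree(n)
            plan = L.PeelingPlan.from_pedigree(ped)
            u = L.build_unary(plan, codes, pw, 0.01, 0.5)
            lods = L.lod_curves([plan], [u], (0.0, 0.5))
            assert lods[0, 0] == pytest.approx(n * np.log10(2), rel=1e-9)

    def test_obligate_recombinant_floored(self):
        ped, codes, pw = _phase_known_pedigree(3, recombinant_kids=1)
        plan = L.PeelingPlan.from_pedigree(ped)
        u = L.build_unary(plan, codes, pw, 0.01, 0.5)
        lods = L.lod_curves([plan], [u], (0.0, 0.1, 0.5))
        assert lods[0, 0] == L.LOD_FLOOR
        assert np.isfinite(lods[0, 1])


class TestHlod:
    def _curves(self, values):
        return np.asarray(values, dtype=float)

    def test_alpha_one_recovers_pooled_lod(self):
        lods = self._curves([[1.2, 0.5, 0.0], [0.8, 0.4, 0.0]])
        res = L.hlod(lods, (0.0, 0.2, 0.5), alpha_grid=(1.0,))
        assert res.hlod == pytest.approx(2.0)
        assert res.theta == 0.0

    def test_all_negative_gives_zero_at_alpha_zero(self):
        lods = self._curves([[-3.0, -1.0, 0.0], [-2.0, -0.5, 0.0]])
        res = L.hlod(lods, (0.0, 0.2, 0.5))
        assert res.hlod == pytest.approx(0.0)
        assert res.alpha == 0.0

    def test_matches_dense_grid_oracle(self):
        lods = self._curves([[2.0, 0.0], [-3.0, 0.0]])
        res = L.hlod(lods, (0.0, 0.5))
        alphas = np.linspace(0, 1, 200001)
        vals = np.log10(alphas[:, None] * 10.0 ** lods[:, 0] + (1 - alphas[:, None])).sum(
            axis=1
        )
        assert res.hlod == pytest.approx(vals.max(), abs=1e-4)

    def test_monotone_in_family_curves(self):
        rng = np.random.default_rng(4)
        lods = rng.normal(0, 1, size=(6, 4))
        base = L.hlod(lods, (0.0, 0.1, 0.2, 0.5)).hlod
        bumped = lods.copy()
        bumped[2] += 0.3  # pointwise increase of one family's curve
        assert L.hlod(bumped, (0.0, 0.1, 0.2, 0.5)).hlod >= base - 1e-12

    def test_empty_rejected(self):
        with pytest.raises(L.LinkageError):
            L.hlod(np.empty((0, 3)), (0.0, 0.2, 0.5))


def _sib_pair(codes):
    mem = [
        Individual("f", "fa", None, None, "male"),
        Individual("f", "mo", None, None, "female"),
        Individual("f", "s1", "fa", "mo", "male"),
        Individual("f", "s2", "fa", "mo", "male"),
    ]
    ped = Pedigree("f", mem)
    aff = np.array([False, False, True, True])
    return ped, np.asarray(codes), aff


class TestNpl:
    def test_uninformative_marker_zero(self):
        ped, codes, aff = _sib_pair([0, 0, 0, 0])
        res = L.npl_statistic([ped], [codes], 0.5, [aff])
        assert res.z == pytest.approx(0.0, abs=1e-12)

    def test_full_sharing_positive(self):
        # het x het parents, both children 1/1: grandparental origin of
        # every allele is identified, so IBD sharing is exactly 2
        ped, codes, aff = _sib_pair([2, 2, 1, 1])
        res = L.npl_statistic([ped], [codes], 0.5, [aff])
        assert res.z > 0
        assert res.p < 0.5

    def test_sharing_score_matches_sixteen_vector_enumeration(self):
        """For a sib pair the posterior mean sharing equals a direct
        enumeration over the 16 inheritance vectors."""
        ped, codes, aff = _sib_pair([2, 2, 1, 1])
        z = L._family_npl(ped, codes, 0.5, aff, max_bits=18)
        # direct enumeration over the 16 inheritance vectors: both parents
        # are het 1/2 and both children 1/1, so a vector is consistent iff
        # the sibs drew the same slot from each parent (that slot carries
        # allele 1); every consistent vector has full sharing
        svals, weights = [], []
        for v in range(16):
            b = [(v >> i) & 1 for i in range(4)]
            s1 = (b[0], b[1])  # slots chosen from father, mother
            s2 = (b[2], b[3])
            share = ((s1[0] == s2[0]) + (s1[1] == s2[1])) / 2
            svals.append(share)
            # sum over founder-slot allele assignments: het parents have
            # one slot "1" and one slot "2" (two arrangements each); the
            # children's 1/1 genotypes force the shared-slot arrangement
            w = 0.0
            for fa_one in (0, 1):  # father slot carrying allele 1
                for mo_one in (0, 1):
                    if s1 == (fa_one, mo_one) and s2 == (fa_one, mo_one):
                        w += 0.5**4  # four slots at freq 0.5 each
            weights.append(w)
        svals = np.array(svals)
        weights = np.array(weights)
        mu0, sd0 = svals.mean(), svals.std()
        expected = ((weights / weights.sum()) @ svals - mu0) / sd0
        assert z == pytest.approx(expected, rel=1e-9)

    def test_bit_cap_skips_family(self):
        ped, codes, aff = _sib_pair([2, 2, 1, 1])
        res = L.npl_statistic([ped], [codes], 0.5, [aff], max_bits=2)
        assert res.n_families_skipped == 1
        assert res.z == 0.0

    def test_null_calibration(self):
        """Combined Z over 30 null sib-pair families is close enough to
        normal for P(Z > 1.645) to sit near 0.05."""
        rng = np.random.default_rng(12)
        n_reps, n_fam = 250, 30
        cache: dict[tuple, float | None] = {}
        exceed = 0
        for _ in range(n_reps):
            zs = []
            for _ in range(n_fam):
                parent_idx = (None, None, (0, 1), (0, 1))
                codes = tuple(
                    drop_marker_genotypes(parent_idx, rng, freq1=0.5, typed_prob=1.0)
                )
                if codes not in cache:
                    ped, c, aff = _sib_pair(list(codes))
                    cache[codes] = L._family_npl(ped, np.array(codes), 0.5, aff, 18)
                z = cache[codes]
                if z is not None:
                    zs.append(z)
            zc = np.sum(zs) / np.sqrt(len(zs))
            exceed += zc > 1.645
        rate = exceed / n_reps
        # binomial 99.7% envelope around 0.05 at 250 replicates
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_reps) + 0.02


class TestLodPvalue:
    @pytest.mark.parametrize(
        "lod,p",
        [
            (1.88, 0.0017),
            (3.30, 0.000048),
            (3.64, 0.000021),
            (3.07, 0.000085),
            (2.91, 0.00013),
            (2.77, 0.00018),
            (2.23, 0.00068),
        ],
    )
    def test_printed_pairs(self, lod, p):
        # agree to one unit in the last printed digit
        import math

        ulp = 10.0 ** math.floor(math.log10(p) - 1)
        assert abs(L.lod_to_pvalue(lod) - p) <= ulp

    def test_lod_zero_is_half(self):
        assert L.lod_to_pvalue(0.0) == pytest.approx(0.5)

    def test_mutual_inverse(self):
        for lod in (0.1, 1.0, 2.5, 4.0):
            assert L.pvalue_to_lod(L.lod_to_pvalue(lod)) == pytest.approx(
                lod, abs=1e-10
            )

    def test_strictly_decreasing(self):
        lods = np.linspace(0, 5, 40)
        ps = [L.lod_to_pvalue(x) for x in lods]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_domain_errors(self):
        with pytest.raises(L.LinkageError):
            L.lod_to_pvalue(-0.1)
        with pytest.raises(L.LinkageError):
            L.pvalue_to_lod(0.6)
        with pytest.raises(L.LinkageError):
            L.pvalue_to_lod(0.0)
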