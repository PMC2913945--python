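"""Generator properties: pedigree classes, gene dropping, phenotypes,
fixture round trips, and the exact ascertainment sampler."""

import numpy as np
import pandas as pd
import pytest

from pedlink import linkage, phenotypes
from pedlink.models import QuantitativeModel, recessive_model
from pedlink.pedigree import read_pedigree_file, validate_pedigree
from pedlink.simulate import (
    SimSpec,
    SimSpecError,
    drop_unlinked_marker,
    gene_drop,
    generate_pedigrees,
    linked_recovery_study,
    sample_ascertained_nuclear,
    simulate_phenotypes,
    write_fixture,
)


class TestGeneratePedigrees:
    def test_small_class_generation_counts(self):
        spec = SimSpec(n_large=0, n_moderate=0, n_small=12, min_affected=0)
        peds = generate_pedigrees(spec, np.random.default_rng(0))
        assert len(peds) == 12
        for p in peds:
            assert p.generation_count() in (2, 3)
            assert validate_pedigree(p).ok

    def test_large_class_generation_counts(self):
        spec = SimSpec(n_large=4, n_moderate=0, n_small=0, min_affected=0)
        peds = generate_pedigrees(spec, np.random.default_rng(1))
        for p in peds:
            assert 6 <= p.generation_count() <= 9

    def test_fixed_seed_reproducible(self):
        spec = SimSpec(n_large=1, n_moderate=1, n_small=3, min_affected=0)
        a = generate_pedigrees(spec, np.random.default_rng(5))
        b = generate_pedigrees(spec, np.random.default_rng(5))
        for x, y in zip(a, b):
            assert [m.indiv_id for m in x.members] == [m.indiv_id for m in y.members]
            assert [m.father_id for m in x.members] == [m.father_id for m in y.members]

    def test_family_sizes_plausible(self):
        spec = SimSpec(n_large=10, n_moderate=0, n_small=0, min_affected=0)
        peds = generate_pedigrees(spec, np.random.default_rng(2))
        mean = np.mean([len(p) for p in peds])
        assert 8 <= mean <= 45  # Table-1-scale extended families


class TestGeneDrop:
    def test_haldane_ten_cm(self):
        assert linkage.haldane_theta(10.0) == pytest.approx(
            (1 - np.exp(-0.2)) / 2, abs=1e-12
        )

    def test_founder_allele_frequency(self):
        spec = SimSpec(
            n_large=0, n_moderate=0, n_small=60, marker_freq1=0.5, min_affected=0
        )
        rng = np.random.default_rng(3)
        peds = generate_pedigrees(spec, rng)
        gm, gmap, truth = gene_drop(peds, spec, rng)
        founder_rows = [
            gm.row_of(p.family_id, m.indiv_id) for p in peds for m in p.founders
        ]
        a = gm.alleles[founder_rows, 0, :]
        a = a[a[:, 0] > 0]
        freq = (a == 1).sum() / (2 * len(a))
        n_alleles = 2 * len(a)
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / n_alleles)

    def test_unlinked_trait_uncorrelated_with_marker(self):
        spec = SimSpec(
            n_large=0,
            n_moderate=0,
            n_small=400,
            alpha_sim=0.0,
            disease_model=recessive_model(disease_allele_freq=0.5),
            min_affected=0,
        )
        rng = np.random.default_rng(4)
        peds = generate_pedigrees(spec, rng)
        gm, gmap, truth = gene_drop(peds, spec, rng)
        g = np.array(
            [truth.disease_genotype[k] for k in gm.row_keys], dtype=float
        )
        dosage = (gm.alleles[:, 2, :] == 1).sum(axis=1).astype(float)
        ok = gm.alleles[:, 2, 0] > 0
        r = np.corrcoef(g[ok], dosage[ok])[0, 1]
        assert abs(r) < 0.1

    def test_truth_consistent_with_linked_flag(self):
        spec = SimSpec(n_large=0, n_moderate=0, n_small=30, alpha_sim=0.5, min_affected=0)
        rng = np.random.default_rng(6)
        peds = generate_pedigrees(spec, rng)
        _, _, truth = gene_drop(peds, spec, rng)
        flags = list(truth.linked.values())
        assert len(flags) == 30 and any(flags) and not all(flags)


@pytest.fixture(scope="module")
def quant_data():
    spec = SimSpec(
        n_large=0,
        n_moderate=0,
        n_small=400,
        disease_model=QuantitativeModel(disease_allele_freq=0.3),
        missing_srs_rate=0.0,
        min_affected=0,
    )
    rng = np.random.default_rng(8)
    peds = generate_pedigrees(spec, rng)
    gm, gmap, truth = gene_drop(peds, spec, rng)
    pheno = simulate_phenotypes(peds, truth, spec, rng)
    return spec, peds, truth, pheno


class TestSimulatePhenotypes:
    def test_genotype_conditional_trait_means(self, quant_data):
        spec, peds, truth, pheno = quant_data
        for g, mean in ((0, -1.552), (2, 2.558)):
            vals = [
                truth.latent_trait[k]
                for k, gg in truth.disease_genotype.items()
                if gg == g
            ]
            sd = spec.disease_model.sds[g]
            assert np.mean(vals) == pytest.approx(
                mean, abs=3 * sd / np.sqrt(len(vals))
            )

    def test_spouse_correlation_recovered(self):
        # default allele frequency (0.05): spouses are mostly zero-risk, so
        # genotype variance attenuates the couple correlation only mildly
        spec = SimSpec(
            n_large=0,
            n_moderate=0,
            n_small=500,
            disease_model=QuantitativeModel(),
            missing_srs_rate=0.0,
            min_affected=0,
        )
        rng = np.random.default_rng(14)
        peds = generate_pedigrees(spec, rng)
        _, _, truth = gene_drop(peds, spec, rng)
        simulate_phenotypes(peds, truth, spec, rng)
        pairs = []
        for ped in peds:
            seen = set()
            for m in ped.members:
                if m.father_id is None or (m.father_id, m.mother_id) in seen:
                    continue
                seen.add((m.father_id, m.mother_id))
                pairs.append(
                    (
                        truth.latent_trait[(ped.family_id, m.father_id)],
                        truth.latent_trait[(ped.family_id, m.mother_id)],
                    )
                )
        pairs = np.array(pairs)
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        # expected ~0.29 after mild genotype-variance attenuation; the
        # band covers that plus sampling noise at ~1000 couples
        assert 0.33 == pytest.approx(r, abs=0.09)

    def test_covariates_recovered_by_adjustment(self, quant_data):
        spec, peds, truth, pheno = quant_data
        out, fit = phenotypes.transform_adjust(
            phenotypes.apply_rater_exclusions(pheno)
        )
        assert fit.beta_age == pytest.approx(-0.074, abs=3 * fit.se_age)
        assert fit.beta_male == pytest.approx(1.6, abs=3 * fit.se_male)

    def test_category_frequency_monotone_in_risk_alleles(self):
        spec = SimSpec(
            n_large=0,
            n_moderate=0,
            n_small=300,
            disease_model=recessive_model(disease_allele_freq=0.4),
            missing_srs_rate=0.0,
            min_affected=0,
        )
        rng = np.random.default_rng(9)
        peds = generate_pedigrees(spec, rng)
        gm, gmap, truth = gene_drop(peds, spec, rng)
        pheno = simulate_phenotypes(peds, truth, spec, rng)
        pheno = phenotypes.apply_rater_exclusions(pheno)
        merged = pheno.set_index(["family_id", "indiv_id"])
        rates = []
        for g in (0, 1, 2):
            keys = [k for k, gg in truth.disease_genotype.items() if gg == g]
            cats = merged.loc[keys, "category"]
            cats = cats[cats != phenotypes.UNKNOWN]
            rates.append((cats == phenotypes.AFFECTED).mean())
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.5  # recessive: two copies are highly penetrant

    def test_all_raw_scores_finite_non_negative(self, quant_data):
        *_, pheno = quant_data
        vals = pheno["raw_srs"].dropna()
        assert np.isfinite(vals).all() and (vals >= 0).all()

    def test_bad_spouse_corr_rejected(self):
        with pytest.raises(SimSpecError):
            SimSpec(spouse_corr=1.0)


class TestFixtureRoundTrip:
    def test_written_fixture_reads_back_identically(self, small_dataset, tmp_path):
        peds, gm, gmap, truth, pheno = small_dataset
        paths = write_fixture(peds, gm, gmap, pheno, truth, tmp_path / "d")
        peds2, gm2 = read_pedigree_file(paths["ped"])
        np.testing.assert_array_equal(gm.alleles, gm2.alleles)
        pheno2 = pd.read_csv(paths["pheno"], sep="\t")
        assert len(pheno2) == len(pheno)

    def test_same_seed_identical_files(self, small_spec, tmp_path):
        def build(out):
            rng = np.random.default_rng(21)
            peds = generate_pedigrees(small_spec, rng)
            gm, gmap, truth = gene_drop(peds, small_spec, rng)
            pheno = simulate_phenotypes(peds, truth, small_spec, rng)
            return write_fixture(peds, gm, gmap, pheno, truth, out)

        pa = build(tmp_path / "a")
        pb = build(tmp_path / "b")
        for key in pa:
            assert open(pa[key]).read() == open(pb[key]).read()

    def test_all_missing_srs_gives_unknown_categories(self, small_spec):
        spec = SimSpec(
            n_large=0, n_moderate=0, n_small=5, missing_srs_rate=1.0, min_affected=0
        )
        rng = np.random.default_rng(13)
        peds = generate_pedigrees(spec, rng)
        _, _, truth = gene_drop(peds, spec, rng)
        pheno = simulate_phenotypes(peds, truth, spec, rng)
        out = phenotypes.apply_rater_exclusions(pheno)
        assert (out["category"] == phenotypes.UNKNOWN).all()


class TestAscertainedSampler:
    def test_every_family_meets_ascertainment(self):
        b = sample_ascertained_nuclear(500, 3, recessive_model(), np.random.default_rng(1))
        assert ((b.categories == 2).sum(axis=1) >= 2).all()

    def test_parent_pair_posterior_matches_enumeration(self):
        """Sampled parent genotype pairs follow the analytic posterior
        HW(gf) HW(gm) P(>=2 affected | pair), computed independently."""
        model = recessive_model(disease_allele_freq=0.3)
        rng = np.random.default_rng(2)
        n = 30000
        b = sample_ascertained_nuclear(n, 2, model, rng)
        q = 0.3
        hw = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
        fa = np.array(model.f_affected)
        post = np.zeros((3, 3))
        for gf in range(3):
            for gm in range(3):
                pf, pm = gf / 2, gm / 2
                kid = np.array(
                    [(1 - pf) * (1 - pm), pf * (1 - pm) + (1 - pf) * pm, pf * pm]
                )
                pk = float(kid @ fa)
                ps = [fa[gf], fa[gm], pk, pk]
                # P(>= 2 affected of 4) by direct expansion
                tot = 0.0
                for mask in range(16):
                    bits = [(mask >> i) & 1 for i in range(4)]
                    if sum(bits) < 2:
                        continue
                    pr = 1.0
                    for bit, p in zip(bits, ps):
                        pr *= p if bit else 1 - p
                    tot += pr
                post[gf, gm] = hw[gf] * hw[gm] * tot
        post /= post.sum()
        obs = np.zeros((3, 3))
        for gf, gm in b.parent_g:
            obs[gf, gm] += 1
        obs /= n
        assert np.abs(obs - post).max() < 0.015

    def test_marker_drop_is_mendelian(self):
        b = sample_ascertained_nuclear(200, 3, recessive_model(), np.random.default_rng(3))
        codes = drop_unlinked_marker(b, 0.7, np.random.default_rng(4))
        # child alleles must be drawable from parent genotypes
        for fam in range(200):
            cf, cm = codes[fam, 0], codes[fam, 1]
            f_alleles = {1: {1}, 2: {1, 2}, 3: {2}}[cf]
            m_alleles = {1: {1}, 2: {1, 2}, 3: {2}}[cm]
            for k in range(3):
                ck = codes[fam, 2 + k]
                kid = {1: (1, 1), 2: (1, 2), 3: (2, 2)}[ck]
                ok = any(
                    a in f_alleles and b_ in m_alleles
                    for a, b_ in (kid, kid[::-1])
                )
                assert ok


class TestRecoveryStudies:
    def test_alpha_recovery_centres_near_half(self):
        """With half the families linked, the admixture estimate at the
        trait marker concentrates around 0.5."""
        alphas = []
        for seed in range(6):
            rng = np.random.default_rng(300 + seed)
            out = linked_recovery_study(
                80, rng, alpha_sim=0.5, n_linked=3, trait_marker=1, n_unlinked=0
            )
            alphas.append(out["alpha_at_trait"])
        assert 0.3 <= float(np.mean(alphas)) <= 0.7

    def test_linked_trait_marker_beats_unlinked(self):
        rng = np.random.default_rng(17)
        out = linked_recovery_study(60, rng)
        hl = out["hlods"]
        assert hl[out["trait_marker"]] > hl[out["n_linked"]:].max()
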