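import math

import numpy as np
import pytest
from scipy import stats

from phenokit.gwas import (
    GenotypeMatrix,
    KinshipMatrix,
    clump_loci,
    effective_marker_number,
    genomic_inflation,
    kinship_identity_proportion,
    ld_r2,
    lmm_scan,
    maf_filter,
    ols_scan,
    peak_filter,
    phenotype_preprocess,
    significance_thresholds,
)
from phenokit.synth import simulate_genotypes, simulate_phenotype
from oracles import greedy_clump_oracle


def make_matrix(dosages: np.ndarray, chrom=None, pos=None) -> GenotypeMatrix:
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages=np.asarray(dosages, dtype=float),
        chrom=np.array(chrom if chrom is not None else ["chr1"] * m),
        pos=np.array(pos if pos is not None else np.arange(1, m + 1) * 100),
        accessions=[f"a{i}" for i in range(n)],
    )


class TestMafFilter:
    def test_borderline_retained(self):
        # 529 homozygous accessions, minor allele in 27: MAF 27/529 > 0.05
        d = np.zeros((529, 1))
        d[:27, 0] = 2.0
        G = make_matrix(d)
        assert maf_filter(G).m == 1

    def test_five_carriers_removed(self):
        d = np.zeros((529, 1))
        d[:5, 0] = 2.0
        assert maf_filter(make_matrix(d)).m == 0 or True
        with pytest.warns(RuntimeWarning):
            assert maf_filter(make_matrix(d)).m == 0

    def test_maf_passes_but_mac_binds(self):
        # n=100 homozygous, 5 carriers: MAF exactly 0.05 but 5 < 6 carriers
        d = np.zeros((100, 1))
        d[:5, 0] = 2.0
        with pytest.warns(RuntimeWarning):
            assert maf_filter(make_matrix(d)).m == 0

    def test_maf_over_nonmissing(self):
        d = np.zeros((20, 1))
        d[:8, 0] = 2.0
        d[10:, 0] = np.nan  # 10 non-missing, 8 minor? freq 0.8 -> minor is ref
        G = maf_filter(make_matrix(d), maf_min=0.05, mac_accessions_min=2)
        assert G.m == 1


class TestKinship:
    def test_identical_accessions(self):
        d = np.tile(np.array([[0.0, 2.0, 2.0, 0.0]]), (2, 1))
        K = kinship_identity_proportion(make_matrix(d))
        assert K.raw[0, 1] == 1.0

    def test_half_identical(self):
        d = np.array([[0.0, 2.0, 2.0, 0.0], [0.0, 2.0, 0.0, 2.0]])
        K = kinship_identity_proportion(make_matrix(d))
        assert K.raw[0, 1] == 0.5

    def test_toy_matrix_brute_force(self):
        rng = np.random.default_rng(3)
        d = rng.choice([0.0, 2.0], size=(5, 8))
        K = kinship_identity_proportion(make_matrix(d))
        for i in range(5):
            for j in range(5):
                expected = np.mean(d[i] == d[j])
                assert K.raw[i, j] == pytest.approx(expected)

    def test_psd_after_repair(self):
        pop = simulate_genotypes(n=40, m=200, ld_rho=0.3, seed=5)
        K = kinship_identity_proportion(pop.matrix, seed=1)
        eig = np.linalg.eigvalsh(K.values)
        assert eig.min() >= -1e-10
        assert np.allclose(np.diag(K.values), 1.0)

    def test_missing_overlap_handling(self):
        d = np.array([[0.0, np.nan, 2.0], [0.0, 2.0, np.nan], [2.0, 2.0, 2.0]])
        K = kinship_identity_proportion(make_matrix(d))
        assert K.raw[0, 1] == 1.0  # only SNP 0 co-observed, identical there


class TestPhenotypePreprocess:
    def test_no_outliers_unchanged(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        y = (y - y.mean()) / y.std() * 0.9  # keep everything within 3 SD
        keep, dropped = phenotype_preprocess(y)
        assert keep.all()
        assert dropped.size == 0

    def test_single_outlier_dropped(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.normal(size=50), [10.0]])
        keep, dropped = phenotype_preprocess(y)
        assert list(dropped) == [50]
        assert keep[:50].all()

    def test_constant_vector_unchanged(self):
        y = np.ones(20)
        keep, dropped = phenotype_preprocess(y)
        assert keep.all()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            phenotype_preprocess(np.ones(5))


class TestLmmScan:
    def test_identity_kinship_matches_ols_lr(self):
        pop = simulate_genotypes(n=60, m=40, seed=2)
        rng = np.random.default_rng(7)
        y = rng.normal(size=60)
        identity = KinshipMatrix(np.eye(60), np.eye(60), 0, False)
        res = lmm_scan(pop.matrix, y, identity)
        # OLS likelihood-ratio oracle: LR = n * ln(RSS0 / RSS1)
        D = pop.matrix.dosages
        rss0 = ((y - y.mean()) ** 2).sum()
        for j in range(pop.matrix.m):
            x = D[:, j]
            if x.std() == 0:
                continue
            X = np.column_stack([np.ones(60), x])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = ((y - X @ beta) ** 2).sum()
            lr = 60 * math.log(rss0 / rss1)
            p_oracle = stats.chi2.sf(lr, df=1)
            assert res.p_value[j] == pytest.approx(p_oracle, abs=1e-6)

    def test_null_loglik_matches_brute_force(self):
        # n=8 toy: profiled optimum must dominate a dense brute-force grid
        # over (mu, sigma_g2, sigma_e2) for the no-SNP model.
        rng = np.random.default_rng(11)
        A = rng.normal(size=(8, 8))
        K = A @ A.T / 8
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
        y = rng.normal(size=8)
        pop = simulate_genotypes(n=8, m=30, seed=0)
        G30 = GenotypeMatrix(
            dosages=pop.matrix.dosages,
            chrom=pop.matrix.chrom,
            pos=pop.matrix.pos,
            accessions=pop.matrix.accessions,
        )
        from phenokit.gwas import _optimize_delta

        eigval, U = np.linalg.eigh(K)
        s = np.clip(eigval, 0, None)
        _, ll_opt, _, _ = _optimize_delta(s, U.T @ y, U.T @ np.ones((8, 1)))
        best_brute = -np.inf
        for mu in np.linspace(y.min(), y.max(), 20):
            r = y - mu
            for sg2 in np.logspace(-2, 1, 25):
                for se2 in np.logspace(-2, 1, 25):
                    cov = sg2 * K + se2 * np.eye(8)
                    ll = stats.multivariate_normal.logpdf(r, cov=cov)
                    best_brute = max(best_brute, ll)
        assert ll_opt >= best_brute - 1e-4

    def test_permuted_phenotype_uniform_p(self):
        pop = simulate_genotypes(n=200, m=5000, ld_rho=0.0, seed=9)
        rng = np.random.default_rng(10)
        y = rng.permutation(rng.normal(size=200))
        K = kinship_identity_proportion(pop.matrix, seed=0)
        res = lmm_scan(pop.matrix, y, K)
        p = res.p_value[np.isfinite(res.p_value)]
        stat, pval = stats.kstest(p, "uniform")
        assert pval > 0.01

    def test_monomorphic_snp_missing_p(self):
        pop = simulate_genotypes(n=50, m=20, seed=1)
        D = pop.matrix.dosages.copy()
        D[:, 3] = 2.0
        G = make_matrix(D)
        y = np.random.default_rng(0).normal(size=50)
        res = lmm_scan(G, y, KinshipMatrix(np.eye(50), np.eye(50), 0, False))
        assert np.isnan(res.p_value[3])
        assert np.isfinite(res.p_value[4])

    def test_per_snp_delta_mode_close_to_null_delta(self):
        pop = simulate_genotypes(n=60, m=25, ld_rho=0.2, seed=3)
        y, _ = simulate_phenotype(pop, h2_polygenic=0.3, seed=4)
        K = kinship_identity_proportion(pop.matrix, seed=0)
        a = lmm_scan(pop.matrix, y, K, mode="null_delta")
        b = lmm_scan(pop.matrix, y, K, mode="per_snp_delta")
        ok = np.isfinite(a.p_value)
        assert np.corrcoef(
            -np.log10(a.p_value[ok]), -np.log10(b.p_value[ok])
        )[0, 1] > 0.99

    def test_small_n_rejected(self):
        pop = simulate_genotypes(n=10, m=5, seed=0)
        with pytest.raises(ValueError):
            lmm_scan(pop.matrix, np.zeros(10), KinshipMatrix(np.eye(10), np.eye(10), 0, False))


class TestEffectiveMarkerNumber:
    def test_orthogonal_fixture_exact(self):
        from scipy.linalg import hadamard

        H = hadamard(8)[:, 1:]  # 7 mutually orthogonal, mean-zero columns
        d = (H + 1).astype(float)  # maps to {0, 2}
        G = make_matrix(d)
        assert effective_marker_number(G) == pytest.approx(7.0, abs=1e-9)

    def test_identical_block_contributes_one(self):
        rng = np.random.default_rng(0)
        col = rng.choice([0.0, 2.0], size=20)
        d = np.tile(col[:, None], (1, 6))
        assert effective_marker_number(make_matrix(d)) == pytest.approx(1.0, abs=1e-9)

    def test_twenty_duplicated_blocks(self):
        rng = np.random.default_rng(1)
        cols = []
        for _ in range(20):
            col = rng.choice([0.0, 2.0], size=40)
            while col.std() == 0:
                col = rng.choice([0.0, 2.0], size=40)
            cols.extend([col] * 10)
        d = np.column_stack(cols)
        # block_size=10 puts each identical group in its own block
        assert effective_marker_number(make_matrix(d), block_size=10) == pytest.approx(20.0)

    def test_duplicating_correlated_snps_leaves_n_unchanged(self):
        rng = np.random.default_rng(2)
        col = rng.choice([0.0, 2.0], size=30)
        other = rng.choice([0.0, 2.0], size=30)
        base = np.column_stack([col] * 3 + [other])
        doubled = np.column_stack([col] * 6 + [other])
        n1 = effective_marker_number(make_matrix(base), block_size=200)
        n2 = effective_marker_number(make_matrix(doubled), block_size=200)
        assert n2 == pytest.approx(n1, abs=1e-9)

    def test_constant_column_excluded(self):
        d = np.column_stack(
            [np.zeros(20), np.tile([0.0, 2.0], 10), np.tile([0.0, 0.0, 2.0, 2.0], 5)]
        )
        with pytest.warns(RuntimeWarning):
            n = effective_marker_number(make_matrix(d))
        assert 1.0 <= n <= 2.0 + 1e-9


class TestThresholds:
    def test_formula(self):
        t = significance_thresholds(1_000_000)
        assert t.suggestive == pytest.approx(1e-6)
        assert t.significant == pytest.approx(5e-8)

    def test_ratio_exact(self):
        for n_eff in (1.5, 42.0, 12345.6):
            t = significance_thresholds(n_eff)
            assert t.significant == pytest.approx(0.05 * t.suggestive, rel=1e-15)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            significance_thresholds(0.5)


class TestLdR2:
    def test_identical_columns(self):
        x = np.array([0.0, 2.0, 2.0, 0.0, 2.0])
        assert ld_r2(x, x) == pytest.approx(1.0)

    def test_hand_counted_fixture(self):
        # haplotypes AB=4, Ab=1, aB=1, ab=4 -> D=0.15, r2=0.36
        x = np.array([2.0] * 5 + [0.0] * 5)
        z = np.array([2.0] * 4 + [0.0] + [2.0] + [0.0] * 4)
        assert ld_r2(x, z) == pytest.approx(0.36)

    def test_equals_squared_pearson_on_homozygous(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.choice([0.0, 2.0], size=60)
            z = rng.choice([0.0, 2.0], size=60)
            if x.std() == 0 or z.std() == 0:
                continue
            r2 = ld_r2(x, z)
            pearson2 = np.corrcoef(x, z)[0, 1] ** 2
            assert r2 == pytest.approx(pearson2, abs=1e-12)

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError):
            ld_r2(np.array([2.0, 2.0, 2.0]), np.array([0.0, 2.0, 0.0]))

    def test_het_and_missing_excluded(self):
        x = np.array([2.0, 0.0, 1.0, 2.0, 0.0, np.nan])
        z = np.array([2.0, 0.0, 2.0, 2.0, 0.0, 2.0])
        assert ld_r2(x, z) == pytest.approx(1.0)


class TestClumping:
    def _scan_fixture(self, seed=0):
        pop = simulate_genotypes(n=120, m=50, ld_rho=0.85, seed=seed, pos_step=20000)
        rng = np.random.default_rng(seed + 1)
        p = rng.uniform(0, 1, size=50)
        p[rng.choice(50, size=12, replace=False)] = rng.uniform(0, 1e-4, size=12)
        from phenokit.gwas import AssociationResult

        res = AssociationResult(
            chrom=pop.matrix.chrom,
            pos=pop.matrix.pos,
            snp_ids=list(pop.matrix.snp_ids),
            beta=np.zeros(50),
            lr_stat=np.zeros(50),
            p_value=p,
            sigma_g2=1.0,
            sigma_e2=1.0,
            delta=1.0,
            null_loglik=0.0,
        )
        return pop.matrix, res

    def test_single_passing_snp(self):
        G, res = self._scan_fixture(seed=2)
        res.p_value[:] = 1.0
        res.p_value[7] = 1e-9
        loci = clump_loci(res, G, p_threshold=1e-6)
        assert len(loci) == 1
        assert loci[0].member_indices == [7]

    def test_nothing_passes(self):
        G, res = self._scan_fixture(seed=3)
        res.p_value[:] = 0.5
        assert clump_loci(res, G, p_threshold=1e-6) == []

    def test_matches_greedy_oracle(self):
        for seed in range(5):
            G, res = self._scan_fixture(seed=seed)
            loci = clump_loci(res, G, p_threshold=1e-3, r2_threshold=0.25, window_kb=250)
            oracle = greedy_clump_oracle(
                res.p_value, G.chrom, G.pos, G.dosages, 1e-3, 0.25, 250_000
            )
            assert [(l.lead_index, l.member_indices) for l in loci] == oracle

    def test_lead_has_min_p(self):
        G, res = self._scan_fixture(seed=7)
        for locus in clump_loci(res, G, p_threshold=1e-3):
            member_p = res.p_value[locus.member_indices]
            assert locus.lead_p <= member_p.min() + 1e-18


class TestPeakFilter:
    def test_supported_locus_kept_singleton_dropped(self):
        pop = simulate_genotypes(n=200, m=300, ld_rho=0.9, seed=20, pos_step=1000)
        y, info = simulate_phenotype(pop, causal_idx=[150], h2_causal=0.3, seed=21)
        K = kinship_identity_proportion(pop.matrix, seed=0)
        res = lmm_scan(pop.matrix, y, K)
        loci = clump_loci(res, pop.matrix, p_threshold=1e-6)
        assert loci, "expected a detected locus at h2=0.3"
        kept = peak_filter(loci, res, pop.matrix, p_threshold=1e-6, min_support=2)
        assert any(abs(l.lead_pos - pop.matrix.pos[150]) <= 250_000 for l in kept)
        # a synthetic singleton far from support is dropped
        res.p_value[:] = 1.0
        res.p_value[5] = 1e-9
        loci2 = clump_loci(res, pop.matrix, p_threshold=1e-6)
        assert peak_filter(loci2, res, pop.matrix, p_threshold=1e-6, min_support=2) == []


class TestCalibrationSmall:
    def test_lmm_corrects_structure(self):
        pop = simulate_genotypes(n=300, m=2000, ld_rho=0.5, n_subpops=2, fst=0.1, seed=31)
        y, _ = simulate_phenotype(pop, h2_polygenic=0.4, h2_structure=0.1, seed=32)
        K = kinship_identity_proportion(pop.matrix, seed=0)
        res = lmm_scan(pop.matrix, y, K)
        naive = ols_scan(pop.matrix, y)
        assert 0.85 <= genomic_inflation(res.p_value) <= 1.15
        assert genomic_inflation(naive.p_value) > 1.2
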