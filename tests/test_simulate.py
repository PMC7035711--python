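import numpy as np
import pytest

from caprigen.io import MISSING
from caprigen.simulate import (
    QTL,
    SimConfig,
    design_array,
    gene_drop,
    markov_mosaic_states,
    sequence_calls,
    simulate_founders,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_study,
)


class TestFounderMosaic:
    def test_zero_switch_rate_copies_one_ancestor(self):
        cfg = SimConfig(n_founders_per_breed=10, n_variants=500, n_chromosomes=1,
                        array_size=50, mosaic_switch_rate=0.0, rare_fraction=0.0, seed=0)
        haps, _ = simulate_founders(cfg)
        for breed, h in haps.items():
            # with no switching each haplotype is one ancestral haplotype
            distinct = np.unique(h, axis=0)
            assert len(distinct) <= cfg.ancestral_pool_size

    def test_markov_state_autocorrelation_closed_form(self):
        # P(state unchanged per step) = 1 - switch_rate; at rate 0.5 with a
        # pool of 2 the state sequence is uncorrelated
        rng = np.random.default_rng(0)
        chrom_start = np.zeros(10_000, dtype=bool)
        chrom_start[0] = True
        for rate, pool in ((0.5, 2), (0.1, 4), (0.02, 8)):
            states = markov_mosaic_states(rng, 8, pool, rate, chrom_start)
            stay = (states[:, 1:] == states[:, :-1]).mean()
            assert stay == pytest.approx(1.0 - rate, abs=0.02)
        # the pool-2 rate-0.5 case: +/-1-coded state autocorrelation ~ 0
        states = markov_mosaic_states(rng, 8, 2, 0.5, chrom_start)
        x = 2.0 * states - 1.0
        r = np.mean([np.corrcoef(row[:-1], row[1:])[0, 1] for row in x])
        assert abs(r) < 0.03

    def test_two_breeds_separable_on_pc1(self):
        from caprigen.assoc import pca
        from caprigen.io import GenotypeMatrix
        cfg = SimConfig(n_founders_per_breed=30, n_variants=500, n_chromosomes=1,
                        array_size=50, pool_overlap=0.0, rare_fraction=0.0, seed=2)
        haps, vt = simulate_founders(cfg)
        dose = np.vstack([(haps[b][0::2] + haps[b][1::2]) for b in cfg.breeds]).astype(np.int8)
        ids = [f"x{i}" for i in range(dose.shape[0])]
        gm = GenotypeMatrix(ids, vt, dose)
        coords, _ = pca(gm, k=2)
        labels = np.repeat([0, 1], cfg.n_founders_per_breed)
        # silhouette on the first two PCs
        from scipy.spatial.distance import cdist
        d = cdist(coords, coords)
        sil = []
        for i in range(len(labels)):
            own = d[i][(labels == labels[i])]
            other = d[i][labels != labels[i]]
            a = own[own > 0].mean()
            b = other.mean()
            sil.append((b - a) / max(a, b))
        assert np.mean(sil) > 0.5

    def test_degenerate_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            SimConfig(ancestral_pool_size=1)


@pytest.fixture(scope="module")
def dropped():
    cfg = SimConfig(n_founders_per_breed=12, n_generations=2, offspring_per_mating=2,
                    n_variants=2000, n_chromosomes=2, array_size=200, seed=4)
    rng = np.random.default_rng(cfg.seed)
    haps, vt = simulate_founders(cfg, rng)
    ped = simulate_pedigree(cfg, rng)
    pop = gene_drop(haps, ped, vt, cfg.recomb_rate, rng)
    return cfg, pop


class TestGeneDrop:

    def test_mendelian_consistency_exhaustive(self, dropped):
        _, pop = dropped
        idx = {s: i for i, s in enumerate(pop.sample_ids)}
        for iid in pop.sample_ids:
            sire, dam = pop.pedigree.parents(iid)
            if sire is None:
                continue
            i = idx[iid]
            for hap_row, parent in ((2 * i, sire), (2 * i + 1, dam)):
                p = idx[parent]
                gamete = pop.haplotypes[hap_row]
                ok = (gamete == pop.haplotypes[2 * p]) | (gamete == pop.haplotypes[2 * p + 1])
                assert ok.all()

    def test_forced_heterozygote(self, dropped):
        _, pop = dropped
        idx = {s: i for i, s in enumerate(pop.sample_ids)}
        dose = pop.dosage
        checked = 0
        for iid in pop.sample_ids:
            sire, dam = pop.pedigree.parents(iid)
            if sire is None:
                continue
            i, s, d = idx[iid], idx[sire], idx[dam]
            forced = ((dose[s] == 0) & (dose[d] == 2)) | ((dose[s] == 2) & (dose[d] == 0))
            assert (dose[i][forced] == 1).all()
            checked += int(forced.sum())
        assert checked > 0

    def test_zero_recombination_transmits_whole_haplotypes(self):
        cfg = SimConfig(n_founders_per_breed=6, n_generations=1, offspring_per_mating=2,
                        n_variants=500, n_chromosomes=2, array_size=50,
                        recomb_rate=0.0, seed=5)
        rng = np.random.default_rng(cfg.seed)
        haps, vt = simulate_founders(cfg, rng)
        ped = simulate_pedigree(cfg, rng)
        pop = gene_drop(haps, ped, vt, 0.0, rng)
        idx = {s: i for i, s in enumerate(pop.sample_ids)}
        chrom = vt.chrom
        for iid in pop.sample_ids:
            sire, dam = pop.pedigree.parents(iid)
            if sire is None:
                continue
            i = idx[iid]
            for hap_row, parent in ((2 * i, sire), (2 * i + 1, dam)):
                p = idx[parent]
                for c in np.unique(chrom):
                    m = chrom == c
                    g = pop.haplotypes[hap_row][m]
                    assert (np.array_equal(g, pop.haplotypes[2 * p][m])
                            or np.array_equal(g, pop.haplotypes[2 * p + 1][m]))

    def test_full_sib_relationship_matches_pedigree_expectation(self):
        # additive relationship between full sibs is 0.5 (kinship 0.25)
        from caprigen.assoc import compute_grm
        cfg = SimConfig(n_founders_per_breed=40, n_generations=1, offspring_per_mating=2,
                        n_variants=10_000, n_chromosomes=3, seed=6)
        study = simulate_study(cfg)
        pop = study.truth
        grm = compute_grm(pop.genotype_matrix(), maf_min=0.01)
        idx = {s: i for i, s in enumerate(grm.sample_ids)}
        vals = []
        seen = {}
        for iid in pop.sample_ids:
            par = pop.pedigree.parents(iid)
            if par[0] is None:
                continue
            if par in seen:
                vals.append(grm.matrix[idx[seen[par]], idx[iid]])
            else:
                seen[par] = iid
        kinship = np.mean(vals) / 2.0
        assert kinship == pytest.approx(0.25, abs=0.03)


class TestDesignArray:
    def test_all_rare_is_an_error(self):
        dosage = np.zeros((10, 50), dtype=np.int8)
        dosage[0, :] = 1  # MAF = 0.05 ... below a 0.2 floor
        from conftest import make_variants
        vt = make_variants(50)
        with pytest.raises(ValueError, match="MAF"):
            design_array(vt, dosage, 10, maf_min=0.2)

    def test_exact_fit_takes_all_eligible(self):
        rng = np.random.default_rng(0)
        from conftest import make_variants
        vt = make_variants(40)
        dosage = rng.integers(0, 3, (30, 40)).astype(np.int8)
        p = dosage.mean(0) / 2
        eligible = int((np.minimum(p, 1 - p) >= 0.1).sum())
        idx = design_array(vt, dosage, eligible, maf_min=0.1)
        assert len(idx) == eligible

    def test_even_spacing_on_uniform_toy(self):
        # 100 equally spaced, equally informative markers: chosen markers
        # should have no gap larger than twice the mean gap
        from conftest import make_variants
        vt = make_variants(100, step=1000)
        rng = np.random.default_rng(1)
        hap = rng.integers(0, 2, (60, 100))
        dosage = (hap[0::2] + hap[1::2]).astype(np.int8)
        idx = design_array(vt, dosage, 25, maf_min=0.01)
        gaps = np.diff(vt.pos[idx])
        assert gaps.max() <= 2 * gaps.mean()


class TestSequenceCalls:
    def test_high_depth_zero_error_recovers_truth(self):
        from conftest import make_variants
        cfg = SimConfig(mean_depth=1000.0, read_error=0.0, depth_shape=1e6)
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 3, (5, 200)).astype(np.int8)
        gm = sequence_calls(truth, make_variants(200), [f"s{i}" for i in range(5)], cfg, rng)
        assert np.array_equal(gm.dosage, truth)
        assert (gm.gq > 50).all()

    def test_zero_coverage_is_all_missing(self):
        from conftest import make_variants
        cfg = SimConfig(mean_depth=1e-9)
        rng = np.random.default_rng(0)
        truth = np.ones((3, 50), dtype=np.int8)
        gm = sequence_calls(truth, make_variants(50), ["a", "b", "c"], cfg, rng)
        assert (gm.dosage == MISSING).all()
        assert (gm.dp == 0).all()

    def test_het_miscall_rate_at_depth4_matches_binomial(self):
        # at DP=4 and negligible read error a heterozygote is miscalled
        # exactly when all 4 reads agree: 2 * 0.5^4 = 0.125
        from conftest import make_variants
        cfg = SimConfig(mean_depth=4.0, read_error=1e-9, depth_shape=1e9)
        rng = np.random.default_rng(7)
        truth = np.ones((40, 2000), dtype=np.int8)
        gm = sequence_calls(truth, make_variants(2000), [f"s{i}" for i in range(40)], cfg, rng)
        at4 = gm.dp == 4
        miscall = (gm.dosage != 1) & at4
        rate = miscall.sum() / at4.sum()
        assert rate == pytest.approx(0.125, abs=0.01)


class TestPhenotypes:
    def _study(self, **kw):
        cfg = SimConfig(n_founders_per_breed=60, n_generations=1, offspring_per_mating=2,
                        n_variants=2000, n_chromosomes=1, array_size=100,
                        seq_panel_size_per_breed=10, seed=8, **kw)
        return cfg, simulate_study(cfg)

    def test_heritability_one_limit_gives_phenotype_equal_bv(self):
        cfg, study = self._study(h2={"t": 0.999}, yd_records=10_000_000)
        y = study.truth.phenotypes.vector("t", study.truth.sample_ids)
        bv = study.truth.breeding_values["t"]
        assert np.corrcoef(y, bv)[0, 1] > 0.999

    def test_qtl_effect_recovered_by_ols(self):
        qtl = QTL(chrom="1", pos=25_000_000, traits=("t",), effects=(0.5,))
        cfg, study = self._study(h2={"t": 0.4}, qtl_spec=(qtl,))
        j, eff = study.truth.qtl_indices["t"][0]
        x = study.truth.dosage[:, j].astype(float)
        y = study.truth.phenotypes.vector("t", study.truth.sample_ids)
        xc = x - x.mean()
        beta = xc @ (y - y.mean()) / (xc @ xc)
        se = np.sqrt(np.var(y) / (len(y) * np.var(x)))
        assert abs(beta - 0.5) < 2 * se

    def test_zero_effect_qtl_is_null(self):
        qtl = QTL(chrom="1", pos=25_000_000, traits=("t",), effects=(0.0,))
        cfg, study = self._study(h2={"t": 0.3}, qtl_spec=(qtl,))
        j, _ = study.truth.qtl_indices["t"][0]
        x = study.truth.dosage[:, j].astype(float)
        y = study.truth.phenotypes.vector("t", study.truth.sample_ids)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(r) < 0.2

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError, match="h2"):
            SimConfig(h2={"t": 1.5})


class TestStudyInvariants:
    def test_site_frequency_spectrum_low_maf_heavy(self, small_study):
        maf = small_study.truth.genotype_matrix().maf()
        seg = maf > 0
        assert ((maf < 0.05) & seg).sum() / seg.sum() >= 0.30

    def test_array_respects_maf_floor(self, small_study):
        assert small_study.array.maf().min() >= small_study.config.array_maf_min

    def test_same_seed_bit_identical(self):
        cfg = dict(n_founders_per_breed=8, n_generations=1, offspring_per_mating=2,
                   n_variants=300, n_chromosomes=1, array_size=50,
                   seq_panel_size_per_breed=6, seed=11)
        a = simulate_study(SimConfig(**cfg))
        b = simulate_study(SimConfig(**cfg))
        assert np.array_equal(a.truth.haplotypes, b.truth.haplotypes)
        assert np.array_equal(a.seq_panel.dosage, b.seq_panel.dosage)
        assert np.array_equal(a.seq_panel.gq, b.seq_panel.gq)
        assert np.array_equal(a.array_indices, b.array_indices)
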