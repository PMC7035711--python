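import itertools

import numpy as np
import pytest

from caprigen.impute import (
    HaplotypeImputer,
    ReferencePanelSpec,
    build_panel,
    impute_to_sequence,
    mendelian_fill,
    phase_panel,
)
from caprigen.io import MISSING, GenotypeMatrix, Pedigree, PedigreeEntry
from caprigen.qc import FilterThresholds, filter_calls, override_with_chip

from conftest import make_gm, make_variants


def trio_pedigree():
    return Pedigree({
        "sire": PedigreeEntry(None, None), "dam": PedigreeEntry(None, None),
        "kid": PedigreeEntry("sire", "dam"),
    })


class TestMendelianFill:
    def test_forced_child_from_opposite_homozygous_parents(self):
        gm = make_gm([[0], [2], [MISSING]], ids=["sire", "dam", "kid"],
                     variants=make_variants(1))
        out = mendelian_fill(gm, trio_pedigree())
        assert out.dosage[2, 0] == 1

    def test_unforced_child_stays_missing(self):
        gm = make_gm([[1], [0], [MISSING]], ids=["sire", "dam", "kid"],
                     variants=make_variants(1))
        out = mendelian_fill(gm, trio_pedigree())
        assert out.dosage[2, 0] == MISSING

    def test_parent_forced_by_two_offspring(self):
        # a parent with one dosage-0 child and one dosage-2 child must be het
        ped = Pedigree({
            "p": PedigreeEntry(None, None), "m1": PedigreeEntry(None, None),
            "m2": PedigreeEntry(None, None),
            "k1": PedigreeEntry("p", "m1"), "k2": PedigreeEntry("p", "m2"),
        })
        gm = make_gm([[MISSING], [0], [2], [0], [2]],
                     ids=["p", "m1", "m2", "k1", "k2"], variants=make_variants(1))
        out = mendelian_fill(gm, ped)
        assert out.dosage[0, 0] == 1

    def test_never_overwrites_observed_calls(self, family_pedigree):
        rng = np.random.default_rng(0)
        ids = family_pedigree.topo_order
        dosage = rng.integers(0, 3, (len(ids), 20)).astype(np.int8)
        gm = make_gm(dosage.copy(), ids=ids, variants=make_variants(20))
        out = mendelian_fill(gm, family_pedigree)
        assert np.array_equal(out.dosage, dosage)  # nothing missing, nothing moved

    def test_matches_bruteforce_constraint_propagation(self, family_pedigree):
        """Fixpoint equals exhaustive enumeration of Mendelian completions."""
        ped = family_pedigree
        ids = ped.topo_order
        idx = {i: j for j, i in enumerate(ids)}
        trios = [(idx[i], idx[ped.parents(i)[0]], idx[ped.parents(i)[1]])
                 for i in ids if ped.parents(i)[0]]
        half = {0: (0,), 1: (0, 1), 2: (1,)}

        def consistent(assign):
            return all(
                any(a + b == assign[c] for a in half[assign[s]] for b in half[assign[d]])
                for c, s, d in trios)

        rng = np.random.default_rng(12)
        for _ in range(15):
            geno = {}
            for i in ids:
                s, d = ped.parents(i)
                if s is None:
                    geno[i] = rng.integers(0, 2) + rng.integers(0, 2)
                else:
                    geno[i] = rng.choice(half[geno[s]]) + rng.choice(half[geno[d]])
            truth = np.array([geno[i] for i in ids], dtype=np.int8)
            obs = truth.copy()
            miss_idx = rng.choice(len(ids), size=5, replace=False)
            obs[miss_idx] = MISSING

            survivors = [c for c in itertools.product([0, 1, 2], repeat=5)
                         if consistent(np.where(
                             np.isin(np.arange(len(ids)), miss_idx),
                             np.array([dict(zip(miss_idx, c)).get(j, 0)
                                       for j in range(len(ids))]),
                             obs))]
            oracle = obs.copy()
            cons = np.array(survivors)
            for jj, mi in enumerate(miss_idx):
                vals = np.unique(cons[:, jj])
                if len(vals) == 1:
                    oracle[mi] = vals[0]

            gm = make_gm(obs.reshape(-1, 1), ids=ids, variants=make_variants(1))
            filled = mendelian_fill(gm, ped).dosage[:, 0]
            assert np.array_equal(filled, oracle)


class TestPhasing:
    def test_trio_resolves_child_phase(self):
        gm = make_gm([[0], [2], [1]], ids=["sire", "dam", "kid"],
                     variants=make_variants(1))
        h = phase_panel(gm, trio_pedigree())
        kid = 2
        assert h[2 * kid, 0] == 0 and h[2 * kid + 1, 0] == 1  # paternal ref

    def test_uninformative_het_gets_lexicographic_tiebreak(self):
        gm = make_gm([[1]], variants=make_variants(1))
        h = phase_panel(gm, None)
        assert h[0, 0] == 0 and h[1, 0] == 1

    def test_phase_accuracy_above_090_at_default_config(self, default_study_phasing):
        acc, n_pairs = default_study_phasing
        assert n_pairs > 10_000
        assert acc > 0.9


@pytest.fixture(scope="session")
def default_study_phasing():
    """Phase the default-scale study panel and score het pairs within 1 Mb."""
    from caprigen.simulate import SimConfig, simulate_study
    study = simulate_study(SimConfig(seed=1))
    filt, _ = filter_calls(study.seq_panel, FilterThresholds(min_qual=30))
    merged = override_with_chip(filt, study.array.subset_samples(study.seq_panel_ids))
    g = mendelian_fill(merged, study.truth.pedigree)
    h = phase_panel(g, study.truth.pedigree)
    truth = study.truth
    vmask = truth.variants.key().get_indexer(g.variants.key())
    chrom = g.variants.chrom
    pos = g.variants.pos
    correct = total = 0
    for i, sid in enumerate(study.seq_panel_ids):
        ti = truth.sample_ids.index(sid)
        t0 = truth.haplotypes[2 * ti][vmask]
        t1 = truth.haplotypes[2 * ti + 1][vmask]
        het = (g.dosage[i] == 1) & (t0 + t1 == 1)
        for c in np.unique(chrom):
            p = np.flatnonzero(het & (chrom == c))
            if len(p) < 2:
                continue
            close = np.diff(pos[p]) <= 1_000_000
            agree = h[2 * i, p] == t0[p]
            pairs = (agree[:-1] == agree[1:])[close]
            correct += pairs.sum()
            total += len(pairs)
    return correct / total, total


class TestImputeToSequence:
    def _panel(self, n=10, v=400, seed=0):
        rng = np.random.default_rng(seed)
        vt = make_variants(v, step=1000)
        haps = rng.integers(0, 2, (4, v)).astype(np.int8)  # 4 ancestral patterns
        rows = haps[rng.integers(0, 4, 2 * n)]
        dosage = (rows[0::2] + rows[1::2]).astype(np.int8)
        ids = [f"p{i}" for i in range(n)]
        return GenotypeMatrix(ids, vt, dosage), rows

    def test_perfect_match_copies_panel_individual(self):
        panel, rows = self._panel()
        marker_idx = np.arange(0, 400, 10)
        imp = HaplotypeImputer((40, 10), use_pedigree=False)
        imp.fit(panel, haplotypes=rows)
        target_full = panel.subset_samples(["p3"])
        dosage = np.full_like(target_full.dosage, MISSING)
        dosage[:, marker_idx] = target_full.dosage[:, marker_idx]
        masked = GenotypeMatrix(["t"], panel.variants, dosage).subset_variants(marker_idx)
        out = imp.transform(masked)
        assert (out.dosage != MISSING).all()
        assert np.array_equal(out.dosage[0], target_full.dosage[0])

    def test_all_missing_target_gets_major_allele_fill(self):
        panel, rows = self._panel()
        imp = HaplotypeImputer((40, 10), use_pedigree=False)
        imp.fit(panel, haplotypes=rows)
        marker_idx = np.arange(0, 400, 10)
        masked = GenotypeMatrix(
            ["t"], panel.variants,
            np.full((1, 400), MISSING, dtype=np.int8)).subset_variants(marker_idx)
        out = imp.transform(masked)
        expected = 2 * imp.major_allele_
        assert np.array_equal(out.dosage[0], expected)

    def test_deterministic(self):
        panel, rows = self._panel(seed=5)
        marker_idx = np.arange(0, 400, 7)
        imp = HaplotypeImputer((40, 10), use_pedigree=False)
        imp.fit(panel)
        rng = np.random.default_rng(1)
        dosage = np.full((2, 400), MISSING, dtype=np.int8)
        dosage[:, marker_idx] = rng.integers(0, 3, (2, len(marker_idx)))
        masked = GenotypeMatrix(["a", "b"], panel.variants, dosage).subset_variants(marker_idx)
        out1 = imp.transform(masked)
        out2 = imp.transform(masked)
        assert np.array_equal(out1.dosage, out2.dosage)

    def test_output_complete_and_chip_calls_authoritative(self, small_study):
        study = small_study
        filt, _ = filter_calls(study.seq_panel, FilterThresholds(min_qual=30))
        merged = override_with_chip(filt, study.array.subset_samples(study.seq_panel_ids))
        targets = study.array.subset_samples(
            [s for s in study.truth.sample_ids if s not in study.seq_panel_ids][:5])
        out = impute_to_sequence(targets, merged,
                                 ReferencePanelSpec(name="all", use_pedigree=True),
                                 study.truth.pedigree, study.breed_map,
                                 window_schedule=(200, 50, 20))
        assert (out.dosage != MISSING).all()
        shared = out.variants.key().get_indexer(targets.variants.key())
        ok = shared >= 0
        assert np.array_equal(out.dosage[:, shared[ok]], targets.dosage[:, ok])


class TestBuildPanel:
    def test_breed_selection(self, small_study):
        spec = ReferencePanelSpec(name="within", breeds=("Saanen",))
        panel = build_panel(small_study.seq_panel, spec, small_study.breed_map)
        assert all(small_study.breed_map[s] == "Saanen" for s in panel.sample_ids)

    def test_custom_ids_order_preserved(self, small_study):
        ids = tuple(small_study.seq_panel_ids[5:1:-1])
        spec = ReferencePanelSpec(name="custom", ids=ids)
        panel = build_panel(small_study.seq_panel, spec)
        assert panel.sample_ids == list(ids)

    def test_empty_selection_is_error(self, small_study):
        spec = ReferencePanelSpec(name="x", breeds=("Boer",))
        with pytest.raises(ValueError, match="selects no samples"):
            build_panel(small_study.seq_panel, spec, small_study.breed_map)

    def test_pca_gate_drops_planted_outlier(self):
        rng = np.random.default_rng(0)
        vt = make_variants(300)
        base = rng.integers(0, 2, 300)
        dosage = np.tile(base, (12, 1)).astype(np.int8)
        dosage[:, :150] += rng.integers(0, 2, (12, 150)).astype(np.int8)
        dosage = np.clip(dosage, 0, 2)
        dosage[11] = 2 - dosage[11]  # planted outlier: mirrored genotypes
        ids = [f"s{i}" for i in range(12)]
        gm = GenotypeMatrix(ids, vt, dosage)
        breed_map = {i: "A" for i in ids}
        spec = ReferencePanelSpec(name="gated", breeds=("A",), pca_gate=True,
                                  pca_threshold=3.0)
        panel = build_panel(gm, spec, breed_map)
        assert "s11" not in panel.sample_ids
        assert len(panel.sample_ids) >= 10
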