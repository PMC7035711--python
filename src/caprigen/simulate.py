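"""Synthetic pedigreed two-breed populations for end-to-end pipeline runs.

The generator emulates the design of a dairy-goat sequencing study: two
related breeds sharing ancestry, a sequence variant set whose site-frequency
spectrum is heavy in low-MAF variants, a medium-density array subset
(MAF >= 1%, evenly spaced), noisy sequence calls with per-call depth and
genotype quality at ~12X mean coverage, and pre-adjusted phenotypes (yield
deviations, daughter yield deviations) under pleiotropic or closely linked
QTL architectures.

Founder haplotypes are Markov mosaics over a small pool of ancestral
haplotypes: at each step along the chromosome a haplotype switches to a
random pool member with a small probability, which yields linkage
disequilibrium decaying with distance at a tunable rate without a coalescent
simulation.  The two breeds draw from overlapping but distinct ancestral
pools, so principal components separate them.  Descendants receive exactly
Mendelian recombined gametes (gene drop), so every truth set is internally
consistent.

All randomness flows from the single ``seed`` in :class:`SimConfig`:
identical configuration gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    GenotypeMatrix,
    Pedigree,
    PedigreeEntry,
    PhenotypeTable,
    VariantTable,
    logger,
)

__all__ = [
    "QTL",
    "SimConfig",
    "TruePopulation",
    "SimStudy",
    "simulate_founders",
    "simulate_pedigree",
    "gene_drop",
    "design_array",
    "sequence_calls",
    "simulate_phenotypes",
    "simulate_study",
]


@dataclass(frozen=True)
class QTL:
    """A causal variant: placed at the variant nearest (chrom, pos).

    ``traits``/``effects`` are parallel; a pleiotropic QTL lists two traits
    on one position, a linked architecture uses two QTL at distance d each
    listing one trait.  Effects are allele-substitution effects in trait
    standard deviations.
    """

    chrom: str
    pos: int
    traits: tuple[str, ...]
    effects: tuple[float, ...]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic population.

    Defaults are the scale every stage of the pipeline runs at in minutes on
    one core: 2 breeds x ~330 individuals, 3 chromosomes x 20k variants,
    a 1,000-marker array, 40 sequenced reference animals per breed at 12X.
    """

    n_founders_per_breed: int = 60
    n_generations: int = 3
    offspring_per_mating: int = 3
    n_variants: int = 20_000
    n_chromosomes: int = 3
    chrom_length_bp: int = 50_000_000
    recomb_rate: float = 1e-8          # per bp per meiosis (~1 cM/Mb)
    mosaic_switch_rate: float = 0.02   # ancestral-switch prob per adjacent variant
    ancestral_pool_size: int = 8       # per breed
    pool_overlap: float = 0.25         # fraction of pool shared between breeds
    freq_beta_a: float = 0.2           # allele-frequency prior Beta(a, b):
    freq_beta_b: float = 2.0           #   concentrated near 0 (low-MAF heavy)
    rare_fraction: float = 0.35        # variants carried by few founder haplotypes
    rare_carrier_mean: float = 1.5     # carriers = 1 + Poisson(mean)
    array_size: int = 1_000
    array_maf_min: float = 0.01
    seq_panel_size_per_breed: int = 40
    mean_depth: float = 12.0           # X; per-individual coverage ~ Gamma
    depth_shape: float = 8.0           # Gamma shape of individual coverage
    read_error: float = 1e-3           # per-read allele error
    qtl_spec: tuple[QTL, ...] = ()
    h2: dict = field(default_factory=lambda: {"trait1": 0.3})
    yd_records: int = 20               # repeated performances averaged into a YD
    dyd_accuracy: float = 50.0         # effective daughter count for DYDs
    pheno_kind: str = "YD"             # "YD" or "DYD"
    breeds: tuple[str, str] = ("Alpine", "Saanen")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders_per_breed", "n_generations", "offspring_per_mating",
                     "n_variants", "n_chromosomes", "chrom_length_bp", "array_size",
                     "seq_panel_size_per_breed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for trait, h in self.h2.items():
            if not 0 < h < 1:
                raise ValueError(f"h2[{trait!r}] must be in (0, 1)")
        if self.array_size > self.n_variants:
            raise ValueError("array_size cannot exceed n_variants")
        if self.ancestral_pool_size < 2:
            raise ValueError("ancestral pool needs at least 2 haplotypes")


@dataclass
class TruePopulation:
    """Ground truth: phased haplotypes, pedigree, breeding values, phenotypes."""

    sample_ids: list[str]
    haplotypes: np.ndarray            # (2*n, n_variants) uint8, rows 2i/2i+1
    variants: VariantTable
    pedigree: Pedigree
    breeding_values: dict[str, np.ndarray] = field(default_factory=dict)
    phenotypes: PhenotypeTable | None = None
    qtl_indices: dict[str, list[tuple[int, float]]] = field(default_factory=dict)

    @property
    def dosage(self) -> np.ndarray:
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(self.sample_ids, self.variants, self.dosage)


def _variant_positions(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_variants // cfg.n_chromosomes)
    per_chrom[: cfg.n_variants % cfg.n_chromosomes] += 1
    rows = []
    bases = np.array(["A", "C", "G", "T"])
    for c in range(cfg.n_chromosomes):
        pos = np.unique(rng.integers(1, cfg.chrom_length_bp, 2 * per_chrom[c]))
        while len(pos) < per_chrom[c]:  # top up after duplicate removal
            pos = np.unique(np.concatenate([pos, rng.integers(1, cfg.chrom_length_bp,
                                                              per_chrom[c])]))
        pos = np.sort(rng.choice(pos, per_chrom[c], replace=False))
        ref = bases[rng.integers(0, 4, per_chrom[c])]
        shift = rng.integers(1, 4, per_chrom[c])
        alt = bases[(np.searchsorted(bases, ref) + shift) % 4]
        rows.append(pd.DataFrame({
            "chrom": str(c + 1), "pos": pos, "ref": ref, "alt": alt,
            "qual": np.round(rng.gamma(4.0, 200.0, per_chrom[c]), 1),
        }))
    return pd.concat(rows, ignore_index=True)


def markov_mosaic_states(rng: np.random.Generator, n_haps: int, pool_size: int,
                         switch_rate: float, chrom_start: np.ndarray) -> np.ndarray:
    """Ancestral-pool member index per haplotype and position.

    At each adjacent-variant step the template switches, with probability
    ``switch_rate``, to a uniformly drawn *different* pool member; the state
    is redrawn at every chromosome start.  P(state unchanged) per step is
    therefore 1 - switch_rate.
    """
    if pool_size < 2:
        raise ValueError("ancestral pool needs at least 2 haplotypes")
    V = len(chrom_start)
    switch = rng.random((n_haps, V)) < switch_rate
    switch[:, chrom_start] = True
    seg = np.cumsum(switch, axis=1)  # segment id per position, >= 1
    n_seg = int(seg.max()) + 1
    # cumulative offsets in 1..K-1 walk the state to a different member per switch
    offsets = rng.integers(1, pool_size, size=(n_haps, n_seg))
    offsets[:, 0] = rng.integers(0, pool_size, n_haps)
    states = np.cumsum(offsets, axis=1) % pool_size
    return np.take_along_axis(states, seg, axis=1)


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Draw founder haplotypes for both breeds.

    Returns ``(founder_haps, variants)`` where ``founder_haps`` maps breed ->
    (2 * n_founders_per_breed, n_variants) phased allele matrix.

    Each founder haplotype is a Markov mosaic over the breed's ancestral
    pool (:func:`markov_mosaic_states`), so linkage disequilibrium decays
    with distance at a rate set by ``mosaic_switch_rate``.  Ancestral allele
    frequencies come from ``Beta(freq_beta_a, freq_beta_b)``; because a
    small pool quantises frequencies, a ``rare_fraction`` of variants is
    instead placed directly on a few random founder haplotypes (1 + Poisson
    carriers), reproducing the heavy low-MAF tail of sequence data.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    vt_df = _variant_positions(cfg, rng)
    variants = VariantTable(vt_df)
    V = len(variants)

    n_shared = int(round(cfg.pool_overlap * cfg.ancestral_pool_size))
    n_total = 2 * cfg.ancestral_pool_size - n_shared
    p = rng.beta(cfg.freq_beta_a, cfg.freq_beta_b, V)
    ancestors = (rng.random((n_total, V)) < p).astype(np.uint8)
    own = cfg.ancestral_pool_size - n_shared
    pools = {
        cfg.breeds[0]: np.arange(cfg.ancestral_pool_size),
        cfg.breeds[1]: np.concatenate([np.arange(n_shared),
                                       cfg.ancestral_pool_size + np.arange(own)]),
    }

    chrom_arr = variants.chrom
    chrom_start = np.zeros(V, dtype=bool)
    chrom_start[0] = True
    chrom_start[1:] = chrom_arr[1:] != chrom_arr[:-1]

    rare = rng.random(V) < cfg.rare_fraction
    ancestors[:, rare] = 0

    founder_haps: dict[str, np.ndarray] = {}
    for breed in cfg.breeds:
        pool = pools[breed]
        H = 2 * cfg.n_founders_per_breed
        states = markov_mosaic_states(rng, H, len(pool), cfg.mosaic_switch_rate,
                                      chrom_start)
        anc_idx = pool[states]
        founder_haps[breed] = ancestors[anc_idx, np.arange(V)[None, :]].astype(np.uint8)

    # rare layer: few carrier haplotypes drawn across both breeds
    H_tot = sum(h.shape[0] for h in founder_haps.values())
    stacked = np.vstack([founder_haps[b] for b in cfg.breeds])
    for j in np.flatnonzero(rare):
        k = 1 + rng.poisson(cfg.rare_carrier_mean)
        carriers = rng.choice(H_tot, size=min(k, H_tot), replace=False)
        stacked[carriers, j] = 1
    offset = 0
    for b in cfg.breeds:
        h = founder_haps[b]
        founder_haps[b] = stacked[offset:offset + h.shape[0]]
        offset += h.shape[0]
    return founder_haps, variants


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator) -> Pedigree:
    """Random discrete-generation pedigree per breed.

    Each generation mates randomly chosen males to females of the previous
    generation (a few sires serve many dams, as in dairy populations); every
    mating produces ``offspring_per_mating`` offspring of random sex.
    """
    entries: dict[str, PedigreeEntry] = {}
    for breed in cfg.breeds:
        tag = breed[0]
        prev: list[tuple[str, str]] = []
        for k in range(cfg.n_founders_per_breed):
            sex = "M" if k % 2 == 0 else "F"
            iid = f"{tag}_G0_{k:04d}"
            entries[iid] = PedigreeEntry(None, None, breed, sex)
            prev.append((iid, sex))
        for g in range(1, cfg.n_generations + 1):
            males = [i for i, s in prev if s == "M"]
            females = [i for i, s in prev if s == "F"]
            n_matings = max(1, len(prev) // 2)
            n_sires = max(1, len(males) // 4)  # few sires serve many dams
            sire_pool = rng.choice(males, size=n_sires, replace=False)
            sires = sire_pool[rng.integers(0, n_sires, n_matings)]
            dams = rng.choice(females, size=n_matings, replace=len(females) < n_matings)
            nxt: list[tuple[str, str]] = []
            k = 0
            for s, d in zip(sires, dams):
                for _ in range(cfg.offspring_per_mating):
                    iid = f"{tag}_G{g}_{k:04d}"
                    sex = "M" if rng.random() < 0.5 else "F"
                    entries[iid] = PedigreeEntry(str(s), str(d), breed, sex)
                    nxt.append((iid, sex))
                    k += 1
            prev = nxt
    return Pedigree(entries)


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, variants: VariantTable,
             recomb_rate: float, rng: np.random.Generator) -> np.ndarray:
    """One recombined gamete from a parent's two haplotypes.

    Crossover count per chromosome is Poisson(recomb_rate * length); crossover
    positions are uniform; the starting haplotype per chromosome is random.
    """
    gamete = np.empty_like(hap_a)
    chrom = variants.chrom
    pos = variants.pos
    for c in dict.fromkeys(chrom):
        m = chrom == c
        cpos = pos[m]
        length = int(cpos[-1]) if len(cpos) else 0
        n_x = rng.poisson(recomb_rate * length)
        cuts = np.sort(rng.integers(1, length + 1, size=n_x)) if n_x else np.empty(0)
        phase = (np.searchsorted(cuts, cpos, side="left") + rng.integers(0, 2)) % 2
        gamete[m] = np.where(phase == 0, hap_a[m], hap_b[m])
    return gamete


def gene_drop(
    founder_haps: dict[str, np.ndarray],
    pedigree: Pedigree,
    variants: VariantTable,
    recomb_rate: float,
    rng: np.random.Generator,
) -> TruePopulation:
    """Drop founder haplotypes through the pedigree with recombination.

    Founders take haplotypes from their breed's founder set in pedigree
    order; every non-founder receives one recombined gamete per parent, so
    transmission is exactly Mendelian.  An individual with exactly one known
    parent draws the unknown parent's gamete from the breed founder pool
    (logged).
    """
    V = len(variants)
    order = pedigree.topo_order
    index = {iid: i for i, iid in enumerate(order)}
    haps = np.zeros((2 * len(order), V), dtype=np.uint8)
    founder_cursor: dict[str, int] = {b: 0 for b in founder_haps}

    def founder_gamete(breed: str) -> np.ndarray:
        fh = founder_haps[breed]
        j = rng.integers(0, fh.shape[0] // 2)
        return _meiosis(fh[2 * j], fh[2 * j + 1], variants, recomb_rate, rng)

    n_half = 0
    for iid in order:
        i = index[iid]
        sire, dam = pedigree.parents(iid)
        breed = pedigree.breed_of(iid)
        if sire is None and dam is None:
            fh = founder_haps[breed]
            k = founder_cursor[breed]
            if 2 * k + 1 >= fh.shape[0]:
                raise ValueError(f"not enough founder haplotypes for breed {breed}")
            haps[2 * i] = fh[2 * k]
            haps[2 * i + 1] = fh[2 * k + 1]
            founder_cursor[breed] = k + 1
            continue
        gametes = []
        for parent in (sire, dam):
            if parent is None:
                gametes.append(founder_gamete(breed))
                n_half += 1
            else:
                p = index[parent]
                gametes.append(_meiosis(haps[2 * p], haps[2 * p + 1],
                                        variants, recomb_rate, rng))
        haps[2 * i] = gametes[0]
        haps[2 * i + 1] = gametes[1]
    if n_half:
        logger.info("gene_drop: %d gametes drawn from founder pool for unknown parents", n_half)
    return TruePopulation(order, haps, variants, pedigree)


def design_array(variants: VariantTable, dosage: np.ndarray, array_size: int,
                 maf_min: float = 0.01, rng: np.random.Generator | None = None) -> np.ndarray:
    """Choose an array marker subset: MAF >= maf_min, approximately even spacing.

    The genome is cut into ``array_size`` windows (allocated to chromosomes
    proportionally to their spans) and the highest-MAF eligible variant per
    window is picked; any shortfall from empty windows is filled with the
    highest-MAF unpicked eligible variants.  Returns sorted variant indices.
    """
    p = dosage.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    eligible = maf >= maf_min
    n_eligible = int(eligible.sum())
    if n_eligible < array_size:
        raise ValueError(
            f"only {n_eligible} variants with MAF >= {maf_min}, need {array_size}"
        )
    chroms = list(dict.fromkeys(variants.chrom))
    spans = {c: variants.pos[variants.chrom == c].max() for c in chroms}
    total = sum(spans.values())
    alloc = {c: max(1, int(round(array_size * spans[c] / total))) for c in chroms}
    chosen: list[int] = []
    for c in chroms:
        m = (variants.chrom == c) & eligible
        idx = np.flatnonzero(m)
        if len(idx) == 0:
            continue
        edges = np.linspace(0, spans[c] + 1, alloc[c] + 1)
        w = np.searchsorted(edges, variants.pos[idx], side="right") - 1
        for window in range(alloc[c]):
            cand = idx[w == window]
            if len(cand):
                chosen.append(int(cand[np.argmax(maf[cand])]))
    if len(chosen) > array_size:
        keep = np.argsort(-maf[np.array(chosen)])[:array_size]
        chosen = [chosen[i] for i in sorted(keep)]
    if len(chosen) < array_size:
        rest = np.setdiff1d(np.flatnonzero(eligible), np.array(chosen, dtype=int))
        extra = rest[np.argsort(-maf[rest])][: array_size - len(chosen)]
        chosen.extend(int(e) for e in extra)
    return np.sort(np.array(chosen, dtype=int))


def sequence_calls(true_dosage: np.ndarray, variants: VariantTable,
                   sample_ids: list[str], cfg: SimConfig,
                   rng: np.random.Generator) -> GenotypeMatrix:
    """Noisy sequencing genotype calls with per-call DP and GQ.

    Per-individual mean coverage is Gamma(depth_shape) around ``mean_depth``;
    per-call depth is Poisson at that coverage.  Alternate-read counts follow
    binomial sampling with per-read error ``read_error``; the call is the
    maximum-likelihood genotype among {hom-ref, het, hom-alt} and GQ is the
    phred-scaled gap between the best and second-best likelihoods (capped at
    99).  Calls at depth zero are missing.
    """
    n, V = true_dosage.shape
    e = max(cfg.read_error, 1e-12)  # zero-error limit stays well defined
    cov = rng.gamma(cfg.depth_shape, cfg.mean_depth / cfg.depth_shape, n)
    dp = rng.poisson(cov[:, None], size=(n, V)).astype(np.int32)
    p_alt = np.array([e, 0.5, 1.0 - e])[true_dosage]
    alt_reads = rng.binomial(dp, p_alt)

    with np.errstate(divide="ignore", invalid="ignore"):
        lls = np.stack([
            alt_reads * np.log(p) + (dp - alt_reads) * np.log1p(-p)
            for p in (e, 0.5, 1.0 - e)
        ])
    order = np.argsort(-lls, axis=0, kind="stable")
    best = order[0]
    ll_sorted = np.take_along_axis(lls, order, axis=0)
    gq = np.clip(np.round(10.0 / np.log(10.0) * (ll_sorted[0] - ll_sorted[1])), 0, 99)

    called = best.astype(np.int8)
    miss = dp == 0
    called[miss] = MISSING
    gq = gq.astype(np.int16)
    gq[miss] = 0
    return GenotypeMatrix(sample_ids, variants, called, gq, dp.astype(np.int16))


def simulate_phenotypes(pop: TruePopulation, cfg: SimConfig,
                        rng: np.random.Generator) -> PhenotypeTable:
    """YD/DYD phenotypes from QTL + pedigree-correlated polygenic effects.

    Raw single records have unit variance by construction: genetic variance
    (QTL + polygenic) equals h2 per trait and residual variance 1 - h2.  A YD
    is BV + residual / sqrt(yd_records); a DYD is BV/2 + residual /
    sqrt(dyd_accuracy).  The variance metadata needed by the pleiotropy test
    (raw-record variance sigma2_y, observed variance sigma2_X) is attached.
    """
    dosage = pop.dosage.astype(float)
    order = pop.sample_ids
    index = {iid: i for i, iid in enumerate(order)}
    p_freq = dosage.mean(axis=0) / 2.0

    traits = sorted(cfg.h2)
    qtl_by_trait: dict[str, list[tuple[int, float]]] = {t: [] for t in traits}
    for q in cfg.qtl_spec:
        m = pop.variants.chrom == str(q.chrom)
        if not m.any():
            raise ValueError(f"QTL chrom {q.chrom} absent from variant table")
        idx_c = np.flatnonzero(m)
        j = int(idx_c[np.argmin(np.abs(pop.variants.pos[idx_c] - q.pos))])
        for t, eff in zip(q.traits, q.effects):
            if t not in qtl_by_trait:
                raise ValueError(f"QTL trait {t!r} has no h2 entry")
            qtl_by_trait[t].append((j, float(eff)))
    pop.qtl_indices = qtl_by_trait

    rows = []
    var_raw: dict[str, float] = {}
    var_obs: dict[str, float] = {}
    for t in traits:
        h2 = cfg.h2[t]
        bv_qtl = np.zeros(len(order))
        var_qtl = 0.0
        for j, eff in qtl_by_trait[t]:
            bv_qtl += eff * (dosage[:, j] - 2 * p_freq[j])
            var_qtl += eff * eff * 2 * p_freq[j] * (1 - p_freq[j])
        sigma2_a = max(h2 - var_qtl, 1e-4)
        if var_qtl > h2:
            logger.warning("trait %s: QTL variance %.3f exceeds h2 %.2f", t, var_qtl, h2)
        poly = np.zeros(len(order))
        for iid in order:
            i = index[iid]
            sire, dam = pop.pedigree.parents(iid)
            if sire is None and dam is None:
                poly[i] = rng.normal(0, np.sqrt(sigma2_a))
            else:
                mid, ms_var = 0.0, 0.5 * sigma2_a
                for par in (sire, dam):
                    if par is None:
                        ms_var += 0.25 * sigma2_a
                    else:
                        mid += 0.5 * poly[index[par]]
                poly[i] = mid + rng.normal(0, np.sqrt(ms_var))
        bv = bv_qtl + poly
        pop.breeding_values[t] = bv
        sigma2_e = 1.0 - h2
        if cfg.pheno_kind == "YD":
            value = bv + rng.normal(0, np.sqrt(sigma2_e / cfg.yd_records), len(order))
        elif cfg.pheno_kind == "DYD":
            value = 0.5 * bv + rng.normal(0, np.sqrt(sigma2_e / cfg.dyd_accuracy), len(order))
        else:
            raise ValueError(f"unknown pheno_kind {cfg.pheno_kind!r}")
        rows.append(pd.DataFrame({"animal_id": order, "trait": t, "value": value}))
        var_raw[t] = float(np.var(bv) + sigma2_e)
        var_obs[t] = float(np.var(value))
    pheno = PhenotypeTable(pd.concat(rows, ignore_index=True), var_raw, var_obs)
    pop.phenotypes = pheno
    return pheno


@dataclass
class SimStudy:
    """Everything a pipeline run needs, from one seed."""

    config: SimConfig
    truth: TruePopulation
    seq_panel: GenotypeMatrix          # noisy calls with GQ/DP, panel samples only
    seq_panel_ids: list[str]
    array_indices: np.ndarray          # variant indices of the array subset
    array: GenotypeMatrix              # error-free chip calls, all samples
    breed_map: dict[str, str]


def simulate_study(cfg: SimConfig) -> SimStudy:
    """Run the full generator: founders -> gene drop -> calls/array/phenotypes.

    The sequence panel comprises the earliest ``seq_panel_size_per_breed``
    individuals per breed in pedigree order, so panel animals are ancestors
    of most array-genotyped animals (the study design maximises kinship
    between reference and target populations).
    """
    rng = np.random.default_rng(cfg.seed)
    founder_haps, variants = simulate_founders(cfg, rng)
    ped = simulate_pedigree(cfg, rng)
    pop = gene_drop(founder_haps, ped, variants, cfg.recomb_rate, rng)
    if cfg.h2:
        simulate_phenotypes(pop, cfg, rng)

    breed_map = {iid: ped.breed_of(iid) for iid in pop.sample_ids}
    dosage = pop.dosage
    # per-breed ALT observation counts on the truth
    for breed in cfg.breeds:
        m = np.array([breed_map[i] == breed for i in pop.sample_ids])
        variants.alt_obs[breed] = dosage[m].sum(axis=0).astype(np.int64)

    # sequence panel: whole families (sire, dam, offspring), largest first —
    # panels are built to maximise kinship with the target population, and
    # pedigree links inside the panel are what both the phasing and the
    # leave-one-out design (sequenced daughters of sequenced sires) rely on
    panel_ids: list[str] = []
    for breed in cfg.breeds:
        size = cfg.seq_panel_size_per_breed
        families: dict[tuple[str, str], list[str]] = {}
        for iid in pop.sample_ids:
            if breed_map[iid] != breed:
                continue
            sire, dam = ped.parents(iid)
            if sire is not None and dam is not None:
                families.setdefault((sire, dam), []).append(iid)
        chosen: list[str] = []
        in_panel: set[str] = set()
        for (sire, dam), kids in sorted(families.items(),
                                        key=lambda kv: (-len(kv[1]), kv[0])):
            block = [sire, dam] + kids
            new = [i for i in block if i not in in_panel]
            if len(chosen) + len(new) > size and len(chosen) >= 3:
                continue
            chosen.extend(new[: size - len(chosen)])
            in_panel.update(chosen)
            if len(chosen) >= size:
                break
        for iid in pop.sample_ids:  # top up if families were too few
            if len(chosen) >= size:
                break
            if breed_map[iid] == breed and iid not in in_panel:
                chosen.append(iid)
                in_panel.add(iid)
        panel_ids.extend(sorted(chosen, key=pop.sample_ids.index))
    panel_idx = [pop.sample_ids.index(i) for i in panel_ids]
    seq_panel = sequence_calls(dosage[panel_idx], variants, panel_ids, cfg, rng)

    array_idx = design_array(variants, dosage, cfg.array_size, cfg.array_maf_min)
    array_vt = variants.subset(array_idx)
    array = GenotypeMatrix(pop.sample_ids, array_vt, dosage[:, array_idx])
    return SimStudy(cfg, pop, seq_panel, panel_ids, array_idx, array, breed_map)
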