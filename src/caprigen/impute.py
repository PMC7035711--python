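"""Pedigree-aware genotype imputation.

Two jobs share the machinery here:

* filling gaps **inside** a sequenced reference panel — Mendelian logic first
  (:func:`mendelian_fill`), then deterministic phasing against a growing
  haplotype library (:func:`phase_panel`), then library-based fill of the
  remaining holes;
* imputing array genotypes **up to** sequence level against a phased panel
  (:class:`HaplotypeImputer`), with a shrinking-window haplotype-library
  matcher: long windows find the long shared segments of close relatives,
  short windows the short segments shared with distant ones.  When a target's
  parent is in the panel, the parent's haplotypes are searched before the
  population library.

The engine is fully deterministic: ties are broken by haplotype frequency
and then lexicographically, and no random number generator is involved, so
the same inputs always give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix, Pedigree, VariantTable, logger

__all__ = [
    "ReferencePanelSpec",
    "mendelian_fill",
    "phase_panel",
    "HaplotypeImputer",
    "impute_to_sequence",
    "build_panel",
]

# candidate-set bitmasks for dosages {0, 1, 2}
_FULL = 0b111
_MASK_OF = {0: 0b001, 1: 0b010, 2: 0b100, MISSING: _FULL}
_SINGLETON = {0b001: 0, 0b010: 1, 0b100: 2}


def _allele_masks(geno_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(can transmit ref, can transmit alt) for a genotype candidate mask."""
    can0 = (geno_mask & 0b011) != 0   # genotype 0 or 1 possible
    can1 = (geno_mask & 0b110) != 0   # genotype 1 or 2 possible
    return can0, can1


def _child_mask_from_parents(s_mask: np.ndarray, d_mask: np.ndarray) -> np.ndarray:
    """Genotypes a child can have given parental candidate masks."""
    s0, s1 = _allele_masks(s_mask)
    d0, d1 = _allele_masks(d_mask)
    out = np.zeros_like(s_mask)
    out[s0 & d0] |= 0b001
    out[s0 & d1] |= 0b010
    out[s1 & d0] |= 0b010
    out[s1 & d1] |= 0b100
    return out


def _parent_mask_from_child(c_mask: np.ndarray, other_mask: np.ndarray) -> np.ndarray:
    """Genotypes a parent can have given a child and the co-parent masks."""
    o0, o1 = _allele_masks(other_mask)
    # allele a transmissible by this parent iff some co-parent allele b gives a+b in child
    a0_ok = ((c_mask & 0b001) != 0) & o0 | ((c_mask & 0b010) != 0) & o1
    a1_ok = ((c_mask & 0b010) != 0) & o0 | ((c_mask & 0b100) != 0) & o1
    out = np.zeros_like(c_mask)
    out[a0_ok] |= 0b011        # genotypes carrying a ref allele
    out[a1_ok] |= 0b110        # genotypes carrying an alt allele
    return out


def mendelian_fill(g: GenotypeMatrix, ped: Pedigree, max_iter: int = 20) -> GenotypeMatrix:
    """Fill missing calls that are logically forced by relatives.

    Constraint propagation over dosage candidate sets: a child's genotype is
    restricted by the alleles its parents can transmit and a parent's by what
    its children (with their co-parent) require.  A call is filled only when
    its candidate set shrinks to a single dosage; non-missing calls are never
    overwritten.  Runs to fixpoint.  Mendelian conflicts among non-missing
    calls leave the calls unchanged and are logged.
    """
    lookup = {s: i for i, s in enumerate(g.sample_ids)}
    trios = []
    for iid in ped.topo_order:
        if iid not in lookup:
            continue
        sire, dam = ped.parents(iid)
        si = lookup.get(sire) if sire else None
        di = lookup.get(dam) if dam else None
        if si is not None or di is not None:
            trios.append((lookup[iid], si, di))

    mask_lut = np.array([_FULL, 0, 0], dtype=np.uint8)
    masks = np.empty(g.dosage.shape, dtype=np.uint8)
    for dose, m in _MASK_OF.items():
        masks[g.dosage == dose] = m

    full_col = np.full(g.n_variants, _FULL, dtype=np.uint8)
    for _ in range(max_iter):
        before = masks.copy()
        for ci, si, di in trios:
            s_mask = masks[si] if si is not None else full_col
            d_mask = masks[di] if di is not None else full_col
            masks[ci] &= _child_mask_from_parents(s_mask, d_mask)
            if si is not None:
                masks[si] &= _parent_mask_from_child(masks[ci], d_mask)
            if di is not None:
                masks[di] &= _parent_mask_from_child(masks[ci], s_mask)
        if np.array_equal(masks, before):
            break

    n_conflicts = int((masks == 0).any(axis=0).sum())
    if n_conflicts:
        logger.warning("mendelian_fill: %d variants with Mendelian conflicts left unchanged",
                       n_conflicts)
    out = g.dosage.copy()
    fillable = (g.dosage == MISSING) & ~(masks == 0).any(axis=0, keepdims=True)
    for bits, dose in _SINGLETON.items():
        out[fillable & (masks == bits)] = dose
    return GenotypeMatrix(g.sample_ids, g.variants, out, g.gq, g.dp)


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------

def _chrom_slices(variants: VariantTable) -> list[np.ndarray]:
    chrom = variants.chrom
    return [np.flatnonzero(chrom == c) for c in dict.fromkeys(chrom)]


def _windows(n: int, size: int) -> list[tuple[int, int]]:
    """Half-open [start, stop) windows of ``size`` with 50% overlap covering n."""
    if n <= size:
        return [(0, n)]
    step = max(size // 2, 1)
    starts = list(range(0, n - size + step, step))
    return [(s, min(s + size, n)) for s in starts]


def _best_match(lib: np.ndarray, counts: np.ndarray, hap: np.ndarray) -> tuple[int, int]:
    """Index and mismatch count of the library row best matching ``hap``.

    Positions where ``hap`` is unresolved (-1) are ignored.  Ties go to the
    higher-frequency row, then to the lexicographically smaller row (library
    rows are stored lexicographically sorted, so first index wins).
    """
    known = hap >= 0
    if not known.any() or len(lib) == 0:
        return -1, 0
    mism = (lib[:, known] != hap[known]).sum(axis=1)
    best = np.flatnonzero(mism == mism.min())
    if len(best) > 1:
        best = best[np.argsort(-counts[best], kind="stable")]
    return int(best[0]), int(mism.min())


def _unique_library(rows: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Deduplicate haplotype rows; returns (lex-sorted unique rows, counts)."""
    if not rows:
        return np.empty((0, 0), dtype=np.int8), np.empty(0, dtype=np.int64)
    arr = np.array(rows, dtype=np.int8)
    uniq, counts = np.unique(arr, axis=0, return_counts=True)
    return uniq, counts


def phase_panel(g: GenotypeMatrix, ped: Pedigree | None = None,
                window: int = 100) -> np.ndarray:
    """Deterministically phase a (nearly complete) genotype panel.

    Returns a (2*n_samples, n_variants) int8 allele matrix, rows 2i (paternal
    where resolvable) and 2i+1 per sample; missing genotypes stay -1 on both
    rows.  Heterozygotes are resolved from parent-offspring trios where a
    parent is homozygous (or the co-parent determines the transmitted
    allele), then window by window against a growing library of already
    phased haplotypes; remaining ties are broken lexicographically (ref
    allele on the first haplotype).
    """
    n, V = g.dosage.shape
    h = np.full((2 * n, V), -1, dtype=np.int8)
    dose = g.dosage
    hom0 = dose == 0
    hom2 = dose == 2
    h[0::2][hom0] = 0
    h[1::2][hom0] = 0
    h[0::2][hom2] = 1
    h[1::2][hom2] = 1

    het = dose == 1
    resolved_het = np.zeros_like(het)
    lookup = {s: i for i, s in enumerate(g.sample_ids)}
    if ped is not None:
        for iid in g.sample_ids:
            if iid not in ped:
                continue
            i = lookup[iid]
            sire, dam = ped.parents(iid)
            si = lookup.get(sire) if sire else None
            di = lookup.get(dam) if dam else None
            m = het[i]
            if si is not None:
                s_hom0, s_hom2 = m & hom0[si], m & hom2[si]
                h[2 * i][s_hom0], h[2 * i + 1][s_hom0] = 0, 1
                h[2 * i][s_hom2], h[2 * i + 1][s_hom2] = 1, 0
                resolved_het[i] |= s_hom0 | s_hom2
            if di is not None:
                m2 = m & ~resolved_het[i]
                d_hom0, d_hom2 = m2 & hom0[di], m2 & hom2[di]
                h[2 * i][d_hom0], h[2 * i + 1][d_hom0] = 1, 0
                h[2 * i][d_hom2], h[2 * i + 1][d_hom2] = 0, 1
                resolved_het[i] |= d_hom0 | d_hom2

    # long-range phasing through offspring: a child's resolved parental
    # haplotype is one (rarely recombined) gamete of that parent, so it pins
    # the parent's heterozygote phase over long stretches.  One gamete per
    # parent keeps the assignment internally consistent.
    if ped is not None:
        h_trio = h.copy()
        kids_of: dict[int, list[tuple[int, int]]] = {}
        for iid in g.sample_ids:
            if iid not in ped:
                continue
            sire, dam = ped.parents(iid)
            for parent, row in ((sire, 0), (dam, 1)):
                pi = lookup.get(parent) if parent else None
                if pi is not None:
                    kids_of.setdefault(pi, []).append((lookup[iid], row))
        for pi, kids in sorted(kids_of.items()):
            u = het[pi] & ~resolved_het[pi]
            if not u.any():
                continue

            def informative(kr):
                ci, row = kr
                return int((u & (h_trio[2 * ci + row] >= 0)).sum())

            ci, row = max(sorted(kids), key=informative)
            gam = h_trio[2 * ci + row]
            sites = u & (gam >= 0)
            h[2 * pi][sites] = gam[sites]
            h[2 * pi + 1][sites] = 1 - gam[sites]
            resolved_het[pi] |= sites

    trio_unresolved = het & ~resolved_het
    h_base = h.copy()
    min_resolved = 0.7  # library rows may carry -1 holes; holes never mismatch

    def dual_donor_fill(dw, h0, h1, u, lib, self_rows):
        """Orient unresolved hets ``u`` by a two-donor decomposition of the
        window dosage.

        Donor 1 is the row with the fewest hard conflicts against the dosage
        vector (a hard conflict — donor allele impossible given the genotype
        — is decisive evidence against haplotype sharing); its alleles fill
        one haplotype, oriented by agreement with already-resolved hets.
        Donor 2 explains the residual ``dosage - donor1`` and fills what
        donor 1 left open.  Donor holes carry a small penalty so informative
        rows win ties.
        """
        known = lib >= 0
        hard = (((dw == 0) & (lib == 1)) | ((dw == 2) & (lib == 0))).sum(axis=1)
        anch = (h0 >= 0) & (h1 >= 0) & (h0 != h1)
        a_m0 = ((lib != h0) & known & anch).sum(axis=1)
        a_m1 = ((lib != h1) & known & anch).sum(axis=1)
        hole_pen = 0.1 * (~known[:, u]).sum(axis=1)
        score1 = hard + np.minimum(a_m0, a_m1) + hole_pen
        score1 = score1.astype(float)
        for r in self_rows:
            score1[r] = np.inf
        r1 = int(np.argmin(score1))
        d1 = lib[r1]
        tgt, oth = (h0, h1) if a_m0[r1] <= a_m1[r1] else (h1, h0)
        f1 = u[d1[u] >= 0]
        tgt[f1] = d1[f1]
        oth[f1] = 1 - d1[f1]
        filled = [f1]
        u2 = u[d1[u] < 0]
        if len(u2):
            resid = dw - d1
            valid = (d1 >= 0) & (resid >= 0) & (resid <= 1)
            hard2 = ((lib != resid) & known & valid).sum(axis=1)
            a_o = ((lib != oth) & known & anch).sum(axis=1)
            score2 = (hard2 + a_o + 0.1 * (~known[:, u2]).sum(axis=1)).astype(float)
            for r in self_rows:
                score2[r] = np.inf
            r2 = int(np.argmin(score2))
            d2 = lib[r2]
            f2 = u2[d2[u2] >= 0]
            oth[f2] = d2[f2]
            tgt[f2] = 1 - d2[f2]
            filled.append(f2)
        return np.concatenate(filled)

    unresolved = trio_unresolved.copy()
    for sweep in range(2):
        if sweep == 1:
            # refinement: re-decide library-derived orientations against the
            # full first-sweep library (own haplotypes excluded)
            h_prev = h.copy()
            h = h_base.copy()
            unresolved = trio_unresolved.copy()
        for idx in _chrom_slices(g.variants):
            for start, stop in _windows(len(idx), window):
                cols = idx[start:stop]
                n_unres = unresolved[:, cols].sum(axis=1)
                order = sorted(range(n), key=lambda i: (int(n_unres[i]), g.sample_ids[i]))
                if sweep == 1:
                    lib = h_prev[:, cols]
                    row_owner = np.repeat(np.arange(n), 2)
                    lib_rows = None
                else:
                    lib_rows = []
                    lib = None
                for i in order:
                    u = np.flatnonzero(unresolved[i][cols])
                    if len(u):
                        h0 = h[2 * i, cols].copy()
                        h1 = h[2 * i + 1, cols].copy()
                        if sweep == 0 and lib_rows and lib is None:
                            lib = np.array(lib_rows, dtype=np.int8)
                        if lib is not None and len(lib):
                            self_rows = ((2 * i, 2 * i + 1) if sweep == 1 else ())
                            fill = dual_donor_fill(dose[i, cols], h0, h1, u,
                                                   lib, self_rows)
                            h[2 * i, cols] = h0
                            h[2 * i + 1, cols] = h1
                            unresolved[i][cols[fill]] = False
                    if sweep == 0:
                        for row in (h[2 * i, cols], h[2 * i + 1, cols]):
                            if (row >= 0).mean() >= min_resolved:
                                lib_rows.append(row.copy())
                                lib = None  # rebuilt lazily on next use

    # anything never covered by an informative donor: deterministic tie-break
    left = unresolved & (dose == 1)
    if left.any():
        h[0::2][left] = 0
        h[1::2][left] = 1
    return h


def library_fill(h: np.ndarray, variants: VariantTable, window: int = 100) -> np.ndarray:
    """Fill unresolved (-1) alleles from the best-matching other haplotype.

    For each window, a haplotype with holes copies the alleles of its best
    match (fewest mismatches over resolved positions) among fully resolved
    haplotypes; remaining holes take the major allele.  Returns a hole-free
    copy.
    """
    out = h.copy()
    for idx in _chrom_slices(variants):
        for start, stop in _windows(len(idx), window):
            cols = idx[start:stop]
            block = out[:, cols]
            complete = (block >= 0).all(axis=1)
            lib, counts = _unique_library([block[r] for r in np.flatnonzero(complete)])
            for r in np.flatnonzero(~complete):
                row = block[r]
                holes = row < 0
                if len(lib):
                    j, _ = _best_match(lib, counts, row)
                    row = row.copy()
                    row[holes] = lib[j][holes]
                    out[r, cols] = row
    holes = out < 0
    if holes.any():
        freq = np.where(out >= 0, out, 0).sum(axis=0) / np.maximum((out >= 0).sum(axis=0), 1)
        major = (freq > 0.5).astype(np.int8)
        out[holes] = np.broadcast_to(major, out.shape)[holes]
    return out


# ---------------------------------------------------------------------------
# Array -> sequence imputation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferencePanelSpec:
    """Which panel samples to impute from.

    ``name`` is a label (within-breed / france / europe / world / custom);
    selection is by ``breeds`` or explicit ``ids`` (order preserved).  With
    ``pca_gate`` the selection is intersected with the samples lying within
    ``pca_threshold`` x the median distance of their breed's PCA centroid.
    """

    name: str = "custom"
    breeds: tuple[str, ...] = ()
    ids: tuple[str, ...] = ()
    use_pedigree: bool = True
    pca_gate: bool = False
    pca_threshold: float = 4.0


def build_panel(seq: GenotypeMatrix, spec: ReferencePanelSpec,
                breed_map: dict[str, str] | None = None) -> GenotypeMatrix:
    """Select the reference-panel samples matching ``spec``."""
    if spec.ids:
        missing = [i for i in spec.ids if i not in seq.sample_ids]
        if missing:
            raise ValueError(f"panel ids absent from data: {missing[:5]}")
        selected = list(spec.ids)
    elif spec.breeds:
        if breed_map is None:
            raise ValueError("breed selection needs a breed_map")
        selected = [s for s in seq.sample_ids if breed_map.get(s) in spec.breeds]
    else:
        selected = list(seq.sample_ids)
    if not selected:
        raise ValueError(f"panel spec {spec.name!r} selects no samples")

    if spec.pca_gate:
        from .assoc import pca
        sub = seq.subset_samples(selected)
        coords, _ = pca(sub, k=min(2, len(selected) - 1))
        labels = np.array([breed_map.get(s, "?") if breed_map else "?" for s in selected])
        keep = np.ones(len(selected), dtype=bool)
        for lab in np.unique(labels):
            m = labels == lab
            centroid = coords[m].mean(axis=0)
            dist = np.linalg.norm(coords[m] - centroid, axis=1)
            med = np.median(dist)
            if med > 0:
                keep[np.flatnonzero(m)[dist > spec.pca_threshold * med]] = False
        dropped = [s for s, k in zip(selected, keep) if not k]
        if dropped:
            logger.info("PCA gate excluded %d samples: %s", len(dropped), dropped[:5])
        selected = [s for s, k in zip(selected, keep) if k]
        if not selected:
            raise ValueError("PCA gating removed every panel sample")
    return seq.subset_samples(selected)


class HaplotypeImputer:
    """Shrinking-window haplotype-library imputer (fit on panel, transform targets).

    Parameters
    ----------
    window_schedule : tuple of int
        Window lengths in array markers, longest first, each pass run with
        50% overlap.  Long windows exploit long shared segments (close
        relatives), short windows short ones.
    use_pedigree : bool
        Search a target's parents' haplotypes before the population library.
    phase_window : int
        Window length (markers) for phasing the panel during ``fit``.
    fallback : str
        ``"major"`` fills still-unresolved alleles with the panel major
        allele; ``"sample"`` draws from the panel frequency (needs ``seed``).

    Attributes (after ``fit``)
    --------------------------
    haplotypes_ : (2*n_panel, n_variants) int8 phased, hole-free panel.
    variants_ : the panel :class:`VariantTable`.
    panel_ids_ : panel sample ids, row pairs 2i/2i+1 of ``haplotypes_``.
    """

    def __init__(self, window_schedule: tuple[int, ...] = (500, 100, 20),
                 use_pedigree: bool = True, phase_window: int = 100,
                 fallback: str = "major", seed: int | None = None):
        self.window_schedule = tuple(window_schedule)
        self.use_pedigree = use_pedigree
        self.phase_window = phase_window
        self.fallback = fallback
        self.seed = seed

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"window_schedule": self.window_schedule,
                "use_pedigree": self.use_pedigree,
                "phase_window": self.phase_window,
                "fallback": self.fallback, "seed": self.seed}

    def set_params(self, **params) -> "HaplotypeImputer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------
    def fit(self, panel: GenotypeMatrix, pedigree: Pedigree | None = None,
            haplotypes: np.ndarray | None = None) -> "HaplotypeImputer":
        """Phase and gap-fill the reference panel.

        ``haplotypes`` may supply already-phased alleles (e.g. simulation
        truth), skipping the phasing step.
        """
        self.variants_ = panel.variants
        self.panel_ids_ = list(panel.sample_ids)
        self.pedigree_ = pedigree if self.use_pedigree else None
        if haplotypes is not None:
            h = np.asarray(haplotypes, dtype=np.int8)
            if h.shape != (2 * panel.n_samples, panel.n_variants):
                raise ValueError("haplotypes shape mismatch")
        else:
            g = panel
            if pedigree is not None:
                g = mendelian_fill(g, pedigree)
            h = phase_panel(g, pedigree, window=self.phase_window)
        self.haplotypes_ = library_fill(h, panel.variants, window=self.phase_window)
        freq = self.haplotypes_.mean(axis=0)
        self.major_allele_ = (freq > 0.5).astype(np.int8)
        self.allele_freq_ = freq
        return self

    # -- imputation ---------------------------------------------------------
    def transform(self, targets: GenotypeMatrix,
                  pedigree: Pedigree | None = None) -> GenotypeMatrix:
        """Impute targets to sequence level.  Output has no missing calls.

        Array markers are matched to panel variants by (chrom, pos, ref,
        alt); markers absent from the panel are dropped with a logged count.
        Target genotypes at their array markers are authoritative and are
        never altered.
        """
        if not hasattr(self, "haplotypes_"):
            raise ValueError("imputer is not fitted")
        ped = pedigree if pedigree is not None else self.pedigree_
        if not self.use_pedigree:
            ped = None
        pkey = self.variants_.key()
        tkey = targets.variants.key()
        t_in_p = pkey.get_indexer(tkey)
        dropped = int((t_in_p < 0).sum())
        if dropped:
            logger.warning("transform: %d array markers absent from panel dropped", dropped)
        t_cols = np.flatnonzero(t_in_p >= 0)          # target variant columns used
        seq_cols = t_in_p[t_cols]                     # their panel variant indices

        n_t = targets.n_samples
        V = len(self.variants_)
        H = self.haplotypes_
        lookup = {s: i for i, s in enumerate(self.panel_ids_)}
        out0 = np.full((n_t, V), -1, dtype=np.int8)
        out1 = np.full((n_t, V), -1, dtype=np.int8)

        chrom = self.variants_.chrom
        chrom_ids = list(dict.fromkeys(chrom))
        # per-chromosome array marker indices (positions within seq_cols)
        marker_chrom = chrom[seq_cols]

        for i, sid in enumerate(targets.sample_ids):
            prio_rows: list[int] = []
            if ped is not None and sid in ped:
                for parent in ped.parents(sid):
                    if parent is not None and parent in lookup:
                        p = lookup[parent]
                        prio_rows.extend((2 * p, 2 * p + 1))
            d_full = targets.dosage[i, t_cols]
            for c in chrom_ids:
                cm = marker_chrom == c
                m_seq = seq_cols[cm]                  # panel indices of markers, sorted
                d = d_full[cm]
                chrom_var = np.flatnonzero(chrom == c)
                if len(m_seq) == 0:
                    continue
                for w_size in self.window_schedule:
                    for start, stop in _windows(len(m_seq), w_size):
                        self._impute_window(
                            H, prio_rows, m_seq, d, start, stop, chrom_var,
                            out0[i], out1[i],
                        )

        # fallback for anything still unresolved
        holes0, holes1 = out0 < 0, out1 < 0
        if self.fallback == "sample":
            rng = np.random.default_rng(self.seed)
            draw = lambda holes: (rng.random(holes.shape) < self.allele_freq_).astype(np.int8)
            out0[holes0] = draw(holes0)[holes0]
            out1[holes1] = draw(holes1)[holes1]
        else:
            out0[holes0] = np.broadcast_to(self.major_allele_, out0.shape)[holes0]
            out1[holes1] = np.broadcast_to(self.major_allele_, out1.shape)[holes1]

        dosage = (out0 + out1).astype(np.int8)
        # chip calls are authoritative at their own markers
        obs = targets.dosage[:, t_cols] != MISSING
        cols_mat = np.broadcast_to(seq_cols, obs.shape)
        rows_mat = np.broadcast_to(np.arange(n_t)[:, None], obs.shape)
        dosage[rows_mat[obs], cols_mat[obs]] = targets.dosage[:, t_cols][obs]
        return GenotypeMatrix(list(targets.sample_ids), self.variants_, dosage)

    def _impute_window(self, H, prio_rows, m_seq, d, start, stop, chrom_var,
                       a0, a1) -> None:
        """Pick two donor haplotypes for one window and copy unresolved alleles."""
        cols = m_seq[start:stop]
        dw = d[start:stop]
        known = dw != MISSING
        # sequence span this window is responsible for
        lo = chrom_var[0] if start == 0 else cols[0]
        hi = chrom_var[-1] if stop == len(m_seq) else cols[-1]
        span = chrom_var[(chrom_var >= lo) & (chrom_var <= hi)]
        if (a0[span] >= 0).all() and (a1[span] >= 0).all():
            return
        lib = H[:, cols]
        if known.any():
            # donor 1: fewest incompatibilities with the dosage vector
            incomp = (((lib == 1) & (dw == 0)) | ((lib == 0) & (dw == 2)))[:, known]
            mism1 = incomp.sum(axis=1)
            j1 = self._pick(mism1, prio_rows)
            # donor 2: residual alleles d - h1 where determinable
            resid = dw - lib[j1]
            valid = known & (resid >= 0) & (resid <= 1)
            mism2 = (lib[:, valid] != resid[valid]).sum(axis=1)
            j2 = self._pick(mism2, prio_rows)
        else:
            return  # nothing known in this window; later passes / fallback handle it
        h0, h1 = a0[span], a1[span]
        d0, d1 = H[j1][span], H[j2][span]
        a0[span] = np.where(h0 >= 0, h0, d0)
        a1[span] = np.where(h1 >= 0, h1, d1)

    @staticmethod
    def _pick(mism: np.ndarray, prio_rows: list[int]) -> int:
        """Row with fewest mismatches; parents win ties, then lower row index
        (library rows are in fixed panel order, making ties deterministic)."""
        best = np.flatnonzero(mism == mism.min())
        if prio_rows:
            for r in prio_rows:
                if r in best:
                    return int(r)
        return int(best[0])

    def fit_transform(self, panel: GenotypeMatrix, targets: GenotypeMatrix,
                      pedigree: Pedigree | None = None) -> GenotypeMatrix:
        return self.fit(panel, pedigree).transform(targets, pedigree)


def impute_to_sequence(targets: GenotypeMatrix, panel: GenotypeMatrix,
                       spec: ReferencePanelSpec | None = None,
                       pedigree: Pedigree | None = None,
                       breed_map: dict[str, str] | None = None,
                       window_schedule: tuple[int, ...] = (500, 100, 20),
                       panel_haplotypes: np.ndarray | None = None) -> GenotypeMatrix:
    """One-shot functional wrapper: build panel, fit, impute."""
    spec = spec or ReferencePanelSpec()
    sub = build_panel(panel, spec, breed_map)
    if panel_haplotypes is not None and sub.sample_ids != panel.sample_ids:
        idx = panel.sample_index(sub.sample_ids)
        rows = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        panel_haplotypes = panel_haplotypes[rows]
    imp = HaplotypeImputer(window_schedule, use_pedigree=spec.use_pedigree)
    imp.fit(sub, pedigree if spec.use_pedigree else None, haplotypes=panel_haplotypes)
    return imp.transform(targets, pedigree if spec.use_pedigree else None)
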