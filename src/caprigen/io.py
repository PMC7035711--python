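"""Core domain types and file I/O.

The in-memory model is deliberately small:

* :class:`VariantTable` — one row per biallelic variant (chrom, pos, ref, alt,
  site QUAL), plus per-breed alternate-allele observation counts.
* :class:`GenotypeMatrix` — samples x variants alternate-allele dosages coded
  ``{0, 1, 2}`` with ``-1`` as the missing sentinel, and optional per-call GQ
  (phred genotype quality) and DP (read depth) planes of the same shape.
* :class:`Pedigree` — acyclic id -> (sire, dam, breed, sex) map.
* :class:`PhenotypeTable` — pre-adjusted records (YD/DYD semantics) per animal
  and trait, with the raw-record and observed variances the CLIP test needs.

VCF reading goes through cyvcf2; writing is plain text because only the
GT/GQ/DP fields produced here are ever emitted.  Multi-allelic records are
split into biallelic records at read time: for each alternate allele a record
is produced where genotypes carrying a *different* alternate allele are set
missing, matching the biallelic dosage model used downstream.

Coordinates are 1-based inclusive (VCF convention) everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from graphlib import TopologicalSorter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("caprigen")

#: Missing-genotype sentinel used in every dosage/GQ/DP matrix.
MISSING: int = -1


class VariantTable:
    """Per-variant site table: chrom, pos, ref, alt, qual (+ per-breed ALT counts).

    Positions are strictly increasing within a chromosome and every record is
    biallelic; both are enforced at construction.
    """

    REQUIRED = ("chrom", "pos", "ref", "alt", "qual")

    def __init__(self, df: pd.DataFrame, alt_obs: Mapping[str, np.ndarray] | None = None):
        missing_cols = [c for c in self.REQUIRED if c not in df.columns]
        if missing_cols:
            raise ValueError(f"VariantTable missing columns {missing_cols}")
        df = df.reset_index(drop=True).copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        if (df["qual"].to_numpy() < 0).any():
            raise ValueError("site QUAL must be >= 0")
        for chrom, sub in df.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            # non-decreasing: biallelic records split from a multi-allelic
            # site legitimately share a position; full records stay unique
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted on chrom {chrom}")
        key = df["chrom"] + ":" + df["pos"].astype(str) + ":" + df["ref"] + ":" + df["alt"]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos, ref, alt) records")
        self.df = df
        self.alt_obs: dict[str, np.ndarray] = {}
        if alt_obs is not None:
            for breed, counts in alt_obs.items():
                counts = np.asarray(counts)
                if counts.shape != (len(df),):
                    raise ValueError("alt_obs length mismatch")
                self.alt_obs[breed] = counts.astype(np.int64)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    def key(self) -> pd.Index:
        """``chrom:pos:ref:alt`` identity keys, unique per record."""
        d = self.df
        return pd.Index(
            d["chrom"].astype(str) + ":" + d["pos"].astype(str) + ":" + d["ref"] + ":" + d["alt"]
        )

    def subset(self, idx: np.ndarray) -> "VariantTable":
        idx = np.asarray(idx)
        sub = VariantTable(self.df.iloc[idx].reset_index(drop=True))
        for breed, counts in self.alt_obs.items():
            sub.alt_obs[breed] = counts[idx]
        return sub

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask for the closed interval [start, end] bp on ``chrom``."""
        return (self.chrom == str(chrom)) & (self.pos >= start) & (self.pos <= end)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with optional GQ/DP planes."""

    sample_ids: list[str]
    variants: VariantTable
    dosage: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        expected = (len(self.sample_ids), len(self.variants))
        if self.dosage.shape != expected:
            raise ValueError(f"dosage shape {self.dosage.shape} != {expected}")
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")
        for name in ("gq", "dp"):
            plane = getattr(self, name)
            if plane is not None:
                plane = np.asarray(plane, dtype=np.int16)
                if plane.shape != expected:
                    raise ValueError(f"{name} shape {plane.shape} != {expected}")
                setattr(self, name, plane)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=np.intp)

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            self.variants,
            self.dosage[idx],
            None if self.gq is None else self.gq[idx],
            None if self.dp is None else self.dp[idx],
        )

    def subset_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.sample_ids,
            self.variants.subset(idx),
            self.dosage[:, idx],
            None if self.gq is None else self.gq[:, idx],
            None if self.dp is None else self.dp[:, idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            self.variants,
            self.dosage.copy(),
            None if self.gq is None else self.gq.copy(),
            None if self.dp is None else self.dp.copy(),
        )

    def allele_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls (NaN if none)."""
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        obs = d != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(obs, d, 0).sum(axis=0) / np.where(n > 0, 2 * n, np.nan)

    def maf(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        p = self.allele_freq(sample_idx)
        return np.minimum(p, 1.0 - p)


@dataclass(frozen=True)
class PedigreeEntry:
    sire: str | None
    dam: str | None
    breed: str = "unknown"
    sex: str = "U"


class Pedigree:
    """Directed acyclic id -> (sire, dam) map with breed labels.

    Iteration order is topological: parents always precede offspring.
    """

    def __init__(self, entries: Mapping[str, PedigreeEntry]):
        self.entries = dict(entries)
        graph = {
            iid: [p for p in (e.sire, e.dam) if p is not None]
            for iid, e in self.entries.items()
        }
        for iid, parents in graph.items():
            for p in parents:
                if p not in self.entries:
                    raise ValueError(f"parent {p!r} of {iid!r} has no pedigree entry")
        self.topo_order: list[str] = list(TopologicalSorter(graph).static_order())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, iid: str) -> bool:
        return iid in self.entries

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        e = self.entries[iid]
        return e.sire, e.dam

    def breed_of(self, iid: str) -> str:
        return self.entries[iid].breed

    def offspring(self) -> dict[str, list[str]]:
        """Map parent id -> ids of its offspring."""
        out: dict[str, list[str]] = {}
        for iid, e in self.entries.items():
            for p in (e.sire, e.dam):
                if p is not None:
                    out.setdefault(p, []).append(iid)
        return out

    def founders(self) -> list[str]:
        return [i for i, e in self.entries.items() if e.sire is None and e.dam is None]


class PhenotypeTable:
    """Pre-adjusted phenotypes (YD/DYD) with per-trait variance metadata.

    ``var_raw[trait]`` is the variance of single raw records (sigma^2_y);
    ``var_obs[trait]`` the observed variance of the pre-adjusted values
    (sigma^2_X).  Both must be positive; one value per (animal, trait).
    """

    def __init__(
        self,
        df: pd.DataFrame,
        var_raw: Mapping[str, float] | None = None,
        var_obs: Mapping[str, float] | None = None,
    ):
        for c in ("animal_id", "trait", "value"):
            if c not in df.columns:
                raise ValueError(f"phenotype table missing column {c!r}")
        if df.duplicated(["animal_id", "trait"]).any():
            raise ValueError("duplicate (animal, trait) phenotype records")
        self.df = df.reset_index(drop=True).copy()
        self.var_raw = dict(var_raw or {})
        self.var_obs = dict(var_obs or {})
        for name, d in (("var_raw", self.var_raw), ("var_obs", self.var_obs)):
            for trait, v in d.items():
                if not v > 0:
                    raise ValueError(f"{name}[{trait!r}] must be > 0")

    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    def vector(self, trait: str, sample_ids: Sequence[str]) -> np.ndarray:
        """Trait values aligned to ``sample_ids`` (NaN where unrecorded)."""
        sub = self.df[self.df["trait"] == trait].set_index("animal_id")["value"]
        return np.array([sub.get(s, np.nan) for s in sample_ids], dtype=float)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _split_genotype_dosage(alleles: np.ndarray, alt_index: int) -> np.ndarray:
    """Dosage of alternate allele ``alt_index`` (1-based) from a genotype array.

    Genotypes carrying any *other* alternate allele become missing for this
    biallelic record, as do genotypes with missing alleles.
    """
    a, b = alleles[:, 0], alleles[:, 1]
    miss = (a < 0) | (b < 0)
    other = ((a > 0) & (a != alt_index)) | ((b > 0) & (b != alt_index))
    dose = (a == alt_index).astype(np.int8) + (b == alt_index).astype(np.int8)
    dose[miss | other] = MISSING
    return dose


def read_vcf(path: str | Path, breed_map: Mapping[str, str] | None = None):
    """Read a VCF 4.x into (:class:`VariantTable`, :class:`GenotypeMatrix`).

    Multi-allelic records are split into one biallelic record per alternate
    allele.  GQ/DP planes are attached when the FORMAT declares them.  Samples
    absent from ``breed_map`` are assigned breed ``"unknown"`` with a warning.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files") from exc

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    breed_map = dict(breed_map or {})
    for s in samples:
        if s not in breed_map:
            logger.warning("sample %s not in breed map; breed set to 'unknown'", s)
            breed_map[s] = "unknown"
    breeds = sorted(set(breed_map.values()))
    breed_of_sample = np.array([breeds.index(breed_map[s]) for s in samples])

    rows, dosages, gqs, dps = [], [], [], []
    has_gq = has_dp = False
    def fmt(rec, key):
        try:
            return rec.format(key)
        except KeyError:
            return None

    for rec in vcf:
        alleles = np.array(rec.genotype.array())[:, :2]
        gq = fmt(rec, "GQ")
        dp = fmt(rec, "DP")
        for k, alt in enumerate(rec.ALT, start=1):
            dose = _split_genotype_dosage(alleles, k)
            rows.append((str(rec.CHROM), rec.POS, rec.REF, alt, float(rec.QUAL or 0.0)))
            dosages.append(dose)
            if gq is not None:
                has_gq = True
                g = gq.astype(float).ravel()[: len(samples)]
                gqs.append(np.where(np.isfinite(g) & (g >= 0), g, MISSING).astype(np.int16))
            else:
                gqs.append(None)
            if dp is not None:
                has_dp = True
                d = dp.astype(float).ravel()[: len(samples)]
                dps.append(np.where(np.isfinite(d) & (d >= 0), d, MISSING).astype(np.int16))
            else:
                dps.append(None)
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")

    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
    dosage = np.array(dosages, dtype=np.int8).T  # samples x variants
    n_s, n_v = dosage.shape

    def plane(cols, flag):
        if not flag:
            return None
        out = np.full((n_s, n_v), MISSING, dtype=np.int16)
        for j, c in enumerate(cols):
            if c is not None:
                out[:, j] = c
        return out

    alt_obs = {}
    for bi, breed in enumerate(breeds):
        mask = breed_of_sample == bi
        d = dosage[mask]
        alt_obs[breed] = np.where(d != MISSING, d, 0).sum(axis=0)

    vt = VariantTable(df, alt_obs)
    gm = GenotypeMatrix(samples, vt, dosage, plane(gqs, has_gq), plane(dps, has_dp))
    return vt, gm


def write_vcf(
    path: str | Path,
    gm: GenotypeMatrix,
    haplotypes: np.ndarray | None = None,
) -> None:
    """Write a minimal VCF 4.2 with GT (and GQ/DP when present).

    If phased ``haplotypes`` (2*n_samples x n_variants, rows 2i/2i+1 per
    sample) are given, GT is written phased (``a|b``); otherwise unphased
    dosage genotypes are written (``0/0``, ``0/1``, ``1/1``, ``./.``).
    """
    vt = gm.variants
    has_gq, has_dp = gm.gq is not None, gm.dp is not None
    fmt = "GT" + (":GQ" if has_gq else "") + (":DP" if has_dp else "")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in dict.fromkeys(vt.chrom):
            mask = vt.chrom == chrom
            fh.write(f"##contig=<ID={chrom},length={int(vt.pos[mask].max()) + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        gt_unphased = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        d = vt.df
        for j in range(len(vt)):
            cols = [
                str(d.at[j, "chrom"]), str(d.at[j, "pos"]), ".",
                d.at[j, "ref"], d.at[j, "alt"], f"{d.at[j, 'qual']:g}", ".", ".", fmt,
            ]
            for i in range(gm.n_samples):
                dose = gm.dosage[i, j]
                if haplotypes is not None and dose != MISSING:
                    gt = f"{haplotypes[2 * i, j]}|{haplotypes[2 * i + 1, j]}"
                else:
                    gt = gt_unphased[int(dose)]
                parts = [gt]
                if has_gq:
                    v = gm.gq[i, j]
                    parts.append("." if v == MISSING else str(int(v)))
                if has_dp:
                    v = gm.dp[i, j]
                    parts.append("." if v == MISSING else str(int(v)))
                cols.append(":".join(parts))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# PLINK text / array genotypes
# ---------------------------------------------------------------------------

def read_array(
    path: str | Path,
    dialect: str = "vcf",
    map_path: str | Path | None = None,
    breed_map: Mapping[str, str] | None = None,
):
    """Read array genotypes from VCF or PLINK .ped/.map text.

    For the PLINK dialect the two observed alleles per marker are oriented
    deterministically (lexicographically smaller allele = ref) and can be
    reconciled to a sequence panel afterwards with :func:`reconcile_alleles`.
    Markers whose position cannot be resolved are dropped with a logged count.
    """
    if dialect == "vcf":
        return read_vcf(path, breed_map)
    if dialect != "plink-ped":
        raise ValueError(f"unknown array dialect {dialect!r}")

    path = Path(path)
    map_path = Path(map_path) if map_path else path.with_suffix(".map")
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "marker", "cm", "pos"], dtype={"chrom": str})
    n_markers = len(mp)
    dropped = int((mp["pos"] <= 0).sum())
    if dropped:
        logger.warning("dropping %d markers with unresolvable positions", dropped)
    keep = mp["pos"] > 0

    ped = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    samples = ped.iloc[:, 1].tolist()
    allele_cols = ped.iloc[:, 6:].to_numpy()
    if allele_cols.shape[1] != 2 * n_markers:
        raise ValueError(
            f"{path}: expected {2 * n_markers} allele columns, found {allele_cols.shape[1]}"
        )
    a1 = allele_cols[:, 0::2]
    a2 = allele_cols[:, 1::2]

    refs, alts, doses = [], [], []
    for j in range(n_markers):
        if not keep.iloc[j]:
            continue
        col = np.concatenate([a1[:, j], a2[:, j]])
        obs = sorted(set(col) - {"0"})
        if len(obs) > 2:
            raise ValueError(f"marker {mp['marker'].iloc[j]} has >2 alleles")
        ref = obs[0] if obs else "A"
        alt = obs[1] if len(obs) > 1 else "."
        d = ((a1[:, j] == alt).astype(np.int8) + (a2[:, j] == alt).astype(np.int8)
             if alt != "." else np.zeros(len(samples), np.int8))
        d[(a1[:, j] == "0") | (a2[:, j] == "0")] = MISSING
        refs.append(ref)
        alts.append(alt)
        doses.append(d)

    sub = mp[keep]
    order = np.lexsort((sub["pos"].to_numpy(), sub["chrom"].to_numpy()))
    df = pd.DataFrame({
        "chrom": sub["chrom"].to_numpy()[order],
        "pos": sub["pos"].to_numpy()[order],
        "ref": np.array(refs)[order],
        "alt": np.array(alts)[order],
        "qual": 0.0,
    })
    dosage = np.array(doses, dtype=np.int8).T[:, order]
    vt = VariantTable(df)
    return vt, GenotypeMatrix(samples, vt, dosage)


def reconcile_alleles(array_vt: VariantTable, array_gm: GenotypeMatrix,
                      seq_vt: VariantTable) -> GenotypeMatrix:
    """Reconcile array ref/alt orientation to a sequence panel's.

    At shared (chrom, pos) sites where the array's ref/alt are the sequence
    panel's alt/ref, dosages are complemented (d -> 2 - d, missing untouched)
    and the alleles swapped.  Markers absent from the panel keep their own
    record.  Complementation is an involution: applying it twice is identity.
    """
    seq_idx = {(c, p): (r, a) for c, p, r, a in
               zip(seq_vt.chrom, seq_vt.pos, seq_vt.df["ref"], seq_vt.df["alt"])}
    df = array_vt.df.copy()
    dosage = array_gm.dosage.copy()
    n_flip = 0
    for j, (c, p, r, a) in enumerate(zip(df["chrom"], df["pos"], df["ref"], df["alt"])):
        hit = seq_idx.get((c, p))
        if hit is None:
            continue
        sr, sa = hit
        if (r, a) == (sa, sr):
            nz = dosage[:, j] != MISSING
            dosage[nz, j] = 2 - dosage[nz, j]
            df.loc[j, ["ref", "alt"]] = [sr, sa]
            n_flip += 1
    if n_flip:
        logger.info("reconciled %d flipped markers to sequence orientation", n_flip)
    vt = VariantTable(df)
    return GenotypeMatrix(array_gm.sample_ids, vt, dosage, array_gm.gq, array_gm.dp)


# ---------------------------------------------------------------------------
# Pedigree / phenotypes / association tables
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV: id,sire,dam[,breed[,sex]]; ``0`` marks unknown."""
    df = pd.read_csv(path, dtype=str).fillna("0")
    entries = {}
    for _, row in df.iterrows():
        entries[row.iloc[0]] = PedigreeEntry(
            sire=None if row.iloc[1] == "0" else row.iloc[1],
            dam=None if row.iloc[2] == "0" else row.iloc[2],
            breed=row.iloc[3] if len(row) > 3 else "unknown",
            sex=row.iloc[4] if len(row) > 4 else "U",
        )
    return Pedigree(entries)


def write_pedigree(path: str | Path, ped: Pedigree) -> None:
    rows = [
        {"id": i, "sire": e.sire or "0", "dam": e.dam or "0", "breed": e.breed, "sex": e.sex}
        for i, e in ((i, ped.entries[i]) for i in ped.topo_order)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype CSV: animal_id,trait,value[,var_raw,var_obs]."""
    df = pd.read_csv(path, dtype={"animal_id": str, "trait": str})
    var_raw, var_obs = {}, {}
    if "var_raw" in df.columns:
        var_raw = df.groupby("trait")["var_raw"].first().to_dict()
    if "var_obs" in df.columns:
        var_obs = df.groupby("trait")["var_obs"].first().to_dict()
    return PhenotypeTable(df[["animal_id", "trait", "value"]], var_raw, var_obs)


def write_phenotypes(path: str | Path, pheno: PhenotypeTable) -> None:
    df = pheno.df.copy()
    if pheno.var_raw:
        df["var_raw"] = df["trait"].map(pheno.var_raw)
    if pheno.var_obs:
        df["var_obs"] = df["trait"].map(pheno.var_obs)
    df.to_csv(path, index=False)


def write_assoc(results: pd.DataFrame, path: str | Path,
                header_lines: Sequence[str] = ()) -> None:
    """Write association results as a Manhattan-ready TSV.

    Columns: chrom, pos, ref, alt, maf, beta, se, p, minus_log10_p, sorted by
    (chrom, pos).  ``header_lines`` are emitted first as ``##key=value`` lines.
    """
    if len(results) == 0:
        raise ValueError("no association results to write")
    out = results.copy()
    out["minus_log10_p"] = -np.log10(out["p"])
    out = out.sort_values(["chrom", "pos"], kind="mergesort")
    cols = ["chrom", "pos", "ref", "alt", "maf", "beta", "se", "p", "minus_log10_p"]
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        out[cols].to_csv(fh, sep="\t", index=False)


def read_assoc(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
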