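"""Leave-one-out imputation-quality evaluation.

A sequenced animal is removed from the reference panel, its genotypes are
masked down to array density, imputed back from the remaining panel, and
compared with its true sequence.  Three metrics are computed per variant and
pooled:

* genotype concordance rate (CR): fraction of exact dosage matches;
* allele CR: per-call ``(2 - |truth - imputed|) / 2`` averaged over calls,
  i.e. the fraction of the two alleles recovered — always >= genotype CR;
* Pearson correlation R of the truth and imputed dosage vectors, undefined
  (and flagged) when either vector is constant.

Because low-MAF variants dominate sequence data and are the hardest to
impute, metrics are also averaged within MAF bins; MAF is computed on the
full reference panel before holdout removal so bins are stable across
holdouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, Pedigree, logger
from .impute import HaplotypeImputer, ReferencePanelSpec, build_panel

__all__ = [
    "EvalReport",
    "pick_holdouts",
    "mask_to_array",
    "concordance_metrics",
    "leave_one_out",
    "bin_by_maf",
]


@dataclass
class EvalReport:
    """Per-variant truth/imputed pairs plus aggregate metrics for one scenario."""

    truth: np.ndarray                 # (n_pairs, n_variants) truth dosages
    imputed: np.ndarray               # same shape
    maf: np.ndarray                   # per-variant reference-panel MAF
    scenario: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return self.truth.shape[1]

    def aggregate(self) -> dict[str, float]:
        """Pooled metrics over every comparable (non-missing) call."""
        a_cr, g_cr, r = concordance_metrics(self.truth.ravel(), self.imputed.ravel())
        return {"allele_cr": a_cr, "genotype_cr": g_cr, "r": r}

    def per_variant(self) -> pd.DataFrame:
        """Per-variant allele CR, genotype CR and R (NaN where undefined)."""
        if getattr(self, "_pv_cache", None) is not None:
            return self._pv_cache
        ok = (self.truth != MISSING) & (self.imputed != MISSING)
        t = np.where(ok, self.truth, 0).astype(float)
        m = np.where(ok, self.imputed, 0).astype(float)
        n = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            g_cr = np.where(n > 0, (ok & (self.truth == self.imputed)).sum(0) / n, np.nan)
            a_cr = np.where(n > 0,
                            np.where(ok, (2.0 - np.abs(t - m)) / 2.0, 0).sum(0) / n, np.nan)
            mt, mm = t.sum(0) / n, m.sum(0) / n
            cov = (t * m).sum(0) / n - mt * mm
            vt = (t * t).sum(0) / n - mt * mt
            vm = (m * m).sum(0) / n - mm * mm
            r = cov / np.sqrt(vt * vm)
            r[(vt <= 0) | (vm <= 0)] = np.nan
        self._pv_cache = pd.DataFrame(
            {"maf": self.maf, "allele_cr": a_cr, "genotype_cr": g_cr, "r": r})
        return self._pv_cache

    def mean_per_variant_r(self) -> float:
        """Mean of per-variant R over variants where R is defined."""
        r = self.per_variant()["r"]
        return float(r.dropna().mean())


def pick_holdouts(panel_ids: list[str], pedigree: Pedigree, n: int = 4,
                  n_sires: int = 2, prefer_sex: str = "F") -> list[str]:
    """Choose leave-one-out animals with a sequenced parent in the panel.

    Mirrors the evaluation design of masking daughters of sequenced sires:
    holdouts are panel members whose sire is also in the panel, spread over
    at least ``n_sires`` different sires where possible, preferring
    ``prefer_sex`` offspring.
    """
    in_panel = set(panel_ids)
    by_sire: dict[str, list[str]] = {}
    for iid in panel_ids:
        if iid not in pedigree:
            continue
        sire, dam = pedigree.parents(iid)
        parent = sire if sire in in_panel else (dam if dam in in_panel else None)
        if parent is not None:
            by_sire.setdefault(parent, []).append(iid)
    for kids in by_sire.values():
        kids.sort(key=lambda i: (pedigree.entries[i].sex != prefer_sex, i))
    sires = sorted(by_sire, key=lambda s: -len(by_sire[s]))[:max(n_sires, 1)]
    chosen: list[str] = []
    k = 0
    while len(chosen) < n:
        advanced = False
        for s in sires:
            if k < len(by_sire[s]) and len(chosen) < n:
                chosen.append(by_sire[s][k])
                advanced = True
        if not advanced:
            break
        k += 1
    if len(chosen) < n:
        raise ValueError(f"only {len(chosen)} panel members have a sequenced parent")
    return chosen


def mask_to_array(seq: GenotypeMatrix, marker_idx: np.ndarray) -> GenotypeMatrix:
    """Set every non-array position missing; array positions untouched."""
    marker_idx = np.asarray(marker_idx)
    if marker_idx.size and (marker_idx.max() >= seq.n_variants or marker_idx.min() < 0):
        raise ValueError("marker indices out of range")
    dosage = np.full_like(seq.dosage, MISSING)
    dosage[:, marker_idx] = seq.dosage[:, marker_idx]
    return GenotypeMatrix(seq.sample_ids, seq.variants, dosage,
                          seq.gq, seq.dp)


def concordance_metrics(truth: np.ndarray, imputed: np.ndarray
                        ) -> tuple[float, float, float]:
    """(allele CR, genotype CR, Pearson R) over comparable calls.

    Pairs where either value is missing are excluded.  All three are NaN when
    no pair is comparable; R alone is NaN when either vector is constant.
    """
    truth = np.asarray(truth)
    imputed = np.asarray(imputed)
    if truth.shape != imputed.shape:
        raise ValueError("truth and imputed vectors differ in length")
    ok = (truth != MISSING) & (imputed != MISSING)
    t, m = truth[ok].astype(float), imputed[ok].astype(float)
    if len(t) == 0:
        return float("nan"), float("nan"), float("nan")
    genotype_cr = float((t == m).mean())
    allele_cr = float(((2.0 - np.abs(t - m)) / 2.0).mean())
    if t.std() == 0 or m.std() == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(t, m)[0, 1])
    return allele_cr, genotype_cr, r


def leave_one_out(
    panel: GenotypeMatrix,
    truth: GenotypeMatrix,
    holdouts: list[str],
    marker_idx: np.ndarray,
    spec: ReferencePanelSpec | None = None,
    pedigree: Pedigree | None = None,
    breed_map: dict[str, str] | None = None,
    window_schedule: tuple[int, ...] = (500, 100, 20),
    panel_haplotypes: np.ndarray | None = None,
    co_removed: dict[str, list[str]] | None = None,
) -> tuple[list[EvalReport], EvalReport]:
    """Mask each holdout to array density, impute from the rest, score vs truth.

    ``panel`` holds the reference genotypes (holdouts included), ``truth``
    the true sequence dosages of at least the holdout samples.  Returns one
    report per holdout and a pooled report.  Per-variant MAF is computed on
    the full panel before any removal.

    ``co_removed`` drops additional samples alongside each holdout — e.g.
    the holdout's dam, when the evaluation design mirrors daughters of
    sequenced sires whose dams were never sequenced.
    """
    co_removed = co_removed or {}
    spec = spec or ReferencePanelSpec()
    for h in holdouts:
        if h not in panel.sample_ids:
            raise ValueError(f"holdout {h!r} not in the panel")
        if h not in truth.sample_ids:
            raise ValueError(f"holdout {h!r} has no sequence truth")
    maf = panel.maf()

    scen = {"panel": spec.name, "pedigree": spec.use_pedigree,
            "n_markers": int(len(marker_idx))}
    reports: list[EvalReport] = []
    for h in holdouts:
        drop = {h, *co_removed.get(h, ())}
        keep = [s for s in panel.sample_ids if s not in drop]
        sub_panel = panel.subset_samples(keep)
        sub_haps = None
        if panel_haplotypes is not None:
            idx = panel.sample_index(keep)
            rows = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
            sub_haps = panel_haplotypes[rows]
        ref = build_panel(sub_panel, spec, breed_map)
        if sub_haps is not None and ref.sample_ids != sub_panel.sample_ids:
            idx = sub_panel.sample_index(ref.sample_ids)
            rows = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
            sub_haps = sub_haps[rows]
        imp = HaplotypeImputer(window_schedule, use_pedigree=spec.use_pedigree)
        imp.fit(ref, pedigree if spec.use_pedigree else None, haplotypes=sub_haps)

        target_truth = truth.subset_samples([h])
        masked = mask_to_array(target_truth, marker_idx)
        masked_sub = masked.subset_variants(marker_idx)
        imputed = imp.transform(masked_sub, pedigree if spec.use_pedigree else None)
        reports.append(EvalReport(
            truth=target_truth.dosage.astype(np.int8),
            imputed=imputed.dosage.astype(np.int8),
            maf=maf, scenario={**scen, "holdout": h},
        ))
        logger.info("leave-one-out %s: %s", h, reports[-1].aggregate())

    pooled = EvalReport(
        truth=np.vstack([r.truth for r in reports]),
        imputed=np.vstack([r.imputed for r in reports]),
        maf=maf, scenario={**scen, "holdout": "pooled"},
    )
    return reports, pooled


def bin_by_maf(report: EvalReport, bin_edges: np.ndarray | None = None) -> pd.DataFrame:
    """Unweighted per-bin means of per-variant allele CR, genotype CR and R.

    Default bins are width 0.01 over (0, 0.5].  Variants with undefined R
    are excluded from the R mean (their count is reported); empty bins are
    kept with NaN means and ``n_variants == 0``.
    """
    if bin_edges is None:
        bin_edges = np.round(np.arange(0.0, 0.51, 0.01), 10)
    bin_edges = np.asarray(bin_edges, dtype=float)
    pv = report.per_variant()
    seg = pv[report.maf > 0].copy()  # monomorphic panel variants carry no signal
    which = np.digitize(seg["maf"], bin_edges, right=True) - 1
    seg["bin"] = which
    rows = []
    for b in range(len(bin_edges) - 1):
        sub = seg[seg["bin"] == b]
        r_def = sub["r"].dropna()
        rows.append({
            "maf_low": bin_edges[b], "maf_high": bin_edges[b + 1],
            "n_variants": len(sub),
            "allele_cr": sub["allele_cr"].mean() if len(sub) else np.nan,
            "genotype_cr": sub["genotype_cr"].mean() if len(sub) else np.nan,
            "r": r_def.mean() if len(r_def) else np.nan,
            "n_r_defined": len(r_def),
        })
    return pd.DataFrame(rows)
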