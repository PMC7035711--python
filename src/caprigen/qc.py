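"""Sequence-panel quality control.

The filtering cascade mirrors standard practice for a low/medium-coverage
sequenced reference panel:

1. site-level: drop variants below a QUAL threshold;
2. call-level: set calls with genotype quality GQ < 8 or depth DP < 7 to
   missing (defaults chosen by comparing chip and sequence genotypes:
   mismatching calls have far lower GQ/DP than matching ones);
3. variant-level: drop variants with no alternate-allele observation left
   among the non-missing calls of the target breeds.

Chip genotypes at shared markers are treated as authoritative: sequence
calls are systematically replaced by non-missing chip calls, and the
per-individual chip/sequence concordance rate is the QC summary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix, VariantTable, logger

__all__ = [
    "FilterThresholds",
    "FilterReport",
    "CallFilter",
    "filter_calls",
    "chip_concordance",
    "override_with_chip",
    "shared_markers",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Cascade thresholds; call-level defaults are GQ >= 8 and DP >= 7."""

    min_qual: float = 30.0
    min_gq: int = 8
    min_dp: int = 7
    require_alt_in_breeds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_gq < 0 or self.min_dp < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class FilterReport:
    """Variant/call counts surviving each cascade stage, in order."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)  # (name, n_var, n_calls)
    concordance: dict[str, float] = field(default_factory=dict)

    def record(self, name: str, n_variants: int, n_calls: int) -> None:
        if self.stages and (n_variants > self.stages[-1][1] or n_calls > self.stages[-1][2]):
            raise ValueError("cascade counts must be non-increasing")
        self.stages.append((name, n_variants, n_calls))


def filter_calls(
    seq: GenotypeMatrix,
    thresholds: FilterThresholds | None = None,
    sample_breeds: dict[str, str] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the QUAL -> GQ/DP -> ALT-observation cascade.

    Calls lacking a GQ or DP value (sentinel) fail the call-level filter.
    Variants whose non-missing calls in the required breeds carry no
    alternate allele are removed; with no breed restriction, all samples
    count.  Filtering is idempotent.
    """
    t = thresholds or FilterThresholds()
    report = FilterReport()
    n_calls = int((seq.dosage != MISSING).sum())
    report.record("input", seq.n_variants, n_calls)

    keep = seq.variants.df["qual"].to_numpy() >= t.min_qual
    gm = seq.subset_variants(np.flatnonzero(keep))
    report.record("site_qual", gm.n_variants, int((gm.dosage != MISSING).sum()))

    if gm.gq is None or gm.dp is None:
        raise ValueError("GQ and DP planes are required for call-level filtering")
    dosage = gm.dosage.copy()
    bad = (gm.gq < t.min_gq) | (gm.dp < t.min_dp)
    dosage[bad] = MISSING
    gm = GenotypeMatrix(gm.sample_ids, gm.variants, dosage, gm.gq, gm.dp)
    report.record("call_gq_dp", gm.n_variants, int((dosage != MISSING).sum()))

    # recompute ALT observations from the cleaned calls
    obs = np.where(dosage != MISSING, dosage, 0)
    breeds = t.require_alt_in_breeds or None
    if breeds:
        if sample_breeds is None:
            raise ValueError("breed-restricted ALT filtering needs sample_breeds")
        labels = np.array([sample_breeds.get(s, "unknown") for s in gm.sample_ids])
        mask = np.isin(labels, breeds)
        if not mask.any():
            raise ValueError(f"no samples belong to breeds {breeds}")
        alt_count = obs[mask].sum(axis=0)
    else:
        alt_count = obs.sum(axis=0)
    keep_alt = alt_count > 0
    gm = gm.subset_variants(np.flatnonzero(keep_alt))
    report.record("alt_observed", gm.n_variants, int((gm.dosage != MISSING).sum()))
    if gm.n_variants == 0:
        logger.warning("filter cascade removed every variant")
    return gm, report


class CallFilter:
    """Estimator-style wrapper over :func:`filter_calls`.

    ``transform`` applies the cascade; ``report_`` holds the stage counts of
    the last call.  Parameters follow the scikit-learn convention.
    """

    def __init__(self, min_qual: float = 30.0, min_gq: int = 8, min_dp: int = 7,
                 require_alt_in_breeds: tuple[str, ...] = ()):
        self.min_qual = min_qual
        self.min_gq = min_gq
        self.min_dp = min_dp
        self.require_alt_in_breeds = require_alt_in_breeds

    def get_params(self, deep: bool = True) -> dict:
        return {
            "min_qual": self.min_qual, "min_gq": self.min_gq,
            "min_dp": self.min_dp, "require_alt_in_breeds": self.require_alt_in_breeds,
        }

    def set_params(self, **params) -> "CallFilter":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, seq: GenotypeMatrix, y=None) -> "CallFilter":
        return self

    def transform(self, seq: GenotypeMatrix,
                  sample_breeds: dict[str, str] | None = None) -> GenotypeMatrix:
        out, self.report_ = filter_calls(
            seq,
            FilterThresholds(self.min_qual, self.min_gq, self.min_dp,
                             tuple(self.require_alt_in_breeds)),
            sample_breeds,
        )
        return out

    def fit_transform(self, seq: GenotypeMatrix, y=None) -> GenotypeMatrix:
        return self.fit(seq).transform(seq)


def shared_markers(a: VariantTable, b: VariantTable) -> tuple[np.ndarray, np.ndarray]:
    """Indices into a and b of markers shared by (chrom, pos, ref, alt)."""
    ka, kb = a.key(), b.key()
    common = ka.intersection(kb)
    ia = ka.get_indexer(common)
    ib = kb.get_indexer(common)
    return ia.astype(np.intp), ib.astype(np.intp)


def chip_concordance(seq: GenotypeMatrix, chip: GenotypeMatrix) -> dict[str, float]:
    """Per-individual fraction of shared non-missing markers with equal dosage.

    Individuals without a chip record or without any comparable call are
    excluded (logged).  Returns id -> rate; the mean/SD summary is left to
    the caller (``np.mean``/``np.std`` over values).
    """
    ia, ib = shared_markers(seq.variants, chip.variants)
    if len(ia) == 0:
        raise ValueError("no shared markers between sequence and chip data")
    chip_lookup = {s: i for i, s in enumerate(chip.sample_ids)}
    rates: dict[str, float] = {}
    for i, sid in enumerate(seq.sample_ids):
        j = chip_lookup.get(sid)
        if j is None:
            continue
        s = seq.dosage[i, ia]
        c = chip.dosage[j, ib]
        comparable = (s != MISSING) & (c != MISSING)
        n = int(comparable.sum())
        if n == 0:
            logger.info("individual %s has no comparable chip/sequence calls", sid)
            continue
        rates[sid] = float((s[comparable] == c[comparable]).mean())
    return rates


def override_with_chip(seq: GenotypeMatrix, chip: GenotypeMatrix) -> GenotypeMatrix:
    """Replace sequence calls by chip calls at shared markers.

    Non-missing chip dosages overwrite the sequence dosage (chip genotyping
    is the more reliable assay at these markers); everything else is
    untouched.  Idempotent.
    """
    ia, ib = shared_markers(seq.variants, chip.variants)
    out = seq.copy()
    chip_lookup = {s: i for i, s in enumerate(chip.sample_ids)}
    for i, sid in enumerate(seq.sample_ids):
        j = chip_lookup.get(sid)
        if j is None:
            continue
        c = chip.dosage[j, ib]
        ok = c != MISSING
        out.dosage[i, ia[ok]] = c[ok]
    return out
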