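"""Genotype/allele benchmarking: matching, stratification, PR curves, concordance.

Calls are compared to truth inside confident regions in two modes.
*Genotype* mode requires the exact allele-dosage multiset at a site; a call
at a truth site with the wrong dosage is a genotype error and is counted as
both a false positive (the call) and a false negative (the truth), mirroring
how combine-mode benchmarking annotates FP_CA/FN_CA pairs.  *Allele* mode
(the "squash-ploidy" comparison) only requires the called variant allele to
exist in truth, regardless of copy number.

Error structure is summarized by genotype-class stratifications ("AAaa"
labels for biallelic records), the copy-number error spectrum (called minus
true dosage), GQ-ranked precision-recall curves, and multi-callset
concordance tables over distinct (site, genotype) or (site, allele) keys.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genotype_model import genotype_class_label

__all__ = [
    "VcfRecord",
    "MatchRecord",
    "PRF",
    "PRPoint",
    "ConcordanceTable",
    "match_callset",
    "prf",
    "stratify_fp_by_called_genotype",
    "fn_rate_by_true_genotype",
    "copy_number_error_spectrum",
    "pr_curve",
    "concordance",
    "normalize_records",
]


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VcfRecord:
    """One VCF data line on the supported feature subset.

    ``position`` is 0-based internally; ``genotype`` holds allele indices
    (0 = ref) of arbitrary ploidy, phase-ordered when ``phased``.
    """

    contig: str
    position: int
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, ...]
    phased: bool = False
    gq: float | None = None
    dp: int | None = None
    ad: tuple[int, ...] | None = None
    ps: int | None = None
    qual: float | None = None
    record_id: str = "."

    @property
    def ploidy(self) -> int:
        return len(self.genotype)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    def allele_multiset(self) -> Counter:
        """Dosage multiset over allele sequences — genotype identity."""
        return Counter(self.alleles[a] for a in self.genotype)

    def alt_dosage(self, alt: str | None = None) -> int:
        """Copy count of ``alt`` (default: the single alt of a biallelic record)."""
        if alt is None:
            if len(self.alts) != 1:
                raise ValueError("alt_dosage() without argument requires a biallelic record")
            alt = self.alts[0]
        if alt not in self.alts:
            return 0
        idx = 1 + self.alts.index(alt)
        return sum(1 for a in self.genotype if a == idx)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


@dataclass
class MatchRecord:
    """Classification of one site (genotype mode) or one allele (allele mode).

    status: TP | FP | FN | GE | OUTSIDE.  A GE (genotype error) carries both
    the truth and the called genotype and counts as one FP and one FN.
    """

    contig: str
    position: int
    status: str
    truth: VcfRecord | None = None
    call: VcfRecord | None = None
    allele: str | None = None  # set in allele mode
    score: float | None = None
    ploidy_mismatch: bool = False

    @property
    def is_error(self) -> bool:
        return self.status in ("FP", "FN", "GE")


def _in_regions(pos: int, regions: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in regions)


def _index_by_position(records: Iterable[VcfRecord], label: str) -> dict[tuple[str, int], VcfRecord]:
    out: dict[tuple[str, int], VcfRecord] = {}
    for rec in records:
        key = (rec.contig, rec.position)
        if key in out:
            raise ValueError(
                f"duplicate {label} record at {rec.contig}:{rec.position + 1}; "
                "normalize (left-align/decompose) inputs first"
            )
        out[key] = rec
    return out


def match_callset(
    calls: Sequence[VcfRecord],
    truth: Sequence[VcfRecord],
    regions: Sequence[tuple[int, int]],
    mode: str = "genotype",
) -> list[MatchRecord]:
    """Classify calls against truth within ``regions``; order-independent.

    Genotype mode: TP needs identical allele-dosage multisets; wrong dosage
    at a truth site is a single GE record (one FP plus one FN).  A ploidy
    mismatch between call and truth is a GE with ``ploidy_mismatch`` set.
    Allele mode: one record per (site, alt allele); TP when the called alt
    exists in truth at that site with dosage >= 1.
    """
    if mode not in ("genotype", "allele"):
        raise ValueError(f"unknown mode {mode!r}")
    call_idx = _index_by_position(calls, "call")
    truth_idx = _index_by_position(truth, "truth")
    out: list[MatchRecord] = []

    keys = sorted(set(call_idx) | set(truth_idx))
    for key in keys:
        contig, pos = key
        call = call_idx.get(key)
        tr = truth_idx.get(key)
        if not _in_regions(pos, regions):
            out.append(MatchRecord(contig, pos, "OUTSIDE", truth=tr, call=call))
            continue
        if mode == "genotype":
            if call is not None and tr is not None:
                if call.allele_multiset() == tr.allele_multiset():
                    status = "TP"
                else:
                    status = "GE"
                out.append(
                    MatchRecord(
                        contig, pos, status, truth=tr, call=call, score=call.gq,
                        ploidy_mismatch=(call.ploidy != tr.ploidy),
                    )
                )
            elif call is not None:
                out.append(MatchRecord(contig, pos, "FP", call=call, score=call.gq))
            else:
                out.append(MatchRecord(contig, pos, "FN", truth=tr))
        else:
            called_alts = {a for a in call.alts if call.alt_dosage(a) >= 1} if call else set()
            truth_alts = {a for a in tr.alts if tr.alt_dosage(a) >= 1} if tr else set()
            for allele in sorted(called_alts | truth_alts):
                if allele in called_alts and allele in truth_alts:
                    status = "TP"
                elif allele in called_alts:
                    status = "FP"
                else:
                    status = "FN"
                out.append(
                    MatchRecord(
                        contig, pos, status, truth=tr, call=call, allele=allele,
                        score=call.gq if call is not None else None,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Summary metrics
# ---------------------------------------------------------------------------

@dataclass
class PRF:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float


def _counts(matches: Iterable[MatchRecord]) -> tuple[int, int, int]:
    tp = fp = fn = 0
    for m in matches:
        if m.status == "TP":
            tp += 1
        elif m.status == "FP":
            fp += 1
        elif m.status == "FN":
            fn += 1
        elif m.status == "GE":  # one false call plus one missed truth
            fp += 1
            fn += 1
    return tp, fp, fn


def prf(matches: Iterable[MatchRecord]) -> PRF:
    """Precision, recall (sensitivity) and harmonic-mean F.

    Undefined ratios (empty denominator) are NaN, never 0.
    """
    tp, fp, fn = _counts(matches)
    precision = tp / (tp + fp) if tp + fp else math.nan
    recall = tp / (tp + fn) if tp + fn else math.nan
    if math.isnan(precision) or math.isnan(recall):
        f = math.nan
    elif precision + recall == 0:
        f = 0.0
    else:
        f = 2 * precision * recall / (precision + recall)
    return PRF(tp, fp, fn, precision, recall, f)


def stratify_fp_by_called_genotype(
    matches: Iterable[MatchRecord], ploidy: int
) -> dict[str, int]:
    """False-positive counts keyed by the called biallelic genotype class.

    Includes genotype-error records (keyed by the *called* class); restricted
    to biallelic calls with nonzero alt dosage.
    """
    table: Counter = Counter()
    for m in matches:
        if m.status not in ("FP", "GE") or m.call is None or not m.call.is_biallelic:
            continue
        c = m.call.alt_dosage()
        if 0 < c <= ploidy:
            table[genotype_class_label(c, ploidy)] += 1
    return dict(table)


def fn_rate_by_true_genotype(
    matches: Sequence[MatchRecord],
    ploidy: int,
    truth_prevalence: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """Missed-truth rate per true biallelic genotype class.

    rate(class) = (FN + GE with that truth class) / prevalence(class), with
    prevalence taken from the evaluated truth records unless supplied.
    Zero-prevalence classes are omitted.
    """
    if truth_prevalence is None:
        prev: Counter = Counter()
        for m in matches:
            if m.status in ("TP", "FN", "GE") and m.truth is not None and m.truth.is_biallelic:
                c = m.truth.alt_dosage()
                if 0 < c <= ploidy:
                    prev[genotype_class_label(c, ploidy)] += 1
        truth_prevalence = prev
    missed: Counter = Counter()
    for m in matches:
        if m.status in ("FN", "GE") and m.truth is not None and m.truth.is_biallelic:
            c = m.truth.alt_dosage()
            if 0 < c <= ploidy:
                missed[genotype_class_label(c, ploidy)] += 1
    return {
        label: missed.get(label, 0) / n
        for label, n in truth_prevalence.items()
        if n > 0
    }


@dataclass
class CopyNumberSpectrum:
    histogram: dict[int, int]  # delta = called - true dosage, delta != 0
    fraction_minus_one: float
    fraction_plus_one: float


def copy_number_error_spectrum(matches: Iterable[MatchRecord]) -> CopyNumberSpectrum:
    """Histogram of dosage errors Delta = called - true variant-allele dosage."""
    hist: Counter = Counter()
    for m in matches:
        if m.status != "GE" or m.call is None or m.truth is None:
            continue
        if not (m.call.is_biallelic and m.truth.is_biallelic):
            continue
        if m.call.alts != m.truth.alts:
            continue
        delta = m.call.alt_dosage() - m.truth.alt_dosage()
        if delta != 0:
            hist[delta] += 1
    total = sum(hist.values())
    return CopyNumberSpectrum(
        histogram=dict(sorted(hist.items())),
        fraction_minus_one=hist.get(-1, 0) / total if total else math.nan,
        fraction_plus_one=hist.get(1, 0) / total if total else math.nan,
    )


@dataclass
class PRPoint:
    threshold: float
    precision: float
    recall: float


def pr_curve(matches: Sequence[MatchRecord], score_field: str = "score") -> list[PRPoint]:
    """(precision, recall) at each distinct score threshold, descending.

    Calls with score >= threshold are kept; dropped TP calls become false
    negatives.  Every call must carry a finite score.
    """
    called = [m for m in matches if m.status in ("TP", "FP", "GE")]
    missing = [
        m for m in called
        if getattr(m, score_field) is None or not math.isfinite(getattr(m, score_field))
    ]
    if missing:
        where = ", ".join(f"{m.contig}:{m.position + 1}" for m in missing[:5])
        raise ValueError(f"records without a finite {score_field}: {where}")
    n_truth = sum(1 for m in matches if m.status in ("TP", "FN", "GE"))
    thresholds = sorted({getattr(m, score_field) for m in called}, reverse=True)
    points: list[PRPoint] = []
    for t in thresholds:
        kept = [m for m in called if getattr(m, score_field) >= t]
        tp = sum(1 for m in kept if m.status == "TP")
        fp = sum(1 for m in kept if m.status in ("FP", "GE"))
        fn = n_truth - tp
        precision = tp / (tp + fp) if tp + fp else math.nan
        recall = tp / (tp + fn) if tp + fn else math.nan
        points.append(PRPoint(t, precision, recall))
    return points


# ---------------------------------------------------------------------------
# Multi-callset concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceTable:
    """Intersection-subset counts over distinct variant keys.

    ``subset_counts`` maps a frozenset of callset keys to the number of
    distinct (site, genotype) [or (site, allele)] keys found in exactly that
    subset of callsets; counts sum to ``total``.  ``discordance`` (when
    callset keys are (caller, dataset) pairs) counts, per caller, keys
    present in exactly one of its two datasets.
    """

    subset_counts: dict[frozenset, int]
    total: int
    per_callset_totals: dict
    discordance: dict[str, int] | None = None


def _variant_keys(records: Iterable[VcfRecord], mode: str) -> set[tuple]:
    keys: set[tuple] = set()
    for rec in records:
        if mode == "genotype":
            ms = tuple(sorted(rec.allele_multiset().items()))
            keys.add((rec.contig, rec.position, rec.ref, ms))
        else:
            for alt in rec.alts:
                if rec.alt_dosage(alt) >= 1:
                    keys.add((rec.contig, rec.position, rec.ref, alt))
    return keys


def concordance(
    callsets: Mapping, mode: str = "genotype", paired: bool | None = None
) -> ConcordanceTable:
    """Assign every distinct variant key to its callset-membership subset.

    With (caller, dataset) callset keys and two datasets per caller
    (``paired`` defaults to true in that case), per-caller discordance
    between the paired datasets is also reported.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two callsets")
    if mode not in ("genotype", "allele"):
        raise ValueError(f"unknown mode {mode!r}")
    keysets = {k: _variant_keys(v, mode) for k, v in callsets.items()}

    membership: dict[tuple, set] = {}
    for cs_key, keys in keysets.items():
        for key in keys:
            membership.setdefault(key, set()).add(cs_key)
    subset_counts: Counter = Counter(frozenset(v) for v in membership.values())

    pairable = all(isinstance(k, tuple) and len(k) == 2 for k in callsets)
    if paired is None:
        paired = pairable
    discordance = None
    if paired:
        if not pairable:
            raise ValueError("discordance requires (caller, dataset) callset keys")
        callers: dict[str, list] = {}
        for caller, dataset in callsets:
            callers.setdefault(caller, []).append(dataset)
        for caller, datasets in callers.items():
            if len(datasets) != 2:
                raise ValueError(f"caller {caller!r} does not have exactly two datasets")
        discordance = {}
        for caller, (d1, d2) in callers.items():
            s1, s2 = keysets[(caller, d1)], keysets[(caller, d2)]
            discordance[caller] = len(s1 ^ s2)

    return ConcordanceTable(
        subset_counts=dict(subset_counts),
        total=len(membership),
        per_callset_totals={k: len(v) for k, v in keysets.items()},
        discordance=discordance,
    )


# ---------------------------------------------------------------------------
# Normalization of imported records
# ---------------------------------------------------------------------------

def normalize_records(
    records: Sequence[VcfRecord], reference: str | None = None
) -> list[VcfRecord]:
    """Trim shared bases and left-align biallelic indels.

    Shared suffix then prefix bases between ref and all alts are trimmed
    (position advanced by the prefix trim).  Biallelic indels are shifted
    left while the base preceding the event equals the last base of the
    longer allele, when a reference sequence is supplied.  Multi-allelic
    records are only jointly trimmed.
    """
    out: list[VcfRecord] = []
    for rec in records:
        ref, alts, pos = rec.ref, list(rec.alts), rec.position
        # joint suffix trim
        while len(ref) > 1 and all(len(a) > 1 for a in alts) and all(
            a[-1] == ref[-1] for a in alts
        ):
            ref = ref[:-1]
            alts = [a[:-1] for a in alts]
        # joint prefix trim
        while len(ref) > 1 and all(len(a) > 1 for a in alts) and all(
            a[0] == ref[0] for a in alts
        ):
            ref = ref[1:]
            alts = [a[1:] for a in alts]
            pos += 1
        if reference is not None and len(alts) == 1 and len(ref) != len(alts[0]):
            ref, alt, pos = _shift_left(ref, alts[0], pos, reference)
            alts = [alt]
        out.append(
            VcfRecord(
                rec.contig, pos, ref, tuple(alts), rec.genotype, rec.phased,
                rec.gq, rec.dp, rec.ad, rec.ps, rec.qual, rec.record_id,
            )
        )
    return sorted(out, key=lambda r: (r.contig, r.position))


def _shift_left(ref: str, alt: str, pos: int, reference: str) -> tuple[str, str, int]:
    """Left-align an indel: truncate equal trailing bases, extending left
    through the reference whenever the anchor base is consumed."""
    while (len(ref) > 1 or len(alt) > 1) and ref[-1] == alt[-1]:
        if len(ref) == 1 or len(alt) == 1:
            if pos == 0:
                break
            ref = reference[pos - 1] + ref[:-1]
            alt = reference[pos - 1] + alt[:-1]
            pos -= 1
        else:
            ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return ref, alt, pos
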