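"""Score predicted SCNA segments against a gold standard.

Three metric families are implemented:

- nucleotide: TP/PP/GP are base counts of same-type interval unions and their
  intersections; precision = TP/PP, sensitivity = TP/GP.
- interval: TP counts predicted intervals overlapping the union of same-type
  gold intervals by >= threshold of their own length; TD counts gold intervals
  covered >= threshold of their length by the union of same-type predictions;
  precision = TP/PP, sensitivity = TD/GP.
- gene: PP/GP are the sets of (gene, type) pairs covered >= threshold of the
  gene length by predicted/gold segments; TP is their intersection.

Thresholds are inclusive (>= 0.8 by default). Matching is by type (amp/del)
only. Zero denominators yield None ("NA") rather than 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from scnabench import intervals as iv
from scnabench.errors import ConfigError, DataError

SEG_TYPES = ("amp", "del")

DEFAULT_AF_BINS = (0.0, 0.1, 0.2, 0.3, 0.4, 1.0)
DEFAULT_SIZE_BINS = (0, 1_000, 10_000, 100_000, 1_000_000, 10_000_000, 100_000_000)


@dataclass(frozen=True)
class Segment:
    """A typed copy-number segment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    type: str
    attrs: tuple = ()

    def __post_init__(self):
        if self.start >= self.end:
            raise DataError(
                f"segment requires start < end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.type not in SEG_TYPES:
            raise DataError(f"segment type must be amp or del, got {self.type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MetricReport:
    """TP/PP/GP (and TD for the interval approach) with derived rates."""

    approach: str
    tp: int
    pp: int
    gp: int
    td: int | None = None

    @property
    def precision(self) -> float | None:
        return self.tp / self.pp if self.pp else None

    @property
    def sensitivity(self) -> float | None:
        if not self.gp:
            return None
        num = self.td if self.approach == "interval" else self.tp
        return num / self.gp

    def as_dict(self) -> dict:
        return {
            "approach": self.approach,
            "TP": self.tp,
            "PP": self.pp,
            "GP": self.gp,
            "TD": self.td,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
        }


def _union_by_type(segments: Sequence[Segment], stype: str) -> dict[str, np.ndarray]:
    return iv.merge_by_chrom(
        (s.chrom, s.start, s.end) for s in segments if s.type == stype
    )


def _segment_union_overlap(seg: Segment, union: dict[str, np.ndarray]) -> int:
    arr = union.get(seg.chrom)
    if arr is None:
        return 0
    return iv.interval_overlap(seg.start, seg.end, arr)


# ---------------------------------------------------------------------------
# Target restriction
# ---------------------------------------------------------------------------


def restrict_to_targets(
    segments: Sequence[Segment],
    targets: dict[str, np.ndarray],
    mode: str = "clip",
) -> list[Segment]:
    """Keep only the target-space part of a call/gold set.

    ``clip`` intersects each segment with target space (possibly splitting it;
    used for nucleotide metrics); ``filter`` keeps segments overlapping any
    target by >= 1 bp unchanged (used for interval and gene metrics).
    """
    if mode not in ("clip", "filter"):
        raise ConfigError(f"unknown restriction mode {mode!r}")
    merged = {c: iv.merge(a) for c, a in targets.items()}
    out: list[Segment] = []
    for seg in segments:
        arr = merged.get(seg.chrom)
        if arr is None or len(arr) == 0:
            continue
        if mode == "filter":
            if iv.interval_overlap(seg.start, seg.end, arr) >= 1:
                out.append(seg)
        else:
            for s, e in iv.clip_interval(seg.start, seg.end, arr):
                out.append(Segment(seg.chrom, s, e, seg.type, seg.attrs))
    return out


# ---------------------------------------------------------------------------
# Metric families
# ---------------------------------------------------------------------------


def nucleotide_metrics(
    gold: Sequence[Segment], pred: Sequence[Segment]
) -> MetricReport:
    """Base-count agreement of same-type interval unions."""
    tp = pp = gp = 0
    for stype in SEG_TYPES:
        gold_u = _union_by_type(gold, stype)
        pred_u = _union_by_type(pred, stype)
        gp += sum(iv.total_length(a) for a in gold_u.values())
        pp += sum(iv.total_length(a) for a in pred_u.values())
        for chrom, parr in pred_u.items():
            garr = gold_u.get(chrom)
            if garr is not None:
                tp += iv.total_length(iv.intersect(parr, garr))
    return MetricReport("nucleotide", tp, pp, gp)


def interval_metrics(
    gold: Sequence[Segment], pred: Sequence[Segment], threshold: float = 0.8
) -> MetricReport:
    """Reciprocal-style interval agreement at an inclusive coverage threshold.

    Overlap denominators use the union of same-type counterpart segments, so
    several small predictions jointly covering one large gold interval count
    that gold interval as discovered once.
    """
    if not (0.0 < threshold <= 1.0):
        raise ConfigError("threshold must lie in (0, 1]")
    tp = 0
    for stype in SEG_TYPES:
        gold_u = _union_by_type(gold, stype)
        for seg in pred:
            if seg.type == stype:
                if _segment_union_overlap(seg, gold_u) >= threshold * seg.length:
                    tp += 1
    td = 0
    for stype in SEG_TYPES:
        pred_u = _union_by_type(pred, stype)
        for seg in gold:
            if seg.type == stype:
                if _segment_union_overlap(seg, pred_u) >= threshold * seg.length:
                    td += 1
    return MetricReport("interval", tp, len(pred), len(gold), td=td)


def _covered_genes(
    segments: Sequence[Segment],
    gene_model: pd.DataFrame,
    threshold: float,
) -> set[tuple[str, str]]:
    """(gene, type) pairs where same-type segments cover >= threshold of the
    gene length."""
    out = set()
    for stype in SEG_TYPES:
        union = _union_by_type(segments, stype)
        for row in gene_model.itertuples(index=False):
            arr = union.get(row.chrom)
            if arr is None:
                continue
            covered = iv.interval_overlap(row.start, row.end, arr)
            if covered >= threshold * (row.end - row.start):
                out.add((row.name, stype))
    return out


def _check_gene_model(gene_model: pd.DataFrame) -> None:
    required = {"chrom", "start", "end", "name"}
    if gene_model is None or len(gene_model) == 0:
        raise DataError("gene model is empty")
    if not required.issubset(gene_model.columns):
        raise DataError(f"gene model requires columns {sorted(required)}")
    if gene_model["name"].duplicated().any():
        raise DataError("gene names must be unique")


def gene_metrics(
    gold: Sequence[Segment],
    pred: Sequence[Segment],
    gene_model: pd.DataFrame,
    threshold: float = 0.8,
) -> MetricReport:
    """Gene-level agreement: genes covered >= threshold by same-type segments."""
    if not (0.0 < threshold <= 1.0):
        raise ConfigError("threshold must lie in (0, 1]")
    _check_gene_model(gene_model)
    pp_set = _covered_genes(pred, gene_model, threshold)
    gp_set = _covered_genes(gold, gene_model, threshold)
    return MetricReport("gene", len(pp_set & gp_set), len(pp_set), len(gp_set))


def evaluate_all(
    gold: Sequence[Segment],
    pred: Sequence[Segment],
    targets: dict[str, np.ndarray] | None = None,
    gene_model: pd.DataFrame | None = None,
    threshold: float = 0.8,
    types: Sequence[str] | None = None,
) -> list[MetricReport]:
    """Run every applicable metric family, with target restriction applied
    per family (clip for nucleotide, >= 1 bp filter for interval/gene).
    Restrict ``types`` to score deletions or amplifications alone."""
    if types:
        gold = [s for s in gold if s.type in types]
        pred = [s for s in pred if s.type in types]
    if targets is not None:
        gold_clip = restrict_to_targets(gold, targets, "clip")
        pred_clip = restrict_to_targets(pred, targets, "clip")
        gold_filt = restrict_to_targets(gold, targets, "filter")
        pred_filt = restrict_to_targets(pred, targets, "filter")
    else:
        gold_clip, pred_clip = list(gold), list(pred)
        gold_filt, pred_filt = list(gold), list(pred)
    reports = [
        nucleotide_metrics(gold_clip, pred_clip),
        interval_metrics(gold_filt, pred_filt, threshold),
    ]
    if gene_model is not None and len(gene_model):
        reports.append(gene_metrics(gold_filt, pred_filt, gene_model, threshold))
    return reports


# ---------------------------------------------------------------------------
# Stratified analyses
# ---------------------------------------------------------------------------


def stratify_sensitivity_by_af(
    gold: Sequence[Segment],
    af: Sequence[float],
    pred: Sequence[Segment],
    bins: Sequence[float] = DEFAULT_AF_BINS,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Per-AF-bin sensitivity; detection uses the interval-approach TD rule
    (gold interval covered >= threshold by the union of same-type calls).
    Bins are half-open on AF except the last, which includes its upper edge."""
    if len(gold) != len(af):
        raise DataError("one allele fraction per gold segment required")
    unions = {t: _union_by_type(pred, t) for t in SEG_TYPES}
    edges = list(bins)
    n_gold = [0] * (len(edges) - 1)
    n_det = [0] * (len(edges) - 1)
    for seg, a in zip(gold, af):
        b = None
        for i in range(len(edges) - 1):
            last = i == len(edges) - 2
            if edges[i] <= a < edges[i + 1] or (last and a == edges[i + 1]):
                b = i
                break
        if b is None:
            continue
        n_gold[b] += 1
        if _segment_union_overlap(seg, unions[seg.type]) >= threshold * seg.length:
            n_det[b] += 1
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "n_gold": n_gold,
            "n_detected": n_det,
            "sensitivity": [
                d / g if g else math.nan for d, g in zip(n_det, n_gold)
            ],
        }
    )


def _size_bin_labels(edges: Sequence[int]) -> list[str]:
    def fmt(x):
        for unit, div in (("Gb", 10**9), ("Mb", 10**6), ("Kb", 10**3)):
            if x >= div:
                return f"{x // div}{unit}"
        return f"{x}b"

    labels = [f"<{fmt(edges[1])}"]
    for lo, hi in zip(edges[1:-1], edges[2:]):
        labels.append(f"{fmt(lo)}-{fmt(hi)}")
    labels.append(f">={fmt(edges[-1])}")
    return labels


def stratify_by_size(
    gold: Sequence[Segment],
    pred: Sequence[Segment],
    size_bins: Sequence[int] = DEFAULT_SIZE_BINS,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Length-class table per type: gold counts, called counts, and called
    true positives. A called segment is TP if it overlaps the union of
    same-type gold by >= threshold of its own length — regardless of the size
    class of the matching gold event."""
    edges = list(size_bins)
    labels = _size_bin_labels(edges)
    upper = edges[1:] + [math.inf]

    def bin_of(length: int) -> int:
        for i, (lo, hi) in enumerate(zip(edges, upper)):
            if lo <= length < hi:
                return i
        return len(labels) - 1

    rows = []
    for stype in SEG_TYPES:
        gold_u = _union_by_type(gold, stype)
        n_gold = [0] * len(labels)
        n_called = [0] * len(labels)
        n_tp = [0] * len(labels)
        for seg in gold:
            if seg.type == stype:
                n_gold[bin_of(seg.length)] += 1
        for seg in pred:
            if seg.type != stype:
                continue
            b = bin_of(seg.length)
            n_called[b] += 1
            if _segment_union_overlap(seg, gold_u) >= threshold * seg.length:
                n_tp[b] += 1
        for i, label in enumerate(labels):
            rows.append(
                {
                    "type": stype,
                    "size_class": label,
                    "n_gold": n_gold[i],
                    "n_called": n_called[i],
                    "n_called_tp": n_tp[i],
                }
            )
    return pd.DataFrame(rows)


def gene_count_log_ratio(
    gold: Sequence[Segment],
    pred: Sequence[Segment],
    gene_model: pd.DataFrame,
    threshold: float = 0.8,
    pseudocount: float | None = None,
    low_scna_cutoff: int = 10,
    log_base: float = 2.0,
) -> dict:
    """Concordance of copy-number-altered gene counts.

    ratio = log(#predicted altered genes / #gold altered genes); None when
    either count is zero and no pseudocount is given. ``low_scna`` flags
    samples with <= ``low_scna_cutoff`` gold SCNAs.
    """
    _check_gene_model(gene_model)
    n_pred = len({g for g, _ in _covered_genes(pred, gene_model, threshold)})
    n_gold = len({g for g, _ in _covered_genes(gold, gene_model, threshold)})
    if pseudocount is not None:
        num, den = n_pred + pseudocount, n_gold + pseudocount
        ratio = math.log(num / den, log_base)
    elif n_pred == 0 or n_gold == 0:
        ratio = None
    else:
        ratio = math.log(n_pred / n_gold, log_base)
    return {
        "log_ratio": ratio,
        "n_pred_genes": n_pred,
        "n_gold_genes": n_gold,
        "low_scna": len(gold) <= low_scna_cutoff,
    }


# ---------------------------------------------------------------------------
# Segment I/O
# ---------------------------------------------------------------------------


def read_segments_bed(path) -> list[Segment]:
    """Read 'chrom start end type' BED-like TSV (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise DataError(f"segment line needs >= 4 columns: {line!r}")
            chrom, start, end, stype = fields[:4]
            stype = stype.lower()
            if stype in ("amplification", "gain", "dup", "duplication"):
                stype = "amp"
            if stype in ("deletion", "loss"):
                stype = "del"
            out.append(Segment(chrom, int(start), int(end), stype))
    return out


def read_seg(path, neutral_threshold: float = 0.0) -> list[Segment]:
    """Read a SEG file (1-based inclusive; ID chrom start end [num.mark] seg.mean)
    and type segments by the sign of the mean log ratio. Segments with
    |seg.mean| <= neutral_threshold are dropped as copy-neutral."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if header and not header.lower().lstrip("'\"").startswith(("id", "sample", "track")):
            fh.seek(0)
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise DataError(f"SEG line needs >= 5 columns: {line!r}")
            chrom = fields[1]
            start = int(float(fields[2])) - 1  # to 0-based half-open
            end = int(float(fields[3]))
            mean = float(fields[-1])
            if abs(mean) <= neutral_threshold:
                continue
            out.append(Segment(chrom, start, end, "amp" if mean > 0 else "del"))
    return out


def write_segments_bed(segments: Sequence[Segment], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\ttype\n")
        for s in sorted(segments, key=lambda s: (s.chrom, s.start, s.end)):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.type}\n")


def reports_to_frame(reports: Sequence[MetricReport], **extra) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = dict(extra)
        row.update(r.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def segments_from_truth(records) -> list[Segment]:
    """Somatic CNV truth records -> typed gold segments."""
    return [Segment(r.chrom, r.start, r.end, r.scna_type) for r in records]
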