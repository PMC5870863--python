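"""Capture-aware paired-end read simulation from a haplotype genome.

Mimics the laboratory workflow of targeted sequencing: random shearing into
fragments, in-silico probe capture against padded target intervals with a
GC-dependent retention weight, and paired-end read emission with a simple
substitution error model. Read names carry truth tags (haplotype coordinates
and reference projections) so downstream depth computation is alignment-free.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from scnabench import intervals as iv
from scnabench.errors import ConfigError, DataError
from scnabench.genome_forge import HaplotypeGenome, reverse_complement

_RETRY_CAP = 100


@dataclass(frozen=True)
class FragmentModel:
    """Shearing model: fixed read length, truncated-normal insert size."""

    read_length: int = 101
    insert_mean: float = 300.0
    insert_sd: float = 50.0

    def __post_init__(self):
        if self.read_length < 1:
            raise ConfigError("read_length must be >= 1")
        if self.insert_mean < self.read_length:
            raise ConfigError("insert_mean must be >= read_length")
        if self.insert_sd < 0:
            raise ConfigError("insert_sd must be >= 0")


@dataclass(frozen=True)
class GCBias:
    """Gaussian retention weight of fragment GC with a floor: weights in (0, 1]."""

    center: float = 0.45
    width: float = 0.15
    floor: float = 0.1

    def __post_init__(self):
        if not (0.0 < self.floor <= 1.0):
            raise ConfigError("GC bias floor must lie in (0, 1]")
        if self.width <= 0:
            raise ConfigError("GC bias width must be > 0")

    def __call__(self, gc):
        z = (np.asarray(gc, dtype=float) - self.center) / self.width
        w = self.floor + (1.0 - self.floor) * np.exp(-0.5 * z * z)
        return float(w) if np.isscalar(gc) else w


@dataclass(frozen=True)
class UniformBias:
    """gc_bias stand-in with no GC dependence (retention weight 1)."""

    def __call__(self, gc: float) -> float:
        return 1.0


@dataclass
class CaptureModel:
    """Probe capture: padded reference targets plus a GC retention weight."""

    targets: dict[str, np.ndarray]  # chrom -> merged (n, 2) intervals
    probe_pad: int = 100
    gc_bias: object = field(default_factory=GCBias)
    min_overlap: int = 1

    def __post_init__(self):
        self.targets = {c: iv.merge(a) for c, a in self.targets.items()}
        if self.min_overlap < 1:
            raise ConfigError("min_overlap must be >= 1")
        if self.probe_pad < 0:
            raise ConfigError("probe_pad must be >= 0")

    def padded(self) -> dict[str, np.ndarray]:
        return {c: iv.pad(a, self.probe_pad) for c, a in self.targets.items()}


@dataclass(frozen=True)
class ErrorModel:
    sub_rate: float = 0.001
    quality: int = 30

    def __post_init__(self):
        if not (0.0 <= self.sub_rate < 1.0):
            raise ConfigError("sub_rate must lie in [0, 1)")


class Fragment(NamedTuple):
    """Sheared fragment in haplotype coordinates."""

    chrom: str
    hap: int
    start: int
    end: int


@dataclass(frozen=True)
class ReadPair:
    """One emitted pair; name encodes truth tags, qualities are constant."""

    name: str
    seq1: str
    seq2: str


def simulate_fragments(
    genome: HaplotypeGenome,
    fragment_model: FragmentModel,
    n_fragments: int,
    seed: int,
) -> list[Fragment]:
    """Shear: start positions uniform per haplotype (haplotypes weighted by
    length), lengths truncated-normal with a floor at read_length."""
    if n_fragments < 0:
        raise ConfigError("n_fragments must be >= 0")
    if n_fragments == 0:
        return []
    rng = np.random.default_rng(seed)
    pools = genome.keys()
    lengths = np.array([genome.length(c, h) for c, h in pools], dtype=float)
    if lengths.sum() <= 0:
        raise DataError("genome has no sequence to shear")
    probs = lengths / lengths.sum()
    pool_idx = rng.choice(len(pools), size=n_fragments, p=probs)
    counts = np.bincount(pool_idx, minlength=len(pools))

    fragments: list[Fragment] = []
    for p, count in enumerate(counts):
        if count == 0:
            continue
        chrom, hap = pools[p]
        L = int(lengths[p])
        flens = _draw_lengths(rng, fragment_model, int(count), L)
        starts = (rng.random(int(count)) * (L - flens + 1)).astype(np.int64)
        for s, fl in zip(starts, flens):
            fragments.append(Fragment(chrom, hap, int(s), int(s + fl)))
    rng.shuffle(fragments)
    return fragments


def _draw_lengths(
    rng: np.random.Generator, model: FragmentModel, n: int, chrom_length: int
) -> np.ndarray:
    if model.insert_mean > chrom_length:
        raise DataError(
            f"fragment length {model.insert_mean:.0f} exceeds haplotype length {chrom_length}"
        )
    lens = np.rint(rng.normal(model.insert_mean, model.insert_sd, size=n)).astype(np.int64)
    lens = np.maximum(lens, model.read_length)
    for _ in range(_RETRY_CAP):
        bad = lens > chrom_length
        if not bad.any():
            return lens
        redraw = np.rint(
            rng.normal(model.insert_mean, model.insert_sd, size=int(bad.sum()))
        ).astype(np.int64)
        lens[bad] = np.maximum(redraw, model.read_length)
    raise DataError("could not draw fragment lengths within chromosome bounds")


def fragment_gc(genome: HaplotypeGenome, frag: Fragment) -> float:
    seq = genome.sequence(frag.chrom, frag.hap)[frag.start:frag.end]
    if not seq:
        return 0.0
    gc = sum(seq.count(b) for b in "GCgc")
    return gc / len(seq)


def targets_on_haplotype(
    genome: HaplotypeGenome, chrom: str, hap: int, ref_targets: np.ndarray
) -> np.ndarray:
    """Image of (padded) reference target intervals on one haplotype, via the
    liftover block map. Overlap of a haplotype interval with this image equals
    the overlap of its reference projection with the targets."""
    pieces: list[tuple[int, int]] = []
    for b in genome.liftover[(chrom, hap)]:
        if b.ref_start is None:
            continue
        blen = b.hap_end - b.hap_start
        off = b.hap_start - b.ref_start
        for rs, re in iv.clip_interval(b.ref_start, b.ref_start + blen, ref_targets):
            pieces.append((rs + off, re + off))
    return iv.merge(pieces)


def _gc_cumsum(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == 71) | (arr == 67) | (arr == 103) | (arr == 99)  # G C g c
    return np.concatenate([[0], np.cumsum(is_gc, dtype=np.int64)])


def capture_filter(
    fragments: Sequence[Fragment],
    capture_model: CaptureModel,
    genome: HaplotypeGenome,
    seed: int,
) -> list[Fragment]:
    """In-silico hybridization: a fragment is eligible iff its reference
    projection overlaps a padded target by >= min_overlap bp; eligible
    fragments are retained with probability gc_bias(fragment GC).

    Vectorized per (chrom, haplotype) group; output preserves input order.
    """
    rng = np.random.default_rng(seed)
    padded = capture_model.padded()
    groups: dict[tuple[str, int], list[int]] = {}
    for i, frag in enumerate(fragments):
        groups.setdefault((frag.chrom, frag.hap), []).append(i)
    keep = np.zeros(len(fragments), dtype=bool)
    for (chrom, hap), idx_list in sorted(groups.items()):
        target_arr = padded.get(chrom)
        if target_arr is None or len(target_arr) == 0:
            continue
        hap_targets = targets_on_haplotype(genome, chrom, hap, target_arr)
        if len(hap_targets) == 0:
            continue
        idx = np.asarray(idx_list)
        starts = np.array([fragments[i].start for i in idx_list], dtype=np.int64)
        ends = np.array([fragments[i].end for i in idx_list], dtype=np.int64)
        overlap = iv.batch_overlap(starts, ends, hap_targets)
        eligible = overlap >= capture_model.min_overlap
        cum = _gc_cumsum(genome.sequence(chrom, hap))
        gc = (cum[ends] - cum[starts]) / np.maximum(ends - starts, 1)
        try:
            weights = np.broadcast_to(np.asarray(capture_model.gc_bias(gc), dtype=float), gc.shape)
        except (TypeError, ValueError):  # scalar-only custom bias
            weights = np.array([capture_model.gc_bias(float(g)) for g in gc])
        keep[idx] = eligible & (rng.random(len(idx)) < weights)
    return [fragments[i] for i in np.nonzero(keep)[0]]


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------


def _span_tag(spans: list[tuple[int, int]]) -> str:
    if not spans:
        return "."
    return ",".join(f"{s}-{e}" for s, e in spans)


def parse_read_name(name: str) -> dict:
    """Decode the truth tags written by :func:`render_reads`."""
    fields = name.split("|")
    if len(fields) != 8:
        raise DataError(f"not a scnabench truth-tagged read name: {name!r}")
    sample, idx, chrom, hap, start, end, r1, r2 = fields

    def spans(tag):
        if tag == ".":
            return []
        return [tuple(int(x) for x in part.split("-")) for part in tag.split(",")]

    return {
        "sample": sample,
        "index": int(idx),
        "chrom": chrom,
        "hap": int(hap),
        "start": int(start),
        "end": int(end),
        "r1_ref_spans": spans(r1),
        "r2_ref_spans": spans(r2),
    }


_SUB_CHOICES = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _substitute(seq: str, rng: np.random.Generator, count: int) -> str:
    if count == 0:
        return seq
    positions = rng.choice(len(seq), size=count, replace=False)
    out = list(seq)
    for p in positions:
        choices = _SUB_CHOICES.get(out[p].upper(), "ACGT")
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def render_reads(
    fragments: Sequence[Fragment],
    genome: HaplotypeGenome,
    error_model: ErrorModel,
    sample_name: str,
    seed: int,
    read_length: int = 101,
) -> tuple[list[ReadPair], int]:
    """Render read pairs in memory; returns (pairs, n_skipped_short).

    Read 1 is the fragment 5' prefix; read 2 the reverse complement of the 3'
    suffix. Fragments shorter than the read length are skipped and counted.
    """
    if "|" in sample_name:
        raise ConfigError("sample_name must not contain '|'")
    rng = np.random.default_rng(seed)
    rl = read_length
    pairs: list[ReadPair] = []
    skipped = 0
    # pre-drawn per-read substitution counts (vectorized binomial)
    if error_model.sub_rate > 0 and len(fragments):
        sub_counts = rng.binomial(rl, error_model.sub_rate, size=2 * len(fragments))
    else:
        sub_counts = np.zeros(2 * len(fragments), dtype=np.int64)
    for i, frag in enumerate(fragments):
        if frag.end - frag.start < rl:
            skipped += 1
            continue
        seq = genome.sequence(frag.chrom, frag.hap)
        r1 = seq[frag.start:frag.start + rl]
        r2 = reverse_complement(seq[frag.end - rl:frag.end])
        r1 = _substitute(r1, rng, int(sub_counts[2 * i]))
        r2 = _substitute(r2, rng, int(sub_counts[2 * i + 1]))
        r1_spans = genome.project(frag.chrom, frag.hap, frag.start, frag.start + rl)
        r2_spans = genome.project(frag.chrom, frag.hap, frag.end - rl, frag.end)
        name = (
            f"{sample_name}|{i}|{frag.chrom}|{frag.hap}|{frag.start}|{frag.end}"
            f"|{_span_tag(r1_spans)}|{_span_tag(r2_spans)}"
        )
        pairs.append(ReadPair(name, r1, r2))
    return pairs, skipped


def write_fastq_pair(
    pairs: Iterable[ReadPair], prefix: str, quality: int = 30
) -> tuple[str, str]:
    """Write R1/R2 gzip FASTQ files ``{prefix}_R1.fastq.gz`` etc."""
    r1_path, r2_path = f"{prefix}_R1.fastq.gz", f"{prefix}_R2.fastq.gz"
    qchar = chr(quality + 33)
    # fileobj form + mtime=0 keeps output byte-deterministic across runs
    with open(r1_path, "wb") as raw1, open(r2_path, "wb") as raw2, \
            gzip.GzipFile(filename="", fileobj=raw1, mode="wb", compresslevel=2, mtime=0) as g1, \
            gzip.GzipFile(filename="", fileobj=raw2, mode="wb", compresslevel=2, mtime=0) as g2:
        buf1, buf2 = [], []
        for pair in pairs:
            buf1.append(f"@{pair.name}/1\n{pair.seq1}\n+\n{qchar * len(pair.seq1)}\n")
            buf2.append(f"@{pair.name}/2\n{pair.seq2}\n+\n{qchar * len(pair.seq2)}\n")
        g1.write("".join(buf1).encode("ascii"))
        g2.write("".join(buf2).encode("ascii"))
    return r1_path, r2_path


def emit_reads(
    fragments: Sequence[Fragment],
    genome: HaplotypeGenome,
    error_model: ErrorModel,
    sample_name: str,
    seed: int,
    out_prefix: str,
    read_length: int = 101,
) -> tuple[str, str, int]:
    """Render and write paired FASTQ; returns (r1_path, r2_path, skipped)."""
    pairs, skipped = render_reads(
        fragments, genome, error_model, sample_name, seed, read_length=read_length
    )
    r1, r2 = write_fastq_pair(pairs, out_prefix, quality=error_model.quality)
    return r1, r2, skipped


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def on_target_read_bases(names: Iterable[str], targets: dict[str, np.ndarray]) -> int:
    """Sum of read bases whose reference projection falls in target space."""
    merged = {c: iv.merge(a) for c, a in targets.items()}
    total = 0
    for name in names:
        tags = parse_read_name(name)
        arr = merged.get(tags["chrom"])
        if arr is None:
            continue
        for s, e in tags["r1_ref_spans"] + tags["r2_ref_spans"]:
            total += iv.interval_overlap(s, e, arr)
    return total


def estimate_coverage(
    reads: Sequence[ReadPair] | Iterable[str],
    targets: dict[str, np.ndarray],
) -> float:
    """Mean on-target depth from truth-tagged reads (pairs or names)."""
    target_bp = sum(iv.total_length(a) for a in targets.values())
    if target_bp == 0:
        raise DataError("targets are empty")
    names = [r.name if isinstance(r, ReadPair) else r for r in reads]
    return on_target_read_bases(names, targets) / target_bp


def fragments_for_depth(
    genome: HaplotypeGenome,
    fragment_model: FragmentModel,
    capture_model: CaptureModel,
    depth: float,
    seed: int,
    pilot_size: int = 10_000,
) -> int:
    """Fragment count needed for a requested mean on-target depth.

    A pilot draw of ``pilot_size`` fragments is sheared and captured; the
    realized on-target read bases per drawn fragment calibrate
    n = depth * target_bp / bases_per_fragment.
    """
    if depth <= 0:
        raise ConfigError("depth must be > 0")
    target_bp = sum(iv.total_length(a) for a in capture_model.targets.values())
    if target_bp == 0:
        raise DataError("targets are empty")
    pilot = simulate_fragments(genome, fragment_model, pilot_size, seed)
    retained = capture_filter(pilot, capture_model, genome, seed + 1)
    pairs, _ = render_reads(
        retained, genome, ErrorModel(sub_rate=0.0), "pilot", seed + 2,
        read_length=fragment_model.read_length,
    )
    bases = on_target_read_bases((p.name for p in pairs), capture_model.targets)
    if bases == 0:
        raise DataError("pilot draw produced no on-target bases; check targets")
    per_fragment = bases / pilot_size
    return int(math.ceil(depth * target_bp / per_fragment))
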