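"""Construct control and tumor-clone genomes by implanting variants.

The workflow is: build (or load) a reference, sample a variant catalog
(germline SNVs/indels/CNVs plus somatic SNVs/indels/SCNAs), implant the
germline set to obtain the diploid control genome, and implant germline plus
per-clone somatic sets to obtain the "pure" tumor clone genomes. Amplifications
are realized as tandem duplications; deletions remove the interval. All truth
coordinates stay on the reference axis, and every haplotype carries a liftover
map back to reference coordinates.

Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

import bisect
import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from scnabench.errors import ConfigError, DataError, PlacementError

VTYPES = ("SNV", "INS", "SMALL_DEL", "CNV_DEL", "CNV_AMP")
CNV_TYPES = ("CNV_DEL", "CNV_AMP")

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantSpec:
    """One germline or somatic variant on reference coordinates.

    ``alt`` holds the substituted/inserted sequence for SNV/INS and the number
    of EXTRA tandem copies (>= 1) for CNV_AMP. ``haplotypes`` is the subset of
    {0, 1} carrying the variant: exactly one for het, both for hom.
    """

    chrom: str
    start: int
    end: int
    vtype: str
    alt: str | int | None = None
    zygosity: str = "het"
    haplotypes: tuple[int, ...] = (0,)
    origin: str = "germline"
    clone_ids: frozenset[int] = frozenset()
    arm_length_flag: bool = False

    def __post_init__(self):
        if self.vtype not in VTYPES:
            raise DataError(f"unknown variant type {self.vtype!r}")
        if self.vtype == "INS":
            if self.start != self.end:
                raise DataError("INS must have start == end")
            if not self.alt:
                raise DataError("INS requires inserted sequence in alt")
        elif self.start >= self.end:
            raise DataError(
                f"{self.vtype} requires start < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.vtype == "SNV" and self.end - self.start != 1:
            raise DataError("SNV must span exactly one base")
        if self.vtype == "CNV_AMP":
            if not isinstance(self.alt, int) or self.alt < 1:
                raise DataError("CNV_AMP alt must be an int >= 1 (extra tandem copies)")
        haps = tuple(sorted(set(self.haplotypes)))
        object.__setattr__(self, "haplotypes", haps)
        if any(h not in (0, 1) for h in haps):
            raise DataError("haplotypes must be a subset of {0, 1}")
        if self.zygosity == "het" and len(haps) != 1:
            raise DataError("het variant must sit on exactly one haplotype")
        if self.zygosity == "hom" and haps != (0, 1):
            raise DataError("hom variant must sit on both haplotypes")
        if self.zygosity not in ("het", "hom"):
            raise DataError(f"unknown zygosity {self.zygosity!r}")
        if self.origin not in ("germline", "somatic"):
            raise DataError(f"unknown origin {self.origin!r}")
        object.__setattr__(self, "clone_ids", frozenset(self.clone_ids))

    @property
    def is_cnv(self) -> bool:
        return self.vtype in CNV_TYPES

    @property
    def scna_type(self) -> str:
        """'amp' or 'del' for CNV records."""
        if self.vtype == "CNV_AMP":
            return "amp"
        if self.vtype == "CNV_DEL":
            return "del"
        raise DataError(f"{self.vtype} is not a copy-number variant")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.vtype}"

    def span(self) -> tuple[int, int]:
        """Reference footprint used for overlap bookkeeping (INS occupies 1 bp)."""
        if self.vtype == "INS":
            return (self.start, self.start + 1)
        return (self.start, self.end)


@dataclass(frozen=True)
class ChromosomeModel:
    """Toy chromosome: length, centromere position (arm split), GC targets.

    ``gc_profile`` lists per-window GC targets; windows partition the
    chromosome evenly.
    """

    name: str
    length: int
    centromere: int | None = None
    gc_profile: tuple[float, ...] = (0.45,)

    def __post_init__(self):
        if self.length <= 0:
            raise ConfigError(f"chromosome {self.name!r} must have positive length")
        cen = self.centromere if self.centromere is not None else self.length // 2
        object.__setattr__(self, "centromere", cen)
        if not (0 < cen < self.length):
            raise ConfigError(f"centromere of {self.name!r} must lie strictly inside")
        if not self.gc_profile or any(not (0.0 <= g <= 1.0) for g in self.gc_profile):
            raise ConfigError("gc_profile values must lie in [0, 1]")

    @property
    def arms(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((0, self.centromere), (self.centromere, self.length))


@dataclass(frozen=True)
class LiftoverBlock:
    """Collinear block: haplotype [hap_start, hap_end) maps to reference
    [ref_start, ref_start + len). ``ref_start`` is None for novel (inserted)
    sequence with no reference image."""

    hap_start: int
    hap_end: int
    ref_start: int | None


class HaplotypeGenome:
    """Two haplotype sequences per chromosome plus liftover maps to reference."""

    def __init__(
        self,
        sequences: dict[tuple[str, int], str],
        liftover: dict[tuple[str, int], list[LiftoverBlock]],
        reference_lengths: dict[str, int],
    ):
        self.sequences = sequences
        self.liftover = liftover
        self.reference_lengths = reference_lengths
        self._block_starts = {
            key: [b.hap_start for b in blocks] for key, blocks in liftover.items()
        }

    def keys(self) -> list[tuple[str, int]]:
        return sorted(self.sequences)

    def length(self, chrom: str, hap: int) -> int:
        return len(self.sequences[(chrom, hap)])

    def sequence(self, chrom: str, hap: int) -> str:
        return self.sequences[(chrom, hap)]

    def project(self, chrom: str, hap: int, start: int, end: int) -> list[tuple[int, int]]:
        """Reference intervals (0-based half-open) underlying haplotype
        [start, end); novel inserted bases contribute nothing."""
        blocks = self.liftover[(chrom, hap)]
        starts = self._block_starts[(chrom, hap)]
        out: list[tuple[int, int]] = []
        i = max(bisect.bisect_right(starts, start) - 1, 0)
        while i < len(blocks) and blocks[i].hap_start < end:
            b = blocks[i]
            lo, hi = max(b.hap_start, start), min(b.hap_end, end)
            if lo < hi and b.ref_start is not None:
                off = b.ref_start - b.hap_start
                out.append((lo + off, hi + off))
            i += 1
        return out

    @classmethod
    def from_reference(cls, reference: dict[str, str]) -> "HaplotypeGenome":
        """Diploid genome identical to the reference on both haplotypes."""
        seqs, lifts = {}, {}
        for chrom, seq in reference.items():
            for hap in (0, 1):
                seqs[(chrom, hap)] = seq
                lifts[(chrom, hap)] = [LiftoverBlock(0, len(seq), 0)]
        return cls(seqs, lifts, {c: len(s) for c, s in reference.items()})


@dataclass
class TruthTable:
    """Gold-standard variant records (reference coordinates) plus metadata."""

    records: list[VariantSpec]
    metadata: dict = field(default_factory=dict)

    def cnv_records(self) -> list[VariantSpec]:
        return [r for r in self.records if r.is_cnv]

    def scna_records(self) -> list[VariantSpec]:
        """Somatic copy-number records: the SCNA gold standard."""
        return [r for r in self.records if r.is_cnv and r.origin == "somatic"]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            key = f"{r.origin}_{r.vtype}"
            out[key] = out.get(key, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Toy reference
# ---------------------------------------------------------------------------


def generate_toy_reference(
    chrom_models: Sequence[ChromosomeModel], seed: int
) -> dict[str, str]:
    """Deterministic toy reference honouring each model's windowed GC targets.

    Each window receives exactly round(gc * window_len) G/C bases at random
    positions, so realized GC matches the profile by construction.
    """
    rng = np.random.default_rng(seed)
    reference: dict[str, str] = {}
    for model in chrom_models:
        n_windows = len(model.gc_profile)
        edges = np.linspace(0, model.length, n_windows + 1).astype(int)
        chunks = []
        for w, gc in enumerate(model.gc_profile):
            wlen = int(edges[w + 1] - edges[w])
            if wlen == 0:
                continue
            n_gc = int(round(gc * wlen))
            arr = np.empty(wlen, dtype="S1")
            order = rng.permutation(wlen)
            arr[order[:n_gc]] = rng.choice(_BASES[1:3], size=n_gc)  # C, G
            arr[order[n_gc:]] = rng.choice(_BASES[[0, 3]], size=wlen - n_gc)  # A, T
            chunks.append(arr.tobytes().decode("ascii"))
        reference[model.name] = "".join(chunks)
    return reference


def default_chrom_models(
    n_chroms: int = 20,
    length: int = 400_000,
    gc_low: float = 0.35,
    gc_high: float = 0.55,
    windows: int = 8,
) -> list[ChromosomeModel]:
    """Toy karyotype: equal-length chromosomes with mid-chromosome centromeres
    and a GC gradient across windows (gives the capture GC bias traction)."""
    models = []
    for i in range(n_chroms):
        profile = tuple(
            gc_low + (gc_high - gc_low) * ((i + w) % windows) / max(windows - 1, 1)
            for w in range(windows)
        )
        models.append(
            ChromosomeModel(
                name=f"chr{i + 1}",
                length=length,
                centromere=length // 2,
                gc_profile=profile,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Catalog sampling
# ---------------------------------------------------------------------------


@dataclass
class CatalogConfig:
    """Counts and distributions for synthetic variant catalogs.

    CNV counts default to the benchmark design: 939 germline deletions and
    1199 germline duplications; per replicate 16 arm-length SCNAs plus 50
    somatic deletions and 50 somatic amplifications. Size ranges are
    log-uniform; the germline default range is 52 bp to 2 191 569 bp and must
    be scaled down for toy genomes.
    """

    germline_snvs: int = 0
    germline_indels: int = 0
    germline_cnv_del: int = 939
    germline_cnv_dup: int = 1199
    somatic_snvs: int = 0
    somatic_indels: int = 0
    somatic_arm: int = 16
    somatic_del: int = 50
    somatic_amp: int = 50
    het_prob: float = 0.9
    somatic_del_het_prob: float | None = None
    somatic_amp_het_prob: float | None = None
    germline_cnv_size_range: tuple[int, int] = (52, 2_191_569)
    somatic_cnv_size_range: tuple[int, int] = (1_000, 1_000_000)
    indel_size_range: tuple[int, int] = (1, 40)
    arm_min_fraction: float = 0.9
    amp_extra_copies: int = 1
    max_retries: int = 1000

    def __post_init__(self):
        for name in (
            "germline_snvs", "germline_indels", "germline_cnv_del",
            "germline_cnv_dup", "somatic_snvs", "somatic_indels",
            "somatic_arm", "somatic_del", "somatic_amp",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.het_prob <= 1.0):
            raise ConfigError("het_prob must lie in [0, 1]")
        if self.amp_extra_copies < 1:
            raise ConfigError("amp_extra_copies must be >= 1")


class _Occupancy:
    """Per-chromosome sorted interval lists for overlap rejection."""

    def __init__(self):
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        ivs = self._by_chrom.get(chrom, [])
        i = bisect.bisect_left(ivs, (start, start))
        if i < len(ivs) and ivs[i][0] < end:
            return True
        return i > 0 and ivs[i - 1][1] > start

    def add(self, chrom: str, start: int, end: int) -> None:
        bisect.insort(self._by_chrom.setdefault(chrom, []), (start, end))


def _log_uniform(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo >= hi:
        return lo
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def _draw_zygosity(rng: np.random.Generator, het_prob: float):
    if rng.random() < het_prob:
        return "het", (int(rng.integers(2)),)
    return "hom", (0, 1)


def sample_variant_catalog(
    config: CatalogConfig,
    chrom_models: Sequence[ChromosomeModel],
    seed: int,
) -> tuple[list[VariantSpec], list[VariantSpec]]:
    """Sample germline and somatic variant lists, mutually non-overlapping.

    Placement uses rejection sampling against a shared occupancy map (so no
    two variants overlap anywhere, which implies per-haplotype non-overlap);
    a category that cannot be placed within the retry cap raises
    :class:`PlacementError` rather than silently under-counting.
    """
    rng = np.random.default_rng(seed)
    models = list(chrom_models)
    lengths = np.array([m.length for m in models], dtype=float)
    chrom_probs = lengths / lengths.sum()
    occ = _Occupancy()
    germline: list[VariantSpec] = []
    somatic: list[VariantSpec] = []

    def place(category: str, count: int, build) -> list[VariantSpec]:
        out = []
        for _ in range(count):
            for _attempt in range(config.max_retries):
                spec = build()
                if spec is None:
                    continue
                s, e = spec.span()
                if not occ.overlaps(spec.chrom, s, e):
                    occ.add(spec.chrom, s, e)
                    out.append(spec)
                    break
            else:
                raise PlacementError(category, len(out), count, config.max_retries)
        return out

    def pick_model() -> ChromosomeModel:
        return models[int(rng.choice(len(models), p=chrom_probs))]

    def build_arm():
        model = pick_model()
        arm_start, arm_end = model.arms[int(rng.integers(2))]
        arm_len = arm_end - arm_start
        size = int(round(rng.uniform(config.arm_min_fraction, 1.0) * arm_len))
        if size < 1:
            return None
        start = arm_start + int(rng.integers(arm_len - size + 1))
        vtype = "CNV_DEL" if rng.random() < 0.5 else "CNV_AMP"
        zyg, haps = _draw_zygosity(rng, config.het_prob)
        return VariantSpec(
            model.name, start, start + size, vtype,
            alt=config.amp_extra_copies if vtype == "CNV_AMP" else None,
            zygosity=zyg, haplotypes=haps, origin="somatic", arm_length_flag=True,
        )

    def build_cnv(vtype: str, origin: str, size_range, het_prob: float):
        model = pick_model()
        size = max(_log_uniform(rng, *size_range), 1)
        if size >= model.length:
            return None
        start = int(rng.integers(model.length - size + 1))
        zyg, haps = _draw_zygosity(rng, het_prob)
        return VariantSpec(
            model.name, start, start + size, vtype,
            alt=config.amp_extra_copies if vtype == "CNV_AMP" else None,
            zygosity=zyg, haplotypes=haps, origin=origin,
        )

    def build_snv(origin: str):
        model = pick_model()
        pos = int(rng.integers(model.length))
        zyg, haps = _draw_zygosity(rng, config.het_prob)
        return VariantSpec(
            model.name, pos, pos + 1, "SNV",
            alt=str(rng.choice(["A", "C", "G", "T"])),
            zygosity=zyg, haplotypes=haps, origin=origin,
        )

    def build_indel(origin: str):
        model = pick_model()
        size = int(rng.integers(config.indel_size_range[0], config.indel_size_range[1] + 1))
        zyg, haps = _draw_zygosity(rng, config.het_prob)
        if rng.random() < 0.5:  # insertion
            pos = int(rng.integers(model.length))
            alt = "".join(rng.choice(["A", "C", "G", "T"], size=size))
            return VariantSpec(model.name, pos, pos, "INS", alt=alt,
                               zygosity=zyg, haplotypes=haps, origin=origin)
        if size >= model.length:
            return None
        pos = int(rng.integers(model.length - size))
        return VariantSpec(model.name, pos, pos + size, "SMALL_DEL",
                           zygosity=zyg, haplotypes=haps, origin=origin)

    del_het = config.somatic_del_het_prob if config.somatic_del_het_prob is not None else config.het_prob
    amp_het = config.somatic_amp_het_prob if config.somatic_amp_het_prob is not None else config.het_prob

    # largest footprints first to keep rejection sampling cheap
    somatic += place("somatic_arm", config.somatic_arm, build_arm)
    somatic += place(
        "somatic_del", config.somatic_del,
        lambda: build_cnv("CNV_DEL", "somatic", config.somatic_cnv_size_range, del_het),
    )
    somatic += place(
        "somatic_amp", config.somatic_amp,
        lambda: build_cnv("CNV_AMP", "somatic", config.somatic_cnv_size_range, amp_het),
    )
    germline += place(
        "germline_cnv_del", config.germline_cnv_del,
        lambda: build_cnv("CNV_DEL", "germline", config.germline_cnv_size_range, config.het_prob),
    )
    germline += place(
        "germline_cnv_dup", config.germline_cnv_dup,
        lambda: build_cnv("CNV_AMP", "germline", config.germline_cnv_size_range, config.het_prob),
    )
    germline += place("germline_snvs", config.germline_snvs, lambda: build_snv("germline"))
    germline += place("germline_indels", config.germline_indels, lambda: build_indel("germline"))
    somatic += place("somatic_snvs", config.somatic_snvs, lambda: build_snv("somatic"))
    somatic += place("somatic_indels", config.somatic_indels, lambda: build_indel("somatic"))
    return germline, somatic


# ---------------------------------------------------------------------------
# Implantation
# ---------------------------------------------------------------------------


def _edit_delta(spec: VariantSpec) -> int:
    """Length change contributed by one edit on one haplotype."""
    if spec.vtype == "INS":
        return len(spec.alt)
    if spec.vtype in ("SMALL_DEL", "CNV_DEL"):
        return -(spec.end - spec.start)
    if spec.vtype == "CNV_AMP":
        return (spec.end - spec.start) * spec.alt
    return 0


def implant_variants(
    reference: dict[str, str],
    specs: Sequence[VariantSpec],
    seed: int = 0,
) -> tuple[HaplotypeGenome, TruthTable]:
    """Apply variant edits to the reference, producing a diploid genome.

    CNV_AMP inserts ``alt`` extra tandem copies immediately after the source
    interval; CNV_DEL/SMALL_DEL remove the interval; SNV substitutes one base
    (resampled if the catalog alt equals the reference base); INS inserts
    ``alt``. The liftover map records, for every haplotype block, its source
    reference interval.
    """
    rng = np.random.default_rng(seed)
    for spec in specs:
        if spec.chrom not in reference:
            raise DataError(f"variant on unknown chromosome {spec.chrom!r}")
        if spec.end > len(reference[spec.chrom]) or spec.start < 0:
            raise DataError(
                f"variant {spec.chrom}:{spec.start}-{spec.end} outside chromosome "
                f"bounds [0, {len(reference[spec.chrom])})"
            )

    by_chrom: dict[str, list[VariantSpec]] = {c: [] for c in reference}
    for spec in specs:
        by_chrom[spec.chrom].append(spec)

    sequences: dict[tuple[str, int], str] = {}
    liftover: dict[tuple[str, int], list[LiftoverBlock]] = {}

    for chrom, ref_seq in reference.items():
        edits = sorted(by_chrom[chrom], key=lambda s: (s.start, s.end))
        for hap in (0, 1):
            prev_end = 0
            for cur in edits:
                if hap not in cur.haplotypes or cur.vtype == "INS":
                    continue
                if cur.start < prev_end:
                    raise DataError(
                        f"overlapping edits on {chrom} haplotype {hap} at "
                        f"{cur.start}-{cur.end}"
                    )
                prev_end = max(prev_end, cur.end)
        # pre-draw SNV substitutions so both haplotypes of a hom SNV agree
        snv_alt: dict[int, str] = {}
        for spec in edits:
            if spec.vtype == "SNV":
                ref_base = ref_seq[spec.start].upper()
                alt = spec.alt if isinstance(spec.alt, str) else None
                if alt is None or alt.upper() == ref_base:
                    choices = [b for b in "ACGT" if b != ref_base]
                    alt = str(rng.choice(choices))
                snv_alt[id(spec)] = alt

        for hap in (0, 1):
            pieces: list[str] = []
            blocks: list[LiftoverBlock] = []
            hap_pos = 0

            def emit(seq: str, ref_start: int | None):
                nonlocal hap_pos
                if not seq:
                    return
                if (
                    blocks
                    and ref_start is not None
                    and blocks[-1].ref_start is not None
                    and blocks[-1].hap_end == hap_pos
                    and blocks[-1].ref_start + (blocks[-1].hap_end - blocks[-1].hap_start) == ref_start
                ):
                    blocks[-1] = LiftoverBlock(blocks[-1].hap_start, hap_pos + len(seq), blocks[-1].ref_start)
                else:
                    blocks.append(LiftoverBlock(hap_pos, hap_pos + len(seq), ref_start))
                pieces.append(seq)
                hap_pos += len(seq)

            cursor = 0
            for spec in edits:
                if hap not in spec.haplotypes:
                    continue
                emit(ref_seq[cursor:spec.start], cursor)
                if spec.vtype == "SNV":
                    emit(snv_alt[id(spec)], spec.start)
                    cursor = spec.end
                elif spec.vtype == "INS":
                    emit(spec.alt, None)
                    cursor = spec.start
                elif spec.vtype in ("SMALL_DEL", "CNV_DEL"):
                    cursor = spec.end
                elif spec.vtype == "CNV_AMP":
                    source = ref_seq[spec.start:spec.end]
                    emit(source, spec.start)
                    for _ in range(spec.alt):
                        emit(source, spec.start)
                    cursor = spec.end
            emit(ref_seq[cursor:], cursor)
            sequences[(chrom, hap)] = "".join(pieces)
            liftover[(chrom, hap)] = blocks

    genome = HaplotypeGenome(sequences, liftover, {c: len(s) for c, s in reference.items()})
    table = TruthTable(records=list(specs), metadata={"seed": seed})
    return genome, table


def build_clone_genomes(
    reference: dict[str, str],
    germline_specs: Sequence[VariantSpec],
    somatic_specs: Sequence[VariantSpec],
    n_clones: int = 5,
    truncal_fraction: float = 0.0,
    assignment: Sequence[Iterable[int]] | None = None,
    seed: int = 0,
) -> tuple[HaplotypeGenome, list[HaplotypeGenome], TruthTable]:
    """Build the control genome and ``n_clones`` tumor clone genomes.

    Each somatic spec is assigned to clones: explicitly via ``assignment``
    (one clone-id collection per spec), or randomly — truncal (all clones)
    with probability ``truncal_fraction``, otherwise private to one uniformly
    chosen clone. Clone genome c implants the germline set plus the somatic
    specs carrying clone id c. Returns (control, clones, merged truth).
    """
    if n_clones < 1:
        raise ConfigError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    if assignment is not None:
        if len(assignment) != len(somatic_specs):
            raise ConfigError("assignment must give clone ids for every somatic spec")
        clone_sets = [frozenset(int(c) for c in ids) for ids in assignment]
        for ids in clone_sets:
            if not ids or any(c < 0 or c >= n_clones for c in ids):
                raise ConfigError("assignment clone ids must be a non-empty subset of range(n_clones)")
    else:
        clone_sets = []
        for _ in somatic_specs:
            if rng.random() < truncal_fraction:
                clone_sets.append(frozenset(range(n_clones)))
            else:
                clone_sets.append(frozenset({int(rng.integers(n_clones))}))

    assigned = [
        dataclasses.replace(spec, clone_ids=ids)
        for spec, ids in zip(somatic_specs, clone_sets)
    ]
    control, _ = implant_variants(reference, germline_specs, seed=seed)
    clones = []
    for c in range(n_clones):
        clone_specs = list(germline_specs) + [s for s in assigned if c in s.clone_ids]
        clone_genome, _ = implant_variants(reference, clone_specs, seed=seed)
        clones.append(clone_genome)
    truth = TruthTable(
        records=list(germline_specs) + assigned,
        metadata={"seed": seed, "n_clones": n_clones},
    )
    return control, clones, truth


# ---------------------------------------------------------------------------
# Truth I/O
# ---------------------------------------------------------------------------

_TRUTH_HEADER = "#chrom\tstart\tend\ttype\tzygosity\tclone_ids\torigin\tarm_flag"


def export_truth(table: TruthTable, path) -> None:
    """Write CNV records as a BED-like TSV (0-based half-open)."""
    lines = [_TRUTH_HEADER]
    for r in sorted(table.cnv_records(), key=lambda r: (r.chrom, r.start, r.end)):
        clone_field = ",".join(str(c) for c in sorted(r.clone_ids)) or "."
        lines.append(
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.scna_type}\t{r.zygosity}\t"
            f"{clone_field}\t{r.origin}\t{int(r.arm_length_flag)}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth(path) -> TruthTable:
    """Read a truth BED written by :func:`export_truth`."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise DataError(f"malformed truth line: {line!r}")
            chrom, start, end, stype, zyg, clones, origin, arm = fields
            vtype = "CNV_AMP" if stype == "amp" else "CNV_DEL"
            clone_ids = frozenset(int(c) for c in clones.split(",")) if clones != "." else frozenset()
            haps = (0,) if zyg == "het" else (0, 1)
            records.append(
                VariantSpec(
                    chrom, int(start), int(end), vtype,
                    alt=1 if vtype == "CNV_AMP" else None,
                    zygosity=zyg, haplotypes=haps, origin=origin,
                    clone_ids=clone_ids, arm_length_flag=bool(int(arm)),
                )
            )
    return TruthTable(records=records)


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA into memory (toy scale) via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}
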