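"""End-to-end orchestration: cohort generation, a naive depth-ratio caller,
aggregation and fixtures.

A cohort run produces, per replicate, a control genome and five tumor clone
genomes, a truth table and expected-AF table, per-clone and control read
pools, one clonal mixture, and one admixed tumor-control FASTQ pair per
admixture level — all listed in a manifest TSV. The naive caller computes
per-target depth ratios from truth-tagged read names (alignment-free) and
segments runs of targets beyond a log2 threshold.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from scnabench import capture_sim as cs
from scnabench import clonal_mixer as cm
from scnabench import genome_forge as gf
from scnabench import intervals as iv
from scnabench import scna_eval as ev
from scnabench.errors import ConfigError, DataError

log = logging.getLogger("scnabench")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Full design of one simulated cohort."""

    n_replicates: int = 5
    admixture_levels: tuple[float, ...] = cm.DEFAULT_ADMIXTURE_LEVELS
    clone_proportions: tuple[float, ...] = cm.DEFAULT_CLONE_PROPORTIONS
    catalog: gf.CatalogConfig = field(default_factory=gf.CatalogConfig)
    n_chroms: int = 20
    chrom_length: int = 400_000
    target_mode: str = "exome"  # exome | panel
    target_length: int = 120
    target_spacing: int = 1500
    probe_pad: int = 100
    n_genes: int = 50
    gene_length: int = 8_000
    depth: float = 60.0
    read_length: int = 101
    insert_mean: float | None = None  # default: 300 exome, 200 panel
    insert_sd: float = 50.0
    sub_rate: float = 0.001
    gc_center: float = 0.45
    gc_width: float = 0.15
    gc_floor: float = 0.1
    truncal_fraction: float = 0.0
    simulate_reads: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        levels = tuple(self.admixture_levels)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ConfigError("admixture levels must be strictly increasing")
        if self.target_mode not in ("exome", "panel"):
            raise ConfigError("target_mode must be 'exome' or 'panel'")
        if isinstance(self.catalog, dict):
            self.catalog = gf.CatalogConfig(**self.catalog)
        self.admixture_levels = levels
        self.clone_proportions = tuple(self.clone_proportions)

    @property
    def effective_insert_mean(self) -> float:
        if self.insert_mean is not None:
            return self.insert_mean
        return 300.0 if self.target_mode == "exome" else 200.0

    def fragment_model(self) -> cs.FragmentModel:
        return cs.FragmentModel(self.read_length, self.effective_insert_mean, self.insert_sd)

    def gc_bias(self) -> cs.GCBias:
        return cs.GCBias(self.gc_center, self.gc_width, self.gc_floor)


def load_config(path) -> CohortConfig:
    """Load a cohort config from YAML; unknown keys are an error."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return CohortConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def paper_design_config(seed: int = 0, simulate_reads: bool = False, depth: float = 30.0) -> CohortConfig:
    """The full benchmark design (5 replicates x 10 admixture levels; per
    replicate 16 arm-length + 50 del + 50 amp somatic SCNAs) scaled onto the
    built-in toy reference."""
    return CohortConfig(
        n_replicates=5,
        catalog=gf.CatalogConfig(
            germline_snvs=1000,
            germline_indels=100,
            somatic_snvs=200,
            somatic_indels=20,
            germline_cnv_size_range=(52, 3_000),
            somatic_cnv_size_range=(2_000, 60_000),
        ),
        depth=depth,
        simulate_reads=simulate_reads,
        seed=seed,
    )


def mini_design_config(seed: int = 0, depth: float = 40.0) -> CohortConfig:
    """CI-scale cohort: 2 replicates x 3 admixture levels on a small genome,
    hom-biased deletions and +1-copy amplifications, half-truncal somatics."""
    return CohortConfig(
        n_replicates=2,
        admixture_levels=(0.0, 0.4, 0.9),
        catalog=gf.CatalogConfig(
            germline_cnv_del=20,
            germline_cnv_dup=20,
            germline_snvs=200,
            germline_indels=20,
            somatic_arm=2,
            somatic_del=8,
            somatic_amp=8,
            somatic_del_het_prob=0.1,
            germline_cnv_size_range=(52, 2_000),
            somatic_cnv_size_range=(5_000, 40_000),
        ),
        n_chroms=4,
        chrom_length=250_000,
        target_spacing=2_500,
        n_genes=30,
        gene_length=5_000,
        depth=depth,
        truncal_fraction=0.5,
        simulate_reads=True,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Targets and genes
# ---------------------------------------------------------------------------


def make_genes(
    chrom_models: Sequence[gf.ChromosomeModel],
    n_genes: int,
    gene_length: int,
    seed: int,
) -> pd.DataFrame:
    """Non-overlapping toy gene intervals spread over the genome."""
    rng = np.random.default_rng(seed)
    lengths = np.array([m.length for m in chrom_models], dtype=float)
    probs = lengths / lengths.sum()
    occupied: dict[str, list[tuple[int, int]]] = {}
    rows = []
    attempts = 0
    while len(rows) < n_genes and attempts < n_genes * 200:
        attempts += 1
        m = chrom_models[int(rng.choice(len(chrom_models), p=probs))]
        if gene_length >= m.length:
            continue
        start = int(rng.integers(m.length - gene_length))
        end = start + gene_length
        if any(start < e and s < end for s, e in occupied.get(m.name, [])):
            continue
        occupied.setdefault(m.name, []).append((start, end))
        rows.append({"chrom": m.name, "start": start, "end": end})
    if len(rows) < n_genes:
        raise DataError(f"could not place {n_genes} genes on the toy genome")
    rows.sort(key=lambda r: (r["chrom"], r["start"]))
    for i, row in enumerate(rows):
        row["name"] = f"GENE{i + 1:04d}"
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def make_targets(
    chrom_models: Sequence[gf.ChromosomeModel],
    mode: str,
    target_length: int,
    target_spacing: int,
    genes: pd.DataFrame | None = None,
) -> dict[str, np.ndarray]:
    """Capture design: exome mode tiles every chromosome at ``target_spacing``;
    panel mode tiles only the gene footprint."""
    targets: dict[str, list[tuple[int, int]]] = {}
    if mode == "exome":
        for m in chrom_models:
            for start in range(0, m.length - target_length, target_spacing):
                targets.setdefault(m.name, []).append((start, start + target_length))
    else:
        if genes is None or len(genes) == 0:
            raise ConfigError("panel mode requires a gene model")
        spacing = min(target_spacing, 400)
        for row in genes.itertuples(index=False):
            for start in range(row.start, row.end - target_length, spacing):
                targets.setdefault(row.chrom, []).append((start, start + target_length))
    return {c: iv.merge(a) for c, a in targets.items()}


def write_targets_bed(targets: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(targets):
            for s, e in targets[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_targets_bed(path) -> dict[str, np.ndarray]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            records.append((fields[0], int(fields[1]), int(fields[2])))
    return iv.merge_by_chrom(records)


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", header=False, index=False,
                 columns=["chrom", "start", "end", "name"])


def read_genes_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name"])
    return df


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def run_cohort(config: CohortConfig, outdir) -> pd.DataFrame:
    """Generate a full cohort on disk; returns (and writes) the manifest."""
    outdir = Path(outdir)
    (outdir / "samples").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    def stage_seed() -> int:
        return int(rng.integers(2**31 - 1))

    models = gf.default_chrom_models(config.n_chroms, config.chrom_length)
    reference = gf.generate_toy_reference(models, stage_seed())
    gf.write_fasta(reference, outdir / "reference.fa")
    genes = make_genes(models, config.n_genes, config.gene_length, stage_seed())
    targets = make_targets(
        models, config.target_mode, config.target_length, config.target_spacing, genes
    )
    write_genes_bed(genes, outdir / "genes.bed")
    write_targets_bed(targets, outdir / "targets.bed")

    n_clones = len(config.clone_proportions)
    design = cm.SampleDesign(
        clone_proportions=config.clone_proportions,
        admixture_levels=config.admixture_levels,
        seed=config.seed,
    )
    capture = cs.CaptureModel(targets, probe_pad=config.probe_pad, gc_bias=config.gc_bias())
    frag_model = config.fragment_model()
    error_model = cs.ErrorModel(sub_rate=config.sub_rate)

    rows = []
    for rep in range(config.n_replicates):
        rep_tag = f"rep{rep + 1}"
        catalog_seed = stage_seed()
        germline, somatic = gf.sample_variant_catalog(config.catalog, models, catalog_seed)
        control_genome, clones, truth = gf.build_clone_genomes(
            reference, germline, somatic,
            n_clones=n_clones,
            truncal_fraction=config.truncal_fraction,
            seed=stage_seed(),
        )
        truth_path = outdir / f"truth_{rep_tag}.bed"
        gf.export_truth(truth, truth_path)
        af = cm.af_table(truth, design)
        af_path = outdir / f"af_{rep_tag}.tsv"
        af.to_csv(af_path, sep="\t", index=False)
        n_gold = len(truth.scna_records())
        log.info("%s: %d gold SCNAs, %d germline CNVs", rep_tag, n_gold,
                 len(truth.cnv_records()) - n_gold)

        clone_pools: list[list[cs.ReadPair]] = []
        control_pool: list[cs.ReadPair] = []
        n_total = 0
        if config.simulate_reads:
            n_frag = cs.fragments_for_depth(
                control_genome, frag_model, capture, config.depth, stage_seed()
            )
            for c, clone in enumerate(clones):
                frags = cs.simulate_fragments(clone, frag_model, n_frag, stage_seed())
                kept = cs.capture_filter(frags, capture, clone, stage_seed())
                pairs, skipped = cs.render_reads(
                    kept, clone, error_model, f"{rep_tag}c{c}", stage_seed(),
                    read_length=config.read_length,
                )
                log.info("%s clone %d: %d fragments kept, %d skipped", rep_tag, c,
                         len(pairs), skipped)
                clone_pools.append(pairs)
            ctrl_frags = cs.simulate_fragments(
                control_genome, frag_model, int(2.2 * n_frag), stage_seed()
            )
            ctrl_kept = cs.capture_filter(ctrl_frags, capture, control_genome, stage_seed())
            control_pool, _ = cs.render_reads(
                ctrl_kept, control_genome, error_model, f"{rep_tag}ctrl", stage_seed(),
                read_length=config.read_length,
            )
            n_total = min(len(p) for p in clone_pools)
            tumor_pool = cm.mix_clones(
                clone_pools, config.clone_proportions, n_total, stage_seed()
            )

        for a in config.admixture_levels:
            sample_id = f"{rep_tag}_a{a:.1f}"
            row = {
                "sample_id": sample_id,
                "replicate": rep + 1,
                "admixture": a,
                "truth": str(truth_path),
                "af_table": str(af_path),
                "n_gold_scna": n_gold,
                "n_read_pairs": n_total,
                "seed": config.seed,
                "tumor_r1": "", "tumor_r2": "", "control_r1": "", "control_r2": "",
            }
            if config.simulate_reads:
                mixed = cm.admix(
                    tumor_pool, control_pool, a, n_total, stage_seed(),
                    str(outdir / "samples" / sample_id), sample_id=sample_id,
                )
                row.update(
                    tumor_r1=mixed.tumor_r1, tumor_r2=mixed.tumor_r2,
                    control_r1=mixed.control_r1, control_r2=mixed.control_r2,
                )
            rows.append(row)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Naive depth-ratio caller
# ---------------------------------------------------------------------------


def read_names_from_fastq(path) -> list[str]:
    names = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            name = entry.name
            names.append(name[:-2] if name.endswith(("/1", "/2")) else name)
    return names


def _target_list(targets: dict[str, np.ndarray]) -> list[tuple[str, int, int]]:
    out = []
    for chrom in sorted(targets):
        for s, e in targets[chrom]:
            out.append((chrom, int(s), int(e)))
    return out


def per_target_depth(
    read_names: Iterable[str], targets: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Mean depth per target from truth-tagged read names (alignment-free)."""
    tlist = _target_list(targets)
    index: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    offset = 0
    for chrom in sorted(targets):
        arr = targets[chrom]
        index[chrom] = (arr[:, 0], arr[:, 1], offset)
        offset += len(arr)
    bases = np.zeros(len(tlist), dtype=np.int64)
    for name in read_names:
        tags = cs.parse_read_name(name)
        entry = index.get(tags["chrom"])
        if entry is None:
            continue
        starts, ends, off = entry
        for s, e in tags["r1_ref_spans"] + tags["r2_ref_spans"]:
            i0 = int(np.searchsorted(ends, s, side="right"))
            i1 = int(np.searchsorted(starts, e, side="left"))
            for i in range(i0, i1):
                bases[off + i] += min(e, ends[i]) - max(s, starts[i])
    df = pd.DataFrame(tlist, columns=["chrom", "start", "end"])
    df["bases"] = bases
    df["depth"] = bases / (df["end"] - df["start"])
    return df


def naive_depth_caller(
    tumor_names: Iterable[str] | str,
    control_names: Iterable[str] | str,
    targets: dict[str, np.ndarray],
    log2_threshold: float = 0.3,
    min_consecutive_targets: int = 2,
) -> tuple[list[ev.Segment], pd.DataFrame]:
    """Call amp/del segments from per-target tumor/control depth ratios.

    Depths are library-size normalized; targets with zero control depth are
    masked; runs of >= ``min_consecutive_targets`` adjacent targets (same
    chromosome, no masked gap) with |log2 ratio| beyond the threshold are
    merged into one segment spanning first-target start to last-target end.
    """
    if isinstance(tumor_names, (str, Path)):
        tumor_names = read_names_from_fastq(tumor_names)
    if isinstance(control_names, (str, Path)):
        control_names = read_names_from_fastq(control_names)
    dt = per_target_depth(tumor_names, targets)
    dc = per_target_depth(control_names, targets)
    table = dt[["chrom", "start", "end"]].copy()
    table["tumor_depth"] = dt["depth"]
    table["control_depth"] = dc["depth"]
    nt, nc = dt["bases"].sum(), dc["bases"].sum()
    if nt == 0 or nc == 0:
        raise DataError("no on-target reads in tumor or control sample")
    scale = nc / nt
    masked = dc["depth"].to_numpy() == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = scale * dt["depth"].to_numpy() / dc["depth"].to_numpy()
        log2r = np.log2(ratio, where=ratio > 0, out=np.full(len(ratio), -np.inf))
    table["log2_ratio"] = np.where(masked, np.nan, log2r)
    table["masked"] = masked

    state = np.zeros(len(table), dtype=int)  # +1 amp, -1 del, 0 neutral/masked
    state[(~masked) & (log2r > log2_threshold)] = 1
    state[(~masked) & (log2r < -log2_threshold)] = -1

    segments: list[ev.Segment] = []
    chroms = table["chrom"].to_numpy()
    starts = table["start"].to_numpy()
    ends = table["end"].to_numpy()
    i = 0
    while i < len(table):
        s = state[i]
        if s == 0 or masked[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < len(table)
            and chroms[j + 1] == chroms[i]
            and state[j + 1] == s
            and not masked[j + 1]
        ):
            j += 1
        if j - i + 1 >= min_consecutive_targets:
            segments.append(
                ev.Segment(str(chroms[i]), int(starts[i]), int(ends[j]),
                           "amp" if s > 0 else "del")
            )
        i = j + 1
    return segments, table


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def summarize(report_frame: pd.DataFrame, by: Sequence[str] = ("admixture", "approach")) -> pd.DataFrame:
    """Mean precision/sensitivity grouped by ``by``; NAs are excluded from the
    means and the number of defined values is reported."""
    if report_frame.empty:
        raise DataError("no reports to summarize")
    df = report_frame.copy()
    grouped = df.groupby(list(by), dropna=False)
    out = grouped.agg(
        mean_precision=("precision", "mean"),
        n_precision=("precision", "count"),
        mean_sensitivity=("sensitivity", "mean"),
        n_sensitivity=("sensitivity", "count"),
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def generate_fixtures(outdir, seed: int = 0) -> pd.DataFrame:
    """Write the deterministic mini-cohort fixture tree (toy reference,
    targets, genes, 2 replicates x 3 admixture levels) and return its
    manifest."""
    config = mini_design_config(seed=seed)
    return run_cohort(config, outdir)
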