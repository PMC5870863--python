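"""Subclonal read mixing and the normal-admixture series.

A heterogeneous tumor read pool is drawn from per-clone pools at multinomial
proportions; an admixture series then replaces a fraction ``a`` of the tumor
reads with control reads at constant total depth, paired with an independent
control sample of equal depth. Expected allele fractions follow the linear
purity-clonality-zygosity model

    AF(variant, a) = (1 - a) * sum_{c in clones(variant)} p_c * z_c

with z = 0.5 for heterozygous and 1.0 for homozygous variants, so a fully
heterozygous cohort is capped at AF 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from scnabench.capture_sim import ReadPair, write_fastq_pair
from scnabench.errors import ConfigError, DataError, PoolExhaustedError
from scnabench.genome_forge import TruthTable, VariantSpec

DEFAULT_CLONE_PROPORTIONS = (0.27, 0.29, 0.36, 0.06, 0.02)
DEFAULT_ADMIXTURE_LEVELS = tuple(round(0.1 * i, 1) for i in range(10))


@dataclass(frozen=True)
class SampleDesign:
    """Clone proportions, admixture series and total depth of one design."""

    clone_proportions: tuple[float, ...] = DEFAULT_CLONE_PROPORTIONS
    admixture_levels: tuple[float, ...] = DEFAULT_ADMIXTURE_LEVELS
    total_read_pairs: int = 0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.clone_proportions) - 1.0) > 1e-9:
            raise ConfigError("clone proportions must sum to 1")
        if any(p < 0 for p in self.clone_proportions):
            raise ConfigError("clone proportions must be >= 0")
        if not self.admixture_levels:
            raise ConfigError("admixture_levels must be non-empty")
        if any(not (0.0 <= a < 1.0) for a in self.admixture_levels):
            raise ConfigError("admixture levels must lie in [0, 1)")


@dataclass
class MixedSample:
    """One admixed tumor-control pair on disk plus realized source counts."""

    sample_id: str
    admixture: float
    tumor_r1: str
    tumor_r2: str
    control_r1: str
    control_r2: str
    realized_counts: dict[str, int] = field(default_factory=dict)


def read_pool_from_fastq(r1_path: str, r2_path: str) -> list[ReadPair]:
    """Load a paired FASTQ pool into memory (toy scale)."""
    pairs = []
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            n1 = e1.name[:-2] if e1.name.endswith("/1") else e1.name
            n2 = e2.name[:-2] if e2.name.endswith("/2") else e2.name
            if n1 != n2:
                raise DataError(f"R1/R2 name mismatch: {e1.name!r} vs {e2.name!r}")
            pairs.append(ReadPair(n1, e1.sequence, e2.sequence))
    return pairs


def mix_clones(
    clone_pools: Sequence[Sequence[ReadPair]],
    proportions: Sequence[float],
    n_total: int,
    seed: int,
) -> list[ReadPair]:
    """Draw a tumor pool: per-clone counts multinomial at ``proportions``,
    sampled without replacement within each clone pool."""
    if len(clone_pools) != len(proportions):
        raise ConfigError("one proportion per clone pool required")
    if n_total < 0:
        raise ConfigError("n_total must be >= 0")
    if n_total == 0:
        return []
    probs = np.asarray(proportions, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_total, probs)
    mixed: list[ReadPair] = []
    for c, (pool, count) in enumerate(zip(clone_pools, counts)):
        if count > len(pool):
            raise PoolExhaustedError(f"clone_{c}", int(count), len(pool))
        idx = rng.choice(len(pool), size=int(count), replace=False)
        mixed.extend(pool[i] for i in idx)
    rng.shuffle(mixed)
    return mixed


def admix(
    tumor_pool: Sequence[ReadPair],
    control_pool: Sequence[ReadPair],
    a: float,
    n_total: int,
    seed: int,
    out_prefix: str,
    sample_id: str | None = None,
    quality: int = 30,
) -> MixedSample:
    """Build one admixed tumor-control pair at constant total depth.

    The tumor sample holds round(a * n_total) control read pairs plus
    n_total - round(a * n_total) tumor pairs, shuffled; the matched control
    sample holds n_total control pairs drawn disjointly from the spike.
    """
    if not (0.0 <= a < 1.0):
        raise ConfigError("admixture level must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_ctrl_spike = int(round(a * n_total))
    n_tumor = n_total - n_ctrl_spike
    if n_tumor > len(tumor_pool):
        raise PoolExhaustedError("tumor", n_tumor, len(tumor_pool))
    if n_ctrl_spike + n_total > len(control_pool):
        raise PoolExhaustedError("control", n_ctrl_spike + n_total, len(control_pool))

    ctrl_idx = rng.choice(len(control_pool), size=n_ctrl_spike + n_total, replace=False)
    spike = [control_pool[i] for i in ctrl_idx[:n_ctrl_spike]]
    matched = [control_pool[i] for i in ctrl_idx[n_ctrl_spike:]]
    tumor_idx = rng.choice(len(tumor_pool), size=n_tumor, replace=False)
    tumor_sample = [tumor_pool[i] for i in tumor_idx] + spike
    rng.shuffle(tumor_sample)

    sample_id = sample_id or f"a{a:.1f}"
    t1, t2 = write_fastq_pair(tumor_sample, f"{out_prefix}_tumor", quality=quality)
    c1, c2 = write_fastq_pair(matched, f"{out_prefix}_control", quality=quality)
    counts: dict[str, int] = {"control_spike": n_ctrl_spike}
    for pair in tumor_sample:
        src = pair.name.split("|", 1)[0]
        counts[src] = counts.get(src, 0) + 1
    return MixedSample(
        sample_id=sample_id,
        admixture=a,
        tumor_r1=t1,
        tumor_r2=t2,
        control_r1=c1,
        control_r2=c2,
        realized_counts=counts,
    )


def expected_allele_fraction(
    variant: VariantSpec, design: SampleDesign, a: float
) -> float:
    """AF = (1 - a) * sum of carrying-clone proportions * zygosity factor."""
    if not (0.0 <= a <= 1.0):
        raise ConfigError("admixture level must lie in [0, 1]")
    p = design.clone_proportions
    for c in variant.clone_ids:
        if c < 0 or c >= len(p):
            raise DataError(f"clone id {c} outside design with {len(p)} clones")
    z = 0.5 if variant.zygosity == "het" else 1.0
    return (1.0 - a) * sum(p[c] for c in variant.clone_ids) * z


def af_table(truth: TruthTable, design: SampleDesign) -> pd.DataFrame:
    """Expected AF of every somatic copy-number record at every admixture
    level; indexed by variant id with chrom/start/end/type columns."""
    rows = []
    for r in truth.scna_records():
        row = {
            "variant_id": r.variant_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "type": r.scna_type,
            "zygosity": r.zygosity,
        }
        for a in design.admixture_levels:
            row[f"af_{a:.1f}"] = expected_allele_fraction(r, design, a)
        rows.append(row)
    columns = ["variant_id", "chrom", "start", "end", "type", "zygosity"] + [
        f"af_{a:.1f}" for a in design.admixture_levels
    ]
    return pd.DataFrame(rows, columns=columns)
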