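import numpy as np
import pytest
from scipy import stats

from scnabench import genome_forge as gf
from scnabench.errors import ConfigError, DataError, PlacementError


# ---------------------------------------------------------------------------
# Toy reference
# ---------------------------------------------------------------------------


def gc_fraction(seq: str) -> float:
    return sum(seq.count(b) for b in "GC") / len(seq)


def test_toy_reference_length_and_gc():
    model = gf.ChromosomeModel("chr1", 1000, centromere=500, gc_profile=(0.5,))
    ref = gf.generate_toy_reference([model], seed=7)
    assert len(ref["chr1"]) == 1000
    assert 0.45 <= gc_fraction(ref["chr1"]) <= 0.55


def test_toy_reference_deterministic():
    model = gf.ChromosomeModel("chr1", 1000, centromere=500, gc_profile=(0.5,))
    a = gf.generate_toy_reference([model], seed=7)
    b = gf.generate_toy_reference([model], seed=7)
    assert a == b
    c = gf.generate_toy_reference([model], seed=8)
    assert a != c


def test_toy_reference_gc_one_is_all_gc():
    model = gf.ChromosomeModel("chr1", 500, centromere=250, gc_profile=(1.0,))
    ref = gf.generate_toy_reference([model], seed=1)
    assert set(ref["chr1"]) <= {"G", "C"}


def test_toy_reference_windowed_profile():
    model = gf.ChromosomeModel("chr1", 4000, centromere=2000, gc_profile=(0.3, 0.7))
    ref = gf.generate_toy_reference([model], seed=2)
    assert abs(gc_fraction(ref["chr1"][:2000]) - 0.3) <= 0.05
    assert abs(gc_fraction(ref["chr1"][2000:]) - 0.7) <= 0.05


def test_zero_length_chromosome_rejected():
    with pytest.raises(ConfigError):
        gf.ChromosomeModel("chr1", 0)


# ---------------------------------------------------------------------------
# VariantSpec invariants
# ---------------------------------------------------------------------------


def test_variant_spec_validation():
    with pytest.raises(DataError):
        gf.VariantSpec("chr1", 10, 10, "CNV_DEL")  # empty deletion
    with pytest.raises(DataError):
        gf.VariantSpec("chr1", 10, 20, "CNV_AMP", alt=0)  # copies < 1
    with pytest.raises(DataError):
        gf.VariantSpec("chr1", 10, 20, "CNV_DEL", zygosity="het", haplotypes=(0, 1))
    with pytest.raises(DataError):
        gf.VariantSpec("chr1", 10, 20, "CNV_DEL", zygosity="hom", haplotypes=(0,))
    spec = gf.VariantSpec("chr1", 10, 10, "INS", alt="ACGT")
    assert spec.span() == (10, 11)


def test_scna_type():
    amp = gf.VariantSpec("chr1", 0, 10, "CNV_AMP", alt=2, origin="somatic",
                         clone_ids={0})
    assert amp.scna_type == "amp"
    snv = gf.VariantSpec("chr1", 0, 1, "SNV", alt="A")
    with pytest.raises(DataError):
        snv.scna_type


# ---------------------------------------------------------------------------
# Catalog sampling
# ---------------------------------------------------------------------------

SMALL_CATALOG = dict(
    germline_snvs=0, germline_indels=0, germline_cnv_del=10, germline_cnv_dup=10,
    germline_cnv_size_range=(52, 1_000), somatic_cnv_size_range=(500, 5_000),
)


def test_catalog_counts_match_config(toy_models):
    config = gf.CatalogConfig(somatic_arm=4, somatic_del=20, somatic_amp=20,
                              **SMALL_CATALOG)
    germline, somatic = gf.sample_variant_catalog(config, toy_models, seed=3)
    assert len(somatic) == 44
    assert sum(1 for s in somatic if s.arm_length_flag) == 4
    assert sum(1 for s in somatic if s.vtype == "CNV_DEL" and not s.arm_length_flag) == 20
    assert sum(1 for s in somatic if s.vtype == "CNV_AMP" and not s.arm_length_flag) == 20
    assert len(germline) == 20


def test_catalog_design_counts(toy_models):
    # per-replicate design: 16 arm + 50 del + 50 amp = 116 somatic SCNAs
    models = gf.default_chrom_models(n_chroms=20, length=400_000)
    config = gf.CatalogConfig(
        germline_cnv_del=0, germline_cnv_dup=0,
        somatic_cnv_size_range=(2_000, 60_000),
    )
    _, somatic = gf.sample_variant_catalog(config, models, seed=4)
    assert len(somatic) == 116


def test_catalog_all_zero(toy_models):
    config = gf.CatalogConfig(
        germline_cnv_del=0, germline_cnv_dup=0, somatic_arm=0, somatic_del=0,
        somatic_amp=0,
    )
    germline, somatic = gf.sample_variant_catalog(config, toy_models, seed=1)
    assert germline == [] and somatic == []


def test_catalog_het_prob_one(toy_models):
    config = gf.CatalogConfig(
        het_prob=1.0, somatic_arm=0, somatic_del=100, somatic_amp=100,
        germline_cnv_del=0, germline_cnv_dup=0,
        somatic_cnv_size_range=(100, 1_000),
    )
    _, somatic = gf.sample_variant_catalog(config, toy_models, seed=9)
    assert all(s.zygosity == "het" for s in somatic)


def test_catalog_non_overlap(toy_models):
    config = gf.CatalogConfig(somatic_arm=2, somatic_del=30, somatic_amp=30,
                              germline_snvs=50, germline_indels=10,
                              germline_cnv_del=10, germline_cnv_dup=10,
                              germline_cnv_size_range=(52, 1_000),
                              somatic_cnv_size_range=(500, 5_000))
    germline, somatic = gf.sample_variant_catalog(config, toy_models, seed=5)
    spans = {}
    for spec in germline + somatic:
        spans.setdefault(spec.chrom, []).append(spec.span())
    for chrom_spans in spans.values():
        chrom_spans.sort()
        for (s1, e1), (s2, e2) in zip(chrom_spans, chrom_spans[1:]):
            assert e1 <= s2


def test_catalog_arm_length_events(toy_models):
    config = gf.CatalogConfig(somatic_arm=4, somatic_del=0, somatic_amp=0,
                              germline_cnv_del=0, germline_cnv_dup=0)
    _, somatic = gf.sample_variant_catalog(config, toy_models, seed=6)
    by_name = {m.name: m for m in toy_models}
    for spec in somatic:
        model = by_name[spec.chrom]
        length = spec.end - spec.start
        for arm_start, arm_end in model.arms:
            if arm_start <= spec.start and spec.end <= arm_end:
                assert length >= 0.9 * (arm_end - arm_start)
                break
        else:
            pytest.fail("arm event does not sit inside a single arm")


def test_placement_failure_names_category():
    tiny = [gf.ChromosomeModel("chr1", 2_000, centromere=1_000)]
    config = gf.CatalogConfig(
        somatic_arm=0, somatic_del=500, somatic_amp=0,
        germline_cnv_del=0, germline_cnv_dup=0,
        somatic_cnv_size_range=(500, 1_000), max_retries=20,
    )
    with pytest.raises(PlacementError, match="somatic_del"):
        gf.sample_variant_catalog(config, tiny, seed=1)


def test_het_fraction_within_binomial_99(toy_models):
    # 2000 CNVs at het_prob 0.9: observed het count inside the exact
    # central 99% binomial interval
    models = gf.default_chrom_models(n_chroms=10, length=400_000)
    config = gf.CatalogConfig(
        somatic_arm=0, somatic_del=1000, somatic_amp=1000,
        germline_cnv_del=0, germline_cnv_dup=0,
        somatic_cnv_size_range=(100, 1_000),
    )
    _, somatic = gf.sample_variant_catalog(config, models, seed=12)
    n_het = sum(1 for s in somatic if s.zygosity == "het")
    lo = stats.binom.ppf(0.005, 2000, 0.9)
    hi = stats.binom.ppf(0.995, 2000, 0.9)
    assert lo <= n_het <= hi


# ---------------------------------------------------------------------------
# Implantation
# ---------------------------------------------------------------------------


def test_implant_tandem_amp_lengths():
    ref = {"chr1": "A" * 40 + "CGCGTTTTGG" + "A" * 50}
    spec = gf.VariantSpec("chr1", 40, 50, "CNV_AMP", alt=1, zygosity="het",
                          haplotypes=(0,))
    genome, truth = gf.implant_variants(ref, [spec])
    assert genome.length("chr1", 0) == 110
    assert genome.length("chr1", 1) == 100
    rec = truth.cnv_records()[0]
    assert (rec.chrom, rec.start, rec.end, rec.scna_type) == ("chr1", 40, 50, "amp")
    # tandem: source followed by extra copy
    assert genome.sequence("chr1", 0)[40:60] == "CGCGTTTTGG" * 2


def test_implant_hom_deletion():
    ref = {"chr1": "ACGT" * 25}
    spec = gf.VariantSpec("chr1", 10, 30, "CNV_DEL", zygosity="hom",
                          haplotypes=(0, 1))
    genome, _ = gf.implant_variants(ref, [spec])
    assert genome.length("chr1", 0) == 80
    assert genome.length("chr1", 1) == 80


def test_implant_snv_and_ins():
    ref = {"chr1": "AAAAAAAAAA"}
    snv = gf.VariantSpec("chr1", 2, 3, "SNV", alt="G", zygosity="het", haplotypes=(0,))
    ins = gf.VariantSpec("chr1", 6, 6, "INS", alt="TTT", zygosity="hom",
                         haplotypes=(0, 1))
    genome, _ = gf.implant_variants(ref, [snv, ins])
    assert genome.sequence("chr1", 0) == "AAGAAATTTAAAA"
    assert genome.sequence("chr1", 1) == "AAAAAATTTAAAA"


def test_implant_length_formula_random(toy_models, toy_reference):
    # closed-form length bookkeeping, independent of the editor
    config = gf.CatalogConfig(somatic_arm=1, somatic_del=15, somatic_amp=15,
                              germline_snvs=30, germline_indels=10,
                              germline_cnv_del=10, germline_cnv_dup=10,
                              germline_cnv_size_range=(52, 1_000),
                              somatic_cnv_size_range=(500, 5_000),
                              amp_extra_copies=2)
    germline, somatic = gf.sample_variant_catalog(config, toy_models, seed=21)
    specs = germline + somatic
    genome, _ = gf.implant_variants(toy_reference, specs)
    for chrom, seq in toy_reference.items():
        for hap in (0, 1):
            expected = len(seq)
            for spec in specs:
                if spec.chrom != chrom or hap not in spec.haplotypes:
                    continue
                if spec.vtype == "INS":
                    expected += len(spec.alt)
                elif spec.vtype in ("SMALL_DEL", "CNV_DEL"):
                    expected -= spec.end - spec.start
                elif spec.vtype == "CNV_AMP":
                    expected += (spec.end - spec.start) * spec.alt
            assert genome.length(chrom, hap) == expected


def test_implant_out_of_bounds_rejected():
    ref = {"chr1": "ACGT" * 10}
    spec = gf.VariantSpec("chr1", 30, 50, "CNV_DEL", zygosity="hom",
                          haplotypes=(0, 1))
    with pytest.raises(DataError, match="30-50"):
        gf.implant_variants(ref, [spec])


def test_implant_overlapping_specs_rejected():
    ref = {"chr1": "ACGT" * 25}
    a = gf.VariantSpec("chr1", 10, 30, "CNV_DEL", zygosity="hom", haplotypes=(0, 1))
    b = gf.VariantSpec("chr1", 20, 40, "CNV_DEL", zygosity="hom", haplotypes=(0, 1))
    with pytest.raises(DataError, match="overlap"):
        gf.implant_variants(ref, [a, b])


def test_liftover_projection_roundtrip():
    ref = {"chr1": "".join("ACGT"[i % 4] for i in range(100))}
    amp = gf.VariantSpec("chr1", 40, 50, "CNV_AMP", alt=1, zygosity="het",
                         haplotypes=(0,))
    deletion = gf.VariantSpec("chr1", 70, 80, "CNV_DEL", zygosity="het",
                              haplotypes=(0,))
    genome, _ = gf.implant_variants(ref, [amp, deletion])
    # extra copy [50, 60) on hap0 projects back to source interval [40, 50)
    assert genome.project("chr1", 0, 50, 60) == [(40, 50)]
    # hap0 length: 100 + 10 (extra copy) - 10 (deletion) = 100; the region
    # after the deletion projects past the removed reference interval
    assert genome.length("chr1", 0) == 100
    assert genome.project("chr1", 0, 90, 100) == [(90, 100)]
    # a window straddling the deletion skips the deleted reference bases
    assert genome.project("chr1", 0, 75, 85) == [(65, 70), (80, 85)]
    # hap1 untouched
    assert genome.project("chr1", 1, 10, 20) == [(10, 20)]
    # liftover blocks sorted, non-overlapping on the haplotype axis
    for (chrom, hap) in genome.keys():
        blocks = genome.liftover[(chrom, hap)]
        for b1, b2 in zip(blocks, blocks[1:]):
            assert b1.hap_end <= b2.hap_start
        assert blocks[-1].hap_end == genome.length(chrom, hap)


# ---------------------------------------------------------------------------
# Clone genomes
# ---------------------------------------------------------------------------


def make_somatic(toy_models, seed, n=12):
    config = gf.CatalogConfig(
        somatic_arm=0, somatic_del=n // 2, somatic_amp=n - n // 2,
        germline_cnv_del=0, germline_cnv_dup=0,
        somatic_cnv_size_range=(500, 5_000),
    )
    return gf.sample_variant_catalog(config, toy_models, seed=seed)[1]


def test_single_clone_truncal(toy_models, toy_reference):
    somatic = make_somatic(toy_models, 31)
    _, clones, truth = gf.build_clone_genomes(
        toy_reference, [], somatic, n_clones=1, truncal_fraction=1.0, seed=1
    )
    assert len(clones) == 1
    assert all(r.clone_ids == frozenset({0}) for r in truth.scna_records())


def test_uniform_assignment_counts(toy_models, toy_reference):
    models = gf.default_chrom_models(n_chroms=20, length=400_000)
    ref = gf.generate_toy_reference(models, seed=40)
    config = gf.CatalogConfig(germline_cnv_del=0, germline_cnv_dup=0,
                              somatic_cnv_size_range=(2_000, 60_000))
    _, somatic = gf.sample_variant_catalog(config, models, seed=41)
    _, clones, truth = gf.build_clone_genomes(ref, [], somatic, n_clones=5, seed=42)
    records = truth.scna_records()
    assert len(records) == 116
    assert all(len(r.clone_ids) == 1 for r in records)
    per_clone = [sum(1 for r in records if c in r.clone_ids) for c in range(5)]
    assert sum(per_clone) == 116


def test_zero_somatic_clones_identical(toy_models, toy_reference):
    control, clones, _ = gf.build_clone_genomes(
        toy_reference, [], [], n_clones=2, seed=3
    )
    for clone in clones:
        for key in control.keys():
            assert clone.sequences[key] == control.sequences[key]


def test_invalid_clone_count(toy_reference):
    with pytest.raises(ConfigError):
        gf.build_clone_genomes(toy_reference, [], [], n_clones=0)


def test_explicit_assignment(toy_models, toy_reference):
    somatic = make_somatic(toy_models, 33, n=4)
    assignment = [{0}, {1}, {0, 1}, {1}]
    _, _, truth = gf.build_clone_genomes(
        toy_reference, [], somatic, n_clones=2, assignment=assignment, seed=1
    )
    got = [set(r.clone_ids) for r in truth.scna_records()]
    assert got == [set(a) for a in assignment]


# ---------------------------------------------------------------------------
# Truth I/O
# ---------------------------------------------------------------------------


def test_truth_round_trip(tmp_path, toy_models):
    somatic = make_somatic(toy_models, 51)
    table = gf.TruthTable(records=somatic)
    path = tmp_path / "truth.bed"
    gf.export_truth(table, path)
    back = gf.read_truth(path)

    def key(r):
        return (r.chrom, r.start, r.end, r.scna_type, r.zygosity,
                frozenset(r.clone_ids), r.origin, r.arm_length_flag)

    assert sorted(map(key, back.records)) == sorted(map(key, table.cnv_records()))


def test_truth_empty_table(tmp_path):
    path = tmp_path / "truth.bed"
    gf.export_truth(gf.TruthTable(records=[]), path)
    content = path.read_text()
    assert content.startswith("#chrom\tstart\tend\ttype")
    assert len(content.strip().splitlines()) == 1


def test_truth_line_format(tmp_path):
    rec = gf.VariantSpec("chr1", 40, 50, "CNV_AMP", alt=1, zygosity="het",
                         haplotypes=(0,), origin="somatic", clone_ids={2})
    path = tmp_path / "truth.bed"
    gf.export_truth(gf.TruthTable(records=[rec]), path)
    line = path.read_text().strip().splitlines()[1]
    assert line == "chr1\t40\t50\tamp\thet\t2\tsomatic\t0"


def test_truth_determinism(tmp_path, toy_models):
    config = gf.CatalogConfig(somatic_arm=2, somatic_del=10, somatic_amp=10,
                              **SMALL_CATALOG)
    for run in (1, 2):
        germ, som = gf.sample_variant_catalog(config, toy_models, seed=77)
        gf.export_truth(gf.TruthTable(records=germ + som), tmp_path / f"t{run}.bed")
    assert (tmp_path / "t1.bed").read_bytes() == (tmp_path / "t2.bed").read_bytes()


def test_fasta_round_trip(tmp_path, toy_reference):
    path = tmp_path / "ref.fa"
    gf.write_fasta(toy_reference, path)
    back = gf.read_fasta(path)
    assert back == toy_reference
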