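import numpy as np
import pytest

from scnabench import bench_harness as bh
from scnabench import genome_forge as gf


@pytest.fixture(scope="session")
def toy_models():
    return gf.default_chrom_models(n_chroms=4, length=100_000)


@pytest.fixture(scope="session")
def toy_reference(toy_models):
    return gf.generate_toy_reference(toy_models, seed=11)


@pytest.fixture(scope="session")
def mini_cohort(tmp_path_factory):
    """One mini cohort (2 replicates x 3 admixture levels, with reads),
    shared across harness and acceptance tests."""
    outdir = tmp_path_factory.mktemp("mini_cohort")
    config = bh.mini_design_config(seed=5)
    manifest = bh.run_cohort(config, outdir)
    return {"dir": outdir, "manifest": manifest, "config": config}


@pytest.fixture(scope="session")
def paper_cohort(tmp_path_factory):
    """Full benchmark-design cohort (5 x 10) on the toy reference, reads off."""
    outdir = tmp_path_factory.mktemp("paper_cohort")
    config = bh.paper_design_config(seed=7)
    manifest = bh.run_cohort(config, outdir)
    return {"dir": outdir, "manifest": manifest, "config": config}


def random_segments(rng: np.random.Generator, n: int, span: int = 100_000, chroms=("chr1", "chr2")):
    """Random typed segments for oracle-equivalence tests."""
    from scnabench.scna_eval import Segment

    out = []
    for _ in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(span - 1))
        end = start + 1 + int(rng.integers(min(5_000, span - start - 1) + 1))
        stype = "amp" if rng.random() < 0.5 else "del"
        out.append(Segment(chrom, start, end, stype))
    return out
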