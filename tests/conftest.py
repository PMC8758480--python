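import textwrap

import pytest

from splicecons.pipeline import RunConfig, run_pipeline
from splicecons.synthetic_data import SimulationConfig, simulate

#: hg38 plus five species at staggered distances; multifurcating on purpose
SMALL_TREE = "(hg38:0.0,spA:0.25,spB:0.5,spC:1.0,spD:2.0,spE:3.0);"

TINY_MAF = textwrap.dedent(
    """\
    ##maf version=1
    a score=0
    s hg38.chr1 10 4 + 1000 AC-GT
    s mm10.chr1 50 5 + 2000 ACTGT
    s rn6.chr1 7 3 + 1500 A--GT

    a score=0
    s hg38.chr1 100 8 + 1000 ACGTACGT
    s mm10.chr1 60 8 + 2000 TTGTACGA
    """
)


@pytest.fixture
def tiny_maf(tmp_path):
    path = tmp_path / "tiny.maf"
    path.write_text(TINY_MAF)
    return path


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Noiseless 40-transcript simulation plus a full pipeline run."""
    outdir = tmp_path_factory.mktemp("small_sim")
    cfg = SimulationConfig(
        seed=42, tree=SMALL_TREE, n_target=10, n_background=30, max_exons=6
    )
    paths = simulate(cfg, outdir)
    run_config = RunConfig(
        annotation=paths["bed"],
        maf=paths["maf"],
        tree=paths["tree"],
        target_ids=paths["target_ids"],
        background_ids=paths["background_ids"],
        outdir=outdir / "out",
        reference="hg38",
    )
    run_pipeline(run_config)
    return {"config": cfg, "paths": paths, "run_config": run_config,
            "outdir": outdir / "out"}
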