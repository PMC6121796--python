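import numpy as np
import pandas as pd
import pytest

from migradiv import pipeline, synthetic_data

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
scf1\t101\t.\tA\tG\t50\tPASS\t.\tGT:DP\t0/0:10\t0/1:12
scf1\t205\t.\tC\tT\t40\tPASS\t.\tGT:DP\t1/1:9\t./.:0
scf1\t300\t.\tG\tA,T\t30\tPASS\t.\tGT:DP\t0/1:8\t1/1:7
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def tiny_sim_config(seed: int = 0) -> synthetic_data.SimConfig:
    """A miniature study (two regions, small genome) for fast pipeline tests."""
    from migradiv.cline_analysis import ClineModel

    sweden = synthetic_data.TransectPlan("sweden", 55.5, 13.0, 68.5, 21.0,
                                         n_sites=12, n_per_site=10)
    sw = sweden.length_km
    regions = [
        synthetic_data.RegionPlan(
            "chr1", "scf_chr1", 40_000, 140_000, theta_n=0.007,
            clines={"sweden": ClineModel(0.5 * sw, 350.0, 0.02, 0.98)}),
        synthetic_data.RegionPlan(
            "chr3", "scf_chr3", 40_000, 140_000, driver="environment",
            environment=synthetic_data.EnvironmentModel()),
        synthetic_data.RegionPlan(
            "chr5", "scf_chr5", 30_000, 110_000, theta_n=0.007,
            clines={"sweden": ClineModel(0.5 * sw, 271.0, 0.02, 0.98)}),
    ]
    return synthetic_data.SimConfig(
        seed=seed,
        scaffold_lengths={"scf_chr1": 180_000, "scf_bg2": 120_000,
                          "scf_chr3": 180_000, "scf_chr5": 150_000},
        scaffold_chromosomes={"scf_chr1": "1", "scf_bg2": "2",
                              "scf_chr3": "3", "scf_chr5": "5"},
        regions=regions,
        transects=[sweden],
        reseq_impurities={"S09": {"chr3": 1}, "N07": {"chr1": 1},
                          "N08": {"chr3": 1}, "N09": {"chr5": 1}},
    )


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """One full default-study pipeline run, shared across tests."""
    workdir = tmp_path_factory.mktemp("study")
    cfg = pipeline.PipelineConfig(workdir=workdir, seed=0)
    pipeline.run_pipeline(cfg)
    return cfg


@pytest.fixture(scope="session")
def study_truth(study_run):
    import json
    return json.load(open(study_run.inputs / "truth.json"))


@pytest.fixture(scope="session")
def study_metadata(study_run):
    return pd.read_csv(study_run.inputs / "metadata.tsv", sep="\t")
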