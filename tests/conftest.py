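from __future__ import annotations

import pytest

from mescan.formats_io import GenomicInterval, PedigreeTrio
from mescan.locus_caller import SampleLibrary
from mescan.read_filtering import MEFamily
from mescan.simulator import (
    FamilySimParams,
    SimulationConfig,
    simulate_reads,
    simulate_truth,
)


@pytest.fixture(scope="session")
def l1hs() -> MEFamily:
    return MEFamily(name="L1HS", bit_cutoff=56.0)


@pytest.fixture()
def trio() -> PedigreeTrio:
    return PedigreeTrio("Y045", "NA18503", "NA18504", "NA18502")


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small noise-free simulated cohort shared by read-level tests.

    Four samples, 30 fixed loci, depth 20; deterministic at seed 11.
    """
    outdir = tmp_path_factory.mktemp("cohort")
    config = SimulationConfig(
        seed=11,
        n_chroms=2,
        chrom_length=400_000,
        families=[FamilySimParams.for_family("L1HS")],
        n_fixed_loci=30,
        samples=[f"S{i:02d}" for i in range(1, 5)],
        depth_mean=20.0,
    )
    truth = simulate_truth(config)
    manifest = simulate_reads(truth, config, outdir)
    return config, truth, manifest


def truth_intervals(truth, cls: str = "fixed_reference"):
    return [
        GenomicInterval(l.chrom, l.position, l.position + 1, l.family)
        for l in truth.loci
        if l.cls == cls
    ]


@pytest.fixture()
def library() -> SampleLibrary:
    return SampleLibrary("S1", "L1HS", total_mapped_reads=1_000_000)
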