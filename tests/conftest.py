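import pytest

from tsrkit.io import CoverageTrack, EndProfile, NORM_FACTOR, NormalizedProfile
from tsrkit.pipeline import analyze_sample
from tsrkit.simulate import SimulationConfig, simulate_all


def make_normalized(entries, total=NORM_FACTOR) -> NormalizedProfile:
    """Normalized profile from (chrom, strand, pos, value) tuples."""
    prof = NormalizedProfile(total_aligned_reads=total)
    for chrom, strand, pos, value in entries:
        prof.add(chrom, strand, pos, value)
    return prof


def make_ends(entries, total=NORM_FACTOR) -> EndProfile:
    prof = EndProfile(total_aligned_reads=total)
    for chrom, strand, pos, value in entries:
        prof.add(chrom, strand, pos, value)
    return prof


def make_coverage(entries, total=NORM_FACTOR) -> CoverageTrack:
    track = CoverageTrack(total_aligned_reads=total)
    for chrom, strand, pos, value in entries:
        track.add(chrom, strand, pos, value)
    return track


@pytest.fixture(scope="session")
def sim_bundle():
    """Default-size simulated dataset shared across test modules."""
    config = SimulationConfig(seed=11)
    genome, annotation, truth, cs, inp, rna, gro, starr = simulate_all(config)
    return {
        "config": config,
        "genome": genome,
        "annotation": annotation,
        "truth": truth,
        "cs": cs,
        "input": inp,
        "rna": rna,
        "gro": gro,
        "starr": starr,
    }


@pytest.fixture(scope="session")
def sim_result(sim_bundle):
    """Full single-sample analysis of the shared simulated dataset."""
    b = sim_bundle
    return analyze_sample(
        "sim", b["cs"].normalize(), b["input"].normalize(), b["rna"].normalize(), b["annotation"]
    )
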