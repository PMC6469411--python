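import pytest

from pevk.scan import ScanParams, find_pevk_exons
from pevk.synthetic import SyntheticTitinSpec, generate_titin


@pytest.fixture(scope="session")
def default_sim():
    """Full-size synthetic titin (99 exons, decoys, N-runs, landmarks)."""
    spec = SyntheticTitinSpec(seed=11)
    genome, truth = generate_titin(spec)
    return spec, genome, truth


@pytest.fixture(scope="session")
def default_exons(default_sim):
    _, genome, _ = default_sim
    return find_pevk_exons(genome, ScanParams())


@pytest.fixture(scope="session")
def small_sim():
    """Compact locus (8 exons, one decoy) that scans in milliseconds."""
    spec = SyntheticTitinSpec(
        n_exons=(5, 2, 1),
        intron_len={"N": (80, 160), "CA": (80, 120), "CB": (80, 160)},
        n_decoys=1,
        n_runs=0,
        flank_len=100,
        seed=3,
    )
    genome, truth = generate_titin(spec)
    return spec, genome, truth
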