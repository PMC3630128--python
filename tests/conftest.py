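import pytest

from subspec.classifier import LibraryBuilder
from subspec.njtree import neighbor_joining, pairwise_distances, substrate_subgroups
from subspec.synthetic import (
    calibrate_threshold,
    convergent_benchmark,
    divergence_contrast_benchmark,
)


@pytest.fixture(scope="session")
def convergent_ds():
    return convergent_benchmark(11)


@pytest.fixture(scope="session")
def contrast_ds():
    return divergence_contrast_benchmark(7)


@pytest.fixture(scope="session")
def convergent_libraries(convergent_ds):
    """Calibrated single and ensemble libraries for the convergent fixture."""
    ds = convergent_ds
    groups = ds.groups()
    tree = neighbor_joining(pairwise_distances(ds.core_alignment))
    partition = substrate_subgroups(
        tree, {s.id: s.substrate for s in ds.sequences}, "S1", max_parts=4, min_part_size=2
    )
    single, _ = LibraryBuilder("A", "single", threshold_bits=0.0).build(groups)
    single.threshold_bits = calibrate_threshold(single, ds.sequences)
    ensemble, _ = LibraryBuilder(
        "A", "ensemble", partitions={"S1": partition}, threshold_bits=0.0
    ).build(groups)
    ensemble.threshold_bits = calibrate_threshold(ensemble, ds.sequences)
    return single, ensemble, partition
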