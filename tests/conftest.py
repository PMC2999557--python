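import numpy as np
import pytest

from znfpipe import ArrayTrack, GenomicInterval, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_peakset(
    rng: np.random.Generator,
    n: int,
    name: str = "random",
    chroms=("chr1", "chr19"),
    span: int = 1_000_000,
) -> PeakSet:
    """Disjoint random peaks with random heights, for oracle comparisons."""
    intervals, heights = [], []
    for chrom in chroms:
        k = n // len(chroms)
        starts = np.sort(rng.choice(span // 200, size=k, replace=False)) * 200
        widths = rng.integers(50, 180, size=k)
        for s, w in zip(starts, widths):
            intervals.append(GenomicInterval(chrom, int(s), int(s + w)))
            heights.append(float(rng.normal(10, 3)))
    return PeakSet.from_intervals(name, intervals, heights)


def dense_track(
    rng: np.random.Generator,
    n_probes: int = 500,
    tile: int = 100,
    probe_len: int = 50,
    chrom: str = "chrT",
) -> ArrayTrack:
    """Gap-free tiling track with Gaussian values plus occasional high runs."""
    starts = np.arange(n_probes, dtype=np.int64) * tile
    values = rng.normal(0, 1, n_probes)
    # sprinkle enriched runs so peaks exist at the tested percentiles
    for _ in range(rng.integers(1, 5)):
        i = int(rng.integers(0, n_probes - 20))
        values[i:i + int(rng.integers(5, 20))] += rng.uniform(2, 5)
    return ArrayTrack(
        probes={chrom: (starts, starts + probe_len, values)}, tile_interval=tile
    )
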