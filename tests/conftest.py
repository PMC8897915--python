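import numpy as np
import pytest

from exondepth import io_coverage, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_regions():
    return [
        io_coverage.make_region("chr1", 100, 200),
        io_coverage.make_region("chr1", 200, 300),
        io_coverage.make_region("chr1", 400, 500),
        io_coverage.make_region("chr2", 50, 150),
    ]


@pytest.fixture
def small_sim():
    spec = synthetic.SimulationSpec(
        n_regions=60,
        n_samples=20,
        seed=123,
        depth_mean=100.0,
        libsize_sd=0.2,
        gc_bias_strength=2.0,
    )
    return synthetic.simulate_coverage(spec)


def random_placements(rng, regions, n_reads, sample="S0"):
    """Random read placements over the span of a region set."""
    chroms = sorted({r.chrom for r in regions})
    hi = max(r.end for r in regions) + 500
    placements = []
    for _ in range(n_reads):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, hi - 10))
        length = int(rng.integers(30, 150))
        mapq = int(rng.choice([0, 10, 30, 60]))
        placements.append(
            synthetic.ReadPlacement(
                sample=sample,
                chrom=chrom,
                start=start,
                end=start + length,
                mapq=mapq,
                is_duplicate=bool(rng.random() < 0.1),
                is_secondary=bool(rng.random() < 0.1),
                is_qcfail=bool(rng.random() < 0.05),
            )
        )
    return placements


def brute_force_counts(placements, regions, read_filter):
    """Independent oracle: scan every read against every region."""
    counts = np.zeros(len(regions), dtype=np.int64)
    for p in placements:
        if p.mapq < read_filter.min_mapq:
            continue
        if p.is_duplicate and not read_filter.include_duplicates:
            continue
        if p.is_secondary and not read_filter.include_secondary:
            continue
        if p.is_qcfail and not read_filter.include_qcfail:
            continue
        for i, r in enumerate(regions):
            if p.chrom == r.chrom and p.start < r.end and p.end > r.start:
                counts[i] += 1
    return counts
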