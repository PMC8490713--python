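"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import cohloop as cl


def make_planted_loops(n=50, seed=3, enrichments=(4.0, 8.0),
                       conditions=("A",)):
    """Loops split evenly over the enrichment levels.

    Weaker loops go at short distances (2-6 bins) where their expected CPM
    clears the retention threshold; stronger ones at 7-12 bins.  Distance
    ranges are disjoint so each group's diagonal fits are not contaminated
    by the other's outliers.
    """
    rng = np.random.default_rng(seed)
    loops, seen = [], set()
    k = 0
    while len(loops) < n:
        enr = enrichments[0] if len(loops) < n // 2 else enrichments[1]
        chrom = "chr1" if k % 2 == 0 else "chr2"
        d = int(rng.integers(2, 7)) if enr == enrichments[0] \
            else int(rng.integers(7, 13))
        b1 = int(rng.integers(20, 980 - d))
        k += 1
        key = (chrom, b1, b1 + d)
        if key in seen:
            continue
        seen.add(key)
        loops.append(cl.PlantedLoop(chrom, b1, b1 + d,
                                    {c: enr for c in conditions}))
    return loops


def checkerboard_config(seed, depth=500_000, n_blocks=10, block_bins=20,
                        strength=1.5):
    """Alternating A/B blocks (2 Mb at 100 kb) on the 2x20 Mb toy genome."""
    blocks = {c: [(k * block_bins, (k + 1) * block_bins,
                   "A" if k % 2 == 0 else "B") for k in range(n_blocks)]
              for c in ("chr1", "chr2")}
    return cl.SimConfig(chrom_sizes={"chr1": 20_000_000, "chr2": 20_000_000},
                        resolution=100_000, depth=depth,
                        compartment_blocks=blocks,
                        checkerboard_strength=strength, seed=seed)


@pytest.fixture(scope="session")
def null_sim():
    """One null library (no loops, no checkerboard) with its matrix."""
    cfg = cl.default_toy_config(depth=200_000, seed=11)
    pairs, truth = cl.simulate_contacts(cfg, "A")
    matrix = cl.bin_pairs(pairs, cfg.chrom_sizes, cfg.resolution)
    return cfg, pairs, truth, matrix


@pytest.fixture(scope="session")
def planted_sim():
    """Recovery conditions: 50 loops at enrichment 4 and 8, tuned depth."""
    loops = make_planted_loops()
    cfg = cl.default_toy_config(depth=2_000_000, seed=7, planted_loops=loops)
    pairs, truth = cl.simulate_contacts(cfg, "A")
    matrix = cl.bin_pairs(pairs, cfg.chrom_sizes, cfg.resolution)
    called = cl.call_loops(matrix)
    return cfg, truth, matrix, called


@pytest.fixture(scope="session")
def checkerboard_tracks():
    """Two same-truth compartment replicates plus their truth objects."""
    out = []
    for seed in (5, 6):
        cfg = checkerboard_config(seed)
        pairs, truth = cl.simulate_contacts(cfg, "A")
        matrix = cl.bin_pairs(pairs, cfg.chrom_sizes, cfg.resolution)
        peaks = pd.DataFrame(truth.reference_peaks,
                             columns=["chrom", "start", "end"])
        signal = cl.peaks_to_bin_signal(peaks, cfg.chrom_sizes, cfg.resolution)
        scorer = cl.CompartmentScorer().fit(matrix, signal)
        out.append((scorer, truth))
    return out
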