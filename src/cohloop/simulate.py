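"""Synthetic Hi-C and somatic-variant data with known ground truth.

The generator emulates the post-alignment products of an in situ Hi-C
experiment on a small toy genome: filtered intra-chromosomal read pairs with
power-law distance decay, optional planted focal loops with
condition-specific enrichment, an A/B compartment checkerboard, and an
H3K27ac-like reference peak track concentrated in A blocks.  It also emits
per-caller somatic variant tables stratified to straddle every hard-filter
boundary, with a truth pass/fail label per variant.

Sampling model: every upper-triangular pixel at bin distance ``d >= 1``
carries an unnormalized weight ``d**(-alpha)`` times a same-compartment
checkerboard boost times any planted-loop enrichment; read pairs are drawn
multinomially over pixels and scattered uniformly within each bin.  This
gives closed-form expected pixel means, which the truth object records per
diagonal so recovery tests can be written against analytic values.
Overdispersion is injected by gamma-distributed per-pixel rate multipliers
(mean 1, variance ``dispersion``); at ``dispersion == 0`` counts are
multinomial/Poisson.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .contacts import PAIR_COLUMNS

__all__ = [
    "SimConfig", "PlantedLoop", "SimTruth",
    "simulate_contacts", "simulate_annotations", "simulate_variant_tables",
    "default_toy_config",
]


@dataclass(frozen=True)
class PlantedLoop:
    """A focal enrichment planted at one pixel, per condition."""
    chrom: str
    bin1: int
    bin2: int
    enrichment: Mapping[str, float]  # condition -> factor >= 1

    def factor(self, condition: str) -> float:
        return float(self.enrichment.get(condition, 1.0))


@dataclass
class SimConfig:
    """Parameters of one simulated Hi-C library.

    ``compartment_blocks`` maps each chromosome to a list of
    ``(start_bin, end_bin, label)`` half-open runs that must tile the
    chromosome; ``checkerboard_strength`` multiplies the weight of pixels
    whose two bins share a label.
    """
    chrom_sizes: Dict[str, int]
    resolution: int = 20_000
    depth: int = 200_000
    decay_exponent: float = 1.0
    planted_loops: List[PlantedLoop] = field(default_factory=list)
    compartment_blocks: Dict[str, List[Tuple[int, int, str]]] = field(default_factory=dict)
    checkerboard_strength: float = 1.0
    dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.checkerboard_strength < 1:
            raise ValueError("checkerboard_strength must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for loop in self.planted_loops:
            n = self.n_bins(loop.chrom)
            if loop.chrom not in self.chrom_sizes:
                raise ValueError(f"planted loop on unknown chromosome {loop.chrom}")
            if not (0 <= loop.bin1 < loop.bin2 < n):
                raise ValueError(
                    f"planted loop anchors ({loop.bin1},{loop.bin2}) outside "
                    f"{loop.chrom} with {n} bins")
            if any(f < 1 for f in loop.enrichment.values()):
                raise ValueError("loop enrichment factors must be >= 1")
        for chrom, blocks in self.compartment_blocks.items():
            n = self.n_bins(chrom)
            pos = 0
            for start, end, label in blocks:
                if start != pos or end <= start or label not in ("A", "B"):
                    raise ValueError(f"blocks must tile {chrom} without overlap")
                pos = end
            if pos != n:
                raise ValueError(f"blocks must cover all {n} bins of {chrom}")

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.resolution)

    def bin_labels(self, chrom: str) -> np.ndarray:
        """Per-bin compartment label array ('A'/'B'); all-'A' if no blocks."""
        n = self.n_bins(chrom)
        labels = np.full(n, "A", dtype="U1")
        for start, end, label in self.compartment_blocks.get(chrom, []):
            labels[start:end] = label
        return labels


def default_toy_config(**overrides) -> SimConfig:
    """Two 20 Mb chromosomes at 20 kb (1,000 bins each): minutes-scale tests."""
    base = dict(chrom_sizes={"chr1": 20_000_000, "chr2": 20_000_000},
                resolution=20_000)
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SimTruth:
    """Ground truth of one simulated library.

    ``expected_diag_mean[chrom]`` is the analytic expected count per pixel at
    each bin distance (index = distance, entry 0 unused), conditional on the
    configured depth.
    """
    config_chrom_sizes: Dict[str, int]
    resolution: int
    condition: str
    loops: List[PlantedLoop]
    bin_labels: Dict[str, List[str]]
    reference_peaks: List[Tuple[str, int, int]]  # H3K27ac-like, BED-style bp
    expected_diag_mean: Dict[str, List[float]]

    def loop_pixels(self) -> List[Tuple[str, int, int]]:
        return [(lp.chrom, lp.bin1, lp.bin2) for lp in self.loops]

    def to_json(self) -> str:
        payload = asdict(self)
        payload["loops"] = [
            {"chrom": lp.chrom, "bin1": lp.bin1, "bin2": lp.bin2,
             "enrichment": dict(lp.enrichment)} for lp in self.loops]
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        payload["loops"] = [PlantedLoop(**lp) for lp in payload["loops"]]
        payload["reference_peaks"] = [tuple(p) for p in payload["reference_peaks"]]
        return cls(**payload)


def _condition_rng(seed: int, condition: str) -> np.random.Generator:
    # stable sub-stream per condition so two conditions from one seed differ
    return np.random.default_rng([seed, zlib.crc32(condition.encode()) % (2**31)])


def _pixel_weights(config: SimConfig, chrom: str, condition: str
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat (i, j, weight) arrays over all upper-tri pixels at distance >= 1."""
    n = config.n_bins(chrom)
    labels = config.bin_labels(chrom)
    ii, jj, ww = [], [], []
    for d in range(1, n):
        i = np.arange(n - d)
        j = i + d
        w = np.full(n - d, float(d) ** (-config.decay_exponent))
        if config.checkerboard_strength > 1:
            same = labels[i] == labels[j]
            w[same] *= config.checkerboard_strength
        ii.append(i)
        jj.append(j)
        ww.append(w)
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    w = np.concatenate(ww)
    for loop in config.planted_loops:
        if loop.chrom != chrom:
            continue
        idx = np.flatnonzero((i == loop.bin1) & (j == loop.bin2))[0]
        w[idx] *= loop.factor(condition)
    return i, j, w


def simulate_contacts(config: SimConfig, condition: str = "A"
                      ) -> Tuple[pd.DataFrame, SimTruth]:
    """Draw ``config.depth`` intra-chromosomal read pairs plus ground truth.

    Deterministic given ``config.seed`` and ``condition``.  Returns the pairs
    as a DataFrame with columns (chrom1, pos1, chrom2, pos2), 0-based bp.
    """
    rng = _condition_rng(config.seed, condition)
    chroms = list(config.chrom_sizes)
    per_chrom = {c: _pixel_weights(config, c, condition) for c in chroms}
    totals = np.array([per_chrom[c][2].sum() for c in chroms])
    grand = totals.sum()

    expected: Dict[str, List[float]] = {}
    for c, tot in zip(chroms, totals):
        i, j, w = per_chrom[c]
        d = j - i
        n = config.n_bins(c)
        mean = np.zeros(n)
        sums = np.bincount(d, weights=w, minlength=n)
        npix = np.bincount(d, minlength=n).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(npix > 0, sums / np.maximum(npix, 1), 0.0) \
                * config.depth / grand
        expected[c] = mean.tolist()

    # gamma rate multipliers give negative-binomial-like marginal counts
    rows = []
    probs = []
    for c in chroms:
        i, j, w = per_chrom[c]
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            w = w * rng.gamma(shape, 1.0 / shape, size=len(w))
        probs.append(w)
    p = np.concatenate(probs)
    p /= p.sum()
    counts = rng.multinomial(config.depth, p)

    res = config.resolution
    offset = 0
    for c in chroms:
        i, j, _ = per_chrom[c]
        cc = counts[offset:offset + len(i)]
        offset += len(i)
        nz = cc > 0
        i_rep = np.repeat(i[nz], cc[nz])
        j_rep = np.repeat(j[nz], cc[nz])
        size = config.chrom_sizes[c]
        pos1 = i_rep * res + rng.integers(0, res, size=len(i_rep))
        pos2 = j_rep * res + rng.integers(0, res, size=len(j_rep))
        pos1 = np.minimum(pos1, size - 1)
        pos2 = np.minimum(pos2, size - 1)
        rows.append(pd.DataFrame({"chrom1": c, "pos1": pos1,
                                  "chrom2": c, "pos2": pos2}))
    pairs = pd.concat(rows, ignore_index=True)
    # shuffle so downstream order-invariance is exercised, deterministically
    pairs = pairs.sample(frac=1.0, random_state=int(rng.integers(2**31))) \
        .reset_index(drop=True)

    truth = SimTruth(
        config_chrom_sizes=dict(config.chrom_sizes),
        resolution=config.resolution,
        condition=condition,
        loops=list(config.planted_loops),
        bin_labels={c: config.bin_labels(c).tolist() for c in chroms},
        reference_peaks=_reference_peaks(config, rng),
        expected_diag_mean=expected,
    )
    return pairs[PAIR_COLUMNS], truth


def _reference_peaks(config: SimConfig, rng: np.random.Generator
                     ) -> List[Tuple[str, int, int]]:
    """H3K27ac-like peaks concentrated in A blocks, ~2 per A bin, 1 kb wide."""
    peaks: List[Tuple[str, int, int]] = []
    res = config.resolution
    for chrom in config.chrom_sizes:
        blocks = config.compartment_blocks.get(chrom)
        if blocks is None:
            blocks = [(0, config.n_bins(chrom), "A")]
        for start, end, label in blocks:
            if label != "A":
                continue
            n_peaks = max(3, 2 * (end - start))
            lo, hi = start * res, min(end * res, config.chrom_sizes[chrom])
            starts = np.sort(rng.integers(lo, max(lo + 1, hi - 1000), size=n_peaks))
            for s in starts:
                peaks.append((chrom, int(s), int(min(s + 1000, hi))))
    return peaks


def expected_loop_pixel_count(config: SimConfig, condition: str = "A"
                              ) -> Dict[Tuple[str, int, int], float]:
    """Analytic expected count at every planted-loop pixel for one condition."""
    chroms = list(config.chrom_sizes)
    per_chrom = {c: _pixel_weights(config, c, condition) for c in chroms}
    grand = sum(per_chrom[c][2].sum() for c in chroms)
    out = {}
    for loop in config.planted_loops:
        i, j, w = per_chrom[loop.chrom]
        idx = np.flatnonzero((i == loop.bin1) & (j == loop.bin2))[0]
        out[(loop.chrom, loop.bin1, loop.bin2)] = float(w[idx]) * config.depth / grand
    return out


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(truth: SimTruth, loops_covered: float = 1.0,
                         n_random_promoters: int = 50,
                         n_random_enhancers: int = 50,
                         seed: int = 0
                         ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter and enhancer BED intervals matched to planted loops.

    A fraction ``loops_covered`` of planted loops (the first ones, in
    registry order after a seeded shuffle) receives a promoter interval
    inside anchor 1 and an enhancer interval inside anchor 2; the remaining
    intervals are placed uniformly at random.  Returns BED6-style DataFrames
    (promoters carry gene names in the name column).
    """
    if not 0 <= loops_covered <= 1:
        raise ValueError("loops_covered must be in [0, 1]")
    rng = np.random.default_rng(seed)
    res = truth.resolution
    sizes = truth.config_chrom_sizes
    loops = list(truth.loops)
    order = rng.permutation(len(loops))
    n_cover = int(round(loops_covered * len(loops)))
    covered = [loops[k] for k in order[:n_cover]]

    prom_rows, enh_rows = [], []
    for g, lp in enumerate(covered):
        a1_lo = lp.bin1 * res
        a2_lo = lp.bin2 * res
        prom_rows.append((lp.chrom, a1_lo + res // 4, a1_lo + res // 4 + 2000,
                          f"gene{g:04d}", 0, "+"))
        enh_rows.append((lp.chrom, a2_lo + res // 2, a2_lo + res // 2 + 1000,
                         f"enh{g:04d}", 0, "."))
    chroms = list(sizes)
    for k in range(n_random_promoters):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, sizes[c] - 2000))
        prom_rows.append((c, s, s + 2000, f"rgene{k:04d}", 0, "+"))
    for k in range(n_random_enhancers):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, sizes[c] - 1000))
        enh_rows.append((c, s, s + 1000, f"renh{k:04d}", 0, "."))
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    promoters = pd.DataFrame(prom_rows, columns=cols) \
        .sort_values(["chrom", "start"]).reset_index(drop=True)
    enhancers = pd.DataFrame(enh_rows, columns=cols) \
        .sort_values(["chrom", "start"]).reset_index(drop=True)
    return promoters, enhancers


# ---------------------------------------------------------------------------
# variant tables

CALLERS = ("MuTect", "Strelka2", "VarScan")

RETAINED_CONSEQUENCES = frozenset({
    "missense_variant", "synonymous_variant", "stop_gained",
    "frameshift_variant", "splice_region_variant", "NMD_transcript_variant",
})
DROPPED_CONSEQUENCES = ("intron_variant", "intergenic_variant",
                        "3_prime_UTR_variant", "upstream_gene_variant")

VARIANT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "tumor_depth",
                   "tumor_alt", "germline_vaf", "consequence", "dbsnp", "gene"]


def simulate_variant_tables(n_variants: int, seed: int = 0,
                            sample_id: str = "tumor1"
                            ) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-caller somatic variant tables stratified across filter boundaries.

    Every variant is assigned: a caller subset of size 1-3, a depth
    straddling 30, alt reads straddling 5, tumor VAF straddling 10%, germline
    VAF straddling 1%, a dbSNP flag, and a consequence class — such that each
    filter dimension is exercised at, below and above its threshold.  The
    returned truth table labels each variant "pass" iff it would survive the
    consensus (>= 2 callers) plus all hard filters.
    """
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    recs = []
    for k in range(n_variants):
        n_callers = int(rng.choice([1, 2, 3], p=[0.25, 0.35, 0.4]))
        callers = sorted(rng.choice(CALLERS, size=n_callers, replace=False))
        # depth straddles 30 (incl. the boundary), alt straddles 5
        depth = int(rng.choice([20, 25, 29, 30, 31, 60, 100, 150]))
        vaf_target = float(rng.choice([0.04, 0.08, 0.099, 0.10, 0.2, 0.4]))
        alt = int(rng.choice([2, 3, 4, 5, 6]) if rng.random() < 0.35
                  else max(0, round(vaf_target * depth)))
        alt = min(alt, depth)
        gvaf = float(rng.choice([0.0, 0.005, 0.01, 0.011, 0.02, 0.08]))
        dbsnp = bool(rng.random() < 0.2)
        if rng.random() < 0.7:
            csq = str(rng.choice(sorted(RETAINED_CONSEQUENCES)))
        else:
            csq = str(rng.choice(DROPPED_CONSEQUENCES))
        ref = str(rng.choice(bases))
        alt_base = str(rng.choice(bases[bases != ref]))
        tvaf = alt / depth if depth > 0 else 0.0
        passed = (len(callers) >= 2 and depth >= 30 and alt >= 5
                  and tvaf >= 0.10 and gvaf <= 0.01 and not dbsnp
                  and csq in RETAINED_CONSEQUENCES)
        recs.append({
            "sample_id": sample_id, "chrom": f"chr{1 + k % 19}",
            "pos": 1_000_000 + 1000 * k, "ref": ref, "alt": alt_base,
            "tumor_depth": depth, "tumor_alt": alt, "germline_vaf": gvaf,
            "consequence": csq, "dbsnp": dbsnp, "gene": f"Gene{k % 40:03d}",
            "callers": callers, "truth": "pass" if passed else "drop",
        })
    truth = pd.DataFrame(recs)
    tables = {}
    for caller in CALLERS:
        sub = truth[[caller in cs for cs in truth["callers"]]]
        tables[caller] = sub[VARIANT_COLUMNS].reset_index(drop=True)
    truth = truth[VARIANT_COLUMNS + ["callers", "truth"]]
    return tables, truth
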