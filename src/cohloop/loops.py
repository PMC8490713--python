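"""Chromatin loop calling by a negative-binomial test per diagonal.

Contact frequency decays with genomic distance, so the background for a
pixel at bin distance ``d`` is the set of all pixels at that same distance.
For each diagonal within the tested distance range a negative binomial is
fitted by the method of moments (mean mu, variance s2; size
``r = mu^2 / (s2 - mu)``), falling back to Poisson when ``s2 <= mu``.
Structural zeros inside the tested range are genuine observations of the
diagonal and enter the moment estimates.  Upper-tail p-values
``P(X >= x)`` are corrected by Benjamini-Hochberg across all tested pixels
genome-wide (one family), and pixels with ``FDR < fdr_threshold`` and
``CPM > cpm_threshold`` are retained as loops.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .contacts import ContactMatrix

__all__ = [
    "DiagonalModel", "LoopCaller", "fit_diagonal", "pixel_pvalue",
    "call_loops", "union_loops", "differential_loops",
    "aggregate_peak_analysis", "write_bedpe", "read_bedpe",
]

LOOP_COLUMNS = ["chrom", "bin1", "bin2", "distance", "count", "cpm",
                "pvalue", "fdr"]


@dataclass(frozen=True)
class DiagonalModel:
    """Moment-fitted background at one bin distance.

    ``dispersion_size`` is the NB size parameter r; ``math.inf`` marks the
    Poisson fallback used when the sample variance does not exceed the mean.
    """
    distance: int
    n_pixels: int
    mean: float
    variance: float
    dispersion_size: float

    @property
    def is_poisson(self) -> bool:
        return math.isinf(self.dispersion_size)

    def sf(self, x: np.ndarray | int) -> np.ndarray | float:
        """Upper tail P(X >= x), inclusive."""
        x = np.asarray(x)
        if self.is_poisson:
            return stats.poisson.sf(x - 1, self.mean)
        r = self.dispersion_size
        p = r / (r + self.mean)
        return stats.nbinom.sf(x - 1, r, p)


def fit_diagonal(counts: np.ndarray, distance: int) -> DiagonalModel:
    """Method-of-moments NB fit to all pixel counts at one distance."""
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    mu = counts.mean() if n else 0.0
    s2 = counts.var() if n else 0.0  # population variance: MoM
    if s2 > mu > 0:
        r = mu * mu / (s2 - mu)
    else:
        r = math.inf
    return DiagonalModel(distance=distance, n_pixels=n, mean=mu,
                         variance=s2, dispersion_size=r)


def pixel_pvalue(model: DiagonalModel, count: int) -> float:
    """Inclusive upper-tail probability of observing >= ``count``."""
    return float(model.sf(count))


class LoopCaller(BaseEstimator):
    """Call significant loops from a binned contact matrix.

    Parameters
    ----------
    min_dist, max_dist : int
        Tested bin-distance range, inclusive (defaults 2 and 100 bins: 40 kb
        to 2 Mb at 20 kb resolution).
    fdr_threshold : float
        BH-adjusted significance cut; loops require ``fdr < fdr_threshold``.
    cpm_threshold : float
        Depth-normalized intensity cut; loops require ``cpm > cpm_threshold``.
    min_pixels : int
        Diagonals with fewer pixels than this are skipped.
    bh_scope : {"genome", "diagonal"}
        Family for the Benjamini-Hochberg correction: all tested pixels at
        once (default) or one family per diagonal.

    Attributes
    ----------
    diagonal_models_ : dict mapping (chrom-agnostic) distance -> DiagonalModel
        Pooled across chromosomes.
    pixels_ : DataFrame
        Every tested nonzero pixel with count, cpm, pvalue, fdr.
    loops_ : DataFrame
        The retained significant pixels.
    n_tested_ : int
        Number of tested pixels (the BH family size), including zeros.
    """

    def __init__(self, min_dist: int = 2, max_dist: int = 100,
                 fdr_threshold: float = 0.1, cpm_threshold: float = 30.0,
                 min_pixels: int = 10, bh_scope: str = "genome"):
        self.min_dist = min_dist
        self.max_dist = max_dist
        self.fdr_threshold = fdr_threshold
        self.cpm_threshold = cpm_threshold
        self.min_pixels = min_pixels
        self.bh_scope = bh_scope

    def _validate(self) -> None:
        if self.min_dist < 1:
            raise ValueError("min_dist must be >= 1")
        if self.max_dist <= self.min_dist:
            raise ValueError("max_dist must exceed min_dist")
        if self.bh_scope not in ("genome", "diagonal"):
            raise ValueError("bh_scope must be 'genome' or 'diagonal'")

    def fit(self, matrix: ContactMatrix) -> "LoopCaller":
        """Fit per-diagonal backgrounds and test every in-range pixel."""
        self._validate()
        if matrix.total_depth <= 0:
            raise ValueError("matrix total_depth must be positive")

        # pool counts per distance across chromosomes; zeros included
        per_dist_n: Dict[int, int] = {}
        pixel_rows = []
        for chrom in matrix.chroms:
            n = matrix.n_bins(chrom)
            coo = matrix.counts(chrom).tocoo()
            d_all = coo.col - coo.row
            keep = (d_all >= self.min_dist) & (d_all <= self.max_dist)
            sub = pd.DataFrame({"bin1": coo.row[keep].astype(np.int64),
                                "bin2": coo.col[keep].astype(np.int64),
                                "count": coo.data[keep].astype(np.int64)})
            sub["chrom"] = chrom
            pixel_rows.append(sub)
            for d in range(self.min_dist, min(self.max_dist, n - 1) + 1):
                per_dist_n[d] = per_dist_n.get(d, 0) + (n - d)

        allpix = pd.concat(pixel_rows, ignore_index=True) if pixel_rows \
            else pd.DataFrame(columns=["bin1", "bin2", "count", "chrom"])
        dist = (allpix["bin2"] - allpix["bin1"]).to_numpy()
        by_dist: Dict[int, np.ndarray] = {}
        if len(allpix):
            order = np.argsort(dist, kind="stable")
            sorted_counts = allpix["count"].to_numpy()[order]
            uniq, starts = np.unique(dist[order], return_index=True)
            for k, d in enumerate(uniq):
                stop = starts[k + 1] if k + 1 < len(starts) else len(sorted_counts)
                by_dist[int(d)] = sorted_counts[starts[k]:stop]

        models: Dict[int, DiagonalModel] = {}
        for d, n_total in per_dist_n.items():
            if n_total < self.min_pixels:
                warnings.warn(f"diagonal {d}: only {n_total} pixels, skipped")
                continue
            nonzero = by_dist.get(d, np.array([]))
            counts = np.zeros(n_total)
            counts[:len(nonzero)] = nonzero
            models[d] = fit_diagonal(counts, d)
        self.diagonal_models_ = models
        self.n_tested_ = sum(per_dist_n[d] for d in models)

        pixels = pd.concat(pixel_rows, ignore_index=True) if pixel_rows \
            else pd.DataFrame(columns=["chrom", "bin1", "bin2", "count"])
        pixels["distance"] = pixels["bin2"] - pixels["bin1"]
        pixels = pixels[pixels["distance"].isin(models)].reset_index(drop=True)
        pixels["cpm"] = pixels["count"] * 1e6 / matrix.total_depth
        pvals = np.ones(len(pixels))
        for d, model in models.items():
            mask = pixels["distance"] == d
            pvals[mask.to_numpy()] = model.sf(pixels.loc[mask, "count"].to_numpy())
        pixels["pvalue"] = np.clip(pvals, 0.0, 1.0)
        pixels = self._adjust(pixels)
        self.pixels_ = pixels[["chrom"] + LOOP_COLUMNS[1:]]
        loops = pixels[(pixels["fdr"] < self.fdr_threshold)
                       & (pixels["cpm"] > self.cpm_threshold)]
        loops = loops.sort_values(["chrom", "bin1", "bin2"]).reset_index(drop=True)
        self.loops_ = loops[["chrom"] + LOOP_COLUMNS[1:]]
        self.loops_.attrs["resolution"] = matrix.resolution
        self.loops_.attrs["sample_id"] = matrix.sample_id
        if self.n_tested_ == 0:
            warnings.warn("no pixels in the tested distance range")
        return self

    def _adjust(self, pixels: pd.DataFrame) -> pd.DataFrame:
        """BH step-up; the family includes the untested-in-frame zero pixels."""
        # stable order on (p, chrom, bin1, bin2) for reproducible ties
        pixels = pixels.sort_values(["pvalue", "chrom", "bin1", "bin2"],
                                    kind="mergesort").reset_index(drop=True)
        if self.bh_scope == "genome":
            n_zero = self.n_tested_ - len(pixels)
            padded = np.concatenate([pixels["pvalue"].to_numpy(),
                                     np.ones(n_zero)])
            _, adj, _, _ = multipletests(padded, method="fdr_bh")
            pixels["fdr"] = adj[:len(pixels)]
        else:
            pixels["fdr"] = 1.0
            for d, model in self.diagonal_models_.items():
                mask = (pixels["distance"] == d).to_numpy()
                n_zero = model.n_pixels - mask.sum()
                padded = np.concatenate([pixels.loc[mask, "pvalue"].to_numpy(),
                                         np.ones(n_zero)])
                _, adj, _, _ = multipletests(padded, method="fdr_bh")
                pixels.loc[mask, "fdr"] = adj[:mask.sum()]
        pixels["fdr"] = np.maximum(pixels["fdr"], pixels["pvalue"])
        return pixels

    def predict(self, matrix: Optional[ContactMatrix] = None) -> pd.DataFrame:
        """Significant loops of the fitted matrix (re-fits if one is given)."""
        if matrix is not None:
            self.fit(matrix)
        if not hasattr(self, "loops_"):
            raise RuntimeError("LoopCaller is not fitted")
        return self.loops_

    def fit_predict(self, matrix: ContactMatrix) -> pd.DataFrame:
        return self.fit(matrix).loops_


def call_loops(matrix: ContactMatrix, min_dist: int = 2, max_dist: int = 100,
               fdr_threshold: float = 0.1, cpm_threshold: float = 30.0,
               **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`LoopCaller`."""
    caller = LoopCaller(min_dist=min_dist, max_dist=max_dist,
                        fdr_threshold=fdr_threshold,
                        cpm_threshold=cpm_threshold, **kwargs)
    return caller.fit_predict(matrix)


def union_loops(set_a: pd.DataFrame, set_b: pd.DataFrame) -> pd.DataFrame:
    """Union of two loop sets keyed by exact pixel coordinates.

    The result records which sample(s) called each loop in ``source``
    ("a", "b" or "both").  Requires matching resolutions when both sets
    carry one.
    """
    res_a = set_a.attrs.get("resolution")
    res_b = set_b.attrs.get("resolution")
    if res_a is not None and res_b is not None and res_a != res_b:
        raise ValueError(f"resolution mismatch: {res_a} vs {res_b}")
    key = ["chrom", "bin1", "bin2"]
    a = set_a[key].drop_duplicates().assign(in_a=True)
    b = set_b[key].drop_duplicates().assign(in_b=True)
    merged = a.merge(b, on=key, how="outer")
    merged["in_a"] = merged["in_a"].notna() & merged["in_a"].eq(True)
    merged["in_b"] = merged["in_b"].notna() & merged["in_b"].eq(True)
    merged["source"] = np.select(
        [merged["in_a"] & merged["in_b"], merged["in_a"]], ["both", "a"], "b")
    merged = merged.sort_values(key).reset_index(drop=True)
    merged.attrs["resolution"] = res_a if res_a is not None else res_b
    return merged[key + ["source"]]


def differential_loops(union: pd.DataFrame, matrix_a: ContactMatrix,
                       matrix_b: ContactMatrix,
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-loop log2 fold-change of CPM between two samples.

    ``log2fc = log2((cpm_a + c) / (cpm_b + c))``; CPM is looked up in both
    matrices even where a sample did not itself call the loop.
    """
    res = union.attrs.get("resolution")
    for m in (matrix_a, matrix_b):
        if res is not None and m.resolution != res:
            raise ValueError("matrix resolution does not match the loop union")
    rows = []
    for rec in union.itertuples(index=False):
        cpm_a = matrix_a.cpm(rec.chrom, rec.bin1, rec.bin2)
        cpm_b = matrix_b.cpm(rec.chrom, rec.bin1, rec.bin2)
        # difference of logs, not log of ratio: swap-negation is then exact
        rows.append((rec.chrom, rec.bin1, rec.bin2, getattr(rec, "source", "both"),
                     cpm_a, cpm_b,
                     math.log2(cpm_a + pseudocount) - math.log2(cpm_b + pseudocount)))
    out = pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "source",
                                      "cpm_a", "cpm_b", "log2fc"])
    out.attrs["resolution"] = res
    return out


def aggregate_peak_analysis(matrix: ContactMatrix, loops: pd.DataFrame,
                            half_window: int = 5, min_dist: int = 2
                            ) -> Tuple[np.ndarray, float]:
    """Average distance-normalized submatrices around a loop list (APA).

    Each eligible loop contributes a ``(2w+1) x (2w+1)`` window of
    observed / expected values, where expected is the mean count of the
    pixel's own diagonal.  Loops closer than ``w`` bins to a matrix edge or
    to the ``min_dist`` boundary are excluded.  The enrichment score is the
    center pixel over the mean of the ``w x w`` lower-left corner (the
    short-distance background).
    """
    w = half_window
    # diagonal means per chromosome over all pixels (zeros included)
    diag_mean: Dict[str, np.ndarray] = {}
    dense: Dict[str, np.ndarray] = {}
    for chrom in matrix.chroms:
        full = matrix.dense(chrom).astype(float)
        n = full.shape[0]
        means = np.empty(n)
        for d in range(n):
            means[d] = np.mean(np.diagonal(full, d)) if d < n else 0.0
        diag_mean[chrom] = means
        dense[chrom] = full

    windows = []
    for rec in loops.itertuples(index=False):
        chrom, b1, b2 = rec.chrom, int(rec.bin1), int(rec.bin2)
        n = dense[chrom].shape[0]
        d = b2 - b1
        if b1 - w < 0 or b2 + w >= n or b1 + w >= n or b2 - w < 0:
            continue
        if d - 2 * w < min_dist:  # window must stay inside the tested range
            continue
        sub = dense[chrom][b1 - w:b1 + w + 1, b2 - w:b2 + w + 1].copy()
        for di in range(-w, w + 1):
            for dj in range(-w, w + 1):
                exp = diag_mean[chrom][d + dj - di]
                sub[di + w, dj + w] = sub[di + w, dj + w] / exp if exp > 0 else np.nan
        windows.append(sub)
    if not windows:
        raise ValueError("no loops eligible for APA with this window")
    apa = np.nanmean(np.stack(windows), axis=0)
    corner = apa[w + 1:, :w]  # lower-left: rows below center, cols left of it
    score = float(apa[w, w] / np.nanmean(corner))
    return apa, score


# ---------------------------------------------------------------------------
# BEDPE persistence

BEDPE_EXTRA = ["count", "cpm", "pvalue", "fdr"]


def write_bedpe(loops: pd.DataFrame, path: str, resolution: Optional[int] = None
                ) -> None:
    """Write loops as BEDPE with count/cpm/pvalue/fdr extra columns."""
    res = resolution or loops.attrs.get("resolution")
    if res is None:
        raise ValueError("resolution required to write BEDPE")
    df = loops.copy()
    out = pd.DataFrame({
        "chrom1": df["chrom"], "start1": df["bin1"] * res,
        "end1": (df["bin1"] + 1) * res,
        "chrom2": df["chrom"], "start2": df["bin2"] * res,
        "end2": (df["bin2"] + 1) * res,
        "name": [f"loop{k}" for k in range(len(df))],
        "score": df.get("fdr", pd.Series(["."] * len(df))),
        "strand1": ".", "strand2": ".",
    })
    for col in BEDPE_EXTRA + ["cpm_a", "cpm_b", "log2fc", "source"]:
        if col in df.columns:
            out[col] = df[col].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_bedpe(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    res = int(df["end1"].iloc[0] - df["start1"].iloc[0]) if len(df) else None
    out = pd.DataFrame({"chrom": df["chrom1"],
                        "bin1": df["start1"] // res if res else 0,
                        "bin2": df["start2"] // res if res else 0})
    for col in BEDPE_EXTRA + ["cpm_a", "cpm_b", "log2fc", "source"]:
        if col in df.columns:
            out[col] = df[col]
    if res:
        out["distance"] = out["bin2"] - out["bin1"]
        out.attrs["resolution"] = res
    return out
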