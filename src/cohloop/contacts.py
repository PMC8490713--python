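"""Binned Hi-C contact matrices.

A :class:`ContactMatrix` holds, per chromosome, the upper-triangular sparse
count matrix of intra-chromosomal read pairs binned at a fixed resolution,
together with the total sequencing depth of the sample.  Counts are stored
once with ``bin1 <= bin2``; inter-chromosomal pairs contribute to
``total_depth`` only.  CPM normalization divides by the total depth, so the
same denominator serves loop CPM and virtual-4C CPM.
"""

from __future__ import annotations

import json
import os
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["ContactMatrix", "bin_pairs", "read_chrom_sizes", "read_pairs"]

PAIR_COLUMNS = ["chrom1", "pos1", "chrom2", "pos2"]


def read_chrom_sizes(path: str) -> Dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file into an ordered dict."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def read_pairs(path: str) -> pd.DataFrame:
    """Read a 4-column pairs TSV (chrom1, pos1, chrom2, pos2; 0-based bp)."""
    df = pd.read_csv(path, sep="\t", header=None, names=PAIR_COLUMNS,
                     dtype={"chrom1": str, "chrom2": str, "pos1": np.int64, "pos2": np.int64})
    return df


def write_pairs(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=PAIR_COLUMNS)


class ContactMatrix:
    """Per-chromosome symmetric sparse contact counts at one resolution.

    Parameters
    ----------
    resolution : int
        Bin width in bp.
    chrom_sizes : mapping of str to int
        Chromosome lengths in bp; defines the bin grids.
    total_depth : int
        Total retained read pairs of the sample (intra + inter); the CPM
        denominator.
    sample_id : str
        Free-form sample label.
    """

    def __init__(self, resolution: int, chrom_sizes: Mapping[str, int],
                 total_depth: int = 0, sample_id: str = "sample"):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.resolution = int(resolution)
        self.chrom_sizes = dict(chrom_sizes)
        self.total_depth = int(total_depth)
        self.sample_id = sample_id
        self._mats: Dict[str, sp.csr_matrix] = {}
        for chrom in self.chrom_sizes:
            n = self.n_bins(chrom)
            self._mats[chrom] = sp.csr_matrix((n, n), dtype=np.int64)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.resolution)

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(self.chrom_sizes)

    def counts(self, chrom: str) -> sp.csr_matrix:
        """Upper-triangular sparse counts (bin1 <= bin2) for one chromosome."""
        return self._mats[chrom]

    def set_counts(self, chrom: str, mat: sp.spmatrix) -> None:
        n = self.n_bins(chrom)
        mat = sp.triu(mat.tocoo(), k=0).tocsr()
        if mat.shape != (n, n):
            raise ValueError(f"matrix for {chrom} must be {n}x{n}")
        self._mats[chrom] = mat

    def add_pixels(self, chrom: str, bin1: np.ndarray, bin2: np.ndarray,
                   count: np.ndarray) -> None:
        n = self.n_bins(chrom)
        i = np.minimum(bin1, bin2)
        j = np.maximum(bin1, bin2)
        add = sp.coo_matrix((count, (i, j)), shape=(n, n), dtype=np.int64)
        self._mats[chrom] = (self._mats[chrom] + add.tocsr()).tocsr()

    def intra_sum(self) -> int:
        return int(sum(m.sum() for m in self._mats.values()))

    def pixel_count(self, chrom: str, bin1: int, bin2: int) -> int:
        i, j = min(bin1, bin2), max(bin1, bin2)
        return int(self._mats[chrom][i, j])

    def cpm(self, chrom: str, bin1: int, bin2: int) -> float:
        """CPM of one pixel: count x 1e6 / total sequencing depth."""
        if self.total_depth <= 0:
            raise ValueError("total_depth must be positive for CPM")
        return self.pixel_count(chrom, bin1, bin2) * 1e6 / self.total_depth

    def dense(self, chrom: str) -> np.ndarray:
        """Symmetrized dense counts for one chromosome (small genomes only)."""
        upper = self._mats[chrom].toarray()
        full = upper + np.triu(upper, k=1).T
        return full

    def pixels(self, chrom: str) -> pd.DataFrame:
        """Stored pixels of one chromosome as (bin1, bin2, count), bin1<=bin2."""
        coo = self._mats[chrom].tocoo()
        return pd.DataFrame({"bin1": coo.row, "bin2": coo.col, "count": coo.data})

    # persistence: per-chromosome 3-column sparse text + JSON sidecar --------

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        meta = {
            "resolution": self.resolution,
            "total_depth": self.total_depth,
            "sample_id": self.sample_id,
            "chrom_sizes": self.chrom_sizes,
        }
        with open(os.path.join(outdir, "matrix.json"), "w") as fh:
            json.dump(meta, fh, indent=1)
        for chrom in self.chroms:
            self.pixels(chrom).to_csv(
                os.path.join(outdir, f"{chrom}.matrix.tsv"),
                sep="\t", index=False, header=False)

    @classmethod
    def load(cls, indir: str) -> "ContactMatrix":
        with open(os.path.join(indir, "matrix.json")) as fh:
            meta = json.load(fh)
        mat = cls(meta["resolution"], meta["chrom_sizes"],
                  meta["total_depth"], meta["sample_id"])
        for chrom in mat.chroms:
            path = os.path.join(indir, f"{chrom}.matrix.tsv")
            if not os.path.exists(path) or os.path.getsize(path) == 0:
                continue
            px = pd.read_csv(path, sep="\t", header=None,
                             names=["bin1", "bin2", "count"])
            mat.add_pixels(chrom, px["bin1"].to_numpy(), px["bin2"].to_numpy(),
                           px["count"].to_numpy())
        return mat

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactMatrix):
            return NotImplemented
        if (self.resolution, self.total_depth, self.chrom_sizes) != \
                (other.resolution, other.total_depth, other.chrom_sizes):
            return False
        return all((self._mats[c] != other._mats[c]).nnz == 0 for c in self.chroms)


def bin_pairs(pairs: pd.DataFrame | Iterable[Tuple[str, int, str, int]],
              chrom_sizes: Mapping[str, int], resolution: int,
              sample_id: str = "sample") -> ContactMatrix:
    """Bin read pairs into a :class:`ContactMatrix`.

    Each intra-chromosomal pair increments exactly one upper-triangular pixel
    ``(floor(pos1/res), floor(pos2/res))``; inter-chromosomal pairs count
    toward ``total_depth`` only.  Raises ``ValueError`` on unknown
    chromosomes or out-of-range coordinates.
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.DataFrame(list(pairs), columns=PAIR_COLUMNS)
    mat = ContactMatrix(resolution, chrom_sizes, total_depth=len(pairs),
                        sample_id=sample_id)
    for col in ("chrom1", "chrom2"):
        unknown = set(pairs[col].unique()) - set(chrom_sizes)
        if unknown:
            raise ValueError(f"unknown chromosome(s) in pairs: {sorted(unknown)}")
    for chrom, pos_col in (("chrom1", "pos1"), ("chrom2", "pos2")):
        sizes = pairs[chrom].map(chrom_sizes).to_numpy()
        pos = pairs[pos_col].to_numpy()
        if np.any(pos < 0) or np.any(pos >= sizes):
            bad = int(np.flatnonzero((pos < 0) | (pos >= sizes))[0])
            raise ValueError(
                f"pair {bad}: position {pos[bad]} outside {pairs[chrom].iloc[bad]}")
    intra = pairs[pairs["chrom1"] == pairs["chrom2"]]
    for chrom, sub in intra.groupby("chrom1", sort=False):
        b1 = sub["pos1"].to_numpy() // resolution
        b2 = sub["pos2"].to_numpy() // resolution
        mat.add_pixels(chrom, b1, b2, np.ones(len(sub), dtype=np.int64))
    return mat
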