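"""Classify loops by overlap of their anchors with promoters and enhancers.

A loop anchor (one matrix bin, a half-open genomic interval) "holds" a
feature when the feature interval overlaps it by at least 1 bp.  A
promoter-enhancer (P-E) loop has a protein-coding gene promoter in one
anchor and an enhancer (e.g. an H3K27ac peak) in the other, in either
orientation.  When anchors carry both feature types the most specific class
wins: P-E > P-P > E-E > P-other > E-other > other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

__all__ = ["AnnotationSet", "classify_loop", "classify_set", "read_bed",
           "write_bed", "LOOP_CLASSES"]

LOOP_CLASSES = ("P-E", "P-P", "E-E", "P-other", "E-other", "other")

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str) -> pd.DataFrame:
    """Read BED (3-6 columns) into a DataFrame with BED6 column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[:df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=[c for c in BED_COLUMNS if c in df.columns])


@dataclass
class AnnotationSet:
    """Promoter and enhancer interval tables (0-based half-open BED6).

    Promoter names are gene symbols; the set is assumed pre-restricted to
    protein-coding genes.
    """
    promoters: pd.DataFrame
    enhancers: pd.DataFrame
    _index: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]] = \
        field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for kind in ("promoters", "enhancers"):
            df = getattr(self, kind)
            if (df["start"] >= df["end"]).any():
                raise ValueError(f"{kind}: intervals require start < end")
            idx: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
            for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom"):
                idx[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                              sub["name"].to_numpy())
            self._index[kind] = idx

    def features_in(self, kind: str, chrom: str, start: int, end: int
                    ) -> List[str]:
        """Names of features overlapping [start, end) by >= 1 bp."""
        idx = self._index[kind].get(chrom)
        if idx is None:
            return []
        starts, ends, names = idx
        hit = (starts < end) & (ends > start)
        return list(names[hit])


def classify_loop(chrom: str, bin1: int, bin2: int, resolution: int,
                  annotations: AnnotationSet) -> Tuple[str, List[str]]:
    """Class label and promoter gene names for one loop.

    Anchors are the two 1-bin intervals; no flanking extension is applied.
    """
    anchors = []
    for b in (bin1, bin2):
        start, end = b * resolution, (b + 1) * resolution
        anchors.append({
            "P": annotations.features_in("promoters", chrom, start, end),
            "E": annotations.features_in("enhancers", chrom, start, end),
        })
    a, b = anchors
    genes = sorted(set(a["P"]) | set(b["P"]))
    if (a["P"] and b["E"]) or (a["E"] and b["P"]):
        return "P-E", genes
    if a["P"] and b["P"]:
        return "P-P", genes
    if a["E"] and b["E"]:
        return "E-E", genes
    if a["P"] or b["P"]:
        return "P-other", genes
    if a["E"] or b["E"]:
        return "E-other", genes
    return "other", genes


def classify_set(loops: pd.DataFrame, annotations: AnnotationSet,
                 resolution: int | None = None
                 ) -> Tuple[pd.DataFrame, pd.Series]:
    """Annotate every loop with its class; return (annotated loops, counts).

    Class counts partition the loop set: they sum to ``len(loops)``.
    Annotation chromosomes absent from the loop set are simply never
    queried; loop chromosomes absent from the annotations yield class
    'other' with a warning.
    """
    res = resolution or loops.attrs.get("resolution")
    if res is None:
        raise ValueError("resolution required to classify loops")
    known = set(annotations.promoters["chrom"]) | set(annotations.enhancers["chrom"])
    missing = set(loops["chrom"]) - known
    if missing and len(loops):
        warnings.warn(f"no annotations on chromosome(s): {sorted(missing)}")
    classes, gene_lists = [], []
    for rec in loops.itertuples(index=False):
        cls, genes = classify_loop(rec.chrom, int(rec.bin1), int(rec.bin2),
                                   res, annotations)
        classes.append(cls)
        gene_lists.append(",".join(genes) if genes else ".")
    out = loops.copy()
    out["loop_class"] = classes
    out["genes"] = gene_lists
    out.attrs["resolution"] = res
    counts = out["loop_class"].value_counts().reindex(LOOP_CLASSES, fill_value=0)
    return out, counts
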