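"""Consensus somatic-variant filtering, percent genome altered, gene tallies.

Somatic calls from multiple callers (Strelka2, MuTect, VarScan) are merged
by (sample, chrom, pos, ref, alt); only variants reported by at least two
callers are retained.  Hard filters then drop variants with total read
depth < 30, fewer than 5 variant-supporting reads, tumor VAF < 10% or
germline VAF > 1%, known dbSNP sites, and consequences outside the retained
set (missense, silent and truncating classes).  Copy-number segments with
|log2 ratio| > 0.1 quantify percent genome altered; retained variants are
tallied per gene across cohort groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "RETAINED_CONSEQUENCES", "FilterReport", "ConsensusVariantFilter",
    "consensus_merge", "apply_hard_filters", "percent_genome_altered",
    "gene_mutation_tally",
]

# "truncating" expanded from the oncoprint categories: stop gained,
# frameshift, splice region, NMD transcript
RETAINED_CONSEQUENCES: FrozenSet[str] = frozenset({
    "missense_variant", "synonymous_variant", "stop_gained",
    "frameshift_variant", "splice_region_variant", "NMD_transcript_variant",
})

KEY = ["sample_id", "chrom", "pos", "ref", "alt"]

RULES = ("min_callers", "depth", "alt_reads", "tumor_vaf", "germline_vaf",
         "dbsnp", "consequence")


@dataclass
class FilterReport:
    """Per-rule drop counts; verdicts partition the input."""
    n_input: int
    n_retained: int
    dropped: Dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, int]:
        out = {"n_input": self.n_input, "n_retained": self.n_retained}
        out.update({f"dropped_{k}": v for k, v in self.dropped.items()})
        return out


def consensus_merge(tables: Mapping[str, pd.DataFrame],
                    priority: Sequence[str] | None = None) -> pd.DataFrame:
    """Merge per-caller variant tables, keeping calls made by >= 2 callers.

    ``tables`` maps caller name to a variant DataFrame (columns: sample_id,
    chrom, pos, ref, alt, tumor_depth, tumor_alt, germline_vaf, consequence,
    dbsnp, gene).  Numeric/annotation fields come from the first caller in
    ``priority`` (default: alphabetical) that reported the variant; the
    ``callers`` column holds the full set.
    """
    if len(tables) < 2:
        raise ValueError("consensus requires at least two caller tables")
    if priority is None:
        priority = sorted(tables)
    frames = []
    for caller in priority:
        df = tables[caller]
        if df.duplicated(subset=KEY).any():
            raise ValueError(f"duplicate variant keys in caller table {caller!r}")
        if len(df):
            frames.append(df.assign(_caller=caller))
    if not frames:
        empty = next(iter(tables.values())).iloc[0:0].copy()
        empty["callers"] = pd.Series(dtype=object)
        empty["n_callers"] = pd.Series(dtype=int)
        return empty
    stacked = pd.concat(frames, ignore_index=True)
    grouped = stacked.groupby(KEY, sort=True)
    callers = grouped["_caller"].agg(lambda s: tuple(sorted(s)))
    # field values from the highest-priority caller (frames concatenated in
    # priority order, so "first" is it)
    first = stacked.drop_duplicates(subset=KEY, keep="first").set_index(KEY)
    merged = first.drop(columns=["_caller"])
    merged["callers"] = callers
    merged["n_callers"] = callers.map(len)
    merged = merged[merged["n_callers"] >= 2].reset_index()
    return merged


def apply_hard_filters(variants: pd.DataFrame,
                       min_depth: int = 30, min_alt: int = 5,
                       min_tumor_vaf: float = 0.10,
                       max_germline_vaf: float = 0.01,
                       retained_consequences: FrozenSet[str] = RETAINED_CONSEQUENCES,
                       require_consensus: bool = False,
                       ) -> Tuple[pd.DataFrame, FilterReport]:
    """Apply the post-consensus hard filters; report the first failing rule.

    The thresholds phrase exclusions strictly (< 30, < 5, < 10%, > 1%), so
    boundary values are retained.  Rules are evaluated in a fixed order
    (callers, depth, alt reads, tumor VAF, germline VAF, dbSNP, consequence)
    and each dropped variant is charged to the first rule it fails; depth 0
    makes the VAF undefined and the variant is dropped at the depth rule.
    """
    df = variants.copy()
    depth = df["tumor_depth"].to_numpy(dtype=float)
    alt = df["tumor_alt"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tvaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    checks = {
        "min_callers": (df["n_callers"].to_numpy() >= 2
                        if require_consensus and "n_callers" in df
                        else np.ones(len(df), bool)),
        "depth": depth >= min_depth,
        "alt_reads": alt >= min_alt,
        "tumor_vaf": np.nan_to_num(tvaf, nan=-1.0) >= min_tumor_vaf,
        "germline_vaf": df["germline_vaf"].to_numpy(dtype=float) <= max_germline_vaf,
        "dbsnp": ~df["dbsnp"].to_numpy(dtype=bool),
        "consequence": df["consequence"].isin(retained_consequences).to_numpy(),
    }
    verdict = np.full(len(df), "", dtype=object)
    for rule in RULES:
        fail = ~checks[rule] & (verdict == "")
        verdict[fail] = rule
    retained = df[verdict == ""].reset_index(drop=True)
    dropped = {rule: int((verdict == rule).sum()) for rule in RULES}
    report = FilterReport(n_input=len(df), n_retained=len(retained),
                          dropped=dropped)
    df["first_failed_rule"] = verdict
    report_frame = df  # kept for callers needing per-variant verdicts
    retained.attrs["verdicts"] = report_frame
    return retained, report


class ConsensusVariantFilter(BaseEstimator):
    """Consensus merge + hard filters as one transformer.

    ``transform`` takes a mapping of caller name -> variant table and
    returns the retained variants; ``report_`` holds the
    :class:`FilterReport` of the last transform.
    """

    def __init__(self, min_depth: int = 30, min_alt: int = 5,
                 min_tumor_vaf: float = 0.10, max_germline_vaf: float = 0.01,
                 priority: Sequence[str] | None = None):
        self.min_depth = min_depth
        self.min_alt = min_alt
        self.min_tumor_vaf = min_tumor_vaf
        self.max_germline_vaf = max_germline_vaf
        self.priority = priority

    def fit(self, tables: Mapping[str, pd.DataFrame], y=None):
        return self

    def transform(self, tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
        merged = consensus_merge(tables, priority=self.priority)
        retained, report = apply_hard_filters(
            merged, min_depth=self.min_depth, min_alt=self.min_alt,
            min_tumor_vaf=self.min_tumor_vaf,
            max_germline_vaf=self.max_germline_vaf)
        self.report_ = report
        self.merged_ = merged
        return retained

    def fit_transform(self, tables: Mapping[str, pd.DataFrame], y=None,
                      **kwargs) -> pd.DataFrame:
        return self.fit(tables).transform(tables)


def percent_genome_altered(segments: pd.DataFrame, genome_size: int,
                           threshold: float = 0.1) -> Tuple[float, float]:
    """(percent gained, percent lost) from copy-number segments.

    A segment counts as gain when ``log2_ratio > threshold`` and loss when
    ``log2_ratio < -threshold``; percentages are segment length sums over
    ``genome_size`` x 100.  Overlapping segments within a sample are an
    error.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    segs = segments.sort_values(["chrom", "start"])
    if (segs["start"] >= segs["end"]).any():
        raise ValueError("segments require start < end")
    for _, sub in segs.groupby("chrom"):
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError("overlapping copy-number segments")
    length = (segs["end"] - segs["start"]).to_numpy(dtype=float)
    log2 = segs["log2_ratio"].to_numpy(dtype=float)
    gain = 100.0 * length[log2 > threshold].sum() / genome_size
    loss = 100.0 * length[log2 < -threshold].sum() / genome_size
    return gain, loss


def gene_mutation_tally(variants: pd.DataFrame, gene_panel: Sequence[str],
                        groups: Mapping[str, str]) -> pd.DataFrame:
    """Per-gene, per-group mutated-sample counts and frequencies.

    A gene is mutated in a sample iff the sample carries >= 1 retained
    variant in it (set semantics — multiplicity does not matter).  Every
    panel gene is reported for every group, with zeros where unmutated.
    Raises on samples missing from ``groups``.
    """
    if not len(gene_panel):
        raise ValueError("gene panel is empty")
    unknown = set(variants["sample_id"]) - set(groups)
    if unknown:
        raise ValueError(f"sample(s) with unknown group: {sorted(unknown)}")
    group_sizes: Dict[str, int] = {}
    for sample, grp in groups.items():
        group_sizes[grp] = group_sizes.get(grp, 0) + 1
    mutated = variants[variants["gene"].isin(gene_panel)][["gene", "sample_id"]] \
        .drop_duplicates()
    mutated["group"] = mutated["sample_id"].map(groups)
    counts = mutated.groupby(["gene", "group"]).size()
    rows = []
    for gene in gene_panel:
        for grp, size in group_sizes.items():
            n = int(counts.get((gene, grp), 0))
            rows.append((gene, grp, n, size, n / size))
    return pd.DataFrame(rows, columns=["gene", "group", "n_mutated",
                                       "group_size", "frequency"])
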