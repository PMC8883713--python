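"""Interval algebra over method-specific candidate regions.

Intervals are 1-based inclusive. Overlapping or book-ended intervals
(``next start <= end + 1``) coalesce when merging; the consensus operation
groups all methods' intervals into connected blocks, flags the methods
present in each block, and retains blocks supported by at least
``min_methods`` distinct methods. Region sizes follow the
(end - start) / 1e6 convention rounded half-up to three decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scans import METHODS, CandidateRegion, region_size_mb


@dataclass
class ConsensusRegion:
    chrom: str
    start_bp: int
    end_bp: int
    method_flags: dict = field(default_factory=dict)  # method -> bool
    top_snp: tuple | None = None

    @property
    def n_methods(self) -> int:
        return sum(bool(v) for v in self.method_flags.values())

    @property
    def size_mb(self) -> float:
        return region_size_mb(self.start_bp, self.end_bp)


def _validate(regions) -> list[CandidateRegion]:
    for r in regions:
        if r.start_bp > r.end_bp:
            raise ValueError(f"invalid interval {r.chrom}:{r.start_bp}-{r.end_bp}")
    return list(regions)


def merge_intervals(regions: list[CandidateRegion],
                    book_ended: bool = True) -> list[CandidateRegion]:
    """Coalesce overlapping (and, by default, book-ended) intervals per
    chromosome. Output is sorted and pairwise disjoint; bp coverage is
    preserved exactly."""
    regions = _validate(regions)
    slack = 1 if book_ended else 0
    out = []
    by_chrom: dict[str, list[CandidateRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start_bp, r.end_bp))
        cur_start, cur_end = rs[0].start_bp, rs[0].end_bp
        cur_score = rs[0].score
        for r in rs[1:]:
            if r.start_bp <= cur_end + slack:
                cur_end = max(cur_end, r.end_bp)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    cur_score = np.nanmax([cur_score, r.score])
            else:
                out.append(CandidateRegion(chrom, cur_start, cur_end,
                                           rs[0].method, cur_score))
                cur_start, cur_end, cur_score = r.start_bp, r.end_bp, r.score
        out.append(CandidateRegion(chrom, cur_start, cur_end, rs[0].method,
                                   cur_score))
    return out


def consensus_regions(
    per_method: dict[str, list[CandidateRegion]],
    min_methods: int = 2,
    book_ended: bool = True,
) -> list[ConsensusRegion]:
    """Blocks of the union of all method intervals supported by at least
    ``min_methods`` distinct methods.

    A block is a maximal chain of intervals connected by overlap (or
    book-ended contact when ``book_ended``); its flags record the methods
    with an interval in the block and its extent is the union of the
    block's intervals.
    """
    tagged = []
    for method, regions in per_method.items():
        for r in _validate(regions):
            tagged.append((r.chrom, r.start_bp, r.end_bp, method))
    slack = 1 if book_ended else 0
    out = []
    by_chrom: dict[str, list] = {}
    for t in tagged:
        by_chrom.setdefault(t[0], []).append(t)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda t: (t[1], t[2]))
        block = [rs[0]]
        block_end = rs[0][2]
        for t in rs[1:]:
            if t[1] <= block_end + slack:
                block.append(t)
                block_end = max(block_end, t[2])
            else:
                out.append(_finish_block(chrom, block))
                block = [t]
                block_end = t[2]
        out.append(_finish_block(chrom, block))
    kept = [r for r in out if r.n_methods >= min_methods]
    kept.sort(key=lambda r: (r.chrom, r.start_bp))
    return kept


def _finish_block(chrom: str, block) -> ConsensusRegion:
    flags = {m: False for m in METHODS}
    for _, _, _, method in block:
        flags[method] = True
    return ConsensusRegion(
        chrom=chrom,
        start_bp=min(t[1] for t in block),
        end_bp=max(t[2] for t in block),
        method_flags=flags,
    )


def assign_top_snp(region, gwas_records: pd.DataFrame):
    """Minimum-p scored SNP within the region (tie: smaller bp), or None."""
    inside = gwas_records[
        (gwas_records["chrom"].astype(str) == str(region.chrom))
        & (gwas_records["bp"] >= region.start_bp)
        & (gwas_records["bp"] <= region.end_bp)
        & np.isfinite(gwas_records["p_value"])
    ]
    if inside.empty:
        return None
    inside = inside.sort_values(["p_value", "bp"], kind="stable")
    top = inside.iloc[0]
    return (top["snp_id"], float(top["p_value"]))


def consensus_table(regions: list[ConsensusRegion],
                    gwas_records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate consensus regions in the region/flags/top-SNP layout."""
    rows = []
    for i, r in enumerate(regions, 1):
        top = (assign_top_snp(r, gwas_records)
               if gwas_records is not None else r.top_snp)
        rows.append({
            "region": i, "chrom": r.chrom, "start_bp": r.start_bp,
            "end_bp": r.end_bp, "size_mb": r.size_mb,
            **{m: bool(r.method_flags.get(m, False)) for m in METHODS},
            "n_methods": r.n_methods,
            "top_snp": top[0] if top else "",
            "top_snp_p": top[1] if top else np.nan,
        })
    return pd.DataFrame(
        rows,
        columns=["region", "chrom", "start_bp", "end_bp", "size_mb",
                 *METHODS, "n_methods", "top_snp", "top_snp_p"],
    )


def to_bed(regions, path) -> None:
    """Export regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            name = getattr(r, "method", None) or f"n_methods={r.n_methods}"
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\n")
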