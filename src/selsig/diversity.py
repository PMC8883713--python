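"""Genetic diversity and demography: heterozygosity, inbreeding (F and
F_ROH), run-of-homozygosity calling, LD decay and effective population size.

Runs of homozygosity are called with a PLINK-style sliding-window scan:
a fixed-size SNP window passes if it holds at most ``window_het_max``
heterozygous and ``window_missing_max`` missing calls; a SNP whose fraction
of passing covering windows reaches ``window_hit_fraction`` is a
homozygosity candidate; maximal candidate runs are split at large inter-SNP
gaps and then filtered on physical length, SNP count and marker density.

Effective population size over time follows Sved's relation between LD and
drift: ``Ne_t = (1/4c) (1/r^2 - 1)`` at recombination distance ``c`` Morgans,
dated ``t = 1/(2c)`` generations ago, so short-range LD reflects ancient and
long-range LD recent population size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, allele_frequencies

AUTOSOME_LENGTH_BP = 2.45e9  # sheep autosome total used for F_ROH


@dataclass
class HetStats:
    per_sample_ho: np.ndarray
    mean_ho: float
    sd_ho: float
    mean_he: float
    sd_he: float


@dataclass
class ROHParams:
    """PLINK-style ROH criteria: 50-SNP window with at most 1 het and 5
    missing calls, minimum segment 1 Mb / 80 SNPs, at least one SNP per
    100 kb, no internal gap above 1 Mb."""

    window_snps: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    min_length_bp: float = 1e6
    min_snps: int = 80
    min_density_bp_per_snp: float = 1e5
    max_gap_bp: float = 1e6
    window_hit_fraction: float = 0.05


def het_stats(G: np.ndarray) -> HetStats:
    """Observed heterozygosity per sample and dataset means.

    H_O(i) = het calls / non-missing calls of sample i; per-SNP
    H_E = 2 p (1 - p) at the non-missing allele frequency; dataset means are
    over samples (H_O) and SNPs (H_E).
    """
    G = np.asarray(G)
    called = G != MISSING
    if not called.any():
        raise ValueError("no called genotypes")
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = (G == 1).sum(axis=1) / called.sum(axis=1)
    p = allele_frequencies(G)
    he = 2.0 * p * (1.0 - p)
    he = he[np.isfinite(he)]
    return HetStats(
        per_sample_ho=ho,
        mean_ho=float(np.nanmean(ho)),
        sd_ho=float(np.nanstd(ho, ddof=1)) if len(ho) > 1 else 0.0,
        mean_he=float(np.mean(he)) if len(he) else 0.0,
        sd_he=float(np.std(he, ddof=1)) if len(he) > 1 else 0.0,
    )


def inbreeding_f(G: np.ndarray) -> np.ndarray:
    """Method-of-moments SNP inbreeding coefficient per sample.

    F_i = (O_hom - E_hom) / (L - E_hom) over sample i's non-missing SNPs,
    with E_hom = sum_l (1 - 2 p_l (1 - p_l)). NaN where the denominator is 0.
    """
    G = np.asarray(G)
    p = allele_frequencies(G)
    e_hom_snp = 1.0 - 2.0 * p * (1.0 - p)
    called = G != MISSING
    obs_hom = ((G == 0) | (G == 2)) & called
    usable = called & np.isfinite(p)[None, :]
    L = usable.sum(axis=1).astype(float)
    O = (obs_hom & np.isfinite(p)[None, :]).sum(axis=1).astype(float)
    E = np.where(usable, e_hom_snp[None, :], 0.0).sum(axis=1)
    denom = L - E
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(np.abs(denom) > 1e-12, (O - E) / denom, np.nan)


# ---------------------------------------------------------------------------
# ROH
# ---------------------------------------------------------------------------


def _roh_candidate_mask(g: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-SNP candidate mask from the sliding-window pass fractions."""
    m = len(g)
    w = params.window_snps
    if m < w:
        return np.zeros(m, dtype=bool)
    het = (g == 1).astype(np.int32)
    mis = (g == MISSING).astype(np.int32)
    kern = np.ones(w, dtype=np.int32)
    het_w = np.convolve(het, kern, mode="valid")
    mis_w = np.convolve(mis, kern, mode="valid")
    passing = (
        (het_w <= params.window_het_max)
        & (mis_w <= params.window_missing_max)
    ).astype(np.int32)
    n_win = m - w + 1
    # windows covering SNP l start in [max(0, l-w+1), min(l, n_win-1)]
    cum = np.concatenate([[0], np.cumsum(passing)])
    lo = np.maximum(0, np.arange(m) - w + 1)
    hi = np.minimum(np.arange(m), n_win - 1)
    n_pass = cum[hi + 1] - cum[lo]
    n_cover = hi - lo + 1
    # a heterozygous call can sit inside a run (the window allowance) but
    # cannot itself seed or extend one; this keeps segment edges tight
    return ((n_pass / n_cover) >= params.window_hit_fraction) & (g != 1)


def _segments_from_candidates(bp: np.ndarray, cand: np.ndarray,
                              params: ROHParams):
    """Split maximal candidate runs at big gaps and apply length/count/density
    filters. Yields (start_bp, end_bp, n_snps)."""
    idx = np.flatnonzero(cand)
    if len(idx) == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) != 1)
    runs = np.split(idx, breaks + 1)
    for run in runs:
        # split at inter-SNP gaps > max_gap_bp
        gaps = np.diff(bp[run])
        cut = np.flatnonzero(gaps > params.max_gap_bp)
        for piece in np.split(run, cut + 1):
            if len(piece) < params.min_snps:
                continue
            start, end = int(bp[piece[0]]), int(bp[piece[-1]])
            length = end - start + 1
            if length < params.min_length_bp:
                continue
            if length / len(piece) > params.min_density_bp_per_snp:
                continue
            yield start, end, len(piece)


def detect_roh(
    G: np.ndarray,
    vmap: pd.DataFrame,
    samples: pd.DataFrame,
    params: ROHParams | None = None,
) -> pd.DataFrame:
    """Call runs of homozygosity per sample.

    Returns a DataFrame with columns sample_id, chrom, start_bp, end_bp
    (1-based inclusive), n_snps, length_bp.
    """
    params = params or ROHParams()
    G = np.asarray(G)
    chroms = vmap["chrom"].to_numpy()
    bp_all = vmap["bp"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        if len(cols) < params.window_snps:
            warnings.warn(
                f"chromosome {chrom}: {len(cols)} SNPs < window size "
                f"{params.window_snps}; no ROH callable"
            )
            continue
        bp = bp_all[cols]
        for si, sid in enumerate(samples["sample_id"]):
            g = G[si, cols]
            cand = _roh_candidate_mask(g, params)
            for start, end, n_snps in _segments_from_candidates(bp, cand,
                                                                params):
                rows.append({
                    "sample_id": sid, "chrom": str(chrom),
                    "start_bp": start, "end_bp": end,
                    "n_snps": n_snps, "length_bp": end - start + 1,
                })
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps",
                 "length_bp"],
    )


def froh(roh_segments: pd.DataFrame, sample_ids,
         autosome_length_bp: float = AUTOSOME_LENGTH_BP) -> pd.Series:
    """Genomic inbreeding: per-sample total ROH length over the autosome
    length (2.45 Gb by default). Samples without ROH get 0."""
    totals = roh_segments.groupby("sample_id")["length_bp"].sum()
    out = pd.Series(0.0, index=pd.Index(sample_ids, name="sample_id"))
    common = totals.index.intersection(out.index)
    out.loc[common] = totals.loc[common] / autosome_length_bp
    return out


# ---------------------------------------------------------------------------
# LD decay and Ne
# ---------------------------------------------------------------------------


def ld_decay(
    G: np.ndarray,
    vmap: pd.DataFrame,
    max_dist_bp: int = 1_000_000,
    n_bins: int = 20,
    max_pairs: int = 500_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean r^2 between SNP pairs binned by physical distance.

    r^2 is the squared Pearson correlation of dosages over jointly
    non-missing samples; only within-chromosome pairs up to ``max_dist_bp``
    enter. When more than ``max_pairs`` pairs exist a seeded random subset is
    scored. Returns columns lo_bp, hi_bp, mid_bp, mean_r2, n_pairs.
    """
    G = np.asarray(G)
    chroms = vmap["chrom"].to_numpy()
    bp_all = vmap["bp"].to_numpy()
    pair_i, pair_j = [], []
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        bp = bp_all[cols]
        for a in range(len(cols)):
            b = np.searchsorted(bp, bp[a] + max_dist_bp, side="right")
            if b > a + 1:
                pair_i.append(np.full(b - a - 1, cols[a]))
                pair_j.append(cols[a + 1:b])
    if not pair_i:
        return pd.DataFrame(
            columns=["lo_bp", "hi_bp", "mid_bp", "mean_r2", "n_pairs"]
        )
    pi = np.concatenate(pair_i)
    pj = np.concatenate(pair_j)
    if len(pi) > max_pairs:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(pi), size=max_pairs, replace=False)
        pi, pj = pi[sel], pj[sel]

    Gf = G.astype(np.float64)
    nan_mask = G == MISSING
    has_missing = nan_mask.any()
    if has_missing:
        Gf[nan_mask] = np.nan
    r2 = _pair_r2(Gf, pi, pj, has_missing)
    dist = bp_all[pj] - bp_all[pi]

    edges = np.linspace(0, max_dist_bp, n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = (which == b) & np.isfinite(r2)
        rows.append({
            "lo_bp": edges[b], "hi_bp": edges[b + 1],
            "mid_bp": 0.5 * (edges[b] + edges[b + 1]),
            "mean_r2": float(r2[sel].mean()) if sel.any() else np.nan,
            "n_pairs": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def _pair_r2(Gf: np.ndarray, pi: np.ndarray, pj: np.ndarray,
             has_missing: bool) -> np.ndarray:
    """Vectorised squared dosage correlation for the listed column pairs."""
    if not has_missing:
        X = Gf - Gf.mean(axis=0)
        sd = X.std(axis=0)
        num = (X[:, pi] * X[:, pj]).mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / (sd[pi] * sd[pj])
        return r * r
    out = np.empty(len(pi))
    for k in range(len(pi)):
        x, y = Gf[:, pi[k]], Gf[:, pj[k]]
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 2:
            out[k] = np.nan
            continue
        xs, ys = x[ok], y[ok]
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            out[k] = np.nan
        else:
            r = ((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy)
            out[k] = r * r
    return out


def sved_ne(r2: float, c_morgan: float) -> tuple[float, float]:
    """Closed-form Sved relation: returns (Ne, t) for one (r^2, c) pair.

    Ne = (1/(4c)) (1/r^2 - 1); t = 1/(2c) generations ago. r^2 = 0 has no
    finite Ne (NaN); c must be positive.
    """
    if c_morgan <= 0:
        raise ValueError("genetic distance c must be positive")
    if r2 <= 0:
        return float("nan"), 1.0 / (2.0 * c_morgan)
    return (1.0 / (4.0 * c_morgan)) * (1.0 / r2 - 1.0), 1.0 / (2.0 * c_morgan)


def ne_from_ld(
    ld_bins: pd.DataFrame,
    cm_per_mb: float = 1.0,
    sample_size_correction: int | None = None,
) -> pd.DataFrame:
    """Effective population size from binned LD via Sved's equation.

    Ne = (1/(4c)) (1/r^2 - 1) with c the bin-midpoint genetic distance in
    Morgans (physical distance converted at ``cm_per_mb``), dated
    t = 1/(2c) generations ago. When ``sample_size_correction`` is a sample
    count n, r^2 is first reduced by 1/n; off by default.
    """
    out = ld_bins.copy()
    c = out["mid_bp"].to_numpy() * cm_per_mb * 1e-8  # bp -> Morgans
    r2 = out["mean_r2"].to_numpy(dtype=float).copy()
    if sample_size_correction:
        r2 = r2 - 1.0 / sample_size_correction
    with np.errstate(invalid="ignore", divide="ignore"):
        ne = np.where(
            (c > 0) & (r2 > 0), (1.0 / (4.0 * c)) * (1.0 / r2 - 1.0), np.nan
        )
        t = np.where(c > 0, 1.0 / (2.0 * c), np.nan)
    out["c_morgan"] = c
    out["ne"] = ne
    out["t_generations"] = t
    return out[out["c_morgan"] > 0].reset_index(drop=True)
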