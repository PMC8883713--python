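"""The four selection-signature scans between two cohorts.

* **ROH islands** — the per-SNP fraction of a cohort's samples whose called
  runs of homozygosity cover the SNP; maximal runs of SNPs at or above a
  frequency cut-off (50% by default) are island regions, and islands of one
  cohort with zero base-pair overlap against the other cohort's islands are
  cohort-specific.
* **Windowed F_ST** — the Weir–Cockerham (1984) two-population ANOVA
  estimator per SNP, aggregated as a ratio of sums over 100 kb windows
  stepped every 10 kb; window values are Z-standardised genome-wide and the
  per-chromosome upper normal tail flagged as candidates.
* **XP-EHH** — pooled-population extended haplotype homozygosity integrated
  over genetic distance on both sides of each core SNP; the log ratio of the
  two cohorts' integrals, standardised genome-wide, with standard-normal
  p-values; significant SNPs cluster around their top SNP within 100 kb.
* **Case-control GWAS** — per-SNP logistic regression of cohort on dosage
  with age, sampling-region and breed covariates (Wald test), or a 2x2
  allele-count Fisher exact test; significant SNPs are summarised in 100 kb
  tiles that merge into candidate regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING

METHODS = ("ROH_HR", "LRGWAS", "FST", "XPEHH")


@dataclass
class CandidateRegion:
    """A candidate interval (1-based inclusive) with its method of origin."""

    chrom: str
    start_bp: int
    end_bp: int
    method: str
    score: float = np.nan
    top_snp: tuple | None = None  # (snp_id, p)

    @property
    def size_mb(self) -> float:
        return region_size_mb(self.start_bp, self.end_bp)


def region_size_mb(start_bp: int, end_bp: int) -> float:
    """Region size in Mb: (end - start) / 1e6 rounded half-up to 3 decimals."""
    mb = Decimal(int(end_bp) - int(start_bp)) / Decimal(1_000_000)
    return float(mb.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def _regions_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
            "method": r.method, "score": r.score, "size_mb": r.size_mb,
            "top_snp": r.top_snp[0] if r.top_snp else "",
            "top_snp_p": r.top_snp[1] if r.top_snp else np.nan,
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start_bp", "end_bp", "method", "score", "size_mb",
                 "top_snp", "top_snp_p"],
    )


# ---------------------------------------------------------------------------
# ROH-frequency islands
# ---------------------------------------------------------------------------


def roh_snp_frequency(roh_segments: pd.DataFrame, vmap: pd.DataFrame,
                      cohort_samples) -> np.ndarray:
    """Fraction of the cohort whose ROH cover each SNP."""
    cohort_samples = list(cohort_samples)
    if not cohort_samples:
        raise ValueError("empty cohort")
    chroms = vmap["chrom"].to_numpy()
    bp = vmap["bp"].to_numpy()
    counts = np.zeros(len(vmap), dtype=np.int32)
    segs = roh_segments[roh_segments["sample_id"].isin(cohort_samples)]
    # a sample may carry overlapping segments; count each sample once per SNP
    for sid, sample_segs in segs.groupby("sample_id"):
        covered = np.zeros(len(vmap), dtype=bool)
        for seg in sample_segs.itertuples():
            covered |= (
                (chroms == str(seg.chrom))
                & (bp >= seg.start_bp) & (bp <= seg.end_bp)
            )
        counts += covered
    return counts / len(cohort_samples)


def roh_islands(freqs: np.ndarray, vmap: pd.DataFrame,
                threshold: float = 0.5,
                method: str = "ROH_HR") -> list[CandidateRegion]:
    """Maximal runs of consecutive SNPs with ROH frequency >= threshold."""
    freqs = np.asarray(freqs)
    chroms = vmap["chrom"].to_numpy()
    bp = vmap["bp"].to_numpy()
    regions = []
    hit = freqs >= threshold
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero((chroms == chrom) & hit)
        if len(cols) == 0:
            continue
        breaks = np.flatnonzero(np.diff(cols) != 1)
        for run in np.split(cols, breaks + 1):
            regions.append(CandidateRegion(
                chrom=str(chrom),
                start_bp=int(bp[run[0]]), end_bp=int(bp[run[-1]]),
                method=method, score=float(freqs[run].max()),
            ))
    return regions


def cohort_specific_islands(islands_a: list[CandidateRegion],
                            islands_b: list[CandidateRegion]
                            ) -> list[CandidateRegion]:
    """Islands of A with zero bp overlap against every island of B
    (book-ended contact does not disqualify)."""
    out = []
    for a in islands_a:
        clash = any(
            b.chrom == a.chrom
            and a.start_bp <= b.end_bp and b.start_bp <= a.end_bp
            for b in islands_b
        )
        if not clash:
            out.append(a)
    return out


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


def wc_fst_per_snp(G: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Per-SNP Weir & Cockerham (1984) variance components for two groups.

    Returns columns a, b, c (among-population, among-individual,
    within-individual components) and theta = a / (a + b + c), NaN where a
    group has fewer than two called genotypes.
    """
    G = np.asarray(G)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    r = 2
    n_i, p_i, h_i = [], [], []
    for g in groups:
        sub = G[labels == g]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(sub != MISSING, sub, 0).sum(axis=0) / (2.0 * n)
            h = ((sub == 1).sum(axis=0)) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)          # 2 x m
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    valid = (n_i >= 2).all(axis=0)
    nbar = n_i.mean(axis=0)
    nsum = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum

        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(np.abs(denom) > 0, a / denom, np.nan)

    for arr in (a, b, c, theta):
        arr[~valid] = np.nan
    return pd.DataFrame({"a": a, "b": b, "c": c, "theta": theta})


def fst_windows(
    components: pd.DataFrame,
    vmap: pd.DataFrame,
    window_bp: int = 100_000,
    step_bp: int = 10_000,
    min_snps: int = 5,
) -> pd.DataFrame:
    """Sliding-window F_ST as a ratio of sums, sum(a) / sum(a + b + c).

    Windows tile each chromosome from bp 1 with the given width and step;
    windows with fewer than ``min_snps`` component-bearing SNPs are dropped.
    """
    chroms = vmap["chrom"].to_numpy()
    bp = vmap["bp"].to_numpy()
    a = components["a"].to_numpy()
    abc = a + components["b"].to_numpy() + components["c"].to_numpy()
    ok = np.isfinite(abc)
    rows = []
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero((chroms == chrom) & ok)
        if len(cols) == 0:
            continue
        cbp = bp[cols]
        order = np.argsort(cbp)
        cols, cbp = cols[order], cbp[order]
        cum_a = np.concatenate([[0.0], np.cumsum(a[cols])])
        cum_abc = np.concatenate([[0.0], np.cumsum(abc[cols])])
        last = cbp[-1]
        for start in range(1, int(last) + 1, step_bp):
            end = start + window_bp - 1
            lo = np.searchsorted(cbp, start, side="left")
            hi = np.searchsorted(cbp, end, side="right")
            n = hi - lo
            if n < min_snps:
                continue
            denom = cum_abc[hi] - cum_abc[lo]
            if denom == 0:
                continue
            rows.append({
                "chrom": str(chrom), "start_bp": start, "end_bp": end,
                "n_snps": int(n),
                "fst": float((cum_a[hi] - cum_a[lo]) / denom),
            })
    return pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "n_snps", "fst"]
    )


def fst_candidates(
    windows: pd.DataFrame,
    tail_mass: float = 0.001,
    per_chromosome: bool = True,
) -> tuple[pd.DataFrame, list[CandidateRegion]]:
    """Z-standardise window F_ST genome-wide and call the upper normal tail.

    Windows with z above the standard-normal (1 - tail_mass) quantile are
    significant (the threshold is the same number per chromosome; the call
    is made chromosome by chromosome). Overlapping or book-ended significant
    windows merge into regions scored by their maximum z. Returns the
    windows with a ``z`` column added, and the region list.
    """
    if len(windows) < 2:
        raise ValueError("need >= 2 windows to standardise")
    windows = windows.copy()
    sd = windows["fst"].std(ddof=1)
    if sd == 0:
        raise ValueError("window F_ST has zero variance")
    windows["z"] = (windows["fst"] - windows["fst"].mean()) / sd
    z_min = stats.norm.ppf(1.0 - tail_mass)

    regions = []
    group_iter = (
        windows.groupby("chrom", sort=False)
        if per_chromosome else [("all", windows)]
    )
    for _, sub in group_iter:
        sig = sub[sub["z"] >= z_min].sort_values("start_bp")
        cur = None
        for w in sig.itertuples():
            if cur is not None and w.start_bp <= cur.end_bp + 1:
                cur.end_bp = max(cur.end_bp, int(w.end_bp))
                cur.score = max(cur.score, float(w.z))
            else:
                if cur is not None:
                    regions.append(cur)
                cur = CandidateRegion(
                    chrom=str(w.chrom), start_bp=int(w.start_bp),
                    end_bp=int(w.end_bp), method="FST", score=float(w.z),
                )
        if cur is not None:
            regions.append(cur)
    regions.sort(key=lambda r: (r.chrom, r.start_bp))
    return windows, regions


# ---------------------------------------------------------------------------
# EHH / XP-EHH
# ---------------------------------------------------------------------------


def ehh(H: np.ndarray, core_snp: int, side: str,
        allele_class: int | None = None) -> np.ndarray:
    """Extended haplotype homozygosity away from a core SNP.

    For the haplotype set carrying the core state (``allele_class`` 0 or 1;
    ``None`` pools the whole sample, the cross-population convention, with
    the core allele included in the extended haplotype identity):
    EHH(x) = sum_h C(n_h, 2) / C(n, 2) over distinct extended haplotypes
    from the core to x. The returned array starts at the core (value 1) and
    moves outward one SNP at a time; ``side`` is "left" or "right".
    """
    H = np.asarray(H)
    n_all, m = H.shape
    if allele_class is None:
        carriers = np.arange(n_all)
        ids = H[:, core_snp].astype(np.int64)
    else:
        carriers = np.flatnonzero(H[:, core_snp] == allele_class)
        ids = np.zeros(len(carriers), dtype=np.int64)
    n = len(carriers)
    if n < 2:
        raise ValueError("fewer than 2 carrier haplotypes at the core")
    sub = H[carriers]
    denom = n * (n - 1) / 2.0
    if side == "right":
        cols = range(core_snp + 1, m)
    elif side == "left":
        cols = range(core_snp - 1, -1, -1)
    else:
        raise ValueError("side must be 'left' or 'right'")
    out = [1.0]
    for j in cols:
        ids = ids * 2 + sub[:, j]
        _, ids, counts = np.unique(ids, return_inverse=True,
                                   return_counts=True)
        out.append(float((counts * (counts - 1) / 2.0).sum() / denom))
    return np.array(out)


def _ihh_one_side(sub: np.ndarray, core: int, step: int, morgans: np.ndarray,
                  bp: np.ndarray, ehh_cutoff: float,
                  max_gap_bp: float) -> float:
    """Trapezoidal EHH integral on one side of the core (pooled sample,
    core allele included), truncated at EHH < cutoff or a large gap."""
    n = sub.shape[0]
    denom = n * (n - 1) / 2.0
    ids = sub[:, core].astype(np.int64)
    prev_ehh = 1.0
    prev_pos = morgans[core]
    total = 0.0
    j = core + step
    m = sub.shape[1]
    while 0 <= j < m:
        if abs(bp[j] - bp[j - step]) > max_gap_bp:
            break
        ids = ids * 2 + sub[:, j]
        uniq, ids, counts = np.unique(ids, return_inverse=True,
                                      return_counts=True)
        e = float((counts * (counts - 1) / 2.0).sum() / denom)
        if e < ehh_cutoff:
            break
        total += 0.5 * (prev_ehh + e) * abs(morgans[j] - prev_pos)
        prev_ehh, prev_pos = e, morgans[j]
        if e == 0.0:
            break
        j += step
    return total


def xpehh_scan(
    H_a: np.ndarray,
    H_b: np.ndarray,
    vmap: pd.DataFrame,
    ehh_cutoff: float = 0.05,
    max_gap_bp: float = 200_000,
) -> pd.DataFrame:
    """XP-EHH between two phased cohorts sharing a variant map.

    Per SNP: iHH of each cohort's pooled EHH curve (both sides of the core,
    trapezoid over Morgans, truncated at EHH < ``ehh_cutoff`` or an
    inter-SNP gap above ``max_gap_bp``); raw XP-EHH = ln(iHH_A / iHH_B),
    standardised by the genome-wide mean and SD of scored SNPs;
    p = 2 (1 - Phi(|z|)). SNPs with a zero integral in either cohort stay
    unscored (NaN).
    """
    H_a = np.asarray(H_a)
    H_b = np.asarray(H_b)
    chroms = vmap["chrom"].to_numpy()
    bp_all = vmap["bp"].to_numpy()
    cm_all = vmap["cm"].to_numpy()
    raw = np.full(len(vmap), np.nan)
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        bp = bp_all[cols]
        if np.any(np.diff(bp) < 0):
            raise ValueError(f"variant map unsorted on chromosome {chrom}")
        morgans = cm_all[cols] / 100.0
        A = np.ascontiguousarray(H_a[:, cols])
        B = np.ascontiguousarray(H_b[:, cols])
        for local, col in enumerate(cols):
            ihh_a = (
                _ihh_one_side(A, local, +1, morgans, bp, ehh_cutoff,
                              max_gap_bp)
                + _ihh_one_side(A, local, -1, morgans, bp, ehh_cutoff,
                                max_gap_bp)
            )
            ihh_b = (
                _ihh_one_side(B, local, +1, morgans, bp, ehh_cutoff,
                              max_gap_bp)
                + _ihh_one_side(B, local, -1, morgans, bp, ehh_cutoff,
                                max_gap_bp)
            )
            if ihh_a > 0 and ihh_b > 0:
                # difference of logs keeps the population swap exactly
                # antisymmetric in floating point
                raw[col] = np.log(ihh_a) - np.log(ihh_b)

    scored = np.isfinite(raw)
    out = pd.DataFrame({
        "snp_id": vmap["snp_id"], "chrom": vmap["chrom"], "bp": vmap["bp"],
        "raw_stat": raw, "std_stat": np.nan, "p_value": np.nan,
    })
    if scored.sum() >= 2:
        mu = raw[scored].mean()
        sd = raw[scored].std(ddof=1)
        if sd > 0:
            z = (raw - mu) / sd
            out["std_stat"] = z
            out["p_value"] = 2.0 * stats.norm.sf(np.abs(z))
    return out


def xpehh_candidates(
    records: pd.DataFrame,
    p_max: float = 0.05,
    cluster_radius_bp: int = 100_000,
) -> list[CandidateRegion]:
    """Greedy clustering of significant SNPs around their top SNP.

    Repeatedly take the unassigned significant SNP with the smallest
    p-value; its cluster is every unassigned significant SNP on the same
    chromosome within ``cluster_radius_bp``; the region spans the cluster
    (a single-SNP cluster is allowed).
    """
    sig = records[records["p_value"] < p_max].copy()
    regions = []
    sig = sig.sort_values(["p_value", "chrom", "bp"], kind="stable")
    unassigned = sig.copy()
    while len(unassigned):
        top = unassigned.iloc[0]
        near = unassigned[
            (unassigned["chrom"] == top["chrom"])
            & ((unassigned["bp"] - top["bp"]).abs() <= cluster_radius_bp)
        ]
        regions.append(CandidateRegion(
            chrom=str(top["chrom"]),
            start_bp=int(near["bp"].min()), end_bp=int(near["bp"].max()),
            method="XPEHH", score=float(top["std_stat"]),
            top_snp=(top["snp_id"], float(top["p_value"])),
        ))
        unassigned = unassigned.drop(near.index)
    regions.sort(key=lambda r: (r.chrom, r.start_bp))
    return regions


# ---------------------------------------------------------------------------
# Case-control association
# ---------------------------------------------------------------------------


def _design_matrix(samples: pd.DataFrame):
    """Covariate design: standardized age + reference-coded region and breed
    dummies. Rows with missing covariates are dropped (reported)."""
    cov = samples[["age", "region", "breed"]].copy()
    keep = cov["age"].notna().to_numpy()
    cov = cov.loc[keep]
    age = cov["age"].to_numpy(dtype=float)
    sd = age.std()
    age_std = (age - age.mean()) / sd if sd > 0 else np.zeros_like(age)
    parts = [np.ones(len(cov)), age_std]
    names = ["const", "age"]
    for col in ("region", "breed"):
        levels = sorted(cov[col].astype(str).unique())
        for lev in levels[1:]:
            parts.append((cov[col].astype(str) == lev).to_numpy(float))
            names.append(f"{col}_{lev}")
    return np.column_stack(parts), names, keep


def logistic_gwas(
    G: np.ndarray,
    samples: pd.DataFrame,
    vmap: pd.DataFrame,
    case_label: str = "HR",
    control_label: str = "LR",
    ci_level: float = 0.99,
    use_covariates: bool = True,
) -> pd.DataFrame:
    """Per-SNP logistic regression of cohort on allele dosage.

    Model: case ~ dosage + age + region + breed (additive coding, covariates
    optional), fitted by iteratively reweighted least squares; the dosage
    Wald z and two-sided p are reported with a ``ci_level`` confidence
    interval for the log-odds. Non-converged or separated SNPs get NaN.
    """
    import statsmodels.api as sm

    G = np.asarray(G)
    cohorts = samples["cohort"].to_numpy()
    keep_rows = np.isin(cohorts, [case_label, control_label])
    if use_covariates:
        # samples with a missing covariate are dropped from the fit
        keep_rows &= samples["age"].notna().to_numpy()
    sub_samples = samples.loc[keep_rows].reset_index(drop=True)
    if use_covariates:
        X_cov, _, _ = _design_matrix(sub_samples)
    else:
        X_cov = np.ones((len(sub_samples), 1))
    y = (sub_samples["cohort"].to_numpy() == case_label).astype(float)
    if len(y) == 0 or y.min() == y.max():
        raise ValueError("case/control label is constant after filtering")
    Gs = G[keep_rows]

    zq = stats.norm.ppf(0.5 + ci_level / 2.0)
    m = G.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pvals = np.full(m, np.nan)
    for l in range(m):
        g = Gs[:, l].astype(float)
        ok = g != MISSING
        if ok.sum() < X_cov.shape[1] + 2:
            continue
        yy = y[ok]
        if yy.min() == yy.max():
            continue
        X = np.column_stack([X_cov[ok], g[ok]])
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(yy, X).fit(disp=0, maxiter=100)
            if not res.mle_retvals.get("converged", False):
                continue
            b, s = res.params[-1], res.bse[-1]
            if not np.isfinite(s) or s > 100:
                continue  # quasi-separation
            beta[l] = b
            se[l] = s
            pvals[l] = 2.0 * stats.norm.sf(abs(b / s))
        except Exception:
            continue
    with np.errstate(invalid="ignore"):
        z = beta / se
    return pd.DataFrame({
        "snp_id": vmap["snp_id"], "chrom": vmap["chrom"], "bp": vmap["bp"],
        "beta": beta, "se": se, "std_stat": z, "p_value": pvals,
        "ci_lo": beta - zq * se, "ci_hi": beta + zq * se,
    })


def fisher_allelic(
    G: np.ndarray,
    samples: pd.DataFrame,
    vmap: pd.DataFrame,
    case_label: str = "HR",
    control_label: str = "LR",
) -> pd.DataFrame:
    """Two-sided Fisher exact test on the 2x2 allele-count table per SNP."""
    G = np.asarray(G)
    cohorts = samples["cohort"].to_numpy()
    pvals = np.full(G.shape[1], np.nan)
    masks = {
        lab: cohorts == lab for lab in (case_label, control_label)
    }
    for l in range(G.shape[1]):
        table = []
        for lab in (case_label, control_label):
            g = G[masks[lab], l]
            g = g[g != MISSING]
            a1 = int(g.sum())
            table.append([a1, 2 * len(g) - a1])
        t = np.array(table)
        if t.sum() == 0 or (t.sum(axis=0) == 0).any() \
                or (t.sum(axis=1) == 0).any():
            pvals[l] = 1.0
            continue
        pvals[l] = stats.fisher_exact(t, alternative="two-sided")[1]
    return pd.DataFrame({
        "snp_id": vmap["snp_id"], "chrom": vmap["chrom"], "bp": vmap["bp"],
        "p_value": pvals,
    })


def gwas_candidates(
    records: pd.DataFrame,
    n_tests: int | None = None,
    alpha: float = 0.001,
    neglog10_min: float | None = 4.25,
    window_bp: int = 100_000,
) -> list[CandidateRegion]:
    """Candidate regions from association p-values.

    A SNP is significant when its Bonferroni-adjusted p
    (min(1, p * n_tests)) is below ``alpha`` and, when ``neglog10_min`` is
    set, -log10 of the raw p reaches that gate (either gate can be disabled
    with None). Significant SNPs fall into fixed ``window_bp`` tiles; runs
    of overlapping/adjacent significant tiles merge into regions carrying
    their minimum-p SNP.
    """
    rec = records[np.isfinite(records["p_value"])].copy()
    if n_tests is None:
        n_tests = len(rec)
    sig = np.ones(len(rec), dtype=bool)
    if alpha is not None:
        p_adj = np.minimum(1.0, rec["p_value"].to_numpy() * n_tests)
        sig &= p_adj < alpha
    if neglog10_min is not None:
        with np.errstate(divide="ignore"):
            sig &= -np.log10(rec["p_value"].to_numpy()) >= neglog10_min
    rec = rec.loc[sig]
    regions = []
    for chrom, sub in rec.groupby("chrom", sort=False):
        tiles = np.unique((sub["bp"].to_numpy() - 1) // window_bp)
        breaks = np.flatnonzero(np.diff(tiles) != 1)
        for run in np.split(tiles, breaks + 1):
            start = int(run[0]) * window_bp + 1
            end = (int(run[-1]) + 1) * window_bp
            inside = sub[(sub["bp"] >= start) & (sub["bp"] <= end)]
            top = inside.loc[inside["p_value"].idxmin()]
            regions.append(CandidateRegion(
                chrom=str(chrom), start_bp=start, end_bp=end,
                method="LRGWAS",
                score=float(-np.log10(top["p_value"]))
                if top["p_value"] > 0 else np.inf,
                top_snp=(top["snp_id"], float(top["p_value"])),
            ))
    regions.sort(key=lambda r: (r.chrom, r.start_bp))
    return regions


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Tabulate candidate regions (1-based inclusive coordinates)."""
    return _regions_frame(regions)
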