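"""Genotype and haplotype file I/O, sample metadata, QC and LD pruning.

Genotypes are held as a samples x SNPs ``numpy`` int8 matrix of allele-1
dosages in {0, 1, 2} with :data:`MISSING` (-1) as the missing sentinel.
The variant map and sample table are plain :class:`pandas.DataFrame` objects
with fixed column sets (see :data:`VARIANT_COLUMNS`, :data:`SAMPLE_COLUMNS`).

Supported formats:

* PLINK-1 binary trio ``.bed``/``.bim``/``.fam`` (SNP-major, magic bytes
  ``6C 1B 01``); 2-bit codes ``00``=hom A1, ``10``=het, ``11``=hom A2,
  ``01``=missing, packed 4 genotypes per byte, lowest bits first.
* PLINK text ``.ped``/``.map`` (read only).
* Oxford phased haplotypes ``.haps``/``.sample`` (no missing alleles).
* Tab-separated sample metadata with header
  ``sample_id  cohort  breed  region  age``.

Coordinates are 1-based inclusive throughout (matching ``.bim``); genetic
positions are centiMorgans. When a ``.bim`` carries no genetic positions a
default map of 1 cM/Mb is applied (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

VARIANT_COLUMNS = ["snp_id", "chrom", "bp", "cm", "allele1", "allele2"]
SAMPLE_COLUMNS = ["sample_id", "cohort", "breed", "region", "age"]

# 2-bit PLINK code -> dosage of allele 1
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class PlinkFormatError(ValueError):
    """Malformed PLINK file (bad magic bytes, truncated body, bad field)."""


def _decode_lut() -> np.ndarray:
    """256 x 4 lookup: byte value -> four dosages, lowest bit-pair first."""
    lut = np.empty((256, 4), dtype=np.int8)
    for b in range(256):
        for k in range(4):
            lut[b, k] = _CODE_TO_DOSAGE[(b >> (2 * k)) & 0b11]
    return lut


_LUT = _decode_lut()


def default_cm(bp: np.ndarray, cm_per_mb: float = 1.0) -> np.ndarray:
    """Genetic positions (cM) from physical positions under a uniform map."""
    return np.asarray(bp, dtype=float) * cm_per_mb * 1e-6


def read_bim(path: str | Path, cm_per_mb: float = 1.0) -> pd.DataFrame:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp", "allele1", "allele2"],
        dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    bim["cm"] = bim["cm"].astype(float)
    bim["bp"] = bim["bp"].astype(np.int64)
    if (bim["cm"] == 0).all() and len(bim) > 1:
        bim["cm"] = default_cm(bim["bp"].to_numpy(), cm_per_mb)
    return bim[VARIANT_COLUMNS]


def read_fam(path: str | Path) -> pd.DataFrame:
    fam = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "sample_id", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    samples = pd.DataFrame(
        {
            "sample_id": fam["sample_id"],
            "cohort": "unassigned",
            "breed": "other",
            "region": "other",
            "age": np.nan,
        }
    )
    return samples[SAMPLE_COLUMNS]


def read_plink(prefix: str | Path, cm_per_mb: float = 1.0):
    """Read a PLINK-1 binary trio ``prefix``.bed/.bim/.fam.

    Returns ``(G, variant_map, samples)`` where ``G`` is samples x SNPs int8
    dosages of allele 1 with -1 for missing.
    """
    prefix = Path(prefix)
    vmap = read_bim(prefix.with_suffix(".bim"), cm_per_mb=cm_per_mb)
    samples = read_fam(prefix.with_suffix(".fam"))
    n, m = len(samples), len(vmap)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix}.bed: bad magic bytes {raw[:3].hex()} (expected 6c1b01)"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{prefix}.bed: size {len(raw)} != expected {expected} "
            f"for {n} samples x {m} SNPs"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if m == 0:
        return np.empty((n, 0), dtype=np.int8), vmap, samples
    decoded = _LUT[body.reshape(m, bytes_per_snp)].reshape(m, 4 * bytes_per_snp)
    G = np.ascontiguousarray(decoded[:, :n].T)
    return G, vmap, samples


def write_plink(G: np.ndarray, vmap: pd.DataFrame, samples: pd.DataFrame,
                prefix: str | Path) -> None:
    """Write a PLINK-1 binary trio. Bit-exact inverse of :func:`read_plink`."""
    G = np.asarray(G, dtype=np.int8)
    n, m = G.shape
    if len(vmap) != m or len(samples) != n:
        raise ValueError("dimension mismatch between G, variant map and samples")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    bim = pd.DataFrame(
        {
            "chrom": vmap["chrom"].fillna("0"),
            "snp_id": vmap["snp_id"],
            "cm": vmap["cm"],
            "bp": vmap["bp"],
            "allele1": vmap["allele1"],
            "allele2": vmap["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": samples["sample_id"],
            "iid": samples["sample_id"],
            "father": "0",
            "mother": "0",
            "sex": "0",
            "phenotype": "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bytes_per_snp = (n + 3) // 4
    codes = np.zeros((m, 4 * bytes_per_snp), dtype=np.uint8)
    col = G.T  # m x n
    enc = np.empty_like(col, dtype=np.uint8)
    enc[col == 2] = 0b00
    enc[col == 1] = 0b10
    enc[col == 0] = 0b11
    enc[col == MISSING] = 0b01
    codes[:, :n] = enc
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def read_ped(prefix: str | Path, cm_per_mb: float = 1.0):
    """Read PLINK text ``.ped``/``.map`` (read only).

    Alleles are recoded per SNP: the ``.map`` has no allele columns, so allele1
    is the first non-missing allele observed at each SNP ('0' = missing).
    """
    prefix = Path(prefix)
    mp = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp"],
        dtype={"chrom": str, "snp_id": str},
    )
    rows = []
    sample_ids = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            sample_ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype="U8").reshape(len(rows), len(mp), 2)
    m = len(mp)
    G = np.full((len(rows), m), MISSING, dtype=np.int8)
    a1 = np.empty(m, dtype="U8")
    a2 = np.empty(m, dtype="U8")
    for l in range(m):
        snp = alleles[:, l, :]
        obs = snp[snp != "0"]
        uniq = pd.unique(obs)
        a1[l] = uniq[0] if len(uniq) > 0 else "0"
        a2[l] = uniq[1] if len(uniq) > 1 else a1[l]
        called = (snp != "0").all(axis=1)
        G[called, l] = (snp[called] == a1[l]).sum(axis=1)
    cm = mp["cm"].astype(float).to_numpy()
    if (cm == 0).all() and m > 1:
        cm = default_cm(mp["bp"].to_numpy(), cm_per_mb)
    vmap = pd.DataFrame(
        {
            "snp_id": mp["snp_id"],
            "chrom": mp["chrom"],
            "bp": mp["bp"].astype(np.int64),
            "cm": cm,
            "allele1": a1,
            "allele2": a2,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": "unassigned",
            "breed": "other",
            "region": "other",
            "age": np.nan,
        }
    )
    return G, vmap, samples


def read_haplotypes(haps_path: str | Path, sample_path: str | Path,
                    cm_per_mb: float = 1.0):
    """Read Oxford ``.haps``/``.sample`` phased haplotypes.

    Returns ``(H, variant_map, samples)`` with ``H`` of shape
    (2 * n_samples) x n_snps; haplotype rows (2i, 2i+1) belong to sample i.
    """
    sample = pd.read_csv(sample_path, sep=r"\s+", dtype=str)
    sample = sample.iloc[1:].reset_index(drop=True)  # drop the type row
    sample_ids = sample.iloc[:, 1].tolist()
    n = len(sample_ids)

    chroms, ids, bps, a1s, a2s = [], [], [], [], []
    hap_rows = []
    with open(haps_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5 + 2 * n:
                raise PlinkFormatError(
                    f"{haps_path}:{lineno}: expected {5 + 2 * n} fields "
                    f"({n} samples), got {len(parts)}"
                )
            chroms.append(parts[0])
            ids.append(parts[1])
            bps.append(int(parts[2]))
            a1s.append(parts[3])
            a2s.append(parts[4])
            alleles = parts[5:]
            if any(a not in ("0", "1") for a in alleles):
                raise PlinkFormatError(
                    f"{haps_path}:{lineno}: allele outside {{0,1}} "
                    "(phased input admits no missing calls)"
                )
            hap_rows.append([int(a) for a in alleles])
    H = np.array(hap_rows, dtype=np.int8).T if hap_rows else np.empty(
        (2 * n, 0), dtype=np.int8
    )
    bp = np.array(bps, dtype=np.int64)
    vmap = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chroms,
            "bp": bp,
            "cm": default_cm(bp, cm_per_mb),
            "allele1": a1s,
            "allele2": a2s,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": "unassigned",
            "breed": "other",
            "region": "other",
            "age": np.nan,
        }
    )
    return H, vmap, samples


def write_haplotypes(H: np.ndarray, vmap: pd.DataFrame, samples: pd.DataFrame,
                     haps_path: str | Path, sample_path: str | Path) -> None:
    """Write Oxford ``.haps``/``.sample``; inverse of :func:`read_haplotypes`."""
    H = np.asarray(H)
    n2, m = H.shape
    if n2 != 2 * len(samples) or m != len(vmap):
        raise ValueError("dimension mismatch between H, variant map and samples")
    with open(haps_path, "w") as fh:
        for l in range(m):
            row = vmap.iloc[l]
            alleles = " ".join(str(int(a)) for a in H[:, l])
            fh.write(
                f"{row.chrom} {row.snp_id} {int(row.bp)} "
                f"{row.allele1} {row.allele2} {alleles}\n"
            )
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for sid in samples["sample_id"]:
            fh.write(f"{sid} {sid} 0\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated sample metadata table (sample_id, cohort, breed,
    region, age)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(SAMPLE_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    meta["age"] = pd.to_numeric(meta["age"], errors="coerce")
    return meta[SAMPLE_COLUMNS]


def write_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def attach_metadata(samples: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Overlay metadata (cohort/breed/region/age) onto a sample table by id."""
    merged = samples[["sample_id"]].merge(meta, on="sample_id", how="left")
    merged["cohort"] = merged["cohort"].fillna("unassigned")
    merged["breed"] = merged["breed"].fillna("other")
    merged["region"] = merged["region"].fillna("other")
    return merged[SAMPLE_COLUMNS]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Counts of samples and SNPs removed by each QC filter."""

    n_samples_in: int = 0
    n_samples_out: int = 0
    n_snps_in: int = 0
    n_snps_out: int = 0
    removed_samples: list = field(default_factory=list)  # (sample_id, reason)
    removed_snps: dict = field(default_factory=lambda: {
        "maf": 0, "snp_callrate": 0, "unmapped": 0,
    })

    def summary(self) -> str:
        return (
            f"samples {self.n_samples_in} -> {self.n_samples_out}; "
            f"SNPs {self.n_snps_in} -> {self.n_snps_out}; "
            f"removed SNPs {self.removed_snps}"
        )


def pairwise_ibs(G: np.ndarray) -> np.ndarray:
    """Pairwise identity-by-state proportions.

    IBS(i, j) = mean over SNPs non-missing in both samples of
    1 - |g_i - g_j| / 2. Symmetric, diagonal 1; NaN for pairs with no jointly
    observed SNP.
    """
    G = np.asarray(G, dtype=np.int8)
    n = G.shape[0]
    if n < 2:
        raise ValueError("pairwise IBS requires at least two samples")
    Gf = G.astype(float)
    Gf[G == MISSING] = np.nan
    out = np.ones((n, n))
    for i in range(n):
        diff = np.abs(Gf[i] - Gf[i + 1:])  # (n-i-1) x m, NaN where missing
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sims = np.nanmean(1.0 - diff / 2.0, axis=1)
        out[i, i + 1:] = sims
        out[i + 1:, i] = sims
    return out


def _call_rates(G: np.ndarray):
    called = G != MISSING
    sample_cr = called.mean(axis=1) if G.shape[1] else np.ones(G.shape[0])
    snp_cr = called.mean(axis=0) if G.shape[0] else np.ones(G.shape[1])
    return sample_cr, snp_cr


def allele_frequencies(G: np.ndarray) -> np.ndarray:
    """Per-SNP allele-1 frequency over non-missing genotypes (NaN if none)."""
    G = np.asarray(G)
    called = G != MISSING
    counts = np.where(called, G, 0).sum(axis=0)
    denom = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, counts / denom, np.nan)


def qc_filter(
    G: np.ndarray,
    vmap: pd.DataFrame,
    samples: pd.DataFrame,
    ibs_max: float = 0.99,
    maf_min: float = 0.01,
    snp_callrate_min: float = 0.95,
    ind_callrate_min: float = 0.90,
    drop_unmapped: bool = True,
):
    """Apply the four-step QC in order: (i) one member of each highly related
    pair (IBS > ibs_max) removed, (ii) SNPs with MAF below maf_min removed,
    (iii) SNPs then individuals below their call-rate thresholds removed,
    (iv) unmapped SNPs removed.

    From a related pair the member with the lower call rate is dropped
    (tie: the later sample index). Returns ``(G', vmap', samples', QCReport)``.
    """
    G = np.asarray(G, dtype=np.int8)
    report = QCReport(
        n_samples_in=G.shape[0],
        n_snps_in=G.shape[1],
        removed_snps={"maf": 0, "snp_callrate": 0, "unmapped": 0},
    )

    keep_s = np.ones(G.shape[0], dtype=bool)
    # (i) relatedness
    if G.shape[0] >= 2:
        ibs = pairwise_ibs(G)
        sample_cr, _ = _call_rates(G)
        n = G.shape[0]
        for i in range(n):
            if not keep_s[i]:
                continue
            for j in range(i + 1, n):
                if not keep_s[j]:
                    continue
                if np.isfinite(ibs[i, j]) and ibs[i, j] > ibs_max:
                    drop = j if sample_cr[j] <= sample_cr[i] else i
                    keep_s[drop] = False
                    report.removed_samples.append(
                        (samples["sample_id"].iloc[drop], "ibs_pair")
                    )
                    if drop == i:
                        break
    G = G[keep_s]
    samples = samples.loc[keep_s].reset_index(drop=True)

    # (ii) MAF on the remaining samples
    freqs = allele_frequencies(G)
    maf = np.minimum(freqs, 1.0 - freqs)
    with np.errstate(invalid="ignore"):
        # all-missing SNPs (NaN MAF) survive here and fall to the call-rate gate
        keep_v = ~(maf < maf_min)
    report.removed_snps["maf"] = int((~keep_v).sum())
    G = G[:, keep_v]
    vmap = vmap.loc[keep_v].reset_index(drop=True)

    # (iii) call rates: SNPs (0.95) then individuals (0.90)
    _, snp_cr = _call_rates(G)
    keep_v = snp_cr >= snp_callrate_min
    report.removed_snps["snp_callrate"] = int((~keep_v).sum())
    G = G[:, keep_v]
    vmap = vmap.loc[keep_v].reset_index(drop=True)

    sample_cr, _ = _call_rates(G)
    keep_s = sample_cr >= ind_callrate_min
    for sid in samples["sample_id"].to_numpy()[~keep_s]:
        report.removed_samples.append((sid, "ind_callrate"))
    G = G[keep_s]
    samples = samples.loc[keep_s].reset_index(drop=True)

    # (iv) unmapped SNPs
    if drop_unmapped:
        unmapped = (vmap["chrom"].astype(str) == "0") | (vmap["bp"] <= 0)
        report.removed_snps["unmapped"] = int(unmapped.sum())
        keep_v = ~unmapped.to_numpy()
        G = G[:, keep_v]
        vmap = vmap.loc[keep_v].reset_index(drop=True)

    report.n_samples_out = G.shape[0]
    report.n_snps_out = G.shape[1]
    if report.n_samples_out == 0:
        raise ValueError("QC removed every sample")
    return G, vmap, samples, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def dosage_r2(G: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages at two SNPs (complete cases)."""
    gi, gj = G[:, i], G[:, j]
    ok = (gi != MISSING) & (gj != MISSING)
    if ok.sum() < 2:
        return np.nan
    x, y = gi[ok].astype(float), gj[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _window_r2(G: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Pairwise r^2 among the given SNP columns, complete cases per pair."""
    sub = G[:, idx].astype(float)
    sub[G[:, idx] == MISSING] = np.nan
    df = pd.DataFrame(sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = df.corr(min_periods=2).to_numpy()
    return corr**2


def ld_prune(
    G: np.ndarray,
    vmap: pd.DataFrame | None = None,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Greedy windowed LD pruning (PLINK ``--indep-pairwise`` style).

    Within each window of ``window_snps`` consecutive columns (advancing by
    ``step_snps``), every pair of still-kept SNPs with r^2 > ``r2_max`` loses
    its later member. Windows never span chromosomes when a variant map is
    given. Returns the kept SNP indices (sorted).
    """
    G = np.asarray(G)
    m = G.shape[1]
    keep = np.ones(m, dtype=bool)
    if vmap is not None:
        boundaries = []
        chroms = vmap["chrom"].to_numpy()
        start = 0
        for i in range(1, m):
            if chroms[i] != chroms[i - 1]:
                boundaries.append((start, i))
                start = i
        boundaries.append((start, m))
    else:
        boundaries = [(0, m)]

    for lo, hi in boundaries:
        for start in range(lo, hi, step_snps):
            idx = np.arange(start, min(start + window_snps, hi))
            idx = idx[keep[idx]]
            if len(idx) < 2:
                continue
            r2 = _window_r2(G, idx)
            alive = np.ones(len(idx), dtype=bool)
            for a in range(len(idx)):
                if not alive[a]:
                    continue
                for b in range(a + 1, len(idx)):
                    if alive[b] and r2[a, b] > r2_max:
                        alive[b] = False
                        keep[idx[b]] = False
            if start + window_snps >= hi:
                break
    return np.flatnonzero(keep)
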