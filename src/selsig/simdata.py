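"""Synthetic two-cohort SNP-chip data with known ground truth.

The generator emulates the statistical structure a selection-signature
analysis relies on, without pretending to be a forward or coalescent
simulation:

* **Cohort divergence** — per-SNP cohort allele frequencies follow the
  Balding–Nichols model: ``p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` around an
  ancestral frequency ``p ~ U(0.05, 0.95)``, with ``F`` the target
  differentiation.
* **Background LD** — each sample haplotype is a Markov mosaic over a small
  pool of founder haplotypes; the copying source switches between adjacent
  SNPs with probability ``1 - exp(-rate * d)`` for genetic distance ``d``
  Morgans, so linkage decays smoothly with distance.
* **Planted sweeps** — in a chosen cohort, a fraction of haplotypes has an
  interval overwritten by one fixed core haplotype, creating the extended
  haplotype homozygosity and allele-frequency differentiation a sweep leaves.
* **Planted autozygosity** — a sample's second haplotype is overwritten by
  its first over an exponentially-sized segment (min 1 Mb), creating an exact
  run of homozygosity.

All randomness flows from ``SimConfig.seed``; identical configs give
byte-identical outputs. Ground truth (frequencies, sweep and ROH intervals)
is returned alongside the data and can be dumped/reloaded as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio

COHORTS = ("HR", "LR")


@dataclass(frozen=True)
class SweepSpec:
    """A planted selective sweep: fixed core haplotype copied over
    [center - half_width, center + half_width] in a fraction of one cohort's
    haplotypes."""

    chrom: str
    center_bp: int
    half_width_bp: int
    carrier_fraction: float
    cohort: str = "HR"

    @property
    def start_bp(self) -> int:
        return self.center_bp - self.half_width_bp

    @property
    def end_bp(self) -> int:
        return self.center_bp + self.half_width_bp


@dataclass
class SimConfig:
    """Study-scale defaults: two cohorts of 74 animals (the analysed cohort
    size), three ~50 Mb chromosomes at one SNP per 10 kb — a desk-scale slice
    of a 600 K chip at comparable marker density per Mb of simulated genome —
    and a founder-mosaic LD structure. Default cohort divergence is near
    zero because resistance cohorts drawn from one population show no
    genome-wide differentiation; experiments that need divergence set it
    explicitly."""

    n_per_cohort: int = 74
    n_chrom: int = 3
    chrom_length_bp: int = 50_000_000
    n_snps_per_chrom: int = 5_000
    fst_divergence: float = 0.01
    n_founder_haplotypes: int = 30
    copy_switch_rate: float = 100.0  # copy-source switches per Morgan
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    roh_rate: float = 0.5
    roh_mean_length_bp: float = 2_000_000.0
    seed: int = 0
    cm_per_mb: float = 1.0

    def __post_init__(self):
        if not (0 <= self.fst_divergence < 1):
            raise ValueError("fst_divergence must be in [0, 1)")
        if self.n_founder_haplotypes < 2:
            raise ValueError("need at least 2 founder haplotypes")
        for sw in self.sweep_specs:
            if not (0 <= sw.carrier_fraction <= 1):
                raise ValueError("carrier_fraction must be in [0, 1]")
            if sw.start_bp < 1 or sw.end_bp > self.chrom_length_bp:
                raise ValueError(
                    f"sweep {sw} extends outside its chromosome "
                    f"(length {self.chrom_length_bp})"
                )


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    ancestral_freq: np.ndarray                 # per SNP
    cohort_freqs: dict[str, np.ndarray]        # cohort -> per-SNP frequency
    sweeps: pd.DataFrame                       # chrom, start_bp, end_bp, cohort, carrier_fraction
    roh: pd.DataFrame                          # sample_id, chrom, start_bp, end_bp


def _founder_pool(rng, pk: np.ndarray, n_founders: int) -> np.ndarray:
    """Founder haplotypes whose per-SNP allele count tracks the cohort
    frequency by randomized rounding.

    A plain Bernoulli draw would add ~1/n_founders of founder-pool drift on
    top of the Balding-Nichols divergence and bias F_ST upward; pinning the
    pool count to round(p * n_founders) keeps the realized cohort frequency
    unbiased with negligible extra variance.
    """
    m = len(pk)
    x = pk * n_founders
    counts = np.floor(x).astype(np.int64)
    counts += (rng.random(m) < (x - counts)).astype(np.int64)
    # random placement of the carrier alleles among founders, per SNP
    ranks = np.argsort(rng.random(size=(n_founders, m)), axis=0)
    ranks = np.argsort(ranks, axis=0)
    return (ranks < counts[None, :]).astype(np.int8)


def _mosaic_haplotypes(rng, founders: np.ndarray, n_hap: int,
                       switch_prob: np.ndarray) -> np.ndarray:
    """Markov founder-copying mosaic for ``n_hap`` haplotypes.

    ``switch_prob[j]`` is the probability of switching copy source between
    SNP j and j+1.
    """
    n_f, m = founders.shape
    choice = rng.integers(0, n_f, size=(n_hap, m))
    switched = rng.random(size=(n_hap, m - 1)) < switch_prob[None, :]
    is_start = np.concatenate(
        [np.ones((n_hap, 1), dtype=bool), switched], axis=1
    )
    # forward-fill the founder chosen at each segment start
    start_idx = np.where(is_start, np.arange(m)[None, :], 0)
    last_start = np.maximum.accumulate(start_idx, axis=1)
    source = np.take_along_axis(choice, last_start, axis=1)
    return founders[source, np.arange(m)[None, :]].astype(np.int8)


def simulate_cohorts(config: SimConfig):
    """Generate one two-cohort dataset.

    Returns ``(H, G, vmap, samples, truth)``: phased haplotypes
    (2 * total samples) x SNPs, diploid dosages, variant map, sample table
    (HR first, then LR) and the :class:`SimTruth` record.
    """
    return _simulate(config, {c: config.n_per_cohort for c in COHORTS})


def simulate_populations(config: SimConfig, pop_sizes: dict[str, int]):
    """Multi-population variant of :func:`simulate_cohorts` (used for
    structure-recovery experiments); sweeps/ROH apply per named population."""
    return _simulate(config, pop_sizes)


def _simulate(config: SimConfig, pop_sizes: dict[str, int]):
    rng = np.random.default_rng(config.seed)
    pops = list(pop_sizes)
    F = config.fst_divergence

    vmaps = []
    anc_all, pop_freq_all = [], {k: [] for k in pops}
    hap_blocks = {k: [] for k in pops}
    core_haps = {}  # (pop, chrom) -> founder row used for sweeps

    for ci in range(config.n_chrom):
        chrom = str(ci + 1)
        pos = np.unique(
            rng.integers(1, config.chrom_length_bp + 1,
                         size=config.n_snps_per_chrom)
        )
        m = len(pos)
        cm = pos * config.cm_per_mb * 1e-6
        vmaps.append(pd.DataFrame({
            "snp_id": [f"snp{chrom}_{i}" for i in range(m)],
            "chrom": chrom,
            "bp": pos.astype(np.int64),
            "cm": cm,
            "allele1": "A",
            "allele2": "G",
        }))
        p = rng.uniform(0.05, 0.95, size=m)
        anc_all.append(p)

        d_morgan = np.diff(cm) / 100.0
        switch_prob = 1.0 - np.exp(-config.copy_switch_rate * d_morgan)

        for pop in pops:
            if F > 0:
                a = p * (1 - F) / F
                b = (1 - p) * (1 - F) / F
                pk = rng.beta(a, b)
            else:
                pk = p.copy()
            pop_freq_all[pop].append(pk)
            founders = _founder_pool(rng, pk, config.n_founder_haplotypes)
            core_haps[(pop, chrom)] = founders[0].copy()
            haps = _mosaic_haplotypes(rng, founders, 2 * pop_sizes[pop],
                                      switch_prob)
            hap_blocks[pop].append(haps)

    vmap = pd.concat(vmaps, ignore_index=True)
    anc = np.concatenate(anc_all)
    pop_freqs = {k: np.concatenate(v) for k, v in pop_freq_all.items()}
    H_pop = {k: np.concatenate(v, axis=1) for k, v in hap_blocks.items()}

    chrom_arr = vmap["chrom"].to_numpy()
    bp_arr = vmap["bp"].to_numpy()

    # planted sweeps: overwrite interval with the population's core haplotype
    sweep_rows = []
    for sw in config.sweep_specs:
        if sw.cohort not in H_pop:
            raise ValueError(f"sweep names unknown cohort {sw.cohort!r}")
        cols = np.flatnonzero(
            (chrom_arr == str(sw.chrom))
            & (bp_arr >= sw.start_bp) & (bp_arr <= sw.end_bp)
        )
        haps = H_pop[sw.cohort]
        n_carriers = int(round(sw.carrier_fraction * haps.shape[0]))
        carriers = rng.choice(haps.shape[0], size=n_carriers, replace=False)
        core = core_haps[(sw.cohort, str(sw.chrom))]
        # core haplotype is defined chromosome-wide; index within-chromosome
        chrom_cols = np.flatnonzero(chrom_arr == str(sw.chrom))
        local = np.searchsorted(chrom_cols, cols)
        haps[np.ix_(carriers, cols)] = core[local][None, :]
        sweep_rows.append({
            "chrom": str(sw.chrom), "start_bp": sw.start_bp,
            "end_bp": sw.end_bp, "cohort": sw.cohort,
            "carrier_fraction": sw.carrier_fraction,
        })

    # planted autozygous segments
    roh_rows = []
    for pop in pops:
        haps = H_pop[pop]
        for s in range(pop_sizes[pop]):
            if rng.random() >= config.roh_rate:
                continue
            chrom = str(int(rng.integers(1, config.n_chrom + 1)))
            length = max(1_000_000, int(rng.exponential(
                config.roh_mean_length_bp)))
            length = min(length, config.chrom_length_bp - 1)
            start = int(rng.integers(1, config.chrom_length_bp - length + 1))
            end = start + length - 1
            cols = np.flatnonzero(
                (chrom_arr == chrom) & (bp_arr >= start) & (bp_arr <= end)
            )
            haps[2 * s + 1, cols] = haps[2 * s, cols]
            roh_rows.append({
                "sample_id": f"{pop}_{s:03d}", "chrom": chrom,
                "start_bp": start, "end_bp": end,
            })

    H = np.concatenate([H_pop[p] for p in pops], axis=0)
    G = (H[0::2] + H[1::2]).astype(np.int8)

    sample_rows = []
    for pop in pops:
        for s in range(pop_sizes[pop]):
            sample_rows.append({
                "sample_id": f"{pop}_{s:03d}",
                "cohort": pop if pop in COHORTS else "unassigned",
                "breed": "B" if rng.random() < 0.64 else "Q",
                "region": ["northeast", "northwest", "southeast"][
                    int(rng.integers(0, 3))],
                "age": float(np.round(rng.uniform(2.0, 8.0), 2)),
            })
    samples = pd.DataFrame(sample_rows, columns=gio.SAMPLE_COLUMNS)

    truth = SimTruth(
        ancestral_freq=anc,
        cohort_freqs=pop_freqs,
        sweeps=pd.DataFrame(
            sweep_rows,
            columns=["chrom", "start_bp", "end_bp", "cohort",
                     "carrier_fraction"],
        ),
        roh=pd.DataFrame(
            roh_rows, columns=["sample_id", "chrom", "start_bp", "end_bp"]
        ),
    )
    return H, G, vmap, samples, truth


def truth_report(truth: SimTruth, vmap: pd.DataFrame,
                 out_dir: str | Path) -> None:
    """Dump the ground truth as TSV files (sweeps, ROH intervals, per-SNP
    frequencies) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.sweeps.to_csv(out / "truth_sweeps.tsv", sep="\t", index=False)
    truth.roh.to_csv(out / "truth_roh.tsv", sep="\t", index=False)
    freqs = pd.DataFrame({
        "snp_id": vmap["snp_id"],
        "chrom": vmap["chrom"],
        "bp": vmap["bp"],
        "ancestral_freq": truth.ancestral_freq,
    })
    for pop, f in truth.cohort_freqs.items():
        freqs[f"freq_{pop}"] = f
    freqs.to_csv(out / "truth_freqs.tsv", sep="\t", index=False)


def read_truth_report(out_dir: str | Path) -> SimTruth:
    """Reload a :func:`truth_report` dump."""
    out = Path(out_dir)
    sweeps = pd.read_csv(out / "truth_sweeps.tsv", sep="\t",
                         dtype={"chrom": str})
    roh = pd.read_csv(out / "truth_roh.tsv", sep="\t", dtype={"chrom": str})
    freqs = pd.read_csv(out / "truth_freqs.tsv", sep="\t", dtype={"chrom": str})
    cohort_freqs = {
        c.removeprefix("freq_"): freqs[c].to_numpy()
        for c in freqs.columns if c.startswith("freq_")
    }
    return SimTruth(
        ancestral_freq=freqs["ancestral_freq"].to_numpy(),
        cohort_freqs=cohort_freqs,
        sweeps=sweeps,
        roh=roh,
    )


def write_dataset(H, G, vmap, samples, truth, out_dir: str | Path,
                  prefix: str = "sim") -> None:
    """Write the full dataset: PLINK trio, .haps/.sample, metadata and truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_plink(G, vmap, samples, out / prefix)
    gio.write_haplotypes(H, vmap, samples, out / f"{prefix}.haps",
                         out / f"{prefix}.sample")
    gio.write_metadata(samples, out / f"{prefix}.meta.tsv")
    truth_report(truth, vmap, out)
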