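"""Pipeline orchestration: configuration, seeded end-to-end runs and
plot-data export.

Stage order: QC -> (diversity, structure) -> ROH/F_ST/XP-EHH/GWAS scans ->
consensus -> annotation. Every stage writes TSV outputs under the run
directory and records row counts in a manifest; re-running an identical
config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import consensus as cons
from . import diversity, io, scans, simdata, structure

log = logging.getLogger("selsig")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis in one validated document."""

    # inputs; when bfile is None a synthetic dataset is generated
    bfile: str | None = None
    haps: str | None = None
    sample: str | None = None
    pheno: str | None = None
    annotation: str | None = None
    terms: str | None = None
    outdir: str = "selsig_run"

    case_label: str = "HR"
    control_label: str = "LR"
    equal_subsample: bool = False

    # QC
    ibs_max: float = 0.99
    maf_min: float = 0.01
    snp_callrate_min: float = 0.95
    ind_callrate_min: float = 0.90
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.5

    # diversity / ROH
    roh: dict = field(default_factory=dict)
    autosome_length_bp: float = diversity.AUTOSOME_LENGTH_BP
    ld_max_dist_bp: int = 1_000_000
    ld_n_bins: int = 20
    cm_per_mb: float = 1.0

    # structure
    n_pcs: int = 10
    admixture_k_values: tuple = (1, 2, 3)
    admixture_replicates: int = 3

    # scans
    roh_island_threshold: float = 0.5
    fst_window_bp: int = 100_000
    fst_step_bp: int = 10_000
    fst_min_snps: int = 5
    fst_tail_mass: float = 0.001
    xpehh_ehh_cutoff: float = 0.05
    xpehh_max_gap_bp: int = 200_000
    xpehh_p_max: float = 0.05
    xpehh_cluster_radius_bp: int = 100_000
    gwas_alpha: float = 0.001
    gwas_neglog10_min: float | None = 4.25
    gwas_window_bp: int = 100_000
    gwas_test: str = "logistic"  # or "fisher"
    min_methods: int = 2

    seed: int = 0
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "admixture_k_values" in data:
            data["admixture_k_values"] = tuple(data["admixture_k_values"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["admixture_k_values"] = list(self.admixture_k_values)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": {}, "seed": config.seed, "inputs": {}}
    rng = np.random.default_rng(config.seed)

    # --- input stage -------------------------------------------------------
    if config.bfile:
        G, vmap, samples = io.read_plink(config.bfile,
                                         cm_per_mb=config.cm_per_mb)
        for ext in (".bed", ".bim", ".fam"):
            manifest["inputs"][config.bfile + ext] = _checksum(
                Path(config.bfile).with_suffix(ext))
        if config.pheno:
            samples = io.attach_metadata(samples,
                                         io.read_metadata(config.pheno))
        H = None
        if config.haps and config.sample:
            H, hmap, _ = io.read_haplotypes(config.haps, config.sample,
                                            cm_per_mb=config.cm_per_mb)
        truth = None
    else:
        sim_kwargs = dict(config.sim)
        sweeps = [simdata.SweepSpec(**s)
                  for s in sim_kwargs.pop("sweep_specs", [])]
        cfg = simdata.SimConfig(seed=config.seed, sweep_specs=sweeps,
                                **sim_kwargs)
        H, G, vmap, samples, truth = simdata.simulate_cohorts(cfg)
        simdata.truth_report(truth, vmap, out / "truth")
    manifest["stages"]["input"] = {"n_samples": len(samples),
                                   "n_snps": len(vmap)}

    # --- QC ---------------------------------------------------------------
    hap_order = samples["sample_id"].tolist()
    G, vmap_q, samples, report = io.qc_filter(
        G, vmap, samples,
        ibs_max=config.ibs_max, maf_min=config.maf_min,
        snp_callrate_min=config.snp_callrate_min,
        ind_callrate_min=config.ind_callrate_min,
    )
    if H is not None:
        keep_snp = vmap["snp_id"].isin(vmap_q["snp_id"]).to_numpy()
        keep_sample = [sid in set(samples["sample_id"]) for sid in hap_order]
        hap_keep = np.repeat(keep_sample, 2)
        H = H[np.ix_(hap_keep, keep_snp)]
    vmap = vmap_q
    (out / "qc_report.txt").write_text(report.summary() + "\n")
    manifest["stages"]["qc"] = {"n_samples": report.n_samples_out,
                                "n_snps": report.n_snps_out}

    if config.equal_subsample:
        G, H, samples = _equal_subsample(G, H, samples, config, rng)
        manifest["stages"]["subsample"] = {"n_samples": len(samples)}

    kept = io.ld_prune(G, vmap, config.prune_window, config.prune_step,
                       config.prune_r2)
    pd.Series(vmap["snp_id"].to_numpy()[kept]).to_csv(
        out / "pruned_snps.txt", index=False, header=False)
    manifest["stages"]["prune"] = {"n_snps": len(kept)}

    # --- diversity ---------------------------------------------------------
    het = diversity.het_stats(G)
    f_snp = diversity.inbreeding_f(G)
    roh = diversity.detect_roh(G, vmap, samples,
                               diversity.ROHParams(**config.roh))
    froh = diversity.froh(roh, samples["sample_id"],
                          config.autosome_length_bp)
    div = pd.DataFrame({
        "sample_id": samples["sample_id"],
        "cohort": samples["cohort"],
        "ho": het.per_sample_ho,
        "f": f_snp,
        "froh": froh.to_numpy(),
    })
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    roh.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
    bins = diversity.ld_decay(G, vmap, config.ld_max_dist_bp,
                              config.ld_n_bins, seed=config.seed)
    ne = diversity.ne_from_ld(bins, cm_per_mb=config.cm_per_mb)
    ne.to_csv(out / "ld_ne.tsv", sep="\t", index=False)
    manifest["stages"]["diversity"] = {
        "mean_ho": het.mean_ho, "mean_he": het.mean_he,
        "n_roh": len(roh),
    }

    # --- structure ---------------------------------------------------------
    pca_res = structure.pca(G[:, kept], n_components=config.n_pcs)
    pd.DataFrame(
        pca_res.scores,
        columns=[f"PC{i+1}" for i in range(pca_res.scores.shape[1])],
    ).assign(sample_id=samples["sample_id"].to_numpy()).to_csv(
        out / "pca_scores.tsv", sep="\t", index=False)
    cv = structure.admixture_cv(
        G[:, kept], config.admixture_k_values,
        n_replicates=config.admixture_replicates, seed=config.seed)
    pd.DataFrame(
        [(k, e) for k, errs in cv.cv_errors.items() for e in errs],
        columns=["K", "cv_error"],
    ).to_csv(out / "admixture_cv.tsv", sep="\t", index=False)
    manifest["stages"]["structure"] = {
        "pc1_fraction": float(pca_res.explained_fraction[0]),
        "best_K": cv.best_K,
    }

    # --- scans --------------------------------------------------------------
    case, ctrl = config.case_label, config.control_label
    cohorts = samples["cohort"].to_numpy()
    case_ids = samples.loc[cohorts == case, "sample_id"]
    ctrl_ids = samples.loc[cohorts == ctrl, "sample_id"]

    freq_case = scans.roh_snp_frequency(roh, vmap, case_ids)
    freq_ctrl = scans.roh_snp_frequency(roh, vmap, ctrl_ids)
    islands_case = scans.roh_islands(freq_case, vmap,
                                     config.roh_island_threshold, "ROH_HR")
    islands_ctrl = scans.roh_islands(freq_ctrl, vmap,
                                     config.roh_island_threshold, "ROH_LR")
    roh_specific = scans.cohort_specific_islands(islands_case, islands_ctrl)

    labels = np.where(cohorts == case, case, ctrl)
    in_study = np.isin(cohorts, [case, ctrl])
    comp = scans.wc_fst_per_snp(G[in_study], labels[in_study])
    windows = scans.fst_windows(comp, vmap, config.fst_window_bp,
                                config.fst_step_bp, config.fst_min_snps)
    windows, fst_regions = scans.fst_candidates(windows,
                                                config.fst_tail_mass)
    windows.to_csv(out / "fst_windows.tsv", sep="\t", index=False)

    xp_regions: list = []
    if H is not None:
        case_rows = np.repeat(cohorts == case, 2)
        ctrl_rows = np.repeat(cohorts == ctrl, 2)
        xp = scans.xpehh_scan(H[case_rows], H[ctrl_rows], vmap,
                              config.xpehh_ehh_cutoff,
                              config.xpehh_max_gap_bp)
        xp.to_csv(out / "xpehh.tsv", sep="\t", index=False)
        xp_regions = scans.xpehh_candidates(xp, config.xpehh_p_max,
                                            config.xpehh_cluster_radius_bp)

    if config.gwas_test == "fisher":
        gwas = scans.fisher_allelic(G, samples, vmap, case, ctrl)
    else:
        gwas = scans.logistic_gwas(G, samples, vmap, case, ctrl)
    gwas.to_csv(out / "gwas.tsv", sep="\t", index=False)
    gwas_regions = scans.gwas_candidates(
        gwas, alpha=config.gwas_alpha,
        neglog10_min=config.gwas_neglog10_min,
        window_bp=config.gwas_window_bp)

    per_method = {
        "ROH_HR": roh_specific, "FST": fst_regions,
        "XPEHH": xp_regions, "LRGWAS": gwas_regions,
    }
    for method, regions in per_method.items():
        scans.regions_to_frame(regions).to_csv(
            out / f"candidates_{method.lower()}.tsv", sep="\t", index=False)
    manifest["stages"]["scans"] = {
        m: len(r) for m, r in per_method.items()
    }

    # --- consensus ----------------------------------------------------------
    regions = cons.consensus_regions(per_method, config.min_methods)
    table = cons.consensus_table(regions, gwas)
    table.to_csv(out / "consensus.tsv", sep="\t", index=False)
    cons.to_bed(regions, out / "consensus.bed")
    manifest["stages"]["consensus"] = {"n_regions": len(regions)}

    # --- annotation ---------------------------------------------------------
    if config.annotation:
        genes = ann.read_annotation(config.annotation)
        gene_rows = []
        region_genes = set()
        for i, r in enumerate(regions, 1):
            hits = ann.genes_in_region(r, genes)
            region_genes.update(hits["gene_id"])
            for g in hits.itertuples():
                gene_rows.append({"region": i, "gene_id": g.gene_id,
                                  "name": g.name})
        pd.DataFrame(gene_rows, columns=["region", "gene_id", "name"]).to_csv(
            out / "region_genes.tsv", sep="\t", index=False)
        manifest["stages"]["annotation"] = {"n_genes": len(region_genes)}
        if config.terms:
            enr = ann.hypergeometric_enrichment(
                region_genes, ann.read_term_map(config.terms),
                genes["gene_id"])
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrichment"] = {"n_terms": len(enr)}
    else:
        manifest["stages"]["annotation"] = {"skipped": True}

    # Manhattan exports
    chrom_lengths = vmap.groupby("chrom", sort=False)["bp"].max().to_dict()
    manhattan_export(
        pd.DataFrame({"chrom": vmap["chrom"], "bp": vmap["bp"],
                      "value": freq_case}),
        chrom_lengths, out / "manhattan_roh.tsv",
        thresholds={"island": config.roh_island_threshold})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    config.to_yaml(out / "config.yaml")
    return manifest


def _equal_subsample(G, H, samples, config, rng):
    """Seeded equal-size cohort down-sampling (the larger cohort is reduced
    to the smaller one's size)."""
    cohorts = samples["cohort"].to_numpy()
    sizes = {lab: int((cohorts == lab).sum())
             for lab in (config.case_label, config.control_label)}
    target = min(sizes.values())
    keep = np.ones(len(samples), dtype=bool)
    for lab, size in sizes.items():
        if size > target:
            idx = np.flatnonzero(cohorts == lab)
            drop = rng.choice(idx, size=size - target, replace=False)
            keep[drop] = False
    G = G[keep]
    if H is not None:
        H = H[np.repeat(keep, 2)]
    samples = samples.loc[keep].reset_index(drop=True)
    log.info("equal subsampling: cohorts reduced to %d each", target)
    return G, H, samples


def manhattan_export(values: pd.DataFrame, chrom_lengths: dict,
                     path, thresholds: dict | None = None) -> None:
    """Write (chrom, bp, cumulative_bp, value) plot data plus threshold rows.

    ``values`` needs columns chrom, bp, value; the cumulative coordinate is
    bp plus the summed lengths of all preceding chromosomes (in the order
    given by ``chrom_lengths``).
    """
    offsets = {}
    total = 0
    for chrom, length in chrom_lengths.items():
        offsets[str(chrom)] = total
        total += int(length)
    df = values.copy()
    df["cumulative_bp"] = [
        int(bp) + offsets[str(c)] for c, bp in zip(df["chrom"], df["bp"])
    ]
    df = df[["chrom", "bp", "cumulative_bp", "value"]]
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        for name, level in (thresholds or {}).items():
            fh.write(f"# threshold\t{name}\t{level}\n")
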