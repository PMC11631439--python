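"""End-to-end orchestration: filter → zygosity/ploidy → CNV → diversity →
rarefaction → structure, with files on disk between stages and a JSON +
text report of the headline numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

import popsaturate
from popsaturate import cnv_aneuploidy as cnv
from popsaturate import diversity_stats as div
from popsaturate import population_structure as structure
from popsaturate import rarefaction_saturation as raref
from popsaturate import variant_io_filter as vio
from popsaturate import zygosity_ploidy as zp


@dataclass
class RunConfig:
    vcf: str
    out_dir: str
    depth_dir: Optional[str] = None
    cds_bed: Optional[str] = None
    chrom_lengths: Optional[str] = None
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: [
            "filter", "zygosity_ploidy", "cnv", "diversity", "rarefaction", "structure",
        ]
    )
    filter_config: vio.FilterConfig = field(default_factory=vio.FilterConfig)
    ploidy_criterion: str = "r2"
    ploidy_min_sites: int = 100
    # het-SNP count above which a sample is heterozygous; 500 matches a
    # ~12-Mb genome with ~9.4M callable sites — scale it for smaller genomes
    het_snp_threshold: int = 500
    cnv_delta: float = 0.25
    cnv_min_windows: int = 2
    pi_window: int = 10_000
    pi_step: int = 1_000
    n_pairs: Optional[int] = 2_000
    rarefaction_points: int = 50
    structure_k: int = 4
    maf_min: float = 0.05
    ld_window: int = 50
    ld_r2_max: float = 0.5
    ancestry_threshold: float = 0.60
    superclades: dict[str, list[int]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fc = raw.pop("filter_config", None)
        cfg = cls(**raw)
        if fc:
            cfg.filter_config = vio.FilterConfig(**fc)
        return cfg

    def validate(self) -> None:
        if not Path(self.vcf).exists():
            raise FileNotFoundError(self.vcf)
        for p in (self.depth_dir, self.cds_bed, self.chrom_lengths):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def digest(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _provenance(cfg: RunConfig) -> dict:
    return {"tool": f"popsaturate {popsaturate.__version__}",
            "config_hash": cfg.digest(), "seed": cfg.seed}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; returns the report dict.

    Each stage writes its tables under ``out_dir`` and the report aggregates
    the headline numbers. A stage failure raises with the stage named;
    outputs of completed stages remain on disk.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(cfg), "stages": {}}
    state: dict = {}
    for stage in cfg.stages:
        fn = _STAGES.get(stage)
        if fn is None:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            fn(cfg, out, state, report)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    with open(out / "report.txt", "w") as fh:
        fh.write(_human_report(report))
    return report


def _stage_filter(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    sites = list(vio.read_multisample_vcf(cfg.vcf))
    matrix, ledger, excluded, miss_report = vio.filter_matrix(sites, cfg.filter_config)
    state.update(matrix=matrix, ledger=ledger)
    ledger.to_frame().to_csv(out / "callable_ledger.tsv", sep="\t", index=False)
    miss_report.to_csv(out / "sample_missingness.tsv", sep="\t", index=False)
    report["stages"]["filter"] = {
        "n_samples": matrix.n_samples,
        "n_excluded_samples": len(excluded),
        "n_snp_loci": matrix.n_loci,
        "callable_total": ledger.total,
        "snp_pct_of_callable": 100 * matrix.n_loci / ledger.total,
    }


def _stage_zygosity_ploidy(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    matrix: vio.GenotypeMatrix = state["matrix"]
    ledger: vio.CallableSiteLedger = state["ledger"]
    sites = list(vio.read_multisample_vcf(cfg.vcf))
    rows = []
    het_fracs, ploidies_for_corr = [], []
    for i, s in enumerate(matrix.samples):
        n_het = zp.count_het_snps(matrix, s)
        zyg = zp.classify_zygosity(n_het, ledger.total, sample=s,
                                   threshold=cfg.het_snp_threshold)
        ref_d, alt_d = _sample_allelic_depths(sites, s, matrix)
        bfs = zp.extract_base_frequencies(ref_d, alt_d, sample=s)
        call = zp.call_ploidy(bfs, criterion=cfg.ploidy_criterion,
                              n_min=cfg.ploidy_min_sites, zygosity=zyg.zygosity,
                              seed=cfg.seed)
        rows.append({
            "sample": s, "n_het": n_het, "het_fraction": zyg.het_fraction,
            "zygosity": zyg.zygosity, "ploidy": call.ploidy,
            "criterion": call.criterion, "n_sites": call.n_sites,
        })
        if call.ploidy != "unknown":
            het_fracs.append(zyg.het_fraction)
            ploidies_for_corr.append(call.ploidy)
    df = pd.DataFrame(rows)
    df.to_csv(out / "zygosity_ploidy.tsv", sep="\t", index=False)
    state["zygosity"] = df
    stage = {
        "n_heterozygous": int((df["zygosity"] == "heterozygous").sum()),
        "n_homozygous": int((df["zygosity"] == "homozygous").sum()),
        "pct_homozygous": 100 * float((df["zygosity"] == "homozygous").mean()),
        "ploidy_counts": df["ploidy"].astype(str).value_counts().to_dict(),
    }
    if len(set(ploidies_for_corr)) > 1 and len(het_fracs) >= 3:
        rc = div.rank_correlation(ploidies_for_corr, het_fracs)
        stage["ploidy_het_spearman_rho"] = rc.rho
    report["stages"]["zygosity_ploidy"] = stage


def _sample_allelic_depths(sites, sample: str, matrix: vio.GenotypeMatrix):
    ref_d, alt_d = [], []
    for site in sites:
        if site.locus_class != "snp" or len(site.alts) != 1:
            continue
        names = getattr(site, "sample_names", None)
        if names is None or sample not in names:
            continue
        i = names.index(sample)
        gt, ad = site.genotypes[i], site.ad[i]
        if gt is None or ad is None or len(ad) < 2:
            continue
        if len(set(a for a in gt if a >= 0)) >= 2:  # heterozygous call
            ref_d.append(ad[0])
            alt_d.append(ad[1])
    return ref_d, alt_d


def _stage_cnv(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    if cfg.depth_dir is None or cfg.chrom_lengths is None:
        report["stages"]["cnv"] = {"skipped": "no depth inputs"}
        return
    lengths = cnv.read_chrom_lengths(cfg.chrom_lengths)
    cds = cnv.read_cds_bed(cfg.cds_bed) if cfg.cds_bed else None
    region_rows, gene_rows, aneu_rows = [], [], []
    for bed in sorted(Path(cfg.depth_dir).glob("*.depth.bed")):
        sample = bed.name.replace(".depth.bed", "")
        prof = cnv.read_depth_bed(str(bed), sample=sample)
        prof.chrom_lengths = lengths
        track = cnv.normalize_depth(prof)
        regions = cnv.segment_cnv(track, delta=cfg.cnv_delta,
                                  min_windows=cfg.cnv_min_windows)
        for r in regions:
            region_rows.append((sample, r.chrom, r.start, r.end, r.rd))
        if cds is not None:
            for rec in cnv.cds_median_rd(cds, regions, lengths, sample=sample):
                gene_rows.append((rec.gene, rec.sample, rec.median_rd))
        for call in cnv.call_aneuploidy(regions, lengths, sample=sample):
            aneu_rows.append((call.sample, call.chrom, call.cnv_fraction, call.aneuploid))
    pd.DataFrame(region_rows, columns=["sample", "chrom", "start", "end", "rd"]).to_csv(
        out / "cnv_regions.bed", sep="\t", index=False)
    if gene_rows:
        pd.DataFrame(gene_rows, columns=["gene", "sample", "median_rd"]).to_csv(
            out / "gene_cnv.tsv", sep="\t", index=False)
    aneu = pd.DataFrame(aneu_rows, columns=["sample", "chrom", "cnv_fraction", "aneuploid"])
    aneu.to_csv(out / "aneuploidy.tsv", sep="\t", index=False)
    state["aneuploidy"] = aneu
    n_samples = aneu["sample"].nunique() if len(aneu) else 0
    n_aneu = aneu[aneu["aneuploid"]]["sample"].nunique() if len(aneu) else 0
    report["stages"]["cnv"] = {
        "n_samples": n_samples,
        "n_aneuploid_samples": n_aneu,
        "pct_aneuploid_samples": 100 * n_aneu / n_samples if n_samples else 0.0,
    }


def _stage_diversity(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    matrix: vio.GenotypeMatrix = state["matrix"]
    ledger: vio.CallableSiteLedger = state["ledger"]
    summary = div.pairwise_distribution(matrix, cfg.n_pairs, cfg.seed, ledger.total)
    pd.DataFrame({"snp_count": summary.counts}).to_csv(
        out / "pairwise_counts.tsv", sep="\t", index=False)
    track = div.windowed_pi(matrix, ledger, window=cfg.pi_window, step=cfg.pi_step)
    track.windows.to_csv(out / "pi_windows.tsv", sep="\t", index=False)
    report["stages"]["diversity"] = {
        "pairwise_mean": summary.mean,
        "pairwise_sd": summary.sd,
        "pairwise_max": summary.max,
        "pairwise_mean_pct_of_callable": 100 * summary.as_fraction(summary.mean),
        "pairwise_max_pct_of_callable": 100 * summary.as_fraction(summary.max),
        "median_pi": track.median_pi,
    }


def _stage_rarefaction(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    matrix: vio.GenotypeMatrix = state["matrix"]
    counts = raref.carrier_counts(matrix)
    curve_all = raref.rarefaction_curve(counts, 1, n_points=cfg.rarefaction_points)
    curve_ns = raref.rarefaction_curve(counts, 2, n_points=cfg.rarefaction_points)
    pd.DataFrame({
        "n": curve_all.n_grid, "y_all": curve_all.y, "y_nonsingleton": curve_ns.y,
    }).to_csv(out / "rarefaction.tsv", sep="\t", index=False)
    pl = raref.fit_power_law(curve_all, seed=cfg.seed)
    mm = raref.fit_michaelis_menten(curve_ns, seed=cfg.seed)
    cov = raref.coverage_fraction(mm, counts=counts)
    fits = {
        "power_law": {**pl.params, "rss": pl.rss},
        "michaelis_menten": {**mm.params, "rss": mm.rss, "asymptote": mm.asymptote},
        "coverage_fraction_pct": 100 * cov.fraction,
        "observed_non_singletons": counts.non_singletons,
        "total_variants": counts.total_variants,
    }
    with open(out / "saturation_fits.json", "w") as fh:
        json.dump(fits, fh, indent=2, default=float)
    report["stages"]["rarefaction"] = fits
    state["carrier_counts"] = counts


def _stage_structure(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    matrix: vio.GenotypeMatrix = state["matrix"]
    pruned = structure.filter_biallelic_maf(matrix, cfg.maf_min)
    pruned = structure.ld_prune(pruned, window=cfg.ld_window, r2_max=cfg.ld_r2_max)
    dm = structure.ibs_distance(pruned)
    tree = structure.neighbor_joining(dm)
    (out / "nj_tree.nwk").write_text(tree.to_newick() + "\n")
    anc = structure.admixture_em(pruned, cfg.structure_k, seed=cfg.seed)
    qdf = pd.DataFrame(anc.Q, columns=[f"q_{k}" for k in range(anc.K)])
    qdf.insert(0, "sample", anc.samples)
    qdf.to_csv(out / "ancestry_Q.tsv", sep="\t", index=False)
    assignments = structure.assign_clades(anc, cfg.ancestry_threshold)
    if cfg.superclades:
        assignments = structure.group_superclades(assignments, cfg.superclades)
    adf = pd.DataFrame([
        {"sample": a.sample, "component": a.component, "max_q": a.max_ancestry,
         "superclade": a.superclade} for a in assignments
    ])
    adf.to_csv(out / "clade_assignments.tsv", sep="\t", index=False)
    sizes = adf["component"].value_counts(dropna=True).to_dict()
    report["stages"]["structure"] = {
        "n_markers": pruned.n_loci,
        "K": anc.K,
        "loglik": anc.loglik,
        "n_assigned": int(adf["component"].notna().sum()),
        "n_admixed_unassigned": int(adf["component"].isna().sum()),
        "clade_sizes": {str(k): int(v) for k, v in sizes.items()},
    }


_STAGES = {
    "filter": _stage_filter,
    "zygosity_ploidy": _stage_zygosity_ploidy,
    "cnv": _stage_cnv,
    "diversity": _stage_diversity,
    "rarefaction": _stage_rarefaction,
    "structure": _stage_structure,
}


def _human_report(report: dict) -> str:
    lines = [f"popsaturate report ({report['provenance']['tool']}, "
             f"seed {report['provenance']['seed']}, "
             f"config {report['provenance']['config_hash']})"]
    for stage, vals in report["stages"].items():
        lines.append(f"\n[{stage}]")
        for k, v in vals.items():
            if isinstance(v, float):
                lines.append(f"  {k} = {v:.6g}")
            else:
                lines.append(f"  {k} = {v}")
    return "\n".join(lines) + "\n"
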