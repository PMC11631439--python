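"""Clade-structured synthetic populations with full truth records.

The generator emulates the data shape of a large yeast isolate survey:
K divergent clades whose allele frequencies follow a Balding–Nichols model
around ancestral frequencies, admixed individuals with Dirichlet ancestry,
mixed ploidy (1n–4n), inbred (homozygous) and outbred heterozygosity
regimes, CNV segments and whole-chromosome aneuploidies expressed in
negative-binomial read depth, and binomial allelic read counts at
heterozygous sites. Every draw is reproducible from the seed and every
latent variable is recorded in machine-readable truth tables, so each
pipeline stage can be scored against ground truth.

Defaults aim at a realistic toy scale: a 3.4-Mb four-chromosome genome,
3,000 SNP loci, ~100 isolates with the survey's ploidy mix (74% diploid,
20% polyploid, 6% haploid), 42% homozygous isolates, and 30x coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from popsaturate.cnv_aneuploidy import WINDOW_SIZE, DepthProfile
from popsaturate.variant_io_filter import MISSING, GenotypeMatrix
from popsaturate.zygosity_ploidy import BaseFrequencySample

DEFAULT_CHROMS = {
    "chrI": 1_500_000,
    "chrII": 1_000_000,
    "chrIII": 600_000,
    "chrIV": 300_000,
}


@dataclass
class SimConfig:
    seed: int = 0
    n_clades: int = 4
    samples_per_clade: int = 22
    n_admixed: int = 12
    n_loci: int = 3000
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROMS))
    ancestral_beta: tuple[float, float] = (0.5, 0.5)
    divergence_f: float = 0.15  # Balding–Nichols F between clades
    ploidy_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.06, 2: 0.74, 3: 0.12, 4: 0.08}
    )
    homozygous_fraction: float = 0.42
    missing_rate: float = 0.01
    mean_coverage: float = 30.0
    read_length: int = 100  # depth noise scale: a 1-kb window averages ~10x this many reads
    nb_dispersion: float = 500.0  # NB size r for per-window read counts
    aneuploidy_rate: float = 0.30  # per-sample chance of one aneuploid chromosome
    cnv_rate: float = 0.30  # per-sample chance of one interstitial CNV segment
    cnv_span_kb: tuple[int, int] = (20, 80)
    n_cds: int = 60
    admix_alpha: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.divergence_f < 1:
            raise ValueError("divergence_f must lie in (0, 1)")
        if any(p not in (1, 2, 3, 4) for p in self.ploidy_weights):
            raise ValueError("ploidies restricted to 1..4")

    @property
    def n_samples(self) -> int:
        return self.n_clades * self.samples_per_clade + self.n_admixed

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass
class TruthTables:
    samples: pd.DataFrame  # sample, clade, ploidy, inbred + q_0..q_{K-1}
    clade_frequencies: np.ndarray  # K x loci
    ancestral_frequencies: np.ndarray
    cnv_truth: pd.DataFrame  # sample, chrom, start, end, copy_ratio, whole_chrom
    total_variants: int = 0
    non_singleton_variants: int = 0


# ---------------------------------------------------------------------------
# latent draws
# ---------------------------------------------------------------------------


def simulate_frequencies(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Ancestral p_l and Balding–Nichols clade frequencies f_kl.

    f_kl ~ Beta(p_l(1−F)/F, (1−p_l)(1−F)/F), so E[f|p] = p and
    Var[f|p] = F·p(1−p).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    a, b = cfg.ancestral_beta
    p = rng.beta(a, b, size=cfg.n_loci)
    p = np.clip(p, 0.01, 0.99)
    F = cfg.divergence_f
    alpha = p * (1 - F) / F
    beta = (1 - p) * (1 - F) / F
    f = rng.beta(alpha[None, :], beta[None, :], size=(cfg.n_clades, cfg.n_loci))
    return p, np.clip(f, 1e-4, 1 - 1e-4)


def _locus_positions(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = list(cfg.chrom_lengths)
    lens = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(cfg.n_loci * lens / lens.sum()).astype(int)
    alloc[0] += cfg.n_loci - alloc.sum()
    rows = []
    bases = np.array(list("ACGT"))
    for c, n in zip(chroms, alloc):
        pos = np.sort(rng.choice(np.arange(100, cfg.chrom_lengths[c] - 100), size=n,
                                 replace=False))
        for pp in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append((c, int(pp), bases[ref], bases[alt]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def simulate_genotypes(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[GenotypeMatrix, TruthTables]:
    """Draw the full population: ancestry, ploidy, regime, dosage matrix."""
    rng = rng or np.random.default_rng(cfg.seed)
    p_anc, f = simulate_frequencies(cfg, rng)
    K, L, n = cfg.n_clades, cfg.n_loci, cfg.n_samples

    Q = np.zeros((n, K))
    clade = np.full(n, -1)
    for k in range(K):
        sl = slice(k * cfg.samples_per_clade, (k + 1) * cfg.samples_per_clade)
        Q[sl, k] = 1.0
        clade[sl] = k
    if cfg.n_admixed:
        Q[K * cfg.samples_per_clade :] = rng.dirichlet(
            np.full(K, cfg.admix_alpha), size=cfg.n_admixed
        )

    ploidies = np.array(sorted(cfg.ploidy_weights))
    w = np.array([cfg.ploidy_weights[p] for p in ploidies], dtype=float)
    ploidy = rng.choice(ploidies, size=n, p=w / w.sum()).astype(np.int16)
    inbred = rng.random(n) < cfg.homozygous_fraction
    inbred[ploidy == 1] = True  # a haploid is homozygous by construction

    pi = Q @ f  # n x L per-copy alt probability
    dosage = np.empty((n, L), dtype=np.int16)
    for i in range(n):
        m = int(ploidy[i])
        if inbred[i]:
            dosage[i] = (m * (rng.random(L) < pi[i])).astype(np.int16)
        else:
            dosage[i] = rng.binomial(m, pi[i]).astype(np.int16)
    if cfg.missing_rate > 0:
        mask = rng.random((n, L)) < cfg.missing_rate
        dosage[mask] = MISSING

    loci = _locus_positions(cfg, rng)
    samples = [f"iso{i:04d}" for i in range(n)]
    matrix = GenotypeMatrix(samples=samples, loci=loci, dosage=dosage, ploidy=ploidy)

    cnv_truth = _simulate_cnv_truth(cfg, samples, rng)
    carriers = np.sum((dosage != MISSING) & (dosage >= 1), axis=0)
    sdf = pd.DataFrame(
        {"sample": samples, "clade": clade, "ploidy": ploidy, "inbred": inbred}
    )
    for k in range(K):
        sdf[f"q_{k}"] = Q[:, k]
    truth = TruthTables(
        samples=sdf,
        clade_frequencies=f,
        ancestral_frequencies=p_anc,
        cnv_truth=cnv_truth,
        total_variants=int(np.sum(carriers >= 1)),
        non_singleton_variants=int(np.sum(carriers >= 2)),
    )
    return matrix, truth


def _simulate_cnv_truth(
    cfg: SimConfig, samples: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Aneuploid chromosomes (short-chromosome-biased) and interstitial CNVs."""
    chroms = list(cfg.chrom_lengths)
    inv_len = np.array([1 / cfg.chrom_lengths[c] for c in chroms])
    rows = []
    for s in samples:
        if rng.random() < cfg.aneuploidy_rate:
            c = chroms[rng.choice(len(chroms), p=inv_len / inv_len.sum())]
            ratio = float(rng.choice([1.5, 2.0, 0.5], p=[0.6, 0.2, 0.2]))
            rows.append((s, c, 0, cfg.chrom_lengths[c], ratio, True))
        if rng.random() < cfg.cnv_rate:
            c = chroms[rng.integers(len(chroms))]
            span = int(rng.integers(cfg.cnv_span_kb[0], cfg.cnv_span_kb[1] + 1)) * 1000
            clen = cfg.chrom_lengths[c]
            start = int(rng.integers(0, max((clen - span) // 1000, 1))) * 1000
            ratio = float(rng.choice([0.5, 1.5, 2.0]))
            rows.append((s, c, start, start + span, ratio, False))
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "copy_ratio", "whole_chrom"]
    )


def simulate_depth(
    cfg: SimConfig, truth: TruthTables, rng: Optional[np.random.Generator] = None
) -> dict[str, DepthProfile]:
    """Per-sample 1-kb window depth.

    The window's READ COUNT is drawn NegBin(mean = coverage × copy ratio ×
    window/read_length, size = nb_dispersion) and converted back to mean
    depth; a window thus aggregates ~coverage×10 reads, giving the ~5–10%
    per-window coefficient of variation seen in real short-read coverage
    rather than the ~25%+ a single NB depth draw would imply.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    r = cfg.nb_dispersion
    reads_per_x = WINDOW_SIZE / cfg.read_length  # reads per 1x coverage per window
    profiles: dict[str, DepthProfile] = {}
    for s in truth.samples["sample"]:
        rows = truth.cnv_truth[truth.cnv_truth["sample"] == s]
        depths: dict[str, np.ndarray] = {}
        for c, clen in cfg.chrom_lengths.items():
            nwin = -(-clen // WINDOW_SIZE)
            ratio = np.ones(nwin)
            for _, ev in rows[rows["chrom"] == c].iterrows():
                w0 = int(ev["start"]) // WINDOW_SIZE
                w1 = -(-int(ev["end"]) // WINDOW_SIZE)
                ratio[w0:w1] = ev["copy_ratio"]
            mean_reads = cfg.mean_coverage * ratio * reads_per_x
            counts = rng.negative_binomial(r, r / (r + mean_reads)).astype(float)
            depths[c] = counts / reads_per_x
        profiles[s] = DepthProfile(sample=s, depths=depths,
                                   chrom_lengths=dict(cfg.chrom_lengths))
    return profiles


def simulate_allele_fractions(
    cfg: SimConfig,
    matrix: GenotypeMatrix,
    rng: Optional[np.random.Generator] = None,
    coverage: Optional[float] = None,
) -> dict[str, BaseFrequencySample]:
    """Binomial alt-read counts at heterozygous sites, per sample."""
    rng = rng or np.random.default_rng(cfg.seed + 2)
    cov_mean = coverage if coverage is not None else cfg.mean_coverage
    out: dict[str, BaseFrequencySample] = {}
    for i, s in enumerate(matrix.samples):
        m = int(matrix.effective_ploidy()[i])
        d = matrix.dosage[i]
        het = (d != MISSING) & (d > 0) & (d < m)
        cov = rng.poisson(cov_mean, size=int(het.sum())).clip(min=1)
        alt = rng.binomial(cov, d[het] / m)
        frac = alt / cov
        keep = (frac > 0) & (frac < 1)
        out[s] = BaseFrequencySample(s, frac[keep], cov[keep].astype(float))
    return out


def simulate_het_fractions(
    ploidy: int,
    n_sites: int,
    coverage: float,
    rng: np.random.Generator,
    dosage_weights: Optional[np.ndarray] = None,
) -> BaseFrequencySample:
    """Allelic fractions for one synthetic sample of known ploidy.

    Each het site gets a dosage d in 1..ploidy−1 (uniform by default) and
    alt reads ~ Binomial(cov, d/ploidy), cov ~ Poisson(coverage). Used by
    the ploidy-criterion benchmark.
    """
    if ploidy < 2:
        raise ValueError("het fractions need ploidy >= 2")
    d_vals = np.arange(1, ploidy)
    wts = dosage_weights if dosage_weights is not None else np.full(len(d_vals), 1 / len(d_vals))
    d = rng.choice(d_vals, size=n_sites, p=wts / wts.sum())
    cov = rng.poisson(coverage, size=n_sites).clip(min=1)
    alt = rng.binomial(cov, d / ploidy)
    frac = alt / cov
    keep = (frac > 0) & (frac < 1)
    return BaseFrequencySample(f"sim_{ploidy}n", frac[keep], cov[keep].astype(float))


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def _gt_string(dose: int, ploidy: int) -> str:
    if dose == MISSING:
        return "/".join(["."] * ploidy)
    return "/".join(["0"] * (ploidy - dose) + ["1"] * dose)


def write_outputs(
    cfg: SimConfig,
    out_dir: str,
    matrix: Optional[GenotypeMatrix] = None,
    truth: Optional[TruthTables] = None,
) -> dict[str, Path]:
    """Emit VCF (GT/DP/GQ/AD, gVCF-style invariant blocks), depth BEDs, CDS
    BED, chromosome lengths, and truth tables. Deterministic given cfg.seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    if matrix is None or truth is None:
        matrix, truth = simulate_genotypes(cfg, rng)
    paths: dict[str, Path] = {}

    # --- VCF -------------------------------------------------------------
    ad_rng = np.random.default_rng(cfg.seed + 3)
    vcf_path = out / "population.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=popsaturate-simulate(seed={cfg.seed})\n")
        for c, ln in cfg.chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="Block end">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        plo = matrix.effective_ploidy()
        dp_inv = int(cfg.mean_coverage)
        gq_inv = min(99, 3 * dp_inv)
        for chrom in cfg.chrom_lengths:
            sub = matrix.loci[matrix.loci["chrom"] == chrom]
            order = sub["pos"].to_numpy().argsort()
            idx = sub.index.to_numpy()[order]
            prev_end = 0
            for j in idx:
                pos = int(matrix.loci.at[j, "pos"])
                if pos > prev_end + 1:
                    inv = "\t".join(
                        f"{_gt_string(0, int(p))}:{dp_inv}:{gq_inv}" for p in plo
                    )
                    fh.write(
                        f"{chrom}\t{prev_end + 1}\t.\tA\t.\t.\t.\tEND={pos - 1}\t"
                        f"GT:DP:GQ\t{inv}\n"
                    )
                ref = matrix.loci.at[j, "ref"]
                alt = matrix.loci.at[j, "alt"]
                cells = []
                for i in range(matrix.n_samples):
                    d = int(matrix.dosage[i, j])
                    m = int(plo[i])
                    if d == MISSING:
                        cells.append(f"{_gt_string(MISSING, m)}:.:.:.")
                        continue
                    cov = max(int(ad_rng.poisson(cfg.mean_coverage)), 4)
                    alt_reads = int(ad_rng.binomial(cov, d / m)) if 0 < d < m else (
                        cov if d == m else 0
                    )
                    dp = cov
                    gq = min(99, 3 * dp)
                    cells.append(
                        f"{_gt_string(d, m)}:{dp}:{gq}:{cov - alt_reads},{alt_reads}"
                    )
                fh.write(
                    f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT:DP:GQ:AD\t"
                    + "\t".join(cells)
                    + "\n"
                )
                prev_end = pos
            clen = cfg.chrom_lengths[chrom]
            if prev_end < clen:
                inv = "\t".join(f"{_gt_string(0, int(p))}:{dp_inv}:{gq_inv}" for p in plo)
                fh.write(
                    f"{chrom}\t{prev_end + 1}\t.\tA\t.\t.\t.\tEND={clen}\tGT:DP:GQ\t{inv}\n"
                )
    paths["vcf"] = vcf_path

    # --- depth, CDS, lengths, truth --------------------------------------
    depth_dir = out / "depth"
    depth_dir.mkdir(exist_ok=True)
    profiles = simulate_depth(cfg, truth)
    for s, prof in profiles.items():
        rows = []
        for c, dvec in prof.depths.items():
            clen = prof.chrom_lengths[c]
            for w, depth in enumerate(dvec):
                rows.append((c, w * WINDOW_SIZE, min((w + 1) * WINDOW_SIZE, clen), depth))
        pd.DataFrame(rows).to_csv(depth_dir / f"{s}.depth.bed", sep="\t",
                                  header=False, index=False)
    paths["depth_dir"] = depth_dir

    cds = _simulate_cds(cfg, rng)
    cds_path = out / "cds.bed"
    cds.to_csv(cds_path, sep="\t", header=False, index=False)
    paths["cds"] = cds_path

    len_path = out / "chrom_lengths.tsv"
    pd.DataFrame(cfg.chrom_lengths.items()).to_csv(len_path, sep="\t",
                                                   header=False, index=False)
    paths["chrom_lengths"] = len_path

    truth.samples.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
    truth.cnv_truth.to_csv(out / "truth_cnv.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "total_variants": [truth.total_variants],
            "non_singleton_variants": [truth.non_singleton_variants],
        }
    ).to_csv(out / "truth_totals.tsv", sep="\t", index=False)
    paths["truth_samples"] = out / "truth_samples.tsv"
    paths["truth_cnv"] = out / "truth_cnv.tsv"
    paths["truth_totals"] = out / "truth_totals.tsv"
    return paths


def _simulate_cds(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = list(cfg.chrom_lengths)
    lens = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(cfg.n_cds * lens / lens.sum()).astype(int)
    alloc[0] += cfg.n_cds - alloc.sum()
    rows = []
    g = 0
    for c, ncds in zip(chroms, alloc):
        clen = cfg.chrom_lengths[c]
        for _ in range(ncds):
            span = int(rng.integers(500, 3000))
            start = int(rng.integers(0, max(clen - span, 1)))
            rows.append((c, start, start + span, f"gene{g:04d}"))
            g += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).sort_values(
        ["chrom", "start"]
    )
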