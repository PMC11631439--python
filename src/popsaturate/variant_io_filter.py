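"""Multi-sample VCF ingestion, locus classification, and cohort filtering.

The filtering rules follow the standard population-survey recipe: per-call
quality thresholds (DP >= 10, GQ >= 20), removal of samples with >= 20%
missing genotypes, removal of sites with >= 1% missing genotypes, and an
exact heterozygote-excess test. Loci carrying both SNP-type and InDel-type
alternate alleles ("complex" loci) are excluded from every downstream
product. The callable-site ledger — non-variant positions plus retained SNP
loci — is the denominator of every rate statistic in the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

MISSING = -1  # dosage sentinel in GenotypeMatrix


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantSite:
    """One VCF record: a locus and its per-sample calls.

    ``genotypes[i]`` is a tuple of allele indices (length = call ploidy) or
    ``None`` when the call is missing. ``end`` > ``pos`` marks a gVCF-style
    non-variant block covering positions ``pos..end`` inclusive.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    genotypes: list[Optional[tuple[int, ...]]]
    dp: list[Optional[int]]
    gq: list[Optional[int]]
    ad: list[Optional[tuple[int, ...]]]
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def locus_class(self) -> str:
        return classify_locus(self)

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    def is_missing(self, i: int) -> bool:
        gt = self.genotypes[i]
        return gt is None or any(a < 0 for a in gt)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the cohort filter (defaults match the survey recipe)."""

    dp_min: int = 10
    gq_min: int = 20
    sample_missing_max: float = 0.20
    site_missing_max: float = 0.01
    exc_het_threshold: float = 0.99
    # remove_below (default) drops sites whose heterozygote-excess tail
    # probability is < 1 - exc_het_threshold, i.e. genuine het excess (the
    # artifact signature the ExcHet filter targets); remove_above instead
    # drops het-DEFICIENT sites (tail > exc_het_threshold), which would gut
    # any inbred or clade-structured cohort.
    exc_het_mode: str = "remove_below"  # remove_above | remove_below | off

    def __post_init__(self) -> None:
        if not (0 <= self.sample_missing_max <= 1 and 0 <= self.site_missing_max <= 1):
            raise ValueError("missingness fractions must lie in [0, 1]")
        if self.dp_min < 0 or self.gq_min < 0:
            raise ValueError("dp_min and gq_min must be >= 0")
        if not 0 <= self.exc_het_threshold <= 1:
            raise ValueError("exc_het_threshold must lie in [0, 1]")
        if self.exc_het_mode not in ("remove_above", "remove_below", "off"):
            raise ValueError(f"unknown exc_het_mode {self.exc_het_mode!r}")


@dataclass
class CallableSiteLedger:
    """Count (and optionally enumerate) callable positions per chromosome.

    Callable = non-variant positions plus retained SNP loci. InDel and
    complex loci never enter the ledger. ``positions`` holds sorted 1-based
    callable coordinates per chromosome when positional resolution is
    available (needed by windowed diversity); counts alone suffice for
    genome-wide rates.
    """

    counts: dict[str, int] = field(default_factory=dict)
    positions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def add(self, chrom: str, n: int) -> None:
        self.counts[chrom] = self.counts.get(chrom, 0) + int(n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": list(self.counts), "callable_count": list(self.counts.values())}
        )

    def window_callable(self, chrom: str, start: int, end: int) -> int:
        """Callable positions with 1-based coordinate in [start, end]."""
        pos = self.positions.get(chrom)
        if pos is None:
            raise ValueError(f"no positional ledger for chromosome {chrom!r}")
        lo, hi = np.searchsorted(pos, [start, end + 1])
        return int(hi - lo)


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP-loci dosage matrix.

    ``dosage[i, j]`` counts alternate-allele copies of sample i at locus j
    (0..ploidy) with ``MISSING`` (-1) for no-calls. ``ploidy`` is per sample
    (0 = unknown, treated as diploid where a copy number is required).
    """

    samples: list[str]
    loci: pd.DataFrame  # columns chrom, pos, ref, alt
    dosage: np.ndarray  # int16, samples x loci
    ploidy: np.ndarray  # int16 per sample

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise ValueError("dosage dimensions inconsistent with sample/locus lists")
        known = self.ploidy > 0
        if known.any():
            d = self.dosage[known]
            p = self.ploidy[known][:, None]
            if ((d > p) & (d != MISSING)).any():
                raise ValueError("dosage exceeds declared ploidy")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id {sample!r}") from None

    def effective_ploidy(self) -> np.ndarray:
        p = self.ploidy.astype(np.int16).copy()
        p[p <= 0] = 2
        return p


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def classify_locus(site: VariantSite) -> str:
    """invariant / snp / indel / complex per allele-length comparison."""
    if not site.ref:
        raise ValueError("empty REF allele")
    alts = [a for a in site.alts if a not in (".", "<NON_REF>", "")]
    if not alts:
        return "invariant"
    has_snp = any(len(a) == 1 and len(site.ref) == 1 for a in alts)
    has_indel = any(len(a) != len(site.ref) for a in alts)
    if has_snp and has_indel:
        return "complex"
    if has_snp:
        return "snp"
    return "indel"


def read_multisample_vcf(path: str, region: Optional[str] = None) -> Iterator[VariantSite]:
    """Stream VariantSite records from a VCF (plain or bgzipped).

    Requires GT; DP/GQ/AD are used when present. gVCF non-variant blocks
    (INFO/END) are passed through with ``end`` set.
    """
    import pysam

    vcf = pysam.VariantFile(path)
    if "GT" not in vcf.header.formats:
        raise ValueError(f"{path}: VCF lacks the mandatory GT FORMAT field")
    names = list(vcf.header.samples)
    records = vcf.fetch(region=region) if region else vcf
    for rec in records:
        genotypes: list[Optional[tuple[int, ...]]] = []
        dp: list[Optional[int]] = []
        gq: list[Optional[int]] = []
        ad: list[Optional[tuple[int, ...]]] = []
        for sample in rec.samples.values():
            gt = sample.get("GT")
            if gt is None or all(a is None for a in gt):
                genotypes.append(None)
            else:
                genotypes.append(tuple(-1 if a is None else int(a) for a in gt))
            v = sample.get("DP")
            dp.append(None if v is None else int(v))
            v = sample.get("GQ")
            gq.append(None if v is None else int(v))
            v = sample.get("AD")
            ad.append(None if v is None or v == (None,) else tuple(int(x) for x in v))
        end = rec.stop if rec.stop > rec.start + len(rec.ref) - 1 else None
        site = VariantSite(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alts=tuple(rec.alts) if rec.alts else (),
            genotypes=genotypes,
            dp=dp,
            gq=gq,
            ad=ad,
            end=end,
        )
        site.sample_names = names  # type: ignore[attr-defined]
        yield site


def apply_quality_filter(site: VariantSite, cfg: FilterConfig) -> VariantSite:
    """Set calls with DP < dp_min or GQ < gq_min (or absent tags) to missing."""
    for i in range(site.n_samples):
        if site.genotypes[i] is None:
            continue
        d, g = site.dp[i], site.gq[i]
        if d is None or g is None or d < cfg.dp_min or g < cfg.gq_min:
            site.genotypes[i] = None
    return site


def excess_het_probability(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Exact one-sided heterozygote-excess tail P(het >= n_AB | allele counts).

    Conditional (Levene–Haldane) distribution of the heterozygote count given
    the observed allele counts in n diploids; small values signal an excess
    of heterozygotes. Monomorphic sites return 1.
    """
    if min(n_AA, n_AB, n_BB) < 0 or n_AA + n_AB + n_BB < 1:
        raise ValueError("genotype counts must be non-negative with >= 1 sample")
    n = n_AA + n_AB + n_BB
    nA = 2 * n_AA + n_AB
    nB = 2 * n_BB + n_AB
    if nA == 0 or nB == 0:
        return 1.0
    # feasible het counts share parity with nA and satisfy 0 <= h <= min(nA, nB)
    h_all = np.arange(nA % 2, min(nA, nB) + 1, 2)
    logw = (
        h_all * math.log(2.0)
        - gammaln((nA - h_all) / 2 + 1)
        - gammaln(h_all + 1)
        - gammaln((nB - h_all) / 2 + 1)
    )
    logz = logsumexp(logw)
    tail = logsumexp(logw[h_all >= n_AB]) - logz
    return float(min(1.0, math.exp(tail)))


def _diploid_genotype_counts(site: VariantSite) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) over diploid biallelic calls only."""
    n_aa = n_ab = n_bb = 0
    for gt in site.genotypes:
        if gt is None or len(gt) != 2 or any(a < 0 or a > 1 for a in gt):
            continue
        s = gt[0] + gt[1]
        if s == 0:
            n_aa += 1
        elif s == 1:
            n_ab += 1
        else:
            n_bb += 1
    return n_aa, n_ab, n_bb


def _invariant_span(site: VariantSite) -> int:
    if site.end is not None and site.end >= site.pos:
        return site.end - site.pos + 1
    return 1


def _site_dosages(site: VariantSite, alt_index: int) -> np.ndarray:
    """Dosage of ``alt_index`` per sample; calls carrying other alts -> missing."""
    out = np.full(site.n_samples, MISSING, dtype=np.int16)
    for i, gt in enumerate(site.genotypes):
        if gt is None or any(a < 0 for a in gt):
            continue
        if any(a not in (0, alt_index) for a in gt):
            continue  # decomposition: calls with another alt are dropped
        out[i] = sum(1 for a in gt if a == alt_index)
    return out


def _major_alt_index(site: VariantSite) -> int:
    """1-based index of the most frequent alt among non-missing calls."""
    counts = np.zeros(len(site.alts), dtype=int)
    for gt in site.genotypes:
        if gt is None:
            continue
        for a in gt:
            if a >= 1:
                counts[a - 1] += 1
    return int(np.argmax(counts)) + 1 if counts.sum() else 1


def filter_matrix(
    sites: Iterable[VariantSite],
    cfg: FilterConfig = FilterConfig(),
    keep_positions: bool = True,
) -> tuple[GenotypeMatrix, CallableSiteLedger, list[str], pd.DataFrame]:
    """Apply the full cohort filter and build matrix + callable ledger.

    Order matters and is fixed: per-call quality masking, then sample
    exclusion (missing fraction >= sample_missing_max over variant loci),
    then site exclusion (missing fraction >= site_missing_max among retained
    samples), then the heterozygote-excess rule. Returns
    ``(matrix, ledger, excluded_samples, report)`` where ``report`` lists
    per-sample missing fractions.

    Thresholds are strict ("below 20%", "below 1%"): a fraction exactly at
    the threshold is excluded.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no sites supplied")
    n_samples = sites[0].n_samples
    if n_samples < 2:
        raise ValueError("cohort filtering requires >= 2 samples")

    variant_sites: list[VariantSite] = []
    invariant: list[VariantSite] = []
    for site in sites:
        cls = site.locus_class
        if cls == "invariant":
            invariant.append(site)
            continue
        if cls == "complex":
            continue  # complex loci leave every downstream product
        apply_quality_filter(site, cfg)
        variant_sites.append(site)

    # --- sample exclusion first (missingness over variant loci) ----------
    miss = np.zeros(n_samples, dtype=float)
    for site in variant_sites:
        for i in range(n_samples):
            if site.is_missing(i):
                miss[i] += 1
    miss /= max(len(variant_sites), 1)
    keep_mask = miss < cfg.sample_missing_max
    sample_names = _sample_names(sites[0], n_samples)
    excluded = [s for s, k in zip(sample_names, keep_mask) if not k]
    report = pd.DataFrame({"sample": sample_names, "missing_fraction": miss})
    if not keep_mask.any():
        raise ValueError(
            "all samples excluded by the missingness filter:\n" + report.to_string(index=False)
        )
    kept_idx = np.flatnonzero(keep_mask)
    kept_samples = [sample_names[i] for i in kept_idx]

    # --- site exclusion on the retained cohort ---------------------------
    retained: list[VariantSite] = []
    for site in variant_sites:
        n_miss = sum(site.is_missing(int(i)) for i in kept_idx)
        if n_miss / len(kept_idx) >= cfg.site_missing_max:
            continue
        if cfg.exc_het_mode != "off" and site.locus_class == "snp":
            counts = _diploid_counts_subset(site, kept_idx)
            if sum(counts) >= 1:
                p = excess_het_probability(*counts)
                if cfg.exc_het_mode == "remove_above" and p > cfg.exc_het_threshold:
                    continue
                if cfg.exc_het_mode == "remove_below" and p < 1 - cfg.exc_het_threshold:
                    continue
        retained.append(site)

    snp_sites = [s for s in retained if s.locus_class == "snp"]

    # --- callable ledger: invariant positions + retained SNP loci --------
    ledger = CallableSiteLedger()
    pos_lists: dict[str, list[np.ndarray]] = {}
    for site in invariant:
        span = _invariant_span(site)
        ledger.add(site.chrom, span)
        if keep_positions:
            pos_lists.setdefault(site.chrom, []).append(
                np.arange(site.pos, site.pos + span, dtype=np.int64)
            )
    for site in snp_sites:
        ledger.add(site.chrom, 1)
        if keep_positions:
            pos_lists.setdefault(site.chrom, []).append(np.array([site.pos], dtype=np.int64))
    if keep_positions:
        ledger.positions = {
            c: np.unique(np.concatenate(parts)) for c, parts in pos_lists.items()
        }

    # --- dosage matrix over biallelic-decomposed SNP loci -----------------
    loci_rows = []
    dosage_cols = []
    ploidy = np.zeros(len(kept_idx), dtype=np.int16)
    for site in snp_sites:
        snp_alts = [k + 1 for k, a in enumerate(site.alts) if len(a) == 1]
        alt_idx = snp_alts[0] if len(snp_alts) == 1 else _major_alt_index(site)
        dose = _site_dosages(site, alt_idx)[kept_idx]
        loci_rows.append((site.chrom, site.pos, site.ref, site.alts[alt_idx - 1]))
        dosage_cols.append(dose)
        for j, i in enumerate(kept_idx):
            gt = site.genotypes[int(i)]
            if gt is not None and ploidy[j] == 0:
                ploidy[j] = len(gt)
    loci = pd.DataFrame(loci_rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = (
        np.stack(dosage_cols, axis=1).astype(np.int16)
        if dosage_cols
        else np.zeros((len(kept_idx), 0), dtype=np.int16)
    )
    matrix = GenotypeMatrix(samples=kept_samples, loci=loci, dosage=dosage, ploidy=ploidy)
    return matrix, ledger, excluded, report


def _sample_names(site: VariantSite, n: int) -> list[str]:
    names = getattr(site, "sample_names", None)
    return list(names) if names else [f"sample_{i}" for i in range(n)]


def _diploid_counts_subset(site: VariantSite, idx: np.ndarray) -> tuple[int, int, int]:
    n_aa = n_ab = n_bb = 0
    for i in idx:
        gt = site.genotypes[int(i)]
        if gt is None or len(gt) != 2 or any(a < 0 or a > 1 for a in gt):
            continue
        s = gt[0] + gt[1]
        if s == 0:
            n_aa += 1
        elif s == 1:
            n_ab += 1
        else:
            n_bb += 1
    return n_aa, n_ab, n_bb


def attach_sample_names(sites: Sequence[VariantSite], names: Sequence[str]) -> None:
    """Annotate sites with sample ids (pysam records carry them; synthetic
    streams may not)."""
    for s in sites:
        s.sample_names = list(names)  # type: ignore[attr-defined]


def read_vcf_sample_names(path: str) -> list[str]:
    import pysam

    with pysam.VariantFile(path) as vcf:
        return list(vcf.header.samples)
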