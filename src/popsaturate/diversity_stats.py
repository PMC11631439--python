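"""Pairwise SNP distances, nucleotide diversity, and rank correlations.

The pairwise distance between two isolates is the number of SNP loci at
which both carry a call and their alternate-allele dosages differ (a
het-vs-hom difference counts as one site). Nucleotide diversity π is the
unbiased per-site pairwise heterozygosity over observed allele copies,
averaged over 10-kb windows sliding by 1 kb with callable positions as the
denominator. Spearman's ρ quantifies the ploidy–heterozygosity association.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from popsaturate.variant_io_filter import MISSING, CallableSiteLedger, GenotypeMatrix


@dataclass
class PairwiseDiffSummary:
    n_pairs: int
    counts: np.ndarray
    callable_total: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd(self) -> float:
        return float(np.std(self.counts, ddof=1)) if self.n_pairs > 1 else 0.0

    @property
    def max(self) -> int:
        return int(np.max(self.counts))

    def as_fraction(self, value: float) -> float:
        return value / self.callable_total


@dataclass
class PiWindowTrack:
    windows: pd.DataFrame  # chrom, start, end (1-based inclusive), pi
    window: int
    step: int

    @property
    def median_pi(self) -> float:
        return float(self.windows["pi"].median())


@dataclass
class RankCorrelation:
    rho: float
    n: int
    p_value: float


def pairwise_snp_count(
    matrix: GenotypeMatrix, sample_i: str, sample_j: str
) -> tuple[int, int]:
    """(differing-site count, comparable-locus count) for one pair."""
    a = matrix.dosage[matrix.sample_index(sample_i)]
    b = matrix.dosage[matrix.sample_index(sample_j)]
    ok = (a != MISSING) & (b != MISSING)
    return int(np.sum(ok & (a != b))), int(np.sum(ok))


def pairwise_distribution(
    matrix: GenotypeMatrix,
    n_pairs: Optional[int],
    seed: int,
    callable_total: int,
) -> PairwiseDiffSummary:
    """Differing-site counts over uniformly sampled unordered sample pairs.

    ``n_pairs=None`` (or a value >= the number of distinct pairs) enumerates
    all pairs; otherwise pairs are drawn without replacement.
    """
    n = matrix.n_samples
    if n < 2:
        raise ValueError("need >= 2 samples")
    total_pairs = n * (n - 1) // 2
    if n_pairs is None or n_pairs >= total_pairs:
        idx = np.arange(total_pairs)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(total_pairs, size=n_pairs, replace=False)
    counts = np.empty(len(idx), dtype=np.int64)
    d = matrix.dosage
    for t, k in enumerate(idx):
        i, j = _pair_from_index(int(k), n)
        a, b = d[i], d[j]
        counts[t] = np.sum((a != MISSING) & (b != MISSING) & (a != b))
    return PairwiseDiffSummary(len(idx), counts, callable_total)


def _pair_from_index(k: int, n: int) -> tuple[int, int]:
    """k-th unordered pair (i<j) in lexicographic order."""
    i = 0
    row = n - 1
    while k >= row:
        k -= row
        i += 1
        row -= 1
    return i, i + 1 + k


def site_pi(dosages: np.ndarray, ploidies: np.ndarray) -> float:
    """Unbiased per-site pairwise diversity over observed allele copies.

    With n copies and allele frequencies p_a: π = n/(n−1) · (1 − Σ p_a²).
    Missing calls reduce n; mixed-ploidy samples contribute their own copy
    numbers. Undefined (ValueError) for fewer than 2 observed copies.
    """
    dosages = np.asarray(dosages)
    ploidies = np.asarray(ploidies)
    ok = dosages != MISSING
    n = int(ploidies[ok].sum())
    if n < 2:
        raise ValueError("site_pi undefined for < 2 observed allele copies")
    alt = int(dosages[ok].sum())
    p1 = alt / n
    p0 = 1 - p1
    return float(n / (n - 1) * (1 - p0 * p0 - p1 * p1))


def windowed_pi(
    matrix: GenotypeMatrix,
    ledger: CallableSiteLedger,
    window: int = 10_000,
    step: int = 1_000,
    raw_length_denominator: bool = False,
) -> PiWindowTrack:
    """Sliding-window π: Σ site_pi over SNPs in window / callable positions.

    Windows with zero callable positions are skipped. The callable-position
    denominator keeps masked regions from deflating π; set
    ``raw_length_denominator`` to divide by window length instead.
    """
    ploidies = matrix.effective_ploidy()
    site_vals = np.zeros(matrix.n_loci)
    for j in range(matrix.n_loci):
        try:
            site_vals[j] = site_pi(matrix.dosage[:, j], ploidies)
        except ValueError:
            site_vals[j] = np.nan
    rows = []
    for chrom in ledger.counts:
        pos_arr = ledger.positions.get(chrom)
        in_chrom = matrix.loci["chrom"] == chrom
        snp_pos = matrix.loci.loc[in_chrom, "pos"].to_numpy()
        snp_val = site_vals[in_chrom.to_numpy()]
        order = np.argsort(snp_pos)
        snp_pos, snp_val = snp_pos[order], snp_val[order]
        cum = np.concatenate([[0.0], np.nancumsum(snp_val)])
        if pos_arr is not None and len(pos_arr):
            chrom_end = int(pos_arr.max())
        elif len(snp_pos):
            chrom_end = int(snp_pos.max())
        else:
            continue
        for start in range(1, max(chrom_end - window + 2, 2), step):
            end = start + window - 1
            if raw_length_denominator:
                denom = window
            else:
                if pos_arr is None:
                    raise ValueError("positional ledger required for callable denominator")
                lo, hi = np.searchsorted(pos_arr, [start, end + 1])
                denom = int(hi - lo)
            if denom == 0:
                continue
            lo, hi = np.searchsorted(snp_pos, [start, end + 1])
            pi = (cum[hi] - cum[lo]) / denom
            rows.append((chrom, start, end, pi))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "pi"])
    return PiWindowTrack(df, window, step)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> RankCorrelation:
    """Spearman ρ with midrank ties and large-sample two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = spearmanr(x, y)
    return RankCorrelation(float(rho), len(x), float(p))
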