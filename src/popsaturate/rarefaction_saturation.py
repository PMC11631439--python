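"""Rarefaction of variant counts and saturation-curve extrapolation.

For a cohort of N isolates, the rarefaction curve gives the expected number
of variants observed in a random subsample of n isolates. Writing c_k for
the number of variants carried by exactly k isolates (a carrier holds >= 1
alternate-allele copy), the expectation has a closed hypergeometric form:

    P(>=1 carrier in subsample) = 1 − C(N−k, n) / C(N, n)
    P(>=2 carriers)             = P(>=1) − k · C(N−k, n−1) / C(N, n)
    E[count] = Σ_k c_k · P(>= min_carriers)

Non-singleton status is evaluated *within the subsample* (the P(>=2)
branch), the standard rarefaction semantics. The all-variant curve grows as
a power law y = a·x^b − c (no finite asymptote), while the non-singleton
curve saturates and is fitted by a Michaelis–Menten form
y = Vmax·x/(K + x); Vmax estimates the species-total non-singleton variant
count, and the cohort's coverage of species diversity is the fraction of
Vmax it has already observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import gammaln

from popsaturate.variant_io_filter import MISSING, GenotypeMatrix


@dataclass
class CarrierCounts:
    """c_k, k = 1..N: number of variants carried by exactly k isolates."""

    n_isolates: int
    counts: np.ndarray  # length N, counts[k-1] = c_k

    def __post_init__(self) -> None:
        if len(self.counts) != self.n_isolates:
            raise ValueError("carrier histogram length must equal isolate count")
        if (self.counts < 0).any():
            raise ValueError("carrier counts must be non-negative")

    @property
    def total_variants(self) -> int:
        return int(self.counts.sum())

    @property
    def singletons(self) -> int:
        return int(self.counts[0])

    @property
    def non_singletons(self) -> int:
        return self.total_variants - self.singletons


@dataclass
class RarefactionCurve:
    n_grid: np.ndarray
    y: np.ndarray
    min_carriers: int
    mode: str  # exact | monte_carlo


@dataclass
class SaturationFit:
    model: str  # power_law | michaelis_menten
    params: dict[str, float]
    rss: float
    converged: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.model == "power_law":
            return p["a"] * x ** p["b"] - p["c"]
        return p["vmax"] * x / (p["k"] + x)

    @property
    def asymptote(self) -> float:
        if self.model == "power_law":
            return np.inf if self.params["b"] > 0 else -self.params["c"]
        return self.params["vmax"]


@dataclass
class CoverageEstimate:
    numerator_mode: str  # observed_count | fitted_at_N
    numerator: float
    asymptote: float

    @property
    def fraction(self) -> float:
        return self.numerator / self.asymptote


# ---------------------------------------------------------------------------
# carrier histogram and rarefaction
# ---------------------------------------------------------------------------


def carrier_counts(matrix: GenotypeMatrix) -> CarrierCounts:
    """Histogram of per-variant carrier numbers (carrier: dosage >= 1)."""
    if matrix.n_samples == 0 or matrix.n_loci == 0:
        raise ValueError("empty genotype matrix")
    carriers = np.sum((matrix.dosage != MISSING) & (matrix.dosage >= 1), axis=0)
    hist = np.bincount(carriers, minlength=matrix.n_samples + 1)[1:]
    return CarrierCounts(matrix.n_samples, hist.astype(np.int64))


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    """log C(n, k), −inf where k > n or k < 0."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def expected_rarefaction(counts: CarrierCounts, n: int, min_carriers: int = 1) -> float:
    """Exact expected variant count in a random n-isolate subsample."""
    N = counts.n_isolates
    if not 1 <= n <= N:
        raise ValueError(f"subsample size {n} outside 1..{N}")
    if min_carriers not in (1, 2):
        raise ValueError("min_carriers must be 1 or 2")
    k = np.arange(1, N + 1, dtype=float)
    log_cNn = _log_comb(N, n)
    # P(0 carriers of a k-carrier variant in the subsample)
    p0 = np.exp(_log_comb(N - k, n) - log_cNn)
    p_ge1 = 1.0 - p0
    if min_carriers == 1:
        probs = p_ge1
    else:
        p1 = k * np.exp(_log_comb(N - k, n - 1) - log_cNn)
        probs = p_ge1 - p1
    return float(np.sum(counts.counts * np.clip(probs, 0.0, 1.0)))


def rarefaction_curve(
    counts: CarrierCounts,
    min_carriers: int = 1,
    grid: Optional[np.ndarray] = None,
    n_points: int = 50,
) -> RarefactionCurve:
    """Exact rarefaction curve on a geometric grid (default 50 points, 2..N)."""
    N = counts.n_isolates
    if grid is None:
        grid = np.unique(np.geomspace(2, N, n_points).round().astype(int))
    y = np.array([expected_rarefaction(counts, int(n), min_carriers) for n in grid])
    return RarefactionCurve(np.asarray(grid), y, min_carriers, "exact")


def monte_carlo_rarefaction(
    matrix: GenotypeMatrix, n: int, reps: int, seed: int, min_carriers: int = 1
) -> float:
    """Monte-Carlo twin of the exact expectation (mean over random subsets)."""
    N = matrix.n_samples
    if not 1 <= n <= N:
        raise ValueError(f"subsample size {n} outside 1..{N}")
    rng = np.random.default_rng(seed)
    carrier = (matrix.dosage != MISSING) & (matrix.dosage >= 1)
    totals = np.empty(reps)
    for r in range(reps):
        rows = rng.choice(N, size=n, replace=False)
        totals[r] = np.sum(carrier[rows].sum(axis=0) >= min_carriers)
    return float(totals.mean())


# ---------------------------------------------------------------------------
# saturation fits
# ---------------------------------------------------------------------------


def fit_power_law(curve: RarefactionCurve, seed: int = 0, n_restarts: int = 5) -> SaturationFit:
    """Least-squares fit of y = a·x^b − c with a > 0, 0 < b < 1."""
    x, y = curve.n_grid.astype(float), curve.y.astype(float)
    if len(x) < 4:
        raise ValueError("power-law fit needs >= 4 grid points")

    def f(x, a, b, c):
        return a * x**b - c

    rng = np.random.default_rng(seed)
    scale = max(y.max(), 1.0)
    best: Optional[tuple[float, np.ndarray]] = None
    inits = [(scale, 0.5, 0.0)] + [
        (scale * rng.uniform(0.2, 5), rng.uniform(0.05, 0.95), scale * rng.uniform(-0.5, 0.5))
        for _ in range(n_restarts)
    ]
    for p0 in inits:
        try:
            popt, _ = curve_fit(
                f, x, y, p0=p0,
                bounds=([1e-12, 1e-6, -np.inf], [np.inf, 1 - 1e-6, np.inf]),
                maxfev=20_000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((f(x, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        return SaturationFit("power_law", {"a": np.nan, "b": np.nan, "c": np.nan},
                             np.inf, converged=False)
    rss, (a, b, c) = best
    return SaturationFit("power_law", {"a": float(a), "b": float(b), "c": float(c)}, rss)


def fit_michaelis_menten(curve: RarefactionCurve, seed: int = 0, n_restarts: int = 5) -> SaturationFit:
    """Least-squares fit of y = Vmax·x/(K + x), Vmax, K > 0.

    Initialized from a double-reciprocal (Lineweaver–Burk) linear pass, with
    jittered restarts.
    """
    x, y = curve.n_grid.astype(float), curve.y.astype(float)
    if len(x) < 3:
        raise ValueError("Michaelis–Menten fit needs >= 3 grid points")

    def f(x, vmax, k):
        return vmax * x / (k + x)

    ok = y > 0
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(1 / x[ok], 1 / y[ok], 1)
        vmax0 = 1 / intercept if intercept > 0 else y.max() * 2
        k0 = slope * vmax0 if slope * vmax0 > 0 else np.median(x)
    else:
        vmax0, k0 = y.max() * 2, np.median(x)
    rng = np.random.default_rng(seed)
    inits = [(vmax0, k0)] + [
        (vmax0 * rng.uniform(0.3, 3), k0 * rng.uniform(0.3, 3)) for _ in range(n_restarts)
    ]
    best: Optional[tuple[float, np.ndarray]] = None
    for p0 in inits:
        p0 = (max(p0[0], 1e-9), max(p0[1], 1e-9))
        try:
            popt, _ = curve_fit(f, x, y, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                                maxfev=20_000)
        except RuntimeError:
            continue
        rss = float(np.sum((f(x, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        return SaturationFit("michaelis_menten", {"vmax": np.nan, "k": np.nan},
                             np.inf, converged=False)
    rss, (vmax, k) = best
    return SaturationFit("michaelis_menten", {"vmax": float(vmax), "k": float(k)}, rss)


def coverage_fraction(
    fit: SaturationFit,
    counts: Optional[CarrierCounts] = None,
    N: Optional[int] = None,
    numerator_mode: str = "observed_count",
) -> CoverageEstimate:
    """Fraction of the species' non-singleton diversity already observed.

    Numerator: the cohort's observed non-singleton count (default) or the
    fitted curve evaluated at N. Denominator: the fit's asymptote Vmax.
    Power-law fits are refused — their variant count tends to infinity.
    """
    if fit.model != "michaelis_menten":
        raise ValueError(
            "coverage fraction requires a saturating (Michaelis–Menten) fit; "
            "a power law has no finite asymptote"
        )
    if numerator_mode == "observed_count":
        if counts is None:
            raise ValueError("observed_count mode needs carrier counts")
        numerator = float(counts.non_singletons)
    elif numerator_mode == "fitted_at_N":
        if N is None:
            raise ValueError("fitted_at_N mode needs N")
        numerator = float(fit.predict(np.array([N]))[0])
    else:
        raise ValueError(f"unknown numerator_mode {numerator_mode!r}")
    return CoverageEstimate(numerator_mode, numerator, fit.asymptote)
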