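"""Rarefaction expectations against brute-force subset enumeration, and
saturation-curve fitting / coverage extrapolation."""

from itertools import combinations

import numpy as np
import pytest

from popsaturate.rarefaction_saturation import (
    CarrierCounts,
    RarefactionCurve,
    carrier_counts,
    coverage_fraction,
    expected_rarefaction,
    fit_michaelis_menten,
    fit_power_law,
    monte_carlo_rarefaction,
    rarefaction_curve,
)
from tests.conftest import make_matrix

M = -1


# ---------------------------------------------------------------------------
# carrier histogram
# ---------------------------------------------------------------------------


def test_carrier_counts_hand_tally():
    # 4 samples x 3 variants: carriers 1, 3, 2
    mat = make_matrix([[1, 1, 0], [0, 1, 2], [0, 1, 0], [0, 0, 1]])
    cc = carrier_counts(mat)
    assert cc.counts.tolist() == [1, 1, 1, 0]
    assert cc.total_variants == 3
    assert cc.singletons == 1
    assert cc.non_singletons == 2


def test_carrier_counts_conserve_total():
    rng = np.random.default_rng(0)
    mat = make_matrix(rng.integers(0, 2, (8, 40)))
    cc = carrier_counts(mat)
    n_variant = int((np.asarray(mat.dosage) >= 1).any(axis=0).sum())
    assert cc.total_variants == n_variant


# ---------------------------------------------------------------------------
# exact expectation vs brute-force enumeration
# ---------------------------------------------------------------------------


def brute_force_expectation(carrier_matrix: np.ndarray, n: int, min_carriers: int) -> float:
    """Average variant count over ALL C(N, n) subsamples (independent oracle)."""
    N = carrier_matrix.shape[0]
    totals = [
        int((carrier_matrix[list(rows)].sum(axis=0) >= min_carriers).sum())
        for rows in combinations(range(N), n)
    ]
    return float(np.mean(totals))


def test_single_variant_pair_subsample():
    """N=4, one doubleton, n=2, min_carriers=2: only 1 of 6 pairs sees both."""
    cc = CarrierCounts(4, np.array([0, 1, 0, 0]))
    assert expected_rarefaction(cc, 2, 2) == pytest.approx(1 / 6)


@pytest.mark.parametrize("min_carriers", [1, 2])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_expectation_equals_enumeration(min_carriers, seed):
    rng = np.random.default_rng(seed)
    N = rng.integers(5, 13)
    carrier = rng.random((N, 30)) < rng.uniform(0.1, 0.6)
    carrier = carrier[:, carrier.any(axis=0)]
    cc = CarrierCounts(
        N, np.bincount(carrier.sum(axis=0), minlength=N + 1)[1:].astype(np.int64)
    )
    for n in range(1, N + 1):
        assert expected_rarefaction(cc, n, min_carriers) == pytest.approx(
            brute_force_expectation(carrier, n, min_carriers), rel=1e-10
        )


def test_full_sample_recovers_observed_counts():
    cc = CarrierCounts(6, np.array([4, 3, 0, 2, 0, 1]))
    assert expected_rarefaction(cc, 6, 1) == cc.total_variants
    assert expected_rarefaction(cc, 6, 2) == cc.non_singletons


def test_universal_variant_always_seen():
    cc = CarrierCounts(5, np.array([0, 0, 0, 0, 1]))
    for n in range(1, 6):
        assert expected_rarefaction(cc, n, 1) == pytest.approx(1.0)


def test_curves_monotone_and_ordered():
    rng = np.random.default_rng(3)
    mat = make_matrix(rng.integers(0, 2, (20, 200)))
    cc = carrier_counts(mat)
    c1 = rarefaction_curve(cc, 1)
    c2 = rarefaction_curve(cc, 2)
    assert (np.diff(c1.y) >= -1e-9).all()
    assert (np.diff(c2.y) >= -1e-9).all()
    assert (c2.y <= c1.y + 1e-9).all()


def test_subsample_level_singleton_semantics():
    """min_carriers=2 is evaluated inside the subsample, which differs from
    pre-dropping full-population singletons."""
    # one variant with 2 carriers among N=4: population-level it is
    # non-singleton everywhere, but a subsample of 2 usually sees <= 1 carrier
    cc = CarrierCounts(4, np.array([0, 1, 0, 0]))
    in_subsample = expected_rarefaction(cc, 2, 2)  # 1/6
    pre_filtered = expected_rarefaction(
        CarrierCounts(4, np.array([0, 1, 0, 0])), 2, 1
    )  # 1 - C(2,2)/C(4,2) = 5/6... (variant kept, then any carrier counts)
    assert in_subsample == pytest.approx(1 / 6)
    assert pre_filtered == pytest.approx(1 - 1 / 6)
    assert in_subsample < pre_filtered


def test_monte_carlo_agrees_with_exact():
    mat = make_matrix([[1, 1, 0], [0, 1, 2], [0, 1, 0], [0, 0, 1]])
    cc = carrier_counts(mat)
    reps = 10_000
    for n, mc in [(2, 1), (2, 2), (3, 2)]:
        exact = expected_rarefaction(cc, n, mc)
        sim = monte_carlo_rarefaction(mat, n, reps, seed=9, min_carriers=mc)
        se = np.sqrt(exact * (1 - exact / cc.total_variants) / reps) + 1e-6
        assert abs(sim - exact) < 3 * max(se, 0.05)


def test_monte_carlo_determinism_and_full_sample():
    mat = make_matrix([[1, 0], [0, 1], [1, 1]])
    a = monte_carlo_rarefaction(mat, 2, 50, seed=5)
    b = monte_carlo_rarefaction(mat, 2, 50, seed=5)
    assert a == b
    assert monte_carlo_rarefaction(mat, 3, 1, seed=0) == 2


# ---------------------------------------------------------------------------
# saturation fits
# ---------------------------------------------------------------------------


def grid_curve(x, y, min_carriers=2):
    return RarefactionCurve(np.asarray(x), np.asarray(y), min_carriers, "exact")


def test_power_law_noise_free_recovery():
    x = np.linspace(2, 3000, 60)
    a, b, c = 242_965.0, 0.276, 288_549.0
    fit = fit_power_law(grid_curve(x, a * x**b - c, 1))
    assert fit.params["a"] == pytest.approx(a, rel=1e-4)
    assert fit.params["b"] == pytest.approx(b, rel=1e-4)
    assert fit.params["c"] == pytest.approx(c, rel=1e-4)
    assert np.isinf(fit.asymptote)


def test_power_law_needs_four_points():
    with pytest.raises(ValueError):
        fit_power_law(grid_curve([1, 2, 3], [1, 2, 3]))


def test_mm_noise_free_recovery_and_half_saturation():
    x = np.linspace(1, 500, 40)
    fit = fit_michaelis_menten(grid_curve(x, 1000 * x / (50 + x)))
    assert fit.params["vmax"] == pytest.approx(1000, rel=1e-6)
    assert fit.params["k"] == pytest.approx(50, rel=1e-6)
    k = fit.params["k"]
    assert fit.predict(np.array([k]))[0] == pytest.approx(fit.asymptote / 2, rel=1e-9)


def test_mm_bias_shrinks_with_noise():
    rng = np.random.default_rng(11)
    x = np.linspace(1, 500, 60)
    truth = 1000 * x / (50 + x)
    errs = []
    for noise in (20.0, 1.0):
        y = truth + rng.normal(0, noise, len(x))
        fit = fit_michaelis_menten(grid_curve(x, y))
        errs.append(abs(fit.params["vmax"] - 1000))
    assert errs[1] < errs[0]


def test_mm_fits_power_law_data_with_residual():
    x = np.linspace(2, 1000, 50)
    fit = fit_power_law(grid_curve(x, 1000 * x / (50 + x)))
    assert fit.rss > 0


# ---------------------------------------------------------------------------
# coverage fraction
# ---------------------------------------------------------------------------


def test_coverage_fitted_at_n_identity():
    from popsaturate.rarefaction_saturation import SaturationFit

    fit = SaturationFit("michaelis_menten", {"vmax": 1_369_438.0, "k": 204.0}, 0.0)
    cov = coverage_fraction(fit, N=3034, numerator_mode="fitted_at_N")
    assert cov.fraction == pytest.approx(3034 / (204 + 3034), rel=1e-12)


def test_coverage_observed_count_mode():
    from popsaturate.rarefaction_saturation import SaturationFit

    fit = SaturationFit("michaelis_menten", {"vmax": 200.0, "k": 10.0}, 0.0)
    cc = CarrierCounts(4, np.array([5, 100, 60, 40]))
    cov = coverage_fraction(fit, counts=cc)
    assert cov.fraction == pytest.approx(200 / 200.0)


def test_coverage_refuses_power_law():
    from popsaturate.rarefaction_saturation import SaturationFit

    fit = SaturationFit("power_law", {"a": 1.0, "b": 0.5, "c": 0.0}, 0.0)
    with pytest.raises(ValueError):
        coverage_fraction(fit, N=100, numerator_mode="fitted_at_N")


def species_pool_coverage(seed: int):
    """Simulate a whole 'species' (360 isolates, generator-default allele
    spectrum), sample a cohort of a third of it, and compare the MM-based
    coverage estimate with the cohort's true share of the species'
    non-singleton variants. Returns (estimate, truth)."""
    from popsaturate.synthetic_population import SimConfig, simulate_genotypes
    from popsaturate.variant_io_filter import GenotypeMatrix

    cfg = SimConfig(
        seed=seed, n_clades=6, samples_per_clade=60, n_admixed=0,
        n_loci=6000, homozygous_fraction=0.3, missing_rate=0.0,
    )
    mat, _ = simulate_genotypes(cfg)
    species = carrier_counts(mat)
    rng = np.random.default_rng(seed + 1)
    rows = rng.choice(mat.n_samples, mat.n_samples // 3, replace=False)
    sub = GenotypeMatrix(
        samples=[mat.samples[i] for i in rows], loci=mat.loci,
        dosage=mat.dosage[rows], ploidy=mat.ploidy[rows],
    )
    cc = carrier_counts(sub)
    fit = fit_michaelis_menten(rarefaction_curve(cc, 2), seed=0)
    est = coverage_fraction(fit, counts=cc).fraction
    return est, cc.non_singletons / species.non_singletons


def test_coverage_recovered_on_synthetic_population():
    """MM extrapolation from a third of the species recovers the captured
    fraction within 5 percentage points of truth."""
    est, truth = species_pool_coverage(seed=17)
    assert est == pytest.approx(truth, abs=0.05)
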