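import numpy as np
import pytest

from avalanchekit.plstats import sample_powerlaw
from avalanchekit.scaling import (
    DegenerateDistributionError,
    check_beta_relation,
    check_scaling_relation,
    collapse_exponential,
    collapse_power_law,
    empirical_pdf,
)


def sample_scaling_family(tau, beta, bin_factor, n, rng, s0=100.0):
    """Integer samples from P(S) ~ S^-tau * exp(-S / (s0 * bin^beta)).

    The generator's parameters are the oracle for collapse recovery.
    """
    cutoff = s0 * bin_factor**beta
    s = np.arange(1, int(cutoff * 15) + 1, dtype=float)
    p = s**-tau * np.exp(-s / cutoff)
    p /= p.sum()
    return rng.choice(s.astype(np.int64), size=n, p=p)


class TestEmpiricalPdf:
    def test_degenerate_input(self):
        with pytest.raises(DegenerateDistributionError):
            empirical_pdf(np.full(50, 7))

    def test_normalisation(self, rng):
        v = rng.integers(1, 500, 5000)
        d = empirical_pdf(v)
        widths = np.diff(d.class_edges)[d.class_counts > 0] if d.class_edges is not None else None
        # density integrates to one over the retained classes
        total = np.sum(d.density * widths)
        assert total == pytest.approx(1.0, rel=1e-9)

    def test_power_law_slope(self, rng):
        """Log-log density slope of truncated power-law samples is -1.5."""
        v = np.round(sample_powerlaw(100_000, 1.5, 1.0, 1e3, rng)).astype(int)
        v = np.clip(v, 1, None)
        d = empirical_pdf(v, n_classes=25)
        keep = (d.bin_centers > 10) & (d.bin_centers < 300)
        slope = np.polyfit(np.log(d.bin_centers[keep]), np.log(d.density[keep]), 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.1)

    def test_uniform_values_flat(self, rng):
        v = rng.integers(1, 101, 200_000)
        d = empirical_pdf(v, n_classes=10)
        keep = d.bin_centers > 5
        assert np.ptp(np.log(d.density[keep])) < 0.2


class TestCollapseRecovery:
    @pytest.mark.parametrize("tau", [1.2, 1.5, 1.8])
    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
    def test_power_law_family(self, tau, beta):
        """Known (tau, beta) recovered within grid resolution + uncertainty."""
        rng = np.random.default_rng(int(tau * 100 + beta * 10))
        dists = [
            empirical_pdf(
                sample_scaling_family(tau, beta, bf, 300_000, rng),
                observable="size", bin_factor=bf,
            )
            for bf in (1, 2, 4, 8)
        ]
        c = collapse_power_law(dists)
        assert abs(c.exponent - tau) <= 0.05 + c.exponent_unc + 1e-9
        assert abs(c.beta - beta) <= 0.05 + c.beta_unc + 1e-9

    @pytest.mark.parametrize("beta", [0.5, 1.3, 2.0])
    def test_exponential_family(self, beta, rng):
        dists = []
        for bf in (1, 2, 4, 8):
            scale = 50.0 * bf**beta
            v = np.maximum(np.round(rng.exponential(scale, 100_000)), 1).astype(np.int64)
            dists.append(empirical_pdf(v, observable="size", bin_factor=bf))
        c = collapse_exponential(dists)
        assert abs(c.beta - beta) <= 0.05 + c.beta_unc + 1e-9

    def test_identical_distributions_give_zero_beta(self, rng):
        v = np.maximum(np.round(rng.exponential(80.0, 50_000)), 1).astype(np.int64)
        dists = [empirical_pdf(v, observable="size", bin_factor=bf) for bf in (1, 2, 4)]
        assert collapse_exponential(dists).beta == 0.0

    def test_quality_invariant_under_reordering(self, rng):
        dists = [
            empirical_pdf(sample_scaling_family(1.5, 1.0, bf, 30_000, rng),
                          observable="size", bin_factor=bf)
            for bf in (1, 2, 4, 8)
        ]
        q1 = collapse_power_law(dists).quality
        q2 = collapse_power_law(dists[::-1]).quality
        assert q1 == pytest.approx(q2)

    def test_requires_three_distributions(self, rng):
        dists = [
            empirical_pdf(sample_scaling_family(1.5, 1.0, bf, 1000, rng),
                          observable="size", bin_factor=bf)
            for bf in (1, 2)
        ]
        with pytest.raises(ValueError):
            collapse_power_law(dists)


class TestModelSelection:
    def test_families_distinguished_by_quality(self, rng):
        """Exponential collapse wins on exponential data and vice versa."""
        exp_dists, pl_dists = [], []
        for bf in (1, 2, 4, 8):
            scale = 50.0 * bf**1.3
            v = np.maximum(np.round(rng.exponential(scale, 80_000)), 1).astype(np.int64)
            exp_dists.append(empirical_pdf(v, observable="size", bin_factor=bf))
            pl_dists.append(
                empirical_pdf(sample_scaling_family(1.5, 1.3, bf, 80_000, rng),
                              observable="size", bin_factor=bf)
            )
        assert collapse_exponential(exp_dists).quality < collapse_power_law(exp_dists).quality
        assert collapse_power_law(pl_dists).quality < collapse_exponential(pl_dists).quality


class TestExponentRelations:
    @pytest.mark.parametrize(
        "tau, alpha, gamma, expected",
        [
            (1.5, 2.0, 0.5, 0.0),
            (1.5, 2.0, 0.6, 2.0 - 1 / 0.6),
        ],
    )
    def test_scaling_relation_residual(self, tau, alpha, gamma, expected):
        out = check_scaling_relation(tau, alpha, gamma)
        assert out["residual"] == pytest.approx(expected)

    def test_undefined_below_tau_one(self):
        out = check_scaling_relation(1.0, 2.0, 0.5)
        assert out["defined"] is False

    @pytest.mark.parametrize(
        "beta_T, beta_S, gamma, expected",
        [
            (1.0, 2.0, 0.5, 0.0),
            (1.2, 1.8, 0.73, 1.2 - 0.73 * 1.8),
            (0.0, 0.0, 0.9, 0.0),
        ],
    )
    def test_beta_relation_residual(self, beta_T, beta_S, gamma, expected):
        out = check_beta_relation(beta_T, beta_S, gamma)
        assert out["residual"] == pytest.approx(expected)

    def test_beta_relation_on_synthetic_scale_free_ensemble(self, rng):
        """beta_T = gamma * beta_S holds when T = S^gamma by construction."""
        gamma, beta_S, tau = 0.5, 2.0, 1.5
        dS, dT = [], []
        for bf in (1, 2, 4, 8):
            # cutoff large enough that T = sqrt(S) spans a usable range
            S = sample_scaling_family(tau, beta_S, bf, 150_000, rng, s0=400.0)
            T = np.maximum(np.round(S**gamma), 1).astype(np.int64)
            dS.append(empirical_pdf(S, observable="size", bin_factor=bf))
            dT.append(empirical_pdf(T, observable="duration", bin_factor=bf))
        cS = collapse_power_law(dS)
        cT = collapse_power_law(dT)
        out = check_beta_relation(
            cT.beta, cS.beta, gamma,
            cT.beta_unc, cS.beta_unc, 0.0,
        )
        assert abs(out["residual"]) <= 0.15 + out["uncertainty"]
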