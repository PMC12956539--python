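"""MR estimators: Wald ratio, IVW (independent and LD-aware), MR-Egger,
weighted median, Steiger filtering, tiering, and BH adjustment."""

import numpy as np
import pytest
from scipy import stats

from sceqtlmr import (
    TierConfig,
    assign_tier,
    bh_adjust,
    ivw,
    ivw_correlated,
    mr_egger,
    simulate_ld,
    steiger_filter,
    wald_ratio,
    weighted_median,
)
from sceqtlmr.mr import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)

from conftest import make_harmonized


class TestWaldRatio:
    def test_algebraic_example(self):
        h = make_harmonized([0.5], [0.1], se_out=[0.05])
        r = wald_ratio(h)
        assert r.beta == pytest.approx(0.2)
        assert r.se == pytest.approx(0.1)
        assert r.method == "wald"

    def test_null_outcome_gives_null_estimate(self):
        h = make_harmonized([0.5], [0.0], se_out=[0.05])
        r = wald_ratio(h)
        assert r.beta == 0.0
        assert r.pvalue == pytest.approx(1.0)

    def test_zero_exposure_beta_is_degenerate(self):
        h = make_harmonized([0.0], [0.1])
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(h)

    def test_second_order_se_matches_monte_carlo(self, rng):
        """Simulation oracle: the second-order delta SE tracks the SD of a
        ratio of two independent normals (regime where the denominator is
        far from zero, so the ratio has near-normal tails)."""
        bx, sx, by, sy = 0.5, 0.02, 0.1, 0.05
        h = make_harmonized([bx], [by], se_exp=[sx], se_out=[sy])
        r = wald_ratio(h, second_order=True)
        draws = rng.normal(by, sy, 100_000) / rng.normal(bx, sx, 100_000)
        assert r.se == pytest.approx(np.std(draws), rel=0.05)

    def test_second_order_se_exceeds_first_order(self):
        h = make_harmonized([0.5], [0.1], se_exp=[0.05], se_out=[0.05])
        assert wald_ratio(h, second_order=True).se > wald_ratio(h).se


class TestIVW:
    def test_single_instrument_reduces_to_wald(self):
        h = make_harmonized([0.4], [0.12], se_out=[0.03])
        r_ivw, r_wald = ivw(h), wald_ratio(h)
        assert r_ivw.beta == r_wald.beta
        assert r_ivw.se == r_wald.se
        assert r_ivw.pvalue == r_wald.pvalue

    def test_two_symmetric_instruments_average(self):
        h = make_harmonized([1.0, 1.0], [0.2, 0.4], se_out=[0.1, 0.1])
        assert ivw(h).beta == pytest.approx(0.3)

    def test_matches_normal_equations_oracle(self, random_harmonized):
        """Brute-force accumulation of (sum xy/se^2)/(sum x^2/se^2)."""
        h = random_harmonized
        num = den = 0.0
        for x, y, s in zip(h.beta_exp, h.beta_out, h.se_out):
            num += x * y / s**2
            den += x * x / s**2
        r = ivw(h, dispersion="fixed")
        assert r.beta == pytest.approx(num / den, rel=1e-12)
        assert r.se == pytest.approx(np.sqrt(1 / den), rel=1e-12)

    def test_cochran_q_reported_with_chi2_pvalue(self, random_harmonized):
        r = ivw(random_harmonized)
        Q, df, p = r.q_stat
        assert df == random_harmonized.k - 1
        assert p == pytest.approx(stats.chi2.sf(Q, df))

    def test_scale_equivariance(self, random_harmonized):
        """Multiplying exposure betas and SEs by c divides the causal
        estimate (and SE) by c: the estimand is per-SD of exposure."""
        h = random_harmonized
        c = 2.5
        h2 = make_harmonized(h.beta_exp * c, h.beta_out, se_exp=h.se_exp * c,
                             se_out=h.se_out)
        for est in (ivw, mr_egger,
                    lambda x: weighted_median(x, n_boot=200, seed=1)):
            r1, r2 = est(h), est(h2)
            assert r2.beta == pytest.approx(r1.beta / c, rel=1e-9)

    def test_sign_equivariance(self, random_harmonized):
        h = random_harmonized
        h2 = make_harmonized(h.beta_exp, -h.beta_out, se_exp=h.se_exp,
                             se_out=h.se_out)
        for est in (ivw, mr_egger,
                    lambda x: weighted_median(x, n_boot=200, seed=1)):
            assert est(h2).beta == pytest.approx(-est(h).beta, rel=1e-9)


class TestIVWCorrelated:
    def test_identity_ld_equals_plain_ivw(self, rng):
        k = 6
        h = make_harmonized(rng.normal(0.3, 0.1, k), rng.normal(0.1, 0.03, k),
                            se_out=rng.uniform(0.005, 0.02, k), ld=np.eye(k))
        r_gls, r_ivw = ivw_correlated(h), ivw(h)
        assert r_gls.beta == pytest.approx(r_ivw.beta, rel=1e-9)
        assert r_gls.se == pytest.approx(r_ivw.se, rel=1e-4)  # ridge 1e-6

    def test_matches_explicit_gls_oracle(self, rng):
        """Independent linear solve of the generalized normal equations."""
        k = 5
        R = simulate_ld(k, 0.6)
        x = rng.normal(0.3, 0.1, k)
        y = rng.normal(0.1, 0.03, k)
        sy = rng.uniform(0.005, 0.02, k)
        h = make_harmonized(x, y, se_out=sy, ld=R)
        Sigma = (R + 1e-6 * np.eye(k)) * np.outer(sy, sy)
        Sinv = np.linalg.inv(Sigma)
        beta = (x @ Sinv @ y) / (x @ Sinv @ x)
        se = np.sqrt(1 / (x @ Sinv @ x))
        r = ivw_correlated(h, dispersion="fixed")
        assert r.beta == pytest.approx(beta, rel=1e-10)
        assert r.se == pytest.approx(se, rel=1e-10)

    def test_duplicated_instrument_limit(self):
        """Two copies of one instrument (r = 1, ridged) behave like the
        single instrument: same estimate, SE not deflated below the
        single-instrument Wald SE beyond the ridge tolerance."""
        h1 = make_harmonized([0.4], [0.12], se_out=[0.03])
        r1 = wald_ratio(h1)
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        h2 = make_harmonized([0.4, 0.4], [0.12, 0.12],
                             se_out=[0.03, 0.03], ld=R)
        r2 = ivw_correlated(h2, dispersion="fixed")
        assert r2.beta == pytest.approx(r1.beta, rel=1e-6)
        assert r2.se >= r1.se * (1 - 1e-3)

    def test_missing_ld_rejected(self, random_harmonized):
        with pytest.raises(ValueError, match="no LD matrix"):
            ivw_correlated(random_harmonized)


class TestMREgger:
    def test_exact_line_recovers_slope_and_intercept(self):
        x = np.array([0.2, 0.3, 0.5, 0.7])
        a, b = 0.05, 0.4
        h = make_harmonized(x, a + b * x, se_out=np.full(4, 0.01))
        r = mr_egger(h)
        assert r.beta == pytest.approx(b, abs=1e-10)
        icpt, se_icpt, _ = r.egger_intercept
        assert icpt == pytest.approx(a, abs=1e-10)

    def test_matches_weighted_least_squares_oracle(self, random_harmonized):
        """Independent WLS solve via the 2x2 normal equations."""
        h = random_harmonized
        flip = np.where(h.beta_exp < 0, -1.0, 1.0)
        x, y = h.beta_exp * flip, h.beta_out * flip
        w = 1 / h.se_out**2
        X = np.column_stack([np.ones_like(x), x])
        XtWX = X.T @ (w[:, None] * X)
        coef = np.linalg.solve(XtWX, X.T @ (w * y))
        r = mr_egger(h)
        assert r.egger_intercept[0] == pytest.approx(coef[0], rel=1e-9)
        assert r.beta == pytest.approx(coef[1], rel=1e-9)

    def test_insufficient_instruments_rejected(self):
        h = make_harmonized([0.3, 0.4], [0.1, 0.12])
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(h)

    def test_null_intercept_simulation_calibration(self, rng):
        """Data generated without pleiotropy: the intercept estimate lies
        within 3 SE of zero in >= 95% of 500 simulations."""
        k, theta = 10, 0.3
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            x_true = rng.normal(0.3, 0.1, k)
            sx, sy = 0.03, 0.01
            x = x_true + rng.normal(0, sx, k)
            y = theta * x_true + rng.normal(0, sy, k)
            h = make_harmonized(x, y, se_exp=np.full(k, sx),
                                se_out=np.full(k, sy))
            icpt, se_icpt, _ = mr_egger(h).egger_intercept
            hits += abs(icpt) <= 3 * se_icpt
        assert hits / n_sim >= 0.95


class TestWeightedMedian:
    def test_identical_ratios_return_the_common_value(self):
        x = np.array([0.2, 0.4, 0.5])
        h = make_harmonized(x, 0.3 * x)
        r = weighted_median(h, n_boot=100, seed=3)
        assert r.beta == pytest.approx(0.3)

    def test_equal_weight_median_of_three(self):
        x = np.array([1.0, 1.0, 1.0])
        y = np.array([0.1, 0.2, 0.9])
        h = make_harmonized(x, y, se_out=np.full(3, 0.05))
        r = weighted_median(h, n_boot=100, seed=3)
        assert r.beta == pytest.approx(0.2)

    def test_matches_breakpoint_scan_oracle(self, rng):
        """Exhaustive scan over cumulative-weight breakpoints."""
        from sceqtlmr.mr import _interp_weighted_median
        for _ in range(50):
            k = int(rng.integers(3, 12))
            b = rng.normal(0, 1, k)
            w = rng.uniform(0.1, 2.0, k)
            got = _interp_weighted_median(b, w)
            order = np.argsort(b)
            bs, ws = b[order], w[order]
            p = (np.cumsum(ws) - 0.5 * ws) / ws.sum()
            if 0.5 <= p[0]:
                expect = bs[0]
            elif 0.5 >= p[-1]:
                expect = bs[-1]
            else:
                j = int(np.searchsorted(p, 0.5)) - 1
                frac = (0.5 - p[j]) / (p[j + 1] - p[j])
                expect = bs[j] + frac * (bs[j + 1] - bs[j])
            assert got == pytest.approx(expect, rel=1e-12)

    def test_bootstrap_is_seed_reproducible(self, random_harmonized):
        r1 = weighted_median(random_harmonized, n_boot=200, seed=42)
        r2 = weighted_median(random_harmonized, n_boot=200, seed=42)
        assert (r1.beta, r1.se) == (r2.beta, r2.se)
        assert weighted_median(random_harmonized, n_boot=200, seed=43).se != r1.se

    def test_seed_is_mandatory(self, random_harmonized):
        with pytest.raises(ValueError, match="seed"):
            weighted_median(random_harmonized, n_boot=100)

    def test_zero_exposure_beta_rejected(self):
        h = make_harmonized([0.3, 0.0, 0.4], [0.1, 0.1, 0.1])
        with pytest.raises(DegenerateInstrumentError):
            weighted_median(h, n_boot=10, seed=1)


class TestSteiger:
    def test_exposure_dominant_variant_passes(self):
        h = make_harmonized([0.3], [0.001], se_exp=[0.03], se_out=[0.001])
        # z_exp = 10, z_out = 1, equal n
        kept, report = steiger_filter(h, n_exp=1000, n_out=1000)
        assert kept is not None and kept.k == 1
        assert report["steiger_pass"].all()

    def test_tied_variance_fails_strict_inequality(self):
        h = make_harmonized([0.3], [0.3], se_exp=[0.03], se_out=[0.03])
        kept, report = steiger_filter(h, n_exp=1000, n_out=1000)
        assert kept is None
        assert not report["steiger_pass"].any()

    def test_r2_formula(self):
        h = make_harmonized([0.3], [0.001], se_exp=[0.03], se_out=[0.001])
        _, report = steiger_filter(h, n_exp=982, n_out=50_000)
        z = 0.3 / 0.03
        assert report["r2_exp"][0] == pytest.approx(z**2 / (z**2 + 980))

    def test_partial_failures_recorded_in_dropped(self):
        h = make_harmonized([0.3, 0.01], [0.001, 0.02],
                            se_exp=[0.03, 0.03], se_out=[0.001, 0.001])
        kept, report = steiger_filter(h, n_exp=1000, n_out=1000)
        assert kept.k == 1
        assert ("rs1", "steiger fail") in kept.dropped


class TestTiering:
    @pytest.mark.parametrize("p, tier", [
        (1e-4, "global"),        # below the across-genes threshold 0.05/150
        (0.0003, "potential"),   # boundary belongs to the weaker tier
        (0.001, "potential"),
        (0.003, "nonsignificant"),
        (0.01, "nonsignificant"),
        (1.0, "nonsignificant"),
    ])
    def test_two_level_thresholds(self, p, tier):
        assert assign_tier(p) == tier

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            assign_tier(bad)

    def test_threshold_config_ordering_enforced(self):
        with pytest.raises(ValueError):
            TierConfig(global_threshold=0.01, potential_threshold=0.003)


def bh_oracle(p):
    """Definition-level BH: adj_i = min over j with p_j >= p_i of
    min(1, m * p_j / rank_j)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_computed_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_matches_definition_oracle_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1, int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(bh_oracle(p))

    def test_per_cell_type_grouping(self, rng):
        p = rng.uniform(1e-6, 1, 30)
        groups = rng.choice(["CD4", "CD8", "NK"], 30)
        adj = bh_adjust(p, grouping="per_cell_type", groups=groups)
        for g in ("CD4", "CD8", "NK"):
            mask = groups == g
            assert adj[mask] == pytest.approx(bh_oracle(p[mask]))

    def test_empty_vector(self):
        assert bh_adjust([]).size == 0
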