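"""Selection coefficients, recurrent-mutation Theta/Ne, survival associations."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from resistscan import selection, simulate
from resistscan.selection import (
    fit_selection,
    hudson_fst,
    recurrent_mutation_estimate,
    resistance_fst_ibd,
    survival_association,
)


def _traj(allele, years, freqs, n=200, population=None):
    return pd.DataFrame(dict(
        allele=allele,
        population=population or [f"p{i}" for i in range(len(years))],
        year=years, freq=freqs, n_chromosomes=n,
    ))


class TestFitSelection:
    def test_constant_frequency_gives_zero_slope(self):
        df = _traj("m", [2018, 2020, 2022, 2024], [0.3, 0.3, 0.3, 0.3], n=10_000)
        fit = fit_selection(df, joint=False)
        row = fit.per_allele.iloc[0]
        assert row["s"] == pytest.approx(0.0, abs=1e-8)
        assert abs(row["z"]) < 1e-6

    def test_noiseless_logistic_recovery(self):
        years = np.array([2017, 2019, 2021, 2023], dtype=float)
        logit = -3 + 0.7 * (years - 2017)
        freqs = 1 / (1 + np.exp(-logit))
        df = _traj("m", years, freqs, n=10**8)
        fit = fit_selection(df, joint=False)
        assert fit.per_allele.iloc[0]["s"] == pytest.approx(0.7, abs=1e-6)

    def test_single_allele_joint_equals_per_allele(self):
        rng = np.random.default_rng(0)
        years = np.repeat([2018, 2020, 2022], 4)
        freqs = np.clip(rng.normal(1 / (1 + np.exp(-(-2 + 0.5 * (years - 2018)))), 0.03), 0.01, 0.99)
        df = _traj("m", years, freqs, n=100)
        fit = fit_selection(df, joint=True)
        assert fit.joint["s"] == pytest.approx(fit.per_allele.iloc[0]["s"], rel=1e-10)
        assert fit.joint["se"] == pytest.approx(fit.per_allele.iloc[0]["se"], rel=1e-10)

    def test_non_estimable_and_separated_flags(self):
        one_year = _traj("a", [2020, 2020], [0.1, 0.2])
        assert fit_selection(one_year, joint=False).per_allele.iloc[0]["status"] == "non-estimable"
        degenerate = _traj("b", [2018, 2020, 2022], [0.0, 0.0, 1.0])
        assert fit_selection(degenerate, joint=False).per_allele.iloc[0]["status"] == "separated"

    def test_wright_fisher_recovery_and_coverage(self):
        # 30 haplodiploid populations under s=0.35/generation; the estimand
        # is the GLM projection of the infinite-N recursion over the same
        # sampling design (the deterministic-recursion oracle)
        gens = np.arange(0, 31, 5)
        years = 2017 + gens / 20.0
        det = simulate.deterministic_trajectory(0.02, 0.35, 0.5, 30)
        truth = fit_selection(
            _traj("m", years, det[gens], n=10**7, population=["d"] * len(gens)),
            joint=False,
        ).per_allele.iloc[0]["s"]
        rng = np.random.default_rng(5)
        est, covered = [], 0
        n_chrom = 50
        for i in range(30):
            f = simulate.wright_fisher_frequencies(
                np.array([0.02]), 100_000, 30, s=0.35, h=0.5, rng=rng, full=True
            )[:, 0]
            samp = rng.binomial(n_chrom, f[gens]) / n_chrom
            fit = fit_selection(
                _traj("m", years, samp, n=n_chrom, population=[f"p{i}"] * len(gens)),
                joint=False,
            ).per_allele.iloc[0]
            est.append(fit["s"])
            if fit["s"] - 1.96 * fit["se"] <= truth <= fit["s"] + 1.96 * fit["se"]:
                covered += 1
        assert abs(np.median(est) / truth - 1) < 0.15
        assert covered / 30 >= 0.90
        # the per-generation conversion is the per-year slope / 20
        assert fit["s_per_generation"] == pytest.approx(fit["s"] / 20)


class TestRecurrentMutation:
    def test_theta_and_ne_worked_example(self):
        est = recurrent_mutation_estimate(2.7, 7, 20, 2.8e-9, 3)
        assert round(est.theta, 4) == pytest.approx(0.0193)
        assert est.ne_implied == pytest.approx(2.29e6, rel=0.01)

    def test_zero_mutations(self):
        est = recurrent_mutation_estimate(0.0, 7, 20, 2.8e-9, 3)
        assert est.theta == 0.0 and est.ne_implied == 0.0

    def test_mu_inverse_proportionality(self):
        a = recurrent_mutation_estimate(2.7, 7, 20, 2.8e-9, 3)
        b = recurrent_mutation_estimate(2.7, 7, 20, 5.6e-9, 3)
        assert b.ne_implied == pytest.approx(a.ne_implied / 2)

    def test_dimensional_identity(self):
        est = recurrent_mutation_estimate(3.1, 4, 20, 2.8e-9, 3)
        assert est.theta * est.years_elapsed * est.gens_per_year == pytest.approx(3.1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            recurrent_mutation_estimate(2.7, 0, 20, 2.8e-9, 3)
        with pytest.raises(ValueError):
            recurrent_mutation_estimate(-1, 7, 20, 2.8e-9, 3)


class TestSurvivalAssociation:
    def test_perfect_linear_relation(self):
        x = np.linspace(0.05, 0.95, 12)
        df = pd.DataFrame(dict(survival=x, predominant=x))
        results, _ = survival_association(df, metrics=("predominant",))
        r = results[0]
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(1.0)

    def test_r_squared_equals_squared_pearson(self, rng):
        x = rng.uniform(0, 1, 15)
        y = np.clip(0.5 * x + rng.normal(0, 0.1, 15), 0, 1)
        df = pd.DataFrame(dict(survival=y, predominant=x))
        results, _ = survival_association(df, metrics=("predominant",))
        assert results[0].r_squared == pytest.approx(pearsonr(x, y)[0] ** 2)

    def test_permutation_null_mean_r_squared(self, rng):
        # with an uninformative predictor E[R^2] = 1/(n-1)
        n = 20
        x = rng.uniform(0, 1, n)
        y = rng.uniform(0, 1, n)
        r2 = []
        for _ in range(1000):
            perm = rng.permutation(y)
            df = pd.DataFrame(dict(survival=perm, predominant=x))
            results, _ = survival_association(df, metrics=("predominant",))
            r2.append(results[0].r_squared)
        assert abs(np.mean(r2) - 1 / (n - 1)) < 0.015

    def test_generative_metric_wins(self, rng):
        # survival generated as the any-carrier frequency plus noise
        # (sigma = 0.1) across 40 populations segregating three mutations:
        # that metric must attain the top R^2 in at least 90% of replicates
        wins, n_pop = 0, 40
        for _ in range(200):
            p = rng.uniform(0.0, 0.6, (n_pop, 3))
            any_carrier = 1 - np.prod((1 - p) ** 2, axis=1)
            hom = 1 - np.prod(1 - p**2, axis=1)
            pred = p.max(axis=1)
            surv = np.clip(any_carrier + rng.normal(0, 0.1, n_pop), 0, 1)
            df = pd.DataFrame(dict(survival=surv, predominant=pred,
                                   any_carrier=any_carrier, homozygous=hom))
            results, _ = survival_association(df)
            best = max(results, key=lambda r: r.r_squared)
            wins += best.metric == "any_carrier"
        assert wins / 200 >= 0.90

    def test_multivariate_fit_reports_coefficients(self, rng):
        cols = ["I260T", "I260V", "D116G", "R119C", "R119L"]
        freq = rng.uniform(0, 0.5, (25, 5))
        surv = np.clip(freq @ np.array([0.8, 0.9, 0.7, 0.2, 0.1])
                       + rng.normal(0, 0.05, 25), 0, 1)
        df = pd.DataFrame(freq, columns=cols)
        df["survival"] = surv
        df["predominant"] = freq.max(axis=1)
        results, multi = survival_association(df, metrics=("predominant",),
                                              mutation_columns=cols)
        assert list(multi["term"]) == ["intercept", *cols]
        assert 0 <= multi.attrs["r_squared"] <= 1

    def test_constant_predictor_flagged(self):
        df = pd.DataFrame(dict(survival=[0.1, 0.5, 0.9], predominant=[0.3, 0.3, 0.3]))
        results, _ = survival_association(df, metrics=("predominant",))
        assert results[0].status == "constant-predictor"
        assert np.isnan(results[0].r_squared)


class TestIsolationByDistance:
    @staticmethod
    def _coords(n, rng=None, shuffle=False):
        lat = np.linspace(22, 45, n)
        lon = np.linspace(100, 125, n)
        if shuffle:
            order = rng.permutation(n)
            lat, lon = lat[order], lon[order]
        return pd.DataFrame(dict(lat=lat, lon=lon),
                            index=[f"p{i}" for i in range(n)])

    def test_hudson_fst_basics(self):
        assert hudson_fst([0.5], [0.5]) == pytest.approx(0.0)
        assert hudson_fst([0.0], [1.0]) == pytest.approx(1.0)
        assert hudson_fst([0.0], [0.0]) == 0.0

    def test_perfect_cline_is_significant(self):
        n = 12
        freqs = pd.DataFrame(dict(a=np.linspace(0.02, 0.98, n)),
                             index=[f"p{i}" for i in range(n)])
        out = resistance_fst_ibd(freqs, self._coords(n), permutations=999, seed=11)
        assert out["p_value"] <= 0.005

    def test_type_one_error_calibration(self):
        # frequencies shuffled against geography: the permutation test must
        # hold its nominal level (<= 0.07 at alpha = 0.05 over 1000 nulls)
        rng = np.random.default_rng(21)
        n, hits = 10, 0
        reps = 1000
        for i in range(reps):
            freqs = pd.DataFrame(
                dict(a=rng.uniform(0.05, 0.95, n), b=rng.uniform(0.05, 0.95, n)),
                index=[f"p{j}" for j in range(n)],
            )
            out = resistance_fst_ibd(freqs, self._coords(n, rng, shuffle=True),
                                     permutations=99, seed=int(rng.integers(2**31)))
            hits += out["p_value"] <= 0.05
        assert hits / reps <= 0.07

    def test_degenerate_inputs_rejected(self):
        freqs = pd.DataFrame(dict(a=[0.1, 0.2, 0.3, 0.4]),
                             index=["p0", "p1", "p2", "p3"])
        same = pd.DataFrame(dict(lat=[30.0] * 4, lon=[110.0] * 4), index=freqs.index)
        with pytest.raises(ValueError):
            resistance_fst_ibd(freqs, same)
        with pytest.raises(ValueError):
            resistance_fst_ibd(freqs.iloc[:3], self._coords(3))
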