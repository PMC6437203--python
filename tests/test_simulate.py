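import numpy as np
import pytest

from _oracles import weir_cockerham_fst
from seabream import simulate
from seabream.popgen import allele_counts
from seabream.stocking import cumulative_recapture_rate


def small_config(**kw):
    base = dict(
        seed=0, n_populations=4, sample_sizes=(30,) * 4, n_loci=3,
        alleles_per_locus=(6, 6, 6), target_fst=0.05,
    )
    base.update(kw)
    return simulate.SimulationConfig(**base)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(target_fst=1.0),
            dict(target_fst=-0.1),
            dict(sample_sizes=(30, 30, 30, 0)),
            dict(mixture_proportions=(0.5, 0.4)),
            dict(decay_rate=-1.0),
            dict(noise_sd=-0.1),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)


class TestBaselineFrequencies:
    def test_zero_fst_degenerates_to_shared_mean(self):
        freqs = simulate.simulate_baseline_frequencies(small_config(target_fst=0.0))
        for locus in freqs.loci:
            mat = freqs.frequencies[locus].to_numpy()
            assert np.allclose(mat, mat[0])

    def test_rows_normalize_to_one(self):
        freqs = simulate.simulate_baseline_frequencies(small_config())
        for locus in freqs.loci:
            assert np.allclose(freqs.frequencies[locus].sum(axis=1), 1.0, atol=1e-9)

    def test_wright_fst_calibration_against_weir_cockerham(self):
        # the Dirichlet concentration (1-F)/F should make the realized
        # multilocus Weir-Cockerham estimate average the target; 50
        # replicate island worlds, independently coded estimator
        target = 0.01
        vals = []
        for rep in range(50):
            cfg = simulate.SimulationConfig(
                seed=9000 + rep, n_populations=20, sample_sizes=(30,) * 20,
                n_loci=5, alleles_per_locus=(30,) * 5, target_fst=target,
            )
            freqs = simulate.simulate_baseline_frequencies(cfg)
            table = simulate.simulate_genotypes(freqs, [30] * 20, 9000 + rep)
            vals.append(weir_cockerham_fst(table))
        vals = np.asarray(vals)
        mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - target) < 3 * mc_se

    def test_biallelic_mean_frequency_moment(self):
        # with pbar fixed at (0.5, 0.5) the Dirichlet draws must average 0.5
        draws = []
        for rep in range(250):
            cfg = simulate.SimulationConfig(
                seed=7000 + rep, n_populations=4, sample_sizes=(5,) * 4,
                n_loci=1, alleles_per_locus=(2,), target_fst=0.1,
            )
            freqs = simulate.simulate_baseline_frequencies(
                cfg, mean_frequencies=[np.array([0.5, 0.5])]
            )
            draws.extend(freqs.frequencies["Locus1"].iloc[:, 0].tolist())
        draws = np.asarray(draws)  # 1000 population draws
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_reproducible_per_seed(self):
        a = simulate.simulate_baseline_frequencies(small_config(seed=42))
        b = simulate.simulate_baseline_frequencies(small_config(seed=42))
        c = simulate.simulate_baseline_frequencies(small_config(seed=43))
        for locus in a.loci:
            assert a.frequencies[locus].equals(b.frequencies[locus])
        assert not a.frequencies["Locus1"].equals(c.frequencies["Locus1"])


class TestGenotypes:
    def test_fixed_locus_yields_homozygotes(self):
        import pandas as pd
        from seabream.popgen import AlleleFrequencyTable

        f = pd.DataFrame([[1.0, 0.0]], index=["P1"], columns=[1, 2])
        freqs = AlleleFrequencyTable({"L1": f})
        g = simulate.simulate_genotypes(freqs, [50], seed=0)
        assert (g.genotypes == 1).all()

    def test_heterozygote_fraction_under_hwe(self):
        import pandas as pd
        from seabream.popgen import AlleleFrequencyTable

        f = pd.DataFrame([[0.5, 0.5]], index=["P1"], columns=[1, 2])
        freqs = AlleleFrequencyTable({"L1": f})
        g = simulate.simulate_genotypes(freqs, [5000], seed=1)
        het = (g.genotypes[:, 0, 0] != g.genotypes[:, 0, 1]).mean()
        se = np.sqrt(0.5 * 0.5 / 5000)
        assert abs(het - 0.5) < 3 * se

    def test_ploidy_conservation(self):
        cfg = small_config()
        freqs = simulate.simulate_baseline_frequencies(cfg)
        g = simulate.simulate_genotypes(freqs, [30] * 4, 0)
        ft = allele_counts(g)
        for locus in ft.loci:
            assert (
                ft.counts[locus].sum(axis=1) == 2 * 30
            ).all()

    def test_nonpositive_sample_size_rejected(self):
        freqs = simulate.simulate_baseline_frequencies(small_config())
        with pytest.raises(ValueError):
            simulate.simulate_genotypes(freqs, [30, 30, 0, 30], 0)


class TestMixture:
    def test_degenerate_proportions_single_origin(self):
        freqs = simulate.simulate_baseline_frequencies(small_config(
            n_populations=2, sample_sizes=(40, 40)))
        base = simulate.simulate_genotypes(freqs, [40, 40], 0)
        _, origins = simulate.simulate_mixture(base, (1.0, 0.0), 50, seed=0)
        assert (origins == "P1").all()

    def test_origin_counts_match_proportions(self):
        freqs = simulate.simulate_baseline_frequencies(small_config(
            n_populations=2, sample_sizes=(40, 40)))
        base = simulate.simulate_genotypes(freqs, [40, 40], 0)
        _, origins = simulate.simulate_mixture(base, (0.4, 0.6), 10_000, seed=1)
        frac = (origins == "P1").mean()
        se = np.sqrt(0.4 * 0.6 / 10_000)
        assert abs(frac - 0.4) < 3 * se

    def test_empty_mixture_allowed(self):
        freqs = simulate.simulate_baseline_frequencies(small_config(
            n_populations=2, sample_sizes=(40, 40)))
        base = simulate.simulate_genotypes(freqs, [40, 40], 0)
        table, origins = simulate.simulate_mixture(base, (0.5, 0.5), 0, seed=0)
        assert table.n_individuals == 0
        assert origins.size == 0

    def test_proportion_length_mismatch_rejected(self):
        freqs = simulate.simulate_baseline_frequencies(small_config())
        base = simulate.simulate_genotypes(freqs, [30] * 4, 0)
        with pytest.raises(ValueError):
            simulate.simulate_mixture(base, (0.5, 0.5), 10, seed=0)


class TestReleaseCohorts:
    def test_no_noise_no_decay_identical_rates(self):
        cfg = small_config(noise_sd=0.0, decay_rate=0.0, years=10)
        cohorts = simulate.simulate_release_cohorts(cfg)
        rates = cumulative_recapture_rate(cohorts, max_age=8)
        assert np.allclose(rates, rates.iloc[0])

    def test_no_noise_log_rates_exactly_linear(self):
        cfg = small_config(noise_sd=0.0, decay_rate=0.14, years=12)
        cohorts = simulate.simulate_release_cohorts(cfg)
        rates = cumulative_recapture_rate(cohorts, max_age=8)
        logr = np.log(rates.to_numpy())
        slopes = np.diff(logr)
        assert np.allclose(slopes, -0.14, atol=1e-12)
        assert rates.iloc[0] == pytest.approx(cfg.initial_recapture)

    def test_true_rates_recorded(self):
        cfg = small_config(noise_sd=0.2, decay_rate=0.14, years=12)
        cohorts = simulate.simulate_release_cohorts(cfg)
        rates = cumulative_recapture_rate(cohorts, max_age=8)
        assert np.allclose(rates.to_numpy(), cohorts.table["true_rate"].to_numpy())


class TestCatchCovariates:
    def test_noise_free_response_is_exact_linear_combination(self):
        cfg = small_config(regression_noise_sd=0.0, years=27)
        df = simulate.simulate_catch_covariates(cfg)
        beta = df.attrs["true_coefficients"]
        pred = (
            beta["intercept"]
            + beta["hijiki"] * df["hijiki"]
            + beta["effort"] * df["effort"]
            + beta["sst"] * df["sst"]
            + beta["ph"] * df["ph"]
        )
        assert np.allclose(df["wild_catch"], pred)

    def test_noise_free_ols_recovers_coefficients(self):
        from seabream.regression import ols_fit

        cfg = small_config(regression_noise_sd=0.0, years=27)
        df = simulate.simulate_catch_covariates(cfg)
        res = ols_fit(df["wild_catch"], df[["hijiki", "effort", "sst", "ph"]])
        beta = df.attrs["true_coefficients"]
        assert res.params["const"] == pytest.approx(beta["intercept"], abs=1e-6)
        for name in ["hijiki", "effort", "sst", "ph"]:
            assert res.params[name] == pytest.approx(beta[name], abs=1e-8)

    def test_stream_separation_is_stable(self):
        # the covariate stream must not shift when another generator is
        # invoked in between (counter-based fan-out)
        cfg = small_config(years=10)
        a = simulate.simulate_catch_covariates(cfg)
        simulate.simulate_release_cohorts(cfg)
        b = simulate.simulate_catch_covariates(cfg)
        assert a.equals(b)
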