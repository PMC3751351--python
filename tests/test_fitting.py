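"""Staged maximum-likelihood fitting: peak detection, recovery, heuristics."""

import numpy as np
import pytest

from kmerspec import (
    FitConfig,
    InsufficientCoverageError,
    KmerSpectrum,
    MixtureModel,
    ReadSimParams,
    SpectrumMixture,
    SyntheticGenomeSpec,
    fit_spectrum,
    generate_genome,
    genome_size_estimate,
    initial_peak_estimate,
    model_expectation,
    recovery_experiment,
    simulate_reads,
    spectrum_log_likelihood,
)


def make_spectrum(pairs):
    xs, zs = zip(*pairs)
    return KmerSpectrum(np.array(xs), np.array(zs))


class TestInitialPeakEstimate:
    def test_peak_after_error_valley(self):
        spectrum = make_spectrum(
            [(1, 10**6), (2, 10**5), (3, 10**3), (54, 10**3), (55, 5 * 10**3), (56, 10**3)]
        )
        assert initial_peak_estimate(spectrum) == 55

    def test_tie_broken_toward_smaller_abundance(self):
        # transformed maxima 50*6 == 60*5 == 300
        spectrum = make_spectrum([(1, 1000), (2, 100), (50, 6), (60, 5)])
        assert initial_peak_estimate(spectrum) == 50

    def test_monotone_spectrum_raises_low_coverage(self):
        spectrum = make_spectrum([(1, 1000), (2, 300), (3, 80), (4, 10)])
        with pytest.raises(InsufficientCoverageError):
            initial_peak_estimate(spectrum)

    def test_no_error_spike_returns_global_argmax(self):
        spectrum = make_spectrum([(10, 5), (20, 50), (30, 10)])
        assert initial_peak_estimate(spectrum) == 20

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            initial_peak_estimate(KmerSpectrum(np.empty(0, int), np.empty(0, int)))

    def test_simulated_depth_matches_expected_kmer_coverage(self):
        genome, _ = generate_genome(SyntheticGenomeSpec(blocks=[(1, 100_000)], seed=7))
        depth, L, k = 50.0, 76, 21
        reads = simulate_reads(
            genome, ReadSimParams(read_length=L, depth=depth, error_rate=0.0, seed=8)
        )
        mix = SpectrumMixture.from_sequences(reads, k=k)
        c0 = initial_peak_estimate(mix.spectrum)
        expected = depth * (L - k + 1) / L
        assert abs(c0 - expected) / expected < 0.10


class TestFitSpectrum:
    def test_noiseless_round_trip_recovers_c_and_genome_size(
        self, reference_mixture, noiseless_spectrum
    ):
        results = fit_spectrum(noiseless_spectrum, max_copy=30)
        true_size = genome_size_estimate(reference_mixture)
        assert abs(results.c - reference_mixture.c) / reference_mixture.c < 0.01
        assert abs(results.genome_size - true_size) / true_size < 0.01
        # the rrn-like 7-copy class is individually resolved
        assert results.a[6] == pytest.approx(reference_mixture.a[6], rel=0.05)

    def test_single_component_constraint(self):
        genome, _ = generate_genome(SyntheticGenomeSpec(blocks=[(1, 30_000)], seed=3))
        reads = simulate_reads(genome, ReadSimParams(depth=80, error_rate=0.0, seed=4))
        results = SpectrumMixture.from_sequences(reads, max_components=1).fit()
        assert results.model.n_components == 1
        assert results.a[0] > 0
        assert abs(results.genome_size - len(genome)) / len(genome) < 0.02

    def test_manual_cutoff_overrides_half_peak_rule(self, noiseless_spectrum):
        manual = 40
        results = fit_spectrum(noiseless_spectrum, min_abundance=manual)
        assert results.model.x_min == manual

    def test_low_abundance_bins_do_not_change_estimate(self, noiseless_spectrum):
        baseline = fit_spectrum(noiseless_spectrum, max_copy=30)
        # inject an arbitrarily large error spike strictly below x_min
        spike = {1: 10**8, 2: 10**7, 3: 10**6}
        merged = dict(zip(noiseless_spectrum.abundance, noiseless_spectrum.count))
        merged.update(spike)
        xs = np.array(sorted(merged))
        polluted = KmerSpectrum(xs, np.array([merged[x] for x in xs]))
        res = fit_spectrum(polluted, max_copy=30)
        assert res.model.x_min == baseline.model.x_min
        assert res.genome_size == baseline.genome_size
        assert res.excluded_low_instances >= sum(x * z for x, z in spike.items())

    def test_scaling_counts_scales_coefficients_only(self, noiseless_spectrum):
        base = fit_spectrum(noiseless_spectrum, max_copy=10)
        scaled_spec = KmerSpectrum(
            noiseless_spectrum.abundance, noiseless_spectrum.count * 3
        )
        scaled = fit_spectrum(scaled_spec, max_copy=10)
        assert scaled.c == pytest.approx(base.c, rel=0.01)
        assert scaled.s == pytest.approx(base.s, rel=0.05, abs=1e-3)
        assert scaled.unique_kmers == pytest.approx(3 * base.unique_kmers, rel=0.01)
        assert scaled.genome_size == pytest.approx(3 * base.genome_size, rel=0.01)

    def test_stagewise_likelihood_never_deteriorates(self, noiseless_spectrum):
        results = fit_spectrum(noiseless_spectrum, max_copy=12)
        spec = noiseless_spectrum
        numbered = [st for st in results.stages if st["stage"] != "final"]
        for prev, cur in zip(numbered, numbered[1:]):
            lo, hi = cur["x_range"]
            cur_model = MixtureModel(c=cur["c"], s=cur["s"], a=cur["a"])
            prev_a = list(prev["a"]) + [0.0] * (len(cur["a"]) - len(prev["a"]))
            prev_model = MixtureModel(c=prev["c"], s=prev["s"], a=prev_a)
            ll_cur = spectrum_log_likelihood(spec, cur_model, (lo, hi))
            ll_prev = spectrum_log_likelihood(spec, prev_model, (lo, hi))
            assert ll_cur >= ll_prev - 1e-6 * abs(ll_prev)

    def test_fit_is_deterministic(self, noiseless_spectrum):
        r1 = fit_spectrum(noiseless_spectrum, max_copy=8)
        r2 = fit_spectrum(noiseless_spectrum, max_copy=8)
        assert np.array_equal(r1.params, r2.params)
        assert r1.llf == r2.llf

    def test_empty_spectrum_rejected(self):
        empty = KmerSpectrum(np.empty(0, int), np.empty(0, int))
        with pytest.raises(ValueError):
            SpectrumMixture(empty).fit()

    def test_size_recovery_accurate_over_many_replicates(self):
        """At 60x the genome-size error stays small across independent
        simulated datasets (median well under 3%)."""
        errs = []
        for seed in range(10):
            spec = SyntheticGenomeSpec(
                blocks=[(1, 93_000), (7, 1_000)], seed=100 + seed
            )
            rep = recovery_experiment(
                spec,
                ReadSimParams(depth=60.0, error_rate=0.01, seed=200 + seed),
            )
            assert rep["status"] == "ok"
            errs.append(abs(rep["genome_size_rel_error"]))
        assert np.median(errs) < 0.03


@pytest.fixture(scope="module")
def results(noiseless_spectrum):
    return fit_spectrum(noiseless_spectrum, max_copy=10)


class TestResultsObject:
    def test_params_layout(self, results):
        assert results.params.shape == (2 + results.model.n_components,)
        assert results.params[0] == results.c
        assert results.params[1] == results.s

    def test_predict_matches_model_expectation(self, results, noiseless_spectrum):
        x = np.arange(30, 80)
        assert np.allclose(
            results.predict(x), model_expectation(x, results.model)
        )

    def test_summary_reports_key_quantities(self, results):
        text = results.summary()
        assert "Genome size" in text and "Overdispersion" in text
        assert f"{results.c0}" in text

    def test_json_round_trip(self, results, tmp_path):
        import json

        path = tmp_path / "fit.json"
        results.to_json(str(path))
        payload = json.loads(path.read_text())
        assert payload["c"] == results.c
        assert payload["genome_size"] == results.genome_size
        assert len(payload["stages"]) == len(results.stages)

    def test_reliability_flag_tracks_coverage(self, results):
        assert results.reliable  # c ~ 50 here
        shallow = MixtureModel(c=5.0, s=0.1, a=[100.0])
        low = results.__class__(
            model=shallow,
            llf=-1.0,
            c0=5,
            x_range=(2, 10),
            stages=[],
            spectrum=results.spectrum,
            config=FitConfig(),
        )
        assert not low.reliable
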