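"""Spectral estimators and exact number/rate spectrum conversions."""

import numpy as np
import pytest

from ratespec.datatypes import (
    FrequencySpectrum,
    RateTCF,
    SpectrumKind,
    StationaryProduct,
    TrajectoryEnsemble,
)
from ratespec.spectra import (
    estimate_fspn,
    estimate_ktl_asymptote,
    estimate_tcf,
    extract_fsrr,
    fspn_from_fsrr,
    heterogeneous_translation_relation,
    lorentzian_background,
    mrna_spectrum_from_protein,
    rate_tcf_from_synchronized_counting,
    sampled_lorentzian_background,
    spectrum_from_tcf,
    transcription_rate_spectrum_from_mrna,
)


def _grid_spectrum(values, omegas=None, kind=SpectrumKind.FSPN):
    w = np.linspace(0.1, 10.0, values.size) if omegas is None else omegas
    return FrequencySpectrum(omegas=w, values=values, kind=kind)


# ---------------------------------------------------------------------------
# periodogram estimator


def test_constant_trajectories_have_zero_spectrum():
    """A noiseless constant count carries no fluctuation power at omega > 0."""
    ens = TrajectoryEnsemble(counts=np.full((3, 64), 7, dtype=np.int64), dt=0.5)
    spec = estimate_fspn(ens)
    assert np.allclose(spec.values, 0.0, atol=1e-24)
    assert 0.0 not in spec.omegas


def test_pure_tone_power_lands_in_its_bin():
    """A sampled cosine concentrates periodogram mass in the matching bin."""
    n, k0, amp = 256, 8, 40
    j = np.arange(n)
    z = 100 + np.round(amp * np.cos(2 * np.pi * k0 * j / n)).astype(np.int64)
    ens = TrajectoryEnsemble(counts=z[None, :], dt=0.1)
    spec = estimate_fspn(ens)
    t_seg = n * 0.1
    # bins are omega_k = 2 pi k / T_seg, k = 1..n/2 -> tone sits at index k0-1
    assert spec.omegas[k0 - 1] == pytest.approx(2 * np.pi * k0 / t_seg)
    assert spec.values[k0 - 1] / spec.values.sum() > 0.95


def test_periodogram_bins_and_dc_exclusion(poisson_ensemble):
    spec = estimate_fspn(poisson_ensemble)
    t_seg = poisson_ensemble.n_points * poisson_ensemble.dt
    assert spec.omegas[0] == pytest.approx(2 * np.pi / t_seg)
    assert spec.values.size == poisson_ensemble.n_points // 2
    assert spec.meta["stderr"].shape == spec.values.shape


def test_poisson_spectrum_matches_lorentzian(poisson_ensemble, poisson_stat):
    """Poisson birth-death counts follow S_z0 = 2<R>/(omega^2 + gamma^2)."""
    spec = estimate_fspn(poisson_ensemble)
    ref = lorentzian_background(poisson_stat, spec.omegas)
    band = (spec.omegas >= 0.1) & (spec.omegas <= 10.0)
    ratio = spec.values[band] / ref.values[band]
    assert abs(ratio.mean() - 1.0) < 0.03


def test_welch_segments_reduce_variance(poisson_ensemble):
    whole = estimate_fspn(poisson_ensemble)
    seg = estimate_fspn(poisson_ensemble, segment_length=50.0)
    assert seg.meta["n_segments"] == 4 * whole.meta["n_segments"]
    # compare stderr at comparable frequencies (every 4th bin of the long run)
    assert np.nanmedian(seg.meta["stderr"]) < np.nanmedian(whole.meta["stderr"][3::4])


def test_estimator_input_validation():
    ens = TrajectoryEnsemble(counts=np.zeros((2, 8), dtype=np.int64), dt=0.1)
    with pytest.raises(ValueError):
        estimate_fspn(ens)
    long_ens = TrajectoryEnsemble(counts=np.zeros((2, 64), dtype=np.int64), dt=0.1)
    with pytest.raises(ValueError):
        estimate_fspn(long_ens, segment_length=100.0)


# ---------------------------------------------------------------------------
# TCF estimator and its transform


def test_tcf_lag_zero_is_count_variance(poisson_ensemble):
    tcf = estimate_tcf(poisson_ensemble, max_lag=5.0)
    dz = poisson_ensemble.counts - poisson_ensemble.counts.mean()
    assert tcf.values[0] == pytest.approx((dz**2).mean(), rel=1e-12)
    assert tcf.lags[0] == 0.0


def test_poisson_count_tcf_decays_exponentially(poisson_ensemble):
    """Birth-death counts decorrelate as <z> e^{-gamma t}."""
    tcf = estimate_tcf(poisson_ensemble, max_lag=4.0)
    mean_z = poisson_ensemble.counts.mean()
    ref = mean_z * np.exp(-tcf.lags)
    err = np.abs(tcf.values - ref)
    assert err.max() < 0.1  # absolute scale: variance is ~2


def test_exponential_tcf_transforms_to_lorentzian():
    lags = np.arange(0, 20.0, 0.01)
    tcf = RateTCF(lags=lags, values=np.exp(-lags), mean_rate=1.0)
    spec = spectrum_from_tcf(tcf, window_T=200.0)
    band = spec.omegas <= 20.0
    ref = 2.0 / (spec.omegas[band] ** 2 + 1.0)
    assert np.allclose(spec.values[band], ref, rtol=2e-3, atol=1e-5)


def test_undecayed_tcf_is_flagged():
    lags = np.linspace(0, 1.0, 50)
    tcf = RateTCF(lags=lags, values=np.exp(-0.01 * lags), mean_rate=1.0)
    with pytest.warns(UserWarning, match="not decayed"):
        spec = spectrum_from_tcf(tcf, window_T=10.0)
    assert spec.meta["tcf_not_decayed"] is True


# ---------------------------------------------------------------------------
# exact conversions


def test_fsrr_round_trip_is_identity(rng):
    """extract_fsrr inverts fspn_from_fsrr to machine precision."""
    w = np.geomspace(0.05, 50.0, 300)
    stat = StationaryProduct.from_mean_rate(2.0, gamma=0.7)
    fsrr = FrequencySpectrum(
        omegas=w, values=rng.normal(0.0, 1.0, w.size), kind=SpectrumKind.FSRR
    )
    back = extract_fsrr(fspn_from_fsrr(fsrr, stat), stat)
    assert np.allclose(back.values, fsrr.values, rtol=1e-12, atol=1e-12)


def test_sampled_background_matches_windowed_lag_sum():
    """Closed form equals the brute-force triangular-windowed lag sum."""
    stat = StationaryProduct.from_mean_rate(2.0, gamma=1.0)
    dt, n = 0.05, 4000
    w = 2 * np.pi * np.array([5, 100, 1000, 1999]) / (n * dt)
    spec = sampled_lorentzian_background(stat, w, dt, n * dt)
    m = np.arange(1, n)
    var = stat.mean_rate / stat.gamma
    brute = [
        dt * var * (1 + 2 * np.sum((1 - m / n) * np.exp(-m * dt) * np.cos(wi * m * dt)))
        for wi in w
    ]
    assert np.allclose(spec.values, brute, rtol=1e-12)


def test_sampled_background_has_continuous_limit():
    """Fine sampling and a long window recover the ideal Lorentzian."""
    stat = StationaryProduct.from_mean_rate(2.0, gamma=1.0)
    w = np.geomspace(0.2, 5.0, 20)
    fine = sampled_lorentzian_background(stat, w, dt=1e-3, window_T=5000.0)
    ideal = lorentzian_background(stat, w)
    assert np.allclose(fine.values, ideal.values, rtol=1e-3)


def test_sampled_background_predicts_poisson_periodogram(poisson_ensemble):
    """Near Nyquist the measured Poisson periodogram follows the sampled
    background (aliasing + window bias), not the ideal Lorentzian."""
    spec = estimate_fspn(poisson_ensemble)
    stat = StationaryProduct.from_mean_count(
        float(poisson_ensemble.counts.mean()), 1.0
    )
    sampled = sampled_lorentzian_background(
        stat, spec.omegas, spec.meta["dt"], spec.meta["T"]
    )
    ideal = lorentzian_background(stat, spec.omegas)
    band = spec.omegas >= 0.5 * spec.omegas[-1]
    err_sampled = abs(spec.values[band].mean() / sampled.values[band].mean() - 1)
    err_ideal = abs(spec.values[band].mean() / ideal.values[band].mean() - 1)
    assert err_sampled < 0.02
    assert err_ideal > 0.5  # aliasing more than doubles the true floor here


def test_extract_fsrr_background_choice_is_recorded(poisson_ensemble):
    """Periodogram inputs get the sampled background; constructed spectra
    keep the ideal one so the conversion stays algebraically invertible."""
    stat = StationaryProduct.from_mean_count(
        float(poisson_ensemble.counts.mean()), 1.0
    )
    from_sim = extract_fsrr(estimate_fspn(poisson_ensemble), stat)
    assert from_sim.meta["background"] == "sampled"
    w = np.geomspace(0.1, 10.0, 30)
    constructed = extract_fsrr(lorentzian_background(stat, w), stat)
    assert constructed.meta["background"] == "ideal"
    assert np.allclose(constructed.values, 0.0, atol=1e-12)


def test_doubled_background_gives_flat_rate_spectrum():
    """S_z = 2 S_z0 maps to the constant S_R = 2<R>."""
    stat = StationaryProduct.from_mean_rate(3.0, gamma=1.5)
    w = np.geomspace(0.1, 20.0, 50)
    fspn = FrequencySpectrum(
        omegas=w, values=2 * lorentzian_background(stat, w).values,
        kind=SpectrumKind.FSPN,
    )
    fsrr = extract_fsrr(fspn, stat)
    assert np.allclose(fsrr.values, 2.0 * stat.mean_rate, rtol=1e-12)


def test_negative_input_bins_are_counted():
    stat = StationaryProduct.from_mean_rate(1.0, gamma=1.0)
    fspn = _grid_spectrum(np.array([1.0, -0.5, 2.0, -0.1]))
    out = extract_fsrr(fspn, stat)
    assert out.meta["n_negative_input_bins"] == 2


def test_kind_mismatch_rejected():
    stat = StationaryProduct.from_mean_rate(1.0, gamma=1.0)
    fsrr = _grid_spectrum(np.ones(5), kind=SpectrumKind.FSRR)
    with pytest.raises(ValueError, match="expected spectrum of kind"):
        extract_fsrr(fsrr, stat)


def test_cascade_deconvolution_round_trip():
    """Protein spectrum built from a known mRNA spectrum deconvolves exactly."""
    w = np.geomspace(0.01, 5.0, 200)
    gamma_m, gamma_p, k_tl, mean_m = 0.2, 0.05, 5.0, 10.0
    s_m = FrequencySpectrum(
        omegas=w,
        values=2 * gamma_m * mean_m / (w**2 + gamma_m**2) * (1 + 0.3 * np.cos(w)),
        kind=SpectrumKind.FSPN,
    )
    translation = StationaryProduct.from_mean_rate(k_tl * mean_m, gamma_p)
    s_p = FrequencySpectrum(
        omegas=w,
        values=(2 * translation.mean_rate + k_tl**2 * s_m.values)
        / (w**2 + gamma_p**2),
        kind=SpectrumKind.FSPN,
    )
    recovered = mrna_spectrum_from_protein(s_p, translation, k_tl)
    assert recovered.kind is SpectrumKind.FSPN
    assert np.allclose(recovered.values, s_m.values, rtol=1e-12)

    # second stage: transcription-rate spectrum from the mRNA spectrum
    transcription = StationaryProduct.from_mean_count(mean_m, gamma_m)
    s_rtx = transcription_rate_spectrum_from_mrna(recovered, transcription)
    expected = (w**2 + gamma_m**2) * s_m.values - 2 * transcription.mean_rate
    assert np.allclose(s_rtx.values, expected, rtol=1e-12)


def test_ktl_asymptote_exact_on_constructed_spectrum():
    """S_p = S_p0 (1 + k_TL gamma_m / omega^2) returns k_TL exactly."""
    w = np.geomspace(1.0, 4.0, 40)
    gamma_m, gamma_p, k_tl = 0.2, 0.05, 5.0
    translation = StationaryProduct.from_mean_rate(50.0, gamma_p)
    sp0 = 2 * translation.mean_rate / (w**2 + gamma_p**2)
    fspn = FrequencySpectrum(
        omegas=w, values=sp0 * (1 + k_tl * gamma_m / w**2), kind=SpectrumKind.FSPN
    )
    est = estimate_ktl_asymptote(fspn, translation, gamma_m, (1.0, 4.0))
    assert est.value == pytest.approx(k_tl, rel=1e-12)
    assert est.n_bins == 40


def test_ktl_asymptote_guards():
    w = np.geomspace(1.0, 4.0, 40)
    translation = StationaryProduct.from_mean_rate(50.0, 0.05)
    sp0 = 2 * translation.mean_rate / (w**2 + translation.gamma**2)
    fspn = FrequencySpectrum(omegas=w, values=sp0 * 0.5, kind=SpectrumKind.FSPN)
    with pytest.raises(ValueError, match="negative over more than half"):
        estimate_ktl_asymptote(fspn, translation, 0.2, (1.0, 4.0))
    good = FrequencySpectrum(omegas=w, values=sp0 * 2, kind=SpectrumKind.FSPN)
    with pytest.raises(ValueError, match="fewer than 2"):
        estimate_ktl_asymptote(good, translation, 0.2, (100.0, 200.0))


def test_heterogeneous_translation_scales_with_spread():
    """Static cell-to-cell k_TL spread multiplies the relation by 1 + eta^2."""
    w = np.geomspace(0.01, 1.0, 50)
    s_m = FrequencySpectrum(
        omegas=w, values=1.0 / (w**2 + 0.04), kind=SpectrumKind.FSPN
    )
    base = heterogeneous_translation_relation(s_m, mean_kTL=5.0, eta2_kTL=0.0, mean_m=10.0)
    spread = heterogeneous_translation_relation(s_m, mean_kTL=5.0, eta2_kTL=1.0, mean_m=10.0)
    assert np.allclose(base.values, 5.0 * s_m.values / 20.0, rtol=1e-12)
    assert np.allclose(spread.values, 2.0 * base.values, rtol=1e-12)
    assert base.kind is SpectrumKind.MEAN_SCALED


# ---------------------------------------------------------------------------
# synchronized counting


def test_synchronized_counting_poisson_gives_flat_rate():
    """<n(t)>* = <R> t for a Poisson process -> zero rate fluctuation TCF."""
    t = np.linspace(0, 10, 101)
    tcf = rate_tcf_from_synchronized_counting(t, 2.0 * t, mean_rate=2.0)
    assert np.allclose(tcf.values, 0.0, atol=1e-12)


def test_synchronized_counting_rejects_decreasing_mean():
    t = np.linspace(0, 1, 11)
    n = np.linspace(0, 1, 11).copy()
    n[5] = 0.0
    with pytest.raises(ValueError, match="nondecreasing"):
        rate_tcf_from_synchronized_counting(t, n, mean_rate=1.0)
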