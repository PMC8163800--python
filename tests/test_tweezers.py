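"""Extension-trace filtering, HMM state decomposition, dwells, WLC model."""

import numpy as np
import pytest

from nsf20s import synth
from nsf20s import tweezers as tw


# -- filtering and noise ----------------------------------------------------

def test_median_filter_preserves_constant_and_removes_spike():
    n = 1200
    x = np.full(n, 10.0)
    tr = tw.ExtensionTrace(np.arange(n) / 1200, x, sample_rate=1200)
    out = tw.median_filter(tr, 60.0)
    assert np.allclose(out.extension, 10.0)
    assert out.sample_rate == pytest.approx(60.0)

    x2 = x.copy()
    x2[600] = 500.0  # single-frame spike
    out2 = tw.median_filter(tw.ExtensionTrace(np.arange(n) / 1200, x2, sample_rate=1200), 60.0)
    assert np.allclose(out2.extension, 10.0)


def test_median_filter_noise_reduction_matches_median_statistics():
    """Median of 20 white-noise frames has SD ~ sigma * sqrt(pi/(2*20))."""
    tr = synth.gen_white_noise_trace(sigma=6.0, duration_s=200.0, seed=5)
    out = tw.median_filter(tr, 60.0)
    expected = 6.0 * np.sqrt(np.pi / (2 * 20))
    assert out.extension.std() == pytest.approx(expected, rel=0.1)


def test_median_filter_parameter_validation():
    tr = synth.gen_white_noise_trace(duration_s=1.0, seed=0)
    with pytest.raises(ValueError):
        tw.median_filter(tr, 600.0)  # window of 2 frames
    with pytest.raises(ValueError):
        tw.median_filter(tr, 2400.0)


def test_allan_deviation_white_noise_closed_form():
    """AD(tau) = sigma / sqrt(f_s * tau) for white noise, within 5% where
    the estimator is well averaged."""
    tr = synth.gen_white_noise_trace(sigma=6.0, duration_s=60.0, seed=3)
    taus, dev = tw.allan_deviation(tr)
    pred = 6.0 / np.sqrt(1200 * taus)
    well_averaged = taus <= 60.0 / 128
    assert np.all(np.abs(dev[well_averaged] / pred[well_averaged] - 1) < 0.05)


def test_allan_deviation_detects_drift_and_zero_signal():
    n = 24000
    t = np.arange(n) / 1200
    drift = tw.ExtensionTrace(t, 5.0 * t, sample_rate=1200)
    taus, dev = tw.allan_deviation(drift)
    assert dev[-1] > dev[len(dev) // 2]  # grows at long averaging times
    zero = tw.ExtensionTrace(t, np.zeros(n), sample_rate=1200)
    _, dz = tw.allan_deviation(zero)
    assert np.allclose(dz, 0.0)


# -- HMM --------------------------------------------------------------------

def test_hmm_exact_on_noiseless_square_wave():
    n = 2400
    x = np.where((np.arange(n) // 120) % 2 == 0, 0.0, 20.0)
    x += np.random.default_rng(0).normal(0, 0.01, n)  # break exact ties
    tr = tw.ExtensionTrace(np.arange(n) / 1200, x, sample_rate=1200)
    fit = tw.fit_hmm(tr, n_states=2, seed=0)
    assert fit.means == pytest.approx([0.0, 20.0], abs=0.01)
    truth = (np.arange(n) // 120) % 2
    assert np.mean(fit.path == truth) == 1.0
    assert np.all(np.diff(fit.ll_history) >= -1e-6)  # Baum-Welch monotone


def test_hmm_three_state_path_accuracy_at_half_spacing_noise():
    trace, truth, _ = synth.gen_disassembly_trace(
        taus={"FZ": 0.05, "I20S": 0.007}, noise_sd=6.5, seed=99
    )
    fit = tw.fit_hmm(trace, n_states=3, seed=1)
    assert np.mean(fit.path == truth) >= 0.90


def test_hmm_flags_collapse_on_single_level_data():
    tr = synth.gen_white_noise_trace(sigma=2.0, duration_s=4.0, seed=7)
    fit = tw.fit_hmm(tr, n_states=2, seed=0)
    assert fit.collapsed


# -- dwell statistics --------------------------------------------------------

def test_dwell_tau_mle_is_mean_for_uncensored():
    ds = tw.DwellSet(durations=np.array([1.0, 2.0, 3.0]),
                     censored=np.zeros(3, dtype=bool))
    fit = tw.fit_dwell_tau(ds)
    assert fit.tau == pytest.approx(2.0)
    assert fit.tau_ci[0] < 2.0 < fit.tau_ci[1]


@pytest.mark.parametrize("tau_ms", [2.0, 7.0, 20.0])
def test_censored_dwell_mle_consistent(tau_ms):
    """Censored MLE with frame quantization and dead time: bias < 5% at
    n = 500."""
    rng = np.random.default_rng(int(tau_ms * 10))
    tau = tau_ms / 1e3
    raw = rng.exponential(tau, 500)
    # right-censor ~20% of dwells at a random observation cutoff
    cutoff = rng.exponential(tau * 4, 500)
    obs = np.minimum(raw, cutoff)
    cens = raw > cutoff
    frames = np.maximum(np.round(obs * 1200), 1) / 1200  # frame quantization
    ds = tw.DwellSet(durations=frames, censored=cens)
    fit = tw.fit_dwell_tau(ds, dead_time=1.5 / 1200)
    assert fit.tau == pytest.approx(tau, rel=0.10)


def test_heavily_censored_mle_still_unbiased():
    rng = np.random.default_rng(8)
    tau = 1.0
    raw = rng.exponential(tau, 400)
    cutoff = np.quantile(raw, 0.5)  # censor ~50% of dwells
    obs = np.minimum(raw, cutoff)
    cens = raw > cutoff
    fit = tw.fit_dwell_tau(tw.DwellSet(durations=obs, censored=cens))
    assert fit.tau_ci[0] <= tau <= fit.tau_ci[1]


def test_all_censored_dwells_raise():
    ds = tw.DwellSet(durations=np.ones(5), censored=np.ones(5, dtype=bool))
    with pytest.raises(ValueError):
        tw.fit_dwell_tau(ds)


def test_intermediate_dwell_recovery_from_hmm_pipeline():
    """Generator -> HMM -> censored-exponential pipeline recovers the 7-ms
    intermediate lifetime within 20%."""
    gen = synth.fig1_disassembly(n_traces=100, seed=11)
    traces = [g[0] for g in gen]
    fit = tw.fit_hmm(traces, n_states=3, seed=0, n_restarts=2)
    dwells = tw.extract_dwells(fit, 1, lengths=[len(t.extension) for t in traces])
    fitted = tw.fit_dwell_tau(dwells, dead_time=1.5 / 1200)
    assert fitted.tau == pytest.approx(0.007, rel=0.20)


# -- latency -----------------------------------------------------------------

def test_force_jump_latency_recovers_exponential_constant():
    rng = np.random.default_rng(0)
    traces = []
    for _ in range(50):
        lat = rng.exponential(1.6)
        n = int(min(lat + 0.5, 20) * 60)
        t = np.arange(n) / 60
        x = np.where(t < lat, 0.0, 28.0) + rng.normal(0, 2, n)
        traces.append(tw.ExtensionTrace(t, x, force=16.0, sample_rate=60))
    res = tw.force_jump_latency(traces, 0.0, threshold=14.0)
    assert res.tau == pytest.approx(1.6, rel=0.25)


def test_immediate_transitions_give_vanishing_latency():
    t = np.arange(120) / 60
    traces = [tw.ExtensionTrace(t, np.full(120, 28.0), sample_rate=60)
              for _ in range(10)]
    res = tw.force_jump_latency(traces, 0.0, threshold=14.0)
    assert res.tau < 0.02


def test_sequential_two_step_latency_adds_stage_means():
    """Total first-passage through two sequential exponential stages has
    mean ~ sum of the stage means (fast unzipping + slow final release)."""
    rng = np.random.default_rng(4)
    tau1, tau2 = 1.6, 15.0
    total = rng.exponential(tau1, 200) + rng.exponential(tau2, 200)
    ds = tw.DwellSet(durations=total, censored=np.zeros(200, dtype=bool))
    fit = tw.fit_dwell_tau(ds)
    assert fit.tau == pytest.approx(tau1 + tau2, rel=0.2)


# -- windowed histograms -----------------------------------------------------

def _planted_intermediate_traces(n_traces=20, delta=17.0, noise=2.0, seed=1):
    """Traces ending in UC at +30 with an exact 7-ms intermediate at 13."""
    rng = np.random.default_rng(seed)
    traces, events = [], []
    fs = 1200
    for _ in range(n_traces):
        n_fz, n_i, n_uc = 60, int(0.007 * fs) + 1, 120
        x = np.concatenate([
            np.zeros(n_fz), np.full(n_i, 30.0 - delta), np.full(n_uc, 30.0)
        ]) + rng.normal(0, noise, n_fz + n_i + n_uc)
        t = np.arange(len(x)) / fs
        traces.append(tw.ExtensionTrace(t, x, sample_rate=fs))
        events.append((n_fz + n_i) / fs)
    return traces, events


def test_windowed_histograms_peak_at_planted_intermediate():
    traces, events = _planted_intermediate_traces()
    hists = tw.windowed_extension_histograms(traces, events, window_ms=10)
    edges, counts = hists[-1]  # last 10 ms before disassembly
    centers = 0.5 * (edges[:-1] + edges[1:])
    assert centers[np.argmax(counts)] == pytest.approx(-17.0, abs=2.5)
    edges0, counts0 = hists[0]  # first 10 ms after
    centers0 = 0.5 * (edges0[:-1] + edges0[1:])
    assert centers0[np.argmax(counts0)] == pytest.approx(0.0, abs=2.5)


def test_windowed_histograms_invariant_under_offset():
    traces, events = _planted_intermediate_traces(n_traces=5)
    shifted = [
        tw.ExtensionTrace(t.time, t.extension + 123.4, sample_rate=t.sample_rate)
        for t in traces
    ]
    h1 = tw.windowed_extension_histograms(traces, events, window_ms=10)
    h2 = tw.windowed_extension_histograms(shifted, events, window_ms=10)
    for w in h1:
        assert np.allclose(h1[w][0], h2[w][0])
        assert np.array_equal(h1[w][1], h2[w][1])


# -- worm-like chain ---------------------------------------------------------

def test_marko_siggia_closed_form_at_half_extension():
    """F(z = 1/2) = 1.25 k_BT/L_p; the numeric inversion agrees."""
    lp = 0.6
    f_half = tw.wlc_force(0.5, lp)
    assert f_half == pytest.approx(1.25 * tw.KBT / lp)
    contour = 40.0
    ext = tw.wlc_extension(f_half, contour, lp)
    assert ext == pytest.approx(0.5 * contour, rel=1e-9)


def test_state_extension_monotone_in_force_and_residues():
    model = tw.StateExtensionModel()
    forces = np.linspace(2, 28, 14)
    ext_tu = [tw.state_extension(model, "TU", f) for f in forces]
    assert np.all(np.diff(ext_tu) > 0)
    by_residues = [
        tw.wlc_extension(16.0, r * model.contour_per_residue, model.lp_protein)
        for r in range(0, 140, 10)
    ]
    assert np.all(np.diff(by_residues) > 0)


def test_state_extension_ordering_and_spans_at_16pN():
    """State ladder FZ < LU < I20S < HU < TU < UC; the unzipping span is
    large (~28 nm) while the final coil step is small (~4 nm)."""
    model = tw.StateExtensionModel()
    ext = {s: tw.state_extension(model, s, 16.0)
           for s in ("FZ", "LU", "I20S", "HU", "TU", "UC")}
    vals = [ext[s] for s in ("FZ", "LU", "I20S", "HU", "TU", "UC")]
    assert np.all(np.diff(vals) > 0)
    span_unzip = ext["TU"] - ext["FZ"]
    span_coil = ext["UC"] - ext["TU"]
    assert span_coil < 0.25 * span_unzip
    assert span_unzip == pytest.approx(28.0, abs=6.0)
    assert span_coil == pytest.approx(4.0, abs=2.0)


def test_state_extension_zero_unfolded_is_core_only():
    model = tw.StateExtensionModel()
    assert tw.state_extension(model, "FZ", 16.0) == pytest.approx(model.states["FZ"][1])


def test_trace_hdf5_round_trip(tmp_path):
    tr = synth.gen_white_noise_trace(duration_s=0.5, seed=2)
    path = tmp_path / "trace.h5"
    tw.write_trace_hdf5(tr, path)
    back = tw.read_trace_hdf5(path)
    assert np.allclose(back.extension, tr.extension)
    assert back.sample_rate == tr.sample_rate
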