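"""Magnetic-tweezers extension-trace analysis for SNARE disassembly.

High-rate (1.2 kHz) bead-extension traces are median-filtered, their noise
characterized by Allan deviation, decomposed into discrete extension
states with a Gaussian-emission hidden Markov model (Baum–Welch /
Viterbi), and the dwell times of short-lived intermediates extracted with
right-censoring and detection-dead-time corrections.  A configurable
worm-like-chain model maps SNARE conformational states (fully zippered
through unstructured coil) to expected extensions at a given force.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy import optimize, stats

KBT = 4.114  # pN nm at 25 C


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExtensionTrace:
    """Bead extension vs time at a (piecewise-)constant force."""

    time: np.ndarray        # s
    extension: np.ndarray   # nm
    force: float | np.ndarray = 12.0  # pN
    sample_rate: float = 1200.0       # Hz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.time.shape != self.extension.shape:
            raise ValueError("time and extension must have equal length")
        if np.any(np.asarray(self.force) <= 0):
            raise ValueError("force must be positive")


@dataclass
class HmmFit:
    """Hidden-state decomposition of an extension trace."""

    n_states: int
    means: np.ndarray           # nm, ascending
    sds: np.ndarray             # nm
    transmat: np.ndarray        # per-frame transition probabilities
    path: np.ndarray            # Viterbi state index per frame
    log_likelihood: float
    ll_history: np.ndarray = field(repr=False, default=None)
    sample_rate: float = 1200.0
    collapsed: bool = False


@dataclass
class DwellSet:
    """Dwell (or latency) durations for one state, with censoring flags."""

    durations: np.ndarray   # s
    censored: np.ndarray    # True where the dwell is cut by a trace boundary
    state: int | str = 0
    tau: float | None = None
    tau_ci: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# filtering and noise
# ---------------------------------------------------------------------------

def median_filter(trace: ExtensionTrace, target_rate: float) -> ExtensionTrace:
    """Running-median filter and decimation to ``target_rate``.

    The window is ``sample_rate / target_rate`` frames; the filtered trace
    is decimated by the same factor, one sample per window.
    """
    if target_rate >= trace.sample_rate:
        raise ValueError("target rate must be below the sample rate")
    window = int(round(trace.sample_rate / target_rate))
    if window < 3:
        raise ValueError("filter window must be at least 3 frames")
    n = len(trace.extension) // window * window
    blocks = trace.extension[:n].reshape(-1, window)
    t_blocks = trace.time[:n].reshape(-1, window)
    return ExtensionTrace(
        time=t_blocks.mean(axis=1),
        extension=np.median(blocks, axis=1),
        force=trace.force,
        sample_rate=trace.sample_rate / window,
    )


def allan_deviation(
    trace: ExtensionTrace, taus: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping Allan deviation of a stationary extension segment.

    Returns ``(averaging_times, deviations)`` at octave-spaced averaging
    times by default.  For white noise of SD sigma at sample rate f_s the
    expected curve is sigma / sqrt(f_s * tau).
    """
    x = trace.extension
    fs = trace.sample_rate
    n = len(x)
    if taus is None:
        max_m = n // 4
        ms = 2 ** np.arange(0, int(np.log2(max(max_m, 2))))
    else:
        ms = np.unique(np.maximum(1, (np.asarray(taus) * fs).astype(int)))
        if ms[-1] > n // 4:
            warnings.warn("segment shorter than 4x the largest averaging time; curve truncated")
            ms = ms[ms <= max(n // 4, 1)]
    out_t, out_dev = [], []
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for m in ms:
        if 2 * m > n:
            break
        block = (csum[m:] - csum[:-m]) / m      # overlapping block means
        d = block[m:] - block[:-m]
        avar = 0.5 * np.mean(d**2)
        out_t.append(m / fs)
        out_dev.append(np.sqrt(avar))
    return np.array(out_t), np.array(out_dev)


# ---------------------------------------------------------------------------
# hidden Markov modeling
# ---------------------------------------------------------------------------

def fit_hmm(
    traces: ExtensionTrace | list[ExtensionTrace],
    n_states: int = 3,
    seed: int = 0,
    n_restarts: int = 3,
    n_iter: int = 200,
    tol: float = 1e-4,
) -> HmmFit:
    """Gaussian-emission HMM trained by Baum–Welch, decoded by Viterbi.

    Multiple traces are concatenated with their lengths passed to the
    estimator.  States are reported sorted by mean extension; two state
    means closer than half their pooled SD raise the ``collapsed`` flag.
    The per-iteration log-likelihood history is retained so monotonic
    convergence can be asserted.
    """
    if isinstance(traces, ExtensionTrace):
        traces = [traces]
    x = np.concatenate([t.extension for t in traces])[:, None]
    lengths = [len(t.extension) for t in traces]
    rate = traces[0].sample_rate

    lo, hi = np.percentile(x, [1, 99])
    rng = np.random.default_rng(seed)
    candidates = []
    for restart in range(n_restarts):
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=n_iter,
            tol=tol,
            random_state=seed + restart,
            min_covar=1e-6,
            init_params="st",  # means/covars set explicitly below
        )
        # spread means over the occupied range: rare short-lived states are
        # easily swallowed by k-means initialization on level-imbalanced data
        mu0 = np.linspace(lo, hi, n_states)
        if restart > 0:
            mu0 = np.sort(mu0 + rng.normal(0, (hi - lo) / (4 * n_states), n_states))
        model.means_ = mu0[:, None]
        model.covars_ = np.full((n_states, 1), np.var(x) / n_states**2)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x, lengths)
        except Exception:
            continue
        score = model.score(x, lengths)
        mu = np.sort(model.means_[:, 0])
        cv = model.covars_
        sd = np.sqrt(cv[:, 0, 0] if cv.ndim == 3 else cv[:, 0])
        # two states closer than ~1.5x the emission noise are not resolvable
        # levels but a split of one noisy level — a degenerate optimum
        collapsed = bool(np.any(np.diff(mu) < 1.5 * np.median(sd)))
        candidates.append((score, collapsed, model))
    if not candidates:
        raise RuntimeError("HMM training failed on all restarts")
    clean = [c for c in candidates if not c[1]]
    score, collapsed, model = max(clean or candidates, key=lambda c: c[0])

    means = model.means_[:, 0]
    sds = np.sqrt(model.covars_[:, 0, 0] if model.covars_.ndim == 3 else model.covars_[:, 0])
    order = np.argsort(means)
    means, sds = means[order], sds[order]
    transmat = model.transmat_[np.ix_(order, order)]
    raw_path = model.predict(x, lengths)
    remap = np.empty(n_states, dtype=int)
    remap[order] = np.arange(n_states)
    path = remap[raw_path]
    return HmmFit(
        n_states=n_states,
        means=means,
        sds=sds,
        transmat=transmat,
        path=path,
        log_likelihood=float(score),
        ll_history=np.array(model.monitor_.history, dtype=float),
        sample_rate=rate,
        collapsed=collapsed,
    )


def extract_dwells(fit: HmmFit, state: int, lengths: list[int] | None = None) -> DwellSet:
    """Dwell durations of one hidden state from the Viterbi path.

    Dwells touching a trace boundary are kept but flagged right-censored.
    ``lengths`` splits a concatenated path back into its traces.
    """
    path = fit.path
    bounds = np.cumsum([0] + (lengths if lengths else [len(path)]))
    durations, censored = [], []
    dt = 1.0 / fit.sample_rate
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = path[a:b]
        changes = np.flatnonzero(np.diff(seg)) + 1
        starts = np.concatenate([[0], changes])
        ends = np.concatenate([changes, [len(seg)]])
        for s, e in zip(starts, ends):
            if seg[s] != state:
                continue
            durations.append((e - s) * dt)
            censored.append(s == 0 or e == len(seg))
    return DwellSet(
        durations=np.array(durations),
        censored=np.array(censored, dtype=bool),
        state=state,
    )


def fit_dwell_tau(
    dwells: DwellSet,
    dead_time: float = 0.0,
    confidence: float = 0.95,
) -> DwellSet:
    """Censored-exponential MLE of the dwell time constant.

    Uncensored dwells contribute density terms and right-censored dwells
    contribute survival terms; a detection dead time ``dead_time`` (dwells
    shorter than it are unresolved) is handled by left truncation, which
    for an exponential amounts to subtracting the dead time from every
    observed duration.  tau_hat = sum(t_i - d) / n_uncensored, with a
    profile-likelihood CI.

    For durations measured in whole frames (Viterbi paths), a dead time of
    m frames corresponds to a continuous truncation point of (m - 1/2)
    frame periods, because an m-frame dwell arises from continuous dwells
    down to (m - 1/2)/f_s; pass that value to avoid a half-frame bias.
    """
    keep = dwells.durations >= dead_time
    t = dwells.durations[keep] - dead_time
    cens = dwells.censored[keep]
    n_unc = int((~cens).sum())
    if n_unc == 0:
        raise ValueError("all dwells are censored; no estimate possible")
    total = float(t.sum())
    tau = total / n_unc
    if total == 0:  # all passages instantaneous at this resolution
        return DwellSet(durations=dwells.durations, censored=dwells.censored,
                        state=dwells.state, tau=0.0, tau_ci=(0.0, 0.0))

    def loglik(tau_):
        return -n_unc * np.log(tau_) - total / tau_

    cut = loglik(tau) - stats.chi2.ppf(confidence, 1) / 2.0
    f = lambda tau_: loglik(tau_) - cut
    lo = optimize.brentq(f, tau * 1e-3, tau) if f(tau * 1e-3) < 0 else 0.0
    hi_bracket = tau * 1e3
    hi = optimize.brentq(f, tau, hi_bracket) if f(hi_bracket) < 0 else np.inf
    return DwellSet(
        durations=dwells.durations,
        censored=dwells.censored,
        state=dwells.state,
        tau=tau,
        tau_ci=(lo, hi),
    )


def force_jump_latency(
    traces: list[ExtensionTrace],
    jump_times: list[float] | float,
    threshold: float,
    direction: str = "up",
    dead_time: float = 0.0,
) -> DwellSet:
    """First-passage latencies from a force jump to a target extension level.

    For each trace the latency is the time from the jump to the first
    crossing of ``threshold`` (upward by default).  Traces with no
    crossing contribute right-censored entries.  The set is fitted with
    the censored-exponential MLE; the fitted tau is the latency time
    constant.
    """
    if np.isscalar(jump_times):
        jump_times = [float(jump_times)] * len(traces)
    lat, cens = [], []
    for tr, t0 in zip(traces, jump_times):
        after = tr.time >= t0
        x = tr.extension[after]
        t = tr.time[after]
        hit = x >= threshold if direction == "up" else x <= threshold
        idx = np.flatnonzero(hit)
        if len(idx) == 0:
            lat.append(t[-1] - t0)
            cens.append(True)
        else:
            lat.append(t[idx[0]] - t0)
            cens.append(False)
    ds = DwellSet(durations=np.array(lat), censored=np.array(cens, dtype=bool), state="latency")
    return fit_dwell_tau(ds, dead_time=dead_time)


# ---------------------------------------------------------------------------
# windowed extension histograms around disassembly
# ---------------------------------------------------------------------------

def windowed_extension_histograms(
    traces: list[ExtensionTrace],
    event_times: list[float],
    window_ms: float = 10.0,
    n_pre: int = 5,
    n_post: int = 2,
    bins: np.ndarray | int = 60,
    align_span_ms: float = 50.0,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Stacked extension histograms in fixed windows around an event.

    Each trace is shifted so that its post-event plateau (the unstructured
    coil level, estimated as the mean extension over ``align_span_ms``
    after the event) sits at zero; samples are pooled across traces per
    window.  Window ``w`` covers time-to-event in
    ``[w*window_ms, (w+1)*window_ms)`` — negative indices are pre-event,
    so ``w = -1`` is the last ``window_ms`` before the event.  Returns
    ``{window_index: (bin_edges, counts)}``.
    """
    dt_w = window_ms / 1e3
    pooled: dict[int, list[np.ndarray]] = {w: [] for w in range(-n_pre, n_post)}
    all_vals = []
    for tr, t_ev in zip(traces, event_times):
        post = (tr.time >= t_ev) & (tr.time < t_ev + align_span_ms / 1e3)
        if not post.any():
            warnings.warn("trace has no post-event samples; skipped for alignment")
            continue
        offset = tr.extension[post].mean()
        rel = tr.time - t_ev
        for w in range(-n_pre, n_post):
            m = (rel >= w * dt_w) & (rel < (w + 1) * dt_w)
            if not m.any():
                if w == -n_pre:
                    warnings.warn("trace shorter than the requested pre-event span")
                continue
            vals = tr.extension[m] - offset
            pooled[w].append(vals)
            all_vals.append(vals)
    if not all_vals:
        raise ValueError("no samples collected in any window")
    flat = np.concatenate(all_vals)
    edges = np.histogram_bin_edges(flat, bins=bins)
    return {
        w: (edges, np.histogram(np.concatenate(v) if v else np.array([]), bins=edges)[0])
        for w, v in pooled.items()
    }


# ---------------------------------------------------------------------------
# state-extension model (worm-like chain)
# ---------------------------------------------------------------------------

def wlc_force(z_frac: float | np.ndarray, lp: float) -> float | np.ndarray:
    """Marko–Siggia interpolation: force (pN) at fractional extension z = x/L."""
    z = np.asarray(z_frac, dtype=float)
    return KBT / lp * (1.0 / (4.0 * (1.0 - z) ** 2) - 0.25 + z)


def wlc_extension(force: float, contour: float, lp: float) -> float:
    """Extension (nm) of an inextensible WLC at ``force``; numeric inversion."""
    if contour <= 0:
        return 0.0
    if force <= 0:
        return 0.0
    f = lambda z: wlc_force(z, lp) - force
    z = optimize.brentq(f, 1e-9, 1 - 1e-9)
    return z * contour


def extensible_wlc_extension(
    force: float, contour: float, lp: float, stretch_modulus: float = 1000.0
) -> float:
    """High-force extensible-WLC approximation for stiff handles (DNA)."""
    if force <= 0 or contour <= 0:
        return 0.0
    return contour * (1.0 - 0.5 * np.sqrt(KBT / (force * lp)) + force / stretch_modulus)


#: Default per-state unfolded residue counts and folded-core projections.
#: The zippered four-helix bundle contributes a short projected length
#: that shrinks as it unwinds; unfolded polypeptide is released in the
#: order linker -> C-terminal layers -> full motifs -> coil.  These are
#: plausibility defaults (the structural inventory per zippering layer is
#: configurable), chosen so that the fully-unzipped transition spans
#: roughly 28 nm and the final coil step ~4 nm at 16 pN.
DEFAULT_STATES: dict[str, tuple[int, float]] = {
    "FZ": (0, 2.0),      # fully zippered
    "LU": (14, 2.0),     # linker-unzipped
    "I20S": (50, 1.5),   # disassembly intermediate (unzipped to ~+4 layer)
    "HU": (66, 1.0),     # half-unzipped
    "TU": (120, 0.5),    # totally unzipped (SNARE motifs unfolded)
    "UC": (137, 0.0),    # unstructured coil
}


@dataclass
class StateExtensionModel:
    """Maps conformational states to expected extensions at a given force."""

    states: dict[str, tuple[int, float]] = field(default_factory=lambda: dict(DEFAULT_STATES))
    lp_protein: float = 0.6          # nm, polypeptide persistence length
    contour_per_residue: float = 0.365  # nm per residue
    handle_contour: float = 340.0    # nm, two 500-bp dsDNA handles
    handle_lp: float = 40.0          # nm
    handle_stretch_modulus: float = 1000.0  # pN
    include_handles: bool = False

    def __post_init__(self) -> None:
        if self.lp_protein <= 0 or self.handle_lp <= 0:
            raise ValueError("persistence lengths must be positive")
        for name, (res, core) in self.states.items():
            if res < 0:
                raise ValueError(f"negative residue count for state {name}")


def state_extension(model: StateExtensionModel, state: str, force: float) -> float:
    """Expected extension (nm) of a conformational state at ``force`` (pN).

    Worm-like-chain extension of the state's unfolded residues plus the
    projected folded-core contribution, optionally plus the DNA-handle
    extension (common to all states and irrelevant for state-to-state
    differences).
    """
    if not 1.0 <= force <= 30.0:
        warnings.warn(f"force {force} pN outside the 1-30 pN validity range")
    if state not in model.states:
        raise KeyError(f"unknown state {state!r}; known: {sorted(model.states)}")
    residues, core = model.states[state]
    contour = residues * model.contour_per_residue
    ext = wlc_extension(force, contour, model.lp_protein) + core
    if model.include_handles:
        ext += extensible_wlc_extension(
            force, model.handle_contour, model.handle_lp, model.handle_stretch_modulus
        )
    return ext


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_trace_hdf5(trace: ExtensionTrace, path) -> None:
    with h5py.File(path, "w") as h5:
        g = h5.create_group("trace")
        g.create_dataset("time", data=trace.time)
        g.create_dataset("extension", data=trace.extension)
        g.create_dataset("force", data=np.atleast_1d(trace.force))
        g.attrs["sample_rate"] = trace.sample_rate


def read_trace_hdf5(path) -> ExtensionTrace:
    with h5py.File(path, "r") as h5:
        g = h5["trace"]
        force = g["force"][()]
        return ExtensionTrace(
            time=g["time"][()],
            extension=g["extension"][()],
            force=float(force[0]) if len(force) == 1 else force,
            sample_rate=float(g.attrs["sample_rate"]),
        )


def write_dwells_tsv(dwells: DwellSet, path) -> None:
    pd.DataFrame({"duration_s": dwells.durations,
                  "censored": dwells.censored.astype(int)}).to_csv(path, sep="\t", index=False)
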