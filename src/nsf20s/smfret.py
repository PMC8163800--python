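"""Single-molecule FRET population analysis for two-color traces.

Corrected FRET efficiencies are computed per molecule from donor/acceptor
intensity traces recorded with alternating laser excitation, molecules
with exactly one donor and one acceptor (verified by single-step
photobleaching in each channel) are selected, and the resulting
efficiency distribution is decomposed into a 1-D Gaussian mixture by
expectation–maximization.

The mixture EM is implemented here (1-D, restarted, with a per-iteration
log-likelihood record) so that monotonic convergence and degenerate
components can be checked explicitly; scikit-learn's mixture model serves
as an independent cross-check in the test suite, not as the fitting path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .photobleach import FluorTrace, detect_steps


@dataclass
class TwoColorTrace:
    """Donor/acceptor intensities with an alternating-excitation schedule.

    ``donor_excitation`` flags the frames recorded under donor excitation;
    the remaining frames are direct acceptor excitations used to verify
    acceptor presence and bleaching.
    """

    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    donor_excitation: np.ndarray
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        self.donor_excitation = np.asarray(self.donor_excitation, dtype=bool)
        n = len(self.time)
        if not (len(self.donor) == len(self.acceptor) == len(self.donor_excitation) == n):
            raise ValueError("all channels and the excitation schedule must cover every frame")


@dataclass(frozen=True)
class FretCorrection:
    """Detection corrections: donor leakage ``l`` and gamma factor."""

    leakage: float = 0.07
    gamma_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.leakage < 1:
            raise ValueError("leakage must be in [0, 1)")
        if self.gamma_factor <= 0:
            raise ValueError("gamma factor must be positive")


@dataclass
class GaussianMixtureFit:
    """A fitted 1-D Gaussian mixture, components sorted by mean."""

    n_components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    ll_history: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    merged: bool = False
    bic: float = np.nan


def fret_efficiency(
    trace: TwoColorTrace,
    corr: FretCorrection = FretCorrection(),
    window: int = 20,
    report_range: tuple[float, float] = (-0.2, 1.2),
) -> tuple[float, dict]:
    """Corrected FRET efficiency averaged over the pre-bleach window.

    E = (I_A - l * I_D) / (I_A + gamma * I_D) on background-subtracted mean
    intensities over the first ``window`` donor-excitation frames (the
    caller guarantees these precede the first bleaching event in either
    channel).  E is invariant under common scaling of both channels.
    Values outside ``report_range`` are flagged, as is a non-positive
    denominator.
    """
    sel = trace.donor_excitation
    i_d = float(np.mean(trace.donor[sel][:window]))
    i_a = float(np.mean(trace.acceptor[sel][:window]))
    den = i_a + corr.gamma_factor * i_d
    if den <= 0:
        return np.nan, {"undefined": True, "out_of_range": False}
    e = (i_a - corr.leakage * i_d) / den
    return e, {"undefined": False,
               "out_of_range": not (report_range[0] <= e <= report_range[1])}


def _first_bleach_frame(trace: TwoColorTrace) -> int:
    """Index of the first bleaching event in either channel (donor frames)."""
    sel = trace.donor_excitation
    t = trace.time[sel]
    frames = []
    for channel, mask in ((trace.donor, sel), (trace.acceptor, ~sel)):
        sub = FluorTrace(np.arange(mask.sum(), dtype=float), channel[mask], trace.frame_rate)
        n, times = detect_steps(sub)
        if n > 0:
            frames.append(times[0])
    if not frames:
        return sel.sum()
    return int(min(frames))


def select_single_pair_traces(
    traces: list[TwoColorTrace],
) -> list[TwoColorTrace]:
    """Keep molecules with exactly one donor and one acceptor fluorophore.

    A molecule qualifies when its donor channel (under donor excitation)
    bleaches in exactly one step and its acceptor channel, under direct
    acceptor excitation, also bleaches in exactly one step.
    """
    kept = []
    for tr in traces:
        sel = tr.donor_excitation
        donor = FluorTrace(np.arange(int(sel.sum()), dtype=float), tr.donor[sel], tr.frame_rate)
        acc = FluorTrace(np.arange(int((~sel).sum()), dtype=float), tr.acceptor[~sel], tr.frame_rate)
        try:
            nd, _ = detect_steps(donor)
            na, _ = detect_steps(acc)
        except ValueError:
            continue
        if nd == 1 and na == 1:
            kept.append(tr)
    return kept


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture EM
# ---------------------------------------------------------------------------

def _em_once(x, n_components, means0, sds0, weights0, max_iter, tol, sd_floor):
    n = len(x)
    mu, sd, w = means0.copy(), sds0.copy(), weights0.copy()
    ll_hist = []
    ll_old = -np.inf
    for _ in range(max_iter):
        # E step in log space
        logpdf = (
            -0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
            - np.log(sd[None, :])
            - 0.5 * np.log(2 * np.pi)
            + np.log(w[None, :])
        )
        m = logpdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logpdf - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logpdf - lse[:, None])
        ll_hist.append(ll)
        if ll - ll_old < tol and np.isfinite(ll_old):
            break
        ll_old = ll
        # M step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            return None  # empty component -> degenerate start
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(var)
        if np.any(sd < sd_floor):
            return None  # collapsing component -> degenerate start
    return mu, sd, w, np.array(ll_hist)


def fit_gaussian_mixture(
    e_values: np.ndarray,
    n_components: int = 3,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> GaussianMixtureFit:
    """Maximum-likelihood 1-D Gaussian mixture of FRET efficiencies.

    EM from ``n_restarts`` initializations (quantile-spaced means with
    jitter, pooled SD, uniform weights); the best log-likelihood solution
    is kept with components sorted by mean.  Degenerate runs (a component
    collapsing to a point) are discarded and restarted; if every restart
    degenerates a fit-failure is raised.  Two components closer than two
    pooled SDs set the ``merged`` flag (label-switching degeneracy).
    """
    x = np.asarray(e_values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 50:
        raise ValueError("need at least 50 efficiency values")
    rng = np.random.default_rng(seed)
    pooled_sd = float(np.std(x)) / max(n_components, 1)
    sd_floor = max(1e-6, 1e-4 * (np.ptp(x) or 1.0))
    qs = np.quantile(x, (np.arange(n_components) + 0.5) / n_components)

    best = None
    for restart in range(n_restarts):
        jitter = 0.0 if restart == 0 else rng.normal(0, pooled_sd / 2, n_components)
        mu0 = np.sort(qs + jitter)
        res = _em_once(
            x, n_components, mu0, np.full(n_components, max(pooled_sd, sd_floor * 10)),
            np.full(n_components, 1.0 / n_components), max_iter, tol, sd_floor,
        )
        if res is None:
            continue
        if best is None or res[3][-1] > best[3][-1]:
            best = res
    if best is None:
        raise RuntimeError("all EM restarts degenerated; mixture fit failed")

    mu, sd, w, ll_hist = best
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    # components separated by < 2 pooled SDs overlap too heavily to be
    # distinct populations — typically a single cluster split by EM
    merged = bool(np.any(np.diff(mu) < 2.0 * np.sqrt(sd[:-1] * sd[1:])))
    n_params = 3 * n_components - 1
    bic = n_params * np.log(len(x)) - 2 * ll_hist[-1]
    return GaussianMixtureFit(
        n_components=n_components,
        means=mu, sds=sd, weights=w,
        log_likelihood=float(ll_hist[-1]),
        ll_history=ll_hist,
        converged=len(ll_hist) < max_iter,
        merged=merged,
        bic=float(bic),
    )


def select_n_components(
    e_values: np.ndarray, candidates=(1, 2, 3, 4), seed: int = 0
) -> tuple[int, dict[int, float]]:
    """BIC-based component-count selection (optional alternative to fixed 3)."""
    bics = {}
    for k in candidates:
        try:
            bics[k] = fit_gaussian_mixture(e_values, n_components=k, seed=seed).bic
        except RuntimeError:
            bics[k] = np.inf
    best = min(bics, key=bics.get)
    return best, bics
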