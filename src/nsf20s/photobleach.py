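"""Photobleaching-step stoichiometry of fluorescently labeled complexes.

Counting discrete photobleaching steps in single-spot fluorescence traces
reports how many labeled subunits a complex carries.  Because labeling is
stochastic (efficiency r < 1), the observed step-count histogram is a
binomially blurred version of the true subunit-count distribution; this
module provides the step detector, the binomial mixing operator and its
inversion, the tandem-dimer estimator for r, relative-avidity ratios, and
simple spot detection / colocalization for snapshot images.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

MAX_SUBUNITS = 6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FluorTrace:
    """Uniformly sampled fluorescence intensity trace for one spot."""

    time: np.ndarray
    intensity: np.ndarray
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("trace is not uniformly sampled")


@dataclass
class StepHistogram:
    """Histogram of photobleaching step counts.

    ``counts[i]`` is the number (or weight) of traces with ``i + 1`` steps:
    spots with zero visible labels are never picked up, so both observed
    and deconvoluted histograms start at 1.  For kind ``"deconvoluted"``
    the index is the true number of taggable subunits (1..6) instead of
    the observed step count.
    """

    counts: np.ndarray
    kind: str = "observed"  # "observed" | "deconvoluted"
    n_traces: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be nonnegative")
        if self.kind not in ("observed", "deconvoluted"):
            raise ValueError(f"unknown histogram kind {self.kind!r}")
        if self.n_traces is None:
            self.n_traces = int(round(self.counts.sum()))

    def fractions(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            raise ValueError("empty histogram")
        return self.counts / tot


@dataclass
class MixingMatrix:
    """Binomial labeling operator A with a_ij = C(j, i) r^i (1-r)^(j-i).

    Column j gives the observed step-count distribution for a complex that
    truly carries j taggable subunits, each labeled independently with
    probability r.  Stored as the full (i, j = 0..6) matrix; each column is
    a probability vector and the diagonal r^j > 0 makes it invertible.
    """

    r: float
    matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.r <= 1.0:
            raise ValueError("labeling efficiency r must be in (0, 1]")
        n = MAX_SUBUNITS + 1
        a = np.zeros((n, n))
        for j in range(n):
            for i in range(j + 1):
                a[i, j] = comb(j, i) * self.r**i * (1.0 - self.r) ** (j - i)
        self.matrix = a

    @property
    def visible_block(self) -> np.ndarray:
        """The 6x6 block over i, j = 1..6 used for deconvolution."""
        return self.matrix[1:, 1:]


def build_mixing_matrix(r: float) -> MixingMatrix:
    return MixingMatrix(r=r)


# ---------------------------------------------------------------------------
# step detection
# ---------------------------------------------------------------------------

def _best_split(y: np.ndarray) -> tuple[int, float]:
    """Best single change point of a segment by RSS reduction (O(n))."""
    n = len(y)
    c = np.cumsum(y)
    c2 = np.cumsum(y * y)
    total_rss = c2[-1] - c[-1] ** 2 / n
    m = np.arange(1, n)  # left segment lengths
    left = c[:-1]
    right = c[-1] - left
    rss = (c2[-1]) - left**2 / m - right**2 / (n - m)
    idx = int(np.argmin(rss))
    return idx + 1, total_rss - rss[idx]


def _noise_sigma(y: np.ndarray) -> float:
    """Robust noise SD from successive differences (steps are sparse)."""
    d = np.diff(y)
    if len(d) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def detect_steps(
    trace: FluorTrace,
    max_steps: int = 10,
    sensitivity: float = 2.5,
) -> tuple[int, np.ndarray]:
    """Count photobleaching steps in a fluorescence trace.

    Change points are inserted greedily, each insertion taking the split
    that most reduces the residual sum of squares, and accepted while the
    Schwarz information criterion ``N log(RSS/N) + k log N`` decreases.
    Steps smaller than ``sensitivity * sigma_noise`` are then merged away,
    and only downward level changes are counted as bleaching events (the
    final plateau is the lowest level).  Saturated/NaN frames are masked
    with a logged warning.

    Returns ``(step_count, step_times)``.
    """
    y = np.asarray(trace.intensity, dtype=float)
    t = np.asarray(trace.time, dtype=float)
    bad = ~np.isfinite(y)
    if bad.any():
        logger.warning("masking %d non-finite frames", int(bad.sum()))
        y, t = y[~bad], t[~bad]
    if len(y) < 20:
        raise ValueError("trace too short for step detection (< 20 frames)")

    n = len(y)
    # greedy change-point insertion with SIC stopping
    breakpoints: list[int] = []
    rss_of = lambda seg: float(np.sum((seg - seg.mean()) ** 2))
    segments = {(0, n): rss_of(y)}
    current_rss = sum(segments.values())
    sic = n * np.log(max(current_rss, 1e-300) / n)
    min_len = 2
    while len(breakpoints) < max(2 * max_steps, 20):
        best = None
        for (a, b), seg_rss in segments.items():
            if b - a < 2 * min_len:
                continue
            split, gain = _best_split(y[a:b])
            if split < min_len or (b - a) - split < min_len:
                continue
            if best is None or gain > best[2]:
                best = (a, b, gain, a + split)
        if best is None:
            break
        a, b, gain, cp = best
        new_rss = current_rss - gain
        new_sic = n * np.log(max(new_rss, 1e-300) / n) + (len(breakpoints) + 1) * np.log(n)
        old_sic = n * np.log(max(current_rss, 1e-300) / n) + len(breakpoints) * np.log(n)
        if new_sic >= old_sic:
            break
        breakpoints.append(cp)
        del segments[(a, b)]
        segments[(a, cp)] = rss_of(y[a:cp])
        segments[(cp, b)] = rss_of(y[cp:b])
        current_rss = new_rss

    breakpoints.sort()
    # piecewise-constant refit, then merge sub-threshold steps
    sigma = _noise_sigma(y)
    thresh = sensitivity * sigma
    while True:
        bounds = [0] + breakpoints + [n]
        levels = [y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        jumps = np.abs(np.diff(levels))
        if len(jumps) == 0 or (jumps >= thresh).all():
            break
        breakpoints.pop(int(np.argmin(jumps)))

    bounds = [0] + breakpoints + [n]
    levels = [y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    down = [i for i in range(len(breakpoints)) if levels[i + 1] < levels[i]]
    step_times = t[np.array([breakpoints[i] for i in down], dtype=int)] if down else np.array([])
    return len(down), step_times


def refit_levels(trace: FluorTrace, step_times: np.ndarray) -> np.ndarray:
    """Piecewise-constant fit at given change times (cross-check of steps)."""
    t, y = trace.time, trace.intensity
    bounds = [0] + [int(np.searchsorted(t, st)) for st in np.sort(step_times)] + [len(y)]
    return np.array([y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])


# ---------------------------------------------------------------------------
# deconvolution and labeling efficiency
# ---------------------------------------------------------------------------

def deconvolve_histogram(observed: StepHistogram, r: float, tol: float = 1e-9) -> StepHistogram:
    """Correct an observed step-count histogram for incomplete labeling.

    Solves R = A^{-1} X on the visible 6x6 block (true and observed counts
    1..6; complexes with zero visible labels never enter the histogram, so
    the true j = 0 bin is unidentifiable and the result is renormalized
    over j >= 1).  If sampling noise drives the exact inverse negative, a
    nonnegativity-constrained least-squares solution is used instead.
    """
    if observed.kind != "observed":
        raise ValueError("input histogram must be of kind 'observed'")
    x = observed.fractions()
    if len(x) < MAX_SUBUNITS:
        x = np.pad(x, (0, MAX_SUBUNITS - len(x)))
    if len(x) != MAX_SUBUNITS:
        raise ValueError(f"expected at most {MAX_SUBUNITS} observed bins (steps 1..6), got {len(x)}")

    a = build_mixing_matrix(r).visible_block
    if np.linalg.cond(a) > 1e9:
        raise np.linalg.LinAlgError(
            f"mixing matrix ill-conditioned at r={r}: condition number > 1e9"
        )
    rtrue = np.linalg.solve(a, x)
    if np.any(rtrue < -tol):
        rtrue, _ = optimize.nnls(a, x)
    rtrue = np.clip(rtrue, 0.0, None)
    rtrue /= rtrue.sum()
    return StepHistogram(counts=rtrue, kind="deconvoluted", n_traces=observed.n_traces)


def estimate_labeling_efficiency(
    dimer_hist: StepHistogram, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Labeling efficiency from the tandem two-site (dimer) control.

    For a two-site construct with independent Bernoulli(r) labeling,
    conditioning on visibility gives P(2 steps | visible) = r / (2 - r);
    the MLE is the closed form r_hat = 2 f2 / (2 f2 + f1).  The interval is
    a profile-likelihood CI from the binomial likelihood of the 1- vs
    2-step split.
    """
    c = dimer_hist.counts
    n1 = float(c[0]) if len(c) > 0 else 0.0
    n2 = float(c[1]) if len(c) > 1 else 0.0
    if n1 + n2 == 0:
        raise ValueError("dimer histogram has no 1- or 2-step traces")
    r_hat = 2 * n2 / (2 * n2 + n1)

    def loglik(r: float) -> float:
        q = r / (2.0 - r)  # P(2 steps | visible)
        q = min(max(q, 1e-12), 1 - 1e-12)
        return n2 * np.log(q) + n1 * np.log(1 - q)

    ll_max = loglik(r_hat) if 0 < r_hat < 1 else max(loglik(1 - 1e-9), loglik(1e-9))
    cut = ll_max - stats.chi2.ppf(confidence, df=1) / 2.0
    f = lambda r: loglik(r) - cut
    lo = optimize.brentq(f, 1e-9, r_hat) if r_hat > 1e-9 and f(1e-9) < 0 else 0.0
    hi = optimize.brentq(f, r_hat, 1 - 1e-9) if r_hat < 1 - 1e-9 and f(1 - 1e-9) < 0 else 1.0
    return r_hat, (lo, hi)


def relative_avidity(
    dist_bound: StepHistogram, dist_reference: StepHistogram
) -> pd.DataFrame:
    """Enrichment of each subunit-count class in the bound population.

    ratio(k) = [bound(k)/ref(k)] / [bound(1)/ref(1)], i.e. the avidity of
    k-mutant hexamers for the binding partner normalized to single-mutant
    hexamers.  Errors are propagated by the delta method from multinomial
    counting error in both histograms.
    """
    for h in (dist_bound, dist_reference):
        if h.kind != "deconvoluted":
            raise ValueError("relative avidity requires deconvoluted histograms")
    fb, fr = dist_bound.fractions(), dist_reference.fractions()
    nb = dist_bound.n_traces or 1
    nr = dist_reference.n_traces or 1
    if len(fb) != len(fr):
        raise ValueError("histograms must cover the same step range")
    # index 0 of a deconvoluted histogram is k=1
    k_index = np.arange(1, len(fb) + 1)
    if fb[0] == 0 or fr[0] == 0:
        raise ValueError("k=1 bins must be nonzero for normalization")
    base = fb[0] / fr[0]
    rows = []
    for i, k in enumerate(k_index):
        if fr[i] == 0:
            rows.append({"k": int(k), "ratio": np.nan, "se": np.nan,
                         "undefined": fb[i] > 0})
            continue
        ratio = (fb[i] / fr[i]) / base
        # delta method on log ratio: sum of relative variances of the four fractions
        rel_var = 0.0
        for f, n in ((fb[i], nb), (fr[i], nr), (fb[0], nb), (fr[0], nr)):
            rel_var += (1 - f) / (max(f, 1e-12) * n)
        se = ratio * np.sqrt(rel_var) if k != 1 else 0.0
        rows.append({"k": int(k), "ratio": ratio, "se": se, "undefined": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spot detection / colocalization
# ---------------------------------------------------------------------------

def detect_spots(
    image: np.ndarray,
    threshold_sd: float = 4.0,
    min_separation: int = 3,
) -> list[tuple[int, int, float]]:
    """Detect fluorescent spots as local maxima in a snapshot image.

    Background is the image median; the noise scale is a robust (MAD) SD.
    Local maxima above ``background + threshold_sd * sigma`` are kept with
    non-maximum suppression within ``min_separation`` pixels.  Returns
    ``(row, col, amplitude)`` tuples sorted by decreasing amplitude.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        warnings.warn("empty image: no spots")
        return []
    if img.shape[0] < 16 or img.shape[1] < 16:
        raise ValueError("image must be at least 16x16 pixels")
    bg = np.median(img)
    sigma = 1.4826 * np.median(np.abs(img - bg))
    thr = bg + threshold_sd * sigma
    size = 2 * int(min_separation) + 1
    local_max = (img == ndimage.maximum_filter(img, size=size)) & (img > thr)
    coords = np.argwhere(local_max)
    spots = [(int(r), int(c), float(img[r, c] - bg)) for r, c in coords]
    spots.sort(key=lambda s: -s[2])
    # non-maximum suppression between equal-plateau neighbours
    kept: list[tuple[int, int, float]] = []
    for s in spots:
        if all((s[0] - k[0]) ** 2 + (s[1] - k[1]) ** 2 >= min_separation**2 for k in kept):
            kept.append(s)
    return kept


def colocalize(
    spots_a: Sequence[tuple[float, float, float]],
    spots_b: Sequence[tuple[float, float, float]],
    radius: float = 2.0,
) -> float:
    """Fraction of channel-A spots with a channel-B spot within ``radius`` px."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(spots_a) == 0:
        return 0.0
    if len(spots_b) == 0:
        return 0.0
    xy_a = np.array([(s[0], s[1]) for s in spots_a], dtype=float)
    xy_b = np.array([(s[0], s[1]) for s in spots_b], dtype=float)
    tree = cKDTree(xy_b)
    d, _ = tree.query(xy_a, k=1)
    return float(np.mean(d <= radius))


# ---------------------------------------------------------------------------
# disassembly kinetics
# ---------------------------------------------------------------------------

def fit_exponential_decay(
    time: np.ndarray, counts: np.ndarray, plateau: bool = False
) -> dict:
    """Fit N(t) = exp(-t/tau) (optionally + plateau) to normalized counts.

    Returns a dict with ``tau``, ``tau_se``, optional ``plateau`` and an
    ``unreliable`` flag raised when the counts are not decreasing.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    unreliable = bool(np.all(np.diff(y) >= 0))
    if unreliable:
        warnings.warn("counts are non-decreasing; tau is unreliable")
    if plateau:
        model = lambda tt, tau, c: (1 - c) * np.exp(-tt / tau) + c
        p0 = [max(t[-1] / 3.0, 1e-6), float(min(y))]
        lb, ub = [1e-9, 0.0], [np.inf, 1.0]
    else:
        model = lambda tt, tau: np.exp(-tt / tau)
        p0 = [max(t[-1] / 3.0, 1e-6)]
        lb, ub = [1e-9], [np.inf]
    popt, pcov = optimize.curve_fit(model, t, y, p0=p0, bounds=(lb, ub), maxfev=10000)
    se = np.sqrt(np.diag(pcov))
    out = {"tau": float(popt[0]), "tau_se": float(se[0]), "unreliable": unreliable}
    if plateau:
        out["plateau"] = float(popt[1])
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trace_tsv(path) -> FluorTrace:
    df = pd.read_csv(path, sep="\t")
    dt = np.diff(df["time"].to_numpy())
    rate = 1.0 / dt[0] if len(dt) else 10.0
    return FluorTrace(df["time"].to_numpy(), df["intensity"].to_numpy(), frame_rate=rate)


def write_histogram_tsv(hist: StepHistogram, path) -> None:
    pd.DataFrame({"steps": np.arange(1, 1 + len(hist.counts)),
                  "count": hist.counts}).to_csv(path, sep="\t", index=False)


def read_histogram_tsv(path, kind: str = "observed") -> StepHistogram:
    df = pd.read_csv(path, sep="\t")
    steps = df["steps"].to_numpy(dtype=int)
    counts = np.zeros(int(steps.max()))
    counts[steps - 1] = df["count"].to_numpy(dtype=float)
    return StepHistogram(counts=counts, kind=kind)
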