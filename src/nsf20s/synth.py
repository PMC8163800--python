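"""Synthetic-data generators for every analysis stage in the package.

The raw single-molecule data behind the analyses are not deposited, so
each generator emulates the statistical structure the corresponding
analysis assumes: binomial subunit mixing and Bernoulli labeling for the
photobleaching stoichiometry, exponential bleach times with Gaussian
frame noise for intensity traces, Gaussian-mixture efficiencies with
anticorrelated two-channel emission for smFRET, Markov state paths with
exponential dwells for tweezer traces, and replicate Gaussian noise on
closed-form rate curves for ATPase titrations.

Every generator takes an explicit seed and draws from its own
``numpy.random.Generator``; identical configurations produce bitwise
identical outputs and no global random state is touched.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import atpase, ringcomb
from .photobleach import FluorTrace, StepHistogram
from .ringcomb import GeometricRule, RingArrangement
from .smfret import TwoColorTrace
from .tweezers import ExtensionTrace


@dataclass
class GeneratorConfig:
    """Serializable record of a generator invocation (for provenance logs)."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# ATPase titrations and progress curves
# ---------------------------------------------------------------------------

def gen_titration(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    atp: np.ndarray | None = None,
    noise_cv: float = 0.05,
    n_rep: int = 6,
    seed: int = 0,
) -> atpase.TitrationDataset:
    """Titration dataset from a rate law with replicate Gaussian noise.

    Each concentration gets ``n_rep`` replicates drawn around the true
    rate with coefficient of variation ``noise_cv``; the dataset carries
    the replicate mean, sample SD, and replicate count.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    rng = np.random.default_rng(seed)
    grid = atpase.default_atp_grid() if atp is None else np.asarray(atp, dtype=float)
    truth = np.asarray(rate_fn(grid), dtype=float)
    if noise_cv == 0:
        return atpase.TitrationDataset(atp=grid, rate=truth,
                                       sd=np.zeros_like(truth),
                                       n_rep=np.full(len(grid), n_rep))
    reps = rng.normal(truth[:, None], noise_cv * np.maximum(truth[:, None], 1e-12),
                      size=(len(grid), n_rep))
    reps = np.clip(reps, 0.0, None)
    return atpase.TitrationDataset(
        atp=grid,
        rate=reps.mean(axis=1),
        sd=reps.std(axis=1, ddof=1),
        n_rep=np.full(len(grid), n_rep),
    )


def gen_progress_curve(
    rate_uM_per_min: float,
    duration_min: float = 10.0,
    dt_min: float = 0.5,
    noise_sd: float = 0.002,
    saturation_uM: float | None = None,
    abs_per_uM: float = 0.01,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """Coupled-assay absorbance time series plus calibration standards.

    Phosphate accumulates linearly at ``rate_uM_per_min`` (optionally
    saturating exponentially toward ``saturation_uM``) and is read out as
    absorbance with slope ``abs_per_uM`` and Gaussian noise.  Returns
    ``(time_min, absorbance, standards)`` where standards are (Pi μM,
    absorbance) pairs.
    """
    if rate_uM_per_min < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + dt_min / 2, dt_min)
    if saturation_uM is None or rate_uM_per_min == 0:
        pi = rate_uM_per_min * t
    else:
        tau = saturation_uM / rate_uM_per_min
        pi = saturation_uM * (1.0 - np.exp(-t / tau))
    absorbance = abs_per_uM * pi + rng.normal(0, noise_sd, len(t))
    std_pi = np.array([0.0, 5.0, 10.0, 20.0, 40.0])
    standards = [(p, abs_per_uM * p + rng.normal(0, noise_sd)) for p in std_pi]
    return t, absorbance, standards


# ---------------------------------------------------------------------------
# hexamer cohorts and photobleaching
# ---------------------------------------------------------------------------

@dataclass
class HexamerCohort:
    """Ground truth and observables for a simulated hexamer population."""

    arrangements: list[RingArrangement]
    mutant_counts: np.ndarray
    observed_steps: np.ndarray   # number of labeled (visible) tagged subunits
    bound: np.ndarray            # binding competence under the rule


def gen_hexamer_cohort(
    x: float,
    r: float,
    rule: GeometricRule,
    n: int = 10_000,
    seed: int = 0,
) -> HexamerCohort:
    """Random re-hexamerization cohort with Bernoulli labeling.

    Subunits are i.i.d. mutant (taggable) with probability ``x``; each
    taggable subunit carries a fluorophore with probability ``r`` and all
    fluorophores bleach visibly.  The bound flag applies the geometric
    rule to the true arrangement.
    """
    rng = np.random.default_rng(seed)
    masks = rng.random((n, 6)) < x
    labeled = masks & (rng.random((n, 6)) < r)
    arrangements = [RingArrangement(tuple(row)) for row in masks]
    return HexamerCohort(
        arrangements=arrangements,
        mutant_counts=masks.sum(axis=1),
        observed_steps=labeled.sum(axis=1),
        bound=np.array([rule(a) for a in arrangements]),
    )


def cohort_step_histogram(cohort_steps: np.ndarray) -> StepHistogram:
    """Observed step histogram (1..6) from per-molecule step counts."""
    counts = np.bincount(np.asarray(cohort_steps, dtype=int), minlength=7)[1:7]
    return StepHistogram(counts=counts.astype(float), kind="observed")


def gen_dimer_step_counts(r: float, n: int = 1000, seed: int = 0) -> StepHistogram:
    """Tandem two-site labeling control: observed 1-/2-step histogram."""
    rng = np.random.default_rng(seed)
    labels = (rng.random((n, 2)) < r).sum(axis=1)
    labels = labels[labels > 0]
    counts = np.bincount(labels, minlength=3)[1:3]
    return StepHistogram(counts=counts.astype(float), kind="observed")


def gen_bleach_trace(
    n_fluor: int,
    bleach_rate: float = 0.03,
    intensity_per_fluor: float = 100.0,
    noise_sd: float = 20.0,
    frame_rate: float = 10.0,
    duration_s: float = 240.0,
    seed: int = 0,
) -> tuple[FluorTrace, np.ndarray]:
    """Multi-step photobleaching trace with exponential bleach times.

    Returns the trace and the ground-truth bleach times (s).  The
    signal-to-noise ratio per fluorophore is
    ``intensity_per_fluor / noise_sd``.
    """
    if n_fluor < 0:
        raise ValueError("n_fluor must be nonnegative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / frame_rate)
    bleach_times = np.sort(rng.exponential(1.0 / bleach_rate, n_fluor))
    active = (t[:, None] < bleach_times[None, :]).sum(axis=1) if n_fluor else np.zeros(len(t))
    intensity = intensity_per_fluor * active + rng.normal(0, noise_sd, len(t))
    return FluorTrace(time=t, intensity=intensity, frame_rate=frame_rate), bleach_times


def gen_spot_image(
    n_spots: int,
    shape: tuple[int, int] = (64, 64),
    amplitude: float = 800.0,
    psf_sd: float = 1.2,
    noise_sd: float = 100.0,
    min_separation: int = 6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Snapshot image with planted Gaussian spots; returns (image, centers)."""
    rng = np.random.default_rng(seed)
    centers = []
    attempts = 0
    while len(centers) < n_spots and attempts < 10_000:
        c = rng.uniform([4, 4], [shape[0] - 4, shape[1] - 4])
        if all(np.hypot(*(c - o)) >= min_separation for o in centers):
            centers.append(c)
        attempts += 1
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = rng.normal(0, noise_sd, shape)
    for cy, cx in centers:
        img += amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * psf_sd**2))
    return img, np.array(centers)


# ---------------------------------------------------------------------------
# smFRET cohorts
# ---------------------------------------------------------------------------

def gen_fret_cohort(
    means: Sequence[float],
    sds: Sequence[float],
    weights: Sequence[float],
    n: int = 765,
    n_frames: int = 400,
    total_intensity: float = 1000.0,
    noise_sd: float = 30.0,
    frame_rate: float = 10.0,
    contaminant_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[TwoColorTrace], dict]:
    """Two-color trace cohort drawn from a Gaussian mixture of efficiencies.

    Each molecule draws a mixture component and a molecular efficiency,
    emits anticorrelated donor/acceptor intensities on donor-excitation
    frames (even frames) and direct acceptor signal on odd frames, and
    bleaches in a single acceptor step followed by a single donor step.
    A ``contaminant_fraction`` of molecules carries two donor fluorophores
    (two donor bleach steps) and should be rejected by single-pair
    selection.  Returns the traces and a ground-truth dict.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    traces, comp_idx, e_true, is_single = [], [], [], []
    for _ in range(n):
        comp = rng.choice(len(weights), p=weights)
        e = float(np.clip(rng.normal(means[comp], sds[comp]), 0.02, 0.98))
        contaminant = rng.random() < contaminant_fraction
        t = np.arange(n_frames) / frame_rate
        donor_exc = np.arange(n_frames) % 2 == 0
        # bleach frames: acceptor first (uniform in mid-trace), then donor
        a_bleach = rng.integers(n_frames // 3, 2 * n_frames // 3)
        d_bleach = rng.integers(a_bleach + n_frames // 6, n_frames - 10)
        donor = np.zeros(n_frames)
        acceptor = np.zeros(n_frames)
        alive_a = np.arange(n_frames) < a_bleach
        alive_d = np.arange(n_frames) < d_bleach
        n_donors = 2 if contaminant else 1
        if contaminant:
            d2_bleach = rng.integers(a_bleach + 5, n_frames - 5)
            alive_d2 = np.arange(n_frames) < d2_bleach
        # donor excitation frames: FRET partitioning while acceptor alive
        de = donor_exc
        donor[de] = total_intensity * (1 - e) * alive_d[de] + (
            total_intensity * alive_d2[de] if contaminant else 0.0
        )
        donor[de & ~alive_a] = total_intensity * alive_d[de & ~alive_a] * 1.0 + (
            total_intensity * alive_d2[de & ~alive_a] if contaminant else 0.0
        )
        acceptor[de] = total_intensity * e * alive_a[de] * alive_d[de]
        # direct acceptor excitation frames
        ae = ~donor_exc
        acceptor[ae] = total_intensity * alive_a[ae]
        donor += rng.normal(0, noise_sd, n_frames)
        acceptor += rng.normal(0, noise_sd, n_frames)
        traces.append(TwoColorTrace(time=t, donor=donor, acceptor=acceptor,
                                    donor_excitation=donor_exc, frame_rate=frame_rate))
        comp_idx.append(comp)
        e_true.append(e)
        is_single.append(not contaminant)
    truth = {
        "component": np.array(comp_idx),
        "e_true": np.array(e_true),
        "single_pair": np.array(is_single, dtype=bool),
    }
    return traces, truth


# ---------------------------------------------------------------------------
# magnetic-tweezers traces
# ---------------------------------------------------------------------------

def gen_disassembly_trace(
    levels: dict[str, float] | None = None,
    taus: dict[str, float] | None = None,
    path: Sequence[str] = ("FZ", "I20S", "UC"),
    sample_rate: float = 1200.0,
    noise_sd: float = 3.0,
    tail_s: float = 0.1,
    force: float = 12.0,
    seed: int = 0,
) -> tuple[ExtensionTrace, np.ndarray, float]:
    """Markov disassembly trace with exponential state dwells.

    ``levels`` maps state names to extension levels (nm) and ``taus`` to
    dwell time constants (s); the final state of ``path`` is absorbing and
    lasts ``tail_s``.  Returns ``(trace, true_state_index_per_frame,
    event_time)`` where the event is entry into the final state.
    """
    levels = levels or {"FZ": 0.0, "I20S": 13.0, "UC": 30.0}
    taus = taus or {"FZ": 0.05, "I20S": 0.007}
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate
    seg_states: list[str] = []
    seg_durations: list[float] = []
    for st in path[:-1]:
        seg_states.append(st)
        seg_durations.append(rng.exponential(taus[st]))
    seg_states.append(path[-1])
    seg_durations.append(tail_s)
    n_frames = [max(1, int(round(d / dt))) for d in seg_durations]
    state_idx = np.concatenate([
        np.full(nf, i) for i, nf in enumerate(n_frames)
    ])
    ext = np.array([levels[seg_states[i]] for i in state_idx], dtype=float)
    ext += rng.normal(0, noise_sd, len(ext))
    t = np.arange(len(ext)) * dt
    event_time = sum(n_frames[:-1]) * dt  # frame-aligned entry into the final state
    trace = ExtensionTrace(time=t, extension=ext, force=force, sample_rate=sample_rate)
    return trace, state_idx, float(event_time)


def gen_white_noise_trace(
    sigma: float = 6.0,
    duration_s: float = 10.0,
    sample_rate: float = 1200.0,
    force: float = 12.0,
    seed: int = 0,
) -> ExtensionTrace:
    """Stationary white-noise extension segment (noise-floor fixture)."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * sample_rate)
    return ExtensionTrace(
        time=np.arange(n) / sample_rate,
        extension=rng.normal(0, sigma, n),
        force=force,
        sample_rate=sample_rate,
    )


def gen_first_passage_latencies(
    tau_s: float,
    n: int = 50,
    observation_s: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential first-passage sample with optional observation cutoff."""
    rng = np.random.default_rng(seed)
    lat = rng.exponential(tau_s, n)
    if observation_s is None:
        return lat, np.zeros(n, dtype=bool)
    cens = lat > observation_s
    return np.where(cens, observation_s, lat), cens


# ---------------------------------------------------------------------------
# scenario presets — the study conditions, named by the figures they emulate
# ---------------------------------------------------------------------------

FIG6C_PARAMS = {"beta": 59.0, "gamma": 7.0, "k_d": 4.8}
FIG6F_PARAMS = {"gamma": 2.9, "k_d": 11.0, "alpha": 1.6}
FIG4C_FRET = {"means": (0.19, 0.46, 0.70), "sds": (0.05, 0.05, 0.05),
              "weights": (0.16, 0.42, 0.42)}
LABELING_EFFICIENCY = 0.90
TAU_I20S_S = 0.007


def fig6c_titration(seed: int = 42, noise_cv: float = 0.05, n_rep: int = 6) -> atpase.TitrationDataset:
    """Stimulated (20S-complex) ATP titration at the fitted two-mode parameters."""
    return gen_titration(
        lambda a: atpase.twomode_rate(a, **FIG6C_PARAMS),
        noise_cv=noise_cv, n_rep=n_rep, seed=seed,
    )


def fig6f_titration(seed: int = 7, noise_cv: float = 0.07, n_rep: int = 5) -> atpase.TitrationDataset:
    """Basal (free hexamer) ATP titration at the fitted sequential-binding parameters."""
    return gen_titration(
        lambda a: atpase.knf_rate(a, beta=0.0, mode="basal", **FIG6F_PARAMS),
        noise_cv=noise_cv, n_rep=n_rep, seed=seed,
    )


def fig1_disassembly(n_traces: int = 100, seed: int = 11, noise_sd: float | None = None):
    """High-rate disassembly traces with the 7-ms intermediate planted.

    Noise SD defaults to half the smaller level spacing, the regime in
    which the intermediate is detectable but not trivial.
    """
    levels = {"FZ": 0.0, "I20S": 13.0, "UC": 30.0}
    spacing = min(13.0, 17.0)
    noise = 0.5 * spacing if noise_sd is None else noise_sd
    out = []
    for i in range(n_traces):
        out.append(
            gen_disassembly_trace(
                levels=levels, taus={"FZ": 0.05, "I20S": TAU_I20S_S},
                noise_sd=noise, seed=seed * 100_000 + i,
            )
        )
    return out


def fig3_cohort(x: float = 0.5, n: int = 10_000, seed: int = 3) -> HexamerCohort:
    """Hybrid-hexamer cohort under the consecutive-WT binding rule."""
    return gen_hexamer_cohort(x=x, r=LABELING_EFFICIENCY,
                              rule=ringcomb.THREE_CONSECUTIVE_WT, n=n, seed=seed)


def dimer_control(n: int = 1000, seed: int = 5, r: float = LABELING_EFFICIENCY) -> StepHistogram:
    """Tandem-dimer labeling-efficiency control at the measured efficiency."""
    return gen_dimer_step_counts(r=r, n=n, seed=seed)
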