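"""Synthetic data with planted ground truth.

Generators for every data modality the pipeline consumes, each a pure
function of (spec, seed) so downstream stages can be validated against
known ground truth without any recordings:

* two-channel photometry traces — cue-/reward-locked transients riding on
  a shared bleaching trend and motion artifact;
* inhomogeneous-Poisson spike sessions with planted encoding profiles
  (cue/reward activated or inhibited, press-inhibited, nonencoding) whose
  gains can drift across trials;
* low-rank unit × trial × time tensors built from planted cell assemblies;
* exponential-demand consumption tables with multiplicative lognormal
  noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .events import TrialEvents
from .photometry import PhotometryRecording
from .spikes import SpikeSession
from .tca import CPModel, TrialTensor

# ---------------------------------------------------------------------------
# photometry


@dataclass
class PhotometryGenSpec:
    """Planted-transient photometry session parameters.

    Amplitudes are ΔF/F fractions of the (unit) fluorescence baseline; the
    bleaching trend and the band-limited motion artifact are shared between
    the signal and isosbestic channels (the artifact with a
    channel-specific gain), while transients appear only on the signal
    channel.
    """

    fs: float = 100.0
    duration: float = 600.0
    artifact_amp: float = 0.02
    artifact_cutoff_hz: float = 1.0
    bleach_tau: float = 1800.0
    transient_times: np.ndarray | None = None
    transient_amp: float = 0.05
    transient_rise_tau: float = 0.1
    transient_decay_tau: float = 0.5
    noise_sd: float = 0.002
    iso_artifact_gain: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.transient_rise_tau <= 0 or self.transient_decay_tau <= 0:
            raise ValueError("kernel taus must be > 0")
        if self.transient_times is not None:
            tt = np.asarray(self.transient_times, dtype=float)
            if len(tt) and (tt.min() < 0 or tt.max() >= self.duration):
                raise ValueError("transient times must lie in [0, duration)")


def transient_kernel(fs: float, rise_tau: float, decay_tau: float, length_s: float = 5.0):
    """Difference-of-exponentials kernel, peak-normalized to 1."""
    t = np.arange(int(length_s * fs)) / fs
    k = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    return k / k.max()


def gen_photometry_session(
    spec: PhotometryGenSpec, events: TrialEvents | None = None
) -> PhotometryRecording:
    """Two-channel synthetic photometry recording.

    Transients are planted at ``spec.transient_times`` if given, otherwise
    at the cue onsets and reward/infusion deliveries of ``events``.  Ground
    truth (transient times and amplitude) is attached as metadata.
    """
    if spec.transient_times is not None:
        times = np.asarray(spec.transient_times, dtype=float)
    elif events is not None:
        times = np.sort(
            np.concatenate(
                [events.times_of("cue_on"), events.times_of("reward"),
                 events.times_of("infusion")]
            )
        )
        times = times[times < spec.duration]
    else:
        times = np.array([])
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    bleach = np.exp(-t / spec.bleach_tau)
    if spec.artifact_amp > 0:
        white = rng.standard_normal(n)
        sos = sps.butter(2, spec.artifact_cutoff_hz, btype="low", fs=spec.fs, output="sos")
        motion = sps.sosfiltfilt(sos, white)
        motion *= spec.artifact_amp / max(motion.std(), 1e-12)
    else:
        motion = np.zeros(n)

    dff = np.zeros(n)
    if len(times) and spec.transient_amp != 0:
        kern = transient_kernel(spec.fs, spec.transient_rise_tau, spec.transient_decay_tau)
        for tt in times:
            i0 = int(round(tt * spec.fs))
            seg = kern[: n - i0]
            dff[i0 : i0 + len(seg)] += spec.transient_amp * seg

    sig = bleach * (1.0 + motion + dff) + spec.noise_sd * rng.standard_normal(n)
    iso = bleach * (1.0 + spec.iso_artifact_gain * motion) + spec.noise_sd * rng.standard_normal(n)
    return PhotometryRecording(
        signal_470=sig,
        iso_405=iso,
        fs=spec.fs,
        ground_truth={
            "transient_times": times,
            "transient_amp": spec.transient_amp,
            "artifact": motion,
        },
    )


# ---------------------------------------------------------------------------
# spikes

PROFILE_WINDOWS = {
    # seconds relative to cue onset during which the profile modulates
    "cue_activated": (0.0, 2.0),
    "cue_inhibited": (0.0, 2.0),
    "reward_activated": (2.0, 7.0),
    "reward_inhibited": (2.0, 7.0),
    "press_inhibited": (-2.0, 2.0),
}


@dataclass
class SpikeGenSpec:
    """Planted-profile spike session parameters.

    ``profile_mix`` gives the proportion of units per encoding profile
    (must sum to 1).  ``gain`` is the in-window rate multiplier for
    activated profiles; inhibited profiles divide by it.  ``trial_drift``
    optionally maps a profile name to a function of normalized trial
    position in [0, 1] scaling the modulation depth across trials.
    """

    n_units: int = 100
    profile_mix: dict = field(
        default_factory=lambda: {
            "cue_activated": 0.2,
            "cue_inhibited": 0.2,
            "reward_activated": 0.2,
            "reward_inhibited": 0.2,
            "nonencoding": 0.2,
        }
    )
    baseline_rate_range: tuple[float, float] = (2.0, 10.0)
    gain: float = 3.0
    trial_drift: dict | None = None
    group_label: str = "CTRL"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.profile_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile_mix must sum to 1, got {total}")
        unknown = set(self.profile_mix) - set(PROFILE_WINDOWS) - {"nonencoding"}
        if unknown:
            raise ValueError(f"unknown profiles: {sorted(unknown)}")
        if self.baseline_rate_range[0] <= 0 or self.gain <= 0:
            raise ValueError("rates and gain must be positive")


def _profile_counts(mix: dict, n: int) -> dict:
    """Largest-remainder apportionment of n units across profiles."""
    items = sorted(mix.items())
    raw = {k: v * n for k, v in items}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(items, key=lambda kv: raw[kv[0]] - counts[kv[0]], reverse=True)
    for k, _ in order[:short]:
        counts[k] += 1
    return counts


def gen_spike_session(spec: SpikeGenSpec, events: TrialEvents) -> SpikeSession:
    """Inhomogeneous-Poisson spike trains with planted encoding profiles.

    Each unit fires at a uniform baseline rate modulated within its
    profile's peri-cue window on every trial: activated profiles multiply
    the rate by an effective gain 1 + (gain−1)·drift(trial), inhibited
    profiles divide by it.  Spikes are generated exactly (extra spikes
    added for excitation, baseline spikes thinned for inhibition).  Ground
    truth profile tags are attached.
    """
    cues = events.times_of("cue_on")
    if len(cues) == 0:
        raise ValueError("events contain no cues")
    duration = events.duration
    rng = np.random.default_rng(spec.seed)
    counts = _profile_counts(spec.profile_mix, spec.n_units)
    profiles: dict = {}
    units = []
    uid = 0
    frac = (
        np.arange(len(cues)) / max(len(cues) - 1, 1)
    )  # normalized trial position in [0, 1]
    for profile in sorted(counts):
        for _ in range(counts[profile]):
            base = rng.uniform(*spec.baseline_rate_range)
            spikes = rng.uniform(0.0, duration, rng.poisson(base * duration))
            if profile != "nonencoding":
                w0, w1 = PROFILE_WINDOWS[profile]
                drift_fn = (spec.trial_drift or {}).get(profile)
                keep = np.ones(len(spikes), dtype=bool)
                extra = []
                for j, c in enumerate(cues):
                    drift = float(drift_fn(frac[j])) if drift_fn else 1.0
                    eff = 1.0 + (spec.gain - 1.0) * drift
                    a, b = c + w0, c + w1
                    if "inhibited" in profile:
                        in_win = (spikes >= a) & (spikes < b)
                        keep &= ~in_win | (rng.uniform(size=len(spikes)) < 1.0 / eff)
                    else:
                        n_extra = rng.poisson(base * (eff - 1.0) * (b - a))
                        extra.append(rng.uniform(a, b, n_extra))
                spikes = spikes[keep]
                if extra:
                    spikes = np.concatenate([spikes] + extra)
            spikes = np.sort(spikes[(spikes >= 0) & (spikes <= duration)])
            units.append((uid, spikes))
            profiles[uid] = profile
            uid += 1
    return SpikeSession(
        units=units,
        session_duration=duration,
        group_label=spec.group_label,
        profiles=profiles,
    )


def pr_like_events(
    n_trials: int,
    trial_spacing: float = 30.0,
    first_cue: float = 10.0,
    reward_delay: float = 2.0,
) -> TrialEvents:
    """Regularly spaced cue/reward event stream for PSTH-stage testing."""
    recs = []
    for i in range(n_trials):
        c = first_cue + i * trial_spacing
        recs.append((c - 5.0, "trial_start", i + 1))
        recs.append((c, "cue_on", i + 1))
        recs.append((c + 2.0, "cue_off", i + 1))
        recs.append((c + reward_delay, "reward", i + 1))
        recs.append((c + reward_delay, "trial_end", i + 1))
    return TrialEvents.from_records(
        recs, session_length=first_cue + n_trials * trial_spacing
    )


# ---------------------------------------------------------------------------
# trial tensors

ASSEMBLY_MOTIFS = ("cue_activated", "reward_activated", "cue_inhibited", "reward_inhibited")


@dataclass
class TensorGenSpec:
    """Planted low-rank trial-tensor parameters.

    The tensor is a sum of ``r_true`` rank-1 cell assemblies — smooth
    within-trial motifs localized to the cue (0–2 s) or reward (2–7 s)
    window, monotone or flat trial trends, and non-negative unit loadings
    concentrated on disjoint unit subsets — plus Gaussian noise.  When
    ``noise_sd`` is None it is set so the signal-to-noise ratio
    ‖signal‖/‖noise‖ is ``snr``.
    """

    U: int = 100
    T: int = 8
    P: int = 60
    r_true: int = 4
    snr: float = 5.0
    noise_sd: float | None = None
    group_labels: np.ndarray | None = None
    group_loading_shift: np.ndarray | None = None
    time_span: tuple[float, float] = (-2.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_true > min(self.U, self.T, self.P):
            raise ValueError("r_true exceeds tensor dimensions")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _assembly_motif(kind: str, time: np.ndarray) -> np.ndarray:
    # distinct center/width per assembly so temporal factors are not collinear
    shapes = {
        "cue_activated": (0.8, 0.45, +1.0),
        "cue_inhibited": (1.3, 0.7, -1.0),
        "reward_activated": (3.5, 1.0, +1.0),
        "reward_inhibited": (5.0, 1.5, -1.0),
    }
    c, w, sign = shapes[kind]
    bump = sign * np.exp(-0.5 * ((time - c) / w) ** 2)
    return bump / np.linalg.norm(bump)


def gen_trial_tensor(spec: TensorGenSpec) -> tuple[TrialTensor, CPModel]:
    """Planted-assembly tensor and its ground-truth CP model."""
    rng = np.random.default_rng(spec.seed)
    time = np.linspace(*spec.time_span, spec.P, endpoint=False)
    time = time + (spec.time_span[1] - spec.time_span[0]) / spec.P / 2.0

    A = np.stack(
        [_assembly_motif(ASSEMBLY_MOTIFS[r % len(ASSEMBLY_MOTIFS)], time)
         for r in range(spec.r_true)],
        axis=1,
    )
    # distinct trial trends: declining, growing, flat, U-shaped, ...
    x = np.linspace(0.0, 1.0, spec.T)
    trend_bank = [
        np.linspace(1.0, 0.4, spec.T),
        np.linspace(0.4, 1.0, spec.T),
        np.ones(spec.T),
        0.4 + (2.0 * x - 1.0) ** 2,
    ]
    trends = [trend_bank[r % len(trend_bank)] for r in range(spec.r_true)]
    B = np.stack([b / np.linalg.norm(b) for b in trends], axis=1)

    labels = (
        np.asarray(spec.group_labels)
        if spec.group_labels is not None
        else np.array(["CTRL"] * spec.U)
    )
    if len(labels) != spec.U:
        raise ValueError("group_labels must have length U")
    shift = (
        np.asarray(spec.group_loading_shift, dtype=float)
        if spec.group_loading_shift is not None
        else np.zeros(spec.r_true)
    )
    W = 0.05 * np.abs(rng.standard_normal((spec.U, spec.r_true)))
    owners = np.arange(spec.U) % spec.r_true
    W[np.arange(spec.U), owners] = np.abs(rng.normal(1.0, 0.3, spec.U))
    is_shifted = labels == "PCE"
    W[is_shifted] += shift[None, :]
    W = np.clip(W, 0.0, None)

    truth = CPModel(r=spec.r_true, W=W, B=B, A=A)
    X = truth.reconstruct()
    if spec.noise_sd is None:
        sd = np.linalg.norm(X) / (spec.snr * math.sqrt(X.size))
    else:
        sd = spec.noise_sd
    X = X + sd * rng.standard_normal(X.shape)
    tensor = TrialTensor(
        X=X,
        unit_ids=list(range(spec.U)),
        group_labels=labels,
        trial_indices=np.arange(1, spec.T + 1),
        time=time,
    )
    return tensor, truth


# ---------------------------------------------------------------------------
# demand observations


@dataclass
class DemandGenSpec:
    """Exponential-demand consumption generator parameters."""

    Q0_true: float = 50.0
    alpha_true: float = 0.002
    k_true: float = 2.0
    prices: tuple = (180, 90, 45, 15, 5)
    noise_sd: float = 0.1  # sd of log-normal multiplicative noise
    additive_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.Q0_true, self.alpha_true, self.k_true) <= 0:
            raise ValueError("Q0_true, alpha_true and k_true must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_demand_observations(spec: DemandGenSpec) -> pd.DataFrame:
    """Consumption-per-price table from the exponential model of demand.

    Consumption Q(price) = Q0·10^(k·(e^(−α·Q0·price) − 1)) perturbed by
    multiplicative lognormal noise (or additive Gaussian noise when
    ``additive_noise``).  Ground-truth parameters are stored in
    ``df.attrs["ground_truth"]``.
    """
    from .demand import demand_model

    rng = np.random.default_rng(spec.seed)
    p = np.asarray(spec.prices, dtype=float)
    q = demand_model(spec.Q0_true, spec.alpha_true, spec.k_true, p)
    if spec.noise_sd > 0:
        if spec.additive_noise:
            q = np.clip(q + spec.noise_sd * rng.standard_normal(len(p)), 0.0, None)
        else:
            q = q * np.exp(spec.noise_sd * rng.standard_normal(len(p)))
    df = pd.DataFrame({"price": p, "consumption": q})
    df.attrs["ground_truth"] = {
        "Q0": spec.Q0_true,
        "alpha": spec.alpha_true,
        "k": spec.k_true,
    }
    return df
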