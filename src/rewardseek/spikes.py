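"""Single-unit encoding-pattern analysis.

Normalizes single-unit firing to each unit's session-mean rate,
standardizes (z-scores) the normalized rates across units per time bin,
smooths with a truncated Gaussian kernel (8 bins, σ = 3 bins), extracts
four features per unit — (i) number of transients (peaks and troughs),
(ii) time to first transient relative to cue onset, (iii) mean activity
during the cue window, (iv) mean activity after reward delivery — and
discovers encoding patterns by iterative k-means: k grows while genuinely
new patterns keep emerging and stops once a newly found pattern resembles
one already discovered.  Units that do not fit any pattern are labeled
"nonencoding".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d
from sklearn.cluster import KMeans

from .events import TrialEvents
from .photometry import trapezoid_window

ENCODING_PROFILES = (
    "cue_activated",
    "cue_inhibited",
    "reward_activated",
    "reward_inhibited",
    "press_inhibited",
    "nonencoding",
)

CUE_WINDOW = (0.0, 2.0)
REWARD_WINDOW = (2.0, 7.0)


@dataclass
class SpikeSession:
    """Spike-time lists per unit plus session metadata.

    ``profiles`` (ground-truth encoding tags) is populated by the synthetic
    generator and never consulted by the analysis stages.
    """

    units: list  # list of (unit_id, np.ndarray of spike times in s)
    session_duration: float
    group_label: str = "CTRL"
    sex: str = "F"
    profiles: dict | None = None

    def __post_init__(self) -> None:
        clean = []
        for uid, st in self.units:
            st = np.asarray(st, dtype=float)
            if len(st) and (st.min() < 0 or st.max() > self.session_duration):
                raise ValueError(f"unit {uid}: spike times outside [0, duration]")
            clean.append((uid, np.sort(st)))
        self.units = clean


@dataclass(frozen=True)
class SmoothingConfig:
    bin_width: float = 0.1
    kernel_bins: int = 8
    kernel_sigma: float = 3.0  # in bins

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.kernel_bins < 1:
            raise ValueError("bin_width must be > 0 and kernel_bins >= 1")


@dataclass
class UnitPSTH:
    """Per-unit trial × time matrices of peri-cue firing.

    ``z`` is the cross-unit standardized rate (population-referenced);
    ``rate`` is the unit's own session-mean-normalized rate (1.0 = the
    unit's average firing), which is independent of the population mix.
    Both are Gaussian-smoothed.
    """

    unit_id: object
    z: np.ndarray  # (n_trials, n_bins), cross-unit z units
    rate: np.ndarray  # (n_trials, n_bins), fraction of session-mean rate
    time: np.ndarray  # bin centers, s relative to cue onset
    session_mean_rate: float
    cross_unit_mean: np.ndarray
    cross_unit_sd: np.ndarray

    @property
    def mean_trace(self) -> np.ndarray:
        return self.z.mean(axis=0)

    @property
    def mean_rate_trace(self) -> np.ndarray:
        return self.rate.mean(axis=0)


@dataclass
class EncodingFeatures:
    unit_id: object
    n_transients: int
    t_first_transient: float
    mean_cue_activity: float
    mean_reward_activity: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.n_transients,
                self.t_first_transient,
                self.mean_cue_activity,
                self.mean_reward_activity,
            ],
            dtype=float,
        )


@dataclass
class ClusterModel:
    """Result of the iterative k-means encoding-pattern search.

    ``k`` counts encoding-pattern clusters; clusters whose mean profile
    shows no appreciable modulation are folded into the "nonencoding"
    label, alongside distance outliers, and are not counted in ``k``.
    """

    k: int
    n_clusters_total: int
    assignments: np.ndarray  # cluster id per unit, -1 for nonencoding
    centroids: np.ndarray  # in standardized feature space
    profiles: np.ndarray  # cluster-mean PSTH traces (n_clusters_total, n_bins)
    semantic_labels: dict  # cluster id -> tag
    unit_ids: list
    history: list = field(default_factory=list)

    def label_of(self, i: int) -> str:
        c = self.assignments[i]
        return "nonencoding" if c < 0 else self.semantic_labels[int(c)]


def gaussian_kernel(n_bins: int = 8, sigma: float = 3.0) -> np.ndarray:
    """Truncated Gaussian kernel of ``n_bins`` taps, renormalized to sum 1."""
    x = np.arange(n_bins) - (n_bins - 1) / 2.0
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def smooth_rows(mat: np.ndarray, cfg: SmoothingConfig) -> np.ndarray:
    """Gaussian-smooth each row along time (reflected edges)."""
    k = gaussian_kernel(cfg.kernel_bins, cfg.kernel_sigma)
    return correlate1d(np.asarray(mat, dtype=float), k, axis=-1, mode="reflect")


def build_unit_psths(
    session: SpikeSession,
    events: TrialEvents,
    cfg: SmoothingConfig | None = None,
    span: tuple[float, float] = (-2.0, 8.0),
) -> list[UnitPSTH]:
    """Session-mean-normalized, cross-unit z-scored, smoothed peri-cue PSTHs.

    Pipeline per unit: binned firing rate around each cue onset → divide by
    the unit's whole-session mean rate → z-score each time bin across units
    (using each unit's trial-averaged normalized rate) → Gaussian smoothing.
    Units with zero session spikes are excluded with a warning.
    """
    cfg = cfg or SmoothingConfig()
    cues = events.times_of("cue_on")
    if len(cues) == 0:
        raise ValueError("no cue events")
    lo, hi = span
    n_bins = int(round((hi - lo) / cfg.bin_width))
    edges_rel = lo + np.arange(n_bins + 1) * cfg.bin_width
    centers = edges_rel[:-1] + cfg.bin_width / 2.0

    usable, norm_rates = [], []
    for uid, st in session.units:
        if len(st) == 0:
            warnings.warn(f"unit {uid} has zero spikes; excluded", stacklevel=2)
            continue
        mean_rate = len(st) / session.session_duration
        counts = np.empty((len(cues), n_bins))
        for j, c in enumerate(cues):
            counts[j] = np.histogram(st, bins=c + edges_rel)[0]
        norm = counts / cfg.bin_width / mean_rate
        usable.append((uid, mean_rate))
        norm_rates.append(norm)
    if not usable:
        raise ValueError("no usable units")

    # cross-unit standardization per time bin, on trial-averaged rates
    trial_means = np.stack([nr.mean(axis=0) for nr in norm_rates])  # units x bins
    mu = trial_means.mean(axis=0)
    sd = trial_means.std(axis=0)
    flat = sd == 0
    if flat.any():
        warnings.warn("zero cross-unit variance in some bins; z set to 0 there", stacklevel=2)
        sd = np.where(flat, 1.0, sd)

    out = []
    for (uid, mean_rate), norm in zip(usable, norm_rates):
        z = (norm - mu) / sd
        z[:, flat] = 0.0
        z = smooth_rows(z, cfg)
        out.append(
            UnitPSTH(
                unit_id=uid,
                z=z,
                rate=smooth_rows(norm, cfg),
                time=centers,
                session_mean_rate=mean_rate,
                cross_unit_mean=mu,
                cross_unit_sd=np.where(flat, 0.0, sd),
            )
        )
    return out


def extract_encoding_features(
    psth: UnitPSTH,
    threshold_rate: float = 0.5,
    threshold_z: float = 2.0,
    transient_mode: str = "rate",
    merge_gap_s: float = 0.3,
    search_window: tuple[float, float] | None = None,
) -> EncodingFeatures:
    """The four clustering features from a unit's trial-averaged PSTH.

    A "transient" is one contiguous excursion of the smoothed trial-averaged
    trace (peaks and troughs each count once).  In the default "rate" mode
    the excursion criterion is |rate − 1| >= ``threshold_rate`` on the
    session-mean-normalized rate — a deviation of at least 50% from the
    unit's own average firing, which is insensitive to the population mix
    entering the cross-unit standardization.  In "z" mode the criterion is
    |z| >= ``threshold_z`` on the cross-unit standardized trace.  The
    first-transient time is the onset of the earliest excursion at or after
    cue onset; the sentinel when none occurs is the end of the search
    window.  Excursions separated by a gap shorter than ``merge_gap_s``
    are one transient (threshold wobble, not a second event).  Mean cue
    and reward activity are in cross-unit z units.
    """
    trace = psth.mean_trace
    t = psth.time
    if transient_mode == "rate":
        excursion_sig = np.abs(psth.mean_rate_trace - 1.0)
        thr = threshold_rate
    elif transient_mode == "z":
        excursion_sig = np.abs(trace)
        thr = threshold_z
    else:
        raise ValueError(f"unknown transient_mode {transient_mode!r}")
    if search_window is None:
        search_window = (0.0, float(t[-1]) + (t[1] - t[0]) / 2.0)
    a, b = search_window
    mask = (t >= a) & (t <= b)
    seg, tseg = excursion_sig[mask], t[mask]
    exc = seg >= thr
    starts = np.flatnonzero(exc & ~np.concatenate(([False], exc[:-1])))
    ends = np.flatnonzero(exc & ~np.concatenate((exc[1:], [False])))
    # merge excursions separated by sub-merge_gap_s gaps (threshold wobble)
    merged = []
    for st, en in zip(starts, ends):
        if merged and tseg[st] - tseg[merged[-1][1]] < merge_gap_s:
            merged[-1] = (merged[-1][0], en)
        else:
            merged.append((st, en))
    n_trans = len(merged)
    t_first = float(tseg[merged[0][0]]) if n_trans else float(b)
    cue_mask = (t >= CUE_WINDOW[0]) & (t < CUE_WINDOW[1])
    rew_mask = (t >= REWARD_WINDOW[0]) & (t < REWARD_WINDOW[1])
    return EncodingFeatures(
        unit_id=psth.unit_id,
        n_transients=int(n_trans),
        t_first_transient=t_first,
        mean_cue_activity=float(trace[cue_mask].mean()),
        mean_reward_activity=float(trace[rew_mask].mean()),
    )


def window_aucz(psth: UnitPSTH, window: tuple[float, float]) -> float:
    """Trapezoidal AUC (z·s) of the trial-averaged z trace over a window."""
    return trapezoid_window(psth.time, psth.mean_trace, window)


def discover_encoding_patterns(
    session: SpikeSession,
    events: TrialEvents,
    cfg: SmoothingConfig | None = None,
    **cluster_kwargs,
) -> tuple[list[UnitPSTH], list[EncodingFeatures], ClusterModel]:
    """Full encoding-pattern pipeline: PSTHs -> features -> iterative k-means."""
    psths = build_unit_psths(session, events, cfg)
    feats = [extract_encoding_features(p) for p in psths]
    profiles = np.stack([p.mean_trace for p in psths])
    rates = np.stack([p.mean_rate_trace for p in psths])
    model = cluster_encoding_patterns(
        feats, profiles=profiles, rate_profiles=rates, time=psths[0].time,
        **cluster_kwargs,
    )
    return psths, feats, model


def _semantic_label(deviation: np.ndarray, time: np.ndarray, threshold: float) -> str:
    """Tag a cluster from its deviation profile (rate − 1, or z fallback).

    Window means relative to cue onset decide the tag; sustained
    suppression spanning the pre-cue pressing epoch into the cue window is
    press-related inhibition.
    """
    pre = deviation[(time >= -2.0) & (time < 0.0)]
    cue = deviation[(time >= CUE_WINDOW[0]) & (time < CUE_WINDOW[1])]
    rew = deviation[(time >= REWARD_WINDOW[0]) & (time < REWARD_WINDOW[1])]
    m_pre = pre.mean() if len(pre) else 0.0
    m_cue, m_rew = cue.mean(), rew.mean()
    if max(abs(m_cue), abs(m_rew), abs(m_pre)) < threshold:
        return "nonencoding"
    if m_pre < -threshold and m_cue < -threshold:
        return "press_inhibited"
    if abs(m_cue) >= abs(m_rew):
        return "cue_activated" if m_cue > 0 else "cue_inhibited"
    return "reward_activated" if m_rew > 0 else "reward_inhibited"


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def cluster_encoding_patterns(
    features: list[EncodingFeatures],
    profiles: np.ndarray | None = None,
    rate_profiles: np.ndarray | None = None,
    time: np.ndarray | None = None,
    k_start: int = 2,
    max_k: int = 8,
    seed: int = 0,
    redundancy_threshold: float = 0.9,
    modulation_threshold: float = 0.5,
    rate_modulation_threshold: float = 0.25,
    min_cluster_frac: float = 0.05,
    outlier_percentile: float = 97.5,
    n_restarts: int = 50,
) -> ClusterModel:
    """Discover encoding patterns by iterative k-means on the four features.

    k-means (``n_restarts`` k-means++ restarts, seeded) runs at increasing
    k.  Growing k is accepted while each refinement either uncovers an
    additional encoding pattern or first isolates a flat (nonencoding)
    cluster; the search stops as soon as a solution splits an existing
    pattern — contains two modulated cluster profiles with cosine
    similarity at or above ``redundancy_threshold`` — or adds nothing new,
    and the last accepted solution is kept.

    A cluster counts as an encoding pattern when it is modulated: when
    ``rate_profiles`` (n_units x n_bins session-mean-normalized rates) is
    given, a cluster is modulated if its mean rate profile deviates from
    the session mean (1.0) by at least ``rate_modulation_threshold``
    anywhere — a criterion independent of the cross-unit population mix;
    otherwise the z-profile magnitude is compared against
    ``modulation_threshold``.  A pattern must also hold at least
    ``min_cluster_frac`` of the units: smaller clusters are outlier debris,
    excluded from the pattern count and the redundancy checks.
    Unmodulated or undersized clusters are labeled "nonencoding" and
    excluded from the returned ``k``, as are units farther from every
    centroid than the ``outlier_percentile`` of within-cluster distances.

    Redundancy between two patterns is cosine similarity of their
    rate-deviation profiles (cluster-mean rate − 1) when ``rate_profiles``
    is given — deviations are localized to each pattern's window, so a
    genuine split of one pattern scores near 1 while distinct patterns
    score near 0 — else of the z profiles (or feature centroids).
    """
    n = len(features)
    if n < k_start:
        raise ValueError(f"need at least {k_start} units, got {n}")
    F = np.stack([f.as_array() for f in features])
    mu, sd = F.mean(axis=0), F.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    X = (F - mu) / sd
    for name, arr in (("profiles", profiles), ("rate_profiles", rate_profiles)):
        if arr is not None and np.asarray(arr).shape[0] != n:
            raise ValueError(f"{name} must have one row per unit")
    if profiles is not None:
        profiles = np.asarray(profiles, dtype=float)
    if rate_profiles is not None:
        rate_profiles = np.asarray(rate_profiles, dtype=float)

    def cluster_means(arr, labels, k):
        return np.stack([arr[labels == c].mean(axis=0) for c in range(k)])

    min_size = max(2, int(np.ceil(min_cluster_frac * n)))

    def fit_solution(k):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed + k).fit(X)
        labels = km.labels_
        sizes = np.bincount(labels, minlength=k)
        profs = cluster_means(profiles if profiles is not None else F, labels, k)
        if rate_profiles is not None:
            dev = cluster_means(rate_profiles, labels, k) - 1.0
            mod = np.abs(dev).max(axis=1) >= rate_modulation_threshold
        else:
            dev = profs
            mod = np.abs(profs).max(axis=1) >= modulation_threshold
        mod &= sizes >= min_size
        return dict(k=k, labels=labels, centroids=km.cluster_centers_,
                    profiles=profs, deviations=dev, mod_flags=mod)

    def has_redundant_pair(sol):
        idx = np.flatnonzero(sol["mod_flags"])
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if _cosine(sol["deviations"][idx[a]], sol["deviations"][idx[b]]) >= redundancy_threshold:
                    return True
        return False

    accepted = None
    history = []
    for k in range(k_start, min(max_k, n) + 1):
        sol = fit_solution(k)
        n_pat = int(sol["mod_flags"].sum())
        n_flat = int((~sol["mod_flags"]).sum())
        if accepted is None:
            accepted = sol
            history.append((k, "accepted", f"{n_pat} patterns"))
            continue
        if has_redundant_pair(sol):
            history.append((k, "rejected", "split of an existing pattern"))
            break
        if n_pat > int(accepted["mod_flags"].sum()):
            accepted = sol
            history.append((k, "accepted", f"{n_pat} patterns"))
        elif n_flat >= 1 and int((~accepted["mod_flags"]).sum()) == 0:
            accepted = sol
            history.append((k, "accepted", "nonencoding cluster isolated"))
        else:
            history.append((k, "rejected", "no new pattern"))
            break

    labels = accepted["labels"]
    k_total = accepted["k"]
    profs = accepted["profiles"]
    mod_flags = accepted["mod_flags"]
    # distance-outlier rule -> nonencoding
    d = np.linalg.norm(X - accepted["centroids"][labels], axis=1)
    thr = np.percentile(d, outlier_percentile)
    assignments = labels.astype(int)
    assignments[d > thr] = -1
    tvec = time if time is not None else np.linspace(-2, 8, profs.shape[1])
    sem = {}
    for c in range(k_total):
        if not mod_flags[c]:
            sem[c] = "nonencoding"
            assignments[labels == c] = -1
        elif rate_profiles is not None:
            sem[c] = _semantic_label(
                accepted["deviations"][c], tvec, rate_modulation_threshold
            )
        elif profiles is not None:
            sem[c] = _semantic_label(profs[c], tvec, modulation_threshold)
        else:
            sem[c] = f"pattern_{c}"
    return ClusterModel(
        k=int(mod_flags.sum()),
        n_clusters_total=k_total,
        assignments=assignments,
        centroids=accepted["centroids"],
        profiles=profs,
        semantic_labels=sem,
        unit_ids=[f.unit_id for f in features],
        history=history,
    )
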