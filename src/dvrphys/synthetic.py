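"""Synthetic ground-truth generators for the whole analysis chain.

Everything downstream of raw data acquisition is testable against these
generators: a known two-input linear system (Laguerre ground truth)
produces beat-level and raw pulsatile waveform data; a Gaussian-copula
cohort model produces marker/score tables with prescribed group means,
SDs and inter-marker correlations; and a voxel generator plants linear
DVR associations in designated fractions of atlas regions.

Defaults emulate the study conditions the analysis targets: 16 control
subjects vs 36 amnestic-MCI patients, resting recordings of 5-6 min,
slow (<0.1 Hz) resting fluctuations of ABP and ETCO2, group DVR means
1.1546 vs 0.5449, and a DVR-FA correlation of 0.6107.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .laguerre import laguerre_basis
from .preprocess import UniformSeries, WaveformRecord

MARKERS = ["DVR", "FA", "MD", "RD", "Trails-B", "WAIS-dig", "WCST-per",
           "LF-F&A&S", "CVLT-LDFR", "CVLT-total", "VRT"]

# Per-group (mean, SD) defaults for the 11 markers/scores; MD and RD on
# the x1e3 scale.  Order matches MARKERS.
GROUP_MOMENTS = {
    "CS": [(1.1546, 0.6461), (0.5950, 0.0283), (0.7190, 0.0219),
           (0.4630, 0.0263), (56.9375, 15.0575), (7.3125, 1.8154),
           (55.3125, 11.9372), (39.6875, 7.5694), (12.0000, 2.5298),
           (53.3750, 10.0391), (51.0000, 15.8661)],
    "MP": [(0.5449, 0.6031), (0.5772, 0.0327), (0.7420, 0.0279),
           (0.4880, 0.0316), (77.1389, 30.9222), (5.7500, 1.9030),
           (55.7941, 22.9502), (36.3056, 11.2016), (9.4444, 2.3354),
           (45.2778, 11.2596), (41.9714, 15.5137)],
}

# Default pairwise correlation targets among the 11 markers/scores
# (pooled across groups, covariate-adjusted scale).
_CORR_PAIRS = {
    (0, 1): 0.6107, (0, 2): -0.6197, (0, 3): -0.6045, (0, 4): -0.2270,
    (0, 5): 0.2104, (0, 6): 0.0025, (0, 7): 0.2105, (0, 8): 0.2826,
    (0, 9): 0.1904, (0, 10): -0.0762,
    (1, 2): -0.6545, (1, 3): -0.8188, (1, 4): -0.4601, (1, 5): 0.1147,
    (1, 6): -0.0682, (1, 7): 0.1455, (1, 8): 0.0629, (1, 9): -0.0071,
    (1, 10): 0.0850,
    (2, 3): 0.8744, (2, 4): 0.5217, (2, 5): -0.1803, (2, 6): 0.1553,
    (2, 7): -0.3402, (2, 8): -0.3605, (2, 9): -0.3506, (2, 10): -0.0371,
    (3, 4): 0.5450, (3, 5): -0.1670, (3, 6): 0.0712, (3, 7): -0.2475,
    (3, 8): -0.2302, (3, 9): -0.1515, (3, 10): -0.0493,
    (4, 5): -0.3288, (4, 6): 0.2312, (4, 7): -0.3092, (4, 8): -0.1536,
    (4, 9): -0.2193, (4, 10): -0.2526,
    (5, 6): -0.2492, (5, 7): 0.2805, (5, 8): 0.1540, (5, 9): 0.2130,
    (5, 10): 0.3745,
    (6, 7): -0.4673, (6, 8): -0.1971, (6, 9): -0.1220, (6, 10): -0.0934,
    (7, 8): 0.2541, (7, 9): 0.3292, (7, 10): -0.0366,
    (8, 9): 0.7265, (8, 10): 0.1831,
    (9, 10): 0.0812,
}


def default_correlation() -> np.ndarray:
    """Default 11x11 marker/score correlation target (positive definite)."""
    R = np.eye(len(MARKERS))
    for (i, j), v in _CORR_PAIRS.items():
        R[i, j] = R[j, i] = v
    return R


@dataclass(frozen=True)
class TrueModel:
    """Generator-side ground-truth two-input linear system.

    First-order kernels are Laguerre expansions: the ABP branch uses
    pole ``alpha_p`` with coefficients ``coeff_p``, the ETCO2 branch
    ``alpha_c``/``coeff_c``; kernels are truncated at memory ``M``
    samples of step ``dt``.
    """

    alpha_p: float
    alpha_c: float
    coeff_p: tuple
    coeff_c: tuple
    baseline_cbfv: float = 60.0    # cm/s
    baseline_abp: float = 90.0     # mmHg
    baseline_etco2: float = 40.0   # mmHg
    dt: float = 1.0                # s
    M: int = 50                    # kernel memory, samples

    def __post_init__(self):
        for a, name in ((self.alpha_p, "alpha_p"), (self.alpha_c, "alpha_c")):
            if not 0.0 <= a < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {a}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for c, name in ((self.coeff_p, "coeff_p"), (self.coeff_c, "coeff_c")):
            if len(c) == 0:
                raise ValueError(f"{name} must be nonempty")
            if not np.all(np.isfinite(c)):
                raise ValueError(f"{name} must be finite")

    def kernel(self, branch: str) -> np.ndarray:
        if branch == "abp":
            alpha, coeff = self.alpha_p, self.coeff_p
        elif branch == "etco2":
            alpha, coeff = self.alpha_c, self.coeff_c
        else:
            raise ValueError(f"unknown branch {branch!r}")
        basis = laguerre_basis(alpha, len(coeff), max(self.M, len(coeff)))
        return np.asarray(coeff, dtype=float) @ basis.values

    @property
    def memory_s(self) -> float:
        return self.M * self.dt


def make_true_model(alpha_p, alpha_c, coeff_p, coeff_c,
                    baseline_cbfv=60.0, baseline_abp=90.0,
                    baseline_etco2=40.0, dt=1.0, M=50) -> TrueModel:
    """Validate and build a ground-truth system (see :class:`TrueModel`)."""
    return TrueModel(alpha_p=float(alpha_p), alpha_c=float(alpha_c),
                     coeff_p=tuple(np.asarray(coeff_p, dtype=float)),
                     coeff_c=tuple(np.asarray(coeff_c, dtype=float)),
                     baseline_cbfv=baseline_cbfv, baseline_abp=baseline_abp,
                     baseline_etco2=baseline_etco2, dt=dt, M=M)


def default_true_model(**overrides) -> TrueModel:
    """A representative resting-physiology ground truth (alpha=0.5, L=3)."""
    kw = dict(alpha_p=0.5, alpha_c=0.5,
              coeff_p=(0.8, -0.4, 0.2), coeff_c=(1.0, 0.5, -0.3))
    kw.update(overrides)
    return make_true_model(**kw)


def true_dvr(model: TrueModel, pulse_duration_s: float = 5.0,
             window_s: float = 5.0) -> float:
    """Closed-form DVR of a ground-truth system.

    For a unit rectangular ETCO2 pulse of ``pulse_duration_s`` the
    response at sample n is the running sum of the CO2 kernel, so the
    DVR (window mean per unit amplitude) is
    (1/K) * sum_{n<K} sum_{m<=n} k_c(m) with K = window / dt.
    """
    k = model.kernel("etco2")
    K = int(round(window_s / model.dt))
    P = int(round(pulse_duration_s / model.dt))
    total = 0.0
    for n in range(K):
        lo = max(0, n - P + 1)
        total += k[lo:n + 1].sum()
    return total / K


def scale_to_dvr(model: TrueModel, target_dvr: float) -> TrueModel:
    """Rescale the CO2 branch so the system's closed-form DVR hits a target."""
    base = true_dvr(model)
    if base == 0:
        raise ValueError("cannot rescale a system with zero DVR")
    s = target_dvr / base
    return make_true_model(model.alpha_p, model.alpha_c, model.coeff_p,
                           tuple(s * np.asarray(model.coeff_c)),
                           baseline_cbfv=model.baseline_cbfv,
                           baseline_abp=model.baseline_abp,
                           baseline_etco2=model.baseline_etco2,
                           dt=model.dt, M=model.M)


def _slow_fluctuations(n: int, dt: float, sd: float, rng,
                       cutoff_hz: float = 0.1) -> np.ndarray:
    """Zero-mean Gaussian noise low-pass filtered below ``cutoff_hz``.

    Resting ABP and ETCO2 variability is concentrated below 0.1 Hz;
    filtered white noise in that band keeps the inputs persistently
    exciting while staying physiological.
    """
    white = rng.standard_normal(n + 200)
    nyq = 0.5 / dt
    if cutoff_hz >= nyq:
        x = white
    else:
        b, a = butter(4, cutoff_hz / nyq)
        x = filtfilt(b, a, white)
    x = x[100:100 + n]
    s = x.std()
    if s > 0 and sd > 0:
        x = x * (sd / s)
    elif sd == 0:
        x = np.zeros(n)
    return x - x.mean()


def simulate_subject(model: TrueModel, duration_s: float = 330.0,
                     noise_sd: float = 0.0, seed: int = 0,
                     abp_sd: float = 3.0, etco2_sd: float = 1.5) -> UniformSeries:
    """Simulate a beat-level resting recording from a ground-truth system.

    ABP and ETCO2 are independent band-limited fluctuations around their
    baselines (SDs ``abp_sd`` mmHg and ``etco2_sd`` mmHg); CBFV is the
    two-branch kernel convolution plus white observation noise of SD
    ``noise_sd`` cm/s.  The same seed always yields the same series.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if duration_s < model.memory_s:
        raise ValueError(
            f"duration {duration_s} s shorter than model memory "
            f"{model.memory_s} s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / model.dt))
    abp_dev = _slow_fluctuations(n, model.dt, abp_sd, rng)
    etco2_dev = _slow_fluctuations(n, model.dt, etco2_sd, rng)
    kp = model.kernel("abp")
    kc = model.kernel("etco2")
    cbfv = (np.convolve(abp_dev, kp)[:n] + np.convolve(etco2_dev, kc)[:n]
            + noise_sd * rng.standard_normal(n))
    return UniformSeries(
        dt=model.dt,
        abp=abp_dev - abp_dev.mean(),
        etco2=etco2_dev - etco2_dev.mean(),
        cbfv=cbfv - cbfv.mean(),
        baseline_abp=model.baseline_abp + float(abp_dev.mean()),
        baseline_etco2=model.baseline_etco2 + float(etco2_dev.mean()),
        baseline_cbfv=model.baseline_cbfv + float(cbfv.mean()),
    )


def clean_output_sd(model: TrueModel, duration_s: float = 330.0,
                    seed: int = 0, **kw) -> float:
    """SD of the noise-free CBFV deviation; anchors relative noise levels."""
    s = simulate_subject(model, duration_s=duration_s, noise_sd=0.0,
                         seed=seed, **kw)
    return float(np.std(s.cbfv))


@dataclass
class WaveformTruth:
    """Ground-truth events and beat-level series behind a raw waveform."""

    beat_onsets: np.ndarray      # s
    breath_endtidal_idx: np.ndarray  # sample index of each end-tidal point
    breath_endtidal: np.ndarray  # mmHg
    abp_beat: np.ndarray         # mmHg, true per-beat mean
    cbfv_beat: np.ndarray        # cm/s, true per-beat mean
    etco2_beat: np.ndarray       # mmHg, breath value held at each beat


def _pulse_contour(n: int, fs: float, rise_s: float = 0.12,
                   tau_s: float = 0.35) -> np.ndarray:
    """Zero-mean intra-beat contour with its minimum at the beat onset."""
    t = np.arange(n) / fs
    s = np.where(t < rise_s, np.sin(0.5 * np.pi * t / rise_s),
                 np.exp(-(t - rise_s) / tau_s))
    return s - s.mean()


def simulate_waveforms(model: TrueModel, heart_rate_bpm: float = 60.0,
                       resp_rate_bpm: float = 15.0, fs: float = 100.0,
                       duration_s: float = 330.0, seed: int = 0,
                       abp_pulse_mmHg: float = 40.0,
                       cbfv_pulse_cms: float = 25.0,
                       jitter_frac: float = 0.02,
                       noise_sd: float = 0.0):
    """Raw pulsatile waveforms with known beat/breath ground truth.

    Beat onsets sit at ``i * 60/HR`` plus small positional jitter, so the
    beat count over the record is exactly ``floor(duration * HR / 60)``.
    Beat-to-beat ABP and CBFV means follow the ground-truth system's slow
    dynamics (the same construction as :func:`simulate_subject`); within
    each beat a fixed systolic/diastolic contour is superimposed.  The
    CO2 channel falls during inspiration and rises to a per-breath
    end-tidal plateau whose value tracks the slow ETCO2 fluctuation.

    Returns ``(WaveformRecord, WaveformTruth)``.
    """
    if fs < 50:
        raise ValueError(f"fs={fs} Hz too low to resolve beats (need >= 50)")
    if not 30 <= heart_rate_bpm <= 180:
        raise ValueError("heart rate outside physiological range 30-180 bpm")
    if not 6 <= resp_rate_bpm <= 30:
        raise ValueError("respiratory rate outside physiological range 6-30 bpm")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # slow beat-level dynamics from the ground-truth system; the CO2
    # branch is driven by the breath-held end-tidal series because that
    # is the only form of ETCO2 an instrument can observe
    dt = model.dt
    n_slow = int(round(duration_s / dt)) + 2
    t_slow = dt * np.arange(n_slow)
    abp_dev = _slow_fluctuations(n_slow, dt, 3.0, rng)
    etco2_fluct = _slow_fluctuations(n_slow, dt, 1.5, rng)

    Tb = 60.0 / resp_rate_bpm
    n_breaths = int(np.ceil(duration_s / Tb)) + 1
    breath_starts = Tb * np.arange(n_breaths)
    # the end-tidal value becomes available mid-plateau of each breath
    et_avail = np.minimum(breath_starts + 0.875 * Tb, t_slow[-1])
    endtidal_dev = np.interp(et_avail, t_slow, etco2_fluct)
    endtidal = model.baseline_etco2 + endtidal_dev
    pos_slow = np.clip(np.searchsorted(et_avail, t_slow, side="right") - 1,
                       0, None)
    etco2_held_dev = endtidal_dev[pos_slow]

    kp = model.kernel("abp")
    kc = model.kernel("etco2")
    cbfv_dev = (np.convolve(abp_dev, kp)[:n_slow]
                + np.convolve(etco2_held_dev - etco2_held_dev.mean(),
                              kc)[:n_slow])
    if noise_sd > 0:
        cbfv_dev = cbfv_dev + noise_sd * rng.standard_normal(n_slow)

    # beat onsets: positional jitter keeps the count exact
    T = 60.0 / heart_rate_bpm
    n_beats = int(np.floor(duration_s * heart_rate_bpm / 60.0))
    eps = np.clip(rng.normal(0.0, jitter_frac * T, n_beats), -0.2 * T, 0.2 * T)
    eps[0] = abs(eps[0])  # keep first onset inside the record
    onsets = np.sort(T * np.arange(n_beats) + eps)
    onsets = onsets[onsets < duration_s - 2.0 / fs]

    abp_mean = model.baseline_abp + np.interp(onsets, t_slow, abp_dev)
    cbfv_mean = model.baseline_cbfv + np.interp(onsets, t_slow, cbfv_dev)

    abp = np.empty(n)
    cbfv = np.empty(n)
    idx = np.round(onsets * fs).astype(int)
    bounds = np.append(idx, n)
    # before the first onset: hold the first beat's mean
    abp[:bounds[0]] = abp_mean[0]
    cbfv[:bounds[0]] = cbfv_mean[0]
    for i in range(len(onsets)):
        seg = slice(bounds[i], bounds[i + 1])
        m = bounds[i + 1] - bounds[i]
        contour = _pulse_contour(m, fs)
        abp[seg] = abp_mean[i] + abp_pulse_mmHg * contour
        cbfv[seg] = cbfv_mean[i] + cbfv_pulse_cms * contour

    # breath cycle: inspiration drop, expiration rise to end-tidal plateau
    co2 = np.empty(n)
    insp_low = 2.0  # mmHg, inspiratory baseline
    et_idx, et_val = [], []
    for j in range(n_breaths):
        lo = int(round(breath_starts[j] * fs))
        hi = min(int(round((breath_starts[j] + Tb) * fs)), n)
        if lo >= n:
            break
        phase = (np.arange(lo, hi) / fs - breath_starts[j]) / Tb
        v = endtidal[j]
        prev = endtidal[j - 1] if j > 0 else endtidal[0]
        seg = np.empty(hi - lo)
        drop = phase < 0.15
        seg[drop] = prev + (insp_low - prev) * 0.5 * (
            1 - np.cos(np.pi * phase[drop] / 0.15))
        low = (phase >= 0.15) & (phase < 0.45)
        seg[low] = insp_low
        rise = (phase >= 0.45) & (phase < 0.75)
        seg[rise] = insp_low + (v - insp_low) * 0.5 * (
            1 - np.cos(np.pi * (phase[rise] - 0.45) / 0.30))
        plateau = phase >= 0.75
        seg[plateau] = v
        co2[lo:hi] = seg
        # the end-tidal value is registered mid-plateau, matching where a
        # flat-top peak detector localises it
        if hi > lo and phase[-1] >= 0.875:
            et_idx.append(lo + int(np.searchsorted(phase, 0.875)))
            et_val.append(v)

    record = WaveformRecord(fs=fs, time=t, abp=abp, cbfv=cbfv, co2=co2)
    et_times = np.asarray(et_idx) / fs
    pos = np.clip(np.searchsorted(et_times, onsets, side="right") - 1, 0, None)
    truth = WaveformTruth(
        beat_onsets=onsets,
        breath_endtidal_idx=np.asarray(et_idx, dtype=int),
        breath_endtidal=np.asarray(et_val),
        abp_beat=abp_mean, cbfv_beat=cbfv_mean,
        etco2_beat=np.asarray(et_val)[pos] if len(et_val) else np.array([]))
    return record, truth


@dataclass
class CohortSpec:
    """Specification of a two-group synthetic cohort.

    ``moments`` maps group label -> list of (mean, sd) per marker in
    ``markers`` order; ``correlation`` is the common within-group
    correlation target among markers/scores.
    """

    n_cs: int = 16
    n_mp: int = 36
    markers: list = field(default_factory=lambda: list(MARKERS))
    moments: dict = field(default_factory=lambda: {
        g: list(v) for g, v in GROUP_MOMENTS.items()})
    correlation: np.ndarray = field(default_factory=default_correlation)
    age_mean: float = 65.0
    age_sd: float = 7.0
    education_mean: float = 16.0
    education_sd: float = 2.0
    education_range: tuple = (10.0, 22.0)
    # interpret `correlation` as the pooled-sample target and calibrate
    # the within-group copula so the pooled correlation matches it in
    # expectation (group-mean separation adds between-group covariance)
    match_pooled_correlation: bool = True
    seed: int = 0

    def within_group_correlation(self) -> np.ndarray:
        """Copula correlation used inside each group.

        When ``match_pooled_correlation`` is set, decompose the pooled
        target into its between-group component (fixed by the group
        means/SDs and sizes) and solve for the within-group remainder;
        otherwise use the target directly.
        """
        R = np.asarray(self.correlation, dtype=float)
        if not self.match_pooled_correlation:
            return R
        w1 = self.n_cs / (self.n_cs + self.n_mp)
        w2 = 1.0 - w1
        mo1 = np.array(self.moments["CS"], dtype=float)
        mo2 = np.array(self.moments["MP"], dtype=float)
        mu1, sd1 = mo1[:, 0], mo1[:, 1]
        mu2, sd2 = mo2[:, 0], mo2[:, 1]
        mubar = w1 * mu1 + w2 * mu2
        d1, d2 = mu1 - mubar, mu2 - mubar
        B = w1 * np.outer(d1, d1) + w2 * np.outer(d2, d2)
        W = w1 * np.outer(sd1, sd1) + w2 * np.outer(sd2, sd2)
        V = w1 * sd1**2 + w2 * sd2**2 + np.diag(B)
        with np.errstate(invalid="ignore", divide="ignore"):
            R_within = (R * np.sqrt(np.outer(V, V)) - B) / W
        R_within[W == 0] = 0.0  # zero-SD markers carry no copula coupling
        np.fill_diagonal(R_within, 1.0)
        w = np.linalg.eigvalsh(R_within)
        if w.min() < -1e-10 or np.abs(R_within).max() > 1.0 + 1e-10:
            raise ValueError(
                "pooled correlation target is not attainable with these "
                "group moments (within-group matrix not positive "
                f"semi-definite); offending matrix:\n{R_within}")
        return R_within

    def validate(self):
        if self.n_cs < 2 or self.n_mp < 2:
            raise ValueError("need at least 2 subjects per group")
        R = np.asarray(self.correlation, dtype=float)
        k = len(self.markers)
        if R.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k}")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit "
                             f"diagonal; offending matrix:\n{R}")
        w = np.linalg.eigvalsh(R)
        if w.min() < -1e-10:
            raise ValueError("correlation target not positive semi-definite "
                             f"(min eigenvalue {w.min():.3g}); offending "
                             f"matrix:\n{R}")
        for g, mo in self.moments.items():
            if len(mo) != k:
                raise ValueError(f"group {g}: expected {k} (mean, sd) pairs")
            if any(sd < 0 for _, sd in mo):
                raise ValueError(f"group {g}: negative SD")
        return self


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a subject table with prescribed moments and correlations.

    Markers/scores are a Gaussian copula: a common correlated standard
    normal vector per subject, scaled by each group's (mean, SD).  Age is
    Normal(65, 7), gender Bernoulli(0.5), education Normal(16, 2)
    truncated to [10, 22] — all independent of the markers.
    """
    spec = (spec or CohortSpec()).validate()
    rng = np.random.default_rng(spec.seed)
    R = spec.within_group_correlation()
    w, V = np.linalg.eigh(R)
    Lchol = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    rows = []
    sid = 0
    for group, size in (("CS", spec.n_cs), ("MP", spec.n_mp)):
        z = rng.standard_normal((size, len(spec.markers))) @ Lchol.T
        mo = spec.moments[group]
        for i in range(size):
            row = {"id": f"S{sid:04d}", "group": group,
                   "age": rng.normal(spec.age_mean, spec.age_sd),
                   "gender": int(rng.integers(0, 2)),
                   "education": float(np.clip(
                       rng.normal(spec.education_mean, spec.education_sd),
                       *spec.education_range))}
            for k, name in enumerate(spec.markers):
                mean, sd = mo[k]
                row[name] = mean + sd * z[i, k]
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows)


def generate_voxel_dataset(subject_dvr, dims, label_volume,
                           frac_assoc_per_region, slope=0.05,
                           noise_sd=0.02, intercept=0.55, seed=0):
    """Plant linear DVR associations in designated voxel fractions.

    For each labelled region, a deterministic (per-seed) fraction of its
    voxels gets metric = intercept + slope * DVR + noise across subjects;
    the remainder are pure noise around the intercept.  Returns
    ``(volumes, mask, truth_mask)`` where ``volumes`` has shape
    (n_subjects, *dims), ``mask`` marks analysed voxels (all labelled
    voxels) and ``truth_mask`` marks the associated ones.
    """
    dvr = np.asarray(subject_dvr, dtype=float)
    if dvr.size < 4:
        raise ValueError("need at least 4 subjects (correlation unstable)")
    labels = np.asarray(label_volume)
    if labels.shape != tuple(dims):
        raise ValueError(f"label volume shape {labels.shape} != dims {tuple(dims)}")
    for f in dict(frac_assoc_per_region).values():
        if not 0.0 <= f <= 1.0:
            raise ValueError("association fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = labels > 0
    truth = np.zeros(labels.shape, dtype=bool)
    for region, frac in frac_assoc_per_region.items():
        vox = np.argwhere(labels == region)
        n_assoc = int(round(frac * len(vox)))
        if n_assoc:
            pick = vox[rng.choice(len(vox), size=n_assoc, replace=False)]
            truth[tuple(pick.T)] = True
    vols = intercept + noise_sd * rng.standard_normal((dvr.size, *labels.shape))
    vols[:, truth] += slope * dvr[:, None]
    return vols, mask, truth


def make_toy_labels(dims=(10, 10, 3), n_regions=3) -> np.ndarray:
    """Small integer label volume tiling regions along the first axis."""
    labels = np.zeros(dims, dtype=int)
    edges = np.linspace(0, dims[0], n_regions + 1).astype(int)
    for r in range(n_regions):
        labels[edges[r]:edges[r + 1], :, :] = r + 1
    return labels
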