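"""Reduction of raw hemodynamic waveforms to beat-to-beat uniform series.

Raw recordings (ABP from finger photoplethysmography, CBFV from
transcranial Doppler, CO2 from capnography, sampled at 100 Hz - 1 kHz)
are reduced to one value per cardiac cycle: per-beat means for ABP and
CBFV, and the most recent end-tidal value for CO2.  The beat series is
artifact-cleaned, interpolated onto a uniform grid (default 1 s, about
one beat at rest), and demeaned; the demeaned triple is what the dynamic
model is estimated from, with the removed channel means kept as
baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks


class PreprocessError(ValueError):
    pass


@dataclass
class WaveformRecord:
    """Raw multi-channel recording at a fixed sampling rate."""

    fs: float
    time: np.ndarray
    abp: np.ndarray
    cbfv: np.ndarray
    co2: np.ndarray

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = len(self.time)
        if not (len(self.abp) == len(self.cbfv) == len(self.co2) == n):
            raise ValueError("all channels must have equal length")
        for name in ("abp", "cbfv", "co2"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite samples in channel {name}")

    @property
    def duration(self) -> float:
        return len(self.time) / self.fs


@dataclass
class BeatSeries:
    """Beat-reduced series: one sample per detected cardiac cycle."""

    beat_times: np.ndarray   # s, onset of each beat
    abp_beat: np.ndarray     # mmHg, per-beat mean
    cbfv_beat: np.ndarray    # cm/s, per-beat mean
    etco2_beat: np.ndarray   # mmHg, last end-tidal value at or before beat

    def __post_init__(self):
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")


@dataclass
class UniformSeries:
    """Uniformly resampled, demeaned beat-level triple with stored baselines.

    Channels hold deviations from their means; ``baseline_*`` hold the
    removed means so absolute values can be restored.
    """

    dt: float
    abp: np.ndarray
    etco2: np.ndarray
    cbfv: np.ndarray
    baseline_abp: float
    baseline_etco2: float
    baseline_cbfv: float

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self):
        return len(self.cbfv)


@dataclass
class RejectionReport:
    """Indices and reasons of beats removed by artifact cleaning."""

    rejected: list = field(default_factory=list)   # (index, reason)
    warnings: list = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def detect_beats(record: WaveformRecord, refractory_s: float = 0.3,
                 smooth_s: float = 0.02) -> np.ndarray:
    """Detect cardiac-cycle onsets from the ABP waveform.

    Systolic upstrokes are located by thresholding the smoothed first
    difference; each upstroke is then refined backwards to the preceding
    diastolic minimum, which is reported as the beat onset.  A 0.3-s
    refractory period suppresses double triggers within one cycle.
    """
    abp = np.asarray(record.abp, dtype=float)
    fs = record.fs
    if abp.size < 10 * fs:
        raise PreprocessError("ABP channel shorter than 10 s")
    if np.std(abp) < 1e-9:
        raise PreprocessError("no beats detected: flatline ABP")
    w = max(1, int(round(smooth_s * fs)))
    kernel = np.ones(w) / w
    sm = np.convolve(abp, kernel, mode="same")
    deriv = np.diff(sm) * fs
    pos = deriv[deriv > 0]
    if pos.size == 0:
        raise PreprocessError("no beats detected: ABP never rises")
    thresh = 0.4 * np.quantile(pos, 0.95)
    peaks, _ = find_peaks(deriv, height=thresh,
                          distance=max(1, int(round(refractory_s * fs))))
    if peaks.size == 0:
        raise PreprocessError("no beats detected above derivative threshold")
    onsets = []
    back = int(round(refractory_s * fs))
    for p in peaks:
        lo = max(0, p - back)
        seg = abp[lo:p + 1]
        # last occurrence of the minimum: on a flat stretch (dropout) the
        # onset sits at the foot of the upstroke, not the start of the flat
        onset = lo + int(np.nonzero(seg == seg.min())[0][-1])
        onsets.append(onset)
    onsets = np.unique(onsets)
    # re-enforce refractory after refinement
    keep = [onsets[0]]
    for o in onsets[1:]:
        if (o - keep[-1]) / fs >= refractory_s:
            keep.append(o)
    return np.asarray(keep) / fs + record.time[0]


def beat_average(channel: np.ndarray, beat_times: np.ndarray, fs: float,
                 t0: float = 0.0) -> np.ndarray:
    """Per-beat means: value i averages samples in [onset_i, onset_{i+1}).

    The final beat averages the remaining samples to the end of the
    record.
    """
    channel = np.asarray(channel, dtype=float)
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 2:
        raise PreprocessError("need at least 2 beats to average")
    idx = np.round((beat_times - t0) * fs).astype(int)
    if idx[0] < 0 or idx[-1] >= channel.size:
        raise PreprocessError("beat times fall outside the recording span")
    bounds = np.append(idx, channel.size)
    out = np.empty(beat_times.size)
    for i in range(beat_times.size):
        seg = channel[bounds[i]:bounds[i + 1]]
        if seg.size == 0:
            raise PreprocessError(f"empty beat interval at index {i}")
        out[i] = seg.mean()
    return out


def extract_etco2(co2: np.ndarray, fs: float, beat_times: np.ndarray,
                  t0: float = 0.0, min_sep_s: float = 1.5):
    """End-tidal CO2 per beat by breath-wise maxima and sample-and-hold.

    Breath maxima (end-tidal plateaus) are local maxima of the CO2
    waveform separated by at least ``min_sep_s``.  Each beat is assigned
    the most recent end-tidal value at or before its onset; beats before
    the first detected breath hold the first breath's value.  Returns
    ``(etco2_per_beat, n_warnings)`` where warnings count candidate
    breath maxima suppressed by the separation rule (breathing faster
    than the rule allows).
    """
    co2 = np.asarray(co2, dtype=float)
    rng_amp = co2.max() - co2.min()
    prominence = 0.1 * rng_amp if rng_amp > 0 else None
    peaks, _ = find_peaks(co2, distance=max(1, int(round(min_sep_s * fs))),
                          prominence=prominence, plateau_size=1)
    if peaks.size == 0:
        # flat channel: a constant plateau has no local maxima but a
        # well-defined end-tidal value
        if rng_amp < 1e-12:
            return np.full(len(beat_times), co2[0]), 0
        raise PreprocessError("no breath maxima found in CO2 channel")
    peak_times = peaks / fs + t0
    values = co2[peaks]
    candidates, _ = find_peaks(co2, prominence=prominence, plateau_size=1)
    n_warn = max(0, int(candidates.size - peaks.size))
    # sample-and-hold at beat onsets
    pos = np.searchsorted(peak_times, np.asarray(beat_times), side="right") - 1
    pos = np.clip(pos, 0, None)
    return values[pos], n_warn


def clean_beats(series: BeatSeries, artifact_sd: float = 4.0,
                ibi_range=(0.3, 2.0), max_reject_frac: float = 0.2):
    """Remove artifactual beats and linearly interpolate across them.

    A beat is rejected when its ABP or CBFV mean lies beyond
    ``artifact_sd`` robust standard deviations (1.4826 * MAD, so heavy
    contamination cannot inflate the scale and hide itself) from the
    channel median, or when the interval to the previous beat falls
    outside ``ibi_range``.  Rejection above ``max_reject_frac`` marks
    the recording unusable.
    """
    n = len(series.beat_times)
    if n < 30:
        raise PreprocessError("need at least 30 beats for cleaning")
    bad = np.zeros(n, dtype=bool)
    reasons = {}
    for name in ("abp_beat", "cbfv_beat"):
        x = getattr(series, name)
        med = np.median(x)
        sd = 1.4826 * np.median(np.abs(x - med))
        if sd > 0:
            out = np.abs(x - med) > artifact_sd * sd
            for i in np.nonzero(out)[0]:
                bad[i] = True
                reasons.setdefault(int(i), []).append(f"{name} outlier")
    ibi = np.diff(series.beat_times)
    for i in np.nonzero((ibi < ibi_range[0]) | (ibi > ibi_range[1]))[0]:
        bad[i + 1] = True
        reasons.setdefault(int(i + 1), []).append("inter-beat interval")
    frac = bad.mean()
    if frac > max_reject_frac:
        raise PreprocessError(
            f"recording unusable: {frac:.0%} of beats rejected "
            f"(limit {max_reject_frac:.0%})")
    report = RejectionReport(
        rejected=[(i, ", ".join(r)) for i, r in sorted(reasons.items())])
    if not bad.any():
        return replace(series), report
    good = ~bad
    t = series.beat_times
    fixed = {}
    for name in ("abp_beat", "cbfv_beat", "etco2_beat"):
        x = getattr(series, name).copy()
        x[bad] = np.interp(t[bad], t[good], getattr(series, name)[good])
        fixed[name] = x
    return BeatSeries(beat_times=t.copy(), **fixed), report


def to_uniform(series: BeatSeries, dt: float = 1.0) -> UniformSeries:
    """Interpolate beat channels onto a uniform grid and demean them.

    Linear interpolation on a grid of step ``dt`` spanning the beat-time
    range; each channel's mean is removed and stored as its baseline.
    """
    if dt <= 0:
        raise PreprocessError("dt must be positive")
    t = series.beat_times
    if t.size < 2:
        raise PreprocessError("need at least 2 beats to resample")
    span = t[-1] - t[0]
    if dt > span / 2:
        raise PreprocessError(f"dt={dt} exceeds half the recording span {span:.1f} s")
    grid = t[0] + dt * np.arange(int(np.floor(span / dt)) + 1)
    out = {}
    baselines = {}
    for name, key in (("abp_beat", "abp"), ("etco2_beat", "etco2"),
                      ("cbfv_beat", "cbfv")):
        v = np.interp(grid, t, getattr(series, name))
        baselines[f"baseline_{key}"] = float(v.mean())
        out[key] = v - v.mean()
    return UniformSeries(dt=dt, **out, **baselines)


def reduce_record(record: WaveformRecord, dt: float = 1.0,
                  refractory_s: float = 0.3, breath_min_sep_s: float = 1.5,
                  artifact_sd: float = 4.0, max_reject_frac: float = 0.2):
    """Full reduction chain: beats -> per-beat values -> clean -> uniform.

    Returns ``(uniform_series, beat_series, rejection_report)``.
    """
    t0 = float(record.time[0])
    onsets = detect_beats(record, refractory_s=refractory_s)
    abp_b = beat_average(record.abp, onsets, record.fs, t0=t0)
    cbfv_b = beat_average(record.cbfv, onsets, record.fs, t0=t0)
    etco2_b, n_warn = extract_etco2(record.co2, record.fs, onsets, t0=t0,
                                    min_sep_s=breath_min_sep_s)
    beats = BeatSeries(beat_times=onsets, abp_beat=abp_b, cbfv_beat=cbfv_b,
                       etco2_beat=etco2_b)
    beats, report = clean_beats(beats, artifact_sd=artifact_sd,
                                max_reject_frac=max_reject_frac)
    if n_warn:
        report.warnings.append(f"{n_warn} suspected missed breaths")
        warnings.warn(f"{n_warn} suspected missed breaths in CO2 channel",
                      stacklevel=2)
    return to_uniform(beats, dt=dt), beats, report
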