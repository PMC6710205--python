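"""The Dynamic Vasomotor Reactivity (DVR) physiomarker.

DVR quantifies the cerebral flow response to a sudden, short change in
blood CO2 tension: the fitted two-input model is probed with a 5-s
rectangular pulse of ETCO2 while ABP is held at baseline (zero
deviation), and the model-predicted CBFV response is averaged over the
5-s window.  Reported per mmHg of pulse amplitude, which for a linear
model makes the index amplitude-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .laguerre import TwoInputModel, kernel_of


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {original}")


def pulse_input(dt: float, duration_s: float = 5.0, amplitude: float = 1.0,
                total_len: int | None = None, memory: int = 0) -> np.ndarray:
    """Rectangular input pulse: ``amplitude`` on [0, duration), 0 after.

    Length is ``total_len`` when given, otherwise the pulse plus the
    model ``memory`` so the response can settle.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration_s < dt:
        raise ValueError(f"pulse duration {duration_s} shorter than dt={dt}")
    n_on = int(round(duration_s / dt))
    n = total_len if total_len is not None else n_on + max(memory, 1)
    if n < n_on:
        raise ValueError("total length shorter than the pulse")
    x = np.zeros(n)
    x[:n_on] = amplitude
    return x


def pulse_response(model: TwoInputModel, pulse: np.ndarray) -> np.ndarray:
    """Model-predicted CBFV deviation driven by the ETCO2 pulse alone.

    ABP stays at baseline (zero deviation) so its branch contributes
    nothing; the intercept is excluded because the response is a
    deviation from baseline flow.
    """
    pulse = np.asarray(pulse, dtype=float)
    if pulse.size < model.basis_c.M:
        raise ValueError("pulse sequence shorter than the model memory")
    kc = kernel_of(model, "etco2")
    return np.convolve(pulse, kc)[:pulse.size]


def dvr_index(response: np.ndarray, dt: float, window_s: float = 5.0,
              amplitude: float = 1.0) -> float:
    """Mean of the response over [0, window) per unit pulse amplitude."""
    K = int(round(window_s / dt))
    if K > len(response):
        raise ValueError(
            f"window {window_s} s exceeds response length {len(response) * dt} s")
    if amplitude == 0:
        raise ValueError("pulse amplitude must be nonzero")
    return float(np.mean(response[:K]) / amplitude)


@dataclass
class DvrResult:
    """Pulse-response trace and scalar DVR for one subject."""

    subject_id: str
    response: np.ndarray        # cm/s deviations over the evaluation window
    dvr: float                  # cm/s per mmHg (or %baseline/mmHg if normalized)
    pulse_amplitude: float      # mmHg
    pulse_duration: float       # s
    window: float               # s
    normalized: bool = False
    fit_nmse: float | None = None
    structure: dict | None = None

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "dvr": self.dvr,
            "pulse_amplitude_mmHg": self.pulse_amplitude,
            "pulse_duration_s": self.pulse_duration,
            "window_s": self.window,
            "normalized": self.normalized,
            "fit_nmse": self.fit_nmse,
            "structure": self.structure,
            "response": np.asarray(self.response).tolist(),
        }


def dvr_from_model(model: TwoInputModel, pulse_duration_s: float = 5.0,
                   window_s: float = 5.0, amplitude: float = 1.0):
    """Pulse response and DVR of an already-fitted model."""
    pulse = pulse_input(model.dt, pulse_duration_s, amplitude,
                        memory=model.basis_c.M)
    resp = pulse_response(model, pulse)
    return resp, dvr_index(resp, model.dt, window_s, amplitude)


def dvr_pipeline(data, config=None, subject_id: str = "subject") -> DvrResult:
    """End-to-end DVR estimation from a raw recording or a uniform series.

    Stages: waveform reduction (skipped when ``data`` is already a
    :class:`dvrphys.preprocess.UniformSeries`), model-structure selection
    (or a fixed structure when the config pins alpha and L), least-squares
    fit, pulse response, and window averaging.  Deterministic given the
    input and config.  Stage failures re-raise as :class:`PipelineError`
    tagged with the stage name.
    """
    from .config import PipelineConfig
    from .laguerre import fit_two_input_model, laguerre_basis, select_structure
    from .preprocess import UniformSeries, WaveformRecord, reduce_record

    cfg = config or PipelineConfig()
    if isinstance(data, WaveformRecord):
        if data.duration < 180.0:
            raise PipelineError("preprocess", ValueError(
                f"recording of {data.duration:.0f} s is shorter than the "
                "3-min minimum for model estimation"))
        try:
            series, _, _ = reduce_record(
                data, dt=cfg.preprocess.dt,
                refractory_s=cfg.preprocess.refractory_s,
                breath_min_sep_s=cfg.preprocess.breath_min_sep_s,
                artifact_sd=cfg.preprocess.artifact_sd,
                max_reject_frac=cfg.preprocess.max_reject_frac)
        except Exception as e:  # noqa: BLE001 - tag and re-raise
            raise PipelineError("preprocess", e) from e
    elif isinstance(data, UniformSeries):
        series = data
    else:
        raise TypeError("data must be a WaveformRecord or UniformSeries")

    m = cfg.model
    try:
        if m.fixed_structure():
            bp = laguerre_basis(m.alpha_p, m.L_p, m.M)
            bc = laguerre_basis(m.alpha_c, m.L_c, m.M)
            model, report = fit_two_input_model(series, bp, bc, ridge=m.ridge)
        else:
            model, report = select_structure(series, m.alpha_grid, m.L_grid,
                                             ridge=m.ridge)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fit", e) from e

    try:
        resp, dvr = dvr_from_model(model, cfg.pulse.duration_s,
                                   cfg.pulse.window_s, cfg.pulse.amplitude)
        if cfg.pulse.normalized:
            dvr = 100.0 * dvr / series.baseline_cbfv
    except Exception as e:  # noqa: BLE001
        raise PipelineError("dvr", e) from e

    return DvrResult(subject_id=subject_id, response=resp, dvr=dvr,
                     pulse_amplitude=cfg.pulse.amplitude,
                     pulse_duration=cfg.pulse.duration_s,
                     window=cfg.pulse.window_s,
                     normalized=cfg.pulse.normalized,
                     fit_nmse=model.fit_nmse, structure=report.structure)
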