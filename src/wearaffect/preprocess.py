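"""Signal conditioning from raw streams to 30-minute pre-prompt segments.

The chain, per modality:

1. tri-axial acceleration is collapsed to its Euclidean magnitude, quantised
   to the device precision of 1/2048 g;
2. GSR (40 Hz) and ACCEL (20 Hz) are decimated to the heart-rate grid (1 Hz)
   by plain every-nth-sample selection;
3. per-subject, per-modality z-scoring over the whole recording (model-input
   scaling; switchable);
4. single-channel adaptive noise cancellation: an LMS-adapted linear
   predictor driven by the signal's own delayed copy (adaptive line
   enhancer).  The predictable, band-limited component is the cleaned
   output; broadband noise lands in the prediction error and is discarded;
5. a moving median filter with kernel size 3 (centre-aligned, edges
   replicated);
6. extraction of the ``window_s`` seconds preceding each ESM prompt into a
   T×3 matrix (columns HR, GSR, ACCEL), with a per-column completeness
   fraction.  Windows below the completeness threshold are dropped and
   counted, never silently padded.

Steps 4–5 operate on gap-filled copies (linear interpolation across NaN
runs) so filter state stays finite; gap positions are restored to NaN
afterwards and only the completeness accounting sees them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from . import labels as _labels
from .io import RawChannel, Segment

__all__ = [
    "ACCEL_QUANTUM_G",
    "LmsConfig",
    "PreprocessConfig",
    "LmsDivergenceError",
    "accel_magnitude",
    "decimate_every_nth",
    "lms_denoise",
    "median_filter3",
    "standardize",
    "extract_window",
    "preprocess_subject",
]

#: Device precision of the acceleration magnitude, in units of g.
ACCEL_QUANTUM_G = 1.0 / 2048.0


class LmsDivergenceError(RuntimeError):
    """LMS weight norm exceeded its bound — the step size is too large."""


@dataclass
class LmsConfig:
    """Adaptive-noise-cancellation settings.

    order
        number of taps of the adaptive FIR predictor.
    mu
        LMS step size; stability requires it small relative to the input
        power (defaults assume z-scored input).
    delay
        decorrelation delay (samples) between the signal and its self
        reference.
    reference
        ``"delayed_self"`` (adaptive line enhancer) or ``"external"`` — an
        externally supplied reference channel (e.g. acceleration as a motion
        reference; provided but unvalidated).
    """

    order: int = 8
    mu: float = 0.01
    delay: int = 1
    reference: str = "delayed_self"
    max_weight_norm: float = 1e6

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.mu < 0:
            raise ValueError("step size mu must be >= 0")
        if self.delay < 1:
            raise ValueError("reference delay must be >= 1 sample")
        if self.reference not in ("delayed_self", "external"):
            raise ValueError(f"unknown reference mode {self.reference!r}")


@dataclass
class PreprocessConfig:
    """Knobs of the conditioning chain (defaults follow the device rates)."""

    gsr_decimation: int = 40
    accel_decimation: int = 20
    decimation_phase: int = 0  # index of the first retained sample
    lms: LmsConfig = field(default_factory=LmsConfig)
    lms_enabled: bool = True
    median_enabled: bool = True
    window_s: int = 1800
    completeness_threshold: float = 1.0
    standardize: bool = True
    quantize_accel: bool = True


def accel_magnitude(ax, ay, az, quantum: float | None = ACCEL_QUANTUM_G) -> np.ndarray:
    """Euclidean norm of the three acceleration axes, quantised to the
    device precision (1/2048 g) unless ``quantum`` is None."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError(f"axis length mismatch: {ax.shape}, {ay.shape}, {az.shape}")
    mag = np.sqrt(ax**2 + ay**2 + az**2)
    if quantum is not None:
        mag = np.round(mag / quantum) * quantum
    return mag


def decimate_every_nth(series, n: int, phase: int = 0) -> np.ndarray:
    """Retain samples at indices ``phase, phase+n, phase+2n, …`` (0-based)."""
    if n < 1:
        raise ValueError(f"decimation factor must be >= 1, got {n}")
    if not 0 <= phase < n:
        raise ValueError(f"phase must lie in [0, {n}), got {phase}")
    series = np.asarray(series)
    return series[phase::n].copy()


def lms_denoise(
    series,
    cfg: LmsConfig | None = None,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Adaptive noise cancellation by the least-mean-squares rule.

    An ``order``-tap FIR filter predicts the current sample from the
    reference vector (the signal delayed by ``cfg.delay`` samples in
    delayed-self mode); the weights follow the stochastic-gradient update
    ``w ← w + mu * e * x`` with ``e`` the prediction error.  The returned
    cleaned series is the filter prediction — the temporally predictable
    component of the input — and has the same length as the input.
    """
    cfg = cfg or LmsConfig()
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("lms_denoise expects a 1-D series")
    n = len(x)
    if cfg.reference == "delayed_self":
        ref = x
        delay = cfg.delay
    else:
        if reference is None:
            raise ValueError("external reference mode needs a reference series")
        ref = np.asarray(reference, dtype=float)
        if ref.shape != x.shape:
            raise ValueError("reference length must match the input")
        delay = cfg.delay

    # lag matrix: taps[t, j] = ref[t - delay - j], zero-padded at the start
    pad = np.concatenate([np.zeros(delay + cfg.order - 1), ref])
    taps = np.lib.stride_tricks.sliding_window_view(pad, cfg.order)[:n, ::-1]

    w = np.zeros(cfg.order)
    out = np.zeros(n)
    mu = cfg.mu
    bound2 = cfg.max_weight_norm**2
    for t in range(n):
        xt = taps[t]
        y = w @ xt
        e = x[t] - y
        out[t] = y
        w = w + (mu * e) * xt
        if w @ w > bound2:
            raise LmsDivergenceError(
                f"LMS weights diverged at sample {t} (mu={cfg.mu}); reduce the step size"
            )
    return out


def median_filter3(series) -> np.ndarray:
    """Moving median, kernel 3, centre-aligned, edge samples replicated."""
    series = np.asarray(series, dtype=float)
    if len(series) == 0:
        raise ValueError("median_filter3 needs at least one sample")
    return median_filter(series, size=3, mode="nearest")


def standardize(series) -> np.ndarray:
    """Z-score ignoring NaN; constant series are centred only."""
    x = np.asarray(series, dtype=float)
    mu = np.nanmean(x)
    sd = np.nanstd(x)
    if not np.isfinite(sd) or sd < 1e-12:
        return x - (mu if np.isfinite(mu) else 0.0)
    return (x - mu) / sd


def _fill_gaps(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate across NaN runs; returns (filled, nan_mask)."""
    mask = ~np.isfinite(x)
    if not mask.any():
        return x.copy(), mask
    filled = x.copy()
    idx = np.arange(len(x))
    if mask.all():
        return np.zeros_like(x), mask
    filled[mask] = np.interp(idx[mask], idx[~mask], x[~mask])
    return filled, mask


def extract_window(
    channel: RawChannel,
    esm_timestamp: float,
    window_s: int = 1800,
) -> tuple[np.ndarray | None, float]:
    """The ``window_s`` 1-Hz samples covering ``[esm − window_s, esm)``.

    Returns ``(values, completeness)``; ``values`` is ``None`` when the
    window lies entirely outside the recording.  Samples missing from the
    recording (outside its span, or inside a gap) are NaN in the returned
    window and reduce the completeness fraction.
    """
    if abs(channel.sample_rate - 1.0) > 1e-9:
        raise ValueError("extract_window expects a 1 Hz channel")
    # last sample strictly before the prompt: index ceil(esm - t0) - 1
    start = int(math.ceil(esm_timestamp - channel.t0 - 1e-9)) - window_s
    idx = np.arange(start, start + window_s)
    valid = (idx >= 0) & (idx < len(channel.values))
    window = np.full(window_s, np.nan)
    if valid.any():
        window[valid] = channel.values[idx[valid]]
    completeness = float(np.isfinite(window).mean())
    if completeness == 0.0:
        return None, 0.0
    return window, completeness


def _condition_1hz(values: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Standardize → LMS → median on one 1-Hz stream, preserving gaps."""
    x = values.astype(float)
    if cfg.standardize:
        x = standardize(x)
    filled, mask = _fill_gaps(x)
    if cfg.lms_enabled:
        filled = lms_denoise(filled, cfg.lms)
    if cfg.median_enabled:
        filled = median_filter3(filled)
    filled[mask] = np.nan
    return filled


def preprocess_subject(
    channels: dict,
    esm_list,
    cfg: PreprocessConfig | None = None,
) -> tuple[list[Segment], dict]:
    """Run the whole conditioning chain for one subject.

    ``channels`` maps ``"hr"`` → RawChannel (1 Hz), ``"gsr"`` → RawChannel
    (40 Hz), ``"accel"`` → (x, y, z) RawChannel triple (20 Hz).  Returns the
    extracted segments and a report of dropped prompts.
    """
    cfg = cfg or PreprocessConfig()
    report = {"n_esm": len(esm_list), "n_segments": 0, "dropped": []}

    missing = [m for m in ("hr", "gsr", "accel") if m not in channels]
    if missing:
        report["skipped_subject"] = f"missing modalities: {missing}"
        return [], report

    hr = channels["hr"]
    gsr = channels["gsr"]
    ax, ay, az = channels["accel"]

    # ACCEL: magnitude at the native rate, then decimate to 1 Hz
    mag = accel_magnitude(ax.values, ay.values, az.values, ACCEL_QUANTUM_G if cfg.quantize_accel else None)
    accel_1hz = RawChannel(
        ax.subject_id,
        "accel_mag",
        1.0,
        ax.t0 + cfg.decimation_phase / ax.sample_rate,
        decimate_every_nth(mag, cfg.accel_decimation, cfg.decimation_phase),
    )
    gsr_1hz = RawChannel(
        gsr.subject_id,
        "gsr",
        1.0,
        gsr.t0 + cfg.decimation_phase / gsr.sample_rate,
        decimate_every_nth(gsr.values, cfg.gsr_decimation, cfg.decimation_phase),
    )
    hr_1hz = RawChannel(hr.subject_id, "hr", 1.0, hr.t0, hr.values.copy())

    processed = {}
    for name, ch in (("hr", hr_1hz), ("gsr", gsr_1hz), ("accel", accel_1hz)):
        processed[name] = RawChannel(
            ch.subject_id, ch.modality, 1.0, ch.t0, _condition_1hz(ch.values, cfg), ch.gaps
        )

    provenance = {
        "chain": "accel_magnitude>decimate>standardize>lms>median>window",
        "gsr_decimation": cfg.gsr_decimation,
        "accel_decimation": cfg.accel_decimation,
        "decimation_phase": cfg.decimation_phase,
        "lms": None
        if not cfg.lms_enabled
        else {"order": cfg.lms.order, "mu": cfg.lms.mu, "delay": cfg.lms.delay, "reference": cfg.lms.reference},
        "median_kernel": 3 if cfg.median_enabled else None,
        "window_s": cfg.window_s,
        "standardize": cfg.standardize,
        "completeness_threshold": cfg.completeness_threshold,
    }

    segments: list[Segment] = []
    for esm in esm_list:
        cols, comps = [], []
        ok = True
        for name in ("hr", "gsr", "accel"):
            win, comp = extract_window(processed[name], esm.timestamp, cfg.window_s)
            if win is None or comp < cfg.completeness_threshold:
                report["dropped"].append(
                    {"esm_timestamp": esm.timestamp, "modality": name, "completeness": comp}
                )
                ok = False
                break
            if comp < 1.0:
                win, _ = _fill_gaps(win)  # interpolate residual holes, flagged via completeness
            cols.append(win)
            comps.append(comp)
        if not ok:
            continue
        segments.append(
            Segment(
                subject_id=esm.subject_id,
                esm_timestamp=esm.timestamp,
                matrix=np.column_stack(cols),
                labels=_labels.label_set(esm).to_dict(),
                completeness=np.array(comps),
                provenance=dict(provenance),
            )
        )
    report["n_segments"] = len(segments)
    return segments, report
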