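"""Synthetic multi-day wrist recordings with known affect structure.

The generator emulates the shape of a multi-day ambulatory study — per
subject a contiguous daily recording block of heart rate (1 Hz), skin
conductance (40 Hz) and tri-axial acceleration (20 Hz), with several ESM
prompts per day at random times — while keeping the ground truth fully
known, so that label derivation, preprocessing and the classifier can be
tested end to end without any download.

Generative model (piecewise-stationary, deliberately simple):

* per prompt, a latent binary affect state ``s ~ Bernoulli(p_positive)``
  refined to a 5-level intensity ``L`` (``L ∈ {4,5}`` when positive,
  ``{1,2,3}`` when negative, uniform within); the drive ``(L−3)/2`` scales
  every physiological effect and is active only during the pre-prompt
  window;
* HR: 65 bpm baseline + subject offset + slow sinusoidal drift +
  ``hr_shift·drive`` + white noise;
* GSR: tonic level + slow drift + phasic events — Poisson arrivals whose
  rate is ``base · ratio^drive`` — each an exponentially decaying bump;
  quantised to the 0.01 μS device resolution;
* ACCEL: gravity plus a shared smoothed activity latent (variance scaled
  by ``accel_var_ratio^drive``) projected onto three axes, quantised to
  1/2048 g;
* spike artifacts injected at a fixed hourly rate in every stream;
* ESM items drawn around level-dependent means so the PANAS item sums
  recover the latent state, and valence = arousal = L.

Setting every effect size to its null value (``SimConfig.null()``) leaves
the labels carrying no signal about the streams, so downstream accuracy
must sit at chance.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import PANAS_ITEMS, EsmResponse, RawChannel
from .preprocess import ACCEL_QUANTUM_G

__all__ = ["SimConfig", "simulate_subject", "simulate_dataset", "iter_subjects", "poisson_event_times"]

# level -> mean item score (positive-affect items, negative-affect items)
_ITEM_MEANS = {
    1: (1.5, 4.5),
    2: (2.0, 4.0),
    3: (2.5, 3.5),
    4: (4.0, 2.0),
    5: (4.5, 1.5),
}
_POSITIVE_ITEMS = ("inspired", "active", "determined", "attentive")

_T0 = 1_700_000_000.0  # recording epoch (POSIX seconds)


@dataclass
class SimConfig:
    """Study-shape and effect-size settings.

    Defaults are the desk-scale study conditions: 12 subjects × 1 day with
    10 prompts/day, 300-second pre-prompt windows inside a 4-hour daily
    wear block, a strong planted effect (8 bpm HR shift, 3× skin-conductance
    event rate, 2× motion variance) and realistic noise levels.
    """

    n_subjects: int = 12
    n_days: int = 1
    esm_per_day: int = 10
    seed: int = 0
    day_seconds: int = 14400  # active wear block per day
    window_s: int = 300
    # effect sizes (positive-affect state relative to negative)
    hr_shift: float = 8.0  # bpm at full drive
    gsr_event_rate_ratio: float = 3.0
    accel_var_ratio: float = 2.0
    positive_prob: float = 0.5
    # noise
    hr_sigma: float = 3.0  # bpm
    gsr_sigma: float = 0.05  # μS
    accel_sigma: float = 0.05  # g
    # artifacts
    artifact_rate_per_hour: float = 10.0
    artifact_amplitude: float = 5.0  # multiples of each stream's noise sigma
    # signal backbone
    hr_baseline: float = 65.0
    gsr_tonic: float = 2.0  # μS
    gsr_event_rate: float = 2.0  # phasic events per minute at drive 0
    gsr_event_tau: float = 4.0  # s decay constant
    accel_activity_std: float = 0.1  # g at drive 0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.n_subjects < 1 or self.esm_per_day < 1:
            raise ValueError("counts must be >= 1")
        if self.gsr_event_rate_ratio <= 0 or self.accel_var_ratio <= 0:
            raise ValueError("effect ratios must be > 0")
        if min(self.hr_sigma, self.gsr_sigma, self.accel_sigma, self.artifact_rate_per_hour) < 0:
            raise ValueError("rates and noise levels must be >= 0")
        slot = self.day_seconds // self.esm_per_day
        if slot < self.window_s + 60:
            raise ValueError(
                f"day of {self.day_seconds}s cannot host {self.esm_per_day} prompts "
                f"with disjoint {self.window_s}s windows"
            )

    @classmethod
    def null(cls, **overrides) -> "SimConfig":
        """All effect sizes at their no-signal values."""
        return replace(cls(**overrides), hr_shift=0.0, gsr_event_rate_ratio=1.0, accel_var_ratio=1.0)


def poisson_event_times(rng: np.random.Generator, rate_per_s: np.ndarray) -> np.ndarray:
    """Event times (seconds) of an inhomogeneous Poisson process whose rate
    is piecewise constant per second."""
    rate_per_s = np.asarray(rate_per_s, dtype=float)
    counts = rng.poisson(rate_per_s)
    seconds = np.repeat(np.arange(len(rate_per_s)), counts)
    return seconds + rng.random(len(seconds))


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def _inject_spikes(rng, x: np.ndarray, sample_rate: float, rate_per_hour: float, amplitude: float) -> None:
    """Add ±amplitude point artifacts at a Poisson hourly rate, in place."""
    n = rng.poisson(rate_per_hour * len(x) / (3600.0 * sample_rate))
    if n == 0:
        return
    pos = rng.integers(0, len(x), size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    x[pos] += sign * amplitude


def simulate_subject(cfg: SimConfig, subject_id: str, subject_index: int = 0):
    """One subject's streams and prompts.

    Returns ``(channels, esm_list)`` where ``channels`` maps ``"hr"`` /
    ``"gsr"`` to a RawChannel and ``"accel"`` to an (x, y, z) triple —
    exactly the input contract of :func:`wearaffect.preprocess.preprocess_subject`.
    Byte-identical for identical arguments.
    """
    rng = np.random.default_rng([cfg.seed, subject_index])
    R = cfg.n_days * cfg.day_seconds  # total recorded seconds, contiguous

    # --- prompts and latent states -------------------------------------
    slot = cfg.day_seconds // cfg.esm_per_day
    esm_times, levels = [], []
    for day in range(cfg.n_days):
        for k in range(cfg.esm_per_day):
            offset = cfg.window_s + rng.integers(0, slot - cfg.window_s)
            esm_times.append(day * cfg.day_seconds + k * slot + int(offset))
            s = rng.random() < cfg.positive_prob
            levels.append(int(rng.choice([4, 5]) if s else rng.choice([1, 2, 3])))

    drive_1hz = np.zeros(R)
    for t, L in zip(esm_times, levels):
        drive_1hz[t - cfg.window_s : t] = (L - 3) / 2.0

    # --- heart rate, 1 Hz ----------------------------------------------
    t_sec = np.arange(R, dtype=float)
    subj_hr = rng.normal(0.0, 2.0)
    drift = 2.0 * np.sin(2 * np.pi * t_sec / 3600.0 + rng.uniform(0, 2 * np.pi))
    hr = cfg.hr_baseline + subj_hr + drift + cfg.hr_shift * drive_1hz + rng.normal(0, cfg.hr_sigma, R)
    _inject_spikes(rng, hr, 1.0, cfg.artifact_rate_per_hour, cfg.artifact_amplitude * cfg.hr_sigma)

    # --- skin conductance, 40 Hz ----------------------------------------
    n_gsr = 40 * R
    t_gsr = np.arange(n_gsr) / 40.0
    tonic = cfg.gsr_tonic + rng.normal(0.0, 0.3) + 0.2 * np.sin(2 * np.pi * t_gsr / 5400.0 + rng.uniform(0, 2 * np.pi))
    rate_per_s = (cfg.gsr_event_rate / 60.0) * np.power(cfg.gsr_event_rate_ratio, drive_1hz)
    events = poisson_event_times(rng, rate_per_s)
    gsr = tonic + rng.normal(0, cfg.gsr_sigma, n_gsr)
    kernel_len = int(40 * 8 * cfg.gsr_event_tau)
    kernel_t = np.arange(kernel_len) / 40.0
    for ev in events:
        amp = rng.uniform(0.1, 0.5)
        start = int(ev * 40)
        stop = min(start + kernel_len, n_gsr)
        gsr[start:stop] += amp * np.exp(-kernel_t[: stop - start] / cfg.gsr_event_tau)
    _inject_spikes(rng, gsr, 40.0, cfg.artifact_rate_per_hour, cfg.artifact_amplitude * 10 * cfg.gsr_sigma)
    gsr = np.round(np.clip(gsr, 0.0, None), 2)  # 0.01 μS resolution

    # --- acceleration, 20 Hz, shared activity latent ---------------------
    n_acc = 20 * R
    scale = np.power(cfg.accel_var_ratio, 0.5 * np.repeat(drive_1hz, 20))
    activity = _smooth(rng.normal(0, 1.0, n_acc), 40) * np.sqrt(40) * cfg.accel_activity_std * scale
    weights = (0.5, 0.3, 0.8)
    gravity = (0.0, 0.0, 1.0)
    axes = []
    for w, g0 in zip(weights, gravity):
        ax = g0 + w * activity + rng.normal(0, cfg.accel_sigma, n_acc)
        _inject_spikes(rng, ax, 20.0, cfg.artifact_rate_per_hour, cfg.artifact_amplitude * cfg.accel_sigma)
        axes.append(np.round(ax / ACCEL_QUANTUM_G) * ACCEL_QUANTUM_G)

    # --- questionnaires ---------------------------------------------------
    esm_list = []
    for t, L in zip(esm_times, levels):
        mu_pos, mu_neg = _ITEM_MEANS[L]
        items = {}
        for name in PANAS_ITEMS:
            mu = mu_pos if name in _POSITIVE_ITEMS else mu_neg
            items[name] = int(np.clip(np.rint(rng.normal(mu, 0.7)), 1, 5))
        esm_list.append(
            EsmResponse(
                subject_id=subject_id,
                timestamp=_T0 + float(t),
                panas_items=items,
                valence=L,
                arousal=L,
            )
        )

    channels = {
        "hr": RawChannel(subject_id, "hr", 1.0, _T0, hr),
        "gsr": RawChannel(subject_id, "gsr", 40.0, _T0, gsr),
        "accel": tuple(
            RawChannel(subject_id, f"accel_{axis}", 20.0, _T0, arr)
            for axis, arr in zip("xyz", axes)
        ),
    }
    return channels, esm_list


def iter_subjects(cfg: SimConfig):
    """Yield ``(subject_id, channels, esm_list)`` for every subject."""
    for i in range(cfg.n_subjects):
        sid = f"sub-{i + 1:03d}"
        channels, esm = simulate_subject(cfg, sid, subject_index=i)
        yield sid, channels, esm


def simulate_dataset(cfg: SimConfig, out_dir) -> dict:
    """Write the whole study to disk in the CSV schemas the readers expect.

    Layout: ``<out_dir>/<subject>/hr.csv|gsr.csv|accel.csv`` plus one
    combined ``esm.csv``.  Returns a manifest with per-subject paths and
    the total prompt count.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"subjects": {}, "esm_csv": os.path.join(out_dir, "esm.csv"), "n_esm": 0}
    esm_rows = []
    for sid, channels, esm_list in iter_subjects(cfg):
        sdir = os.path.join(out_dir, sid)
        os.makedirs(sdir, exist_ok=True)
        paths = {}
        for name in ("hr", "gsr"):
            ch = channels[name]
            path = os.path.join(sdir, f"{name}.csv")
            pd.DataFrame({"timestamp": ch.times, "value": ch.values}).to_csv(path, index=False)
            paths[name] = path
        cx, cy, cz = channels["accel"]
        path = os.path.join(sdir, "accel.csv")
        pd.DataFrame(
            {"timestamp": cx.times, "x": cx.values, "y": cy.values, "z": cz.values}
        ).to_csv(path, index=False)
        paths["accel"] = path
        manifest["subjects"][sid] = paths
        for esm in esm_list:
            row = {"subject_id": esm.subject_id, "timestamp": esm.timestamp}
            row.update(esm.panas_items)
            row["valence"] = esm.valence
            row["arousal"] = esm.arousal
            esm_rows.append(row)
    pd.DataFrame(esm_rows).to_csv(manifest["esm_csv"], index=False)
    manifest["n_esm"] = len(esm_rows)
    return manifest
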