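"""Synthetic continuous EEG and behaviour with known ground truth.

The generator concatenates per-trial evoked responses (template map x
smooth time course per component) into a continuous CZ-referenced record,
adds temporally autocorrelated and spatially correlated background noise,
stereotyped eye blinks propagated from a VEOG channel, and occasional gross
amplitude artifacts. Because every planted quantity is stored, each
downstream stage can be validated by parameter recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import GroundTruth, Montage, make_ground_truth
from .stimuli import Condition, TrialSchedule, build_schedule

SFREQ = 1000.0
EPOCH_TMIN_MS = -100.0
EPOCH_TMAX_MS = 1000.0
STIMULUS_DURATION_MS = 100.0
ITI_MS = 1100.0               # 100 ms stimulus + 1000 ms blank


@dataclass
class RawRecording:
    """Continuous multichannel signal in microvolts at 1 kHz, CZ reference."""

    data: np.ndarray             # (n_channels, n_samples), EEG then VEOG last
    sfreq: float
    ch_names: list[str]
    events: pd.DataFrame         # columns: sample, condition
    montage: Montage
    veog_index: int
    blink_segments: np.ndarray | None = None   # boolean (n_samples,)
    artifact_trials: list[int] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def eeg_indices(self) -> list[int]:
        return [i for i in range(self.data.shape[0]) if i != self.veog_index]

    def copy(self) -> "RawRecording":
        return RawRecording(
            self.data.copy(), self.sfreq, list(self.ch_names),
            self.events.copy(), self.montage, self.veog_index,
            None if self.blink_segments is None else self.blink_segments.copy(),
            list(self.artifact_trials),
        )

    def to_mne(self):
        """Convert to an mne.io.RawArray (volts) with stimulus annotations."""
        import mne

        ch_types = ["eeg"] * len(self.ch_names)
        ch_types[self.veog_index] = "eog"
        info = mne.create_info(self.ch_names, self.sfreq, ch_types)
        raw = mne.io.RawArray(self.data * 1e-6, info, verbose="error")
        onsets = self.events["sample"].to_numpy() / self.sfreq
        raw.set_annotations(
            mne.Annotations(onsets, 0.0, self.events["condition"].tolist())
        )
        return raw

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        np.savez(stem.with_suffix(".npz"), data=self.data)
        meta = {
            "sfreq": self.sfreq,
            "ch_names": self.ch_names,
            "veog_index": self.veog_index,
            "events": self.events.to_dict(orient="list"),
        }
        stem.with_suffix(".json").write_text(json.dumps(meta))


# ---------------------------------------------------------------------------
# evoked responses

def _component_waveform(name: str, window: tuple[float, float],
                        t_ms: np.ndarray) -> np.ndarray:
    """Unit-peak time course confined to the component's window.

    N1/N2 are Gaussian pulses centred in their windows; the LMF is a
    raised-cosine plateau spanning its window. All are smooth and
    band-limited well within 0.1-30 Hz.
    """
    lo, hi = window
    centre = 0.5 * (lo + hi)
    if name == "LMF":
        w = np.zeros_like(t_ms)
        ramp = 0.2 * (hi - lo)
        rise = (t_ms >= lo) & (t_ms < lo + ramp)
        flat = (t_ms >= lo + ramp) & (t_ms <= hi - ramp)
        fall = (t_ms > hi - ramp) & (t_ms <= hi)
        w[rise] = 0.5 * (1 - np.cos(np.pi * (t_ms[rise] - lo) / ramp))
        w[flat] = 1.0
        w[fall] = 0.5 * (1 - np.cos(np.pi * (hi - t_ms[fall]) / ramp))
        return w
    sd = (hi - lo) / 4.0
    return np.exp(-((t_ms - centre) ** 2) / (2 * sd ** 2))


def _unit_component_epochs(gt: GroundTruth,
                           t_ms: np.ndarray) -> dict[str, np.ndarray]:
    """Unit-GFP template x unit-peak waveform, per component."""
    return {
        comp: np.outer(template,
                       _component_waveform(comp, gt.windows[comp], t_ms))
        for comp, template in gt.templates.items()
    }


def _calibration_matrix(gt: GroundTruth, t_ms: np.ndarray,
                        units: dict[str, np.ndarray]) -> np.ndarray:
    """M[w, c]: window/electrode-set mean of unit component c in analysis
    window w. Planted amplitudes are defined as these means, so component
    scales solve M s = amps (the small Gaussian tails that leak across
    windows are accounted for exactly)."""
    comps = list(gt.templates)
    M = np.empty((len(comps), len(comps)))
    for i, w in enumerate(comps):
        lo, hi = gt.windows[w]
        sel = (t_ms >= lo) & (t_ms <= hi)
        idx = gt.montage.indices(list(gt.analysis_electrodes[w]))
        for j, c in enumerate(comps):
            M[i, j] = units[c][np.ix_(idx, np.flatnonzero(sel))].mean()
    return M


def _admixture_epoch(gt: GroundTruth, t_ms: np.ndarray) -> np.ndarray:
    """N1-map generator active during the N2 window (unit amplitude)."""
    return np.outer(gt.templates["N1"],
                    _component_waveform("N2", gt.windows["N2"], t_ms))


def _admixture_means(gt: GroundTruth, t_ms: np.ndarray,
                     adm: np.ndarray) -> np.ndarray:
    comps = list(gt.templates)
    v = np.empty(len(comps))
    for i, w in enumerate(comps):
        lo, hi = gt.windows[w]
        sel = np.flatnonzero((t_ms >= lo) & (t_ms <= hi))
        idx = gt.montage.indices(list(gt.analysis_electrodes[w]))
        v[i] = adm[np.ix_(idx, sel)].mean()
    return v


def _has_admixture(gt: GroundTruth, label: str) -> bool:
    return (gt.topo_admixture_uv != 0.0 and gt.experiment in (1, 2)
            and label.startswith("S"))


def _build_epoch(gt: GroundTruth, label: str, t_ms: np.ndarray,
                 units: dict[str, np.ndarray], M: np.ndarray,
                 target_amps: np.ndarray, adm: np.ndarray,
                 adm_means: np.ndarray) -> np.ndarray:
    """Calibrated evoked epoch: window/electrode-set means equal
    ``target_amps`` exactly, including any topographic admixture."""
    comps = list(gt.templates)
    alpha = gt.topo_admixture_uv if _has_admixture(gt, label) else 0.0
    scales = np.linalg.solve(M, target_amps - alpha * adm_means)
    epoch = alpha * adm if alpha else np.zeros_like(adm)
    for s, comp in zip(scales, comps):
        epoch = epoch + s * units[comp]
    return epoch


def evoked_signal(condition: Condition | str, gt: GroundTruth,
                  t_ms: np.ndarray | None = None) -> np.ndarray:
    """Noise-free evoked epoch (channels x samples) for one condition, on the
    0..1000 ms post-onset time base unless ``t_ms`` is given.

    The epoch is calibrated so the mean amplitude over each component's
    analysis window and electrode set equals the planted table entry.
    """
    label = condition if isinstance(condition, str) else condition.label
    if t_ms is None:
        t_ms = np.arange(0.0, EPOCH_TMAX_MS + 1)
    units = _unit_component_epochs(gt, t_ms)
    M = _calibration_matrix(gt, t_ms, units)
    comps = list(gt.templates)
    amps = np.array([gt.amplitudes[label][c] for c in comps])
    adm = _admixture_epoch(gt, t_ms)
    return _build_epoch(gt, label, t_ms, units, M, amps, adm,
                        _admixture_means(gt, t_ms, adm))


# ---------------------------------------------------------------------------
# noise, blinks, artifacts

def _spatial_mixing(montage: Montage, length_scale_rad: float = 1.0) -> np.ndarray:
    """Cholesky factor of an exponential spatial covariance."""
    d = montage.great_circle_distances()
    cov = np.exp(-d / length_scale_rad)
    cov += 1e-9 * np.eye(len(cov))
    return np.linalg.cholesky(cov)

def ar1_spatial_noise(n_channels: int, n_samples: int, rng: np.random.Generator,
                      sigma_uv: float, ar_coef: float = 0.97,
                      mixing: np.ndarray | None = None) -> np.ndarray:
    """AR(1)-in-time, spatially correlated noise with stationary SD sigma_uv."""
    white = rng.standard_normal((n_channels, n_samples))
    if mixing is not None:
        white = mixing @ white
    from scipy.signal import lfilter

    noise = lfilter([1.0], [1.0, -ar_coef], white, axis=1)
    noise *= sigma_uv * math.sqrt(1 - ar_coef ** 2)
    return noise


def _blink_prototype(sfreq: float = SFREQ) -> np.ndarray:
    """Fixed 400 ms biphasic blink waveform, unit peak."""
    t = np.arange(int(0.4 * sfreq)) / sfreq
    w = np.sin(np.pi * t / 0.4) ** 2 * np.sin(2 * np.pi * t / 0.4 * 0.75)
    return w / np.abs(w).max()


@dataclass
class NoiseSpec:
    sigma_uv: float = 8.0
    ar_coef: float = 0.97
    spatial_scale_rad: float = 1.0
    blinks: bool = True
    artifacts: bool = True


def simulate_recording(schedule: TrialSchedule, gt: GroundTruth,
                       noise: NoiseSpec | None = None,
                       seed: int | None = None) -> RawRecording:
    """Continuous recording realizing a trial schedule.

    Trials are spaced ITI_MS apart plus 0-100 ms uniform jitter, with
    pre/post rolls long enough for full epoch windows and filter transients.
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    montage = gt.montage
    K = montage.n_channels
    n_trials = len(schedule)

    pre_roll = int(1.0 * SFREQ)
    iti = int(ITI_MS / 1000 * SFREQ)
    jitter = rng.integers(0, int(0.1 * SFREQ), size=n_trials)
    onsets = pre_roll + np.cumsum(np.concatenate([[0], iti + jitter[:-1]]))
    n_samples = int(onsets[-1] + int(1.5 * SFREQ))

    if noise.sigma_uv > 0:
        mixing = _spatial_mixing(montage, noise.spatial_scale_rad)
        data = ar1_spatial_noise(K, n_samples, rng, noise.sigma_uv,
                                 noise.ar_coef, mixing)
    else:
        data = np.zeros((K, n_samples))

    # evoked responses, cached per condition
    t_ms = np.arange(0.0, EPOCH_TMAX_MS + 1)
    cache = {c.label: evoked_signal(c, gt, t_ms) for c in schedule.conditions}
    for onset, label in zip(onsets, schedule.rows["condition"]):
        seg = cache[label]
        data[:, onset:onset + seg.shape[1]] += seg

    # VEOG channel + blinks
    veog = np.zeros(n_samples)
    blink_mask = np.zeros(n_samples, dtype=bool)
    if noise.blinks and gt.blink_rate_hz > 0:
        proto = _blink_prototype()
        n_blinks = rng.poisson(gt.blink_rate_hz * n_samples / SFREQ)
        starts = rng.integers(0, n_samples - len(proto), size=n_blinks)
        for s in starts:
            amp = gt.blink_amplitude_uv * rng.uniform(0.7, 1.3)
            veog[s:s + len(proto)] += amp * proto
            blink_mask[s:s + len(proto)] = True
        data += gt.blink_coeffs[:, None] * veog[None, :]
    veog += ar1_spatial_noise(1, n_samples, rng, 3.0, 0.9)[0] if noise.sigma_uv > 0 else 0.0

    # gross artifacts: square-ish pulses inside randomly chosen epochs
    artifact_trials: list[int] = []
    if noise.artifacts and gt.artifact_rate > 0:
        hit = rng.uniform(size=n_trials) < gt.artifact_rate
        pulse_len = int(0.05 * SFREQ)
        for i in np.flatnonzero(hit):
            ch = rng.integers(0, K)
            t0 = onsets[i] + rng.integers(int(0.15 * SFREQ), int(0.85 * SFREQ))
            sign = 1 if rng.uniform() < 0.5 else -1
            data[ch, t0:t0 + pulse_len] += sign * gt.artifact_amplitude_uv
            artifact_trials.append(int(i))

    full = np.vstack([data, veog])
    events = pd.DataFrame({"sample": onsets,
                           "condition": schedule.rows["condition"].to_numpy()})
    return RawRecording(
        data=full, sfreq=SFREQ,
        ch_names=list(montage.ch_names) + [montage.veog],
        events=events, montage=montage,
        veog_index=K, blink_segments=blink_mask,
        artifact_trials=artifact_trials,
    )


# ---------------------------------------------------------------------------
# behaviour

def simulate_behavior(schedule: TrialSchedule, gt: GroundTruth,
                      seed: int | None = None,
                      subject: int = 0,
                      subject_acc_logit_sd: float = 0.0,
                      subject_log_rt_sd: float = 0.0) -> pd.DataFrame:
    """Trial-level responses: Bernoulli accuracy, shifted-lognormal RTs.

    Optional subject-level random offsets (on the accuracy logit and log
    median RT) generate between-subject variability for group analyses.
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    rng = np.random.default_rng(seed)
    acc_off = rng.normal(0, subject_acc_logit_sd) if subject_acc_logit_sd else 0.0
    rt_off = rng.normal(0, subject_log_rt_sd) if subject_log_rt_sd else 0.0

    rows = []
    for row in schedule.rows.itertuples():
        cond = schedule.condition_for(row.condition)
        b = gt.behavior[row.condition]
        p = b["p_correct"]
        if acc_off:
            logit = math.log(p / (1 - p)) + acc_off
            p = 1 / (1 + math.exp(-logit))
        correct = rng.uniform() < p
        mu = math.log(b["rt_median_ms"] - b["rt_shift_ms"]) + rt_off
        rt = b["rt_shift_ms"] + math.exp(rng.normal(mu, b["rt_sigma"]))
        if correct:
            reported = cond.n_elements
        else:
            options = [n for n in (3, 4, 5, 6) if n != cond.n_elements]
            reported = int(rng.choice(options))
        rows.append((subject, row.trial_index, row.condition, reported,
                     bool(correct), rt))
    return pd.DataFrame(
        rows, columns=["subject", "trial_index", "condition",
                       "reported_number", "correct", "rt_ms"],
    )


# ---------------------------------------------------------------------------
# fast subject-level ERP simulation (used for group-level power studies)

def simulate_subject_erp(gt: GroundTruth, seed: int | None = None,
                         n_trials: int = 100, sigma_uv: float = 8.0,
                         amp_scale_sd: float = 0.15,
                         amp_shift_sd_uv: float = 0.8,
                         amp_cond_sd_uv: float = 0.4) -> dict[str, np.ndarray]:
    """Per-condition subject ERPs without the continuous-recording detour.

    The subject ERP is the planted evoked response with a subject-specific
    multiplicative gain, an additive per-component amplitude shift (shared
    across conditions), and an independent per-condition-per-component
    amplitude jitter (``amp_cond_sd_uv``, the window-mean sampling noise a
    finite-trial average of temporally autocorrelated EEG carries), plus
    white residual noise with standard deviation ``sigma_uv /
    sqrt(n_trials)``.
    """
    rng = np.random.default_rng(seed)
    t_ms = np.arange(EPOCH_TMIN_MS, EPOCH_TMAX_MS + 1)
    gain = rng.normal(1.0, amp_scale_sd)
    comps = list(gt.templates)
    shifts = {comp: rng.normal(0.0, amp_shift_sd_uv) for comp in comps}
    units = _unit_component_epochs(gt, t_ms)
    M = _calibration_matrix(gt, t_ms, units)
    adm = _admixture_epoch(gt, t_ms)
    adm_means = _admixture_means(gt, t_ms, adm)
    out = {}
    resid_sd = sigma_uv / math.sqrt(max(n_trials, 1))
    for label, amps in gt.amplitudes.items():
        target = np.array([
            gain * amps[c] + shifts[c] + rng.normal(0.0, amp_cond_sd_uv)
            for c in comps])
        epoch = _build_epoch(gt, label, t_ms, units, M, target, adm,
                             adm_means)
        if resid_sd > 0:
            epoch = epoch + rng.standard_normal(epoch.shape) * resid_sd
        out[label] = epoch
    return out


def simulate_experiment_behavior(experiment: int, n_subjects: int,
                                 reps: int = 100, seed: int | None = None,
                                 gt: GroundTruth | None = None) -> pd.DataFrame:
    """Behaviour tables for a whole experiment's sample of subjects."""
    gt = gt or make_ground_truth(experiment)
    ss = np.random.SeedSequence(seed)
    tables = []
    for subj, child in enumerate(ss.spawn(n_subjects)):
        s1, s2 = child.spawn(2)
        sched = build_schedule(experiment, reps,
                               int(s1.generate_state(1)[0] % 2**31))
        tables.append(
            simulate_behavior(sched, gt, int(s2.generate_state(1)[0] % 2**31),
                              subject=subj, subject_acc_logit_sd=0.3,
                              subject_log_rt_sd=0.06)
        )
    return pd.concat(tables, ignore_index=True)
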