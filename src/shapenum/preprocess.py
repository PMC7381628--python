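"""Continuous recording -> per-subject, per-condition average ERPs.

Stages, in order: zero-phase 0.1-30 Hz band-pass, regression-based blink
correction on the continuous data, epoching (-100..1000 ms) with baseline
subtraction, +-75 uV artifact rejection, per-condition averaging, and
common-average re-referencing for grand averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import RawRecording, EPOCH_TMIN_MS, EPOCH_TMAX_MS

REJECT_THRESHOLD_UV = 75.0


class SignalTooShortError(ValueError):
    pass


class TruncatedEpochError(ValueError):
    pass


class EmptyCellError(ValueError):
    pass


@dataclass
class EpochSet:
    subject: int
    data: np.ndarray              # (n_trials, n_channels, n_samples) uV
    times_ms: np.ndarray
    conditions: np.ndarray        # (n_trials,) labels
    ch_names: list[str]
    veog_index: int
    retained: np.ndarray = field(default=None)  # bool per trial

    def __post_init__(self) -> None:
        if self.retained is None:
            self.retained = np.ones(len(self.data), dtype=bool)

    @property
    def n_trials(self) -> int:
        return len(self.data)


@dataclass
class SubjectERP:
    subject: int
    condition: str
    data: np.ndarray              # (n_channels, n_samples) uV
    times_ms: np.ndarray
    ch_names: list[str]
    reference: str = "Cz"         # "Cz" or "average"
    n_trials: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ch_names,
                            columns=self.times_ms)


def bandpass_zero_phase(recording: RawRecording, low_hz: float = 0.1,
                        high_hz: float = 30.0) -> RawRecording:
    """Forward-backward Butterworth band-pass.

    The high-pass is order 2 (12 dB/octave) and the low-pass order 8
    (48 dB/octave) before the bidirectional pass; filtfilt makes the net
    response zero-phase. Edges are handled by odd reflection padding.
    """
    nyq = recording.sfreq / 2
    sos_hp = signal.butter(2, low_hz / nyq, btype="highpass", output="sos")
    sos_lp = signal.butter(8, high_hz / nyq, btype="lowpass", output="sos")
    padlen = min(recording.n_samples - 1, int(3 * recording.sfreq / low_hz))
    if recording.n_samples < 100:
        raise SignalTooShortError("recording too short to filter")
    out = recording.copy()
    x = signal.sosfiltfilt(sos_hp, out.data, axis=1, padlen=padlen)
    x = signal.sosfiltfilt(sos_lp, x, axis=1)
    out.data = x
    return out


def detect_blinks(veog: np.ndarray, threshold_uv: float = 50.0,
                  pad_ms: float = 50.0, sfreq: float = 1000.0) -> np.ndarray:
    """Boolean mask of blink segments: |VEOG| above threshold, padded."""
    mask = np.abs(veog) > threshold_uv
    if mask.any():
        pad = int(pad_ms / 1000 * sfreq)
        idx = np.flatnonzero(mask)
        for i in idx:
            mask[max(0, i - pad):i + pad] = True
    return mask


def correct_blinks(recording: RawRecording,
                   blink_mask: np.ndarray | None = None,
                   subtract_evoked: bool = True) -> tuple[RawRecording, np.ndarray]:
    """Regression-based ocular artifact correction.

    For each EEG channel a propagation coefficient ``b_i`` is estimated by
    least squares of the channel on VEOG over blink segments, after
    removing the average event-related activity from both; the corrected
    channel is ``EEG_i - b_i * VEOG``. Returns the corrected recording and
    the coefficient vector.
    """
    veog = recording.data[recording.veog_index]
    if blink_mask is None:
        blink_mask = detect_blinks(veog, sfreq=recording.sfreq)
    eeg_idx = recording.eeg_indices
    out = recording.copy()
    if not blink_mask.any() or np.allclose(veog, 0):
        warnings.warn("no blinks detected; returning input unchanged")
        return out, np.zeros(len(eeg_idx))

    work = recording.data.copy()
    if subtract_evoked and len(recording.events):
        work = work - _event_related_activity(recording)

    v = work[recording.veog_index, blink_mask]
    v = v - v.mean()
    denom = float(v @ v)
    coeffs = np.empty(len(eeg_idx))
    for k, i in enumerate(eeg_idx):
        y = work[i, blink_mask]
        coeffs[k] = float(v @ (y - y.mean())) / denom
        out.data[i] = recording.data[i] - coeffs[k] * veog
    return out, coeffs


def _event_related_activity(recording: RawRecording) -> np.ndarray:
    """Average stimulus-locked activity, tiled back onto the record."""
    n_post = int(EPOCH_TMAX_MS / 1000 * recording.sfreq) + 1
    segs = []
    for s in recording.events["sample"]:
        if s + n_post <= recording.n_samples:
            segs.append(recording.data[:, s:s + n_post])
    if not segs:
        return np.zeros_like(recording.data)
    erp = np.mean(segs, axis=0)
    model = np.zeros_like(recording.data)
    for s in recording.events["sample"]:
        if s + n_post <= recording.n_samples:
            model[:, s:s + n_post] = erp
    return model


def epoch(recording: RawRecording, subject: int = 0,
          window_ms: tuple[float, float] = (EPOCH_TMIN_MS, EPOCH_TMAX_MS),
          baseline: bool = True) -> EpochSet:
    """Cut stimulus-locked epochs and subtract the pre-stimulus baseline."""
    sf = recording.sfreq
    n_pre = int(round(-window_ms[0] / 1000 * sf))
    n_post = int(round(window_ms[1] / 1000 * sf))
    times = np.arange(-n_pre, n_post + 1) / sf * 1000
    trials, labels = [], []
    for s, cond in zip(recording.events["sample"], recording.events["condition"]):
        lo, hi = s - n_pre, s + n_post + 1
        if lo < 0 or hi > recording.n_samples:
            raise TruncatedEpochError(f"event at sample {s} lacks a full window")
        trials.append(recording.data[:, lo:hi])
        labels.append(cond)
    data = np.array(trials)
    if baseline:
        base = data[:, :, :n_pre + 1].mean(axis=2, keepdims=True)
        data = data - base
    return EpochSet(subject, data, times, np.array(labels),
                    list(recording.ch_names), recording.veog_index)


def reject_artifacts(epochs: EpochSet,
                     threshold_uv: float = REJECT_THRESHOLD_UV) -> EpochSet:
    """Flag epochs whose absolute value exceeds the threshold on any EEG
    channel at any sample (VEOG excluded)."""
    eeg = np.delete(epochs.data, epochs.veog_index, axis=1)
    bad = np.abs(eeg).max(axis=(1, 2)) > threshold_uv
    out = EpochSet(epochs.subject, epochs.data, epochs.times_ms,
                   epochs.conditions, epochs.ch_names, epochs.veog_index,
                   retained=epochs.retained & ~bad)
    if not out.retained.any():
        warnings.warn("all epochs rejected")
    return out


def average_erp(epochs: EpochSet, condition: str) -> SubjectERP:
    """Mean over retained trials of one condition (CZ-referenced)."""
    sel = (epochs.conditions == condition) & epochs.retained
    if not sel.any():
        raise EmptyCellError(f"no retained trials for condition {condition}")
    mean = epochs.data[sel].mean(axis=0)
    return SubjectERP(epochs.subject, condition, mean, epochs.times_ms,
                      list(epochs.ch_names), "Cz", int(sel.sum()))


def average_all_conditions(epochs: EpochSet) -> dict[str, SubjectERP]:
    return {c: average_erp(epochs, c) for c in np.unique(epochs.conditions)}


def rereference_average(erp: SubjectERP,
                        veog_name: str = "VEOG") -> SubjectERP:
    """Common-average re-reference over EEG channels (idempotent)."""
    keep = [i for i, n in enumerate(erp.ch_names) if n != veog_name]
    data = erp.data[keep]
    data = data - data.mean(axis=0, keepdims=True)
    return SubjectERP(erp.subject, erp.condition, data, erp.times_ms,
                      [erp.ch_names[i] for i in keep], "average", erp.n_trials)


def grand_average(erps: list[SubjectERP]) -> SubjectERP:
    """Across-subject mean after common-average re-referencing each input."""
    if len(erps) < 2:
        raise EmptyCellError("grand average needs at least 2 subjects")
    reref = [e if e.reference == "average" else rereference_average(e)
             for e in erps]
    data = np.mean([e.data for e in reref], axis=0)
    return SubjectERP(-1, reref[0].condition, data, reref[0].times_ms,
                      list(reref[0].ch_names), "average", len(erps))


def preprocess_subject(recording: RawRecording, subject: int = 0,
                       filter_data: bool = True,
                       blink_correct: bool = True) -> dict[str, SubjectERP]:
    """Full per-subject pipeline: filter -> blink-correct -> epoch ->
    reject -> average per condition."""
    rec = bandpass_zero_phase(recording) if filter_data else recording
    if blink_correct:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec, _ = correct_blinks(rec)
    ep = epoch(rec, subject)
    ep = reject_artifacts(ep)
    return average_all_conditions(ep)
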