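"""Continuous-EEG preprocessing: downsample, band-limit, reject/repair
channels, epoch around cues, and re-reference.

The chain mirrors standard swallowing-ERD practice: polyphase
downsampling to 512 Hz, zero-phase Butterworth band-limiting to
7-35 Hz (5th order each way, so no group delay), a robust
amplitude-based bad-channel stage with inverse-distance spatial
interpolation standing in for subspace artifact reconstruction,
epoching from -1000 to +5000 ms around each swallow cue, and a Common
Average Reference.  Trials and subjects falling below the
valid-swallow minimum are excluded and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .containers import Recording, EpochedRecording, EPOCH_SPAN_MS
from .montage import nearest_neighbors

logger = logging.getLogger(__name__)

#: Butterworth order used for each of the high- and low-pass stages;
#: forward-backward application doubles the effective order.
FILTER_ORDER = 5


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain (defaults = study settings)."""

    target_rate: float = 512.0
    hp_cutoff: float = 7.0
    lp_cutoff: float = 35.0
    reject_sd: float = 10.0
    min_valid_trials: int = 20
    reference: str = "common_average"

    def __post_init__(self) -> None:
        if not (0 < self.hp_cutoff < self.lp_cutoff < self.target_rate / 2):
            raise ValueError(
                "need 0 < hp_cutoff < lp_cutoff < target_rate/2, got "
                f"hp={self.hp_cutoff}, lp={self.lp_cutoff}, "
                f"rate={self.target_rate}"
            )
        if self.reference != "common_average":
            raise ValueError(f"unknown reference {self.reference!r}")


def resample(recording: Recording, target_rate: float) -> Recording:
    """Anti-aliased polyphase downsampling."""
    if target_rate > recording.rate:
        raise ValueError(
            f"upsampling ({recording.rate} -> {target_rate} Hz) is not part "
            "of the pipeline contract"
        )
    if target_rate == recording.rate:
        return recording.copy_with(recording.data.copy())
    frac = Fraction(target_rate / recording.rate).limit_denominator(10000)
    # sharp Kaiser design: passband ripple ~1e-8, so DC and in-band
    # amplitudes survive to well below the quantization floor
    out = signal.resample_poly(recording.data, frac.numerator,
                               frac.denominator, axis=-1,
                               window=("kaiser", 12.0))
    return recording.copy_with(out, rate=target_rate)


def _band_sos(hp_cutoff: float, lp_cutoff: float, rate: float) -> np.ndarray:
    nyq = rate / 2.0
    if lp_cutoff >= nyq:
        raise ValueError(f"low-pass cutoff {lp_cutoff} Hz >= Nyquist {nyq} Hz")
    hp = signal.butter(FILTER_ORDER, hp_cutoff, btype="highpass",
                       fs=rate, output="sos")
    lp = signal.butter(FILTER_ORDER, lp_cutoff, btype="lowpass",
                       fs=rate, output="sos")
    return np.vstack([hp, lp])


def bandlimit(recording: Recording, hp_cutoff: float = 7.0,
              lp_cutoff: float = 35.0) -> Recording:
    """Zero-phase 7-35 Hz band-limiting (forward-backward Butterworth).

    With a 5th-order section each way the effective magnitude response
    leaves < 0.4% amplitude error at 20 Hz and attenuates 1 Hz drift and
    50 Hz mains each to below 3% of their input amplitude.
    """
    sos = _band_sos(hp_cutoff, lp_cutoff, recording.rate)
    out = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return recording.copy_with(out)


def _robust_amplitudes(data: np.ndarray) -> np.ndarray:
    """Per-channel MAD-scaled amplitude (robust SD equivalent)."""
    med = np.median(data, axis=-1, keepdims=True)
    return 1.4826 * np.median(np.abs(data - med), axis=-1)


def reject_and_interpolate(recording: Recording, reject_sd: float = 10.0,
                           k_neighbors: int = 4
                           ) -> tuple[Recording, list[str]]:
    """Reject artifact channels and rebuild them from their neighbors.

    A channel is rejected when its robust (MAD-scaled) amplitude exceeds
    ``reject_sd`` times the recording's channel norm (the median robust
    amplitude across channels).  Rejected channels are replaced by the
    inverse-distance-weighted mean of their ``k_neighbors`` nearest
    clean electrodes on the flattened 10-20 layout.  Channel count and
    order are preserved.
    """
    if recording.n_channels < 4:
        raise ValueError("need at least 4 channels for rejection/interpolation")
    amps = _robust_amplitudes(recording.data)
    norm = np.median(amps)
    bad = np.flatnonzero(amps > reject_sd * norm)
    if len(bad) > 0.25 * recording.n_channels:
        raise ValueError(
            f"recording {recording.subject_id!r} unusable: "
            f"{len(bad)}/{recording.n_channels} channels rejected"
        )
    if len(bad) == 0:
        return recording.copy_with(recording.data.copy()), []

    labels = recording.channel_labels
    bad_set = {labels[i] for i in bad}
    neigh = nearest_neighbors(tuple(labels), k=recording.n_channels - 1)
    out = recording.data.copy()
    for i in bad:
        picks, weights = [], []
        for lab, dist in neigh[labels[i]]:
            if lab in bad_set:
                continue
            picks.append(labels.index(lab))
            weights.append(1.0 / max(dist, 1e-12))
            if len(picks) == k_neighbors:
                break
        w = np.asarray(weights) / np.sum(weights)
        out[i] = w @ recording.data[picks]
        logger.info("interpolated channel %s from %s",
                    labels[i], [labels[j] for j in picks])
    return recording.copy_with(out), [labels[i] for i in bad]


def epoch(recording: Recording, events: pd.DataFrame,
          span_ms: tuple[float, float] = EPOCH_SPAN_MS) -> EpochedRecording:
    """Cut cue-locked epochs; events too close to an edge are dropped.

    The span is half-open in samples, ``[t0, t1)``, so every trial has
    exactly ``(t1 - t0) * rate / 1000`` samples and the sample at t = 0
    is the recording sample at the event onset.
    """
    t0, t1 = span_ms
    if not t0 < t1:
        raise ValueError("epoch span must be increasing")
    i0 = int(round(t0 * recording.rate / 1000.0))
    i1 = int(round(t1 * recording.rate / 1000.0))
    trials = []
    for onset in np.asarray(events["onset_sample"], dtype=int):
        lo, hi = onset + i0, onset + i1
        if lo < 0 or hi > recording.n_samples:
            logger.warning(
                "subject %s: dropping event at sample %d (epoch outside "
                "recording)", recording.subject_id, onset)
            continue
        trials.append(recording.data[:, lo:hi])
    if not trials:
        raise ValueError(
            f"subject {recording.subject_id!r}: no event leaves a full epoch")
    return EpochedRecording(
        data=np.stack(trials), rate=recording.rate,
        channel_labels=list(recording.channel_labels), tmin_ms=t0,
        subject_id=recording.subject_id, group_label=recording.group_label)


def common_average_reference(epoched: EpochedRecording) -> EpochedRecording:
    """Subtract the instantaneous mean across channels (CAR)."""
    if epoched.n_channels < 2:
        raise ValueError("CAR needs at least 2 channels")
    out = epoched.data - epoched.data.mean(axis=1, keepdims=True)
    return epoched.copy_with(out)


def reject_trials(epoched: EpochedRecording, reject_sd: float = 10.0
                  ) -> EpochedRecording:
    """Drop trials whose peak amplitude is an outlier for the subject.

    A trial is invalid when its maximum absolute value across channels
    exceeds ``reject_sd`` times the robust amplitude norm pooled over
    all trials.  Updates ``n_valid_trials``.
    """
    norm = np.median(_robust_amplitudes(
        epoched.data.reshape(-1, epoched.n_samples)))
    peaks = np.max(np.abs(epoched.data), axis=(1, 2))
    keep = peaks <= reject_sd * norm
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("subject %s: dropped %d artifact trial(s)",
                       epoched.subject_id, dropped)
    out = epoched.copy_with(epoched.data[keep])
    out.n_valid_trials = int(keep.sum())
    return out


def filter_subjects(cohort: list[EpochedRecording], min_valid_trials: int = 20
                    ) -> list[EpochedRecording]:
    """Keep subjects with at least ``min_valid_trials`` valid swallows."""
    kept = []
    for rec in cohort:
        if rec.n_valid_trials >= min_valid_trials:
            kept.append(rec)
        else:
            logger.warning("excluding subject %s: %d valid trials < %d",
                           rec.subject_id, rec.n_valid_trials, min_valid_trials)
    if not kept:
        raise ValueError("no subject satisfies the valid-trial minimum")
    return kept


def preprocess_recording(recording: Recording, events: pd.DataFrame,
                         config: PreprocessConfig | None = None
                         ) -> tuple[EpochedRecording, list[str]]:
    """Full chain for one subject; returns epochs and rejected channels.

    Order: downsample -> band-limit -> channel reject/interpolate ->
    epoch -> trial reject -> common average reference.  Event onsets are
    rescaled to the target rate.
    """
    cfg = config or PreprocessConfig()
    rec = resample(recording, cfg.target_rate)
    ratio = cfg.target_rate / recording.rate
    events = events.assign(
        onset_sample=np.rint(events["onset_sample"] * ratio).astype(int))
    rec = bandlimit(rec, cfg.hp_cutoff, cfg.lp_cutoff)
    rec, bad = reject_and_interpolate(rec, cfg.reject_sd)
    epoched = epoch(rec, events)
    epoched = reject_trials(epoched, cfg.reject_sd)
    epoched = common_average_reference(epoched)
    return epoched, bad
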