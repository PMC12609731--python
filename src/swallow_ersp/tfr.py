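"""Morlet-wavelet ERSP with two-stage baseline correction.

Trial power is the squared magnitude of a complex Morlet convolution on
a 7-30 Hz grid whose cycle count rises linearly from 3 cycles at 7 Hz
to 20 cycles at 30 Hz (time resolution is traded for frequency
resolution as frequency grows).  Each trial map is first normalized by
its own full-epoch mean power per frequency (single-trial baseline,
which tames outlier trials), maps are averaged across trials, and the
average is divided by its pre-stimulus (-1000..0 ms) mean per frequency
and expressed as 10*log10 of the ratio: negative dB values are
event-related desynchronization (ERD), positive are synchronization.

Wavelets are unit-energy, so raw white-noise power is flat across
frequency; only power ratios matter downstream.  Cells whose wavelet
support crosses an epoch edge are masked, not zero-filled, and every
later aggregation skips masked cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .containers import EpochedRecording, EPOCH_SPAN_MS

#: Wavelet kernels are truncated at this many temporal SDs; the same
#: half-width defines the edge-invalidity mask.
KERNEL_HALF_WIDTH_SD = 3.5

STAGES = ("raw_power", "trial_normalized", "averaged", "db_corrected")


@dataclass
class WaveletPlan:
    """Frequency grid and cycle law for the Morlet transform."""

    freqs: np.ndarray
    cycles: np.ndarray
    rate: float
    n_times: int = 200  # target number of output time points per epoch
    f_min: float = 7.0
    f_max: float = 30.0
    c_min: float = 3.0
    c_max: float = 20.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.cycles = np.asarray(self.cycles, dtype=float)
        if np.any(self.freqs < self.f_min) or np.any(self.freqs > self.f_max):
            raise ValueError(
                f"frequency grid must lie in [{self.f_min}, {self.f_max}] Hz")
        if self.rate < 2 * self.f_max:
            raise ValueError("sampling rate below twice the top frequency")
        if np.any(np.diff(self.cycles) <= 0):
            raise ValueError("cycle counts must be strictly increasing")

    def sigma_t(self, f: float) -> float:
        """Temporal SD (s) of the wavelet at frequency f on this plan's law."""
        n = self.c_min + (self.c_max - self.c_min) * \
            (f - self.f_min) / (self.f_max - self.f_min)
        return n / (2.0 * np.pi * f)


def make_wavelet_plan(f_grid_spacing: float = 0.5, rate: float = 512.0,
                      f_min: float = 7.0, f_max: float = 30.0,
                      c_min: float = 3.0, c_max: float = 20.0,
                      n_times: int = 200) -> WaveletPlan:
    """Linear cycle law anchored at (f_min, c_min) and (f_max, c_max)."""
    freqs = np.arange(f_min, f_max + 1e-9, f_grid_spacing)
    cycles = c_min + (c_max - c_min) * (freqs - f_min) / (f_max - f_min)
    return WaveletPlan(freqs=freqs, cycles=cycles, rate=rate,
                       n_times=n_times, f_min=f_min, f_max=f_max,
                       c_min=c_min, c_max=c_max)


def morlet_kernel(f: float, n_cycles: float, rate: float) -> np.ndarray:
    """Unit-energy complex Morlet wavelet, truncated at +-3.5 sigma_t."""
    sigma_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(KERNEL_HALF_WIDTH_SD * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    w = np.exp(2j * np.pi * f * t) * np.exp(-t ** 2 / (2.0 * sigma_t ** 2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


@dataclass
class TimeFrequencyMap:
    """ERSP values on a time x frequency grid for one channel.

    ``values`` has shape (n_times, n_freqs); ``valid`` is False where the
    wavelet support crossed the epoch edge.  ``stage`` tracks which
    corrections have been applied.
    """

    values: np.ndarray
    valid: np.ndarray
    time_axis_ms: np.ndarray
    freqs: np.ndarray
    channel: str = ""
    stage: str = "raw_power"
    n_trials: int = 1
    subject_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.shape != (len(self.time_axis_ms), len(self.freqs)):
            raise ValueError("values shape does not match axes")
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask shape does not match values")

    def same_grid(self, other: "TimeFrequencyMap") -> bool:
        return (self.values.shape == other.values.shape
                and np.allclose(self.time_axis_ms, other.time_axis_ms)
                and np.allclose(self.freqs, other.freqs))

    def copy_with(self, values: np.ndarray, stage: str,
                  n_trials: int | None = None) -> "TimeFrequencyMap":
        return TimeFrequencyMap(
            values=values, valid=self.valid.copy(),
            time_axis_ms=self.time_axis_ms.copy(), freqs=self.freqs.copy(),
            channel=self.channel, stage=stage,
            n_trials=self.n_trials if n_trials is None else n_trials,
            subject_id=self.subject_id, group_label=self.group_label)


def _power_batch(data: np.ndarray, plan: WaveletPlan, tmin_ms: float
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_trials, n_out, n_freqs) power, validity mask, output times."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if np.any(~np.isfinite(data)):
        raise ValueError("input contains NaN or infinite samples")
    n = data.shape[1]
    hop = max(1, n // plan.n_times)
    idx = np.arange(0, n, hop)
    times = tmin_ms + 1000.0 * idx / plan.rate

    kernels = [morlet_kernel(f, c, plan.rate)
               for f, c in zip(plan.freqs, plan.cycles)]
    halves = np.array([(len(k) - 1) // 2 for k in kernels])
    nfft = sfft.next_fast_len(n + int(halves.max()) * 2 + 1)
    spec = sfft.fft(data, nfft, axis=1)

    power = np.empty((data.shape[0], len(idx), len(plan.freqs)))
    valid = np.empty((len(idx), len(plan.freqs)), dtype=bool)
    for j, (k, half) in enumerate(zip(kernels, halves)):
        kf = sfft.fft(k, nfft)
        conv = sfft.ifft(spec * kf[None, :], axis=1)
        # 'same' alignment: kernel center at each sample
        seg = conv[:, half:half + n]
        power[:, :, j] = np.abs(seg[:, idx]) ** 2
        valid[:, j] = (idx >= half) & (idx <= n - 1 - half)
    return power, valid, times


def trial_power(epoch_channel: np.ndarray, plan: WaveletPlan,
                tmin_ms: float = EPOCH_SPAN_MS[0], channel: str = ""
                ) -> TimeFrequencyMap:
    """Raw Morlet power of a single trial of one channel."""
    power, valid, times = _power_batch(epoch_channel, plan, tmin_ms)
    return TimeFrequencyMap(values=power[0], valid=valid,
                            time_axis_ms=times, freqs=plan.freqs.copy(),
                            channel=channel, stage="raw_power")


def single_trial_full_epoch_baseline(tfmap: TimeFrequencyMap,
                                     center: str = "mean"
                                     ) -> TimeFrequencyMap:
    """Divide each frequency column by its own full-epoch mean power."""
    if tfmap.stage != "raw_power":
        raise ValueError(f"expected raw_power stage, got {tfmap.stage}")
    out = np.empty_like(tfmap.values)
    agg = np.mean if center == "mean" else np.median
    for j in range(tfmap.values.shape[1]):
        v = tfmap.valid[:, j]
        if not v.any():
            raise ValueError(
                f"frequency {tfmap.freqs[j]:g} Hz has no valid samples")
        out[:, j] = tfmap.values[:, j] / agg(tfmap.values[v, j])
    return tfmap.copy_with(out, "trial_normalized")


def average_trials(maps: list[TimeFrequencyMap], min_trials: int = 1
                   ) -> TimeFrequencyMap:
    """Pointwise mean over trial maps (masked cells are skipped)."""
    if len(maps) < max(1, min_trials):
        raise ValueError(f"need at least {min_trials} trial maps, got {len(maps)}")
    first = maps[0]
    for m in maps[1:]:
        if not first.same_grid(m):
            raise ValueError("trial maps are on different grids")
        if m.channel != first.channel:
            raise ValueError("trial maps come from different channels")
    stack = np.stack([m.values for m in maps])
    vstack = np.stack([m.valid for m in maps])
    counts = vstack.sum(axis=0)
    summed = np.where(vstack, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, summed / np.maximum(counts, 1), np.nan)
    out = first.copy_with(mean, "averaged", n_trials=len(maps))
    out.valid = counts > 0
    return out


def prestimulus_db_correction(tfmap: TimeFrequencyMap,
                              baseline_window: tuple[float, float] = (-1000.0, 0.0),
                              min_baseline_samples: int = 10
                              ) -> TimeFrequencyMap:
    """Divide by the pre-stimulus mean per frequency and take 10*log10."""
    if tfmap.stage != "averaged":
        raise ValueError(f"expected averaged stage, got {tfmap.stage}")
    t0, t1 = baseline_window
    in_bl = (tfmap.time_axis_ms >= t0) & (tfmap.time_axis_ms < t1)
    out = np.full_like(tfmap.values, np.nan)
    for j in range(tfmap.values.shape[1]):
        sel = in_bl & tfmap.valid[:, j]
        if sel.sum() < min_baseline_samples:
            raise ValueError(
                f"frequency {tfmap.freqs[j]:g} Hz: only {int(sel.sum())} valid "
                f"baseline samples (need {min_baseline_samples})")
        base = tfmap.values[sel, j].mean()
        if not base > 0:
            raise ValueError(
                f"nonpositive baseline mean at {tfmap.freqs[j]:g} Hz")
        v = tfmap.valid[:, j]
        out[v, j] = 10.0 * np.log10(tfmap.values[v, j] / base)
    return tfmap.copy_with(out, "db_corrected")


def ersp_from_epochs(epoched: EpochedRecording, channel: str,
                     plan: WaveletPlan | None = None,
                     baseline_window: tuple[float, float] = (-1000.0, 0.0),
                     trial_baseline: str = "mean") -> TimeFrequencyMap:
    """Full ERSP chain for one channel of one subject.

    trial power -> single-trial full-epoch baseline -> trial average ->
    pre-stimulus dB correction.  Vectorized across trials.
    """
    plan = plan or make_wavelet_plan(rate=epoched.rate)
    if plan.rate != epoched.rate:
        raise ValueError("wavelet plan rate does not match the recording")
    data = epoched.channel(channel)
    power, valid, times = _power_batch(data, plan, epoched.tmin_ms)

    # single-trial full-epoch baseline, vectorized: per trial & frequency
    agg = np.mean if trial_baseline == "mean" else np.median
    norm = np.empty((power.shape[0], power.shape[2]))
    for j in range(power.shape[2]):
        v = valid[:, j]
        if not v.any():
            raise ValueError(
                f"frequency {plan.freqs[j]:g} Hz has no valid samples")
        norm[:, j] = agg(power[:, v, j], axis=1)
    power = power / norm[:, None, :]

    mean = power.mean(axis=0)
    avg = TimeFrequencyMap(values=mean, valid=valid, time_axis_ms=times,
                           freqs=plan.freqs.copy(), channel=channel,
                           stage="averaged", n_trials=power.shape[0],
                           subject_id=epoched.subject_id,
                           group_label=epoched.group_label)
    return prestimulus_db_correction(avg, baseline_window)
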