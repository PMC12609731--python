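"""Synthetic swallowing-EEG cohorts with controllable ERD structure.

The signal model for one trial and channel is

    x(t) = b(t) + a(t) * (1 - d_alpha * w(t)) + g(t) * (1 - d_beta * w(t))

where ``b`` is 1/f background noise, ``a`` and ``g`` are band-limited
Gaussian oscillators occupying the alpha (7-13 Hz) and beta (13-30 Hz)
analysis bands, ``d`` is the fractional amplitude suppression depth of
the event-related desynchronization (ERD), and ``w(t)`` is a
raised-cosine window that ramps from 0 to 1 after the swallowing cue
and back to 0 when the ERD ends.  Because the oscillators are
spectrally flat inside their bands and statistically independent of
the background, the expected band-power ratio between the ERD plateau
and the pre-cue baseline has the closed form

    (P_bg + (1 - d)^2 * P_osc) / (P_bg + P_osc)

which every downstream stage is tested against (see
:func:`expected_plateau_db`).

Randomness is counter-based (Philox keyed on ``(seed, group, subject)``)
so cohorts are bit-reproducible and adding a subject never perturbs the
signals of any other subject.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Recording, EpochedRecording, EPOCH_SPAN_MS
from .montage import MONTAGE_32, montage_for

#: Generation bands of the two oscillators (Hz); they coincide with the
#: alpha/beta analysis bands so per-band power bookkeeping is exact.
ALPHA_GEN_BAND = (7.0, 13.0)
BETA_GEN_BAND = (13.0, 30.0)

#: Background 1/f shaping is applied above this frequency; below it the
#: spectrum is zeroed (no DC / drift component).
_BG_F_LO = 1.0

# Continuous-recording layout: each trial occupies one slot, with the cue
# placed so that the epoch plus filter/wavelet guard fits inside the slot.
_SLOT_MS = 8000.0
_CUE_IN_SLOT_MS = 2000.0


@dataclass
class GroupProfile:
    """Generative parameters of one subject group.

    Depths are fractional amplitude suppressions in [0, 1) per channel;
    channels without an entry get depth 0.  Amplitudes are RMS in uV.
    """

    name: str = "custom"
    alpha_depth: dict[str, float] = field(default_factory=dict)
    beta_depth: dict[str, float] = field(default_factory=dict)
    erd_onset_ms: float = 200.0
    erd_offset_ms: float = 4200.0
    ramp_ms: float = 300.0
    alpha_amp: float = 4.0
    beta_amp: float = 4.5
    background_scale: float = 10.0
    trial_jitter_ms: float = 100.0

    def __post_init__(self) -> None:
        for band, depths in (("alpha", self.alpha_depth), ("beta", self.beta_depth)):
            for ch, d in depths.items():
                if not (0.0 <= d < 1.0):
                    raise ValueError(
                        f"{band} depth for {ch} must be in [0, 1), got {d}"
                    )
        if not self.erd_onset_ms < self.erd_offset_ms:
            raise ValueError("erd_onset_ms must be earlier than erd_offset_ms")
        if self.ramp_ms < 0:
            raise ValueError("ramp_ms must be nonnegative")

    def depth(self, band: str, channel: str) -> float:
        table = self.alpha_depth if band == "alpha" else self.beta_depth
        return float(table.get(channel, 0.0))


# Preset depths are chosen from the analytic plateau formula so that the
# three groups reproduce the *ordering* and approximate dB scale of the
# reported group medians: healthy = deep symmetric ERD in both bands;
# control = preserved alpha, reduced beta; dysphagic = shallow ERD in
# both bands with C3 (left) weaker than C4 (right), which makes |LI|
# largest in that group.
_PRESETS: dict[str, dict] = {
    "healthy": dict(
        alpha_depth={"C3": 0.35, "Cz": 0.30, "C4": 0.35},
        beta_depth={"C3": 0.50, "Cz": 0.45, "C4": 0.50},
    ),
    "control": dict(
        alpha_depth={"C3": 0.33, "Cz": 0.28, "C4": 0.33},
        beta_depth={"C3": 0.25, "Cz": 0.22, "C4": 0.25},
    ),
    "dysphagic": dict(
        alpha_depth={"C3": 0.10, "Cz": 0.08, "C4": 0.22},
        beta_depth={"C3": 0.12, "Cz": 0.10, "C4": 0.25},
    ),
}


def group_preset(name: str, **overrides) -> GroupProfile:
    """Built-in group profile (``healthy``, ``control`` or ``dysphagic``)."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(_PRESETS)}")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return GroupProfile(name=name, **kw)


@dataclass
class CohortSpec:
    """Cohort layout and acquisition parameters.

    ``groups`` is a list of ``(GroupProfile, n_subjects)``.  Per-subject
    biological variability is injected by jittering depths (SD
    ``subject_depth_sd``) and scaling amplitudes (lognormal, CV
    ``subject_amp_cv``); set both to 0 for identical subjects.
    """

    groups: list[tuple[GroupProfile, int]]
    n_trials_per_subject: int = 40
    trial_count_sd: float = 0.0  # truncated-normal heterogeneity; 0 = off
    sampling_rate: float = 2000.0
    n_channels: int = 32
    channel_labels: tuple[str, ...] | None = None
    epoch_span_ms: tuple[float, float] = EPOCH_SPAN_MS
    seed: int = 0
    subject_depth_sd: float = 0.04
    subject_amp_cv: float = 0.15

    def __post_init__(self) -> None:
        for profile, n in self.groups:
            if n <= 0:
                raise ValueError(f"group {profile.name!r} has n_subjects={n} <= 0")
        if self.n_trials_per_subject < 1:
            raise ValueError("n_trials_per_subject must be >= 1")
        if self.sampling_rate <= 2 * 35.0:
            raise ValueError("sampling_rate must exceed twice the 35 Hz band edge")
        if self.channel_labels is None:
            self.channel_labels = montage_for(self.n_channels)
        else:
            self.channel_labels = tuple(self.channel_labels)
            self.n_channels = len(self.channel_labels)


# ---------------------------------------------------------------------------
# spectral synthesis


def _spectral_weights(envelope: np.ndarray, n: int) -> float:
    """Variance of irfft(rfft(white) * envelope) per sample, for unit white noise."""
    w2 = envelope ** 2
    # full-spectrum sum: interior rfft bins appear twice
    total = w2[0] + 2.0 * w2[1:-1].sum() + (w2[-1] if n % 2 == 0 else 2.0 * w2[-1])
    return float(total / n)


def _shaped_noise(rng: np.random.Generator, n_trials: int, n: int,
                  envelope: np.ndarray, rms: float) -> np.ndarray:
    """(n_trials, n) Gaussian noise with spectral magnitude ``envelope``
    and expected RMS ``rms`` per sample."""
    var = _spectral_weights(envelope, n)
    if var <= 0:
        return np.zeros((n_trials, n))
    g = envelope * (rms / np.sqrt(var))
    white = rng.standard_normal((n_trials, n))
    return np.fft.irfft(np.fft.rfft(white, axis=-1) * g, n=n, axis=-1)


def _band_envelope(freqs: np.ndarray, f1: float, f2: float) -> np.ndarray:
    return ((freqs >= f1) & (freqs <= f2)).astype(float)


def _background_envelope(freqs: np.ndarray) -> np.ndarray:
    env = np.zeros_like(freqs)
    m = freqs >= _BG_F_LO
    env[m] = 1.0 / np.sqrt(freqs[m])
    return env


def _raised_cosine(t_ms: np.ndarray, onset: float, offset: float,
                   ramp: float) -> np.ndarray:
    """0 outside [onset, offset]; 1 inside [onset+ramp, offset-ramp];
    raised-cosine transitions in between."""
    w = np.zeros_like(t_ms)
    if ramp > 0:
        up = (t_ms > onset) & (t_ms < onset + ramp)
        w[up] = 0.5 * (1.0 - np.cos(np.pi * (t_ms[up] - onset) / ramp))
        down = (t_ms > offset - ramp) & (t_ms < offset)
        w[down] = 0.5 * (1.0 - np.cos(np.pi * (offset - t_ms[down]) / ramp))
    w[(t_ms >= onset + ramp) & (t_ms <= offset - ramp)] = 1.0
    return w


# ---------------------------------------------------------------------------
# analytic expectations (used by tests and docs, not by the pipeline)


def expected_band_powers(profile: GroupProfile, band: str, rate: float = 2000.0,
                         duration_ms: float = _SLOT_MS) -> tuple[float, float]:
    """Expected in-band power (uV^2) of (background, oscillator) for one band.

    Computed from the same spectral envelopes and normalization used by
    the generator, so it is exact in expectation for any rate/duration.
    """
    n = int(round(duration_ms * rate / 1000.0))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    f1, f2 = ALPHA_GEN_BAND if band == "alpha" else BETA_GEN_BAND
    in_band = _band_envelope(freqs, f1, f2)

    bg_env = _background_envelope(freqs)
    bg_total = _spectral_weights(bg_env, n)
    bg_in = _spectral_weights(bg_env * in_band, n)
    p_bg = profile.background_scale ** 2 * bg_in / bg_total

    amp = profile.alpha_amp if band == "alpha" else profile.beta_amp
    p_osc = amp ** 2  # oscillator fully inside its band
    return p_bg, p_osc


def expected_plateau_db(profile: GroupProfile, channel: str, band: str,
                        rate: float = 2000.0) -> float:
    """Analytic ERD plateau depth in dB relative to baseline:
    10*log10((P_bg + (1-d)^2 P_osc) / (P_bg + P_osc))."""
    p_bg, p_osc = expected_band_powers(profile, band, rate)
    d = profile.depth(band, channel)
    return 10.0 * np.log10((p_bg + (1.0 - d) ** 2 * p_osc) / (p_bg + p_osc))


# ---------------------------------------------------------------------------
# generation


def study_cohort_spec(seed: int, n_trials_per_subject: int = 20,
                      n_channels: int = 9,
                      sampling_rate: float = 2000.0) -> CohortSpec:
    """Cohort spec matching the study's group structure.

    21 healthy, 32 post-stroke controls and 50 dysphagic patients,
    acquired at 2 kHz.  Desk-scale defaults keep the run tractable:
    20 trials per subject (the study's valid-swallow minimum) and the
    reduced 9-channel sensorimotor montage; pass ``n_channels=32`` and
    ``n_trials_per_subject=40`` for the full acquisition layout.
    """
    return CohortSpec(
        groups=[(group_preset("healthy"), 21),
                (group_preset("control"), 32),
                (group_preset("dysphagic"), 50)],
        n_trials_per_subject=n_trials_per_subject,
        sampling_rate=sampling_rate, n_channels=n_channels, seed=seed)


def generate_trial(profile: GroupProfile, channel: str, duration_ms: float,
                   rate_hz: float, rng: np.random.Generator,
                   tmin_ms: float = EPOCH_SPAN_MS[0],
                   jitter_ms: float | None = None) -> np.ndarray:
    """One trial of one channel: 1/f background plus two suppressible
    band-limited oscillators.  ``tmin_ms`` positions the cue (t = 0)
    inside the generated window."""
    if channel not in MONTAGE_32:
        raise KeyError(f"unknown channel label {channel!r}")
    n = int(round(duration_ms * rate_hz / 1000.0))
    sig = _generate_trials_batch(profile, channel, 1, n, rate_hz, tmin_ms, rng,
                                 jitter_ms=jitter_ms)
    return sig[0]


def _generate_trials_batch(profile: GroupProfile, channel: str, n_trials: int,
                           n: int, rate_hz: float, tmin_ms: float,
                           rng: np.random.Generator,
                           jitter_ms: float | None = None) -> np.ndarray:
    """(n_trials, n) trials for one channel; vectorized over trials."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    t_ms = tmin_ms + 1000.0 * np.arange(n) / rate_hz

    bg = _shaped_noise(rng, n_trials, n, _background_envelope(freqs),
                       profile.background_scale)
    alpha = _shaped_noise(rng, n_trials, n, _band_envelope(freqs, *ALPHA_GEN_BAND),
                          profile.alpha_amp)
    beta = _shaped_noise(rng, n_trials, n, _band_envelope(freqs, *BETA_GEN_BAND),
                         profile.beta_amp)

    jit_amp = profile.trial_jitter_ms if jitter_ms is None else jitter_ms
    jitter = rng.uniform(-jit_amp, jit_amp, size=n_trials) if jit_amp > 0 \
        else np.zeros(n_trials)

    d_a = profile.depth("alpha", channel)
    d_b = profile.depth("beta", channel)
    out = bg
    for osc, d in ((alpha, d_a), (beta, d_b)):
        if d == 0.0:
            out = out + osc
            continue
        for i in range(n_trials):
            w = _raised_cosine(t_ms, profile.erd_onset_ms + jitter[i],
                               profile.erd_offset_ms + jitter[i],
                               profile.ramp_ms)
            out[i] += osc[i] * (1.0 - d * w)
    return out


def _subject_rng(seed: int, group_index: int, subject_index: int
                 ) -> np.random.Generator:
    key = (np.uint64(group_index) << np.uint64(32)) | np.uint64(subject_index)
    return np.random.Generator(np.random.Philox(key=[np.uint64(seed), key]))


def _perturb_profile(profile: GroupProfile, rng: np.random.Generator,
                     depth_sd: float, amp_cv: float) -> GroupProfile:
    """Subject-level biological variability: jitter depths, scale amplitudes."""
    def jit(depths: dict[str, float]) -> dict[str, float]:
        return {ch: float(np.clip(d + rng.normal(0.0, depth_sd), 0.0, 0.95))
                for ch, d in depths.items()}

    scale_a = float(np.exp(rng.normal(0.0, amp_cv)))
    scale_b = float(np.exp(rng.normal(0.0, amp_cv)))
    return dataclasses.replace(
        profile,
        alpha_depth=jit(profile.alpha_depth) if depth_sd > 0 else dict(profile.alpha_depth),
        beta_depth=jit(profile.beta_depth) if depth_sd > 0 else dict(profile.beta_depth),
        alpha_amp=profile.alpha_amp * (scale_a if amp_cv > 0 else 1.0),
        beta_amp=profile.beta_amp * (scale_b if amp_cv > 0 else 1.0),
    )


def generate_subject(spec: CohortSpec, group_index: int, subject_index: int
                     ) -> tuple[Recording, pd.DataFrame]:
    """Continuous recording plus swallow-cue event table for one subject.

    Trials are laid out in 8 s slots with the cue 2 s into each slot, so
    every epoch retains a filter/wavelet guard on both sides.
    """
    profile, _ = spec.groups[group_index]
    rng = _subject_rng(spec.seed, group_index, subject_index)
    profile = _perturb_profile(profile, rng, spec.subject_depth_sd,
                               spec.subject_amp_cv)

    n_trials = spec.n_trials_per_subject
    if spec.trial_count_sd > 0:
        draw = rng.normal(n_trials, spec.trial_count_sd)
        n_trials = int(np.clip(round(draw), 1, spec.n_trials_per_subject))

    rate = spec.sampling_rate
    slot_n = int(round(_SLOT_MS * rate / 1000.0))
    cue_off = int(round(_CUE_IN_SLOT_MS * rate / 1000.0))
    n_total = slot_n * n_trials

    data = np.empty((spec.n_channels, n_total))
    for ci, ch in enumerate(spec.channel_labels):
        trials = _generate_trials_batch(profile, ch, n_trials, slot_n, rate,
                                        -_CUE_IN_SLOT_MS, rng)
        data[ci] = trials.reshape(-1)

    onsets = np.arange(n_trials) * slot_n + cue_off
    events = pd.DataFrame({"onset_sample": onsets,
                           "label": ["swallow"] * n_trials})
    subject_id = f"{profile.name}-{subject_index:03d}"
    rec = Recording(data=data, rate=rate,
                    channel_labels=list(spec.channel_labels),
                    subject_id=subject_id, group_label=profile.name)
    return rec, events


def iter_subjects(spec: CohortSpec):
    """Yield ``(recording, events, meta_dict)`` subject by subject.

    Streaming interface for large cohorts; ``generate_cohort`` holds
    everything in memory and is only for small test cohorts.
    """
    for gi, (profile, n_subj) in enumerate(spec.groups):
        for si in range(n_subj):
            rec, events = generate_subject(spec, gi, si)
            meta = {
                "subject_id": rec.subject_id,
                "group": profile.name,
                "group_index": gi,
                "subject_index": si,
                "n_trials": len(events),
            }
            yield rec, events, meta


def generate_cohort(spec: CohortSpec
                    ) -> tuple[list[EpochedRecording], pd.DataFrame]:
    """All subjects epoched at the native rate, plus a metadata table.

    Epochs are cut directly around each cue without any preprocessing;
    use the preprocess module for the full pipeline path.
    """
    t0, t1 = spec.epoch_span_ms
    rows = []
    recordings = []
    for rec, events, meta in iter_subjects(spec):
        i0 = int(round(t0 * rec.rate / 1000.0))
        i1 = int(round(t1 * rec.rate / 1000.0))
        trials = np.stack([rec.data[:, s + i0:s + i1]
                           for s in events["onset_sample"].to_numpy()])
        recordings.append(EpochedRecording(
            data=trials, rate=rec.rate,
            channel_labels=list(rec.channel_labels), tmin_ms=t0,
            subject_id=rec.subject_id, group_label=rec.group_label))
        rows.append(meta)
    return recordings, pd.DataFrame(rows)
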