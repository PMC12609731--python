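"""Band/time aggregates of the dB-corrected ERSP map.

Three descriptors summarize event-related (de)synchronization:

* ERO(t) — the ERSP averaged over a frequency band, a band-power time
  course in dB (negative = ERD).
* ERI — the ERO additionally averaged over a time window (default
  500-2000 ms, the interval of maximal swallowing-related ERD), one
  scalar in dB per subject x channel x band.
* LI — the hemispheric lateralization index
  (ERI_C3 - ERI_C4) / (ERI_C3 + ERI_C4); 0 means bilateral dominance,
  and the ratio is flagged as undefined when the denominator is within
  ``epsilon`` of zero (the index is unbounded there).

Averages are trapezoidal on the native ERSP grid, restricted to
unmasked cells.  The alpha band is [7, 13] Hz and beta [13, 30] Hz;
the shared 13 Hz edge belongs to both, as the band definitions print.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tfr import TimeFrequencyMap

#: Denominator guard for the lateralization index, in dB.
LI_EPSILON = 1e-3


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not self.f1 < self.f2:
            raise ValueError(f"band {self.name!r}: need f1 < f2")


@dataclass(frozen=True)
class TimeWindow:
    t1: float = 500.0
    t2: float = 2000.0

    def __post_init__(self) -> None:
        if not self.t1 < self.t2:
            raise ValueError("time window: need t1 < t2")


ALPHA = FrequencyBand("alpha", 7.0, 13.0)
BETA = FrequencyBand("beta", 13.0, 30.0)


@dataclass
class BandTrace:
    """ERO(t): band-averaged ERSP in dB over the epoch time axis."""

    values: np.ndarray
    valid: np.ndarray
    time_axis_ms: np.ndarray
    band: FrequencyBand
    channel: str = ""
    subject_id: str = ""
    group_label: str = ""


def _trapz_weights(n: int) -> np.ndarray:
    """Uniform-grid trapezoid weights (average form): 1/2 at ends, 1 inside."""
    if n == 1:
        return np.ones(1)
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    return w


def _masked_band_average(values: np.ndarray, valid: np.ndarray) -> tuple[float, bool]:
    """Trapezoidal average over the valid cells of one row/column."""
    v = np.flatnonzero(valid)
    if v.size == 0:
        return np.nan, False
    sub = values[v[0]:v[-1] + 1]
    sub_ok = valid[v[0]:v[-1] + 1]
    w = _trapz_weights(len(sub))
    w = np.where(sub_ok, w, 0.0)  # interior gaps get zero weight
    return float(np.sum(w * np.where(sub_ok, sub, 0.0)) / np.sum(w)), True


def compute_ero(tfmap: TimeFrequencyMap, band: FrequencyBand) -> BandTrace:
    """Frequency-average of the ERSP over [f1, f2]: the ERO time course."""
    if tfmap.stage != "db_corrected":
        raise ValueError(f"expected db_corrected stage, got {tfmap.stage}")
    sel = (tfmap.freqs >= band.f1) & (tfmap.freqs <= band.f2)
    if not sel.any():
        raise ValueError(
            f"band {band.name!r} [{band.f1}, {band.f2}] Hz contains no grid bins")
    vals = np.empty(len(tfmap.time_axis_ms))
    ok = np.empty(len(tfmap.time_axis_ms), dtype=bool)
    sub_v = tfmap.values[:, sel]
    sub_m = tfmap.valid[:, sel]
    for i in range(len(vals)):
        vals[i], ok[i] = _masked_band_average(sub_v[i], sub_m[i])
    return BandTrace(values=vals, valid=ok, time_axis_ms=tfmap.time_axis_ms.copy(),
                     band=band, channel=tfmap.channel,
                     subject_id=tfmap.subject_id, group_label=tfmap.group_label)


def compute_eri(tfmap: TimeFrequencyMap, band: FrequencyBand,
                window: TimeWindow = TimeWindow()) -> float:
    """Band- and time-averaged ERSP over the window, one scalar in dB.

    Computed as the time-trapezoid of the ERO trace restricted to the
    window, so the nesting identity ERI = time-average of ERO holds
    exactly on the discrete grid.
    """
    ero = compute_ero(tfmap, band)
    in_w = (ero.time_axis_ms >= window.t1) & (ero.time_axis_ms <= window.t2)
    value, ok = _masked_band_average(np.where(in_w, ero.values, np.nan),
                                    in_w & ero.valid)
    if not ok or not np.isfinite(value):
        raise ValueError(
            f"window [{window.t1}, {window.t2}] ms has no valid cells "
            f"for band {band.name!r}")
    return value


def compute_li(eri_c3: float, eri_c4: float,
               epsilon: float = LI_EPSILON) -> tuple[float, bool]:
    """Lateralization index (C3 = left, C4 = right hemisphere).

    Returns ``(LI, denominator_flag)``; when |ERI_C3 + ERI_C4| < epsilon
    the index is unbounded, LI is reported as NaN and the flag is set.
    """
    if not (np.isfinite(eri_c3) and np.isfinite(eri_c4)):
        raise ValueError("both ERIs must be finite")
    denom = eri_c3 + eri_c4
    if abs(denom) < epsilon:
        return np.nan, True
    return (eri_c3 - eri_c4) / denom, False


def build_biomarker_table(subject_maps: dict[str, dict[str, TimeFrequencyMap]],
                          groups: dict[str, str],
                          bands: tuple[FrequencyBand, ...] = (ALPHA, BETA),
                          window: TimeWindow = TimeWindow(),
                          channels: tuple[str, ...] = ("C3", "Cz", "C4"),
                          epsilon: float = LI_EPSILON
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-subject ERI and LI tables.

    ``subject_maps`` maps subject_id -> channel -> db_corrected map;
    ``groups`` maps subject_id -> group label.  Subjects missing a
    channel lose the dependent rows (LI needs both C3 and C4); subjects
    missing all channels are skipped with a warning.
    """
    import logging
    logger = logging.getLogger(__name__)

    eri_rows, li_rows = [], []
    for sid, maps in subject_maps.items():
        present = [ch for ch in channels if ch in maps]
        if not present:
            logger.warning("subject %s: no sensorimotor channels, skipped", sid)
            continue
        group = groups.get(sid, "")
        eri: dict[tuple[str, str], float] = {}
        for ch in present:
            for band in bands:
                val = compute_eri(maps[ch], band, window)
                eri[(ch, band.name)] = val
                eri_rows.append({"subject_id": sid, "group": group,
                                 "channel": ch, "band": band.name,
                                 "eri_db": val})
        if "C3" in present and "C4" in present:
            for band in bands:
                li, flag = compute_li(eri[("C3", band.name)],
                                      eri[("C4", band.name)], epsilon)
                li_rows.append({"subject_id": sid, "group": group,
                                "band": band.name, "li": li,
                                "denominator_flag": flag})
    eri_df = pd.DataFrame(eri_rows, columns=["subject_id", "group", "channel",
                                             "band", "eri_db"])
    li_df = pd.DataFrame(li_rows, columns=["subject_id", "group", "band",
                                           "li", "denominator_flag"])
    return eri_df, li_df
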