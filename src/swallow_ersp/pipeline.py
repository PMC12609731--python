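"""End-to-end orchestration: simulate -> preprocess -> ERSP ->
biomarkers -> statistics, as one configured, logged, reproducible run.

A run is described by a :class:`RunConfig` (YAML/JSON on disk).  The
cohort is either synthetic (group presets or custom profiles) or a
directory of EDF recordings with event sidecars and a metadata table.
Subjects are processed one at a time (streaming), so cohort size is
bounded by disk, not memory.  Every run directory receives the
biomarker tables, the statistics report, grand-average ERO/ERSP
exports, a processing log, and a snapshot of the resolved
configuration; identical config + seed reproduces every numeric
output bit for bit in synthetic mode.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthgen
from .biomarkers import (ALPHA, BETA, FrequencyBand, TimeWindow, LI_EPSILON,
                         build_biomarker_table, compute_ero)
from .containers import Recording
from .edf import read_edf, write_edf
from .montage import SENSORIMOTOR
from .preprocess import PreprocessConfig, preprocess_recording
from .stats import run_group_analysis, summarize_report
from .tfr import make_wavelet_plan, ersp_from_epochs

logger = logging.getLogger(__name__)


@dataclass
class TfrConfig:
    f_grid_spacing: float = 0.5
    n_times: int = 200
    f_min: float = 7.0
    f_max: float = 30.0
    c_min: float = 3.0
    c_max: float = 20.0


@dataclass
class StatsConfig:
    correction: str | None = None
    li_epsilon: float = LI_EPSILON


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    cohort: synthgen.CohortSpec | None = None
    data_dir: str | None = None  # real-data alternative to a synthetic cohort
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    tfr: TfrConfig = field(default_factory=TfrConfig)
    bands: tuple[FrequencyBand, ...] = (ALPHA, BETA)
    window: TimeWindow = field(default_factory=TimeWindow)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cohort is None and self.data_dir is None:
            raise ValueError("config needs either a synthetic cohort or data_dir")


# ---------------------------------------------------------------------------
# config parsing / validation


def _config_from_dict(doc: dict) -> RunConfig:
    cohort = None
    if "cohort" in doc and doc["cohort"] is not None:
        c = dict(doc["cohort"])
        groups = []
        for entry in c.pop("groups"):
            entry = dict(entry)
            n = int(entry.pop("n_subjects"))
            name = entry.pop("name")
            if entry:
                depth_keys = {"alpha_depth", "beta_depth"}
                if depth_keys & entry.keys() or name not in ("healthy", "control", "dysphagic"):
                    profile = synthgen.GroupProfile(name=name, **entry)
                else:
                    profile = synthgen.group_preset(name, **entry)
            else:
                profile = synthgen.group_preset(name)
            groups.append((profile, n))
        if "epoch_span_ms" in c:
            c["epoch_span_ms"] = tuple(c["epoch_span_ms"])
        cohort = synthgen.CohortSpec(groups=groups, **c)
    bands = tuple(FrequencyBand(**b) for b in doc.get(
        "bands", [{"name": "alpha", "f1": 7.0, "f2": 13.0},
                  {"name": "beta", "f1": 13.0, "f2": 30.0}]))
    return RunConfig(
        cohort=cohort,
        data_dir=doc.get("data_dir"),
        preprocess=PreprocessConfig(**doc.get("preprocess", {})),
        tfr=TfrConfig(**doc.get("tfr", {})),
        bands=bands,
        window=TimeWindow(**doc.get("window", {})),
        stats=StatsConfig(**doc.get("stats", {})),
        seed=doc.get("seed"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON) run configuration."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return _config_from_dict(doc)


def validate_config(path_or_doc) -> list[str]:
    """Collect invariant violations (empty list = valid).

    Accepts a config file path or an already-parsed mapping; every
    sub-config's constructor enforces its own invariants, and the
    violations are reported with the offending section.
    """
    violations: list[str] = []
    if isinstance(path_or_doc, (str, Path)):
        try:
            doc = yaml.safe_load(Path(path_or_doc).read_text())
        except (OSError, yaml.YAMLError) as exc:
            return [f"config file unreadable: {exc}"]
    else:
        doc = path_or_doc
    if not isinstance(doc, dict):
        return ["configuration must be a mapping"]

    # section-by-section so one bad section does not hide another
    for section, builder in [
        ("cohort", lambda d: _config_from_dict({"cohort": d["cohort"]})
            if d.get("cohort") else None),
        ("preprocess", lambda d: PreprocessConfig(**d.get("preprocess", {}))),
        ("bands", lambda d: [FrequencyBand(**b) for b in d.get("bands", [])]),
        ("window", lambda d: TimeWindow(**d.get("window", {}))),
        ("stats", lambda d: StatsConfig(**d.get("stats", {}))),
        ("tfr", lambda d: TfrConfig(**d.get("tfr", {}))),
    ]:
        try:
            builder(doc)
        except (TypeError, ValueError, KeyError) as exc:
            violations.append(f"{section}: {exc}")
    if not violations:
        try:
            cfg = _config_from_dict(doc)
            if (cfg.cohort is not None and doc.get("seed") is None
                    and (doc.get("cohort") or {}).get("seed") is None):
                violations.append("seed: mandatory for synthetic cohorts")
            nyq = cfg.preprocess.target_rate / 2
            if cfg.tfr.f_max >= nyq:
                violations.append(
                    f"tfr.f_max: {cfg.tfr.f_max} Hz >= Nyquist {nyq} Hz")
        except (TypeError, ValueError, KeyError) as exc:
            violations.append(str(exc))
    return violations


# ---------------------------------------------------------------------------
# cohort iteration (synthetic or from disk)


def iter_cohort(config: RunConfig):
    """Yield (recording, events, meta) for every subject."""
    if config.cohort is not None:
        spec = config.cohort
        if config.seed is not None:
            spec = dataclasses.replace(spec, seed=config.seed)
        yield from synthgen.iter_subjects(spec)
        return
    root = Path(config.data_dir)
    meta = pd.read_csv(root / "subjects.csv")
    for _, row in meta.iterrows():
        rec, events = read_edf(root / row["edf_file"])
        rec.subject_id = str(row["subject_id"])
        rec.group_label = str(row["group"])
        yield rec, events, {"subject_id": rec.subject_id,
                            "group": rec.group_label,
                            "n_trials": len(events)}


def simulate_to_dir(config: RunConfig, out_dir: str | Path) -> Path:
    """Materialize the synthetic cohort as EDF + event CSV files."""
    if config.cohort is None:
        raise ValueError("simulate requires a synthetic cohort section")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, events, meta in iter_cohort(config):
        fname = f"{meta['subject_id']}.edf"
        write_edf(rec, events, out / fname)
        rows.append({**meta, "edf_file": fname})
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)
    return out


# ---------------------------------------------------------------------------
# the run itself


def _process_subject(rec: Recording, events: pd.DataFrame, config: RunConfig,
                     plan) -> tuple[dict, dict, int, list[str]]:
    """One subject: preprocess + ERSP on the sensorimotor channels."""
    epoched, bad = preprocess_recording(rec, events, config.preprocess)
    maps = {}
    for ch in SENSORIMOTOR:
        if ch in epoched.channel_labels:
            maps[ch] = ersp_from_epochs(epoched, ch, plan)
    return maps, {"subject_id": epoched.subject_id,
                  "group": epoched.group_label}, epoched.n_valid_trials, bad


def run(config: RunConfig, out_dir: str | Path, plot: bool = False,
        demographics: dict[str, pd.DataFrame] | None = None) -> Path:
    """Execute the full pipeline and write all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "processing.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("swallow_ersp")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    try:
        plan = make_wavelet_plan(
            f_grid_spacing=config.tfr.f_grid_spacing,
            rate=config.preprocess.target_rate,
            f_min=config.tfr.f_min, f_max=config.tfr.f_max,
            c_min=config.tfr.c_min, c_max=config.tfr.c_max,
            n_times=config.tfr.n_times)

        subject_maps: dict[str, dict] = {}
        groups: dict[str, str] = {}
        ero_accum: dict[tuple[str, str, str], list[np.ndarray]] = {}
        ersp_accum: dict[tuple[str, str], list[np.ndarray]] = {}
        n_excluded = 0
        for rec, events, meta in iter_cohort(config):
            try:
                maps, info, n_valid, bad = _process_subject(
                    rec, events, config, plan)
            except ValueError as exc:
                logger.warning("subject %s failed preprocessing: %s",
                               meta["subject_id"], exc)
                n_excluded += 1
                continue
            if n_valid < config.preprocess.min_valid_trials:
                logger.warning("excluding subject %s: %d valid trials < %d",
                               info["subject_id"], n_valid,
                               config.preprocess.min_valid_trials)
                n_excluded += 1
                continue
            sid = info["subject_id"]
            subject_maps[sid] = maps
            groups[sid] = info["group"]
            for ch, m in maps.items():
                ersp_accum.setdefault((info["group"], ch), []).append(m.values)
                for band in config.bands:
                    tr = compute_ero(m, band)
                    ero_accum.setdefault((info["group"], ch, band.name),
                                         []).append(tr.values)
            logger.info("subject %s done (%d valid trials, rejected %s)",
                        sid, n_valid, bad or "none")
        if not subject_maps:
            raise ValueError("no subject survived preprocessing")
        logger.info("cohort: %d analyzed, %d excluded",
                    len(subject_maps), n_excluded)

        eri_df, li_df = build_biomarker_table(
            subject_maps, groups, bands=config.bands, window=config.window,
            epsilon=config.stats.li_epsilon)
        eri_df.to_csv(out / "eri.csv", index=False)
        li_df.to_csv(out / "li.csv", index=False)

        # grand-average exports (ERO traces and ERSP maps per group);
        # epoch-edge cells are masked (NaN) for every subject, so the
        # all-NaN mean warning there is expected noise
        import warnings as _warnings
        any_map = next(iter(next(iter(subject_maps.values())).values()))
        with _warnings.catch_warnings():
            _warnings.filterwarnings("ignore", message="Mean of empty slice")
            ero_rows = []
            for (grp, ch, band), traces in sorted(ero_accum.items()):
                mean = np.nanmean(np.stack(traces), axis=0)
                for t, v in zip(any_map.time_axis_ms, mean):
                    ero_rows.append({"group": grp, "channel": ch, "band": band,
                                     "time_ms": t, "ero_db": v})
            pd.DataFrame(ero_rows).to_csv(out / "ero_grand_average.csv",
                                          index=False)
            for (grp, ch), stack in sorted(ersp_accum.items()):
                mean = np.nanmean(np.stack(stack), axis=0)
                df = pd.DataFrame(mean, index=any_map.time_axis_ms,
                                  columns=any_map.freqs)
                df.index.name = "time_ms"
                df.to_csv(out / f"ersp_grand_average_{grp}_{ch}.csv")

        report = run_group_analysis(
            eri_df, li_df, demographics=demographics,
            bands=tuple(b.name for b in config.bands),
            correction=config.stats.correction)
        report.to_csv(out / "stats_report.csv", index=False)
        (out / "stats_report.md").write_text(summarize_report(report))

        snapshot = config_to_dict(config)
        (out / "config_snapshot.yaml").write_text(
            yaml.safe_dump(snapshot, sort_keys=False))

        if plot:
            _plot_outputs(out, ersp_accum, ero_accum, any_map)
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    return out


def config_to_dict(config: RunConfig) -> dict:
    """JSON/YAML-safe dump of a resolved configuration."""
    doc: dict = {}
    if config.cohort is not None:
        c = config.cohort
        doc["cohort"] = {
            "groups": [{"name": p.name, "n_subjects": n,
                        "alpha_depth": p.alpha_depth, "beta_depth": p.beta_depth,
                        "erd_onset_ms": p.erd_onset_ms,
                        "erd_offset_ms": p.erd_offset_ms,
                        "ramp_ms": p.ramp_ms, "alpha_amp": p.alpha_amp,
                        "beta_amp": p.beta_amp,
                        "background_scale": p.background_scale,
                        "trial_jitter_ms": p.trial_jitter_ms}
                       for p, n in c.groups],
            "n_trials_per_subject": c.n_trials_per_subject,
            "trial_count_sd": c.trial_count_sd,
            "sampling_rate": c.sampling_rate,
            "channel_labels": list(c.channel_labels),
            "epoch_span_ms": list(c.epoch_span_ms),
            "seed": c.seed,
            "subject_depth_sd": c.subject_depth_sd,
            "subject_amp_cv": c.subject_amp_cv,
        }
    if config.data_dir:
        doc["data_dir"] = str(config.data_dir)
    doc["preprocess"] = dataclasses.asdict(config.preprocess)
    doc["tfr"] = dataclasses.asdict(config.tfr)
    doc["bands"] = [dataclasses.asdict(b) for b in config.bands]
    doc["window"] = dataclasses.asdict(config.window)
    doc["stats"] = dataclasses.asdict(config.stats)
    doc["seed"] = config.seed
    return json.loads(json.dumps(doc))  # normalize numpy scalars


def _plot_outputs(out: Path, ersp_accum, ero_accum, template) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grps = sorted({g for g, _ in ersp_accum})
    chans = sorted({c for _, c in ersp_accum})
    fig, axes = plt.subplots(len(grps), len(chans),
                             figsize=(4 * len(chans), 3 * len(grps)),
                             squeeze=False)
    for i, g in enumerate(grps):
        for j, ch in enumerate(chans):
            ax = axes[i][j]
            stack = ersp_accum.get((g, ch))
            if not stack:
                continue
            mean = np.nanmean(np.stack(stack), axis=0)
            im = ax.pcolormesh(template.time_axis_ms, template.freqs,
                               mean.T, shading="auto", cmap="RdBu_r",
                               vmin=-3, vmax=3)
            ax.axhline(13.0, color="k", ls="--", lw=0.5)
            ax.set_title(f"{g} {ch}")
    fig.colorbar(im, ax=axes, label="ERSP (dB)")
    fig.savefig(out / "ersp_grand_average.png", dpi=120)
    plt.close(fig)

    bands = sorted({b for _, _, b in ero_accum})
    chans = sorted({c for _, c, _ in ero_accum})
    fig, axes = plt.subplots(len(bands), len(chans),
                             figsize=(4 * len(chans), 3 * len(bands)),
                             squeeze=False)
    for i, band in enumerate(bands):
        for j, ch in enumerate(chans):
            ax = axes[i][j]
            for g in grps:
                traces = ero_accum.get((g, ch, band))
                if traces:
                    ax.plot(template.time_axis_ms,
                            np.nanmean(np.stack(traces), axis=0), label=g)
            ax.axvline(0, color="k", lw=0.5)
            ax.set_title(f"{ch} {band}")
    axes[0][0].legend(fontsize=8)
    fig.savefig(out / "ero_grand_average.png", dpi=120)
    plt.close(fig)
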