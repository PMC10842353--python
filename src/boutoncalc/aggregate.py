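"""Cohort-level aggregation and the end-to-end pipeline.

Statistics in this workflow are computed on coverslip averages rather than
on pooled synapses (thousands of synapses would otherwise produce falsely
significant results), so the aggregation unit is the coverslip: a group of
ROIs recorded together.  Spontaneous frequencies are aggregated both over
all synapses (silent ROIs enter with frequency 0) and over active synapses
only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import (
    BoutonSimConfig,
    ConfigError,
    DetectionParams,
    StimulusSchedule,
    dump_json,
    load_json,
)
from .bleach import analyze_epoch, summaries_frame
from .simulate import simulate_cohort


def aggregate_coverslips(synapse_table: pd.DataFrame) -> pd.DataFrame:
    """Per-coverslip means of every metric column.

    ``synapse_table`` must carry a ``coverslip`` column; the remaining
    numeric columns are averaged per coverslip.  For ``spont_frequency``
    two variants are emitted: ``spont_frequency_all`` (silent ROIs counted
    at 0) and ``spont_frequency_active`` (active ROIs only).  The fraction
    of silent ROIs is reported per coverslip.
    """
    if "coverslip" not in synapse_table.columns:
        raise ConfigError("synapse table needs a 'coverslip' column")
    df = synapse_table.copy()
    groups = df.groupby("coverslip")
    if (groups.size() < 1).any() or len(groups) == 0:
        raise ConfigError("every coverslip needs at least one ROI")
    num = df.select_dtypes(include=[np.number]).columns
    out = groups[num].mean()
    out["n_roi"] = groups.size()
    if "spont_frequency" in df.columns:
        freq = df["spont_frequency"].fillna(0.0)
        active = freq > 0
        out["spont_frequency_all"] = freq.groupby(df["coverslip"]).mean()
        act = freq[active].groupby(df.loc[active, "coverslip"]).mean()
        out["spont_frequency_active"] = act.reindex(out.index)
        out["silent_fraction"] = (~active).groupby(df["coverslip"]).mean()
        out = out.drop(columns=["spont_frequency"])
    return out


def run_pipeline(
    config: BoutonSimConfig,
    schedule: StimulusSchedule,
    out_dir,
    n_roi: int = 20,
    n_coverslips: int = 1,
    seed: int | None = None,
    silent_fraction: float = 0.0,
    params: DetectionParams | None = None,
) -> dict:
    """simulate -> detect -> summarize -> aggregate, with a run manifest.

    Writes traces, events, per-ROI summaries and coverslip aggregates as
    CSV under ``out_dir``; identical inputs (config + seed) give
    byte-identical outputs.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or DetectionParams()
    seed = config.seed if seed is None else seed
    rate = config.sampling_rate

    all_events = []
    all_summaries = []
    for cs in range(n_coverslips):
        traces, truths = simulate_cohort(
            config, schedule, n_roi, seed=seed + cs,
            silent_fraction=silent_fraction,
        )
        if cs == 0:
            traces.to_csv(out / "traces.csv", index=False, float_format="%.6g")
        stims = list(schedule.stim_times)
        for col in traces.columns:
            if col == "time_s":
                continue
            events, summ = analyze_epoch(
                traces[col].to_numpy(), rate, stims, params, roi_id=col
            )
            for ev in events:
                all_events.append(
                    {
                        "coverslip": cs,
                        "roi_id": col,
                        "onset_s": ev.onset_s,
                        "peak_s": ev.peak_s,
                        "class": ev.klass,
                        "amplitude_df": ev.amplitude_df,
                        "amplitude_dff": ev.amplitude_dff,
                        "rise_s": ev.rise_s,
                        "decay_s": ev.decay_s,
                        "stim_index": ev.stim_index,
                    }
                )
            all_summaries.append((cs, summ))

    events_df = pd.DataFrame(
        all_events,
        columns=[
            "coverslip", "roi_id", "onset_s", "peak_s", "class",
            "amplitude_df", "amplitude_dff", "rise_s", "decay_s", "stim_index",
        ],
    )
    events_df.to_csv(out / "events.csv", index=False, float_format="%.6g")

    summary_df = summaries_frame([s for _, s in all_summaries]).reset_index()
    summary_df.insert(0, "coverslip", [cs for cs, _ in all_summaries])
    summary_df.to_csv(out / "summary.csv", index=False, float_format="%.6g")

    agg = aggregate_coverslips(summary_df)
    agg.to_csv(out / "coverslips.csv", float_format="%.6g")

    manifest = {
        "pipeline_version": __version__,
        "seed": seed,
        "n_roi": n_roi,
        "n_coverslips": n_coverslips,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "schedule": schedule.to_dict(),
        "detection_params": params.to_dict(),
        "outputs": ["traces.csv", "events.csv", "summary.csv", "coverslips.csv"],
    }
    dump_json(manifest, out / "manifest.json")
    return manifest


def load_config_file(path) -> BoutonSimConfig:
    try:
        return BoutonSimConfig.from_dict(load_json(path))
    except FileNotFoundError as exc:
        raise ConfigError(f"[config] file not found: {path}") from exc


def load_schedule_file(path) -> StimulusSchedule:
    try:
        return StimulusSchedule.from_dict(load_json(path))
    except FileNotFoundError as exc:
        raise ConfigError(f"[schedule] file not found: {path}") from exc
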