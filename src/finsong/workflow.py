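"""Pipeline orchestration: simulate -> measure -> analyze -> report.

Stages run in a fixed order with per-stage audit counts (songs and notes
in/out of each filter), and every run emits a manifest recording the
configuration hash, seed, package version, thresholds in force and output
file hashes — identical config and seed give identical manifests for all
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import __version__
from .audio_annotations import (EffortPlan, Recording, selections_from_table,
                                subsample_effort, write_selection_table,
                                write_wav)
from .config import RunConfig
from .ini_pipeline import (Song, build_songs, compute_inis, effort_summary,
                           period_means, summarize_song)
from .note_measures import measure_notes
from .pattern_class import (classify_song, classify_song_year,
                            detect_cooccurrence, detect_transitions)
from .songsynth import deployment_index, make_deployment

log = logging.getLogger("finsong")

__all__ = ["run_pipeline", "measure_deployment", "analyze_measurements",
           "simulate_song_year", "recover_period_mean"]


def measure_deployment(recordings: list[Recording], truth: pd.DataFrame,
                       plan: EffortPlan | None = None) -> pd.DataFrame:
    """Measure every annotated note in every (reviewed) recording."""
    if truth.empty:
        return pd.DataFrame()
    by_rec = dict(tuple(truth.groupby("Begin File")))
    frames = []
    for rec in recordings:
        rows = by_rec.get(rec.id)
        if rows is None or (plan is not None and not plan.covers(rec.start)):
            continue
        sels = selections_from_table(rows)
        frames.append(measure_notes(rec, sels))
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["Begin File", "Center Time (s)"],
                           ignore_index=True)


def analyze_measurements(measurements: pd.DataFrame, cfg: RunConfig) -> dict:
    """Songs, INI series, summaries, period means and pattern labels."""
    ana = cfg.analysis
    songs = build_songs(measurements,
                        min_duration_s=ana.min_song_duration_s,
                        min_mean_snr_db=ana.min_mean_snr_db)
    included = [s for s in songs if s.included]
    series = {s.song_id: compute_inis(s, ana.ini_min_s, ana.ini_max_s)
              for s in songs}
    summaries = {sid: summarize_song(ser) for sid, ser in series.items()}
    labels = []
    for s in included:
        summ = summaries[s.song_id]
        if summ is None:
            continue
        lab = classify_song(summ, threshold_s=ana.short_long_threshold_s)
        labels.append(dict(song_id=s.song_id, month=s.month,
                           song_year=s.song_year, label=lab.label,
                           median_ini=lab.median_ini, variable=lab.variable))
    labels_df = pd.DataFrame(labels)

    year_patterns, cooccur, transitions = {}, [], {}
    if not labels_df.empty:
        for sy, grp in labels_df.groupby("song_year"):
            yp = classify_song_year(grp)
            tr = detect_transitions(grp.rename(columns={"median_ini":
                                                        "median_ini"}))
            yp.transition_months = tr
            for m, mg in grp.groupby("month"):
                flag, counts = detect_cooccurrence(mg)
                if flag:
                    yp.cooccurrence_months.append(int(m))
                    cooccur.append(dict(song_year=int(sy), month=int(m),
                                        **counts))
            year_patterns[int(sy)] = yp
            transitions[int(sy)] = tr

    pmeans = {}
    for period in ("short", "long"):
        for pm in period_means(included, series, period):
            pmeans[(pm.song_year, period)] = pm
    counts_table = effort_summary(songs, series)

    log.info("analysis: %d songs annotated, %d included, %d labeled",
             len(songs), len(included), len(labels_df))
    return dict(songs=songs, series=series, summaries=summaries,
                labels=labels_df, year_patterns=year_patterns,
                cooccurrence=cooccur, period_means=pmeans,
                effort_table=counts_table)


# ---------------------------------------------------------------------------
# parameter-recovery simulations (period-mean validation scenarios)
# ---------------------------------------------------------------------------

#: Per-song-year recovery scenarios: the observed period means drive the
#: generator (via the presets), and the full audio -> measurement -> INI
#: chain must give them back.  Song counts per period match the observed
#: effort; the anomalous year carries its three short-INI intruder songs
#: (one in October, two in November) among the long-INI majority.
_RECOVERY_SCENARIOS: dict[tuple[int, str], dict] = {
    (2, "short"): dict(months=(dt.date(2017, 9, 1), dt.date(2017, 12, 31)),
                       n_songs=16, preset=("SEASONAL", 2)),
    (1, "long"): dict(months=(dt.date(2017, 3, 1), dt.date(2017, 5, 31)),
                      n_songs=13, preset=("SEASONAL", 1)),
    (4, "short"): dict(months=(dt.date(2019, 9, 1), dt.date(2019, 12, 31)),
                       n_songs=39, preset="constant_long_sy4"),
}


def simulate_song_year(song_year: int, period: str, seed: int):
    """Synthesize one song year's period scenario; returns (recs, truth).

    Song days are spread evenly across the period's months; the
    anomalous-year scenario uses the long-INI preset calibrated so the
    pooled true period mean (including its intruder songs) equals the
    observed value.
    """
    from .songsynth import (DeploymentSpec, TABLE3_PRESET_MEANS,
                            constant_long_mean_for_pooled_target)

    sc = _RECOVERY_SCENARIOS[(song_year, period)]
    d0, d1 = sc["months"]
    span = (d1 - d0).days
    step = max(span // sc["n_songs"], 1)
    song_days = tuple(d0 + dt.timedelta(days=i * step)
                      for i in range(sc["n_songs"]))
    intruders: tuple = ()
    if sc["preset"] == "constant_long_sy4":
        target = TABLE3_PRESET_MEANS[4]["short"]
        long_mean = constant_long_mean_for_pooled_target(
            target, sc["n_songs"], 3)
        preset = ("CONSTANT_LONG", long_mean)
        oct_days = [d for d in song_days if d.month == 10]
        nov_days = [d for d in song_days if d.month == 11]
        intruders = (oct_days[0], nov_days[0], nov_days[1])
    else:
        preset = sc["preset"]
    spec = DeploymentSpec(date_range=(d0, d1), song_days=song_days,
                          pattern_preset=preset, intruder_days=intruders,
                          seed=seed)
    return make_deployment(spec, render="song_only")


def recover_period_mean(song_year: int, period: str,
                        seeds: list[int]) -> dict:
    """Full-chain period-mean recovery pooled over seeds.

    For each seed: synthesize the scenario, measure every truth note from
    the waveforms, build songs, apply the inclusion and INI filters, and
    pool the kept period INIs.  Returns mean, s.e.m., and counts.
    """
    from .config import RunConfig

    pool, n_songs = [], 0
    cfg = RunConfig()
    for seed in seeds:
        recs, truth = simulate_song_year(song_year, period, seed)
        measurements = measure_deployment(recs, truth)
        res = analyze_measurements(measurements, cfg)
        pm = res["period_means"].get((song_year, period))
        if pm is None or pm.no_data:
            continue
        for s in res["songs"]:
            if (s.included and s.song_year == song_year
                    and s.month in (cfg.analysis.short_period_months
                                    if period == "short"
                                    else cfg.analysis.long_period_months)):
                pool.append(res["series"][s.song_id].kept)
                n_songs += 1
    inis = np.concatenate(pool)
    return dict(mean=float(inis.mean()),
                sem=float(inis.std(ddof=1) / np.sqrt(inis.size)),
                n_inis=int(inis.size), n_songs=n_songs)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(cfg: RunConfig, out_dir: str, seed: int | None = None) -> dict:
    """Run all stages and write artifacts + manifest under ``out_dir``.

    Returns the manifest dict.  Any stage failure propagates after the
    partial manifest is written.
    """
    os.makedirs(out_dir, exist_ok=True)
    if seed is not None:
        cfg.deployment = dataclasses.replace(cfg.deployment, seed=seed)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.deployment.seed,
        "thresholds": dataclasses.asdict(cfg.analysis),
        "stages": {},
        "started_utc": dt.datetime.now(dt.timezone.utc).isoformat(),
    }
    manifest_path = os.path.join(out_dir, "manifest.json")

    def _save() -> None:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        # stage 1: simulate
        recordings, truth = make_deployment(cfg.deployment, render=cfg.render)
        truth_path = os.path.join(out_dir, "truth_selections.tsv")
        write_selection_table(truth, truth_path)
        if cfg.write_audio:
            wav_dir = os.path.join(out_dir, "audio")
            os.makedirs(wav_dir, exist_ok=True)
            for rec in recordings:
                write_wav(rec, os.path.join(wav_dir, rec.id + ".wav"))
        manifest["stages"]["simulate"] = {
            "n_recordings": len(recordings), "n_truth_notes": len(truth),
            "truth_table": _hash_file(truth_path)}
        _save()

        # stage 2: effort plan (from the full duty-cycle schedule, not just
        # the rendered recordings)
        plan = subsample_effort(deployment_index(cfg.deployment))
        manifest["stages"]["plan_effort"] = {
            "n_days": plan.n_days, "review_hours": plan.review_hours_total}
        _save()

        # stage 3: measure
        measurements = measure_deployment(recordings, truth, plan)
        meas_path = os.path.join(out_dir, "note_measurements.tsv")
        write_selection_table(measurements, meas_path)
        manifest["stages"]["measure"] = {
            "n_notes": len(measurements), "table": _hash_file(meas_path)}
        _save()

        # stage 4: analyze
        results = analyze_measurements(measurements, cfg)
        eff_path = os.path.join(out_dir, "effort_table.tsv")
        results["effort_table"].to_csv(eff_path, sep="\t", index=False)
        pm_rows = [dataclasses.asdict(pm)
                   for pm in results["period_means"].values()]
        pm_path = os.path.join(out_dir, "period_means.tsv")
        pd.DataFrame(pm_rows).to_csv(pm_path, sep="\t", index=False)
        lab_path = os.path.join(out_dir, "song_labels.tsv")
        results["labels"].to_csv(lab_path, sep="\t", index=False)
        patt = {sy: {"pattern": yp.pattern,
                     "cooccurrence_months": yp.cooccurrence_months,
                     "transition_months": yp.transition_months,
                     "short_long_threshold_s":
                         cfg.analysis.short_long_threshold_s}
                for sy, yp in results["year_patterns"].items()}
        with open(os.path.join(out_dir, "year_patterns.json"), "w") as fh:
            json.dump(patt, fh, indent=2)
        manifest["stages"]["analyze"] = {
            "n_songs": len(results["songs"]),
            "n_included": sum(s.included for s in results["songs"]),
            "effort_table": _hash_file(eff_path),
            "period_means": _hash_file(pm_path),
        }
        manifest["finished_utc"] = dt.datetime.now(dt.timezone.utc).isoformat()
        _save()
        return manifest
    except Exception:
        manifest["failed"] = True
        _save()
        raise
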