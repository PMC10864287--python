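"""Structured run configuration.

One YAML file governs every analysis threshold — subsampling scheme,
song-duration and SNR inclusion limits, INI range filter, high-SNR
quantile rule, period month sets, spline basis dimensions — plus the
synthetic-deployment parameters, so nothing is hard-coded in a run.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .songsynth import DeploymentSpec, NoiseSpec

__all__ = ["AnalysisConfig", "RunConfig", "load_config", "default_config"]


@dataclass
class AnalysisConfig:
    """Every filter and threshold of the analysis chain."""

    min_song_duration_s: float = 120.0
    min_mean_snr_db: float = 10.0
    ini_min_s: float = 4.5
    ini_max_s: float = 30.0
    high_snr_quantile: float = 0.75
    min_high_snr_notes_per_day: int = 10
    short_period_months: tuple[int, ...] = (9, 10, 11, 12)
    long_period_months: tuple[int, ...] = (3, 4, 5)
    month_spline_k: int = 12
    spectral_month_spline_k: int = 10
    year_spline_k: int = 5
    short_long_threshold_s: float = 12.5
    # note-recipe defaults are assumptions: note duration and received
    # levels are not reported for this population
    assumed_note_duration_s: float = 0.9
    assumed_singer_levels_db: tuple[float, ...] = (-20.0, -26.0)


@dataclass
class RunConfig:
    deployment: DeploymentSpec = field(default_factory=DeploymentSpec)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    render: str = "song_only"
    write_audio: bool = False

    def config_hash(self) -> str:
        payload = repr(sorted(_flatten(asdict(self)).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = repr(v)
    return out


def default_config(seed: int = 0) -> RunConfig:
    cfg = RunConfig()
    cfg.deployment = DeploymentSpec(seed=seed)
    return cfg


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; missing keys fall back to defaults,
    unknown keys raise a schema error listing them."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"deployment", "analysis", "render", "write_audio", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    dep_kwargs = dict(raw.get("deployment") or {})
    dep_unknown = set(dep_kwargs) - set(DeploymentSpec.__dataclass_fields__)
    if dep_unknown:
        raise ValueError(f"unknown deployment keys: {sorted(dep_unknown)}")
    if "date_range" in dep_kwargs:
        d0, d1 = dep_kwargs["date_range"]
        dep_kwargs["date_range"] = (_to_date(d0), _to_date(d1))
    if "song_days" in dep_kwargs and dep_kwargs["song_days"] is not None:
        dep_kwargs["song_days"] = tuple(_to_date(d)
                                        for d in dep_kwargs["song_days"])
    if "intruder_days" in dep_kwargs:
        dep_kwargs["intruder_days"] = tuple(_to_date(d)
                                            for d in dep_kwargs["intruder_days"])
    if "monthly_song_prob" in dep_kwargs:
        dep_kwargs["monthly_song_prob"] = {
            int(k): float(v) for k, v in dep_kwargs["monthly_song_prob"].items()}
    if "noise" in dep_kwargs:
        dep_kwargs["noise"] = NoiseSpec(**dep_kwargs["noise"])
    if "pattern_preset" in dep_kwargs:
        dep_kwargs["pattern_preset"] = tuple(dep_kwargs["pattern_preset"])
    if "duty_cycle" in dep_kwargs:
        dep_kwargs["duty_cycle"] = tuple(dep_kwargs["duty_cycle"])
    if "singer_levels" in dep_kwargs:
        dep_kwargs["singer_levels"] = tuple(dep_kwargs["singer_levels"])
    if "seed" in raw:
        dep_kwargs.setdefault("seed", int(raw["seed"]))

    ana_kwargs = dict(raw.get("analysis") or {})
    ana_unknown = set(ana_kwargs) - set(AnalysisConfig.__dataclass_fields__)
    if ana_unknown:
        raise ValueError(f"unknown analysis keys: {sorted(ana_unknown)}")
    for key in ("short_period_months", "long_period_months",
                "assumed_singer_levels_db"):
        if key in ana_kwargs:
            ana_kwargs[key] = tuple(ana_kwargs[key])

    return RunConfig(deployment=DeploymentSpec(**dep_kwargs),
                     analysis=AnalysisConfig(**ana_kwargs),
                     render=raw.get("render", "song_only"),
                     write_audio=bool(raw.get("write_audio", False)))


def _to_date(v) -> dt.date:
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v))
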