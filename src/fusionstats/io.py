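"""Tabular readers/writers and the end-to-end pipeline.

All tables are comma-separated text with a mandatory header; angles are in
degrees, lengths in µm, times in minutes. Egg models and result bundles are
JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bias_test import FusionEvent, run_bias_test
from .geometry import AngularBinning, DistanceBinning, EggModel
from .null_model import NullDistribution, build_null_distribution
from .trajectories import (
    Track,
    angle_series,
    angular_velocity_series,
    fit_velocity_models,
    half_sphere_comparison,
    rank_models_aic,
)

__all__ = [
    "RunConfig",
    "read_tracks",
    "write_tracks",
    "read_fusion_events",
    "write_fusion_events",
    "read_egg",
    "write_egg",
    "read_force_cycles",
    "read_intensity_profile",
    "build_velocity_records",
    "run_pipeline",
]

log = logging.getLogger(__name__)

TRACK_COLUMNS = ["egg_id", "object", "time_min", "x_um", "y_um", "z_um"]
EVENT_COLUMNS = ["egg_id", "x_um", "y_um", "z_um", "time_min", "monospermic"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_tracks(path, fusion_times: dict[str, float] | None = None) -> list[Track]:
    """Read tracks grouped by (egg_id, object), time-sorted.

    Rows with non-numeric coordinates or times are dropped with their line
    numbers logged. ``fusion_times`` optionally supplies the sperm-fusion
    time per egg.
    """
    df = pd.read_csv(path)
    _require_columns(df, TRACK_COLUMNS, path)
    numeric = df[["time_min", "x_um", "y_um", "z_um"]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = numeric.isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = (df.index[bad] + 2).tolist()
        log.warning("%s: dropping %d malformed row(s) at line(s) %s", path, bad.sum(), lines)
        df = df[~bad]
        numeric = numeric[~bad]
    df = df.assign(**{c: numeric[c] for c in numeric.columns})
    tracks = []
    for (egg_id, obj), grp in df.groupby(["egg_id", "object"], sort=True):
        grp = grp.sort_values("time_min")
        tracks.append(
            Track(
                object_id=str(obj),
                times=grp["time_min"].to_numpy(),
                positions=grp[["x_um", "y_um", "z_um"]].to_numpy(),
                egg_id=str(egg_id),
                fusion_time=(fusion_times or {}).get(str(egg_id)),
            )
        )
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    rows = []
    for tr in tracks:
        for t, (x, y, z) in zip(tr.times, tr.positions):
            rows.append((tr.egg_id, tr.object_id, t, x, y, z))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_fusion_events(path) -> list[FusionEvent]:
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS[:4], path)
    events = []
    for _, row in df.iterrows():
        mono = row.get("monospermic")
        events.append(
            FusionEvent(
                egg_id=str(row["egg_id"]),
                position=np.array([row["x_um"], row["y_um"], row["z_um"]]),
                time_min=float(row["time_min"]) if "time_min" in df.columns else None,
                monospermic=bool(mono) if mono is not None and not pd.isna(mono) else None,
            )
        )
    return events


def write_fusion_events(events: list[FusionEvent], path) -> None:
    rows = [
        (
            e.egg_id,
            e.position[0],
            e.position[1],
            e.position[2],
            e.time_min,
            e.monospermic,
        )
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_egg(path) -> EggModel | dict[str, EggModel]:
    """Read one egg model, or a mapping egg_id -> model, from JSON."""
    with open(path) as fh:
        d = json.load(fh)
    if "radius_um" in d:
        return EggModel.from_dict(d)
    return {k: EggModel.from_dict(v) for k, v in d.items()}


def write_egg(egg: EggModel | dict[str, EggModel], path) -> None:
    if isinstance(egg, dict):
        payload = {k: v.to_dict() for k, v in egg.items()}
    else:
        payload = egg.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_force_cycles(path):
    """Force-deformation cycle table: columns deflection_um, deformation_um
    and optionally needle_stiffness_nn_per_um, cardinal_point_deg."""
    from .mechanics import DEFAULT_NEEDLE_STIFFNESS, ForceDeformationSeries

    df = pd.read_csv(path)
    _require_columns(df, ["deflection_um", "deformation_um"], path)
    kf = (
        float(df["needle_stiffness_nn_per_um"].iloc[0])
        if "needle_stiffness_nn_per_um" in df.columns
        else DEFAULT_NEEDLE_STIFFNESS
    )
    point = (
        int(df["cardinal_point_deg"].iloc[0])
        if "cardinal_point_deg" in df.columns
        else 0
    )
    return ForceDeformationSeries(
        deflections=df["deflection_um"].to_numpy(),
        deformations=df["deformation_um"].to_numpy(),
        needle_stiffness=kf,
        cardinal_point_deg=point,
    )


def read_intensity_profile(path):
    """Circumferential scan table: columns angle_deg, intensity."""
    from .mechanics import IntensityProfile

    df = pd.read_csv(path)
    _require_columns(df, ["angle_deg", "intensity"], path)
    return IntensityProfile(
        angles_deg=df["angle_deg"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
    )


def build_velocity_records(
    tracks: list[Track], eggs: EggModel | dict[str, EggModel], lag_frames: int = 2
) -> pd.DataFrame:
    """Pair paternal/maternal tracks per egg and assemble the pooled
    angular-displacement records for the regression."""
    by_egg: dict[str, dict[str, Track]] = {}
    for tr in tracks:
        by_egg.setdefault(tr.egg_id, {})[tr.object_id] = tr
    frames = []
    for egg_id, objs in sorted(by_egg.items()):
        if "paternal" not in objs or "maternal" not in objs:
            log.warning("egg %s lacks a paternal/maternal pair; skipped", egg_id)
            continue
        egg = eggs[egg_id] if isinstance(eggs, dict) else eggs
        pat = objs["paternal"]
        series = angle_series(pat, objs["maternal"], egg)
        fusion = pat.fusion_time if pat.fusion_time is not None else series["time_min"].iloc[0]
        frames.append(
            angular_velocity_series(series, fusion_time=fusion, lag_frames=lag_frames, egg_id=egg_id)
        )
    if not frames:
        raise ValueError("no egg had both a paternal and a maternal track")
    return pd.concat(frames, ignore_index=True)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    events_path: str | None = None
    tracks_path: str | None = None
    egg_path: str | None = None
    out_dir: str = "results"
    n_null: int = 40_000
    seed: int = 0
    alpha: float = 0.05
    lag_frames: int = 2
    angle_bin_deg: float = 30.0
    distance_bin_um: float = 10.0
    monospermic_only: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def run_pipeline(
    cfg: RunConfig,
    events=None,
    tracks=None,
    eggs=None,
) -> dict:
    """Run the two headline analyses end to end.

    Inputs can be passed in memory or read from the configured paths:
    (1) fusion-site bias — simulate the uniform null, bin observed events,
    Fisher per bin, Holm across bins, area-corrected rates; (2) trajectory
    model selection — pooled angular-velocity records, four OLS fits, AIC
    ranking, spindle-half Welch comparison. Writes JSON plus a short text
    summary under ``cfg.out_dir`` and returns the bundle as a dict.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if eggs is None:
        if cfg.egg_path is None:
            raise ValueError("pipeline stage 'inputs': no egg model given")
        eggs = read_egg(cfg.egg_path)
    if events is None and cfg.events_path:
        events = read_fusion_events(cfg.events_path)
    if tracks is None and cfg.tracks_path:
        tracks = read_tracks(cfg.tracks_path)
    if events is not None and len(events) == 0:
        raise ValueError("pipeline stage 'bias test': no fusion events supplied")
    if tracks is not None and len(tracks) == 0:
        raise ValueError("pipeline stage 'trajectories': no tracks supplied")

    any_egg = next(iter(eggs.values())) if isinstance(eggs, dict) else eggs
    abins = AngularBinning(np.arange(0.0, 180.0 + 1e-9, cfg.angle_bin_deg))
    bundle: dict = {"seed": cfg.seed, "n_null": cfg.n_null, "alpha": cfg.alpha}
    log.info("null simulation: n=%d seed=%d", cfg.n_null, cfg.seed)
    null = build_null_distribution(any_egg, n=cfg.n_null, angle_binning=abins, seed=cfg.seed)
    bundle["null"] = null.to_dict()

    if events:
        result = run_bias_test(
            events, eggs, null, binning=abins, alpha=cfg.alpha,
            monospermic_only=cfg.monospermic_only,
        )
        bundle["bias_test"] = result.to_dict()

    if tracks:
        records = build_velocity_records(tracks, eggs, lag_frames=cfg.lag_frames)
        fits = fit_velocity_models(records)
        ranking = rank_models_aic(fits)
        bundle["model_fits"] = {
            m: {
                "coefficients": f.coefficients,
                "rss": f.rss,
                "loglik": f.loglik,
                "k": f.k,
                "aic": f.aic,
                "n": f.n,
                "valid": f.valid,
            }
            for m, f in fits.items()
        }
        bundle["aic_ranking"] = ranking.to_dict(orient="records")
        bundle["aic_convention"] = (
            "AIC = 2k - 2*loglik, full Gaussian log-likelihood, "
            "k counts the error variance"
        )
        try:
            welch = half_sphere_comparison(records)
            bundle["half_sphere_welch"] = welch.__dict__
        except ValueError as exc:
            log.warning("half-sphere comparison skipped: %s", exc)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=1, default=float)
    _write_summary(bundle, out_dir / "summary.txt")
    return bundle


def _write_summary(bundle: dict, path) -> None:
    lines = [
        f"fusionstats pipeline report (seed {bundle['seed']}, "
        f"null n={bundle['n_null']}, alpha={bundle['alpha']})",
    ]
    if "bias_test" in bundle:
        bt = bundle["bias_test"]
        lines.append("\nFusion-site bias test (Fisher per bin vs simulated null, Holm):")
        for i, label in enumerate(bt["bins"]):
            star = " *" if bt["significant"][i] else ""
            lines.append(
                f"  {label:>9} deg: obs={bt['observed'][i]:3d}  "
                f"null_p={bt['null_prob'][i]:.4f}  holm_p={bt['holm_p'][i]:.3g}{star}"
            )
    if "aic_ranking" in bundle:
        lines.append("\nAngular-velocity model selection (ascending AIC):")
        for row in bundle["aic_ranking"]:
            lines.append(
                f"  {row['model']:>12}: AIC={row['aic']:.1f}  dAIC={row['delta_aic']:.1f}"
            )
    if "half_sphere_welch" in bundle:
        w = bundle["half_sphere_welch"]
        lines.append(
            f"\nSpindle half vs opposite half (Welch): t={w['t_statistic']:.2f}, "
            f"p={w['p_value']:.3g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
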