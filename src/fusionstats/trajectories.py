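"""Paternal-chromosome trajectory statistics.

From tracked 3D positions of paternal and maternal chromosomes the module
computes the axis-angle time series θ(t), the signed angular velocity ω
toward the maternal chromosomes over a two-frame lag, displacement and
pairwise-distance series, and fits four nested linear models of ω on the
angle θ and the time t since sperm fusion:

    angle_only    ω = β0 + β1·θ
    time_only     ω = β0 + β2·t
    additive      ω = β0 + β1·θ + β2·t
    interaction   ω = β0 + β1·θ + β2·t + β3·θ·t

Models are compared by AIC; a Welch two-sample t test compares ω between
the spindle half (θ < 90°) and the opposite half of the zygote within a
time window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .geometry import EggModel

__all__ = [
    "Track",
    "RegressionModelFit",
    "WelchResult",
    "MODEL_TERMS",
    "angle_series",
    "angular_velocity_series",
    "normalize_track",
    "displacement_series",
    "pairwise_distance_series",
    "fit_velocity_models",
    "rank_models_aic",
    "half_sphere_comparison",
]

log = logging.getLogger(__name__)

#: regressor columns per model (an intercept is always included)
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "angle_only": ("theta",),
    "time_only": ("t",),
    "additive": ("theta", "t"),
    "interaction": ("theta", "t", "theta_t"),
}

#: floor on the residual sum of squares before taking its log
_RSS_FLOOR = 1e-12


@dataclass(frozen=True)
class Track:
    """Time-ordered 3D positions of one tracked object.

    Times in minutes, positions in µm; ``object_id`` is typically one of
    paternal / maternal / sperm_tail / spindle.
    """

    object_id: str
    times: np.ndarray
    positions: np.ndarray
    egg_id: str = ""
    frame_interval: float | None = None
    fusion_time: float | None = None
    anaphase_onset_time: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.positions, dtype=float)
        if x.ndim != 2 or x.shape[1] != 3 or len(t) != len(x):
            raise ValueError("positions must be (n, 3) matching times")
        if np.any(np.diff(t) <= 0):
            raise ValueError("track times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", x)

    def __len__(self) -> int:
        return len(self.times)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("zero-length vector: position coincides with egg center")
    c = np.clip(np.sum(u * v, axis=-1) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def angle_series(
    paternal: Track, maternal: Track, egg: EggModel, time_tol: float = 1e-6
) -> pd.DataFrame:
    """Per-frame angle θ at the egg center between paternal and maternal
    chromosome positions.

    The maternal position at the same frame is used (the maternal spindle
    moves); if the maternal track ends earlier, its last observed position
    is carried forward with a warning.

    Returns a DataFrame with columns ``time_min`` and ``theta_deg``.
    """
    t0 = max(paternal.times[0], maternal.times[0])
    if paternal.times[-1] < maternal.times[0] or maternal.times[-1] < paternal.times[0]:
        raise ValueError("paternal and maternal tracks do not overlap in time")
    times, thetas = [], []
    carried = False
    for t, p in zip(paternal.times, paternal.positions):
        if t < t0 - time_tol:
            continue
        j = np.searchsorted(maternal.times, t + time_tol) - 1
        if j < 0:
            continue
        if t - maternal.times[j] > time_tol and j == len(maternal) - 1:
            carried = True
        m = maternal.positions[j]
        thetas.append(_angle_deg(p - egg.center, m - egg.center))
        times.append(t)
    if carried:
        log.warning(
            "maternal track ends before paternal; last maternal position carried forward"
        )
    return pd.DataFrame({"time_min": times, "theta_deg": thetas})


def angular_velocity_series(
    series: pd.DataFrame,
    fusion_time: float,
    lag_frames: int = 2,
    egg_id: str = "",
) -> pd.DataFrame:
    """Signed angular velocity of the paternal chromosomes toward the
    maternal chromosomes.

    For frames n and n+lag, ω_n = (θ_n − θ_{n+lag}) / (t_{n+lag} − t_n), so
    a positive ω means the paternal chromosomes are approaching. Dividing
    by the actual elapsed time unifies recordings taken at different frame
    intervals (2.5 or 3 min). The record's time is the window start minus
    ``fusion_time``.

    Returns a DataFrame with columns egg_id, theta (deg), t (min since
    fusion), omega (deg/min).
    """
    if fusion_time is None:
        raise ValueError("fusion_time is required to reference t")
    t = series["time_min"].to_numpy()
    th = series["theta_deg"].to_numpy()
    if len(t) < lag_frames + 1:
        raise ValueError(f"need at least {lag_frames + 1} samples")
    dt = t[lag_frames:] - t[:-lag_frames]
    omega = (th[:-lag_frames] - th[lag_frames:]) / dt
    return pd.DataFrame(
        {
            "egg_id": egg_id,
            "theta": th[:-lag_frames],
            "t": t[:-lag_frames] - fusion_time,
            "omega": omega,
        }
    )


def normalize_track(track: Track, fusion_site: np.ndarray, egg: EggModel) -> Track:
    """Express positions relative to the egg center, scaled so the fusion
    site sits at radius 1."""
    scale = np.linalg.norm(np.asarray(fusion_site, dtype=float) - egg.center)
    if scale == 0:
        raise ValueError("fusion site coincides with the egg center")
    return Track(
        object_id=track.object_id,
        times=track.times,
        positions=(track.positions - egg.center) / scale,
        egg_id=track.egg_id,
        frame_interval=track.frame_interval,
        fusion_time=track.fusion_time,
        anaphase_onset_time=track.anaphase_onset_time,
    )


def displacement_series(track: Track, origin: np.ndarray) -> pd.DataFrame:
    """Euclidean distance from ``origin`` per frame, plus its maximum in
    the ``max`` attribute of the returned frame."""
    d = np.linalg.norm(track.positions - np.asarray(origin, dtype=float), axis=1)
    out = pd.DataFrame({"time_min": track.times, "displacement_um": d})
    out.attrs["max_displacement_um"] = float(d.max())
    return out


def pairwise_distance_series(
    a: Track, b: Track, proximity_um: float = 30.0, time_tol: float = 1e-6
) -> pd.DataFrame:
    """Per-frame Euclidean distance between two tracks on their common
    frames; flags the first entry, if any, into the proximity region
    (default the 30-µm region surrounding the maternal chromosomes)."""
    common, ia, ib = np.intersect1d(
        np.round(a.times / time_tol).astype(np.int64),
        np.round(b.times / time_tol).astype(np.int64),
        return_indices=True,
    )
    if len(common) == 0:
        raise ValueError("tracks share no frames")
    d = np.linalg.norm(a.positions[ia] - b.positions[ib], axis=1)
    out = pd.DataFrame({"time_min": a.times[ia], "distance_um": d})
    inside = np.flatnonzero(d < proximity_um)
    out.attrs["first_proximity_entry_min"] = (
        float(a.times[ia][inside[0]]) if inside.size else None
    )
    return out


@dataclass(frozen=True)
class RegressionModelFit:
    """One OLS fit of ω on a subset of {θ, t, θ·t} with intercept.

    AIC = 2k − 2·loglik with the full Gaussian log-likelihood and k
    counting the error variance in addition to the regression coefficients.
    """

    model_id: str
    coefficients: dict[str, float]
    stderr: dict[str, float]
    n: int
    rss: float
    loglik: float
    k: int
    aic: float
    valid: bool = True

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t-based confidence interval for one coefficient."""
        df = self.n - (self.k - 1)
        half = stats.t.ppf(0.5 + level / 2, df) * self.stderr[term]
        b = self.coefficients[term]
        return (b - half, b + half)


def _design(records: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame(index=records.index)
    for term in terms:
        if term == "theta_t":
            X[term] = records["theta"] * records["t"]
        else:
            X[term] = records[term]
    return sm.add_constant(X, has_constant="add")


def fit_velocity_models(records: pd.DataFrame) -> dict[str, RegressionModelFit]:
    """Fit the four nested linear models of ω and compute each AIC.

    ``records`` needs columns theta, t, omega. Rank-deficient designs
    (e.g. constant θ in an angle model) are returned with ``valid=False``
    and excluded from ranking.
    """
    required = {"theta", "t", "omega"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    n = len(records)
    if n < 6:
        raise ValueError("need at least 6 records to fit the models")
    y = records["omega"].to_numpy()
    fits: dict[str, RegressionModelFit] = {}
    for model_id, terms in MODEL_TERMS.items():
        X = _design(records, terms)
        rank = np.linalg.matrix_rank(X.to_numpy())
        p = X.shape[1]
        if rank < p:
            fits[model_id] = RegressionModelFit(
                model_id=model_id,
                coefficients={c: float("nan") for c in X.columns},
                stderr={c: float("nan") for c in X.columns},
                n=n,
                rss=float("nan"),
                loglik=float("nan"),
                k=p + 1,
                aic=float("nan"),
                valid=False,
            )
            continue
        res = sm.OLS(y, X).fit()
        rss = max(float(res.ssr), _RSS_FLOOR)
        sigma2 = rss / n
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        k = p + 1  # coefficients + error variance
        fits[model_id] = RegressionModelFit(
            model_id=model_id,
            coefficients={c: float(v) for c, v in res.params.items()},
            stderr={c: float(v) for c, v in res.bse.items()},
            n=n,
            rss=rss,
            loglik=loglik,
            k=k,
            aic=2 * k - 2 * loglik,
        )
    return fits


def rank_models_aic(fits: dict[str, RegressionModelFit]) -> pd.DataFrame:
    """Ascending-AIC ranking with ΔAIC to the best model.

    Ties break toward fewer parameters, then lexicographic model id.
    Invalid (rank-deficient) fits are excluded.
    """
    valid = [f for f in fits.values() if f.valid]
    if len(valid) < 2:
        raise ValueError("need at least two valid fits to rank")
    ordered = sorted(valid, key=lambda f: (f.aic, f.k, f.model_id))
    best = ordered[0].aic
    return pd.DataFrame(
        {
            "model": [f.model_id for f in ordered],
            "aic": [f.aic for f in ordered],
            "delta_aic": [f.aic - best for f in ordered],
            "k": [f.k for f in ordered],
            "rss": [f.rss for f in ordered],
        }
    )


@dataclass(frozen=True)
class WelchResult:
    mean_spindle: float
    mean_opposite: float
    n_spindle: int
    n_opposite: int
    t_statistic: float
    df: float
    p_value: float


def half_sphere_comparison(
    records: pd.DataFrame,
    window: tuple[float, float] | None = None,
    time_column: str = "t",
) -> WelchResult:
    """Welch's two-sample t test of ω between the spindle half and the
    opposite half of the zygote.

    Records with θ < 90° belong to the spindle half; θ = 90° exactly is
    assigned to the opposite half. ``window`` restricts to records whose
    ``time_column`` value lies in [lo, hi).
    """
    df = records
    if window is not None:
        lo, hi = window
        df = df[(df[time_column] >= lo) & (df[time_column] < hi)]
    spindle = df.loc[df["theta"] < 90.0, "omega"].to_numpy()
    opposite = df.loc[df["theta"] >= 90.0, "omega"].to_numpy()
    if len(spindle) < 2 or len(opposite) < 2:
        raise ValueError("each hemisphere needs at least 2 records")
    res = stats.ttest_ind(spindle, opposite, equal_var=False)
    return WelchResult(
        mean_spindle=float(spindle.mean()),
        mean_opposite=float(opposite.mean()),
        n_spindle=len(spindle),
        n_opposite=len(opposite),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )
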