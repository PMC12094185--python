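"""Single-particle tracking and MSD-based motion classification.

Spot detections are linked frame to frame (maximum linking distance 5 µm,
gap closing over up to two missing frames within 5 µm, matching the
acquisition analysis settings for satellite tracking at 0.2 frames/s).
Per-track statistics follow the standard single-particle repertoire:
instantaneous speeds, time-averaged MSD, and a weighted linear MSD fit whose
slope estimates the diffusion coefficient (slope = 4D in 2D). Tracks are
classified into normal / subdiffusive / confined / directed motion with a
transparent feature-threshold rule on the anomalous exponent α, a
confinement ratio, and window straightness, evaluated over sliding windows
of 10 positions on tracks of at least 11 frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from satquant.core import InsufficientDataError, InvalidParameterError

MOTION_CLASSES = ("normal", "subdiffusive", "confined", "directed")

#: Frozen feature thresholds of the motion classifier (tuned once on
#: held-out synthetic tracks and fixed thereafter).
DEFAULT_THRESHOLDS = {
    "alpha_sub": 0.65,
    "alpha_dir": 1.4,
    "confinement": 0.3,
    "straightness": 0.6,
}


@dataclass
class Trajectory:
    """Ordered (frame, position) samples of one particle.

    Frames are strictly increasing but may contain gaps bridged at linking
    time; positions are (x, y) in µm; ``dt_s`` is the frame interval
    (default 5 s, i.e. 0.2 frames/s).
    """

    track_id: int
    frames: np.ndarray
    positions_um: np.ndarray
    dt_s: float = 5.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if len(self.frames) != len(self.positions_um):
            raise InvalidParameterError("frames and positions length mismatch")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise InvalidParameterError("frames must be strictly increasing")
        if self.dt_s <= 0:
            raise InvalidParameterError("dt_s must be > 0")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class MSDCurve:
    """Time-averaged MSD per lag, with the pair count entering each lag."""

    lag_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray


@dataclass
class MotionClassification:
    track_id: int
    final_class: str
    window_classes: list[str]
    features: dict


def link(
    spots: pd.DataFrame,
    max_link_um: float = 5.0,
    max_gap_frames: int = 2,
    max_gap_um: float = 5.0,
    dt_s: float = 5.0,
) -> list[Trajectory]:
    """Link per-frame spot detections into trajectories.

    Greedy mutual-nearest assignment per frame: among all (open track, new
    spot) pairs within the distance gate, the globally closest pair is
    linked first, then the next, and so on. Tracks silent for up to
    ``max_gap_frames`` frames may be resumed if the bridging displacement is
    at most ``max_gap_um``; frame-adjacent links are gated at
    ``max_link_um``. Unmatched spots start new tracks, so every spot belongs
    to exactly one track.

    ``spots`` uses the tracker-export dialect (``FRAME``, ``POSITION_X``,
    ``POSITION_Y`` in µm).
    """
    df = spots.sort_values("FRAME", kind="stable")
    frames = df["FRAME"].to_numpy(int)
    xy = df[["POSITION_X", "POSITION_Y"]].to_numpy(float)

    next_id = 0
    open_tracks: list[dict] = []  # {'id', 'frames': [...], 'pos': [...]}
    done: list[dict] = []

    for f in np.unique(frames):
        pts = xy[frames == f]
        # retire tracks whose gap can no longer be closed
        still_open = []
        for tr in open_tracks:
            if f - tr["frames"][-1] > max_gap_frames + 1:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        n_t, n_s = len(open_tracks), len(pts)
        assigned_spot = np.zeros(n_s, dtype=bool)
        if n_t and n_s:
            last = np.array([tr["pos"][-1] for tr in open_tracks])
            gaps = np.array([f - tr["frames"][-1] for tr in open_tracks])
            dist = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
            gate = np.where(gaps == 1, max_link_um, max_gap_um)
            dist[dist > gate[:, None]] = np.inf
            assigned_track = np.zeros(n_t, dtype=bool)
            order = np.argsort(dist, axis=None)
            for flat in order:
                i, j = divmod(int(flat), n_s)
                if not np.isfinite(dist[i, j]):
                    break
                if assigned_track[i] or assigned_spot[j]:
                    continue
                assigned_track[i] = True
                assigned_spot[j] = True
                open_tracks[i]["frames"].append(int(f))
                open_tracks[i]["pos"].append(pts[j])
        for j in np.where(~assigned_spot)[0]:
            open_tracks.append({"id": next_id, "frames": [int(f)],
                                "pos": [pts[j]]})
            next_id += 1

    done.extend(open_tracks)
    done.sort(key=lambda tr: tr["id"])
    return [Trajectory(tr["id"], np.array(tr["frames"]),
                       np.array(tr["pos"]), dt_s=dt_s) for tr in done]


def instantaneous_speeds(traj: Trajectory) -> np.ndarray:
    """Euclidean displacement per consecutive sample over its elapsed time."""
    if len(traj) < 2:
        return np.empty(0)
    disp = np.linalg.norm(np.diff(traj.positions_um, axis=0), axis=1)
    dt = np.diff(traj.frames) * traj.dt_s
    return disp / dt


def _msd_on_positions(positions, frames, max_lag, dt_s):
    """Time-averaged MSD over all ordered pairs exactly ℓ frames apart."""
    lags = np.arange(max_lag + 1)
    msd = np.zeros(max_lag + 1)
    n_pairs = np.zeros(max_lag + 1, dtype=int)
    n_pairs[0] = len(positions)
    frame_index = {int(f): i for i, f in enumerate(frames)}
    for ell in range(1, max_lag + 1):
        sq = []
        for f, i in frame_index.items():
            j = frame_index.get(f + ell)
            if j is not None:
                sq.append(np.sum((positions[j] - positions[i]) ** 2))
        if sq:
            msd[ell] = float(np.mean(sq))
            n_pairs[ell] = len(sq)
    return MSDCurve(lags * dt_s, msd, n_pairs)


def compute_msd(traj: Trajectory, max_lag_fraction: float = 0.5) -> MSDCurve:
    """Time-averaged MSD of one track up to a fraction of its length."""
    if len(traj) < 3:
        raise InsufficientDataError("MSD needs a track of length >= 3")
    span = int(traj.frames[-1] - traj.frames[0])
    max_lag = max(1, int(np.floor(max_lag_fraction * span)))
    return _msd_on_positions(traj.positions_um, traj.frames, max_lag, traj.dt_s)


@dataclass
class DiffusionFit:
    """Weighted linear MSD fit: MSD(τ) = intercept + 4·D·τ (2D)."""

    D_um2_s: float
    intercept_um2: float
    r_squared: float


def ensemble_weighted_msd(
    trajs: list[Trajectory],
    min_len_frames: int = 11,
    max_lag_fraction: float = 0.5,
) -> tuple[MSDCurve, DiffusionFit]:
    """Pair-count-weighted ensemble MSD and its linear diffusion fit.

    Per lag, individual-track MSD values are averaged weighted by their pair
    counts (equivalent to pooling all displacement pairs); the weighted
    least-squares line through the positive lags gives D = slope / 4.
    """
    eligible = [t for t in trajs if len(t) >= min_len_frames]
    if len(eligible) < 2:
        raise InsufficientDataError("need >= 2 tracks of sufficient length")
    curves = [compute_msd(t, max_lag_fraction) for t in eligible]
    dt = eligible[0].dt_s
    max_lag = max(len(c.lag_s) - 1 for c in curves)
    w_sum = np.zeros(max_lag + 1)
    m_sum = np.zeros(max_lag + 1)
    for c in curves:
        k = len(c.lag_s)
        w_sum[:k] += c.n_pairs
        m_sum[:k] += c.n_pairs * c.msd_um2
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = np.where(w_sum > 0, m_sum / np.maximum(w_sum, 1), 0.0)
    curve = MSDCurve(np.arange(max_lag + 1) * dt, msd, w_sum.astype(int))

    lag = curve.lag_s[1:]
    y = curve.msd_um2[1:]
    w = w_sum[1:]
    ok = w > 0
    W = np.diag(w[ok])
    A = np.column_stack([np.ones(ok.sum()), lag[ok]])
    beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ y[ok])
    resid = y[ok] - A @ beta
    ss_res = float(resid @ (w[ok] * resid))
    ybar = float(np.average(y[ok], weights=w[ok]))
    ss_tot = float((y[ok] - ybar) @ (w[ok] * (y[ok] - ybar)))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return curve, DiffusionFit(D_um2_s=float(beta[1] / 4),
                               intercept_um2=float(beta[0]), r_squared=r2)


def fit_alpha(curve: MSDCurve, max_lag: int | None = None) -> float:
    """Anomalous exponent: slope of log MSD against log lag."""
    msd = curve.msd_um2[1:max_lag + 1 if max_lag else None]
    lag = curve.lag_s[1:max_lag + 1 if max_lag else None]
    ok = msd > 0
    if ok.sum() < 2:
        return 0.0
    slope, _ = np.polyfit(np.log(lag[ok]), np.log(msd[ok]), 1)
    return float(slope)


def _window_features(positions, dt_s, alpha_lags):
    """α, confinement ratio, and straightness of one window.

    α is the log–log MSD slope over lags ``1..alpha_lags``. The confinement
    ratio compares the MSD at the full window span with the linear
    (free-diffusion) extrapolation ``4·D̂·τ_max``, where D̂ is the
    through-origin slope over the first two lags; free diffusion gives ≈ 1,
    a plateau pushes it toward 0.
    """
    frames = np.arange(len(positions))
    span = len(positions) - 1
    curve = _msd_on_positions(positions, frames, span, dt_s)
    alpha = fit_alpha(curve, max_lag=alpha_lags)
    # short-lag through-origin slope as the local diffusion estimate
    tau = curve.lag_s[1:3]
    m = curve.msd_um2[1:3]
    s = float(np.dot(tau, m) / np.dot(tau, tau))
    conf_ratio = curve.msd_um2[span] / (s * curve.lag_s[span]) if s > 0 else 0.0
    path = np.sum(np.linalg.norm(np.diff(positions, axis=0), axis=1))
    net = np.linalg.norm(positions[-1] - positions[0])
    straightness = float(net / path) if path > 0 else 0.0
    return alpha, conf_ratio, straightness


def _rule(alpha, ratio, straightness, thr) -> str:
    """The four-way feature-threshold decision."""
    if ratio < thr["confinement"] and alpha < thr["alpha_sub"]:
        return "confined"
    if alpha < thr["alpha_sub"]:
        return "subdiffusive"
    if alpha > thr["alpha_dir"] and straightness > thr["straightness"]:
        return "directed"
    return "normal"


def classify_track(
    traj: Trajectory,
    min_len_frames: int = 11,
    window: int = 10,
    thresholds: dict | None = None,
) -> MotionClassification:
    """Four-way motion classification by sliding-window feature thresholds.

    Each window of ``window`` positions yields the anomalous exponent α
    (log–log MSD slope over lags 1..window//2), a confinement ratio (MSD at
    the full window span relative to the short-lag linear extrapolation
    ``4·D̂·τ_max``), and the straightness (net displacement / path length).
    Decision rule: confined if ratio < ``confinement`` and α < ``alpha_sub``;
    else subdiffusive if α < ``alpha_sub``; else directed if
    α > ``alpha_dir`` and straightness > ``straightness``; else normal.

    Per-window classes are reported for inspection, but the final class
    applies the rule to the across-window *mean* features: window-level
    feature estimates from 10 positions are noisy, and averaging them before
    thresholding is markedly more accurate than majority-voting the window
    labels on tracks whose motion type does not switch.
    """
    if len(traj) < min_len_frames:
        raise InsufficientDataError(
            f"track shorter than the {min_len_frames}-frame minimum")
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    pos = traj.positions_um
    n_lags = window // 2
    window_classes = []
    feats = []
    for start in range(0, len(pos) - window + 1):
        seg = pos[start:start + window]
        alpha, ratio, straight = _window_features(seg, traj.dt_s, n_lags)
        feats.append((alpha, ratio, straight))
        window_classes.append(_rule(alpha, ratio, straight, thr))

    mean_alpha, mean_ratio, mean_straight = np.mean(np.asarray(feats), axis=0)
    final = _rule(mean_alpha, mean_ratio, mean_straight, thr)
    return MotionClassification(
        track_id=traj.track_id,
        final_class=final,
        window_classes=window_classes,
        features={
            "alpha": float(mean_alpha),
            "confinement_ratio": float(mean_ratio),
            "straightness": float(mean_straight),
        },
    )


def summarize_fractions(per_cell_classes: dict) -> pd.DataFrame:
    """Across-cell mean ± SEM of per-cell motion-class fractions.

    ``per_cell_classes`` maps a cell label to the list of final classes of
    its tracks. Per-cell fractions sum to 1 over the four classes.
    """
    cells = {k: v for k, v in per_cell_classes.items() if len(v)}
    if not cells:
        raise InsufficientDataError("no classified tracks")
    frac = pd.DataFrame(
        {cell: [classes.count(c) / len(classes) for c in MOTION_CLASSES]
         for cell, classes in cells.items()},
        index=MOTION_CLASSES,
    ).T
    n = len(frac)
    sem = frac.std(ddof=1) / np.sqrt(n) if n > 1 else pd.Series(np.nan, frac.columns)
    return pd.DataFrame({
        "mean_fraction": frac.mean(),
        "sem": sem,
        "n_cells": n,
    })


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    """Export linked tracks in the tracker CSV dialect."""
    rows = []
    for t in trajs:
        for f, (x, y) in zip(t.frames, t.positions_um):
            rows.append((t.track_id, f, x, y))
    return pd.DataFrame(rows, columns=["TRACK_ID", "FRAME",
                                       "POSITION_X", "POSITION_Y"])
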