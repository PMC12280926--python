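"""Posture and fin-motion metrics from 3-D landmark trajectories.

Coordinate convention: x runs anterior-posterior, y lateral (left fins at
negative y), z vertical (up positive).  Fifteen named landmarks are
tracked per frame: snout tip, eye, bottom of the eye, dorsal-fin tip,
left/right pectoral base and tip, left/right pelvic base and tip, anal-fin
tip, caudal peduncle and caudal-fin tip.

Metrics
-------
roll(t)
    Angle of the eye -> bottom-of-eye segment projected on the transverse
    (y-z) plane, measured from the vertical.  Zero when the eye axis is
    plumb.
pitch(t)
    Elevation angle of the snout -> caudal-peduncle segment relative to
    its time-mean direction (the fish's own reference posture).
body angle(t)
    Signed angle between the eye -> peduncle line and the horizontal
    plane; head-up positive.
curvature
    Menger curvature of the snout / peduncle / caudal-fin-tip triplet:
    4 * triangle area / product of side lengths, the curvature of the
    circumscribed circle and a three-point discretisation of dT/ds.
phase lag
    Left-right pectoral synchrony from the normalised cross-correlation
    of the two abduction signals, converted to degrees via the dominant
    oscillation period and folded into [0, 180].
fin distance
    Path length travelled by a fin tip per second, in body lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LANDMARKS",
    "LandmarkSeries",
    "KinematicsSummary",
    "roll_pitch",
    "body_angle",
    "curvature",
    "phase_lag",
    "fin_distance",
    "extract_cycles",
    "dominant_period",
    "abduction_signal",
    "summarize",
    "read_landmarks_tsv",
    "write_landmarks_tsv",
]

LANDMARKS: tuple[str, ...] = (
    "snout",
    "eye",
    "eye_bottom",
    "dorsal_fin_tip",
    "pectoral_base_left",
    "pectoral_tip_left",
    "pectoral_base_right",
    "pectoral_tip_right",
    "pelvic_base_left",
    "pelvic_tip_left",
    "pelvic_base_right",
    "pelvic_tip_right",
    "anal_fin_tip",
    "caudal_peduncle",
    "caudal_fin_tip",
)

FIN_TIPS: tuple[str, ...] = (
    "pectoral_tip_left",
    "pectoral_tip_right",
    "pelvic_tip_left",
    "pelvic_tip_right",
    "dorsal_fin_tip",
    "anal_fin_tip",
    "caudal_fin_tip",
)


@dataclass
class LandmarkSeries:
    """Per-frame 3-D coordinates of named landmarks.

    ``points`` maps landmark name -> (n_frames, 3) array; all landmarks
    share the same frame count.  ``bl`` is the body length in the same
    units as the coordinates.
    """

    fps: float
    bl: float
    points: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.bl <= 0:
            raise ValueError("body length must be positive")
        if len(self.points) != len(set(self.points)):
            raise ValueError("duplicated landmark name")
        n = None
        for name, arr in self.points.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"landmark {name!r} must be (n_frames, 3)")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError("landmarks differ in frame count")
            self.points[name] = arr
        if n is None or n < 2:
            raise ValueError("need at least 2 frames")
        self.n_frames = n

    @property
    def t(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) / self.fps

    def require(self, *names: str) -> list[np.ndarray]:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise KeyError(f"missing landmarks: {missing}")
        return [self.points[n] for n in names]


@dataclass
class KinematicsSummary:
    roll_max_excursion: float
    roll_mean: float
    pitch_max_excursion: float
    pitch_mean: float
    body_angle_mean: float
    curvature: float
    phase_lag: float | None
    fin_distance: dict[str, float]


def roll_pitch(
    series: LandmarkSeries, roll_reference: str = "vertical"
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Roll and pitch angle time series (degrees) with summaries.

    Roll is measured from the vertical by default (``roll_reference`` may
    be set to ``"mean"`` to use the time-mean eye-axis direction instead);
    pitch is always relative to the time-mean snout->peduncle elevation,
    since the absolute body angle is reported separately.
    """
    eye, eye_bot, snout, ped = series.require(
        "eye", "eye_bottom", "snout", "caudal_peduncle"
    )
    seg = eye_bot - eye  # points ventrally in neutral posture
    trans = np.linalg.norm(seg[:, 1:], axis=1)
    if np.any(trans < 1e-12):
        raise ValueError("degenerate eye segment (zero transverse extent)")
    roll = np.degrees(np.arctan2(seg[:, 1], -seg[:, 2]))
    if roll_reference == "mean":
        roll = roll - roll.mean()
    elif roll_reference != "vertical":
        raise ValueError("roll_reference must be 'vertical' or 'mean'")

    ax = ped - snout
    norms = np.linalg.norm(ax, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("degenerate snout-peduncle segment")
    elev = np.degrees(np.arcsin(np.clip(ax[:, 2] / norms, -1.0, 1.0)))
    pitch = elev - elev.mean()

    summaries = {
        "roll_max_excursion": float(np.max(np.abs(roll))),
        "roll_mean": float(np.mean(roll)),
        "pitch_max_excursion": float(np.max(np.abs(pitch))),
        "pitch_mean": float(np.mean(pitch)),
    }
    return roll, pitch, summaries


def body_angle(series: LandmarkSeries) -> np.ndarray:
    """Signed angle (degrees) of the eye->peduncle line above horizontal.

    Head-up postures (eye above the peduncle) are positive.
    """
    eye, ped = series.require("eye", "caudal_peduncle")
    d = eye - ped
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist < 1e-12):
        raise ValueError("eye and caudal peduncle coincide")
    return np.degrees(np.arcsin(np.clip(d[:, 2] / dist, -1.0, 1.0)))


def curvature(p_snout, p_peduncle, p_tail) -> float:
    """Menger curvature of three body points (1/length units).

    4 * area / (|ab| |bc| |ca|): the inverse circumradius of the triangle,
    zero for collinear points.  Accepts 2-D or 3-D points.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (p_snout, p_peduncle, p_tail))
    if a.size == 2:
        a, b, c = (np.append(p, 0.0) for p in (a, b, c))
    ab, bc, ca = b - a, c - b, a - c
    lab, lbc, lca = (np.linalg.norm(v) for v in (ab, bc, ca))
    if min(lab, lbc, lca) < 1e-12:
        raise ValueError("duplicated points")
    area = 0.5 * np.linalg.norm(np.cross(ab, -ca))
    return float(4.0 * area / (lab * lbc * lca))


def dominant_period(x: np.ndarray) -> float:
    """Dominant oscillation period of a signal, in samples.

    A coarse estimate from the periodogram peak seeds a refinement by the
    mean spacing of upward zero crossings of the lightly smoothed,
    mean-centred signal.  Crossing spacing is unbiased (the raw
    autocorrelation's triangular taper drags peaks toward shorter lags)
    and exact for sinusoids sampled over whole periods.  Raises for flat
    or non-oscillatory signals.
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    amp = np.max(np.abs(xc))
    if amp < 1e-12 or np.std(xc) < 1e-12 * max(1.0, np.max(np.abs(x))):
        raise ValueError("flat signal: oscillation period undefined")
    n = x.size
    spec = np.abs(np.fft.rfft(xc))
    k = int(np.argmax(spec[1:])) + 1
    per0 = n / k
    w = max(1, int(round(per0 / 20)))
    xs = np.convolve(xc, np.ones(w) / w, mode="same") if w > 1 else xc
    up = np.flatnonzero((xs[:-1] <= 0) & (xs[1:] > 0))
    kept: list[int] = []
    for i in up:
        if not kept or i - kept[-1] >= 0.5 * per0:
            kept.append(int(i))
    if len(kept) < 2:
        raise ValueError("signal not oscillatory: fewer than two cycles")
    return float(np.mean(np.diff(kept)))


def phase_lag(left: np.ndarray, right: np.ndarray, fps: float) -> float:
    """Left-right phase lag in degrees, folded into [0, 180].

    Both abduction signals are mean-centred and cross-correlated; the lag
    maximising the correlation (searched within +-half the dominant
    period) is converted to phase via that period.  0 deg means both fins
    reach maximum abduction together; 180 deg means one is maximally
    abducted when the other is maximally adducted.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("signals must be equal-length 1-D arrays")
    period = dominant_period(left)
    if left.size < 2 * period:
        raise ValueError("need at least two oscillation cycles")
    # correlate circularly over a whole number of periods: a linear
    # cross-correlation's triangular overlap taper drags the peak toward
    # zero lag, while the circular one is exact for sinusoids
    n_cycles = int(left.size // period)
    L = int(round(n_cycles * period))
    lc = left[:L] - left[:L].mean()
    rc = right[:L] - right[:L].mean()
    cc = np.fft.irfft(np.fft.rfft(lc) * np.conj(np.fft.rfft(rc)), n=L)
    lags = np.arange(L)
    lags[lags > L // 2] -= L  # wrap to signed lags
    half = int(round(period / 2.0))
    sel = np.abs(lags) <= half
    order = np.argsort(lags[sel])
    lag = float(lags[sel][order][np.argmax(cc[sel][order])])
    phase = 360.0 * lag / period
    return float(abs((phase + 180.0) % 360.0 - 180.0))


def fin_distance(track: np.ndarray, fps: float, bl: float) -> float:
    """Cumulative 3-D path length of a fin tip, standardised to BL s^-1."""
    track = np.atleast_2d(np.asarray(track, dtype=float))
    if track.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    steps = np.linalg.norm(np.diff(track, axis=0), axis=1)
    elapsed = (track.shape[0] - 1) / fps
    return float(steps.sum() / elapsed / bl)


def extract_cycles(x: np.ndarray, min_separation: float = 0.5) -> list[tuple[int, int]]:
    """Complete oscillation cycles as (start, end) sample-index windows.

    Cycles are delimited by successive upward zero crossings of the
    mean-centred signal, detected after light smoothing (a window of a
    twentieth of the dominant period) so that noise chatter at the zero
    line does not split cycles.  Crossings closer than ``min_separation``
    periods are merged.  Exact zeros at the first or last sample count as
    crossings so that an integer number of sampled periods yields that
    many cycles.
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    period = dominant_period(x)
    amp = np.max(np.abs(xc))
    tol = 1e-9 * amp
    w = max(1, int(round(period / 20.0)))
    w += 1 - w % 2  # odd window keeps crossings unshifted
    xs = np.convolve(xc, np.ones(w) / w, mode="same") if w > 1 else xc
    up = np.flatnonzero((xs[:-1] <= 0) & (xs[1:] > 0)).tolist()
    if abs(xc[-1]) <= tol and xc[-2] < -tol and (not up or up[-1] != x.size - 1):
        up.append(x.size - 1)
    if abs(xc[0]) <= tol and xc[1] > tol and (not up or up[0] != 0):
        up.insert(0, 0)
    # merge chatter from noise near the zero line
    kept: list[int] = []
    for i in sorted(set(up)):
        if not kept or i - kept[-1] >= min_separation * period:
            kept.append(i)
    cycles = [(kept[i], kept[i + 1]) for i in range(len(kept) - 1)]
    if not cycles:
        raise ValueError("fewer than one complete cycle in the signal")
    return cycles


def abduction_signal(series: LandmarkSeries, side: str) -> np.ndarray:
    """Signed outward (abduction) displacement of a pectoral-fin tip.

    Lateral (y) displacement of the tip relative to its base, signed so
    that movement away from the body midline is positive on both sides.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    tip, base = series.require(f"pectoral_tip_{side}", f"pectoral_base_{side}")
    sign = -1.0 if side == "left" else 1.0
    return sign * (tip[:, 1] - base[:, 1])


def summarize(series: LandmarkSeries) -> KinematicsSummary:
    """All posture and fin metrics for one landmark series."""
    _, _, rp = roll_pitch(series)
    ba = body_angle(series)
    snout, ped, tail = series.require("snout", "caudal_peduncle", "caudal_fin_tip")
    kappa = float(
        np.mean(
            [curvature(snout[i], ped[i], tail[i]) for i in range(series.n_frames)]
        )
    )
    try:
        lag = phase_lag(
            abduction_signal(series, "left"),
            abduction_signal(series, "right"),
            series.fps,
        )
    except (ValueError, KeyError):
        lag = None
    dists = {
        name: fin_distance(series.points[name], series.fps, series.bl)
        for name in FIN_TIPS
        if name in series.points
    }
    return KinematicsSummary(
        roll_max_excursion=rp["roll_max_excursion"],
        roll_mean=rp["roll_mean"],
        pitch_max_excursion=rp["pitch_max_excursion"],
        pitch_mean=rp["pitch_mean"],
        body_angle_mean=float(np.mean(ba)),
        curvature=kappa,
        phase_lag=lag,
        fin_distance=dists,
    )


def write_landmarks_tsv(series: LandmarkSeries, path) -> None:
    """Write ``frame  landmark  x  y  z`` rows with fps/bl header comments."""
    with open(path, "w") as fh:
        fh.write(f"# fps={series.fps}\n# bl={series.bl}\n")
        fh.write("frame\tlandmark\tx\ty\tz\n")
        for name, arr in series.points.items():
            for i, (x, y, z) in enumerate(arr):
                fh.write(f"{i}\t{name}\t{x:.8g}\t{y:.8g}\t{z:.8g}\n")


def read_landmarks_tsv(path) -> LandmarkSeries:
    """Inverse of :func:`write_landmarks_tsv`."""
    import pandas as pd

    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].strip().partition("=")
        meta[key.strip()] = float(val)
        n_header += 1
    import io

    df = pd.read_csv(io.StringIO("".join(lines[n_header:])), sep="\t")
    points = {
        name: g.sort_values("frame")[["x", "y", "z"]].to_numpy()
        for name, g in df.groupby("landmark")
    }
    return LandmarkSeries(fps=meta["fps"], bl=meta["bl"], points=points)
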