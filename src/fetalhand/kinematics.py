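"""MT/TPV extraction from calibrated 2-D tracked trajectories (nominal 4 Hz).

Positions are expressed in intraocular-distance units after calibration;
speeds are finite-difference derivatives of the tracked path (central
differences on interior samples, one-sided at the ends).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fetalhand.errors import ValidationError

DEFAULT_THRESHOLD_FRAC = 0.05  # onset/offset threshold as a fraction of peak speed


@dataclass(frozen=True)
class Trajectory:
    """A calibrated 2-D tracked path.

    times are in seconds and strictly increasing; positions are (n, 2) in
    intraocular-distance units; calibration_length is the intraocular
    segment length in the raw pixel units.
    """

    times: np.ndarray
    positions: np.ndarray
    calibration_length: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if t.ndim != 1 or t.size < 3:
            raise ValidationError("trajectory needs at least 3 samples")
        if p.shape != (t.size, 2):
            raise ValidationError(f"positions must be (n, 2), got {p.shape}")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not self.calibration_length > 0:
            raise ValidationError("calibration_length must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)


def calibrate(raw_positions, times, calibration_px: float) -> Trajectory:
    """Convert raw pixel coordinates to intraocular-distance units.

    Divides positions by the length (in pixels) of the intraocular
    calibration segment; times are unchanged.
    """
    if not calibration_px > 0:
        raise ValidationError("calibration_px must be > 0")
    raw = np.asarray(raw_positions, dtype=float)
    return Trajectory(
        times=np.asarray(times, dtype=float),
        positions=raw / calibration_px,
        calibration_length=float(calibration_px),
    )


def speed_profile(traj: Trajectory) -> np.ndarray:
    """Per-sample speed (intraocular units / s) via finite differences.

    Uses central differences on interior samples and one-sided differences
    at the two ends (``np.gradient`` semantics, second-order for the
    nominally uniform 4 Hz grid).
    """
    vel = np.gradient(traj.positions, traj.times, axis=0)
    return np.hypot(vel[:, 0], vel[:, 1])


def extract_metrics(traj: Trajectory, onset_index: int, offset_index: int) -> tuple[float, float]:
    """MT (ms) and TPV (% of MT) for the movement spanning the given samples.

    MT is the elapsed time between the onset and offset samples.  TPV is the
    relative time of the speed maximum searched over (onset, offset]; the
    onset sample itself is excluded so that TPV is always in (0, 100].
    """
    n = traj.times.size
    if not (0 <= onset_index < offset_index <= n - 1):
        raise ValidationError(
            f"need 0 <= onset < offset <= {n - 1}, got ({onset_index}, {offset_index})"
        )
    speed = speed_profile(traj)
    t = traj.times
    seg = speed[onset_index + 1 : offset_index + 1]
    peak_index = onset_index + 1 + int(np.argmax(seg))
    duration = t[offset_index] - t[onset_index]
    mt = duration * 1000.0
    tpv = 100.0 * (t[peak_index] - t[onset_index]) / duration
    return mt, tpv


def read_trajectory(path, calibration_px: float) -> Trajectory:
    """Read a raw tracked-trajectory CSV (columns ``t_s,x,y``) and calibrate it.

    ``calibration_px`` is the intraocular segment length in the same pixel
    units as the x/y columns.
    """
    import pandas as pd

    df = pd.read_csv(path)
    missing = [c for c in ("t_s", "x", "y") if c not in df.columns]
    if missing:
        from fetalhand.errors import FormatError

        raise FormatError(f"{path}: missing column(s): {missing}")
    return calibrate(
        df[["x", "y"]].to_numpy(dtype=float),
        df["t_s"].to_numpy(dtype=float),
        calibration_px,
    )


def detect_bounds(speed, threshold_frac: float = DEFAULT_THRESHOLD_FRAC) -> tuple[int, int]:
    """Locate movement onset/offset by a fraction-of-peak speed threshold.

    Onset is the first sample with speed above ``threshold_frac * peak``
    (sample 0 when the threshold is 0).  Offset is the first later sample
    where speed falls below the threshold and stays below for at least two
    samples (or through the end of the series).
    """
    s = np.asarray(speed, dtype=float)
    if s.size == 0:
        raise ValidationError("empty speed series")
    peak = float(np.max(s))
    if not peak > 0:
        raise ValidationError("speed series has no positive peak")
    if threshold_frac < 0:
        raise ValidationError("threshold_frac must be >= 0")
    thr = threshold_frac * peak

    if threshold_frac == 0:
        onset = 0
    else:
        above = np.flatnonzero(s > thr)
        if above.size == 0:
            raise ValidationError("no onset crossing found")
        onset = int(above[0])

    n = s.size
    for j in range(onset + 1, n):
        if s[j] < thr or (threshold_frac == 0 and s[j] <= thr):
            stays = j == n - 1 or (s[j + 1] < thr or (threshold_frac == 0 and s[j + 1] <= thr))
            if stays:
                return onset, j
    raise ValidationError("no offset crossing found")
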