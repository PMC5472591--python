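"""FRAP double-ratio normalization and single-exponential recovery fitting.

Raw fluorescence-recovery-after-photobleaching traces (bleach-ROI mean B(t)
and whole-cell mean Cell(t)) are normalized with the double ratio

    F(t) = [B(t) / <B>_pre] / [Cell(t) / <Cell>_pre],

which cancels acquisition fading, then full-scale normalized so the first
post-bleach value is 0 and the pre-bleach plateau is 1.  A single exponential
F(t) = M (1 - exp(-k t)), with t measured from the bleach, is fitted on the
post-bleach points; the plateau M is the mobile fraction and t1/2 = ln2 / k
the half-recovery time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

MIN_PRE_FRAMES = 2
MIN_POST_FRAMES = 10


@dataclass
class FrapRecord:
    """Raw ROI intensity series; ``bleach_index`` is the first post-bleach frame."""

    times_s: np.ndarray
    bleach_roi: np.ndarray
    whole_cell: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.bleach_roi = np.asarray(self.bleach_roi, dtype=float)
        self.whole_cell = np.asarray(self.whole_cell, dtype=float)
        n = self.times_s.size
        if not (self.bleach_roi.size == n and self.whole_cell.size == n):
            raise ValueError("times, bleach_roi, whole_cell must have equal length")
        if not 0 < self.bleach_index < n:
            raise ValueError(f"bleach_index {self.bleach_index} out of range")
        if self.bleach_index < MIN_PRE_FRAMES:
            raise ValueError(f"need >= {MIN_PRE_FRAMES} pre-bleach frames")
        if n - self.bleach_index < MIN_POST_FRAMES:
            raise ValueError(f"need >= {MIN_POST_FRAMES} post-bleach frames")
        if np.any(self.bleach_roi < 0) or np.any(self.whole_cell < 0):
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class NormalizedFrap:
    """Normalized recovery curve on the record's full time axis."""

    times_s: np.ndarray
    values: np.ndarray
    bleach_index: int

    @property
    def post_times(self) -> np.ndarray:
        """Times measured from the bleach frame (t=0 at the bleach)."""
        return self.times_s[self.bleach_index :] - self.times_s[self.bleach_index]

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.bleach_index :]


@dataclass(frozen=True)
class FrapFit:
    mobile_fraction: float
    half_time_s: float
    rate_k: float  # 1/s
    fit_residual: float  # RMS of fit residuals
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.flags


def double_ratio(rec: FrapRecord) -> np.ndarray:
    """The double-ratio curve F(t) = [B(t)/<B>_pre] / [Cell(t)/<Cell>_pre].

    Uses the mean over all pre-bleach frames as the pre-bleach reference;
    whole-cell acquisition fading multiplies both channels and cancels.
    """
    pre = slice(0, rec.bleach_index)
    b_pre = rec.bleach_roi[pre].mean()
    c_pre = rec.whole_cell[pre].mean()
    if b_pre <= 0 or c_pre <= 0:
        raise ValueError("pre-bleach mean intensity must be > 0")
    if np.any(rec.whole_cell == 0):
        raise ValueError("whole-cell intensity contains zeros")
    return (rec.bleach_roi / b_pre) / (rec.whole_cell / c_pre)


def normalize_frap(rec: FrapRecord, mode: str = "fullscale") -> NormalizedFrap:
    """Double-ratio normalization followed by zero-normalization.

    In ``fullscale`` mode (default, EasyFRAP-style) the double-ratio curve is
    shifted and rescaled so the first post-bleach value is 0 and the
    pre-bleach level 1, letting the fitted plateau read directly as the mobile
    fraction; ``subtract`` only shifts the post-bleach floor to 0.
    """
    pre = slice(0, rec.bleach_index)
    f = double_ratio(rec)
    f0 = f[rec.bleach_index]
    if mode == "fullscale":
        f_pre = f[pre].mean()
        scale = f_pre - f0
        if scale <= 0:
            raise ValueError("no bleach detected: post-bleach value >= pre-bleach level")
        f = (f - f0) / scale
    elif mode == "subtract":
        f = f - f0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return NormalizedFrap(rec.times_s.copy(), f, rec.bleach_index)


def fit_frap(norm: NormalizedFrap) -> FrapFit:
    """Least-squares single-exponential fit of the post-bleach recovery.

    Model F(t) = M (1 - exp(-k t)) with M in [0, 1.5] and k > 0; initial M
    from the last decile of the curve, initial k from the time to half of
    that level.  Non-convergence or a rate stuck at its bound is flagged in
    ``flags``, never silent.
    """
    from lmfit import Model

    t = norm.post_times
    y = norm.post_values
    m0 = float(np.clip(y[-max(1, len(y) // 10) :].mean(), 0.05, 1.5))
    above = np.nonzero(y >= m0 / 2)[0]
    t_half_guess = t[above[0]] if above.size and t[above[0]] > 0 else (t[-1] / 4 or 1.0)
    k0 = math.log(2) / t_half_guess

    model = Model(lambda t, M, k: M * (1.0 - np.exp(-k * t)))
    params = model.make_params(M=m0, k=k0)
    params["M"].set(min=0.0, max=1.5)
    params["k"].set(min=1e-9)
    result = model.fit(y, params, t=t)

    flags: list[str] = []
    if not result.success:
        flags.append(f"no_convergence: {result.message}")
    k = float(result.params["k"].value)
    m = float(result.params["M"].value)
    if k <= 1e-8:
        flags.append("rate_at_lower_bound")
    if m < 1e-3:
        flags.append("no_recovery: plateau near zero, rate unidentifiable")
    rms = float(np.sqrt(np.mean(result.residual**2)))
    return FrapFit(
        mobile_fraction=m,
        half_time_s=math.log(2) / k,
        rate_k=k,
        fit_residual=rms,
        flags=tuple(flags),
    )


def analyze_frap(rec: FrapRecord, mode: str = "fullscale") -> FrapFit:
    """Normalize and fit one record."""
    return fit_frap(normalize_frap(rec, mode))


# --- CSV I/O -----------------------------------------------------------------


def read_frap_csv(path: str | Path, bleach_index: int | None = None) -> FrapRecord:
    """Read a (time_s, bleach_roi, whole_cell) CSV.

    If ``bleach_index`` is not given it is detected as the frame with the
    largest single-step drop in the bleach-ROI trace.
    """
    import pandas as pd

    df = pd.read_csv(path)
    b = df["bleach_roi"].to_numpy(dtype=float)
    if bleach_index is None:
        bleach_index = int(np.argmin(np.diff(b)) + 1)
    return FrapRecord(
        df["time_s"].to_numpy(dtype=float), b, df["whole_cell"].to_numpy(dtype=float),
        bleach_index,
    )


def write_fits_csv(fits: dict[str, FrapFit], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "cell_id": cid,
                "mobile_fraction": f.mobile_fraction,
                "half_time_s": f.half_time_s,
                "k": f.rate_k,
                "rms": f.fit_residual,
                "flags": ";".join(f.flags),
            }
            for cid, f in fits.items()
        ]
    ).to_csv(path, index=False)
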