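"""Adhesion image quantification and migration-track statistics.

Covers the microscopy-side readouts of talin destabilization: adhesion/cytosol
intensity ratios (expression-robust enrichment), vinculin/talin ratios,
paxillin-based masking of cytosolic signal, the thresholded Mander's split
coefficient M1, the fraction of adhesion area on fibronectin squares of a
micropatterned substrate, the square-lattice pattern itself, and per-track
migration speeds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CHANNEL_NAMES = ("talin", "vinculin", "paxillin", "pattern", "integrin")


@dataclass
class BinaryMask:
    """A {0,1} raster with the same shape as its scene."""

    data: np.ndarray
    provenance: str = ""
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)

    @property
    def area_px(self) -> int:
        return int(self.data.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.data & other.data, provenance=self.provenance,
                          pixel_size_um=self.pixel_size_um)


@dataclass
class AdhesionScene:
    """Registered multi-channel image stack with a common pixel size (um)."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if np.any(ch < 0):
                raise ValueError(f"negative intensities in channel {name!r}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"scene has no channel {name!r}") from None


@dataclass
class TrackSet:
    """Migration tracks: list of (track_id, times_min, xy_um)."""

    tracks: list[tuple[str, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        checked = []
        for tid, t, xy in self.tracks:
            t = np.asarray(t, dtype=float)
            xy = np.asarray(xy, dtype=float).reshape(-1, 2)
            if t.size < 2:
                raise ValueError(f"track {tid}: needs >= 2 points")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"track {tid}: times must be strictly increasing")
            checked.append((str(tid), t, xy))
        self.tracks = checked

    @classmethod
    def from_frame(cls, df) -> "TrackSet":
        tracks = []
        for tid, grp in df.groupby("track_id", sort=False):
            grp = grp.sort_values("t_min")
            tracks.append(
                (str(tid), grp["t_min"].to_numpy(), grp[["x_um", "y_um"]].to_numpy())
            )
        return cls(tracks)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrackSet":
        import pandas as pd

        return cls.from_frame(pd.read_csv(path))

    def to_frame(self):
        import pandas as pd

        rows = []
        for tid, t, xy in self.tracks:
            for ti, (x, y) in zip(t, xy):
                rows.append((tid, ti, x, y))
        return pd.DataFrame(rows, columns=["track_id", "t_min", "x_um", "y_um"])


# --- intensity ratios --------------------------------------------------------


def adhesion_cytosol_ratio(
    scene: AdhesionScene,
    channel: str,
    adhesion_mask: BinaryMask,
    cytosol_mask: BinaryMask,
) -> float:
    """Mean intensity over adhesions / mean intensity over cytosol.

    This ratio is invariant to a global gain and therefore robust to
    cell-to-cell expression differences; an additive offset does change it,
    so background subtraction should precede it where offsets exist.
    """
    if adhesion_mask.area_px == 0 or cytosol_mask.area_px == 0:
        raise ValueError("empty mask")
    if np.any(adhesion_mask.data & cytosol_mask.data):
        raise ValueError("adhesion and cytosol masks overlap")
    img = scene.channel(channel)
    cyt = img[cytosol_mask.data].mean()
    if cyt == 0:
        raise ValueError("zero cytosolic mean intensity")
    return float(img[adhesion_mask.data].mean() / cyt)


def vinculin_talin_ratio(talin_ratio: float, vinculin_ratio: float) -> float:
    """Quotient of the vinculin and talin adhesion/cytosol ratios."""
    if talin_ratio <= 0 or vinculin_ratio <= 0:
        raise ValueError("ratios must be > 0")
    return vinculin_ratio / talin_ratio


# --- masks -------------------------------------------------------------------


def build_paxillin_mask(
    channel: np.ndarray,
    pixel_size_um: float,
    blur_sigma_um: float = 0.3,
    threshold: float | None = None,
) -> BinaryMask:
    """Gaussian-blur the paxillin channel and threshold it into a mask.

    Blurring extends the signal so the mask generously covers adhesion sites;
    ``threshold`` is manual (intensity units of the blurred image) with an
    Otsu fallback.  A degenerate threshold producing an empty or full mask
    triggers a warning rather than an error.
    """
    from skimage.filters import gaussian, threshold_otsu

    if blur_sigma_um <= 0:
        raise ValueError("blur sigma must be > 0")
    blurred = gaussian(
        np.asarray(channel, dtype=float), sigma=blur_sigma_um / pixel_size_um,
        preserve_range=True,
    )
    if threshold is None:
        if np.ptp(blurred) == 0:
            threshold = np.inf  # flat image: no structure
        else:
            threshold = float(threshold_otsu(blurred))
    mask = blurred >= threshold
    if mask.all() or (not mask.any() and np.any(np.asarray(channel) > 0)):
        warnings.warn(
            f"degenerate paxillin mask (threshold {threshold:g} outside the "
            "useful intensity range)", stacklevel=2,
        )
    return BinaryMask(mask, provenance="paxillin", pixel_size_um=pixel_size_um)


def segment_adhesions(
    scene: AdhesionScene,
    channel: str = "talin",
    blur_sigma_um: float = 0.2,
    tophat_radius_um: float = 2.0,
    min_area_um2: float = 0.25,
) -> BinaryMask:
    """Segment focal adhesions: blur, top-hat background removal, Otsu,
    minimum object area."""
    from skimage.filters import gaussian, threshold_otsu
    from skimage.morphology import disk, remove_small_objects, white_tophat

    px = scene.pixel_size_um
    img = gaussian(scene.channel(channel).astype(float), sigma=blur_sigma_um / px,
                   preserve_range=True)
    img = white_tophat(img, footprint=disk(max(1, round(tophat_radius_um / px))))
    if np.ptp(img) == 0:
        return BinaryMask(np.zeros_like(img, bool), "adhesion", px)
    mask = img >= threshold_otsu(img)
    # drop objects strictly smaller than the minimum area
    mask = remove_small_objects(mask, max_size=max(0, round(min_area_um2 / px**2) - 1))
    return BinaryMask(mask, provenance="adhesion", pixel_size_um=px)


def cytosol_mask(
    cell_mask: BinaryMask, adhesion_mask: BinaryMask, dilation_um: float = 0.5
) -> BinaryMask:
    """Cell interior minus the (dilated) adhesions."""
    from skimage.morphology import dilation, disk

    px = cell_mask.pixel_size_um
    dilated = dilation(
        adhesion_mask.data, footprint=disk(max(1, round(dilation_um / px)))
    ).astype(bool)
    return BinaryMask(cell_mask.data & ~dilated, "cytosol", px)


# --- colocalization ----------------------------------------------------------


def manders_overlap(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    mask: BinaryMask,
    threshold_b: float,
) -> float:
    """Mander's split coefficient M1 within a mask.

    Fraction of channel-a intensity (inside the mask) that sits on pixels
    where channel b exceeds the manual threshold; in [0, 1] and invariant to
    uniform scaling of channel a.
    """
    if mask.area_px == 0:
        raise ValueError("empty mask")
    a = np.asarray(ch_a, dtype=float)
    b = np.asarray(ch_b, dtype=float)
    total = a[mask.data].sum()
    if total == 0:
        raise ValueError("no channel-a signal inside the mask: coefficient undefined")
    overlap = a[mask.data & (b > threshold_b)].sum()
    return float(overlap / total)


def fn_fraction(adhesion_mask: BinaryMask, pattern_mask: BinaryMask) -> float:
    """Fraction of adhesion-mask area lying on the patterned (Fn) area."""
    if adhesion_mask.data.shape != pattern_mask.data.shape:
        raise ValueError("mask shapes differ")
    total = adhesion_mask.area_px
    if total == 0:
        raise ValueError("empty adhesion mask: fraction undefined")
    on = int((adhesion_mask.data & pattern_mask.data).sum())
    return on / total


def make_micropattern(
    field_um: float,
    square_um: float,
    pitch_um: float,
    pixel_size_um: float = 0.1,
) -> BinaryMask:
    """Periodic square lattice mask (Fn squares in a Vn background).

    Covered fraction approaches (square/pitch)^2; a 0.75 square/pitch ratio
    gives the 56% fibronectin coverage of the study's substrates.  Pixel
    centers decide membership.
    """
    if square_um <= 0 or pitch_um <= 0 or field_um <= 0 or pixel_size_um <= 0:
        raise ValueError("dimensions must be > 0")
    if square_um > pitch_um:
        raise ValueError("square must not exceed pitch")
    n = int(round(field_um / pixel_size_um))
    centers = (np.arange(n) + 0.5) * pixel_size_um
    on_1d = np.mod(centers, pitch_um) < square_um
    return BinaryMask(
        np.outer(on_1d, on_1d), provenance="pattern", pixel_size_um=pixel_size_um
    )


# --- migration ---------------------------------------------------------------


def migration_rate(tracks: TrackSet):
    """Per-track path speed (um/h) plus net-displacement speed.

    Path speed sums step lengths over the total duration; zero-duration tracks
    are rejected and logged.  Returns a pandas DataFrame with one row per
    retained track.
    """
    import pandas as pd

    rows = []
    for tid, t, xy in tracks.tracks:
        duration_h = (t[-1] - t[0]) / 60.0
        if duration_h <= 0:
            logger.warning("track %s rejected: zero duration", tid)
            continue
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        path = float(steps.sum())
        net = float(np.linalg.norm(xy[-1] - xy[0]))
        rows.append(
            {
                "track_id": tid,
                "duration_h": duration_h,
                "path_length_um": path,
                "path_speed_um_per_h": path / duration_h,
                "net_speed_um_per_h": net / duration_h,
            }
        )
    return pd.DataFrame(rows)


def cohort_summary(per_track) -> dict[str, float]:
    """Cohort mean +- SD of the per-track path speeds."""
    speeds = per_track["path_speed_um_per_h"].to_numpy()
    return {
        "n": int(speeds.size),
        "mean_um_per_h": float(speeds.mean()),
        "sd_um_per_h": float(speeds.std(ddof=1)) if speeds.size > 1 else 0.0,
    }


# --- TIFF I/O ----------------------------------------------------------------


def read_scene(
    channel_paths: Mapping[str, str | Path], pixel_size_um: float
) -> AdhesionScene:
    """Read one single-page TIFF per channel into a scene."""
    import tifffile

    channels = {
        name: tifffile.imread(str(p)).astype(float) for name, p in channel_paths.items()
    }
    return AdhesionScene(channels, pixel_size_um)


def write_mask_tiff(mask: BinaryMask, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), (mask.data.astype(np.uint8) * 255))
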