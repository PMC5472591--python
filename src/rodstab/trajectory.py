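"""Mechanostability metrics from solvated helix-bundle trajectories.

The unfolding readout of a constant-force pulling simulation is the number of
water molecules penetrating the hydrophobic core, operationalized as water
oxygens within a cutoff (default 0.5 nm) of at least one heavy atom of EVERY
one of the four helices.  This module implements that counter (KD-tree fast
path plus an all-pairs brute-force reference), the four H1-H4 alpha-carbon
displacement series, the 10-frame sliding average used for plotting, replicate
averaging, and the refolding-time metric on the central d3 vector.

All operations take explicit per-frame timestamps; no frame rate is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import DEFAULT_HELIX_RANGES, DISPLACEMENT_VECTORS

HELIX_IDS = ("H1", "H2", "H3", "H4")
DEFAULT_CUTOFF_NM = 0.5  # 5 Angstrom
DEFAULT_WINDOW = 10
#: A trajectory is considered refolded once d3 stays within this band of the
#: pre-pull baseline until the end of the relaxation run.
DEFAULT_REFOLD_TOL_NM = 0.05

NOT_REFOLDED = None  # sentinel returned by refold_time


@dataclass
class SolvatedFrame:
    """One trajectory time point: protein heavy atoms + water oxygens, nm.

    ``atoms`` maps residue_number -> {atom_name: xyz}; hydrogens may be
    present but are ignored by the penetration criterion.  ``water_oxygens``
    is an (n, 3) array.
    """

    time_ns: float
    atoms: dict[int, dict[str, np.ndarray]]
    water_oxygens: np.ndarray

    def __post_init__(self) -> None:
        if self.time_ns < 0:
            raise ValueError("time must be >= 0 ns")
        self.water_oxygens = np.asarray(self.water_oxygens, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.water_oxygens)):
            raise ValueError("non-finite water coordinates")

    def alpha_carbon(self, resnum: int) -> np.ndarray:
        try:
            return self.atoms[resnum]["CA"]
        except KeyError:
            raise KeyError(f"residue {resnum} has no CA in frame t={self.time_ns}") from None

    def helix_heavy_coords(self, helix_range: tuple[int, int]) -> np.ndarray:
        lo, hi = helix_range
        coords = [
            xyz
            for num in range(lo, hi + 1)
            if num in self.atoms
            for name, xyz in self.atoms[num].items()
            if not name.startswith("H")
        ]
        return np.asarray(coords, dtype=float).reshape(-1, 3)


@dataclass(frozen=True)
class WaterPenetrationSeries:
    times_ns: np.ndarray
    counts: np.ndarray  # integer per-frame penetrating-water counts
    smoothed: np.ndarray  # sliding average of counts, same length

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_ns": self.times_ns, "count": self.counts, "smoothed": self.smoothed}
        )


@dataclass(frozen=True)
class DisplacementSeries:
    times_ns: np.ndarray
    distances: dict[str, np.ndarray]  # vector id (d1..d4) -> nm series

    def to_frame(self):
        import pandas as pd

        frames = [
            pd.DataFrame({"time_ns": self.times_ns, "metric": vid, "value_nm": d})
            for vid, d in self.distances.items()
        ]
        return pd.concat(frames, ignore_index=True)


# --- water penetration -------------------------------------------------------


def _helix_coords(frame: SolvatedFrame, helix_ranges) -> list[np.ndarray]:
    coords = []
    for hid in HELIX_IDS:
        c = frame.helix_heavy_coords(helix_ranges[hid])
        if len(c) == 0:
            raise ValueError(f"helix {hid} has no heavy atoms in frame t={frame.time_ns}")
        coords.append(c)
    return coords


def penetration_flags(
    frame: SolvatedFrame,
    helix_ranges: Mapping[str, tuple[int, int]] = DEFAULT_HELIX_RANGES,
    cutoff_nm: float = DEFAULT_CUTOFF_NM,
) -> np.ndarray:
    """Boolean flag per water oxygen: within cutoff of every helix.

    Waters at the bundle ends count; the clipping planes seen in
    visualizations have no counterpart here.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be > 0 nm")
    helix_coords = _helix_coords(frame, helix_ranges)  # validates all four helices
    waters = frame.water_oxygens
    if len(waters) == 0:
        return np.zeros(0, dtype=bool)
    inside = np.ones(len(waters), dtype=bool)
    for coords in helix_coords:
        d, _ = cKDTree(coords).query(waters, k=1)
        inside &= d <= cutoff_nm
        if not inside.any():
            break
    return inside


def count_penetrating_waters(
    frame: SolvatedFrame,
    helix_ranges: Mapping[str, tuple[int, int]] = DEFAULT_HELIX_RANGES,
    cutoff_nm: float = DEFAULT_CUTOFF_NM,
) -> int:
    """Number of water oxygens within ``cutoff_nm`` of all four helices."""
    return int(penetration_flags(frame, helix_ranges, cutoff_nm).sum())


def brute_force_count(
    frame: SolvatedFrame,
    helix_ranges: Mapping[str, tuple[int, int]] = DEFAULT_HELIX_RANGES,
    cutoff_nm: float = DEFAULT_CUTOFF_NM,
) -> int:
    """All-pairs reference implementation of the penetration count.

    O(n_waters x n_protein); kept as an independent code path for validation
    of the KD-tree counter and of synthetic water placement.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be > 0 nm")
    waters = frame.water_oxygens
    if len(waters) == 0:
        return 0
    inside = np.ones(len(waters), dtype=bool)
    for coords in _helix_coords(frame, helix_ranges):
        diff = waters[:, None, :] - coords[None, :, :]
        dmin = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
        inside &= dmin <= cutoff_nm
    return int(inside.sum())


def sliding_average(
    values: Sequence[float], window: int = DEFAULT_WINDOW, mode: str = "trailing"
) -> np.ndarray:
    """Sliding mean over ``window`` frames, same length as the input.

    ``trailing`` (default) averages the last min(i+1, window) values, matching
    progressive plotting of a trace; ``centered`` averages a symmetric window
    of half-width window//2, truncated at the ends.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v
    out = np.empty_like(v)
    if mode == "trailing":
        for i in range(v.size):
            out[i] = v[max(0, i - window + 1) : i + 1].mean()
    elif mode == "centered":
        half = window // 2
        for i in range(v.size):
            out[i] = v[max(0, i - half) : i + half + 1].mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def penetration_series(
    traj: Sequence[SolvatedFrame],
    helix_ranges: Mapping[str, tuple[int, int]] = DEFAULT_HELIX_RANGES,
    cutoff_nm: float = DEFAULT_CUTOFF_NM,
    window: int = DEFAULT_WINDOW,
    smooth_mode: str = "trailing",
) -> WaterPenetrationSeries:
    """Per-frame penetrating-water counts plus their sliding average."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    counts = np.empty(len(traj), dtype=int)
    for i, frame in enumerate(traj):
        try:
            counts[i] = count_penetrating_waters(frame, helix_ranges, cutoff_nm)
        except ValueError as exc:
            raise ValueError(f"frame {i} (t={frame.time_ns} ns): {exc}") from exc
    times = np.asarray([f.time_ns for f in traj], dtype=float)
    return WaterPenetrationSeries(times, counts, sliding_average(counts, window, smooth_mode))


def average_penetration_series(
    series: Sequence[WaterPenetrationSeries],
    window: int = DEFAULT_WINDOW,
    smooth_mode: str = "trailing",
) -> WaterPenetrationSeries:
    """Element-wise mean over replicate runs (e.g. 5 pulling repeats).

    Series on identical time grids are averaged directly; otherwise each is
    linearly interpolated onto the first series' grid.
    """
    if not series:
        raise ValueError("no series to average")
    times = series[0].times_ns
    stacked = []
    for s in series:
        if len(s.times_ns) == len(times) and np.allclose(s.times_ns, times):
            stacked.append(np.asarray(s.counts, dtype=float))
        else:
            stacked.append(np.interp(times, s.times_ns, s.counts))
    mean = np.mean(stacked, axis=0)
    return WaterPenetrationSeries(times, mean, sliding_average(mean, window, smooth_mode))


# --- displacements -----------------------------------------------------------


def displacement_series(
    traj: Sequence[SolvatedFrame],
    anchor_pairs: Mapping[str, tuple[int, int]] = DISPLACEMENT_VECTORS,
) -> DisplacementSeries:
    """Euclidean alpha-carbon distances for the H1-H4 anchor pairs, per frame."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    times = np.asarray([f.time_ns for f in traj], dtype=float)
    out: dict[str, np.ndarray] = {}
    for vid, (a, b) in anchor_pairs.items():
        d = np.empty(len(traj))
        for i, frame in enumerate(traj):
            try:
                ca, cb = frame.alpha_carbon(a), frame.alpha_carbon(b)
            except KeyError as exc:
                raise ValueError(f"frame {i}: {exc}") from exc
            d[i] = float(np.linalg.norm(cb - ca))
        out[vid] = d
    return DisplacementSeries(times, out)


def refold_time(
    times_ns: Sequence[float],
    d3_nm: Sequence[float],
    baseline_nm: float,
    tol_nm: float = DEFAULT_REFOLD_TOL_NM,
) -> float | None:
    """Earliest time from which d3 stays within ``tol_nm`` of the baseline.

    A relaxation trajectory counts as refolded at the first time t* such that
    |d3(t) - baseline| <= tol for ALL t >= t* (transient touches of the band
    do not count).  Returns None if the series ends outside the band.
    """
    times = np.asarray(times_ns, dtype=float)
    d3 = np.asarray(d3_nm, dtype=float)
    if times.size == 0:
        raise ValueError("empty series")
    if baseline_nm <= 0:
        raise ValueError("baseline must be > 0 nm")
    if tol_nm <= 0:
        raise ValueError("tolerance must be > 0 nm")
    ok = np.abs(d3 - baseline_nm) <= tol_nm
    if not ok[-1]:
        return NOT_REFOLDED
    # last index where ok is False, +1 -> start of the terminal in-band run
    bad = np.nonzero(~ok)[0]
    start = bad[-1] + 1 if bad.size else 0
    return float(times[start])


# --- file I/O ----------------------------------------------------------------

#: CSV frame-table columns: time_ns, resid (empty for water), atom, x_nm, y_nm, z_nm.
FRAME_CSV_COLUMNS = ("time_ns", "resid", "atom", "x_nm", "y_nm", "z_nm")


def frames_to_csv(traj: Sequence[SolvatedFrame], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for f in traj:
        for resid, atoms in f.atoms.items():
            for name, xyz in atoms.items():
                rows.append((f.time_ns, resid, name, *xyz))
        for xyz in f.water_oxygens:
            rows.append((f.time_ns, "", "OW", *xyz))
    pd.DataFrame(rows, columns=list(FRAME_CSV_COLUMNS)).to_csv(path, index=False)


def frames_from_csv(path: str | Path) -> list[SolvatedFrame]:
    import pandas as pd

    df = pd.read_csv(path)
    frames = []
    for t, grp in df.groupby("time_ns", sort=True):
        water = grp[grp["resid"].isna() | (grp["resid"].astype(str) == "")]
        prot = grp.drop(water.index)
        atoms: dict[int, dict[str, np.ndarray]] = {}
        for _, row in prot.iterrows():
            atoms.setdefault(int(row["resid"]), {})[str(row["atom"])] = np.array(
                [row["x_nm"], row["y_nm"], row["z_nm"]]
            )
        frames.append(
            SolvatedFrame(float(t), atoms, water[["x_nm", "y_nm", "z_nm"]].to_numpy())
        )
    return frames


def load_trajectory(
    topology: str | Path,
    trajectory: str | Path | None = None,
    stride: int = 1,
) -> list[SolvatedFrame]:
    """Read a standard-format trajectory (GRO/PDB topology, XTC/DCD frames).

    Protein heavy atoms and water oxygens are extracted, coordinates converted
    from Angstrom to nm, frame times from ps to ns.
    """
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology), *([str(trajectory)] if trajectory else []))
        protein = u.select_atoms("protein and not name H*")
        water_o = u.select_atoms("(resname SOL HOH TIP3 WAT) and (name OW O OH2)")
        frames = []
        for ts in u.trajectory[::stride]:
            atoms: dict[int, dict[str, np.ndarray]] = {}
            for atom in protein:
                atoms.setdefault(int(atom.resid), {})[str(atom.name)] = (
                    atom.position.astype(float) / 10.0
                )
            frames.append(
                SolvatedFrame(
                    max(float(ts.time) / 1000.0, 0.0),
                    atoms,
                    water_o.positions.astype(float) / 10.0,
                )
            )
    return frames
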