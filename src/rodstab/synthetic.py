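"""Synthetic fixtures with known ground truth for every pipeline stage.

Each generator emulates one of the study's measurement types — a solvated
four-helix bundle opening under load, single-exponential FRAP recovery,
micropatterned two-ECM adhesion scenes, sigmoidal two-state melts, persistent
random-walk migration tracks — and returns the generated object together with
a ground-truth parameter dict, so generate -> analyze -> compare round trips
anchor the test suite.  All randomness flows through one seeded
``numpy.random.Generator`` per call; outputs written to disk get a JSON
sidecar of the ground truth.

The synthetic "helices" are straight dummy-atom chains at the corners of a
square prism: the analysis operators consume only coordinates, so geometric
fidelity (separations, anchor placement) is what matters, not physical helix
structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .frap import FrapRecord
from .imaging import AdhesionScene, BinaryMask, TrackSet, make_micropattern
from .melt import MeltCurve, two_state_signal
from .structure import DEFAULT_HELIX_RANGES, HelixBundle, Residue
from .trajectory import SolvatedFrame, brute_force_count

GENERATOR_KINDS = ("bundle_traj", "frap", "scene", "melt", "tracks")

#: Side of the square on whose corners the dummy helices stand, nm.  Chosen
#: so the core centroid sits 0.42 nm from every helix, inside the 0.5 nm
#: penetration cutoff.
CORE_SQUARE_NM = 0.6
#: Spacing of dummy residues along a helix axis, nm (~ alpha-helical rise).
RESIDUE_RISE_NM = 0.15


@dataclass(frozen=True)
class GeneratorSpec:
    """One fixture request: kind, ground-truth parameters, seed."""

    kind: str
    parameters: dict
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in GENERATOR_KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")


def write_sidecar(path: str | Path, truth: Mapping) -> None:
    """Write the ground-truth parameter dict next to a generated artifact."""
    Path(path).write_text(json.dumps(dict(truth), indent=2, default=float) + "\n")


# --- solvated bundle trajectories --------------------------------------------


def _helix_corners(square_nm: float, h4_shift_nm: float) -> dict[str, np.ndarray]:
    s = square_nm
    return {
        "H1": np.array([0.0, 0.0]),
        "H2": np.array([s, 0.0]),
        "H3": np.array([s, s]),
        "H4": np.array([0.0, s + h4_shift_nm]),
    }


def _bundle_atoms(
    square_nm: float, h4_shift_nm: float
) -> dict[int, dict[str, np.ndarray]]:
    """Dummy CA chains, one per helix; anchors 808 and 896 at equal height so
    the d3 distance is purely horizontal and opens linearly with the H4 shift."""
    corners = _helix_corners(square_nm, h4_shift_nm)
    z0 = {"H1": 0.0, "H2": 0.0, "H3": 0.0, "H4": 0.3}  # aligns z(896) with z(808)
    atoms: dict[int, dict[str, np.ndarray]] = {}
    for hid, (lo, hi) in DEFAULT_HELIX_RANGES.items():
        cx, cy = corners[hid]
        for num in range(lo, hi + 1):
            z = z0[hid] + (num - lo) * RESIDUE_RISE_NM
            atoms[num] = {"CA": np.array([cx, cy, z])}
    return atoms


def gen_bundle(square_nm: float = CORE_SQUARE_NM) -> HelixBundle:
    """Static synthetic bundle containing all pull/displacement anchors."""
    atoms = _bundle_atoms(square_nm, 0.0)
    residues = [
        Residue(num, "DUM", (("CA", xyz["CA"]),)) for num, xyz in sorted(atoms.items())
    ]
    return HelixBundle(residues, dict(DEFAULT_HELIX_RANGES))


def gen_bundle_trajectory(
    n_frames: int,
    open_rate_nm_per_ns: float = 0.0,
    n_core_waters: int | Callable[[float], int] = 0,
    seed: int = 0,
    dt_ns: float = 0.02,
    square_nm: float = CORE_SQUARE_NM,
    n_bulk_waters: int = 50,
    cutoff_nm: float = 0.5,
) -> tuple[list[SolvatedFrame], dict]:
    """Trajectory of an idealized bundle whose H1-H4 separation opens linearly.

    ``n_core_waters`` (an int or a function of time in ns) waters are placed
    near the core centroid so that exactly that many satisfy the penetration
    criterion in each frame — verified against the all-pairs brute-force
    counter before the frame is emitted.  ``n_bulk_waters`` decoys sit >= 3 nm
    outside the bundle.  Raises if the requested core schedule is infeasible
    (core opened beyond the cutoff).
    """
    if n_frames < 2:
        raise ValueError("need >= 2 frames")
    rng = np.random.default_rng(seed)
    want = n_core_waters if callable(n_core_waters) else (lambda t: int(n_core_waters))

    frames: list[SolvatedFrame] = []
    schedule: list[int] = []
    for i in range(n_frames):
        t = i * dt_ns
        shift = open_rate_nm_per_ns * t
        atoms = _bundle_atoms(square_nm, shift)
        corners = _helix_corners(square_nm, shift)
        core_xy = np.mean(list(corners.values()), axis=0)
        z_mid = 1.5  # mid-height of the dummy chains
        k = want(t)
        if k < 0:
            raise ValueError("negative core-water count requested")

        for attempt in range(20):
            jitter = 0.03 if attempt < 19 else 0.0
            core = np.column_stack(
                [
                    core_xy[0] + rng.uniform(-jitter, jitter, k),
                    core_xy[1] + rng.uniform(-jitter, jitter, k),
                    z_mid + rng.uniform(-jitter, jitter, k),
                ]
            ) if k else np.zeros((0, 3))
            theta = rng.uniform(0, 2 * np.pi, n_bulk_waters)
            radius = rng.uniform(3.0, 5.0, n_bulk_waters)
            bulk = np.column_stack(
                [
                    core_xy[0] + radius * np.cos(theta),
                    core_xy[1] + radius * np.sin(theta),
                    rng.uniform(-1.0, 4.0, n_bulk_waters),
                ]
            )
            frame = SolvatedFrame(t, atoms, np.vstack([core, bulk]))
            if brute_force_count(frame, DEFAULT_HELIX_RANGES, cutoff_nm) == k:
                break
        else:
            raise ValueError(
                f"infeasible water placement at t={t:g} ns: core too open for "
                f"{k} penetrating waters at cutoff {cutoff_nm} nm"
            )
        frames.append(frame)
        schedule.append(k)

    truth = {
        "kind": "bundle_traj",
        "seed": seed,
        "n_frames": n_frames,
        "dt_ns": dt_ns,
        "open_rate_nm_per_ns": open_rate_nm_per_ns,
        "square_nm": square_nm,
        "n_bulk_waters": n_bulk_waters,
        "cutoff_nm": cutoff_nm,
        "core_water_schedule": schedule,
        "d3_baseline_nm": square_nm,
    }
    return frames, truth


# --- FRAP --------------------------------------------------------------------


def gen_frap(
    mobile_fraction: float,
    half_time_s: float = 10.0,
    noise_sigma: float = 0.0,
    fading_rate: float = 0.0,
    seed: int = 0,
    dt_s: float = 0.5,
    pre_s: float = 5.0,
    post_s: float = 90.0,
    bleach_depth: float = 0.3,
    roi_level: float = 1000.0,
    cell_level: float = 5000.0,
) -> tuple[FrapRecord, dict]:
    """Raw two-channel FRAP record whose double-ratio normalization recovers
    F(t) = M (1 - exp(-k t)) exactly at zero noise.

    Acquisition fading exp(-fading_rate * t) multiplies both channels and so
    cancels in the normalization; ``noise_sigma`` is relative Gaussian noise
    applied to each channel independently.  Defaults mirror the study's
    acquisition: 0.5 s sampling, 5 s pre-bleach, 90 s post-bleach.
    """
    if not 0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile fraction must be in [0, 1]")
    if half_time_s <= 0:
        raise ValueError("half time must be > 0")
    rng = np.random.default_rng(seed)
    k = np.log(2) / half_time_s
    n_pre = int(round(pre_s / dt_s))
    n_post = int(round(post_s / dt_s)) + 1
    times = np.arange(n_pre + n_post) * dt_s
    t_post = times[n_pre:] - times[n_pre]

    g = np.ones_like(times)
    g[n_pre:] = bleach_depth + (1.0 - bleach_depth) * mobile_fraction * (
        1.0 - np.exp(-k * t_post)
    )
    fade = np.exp(-fading_rate * times)
    b = roi_level * fade * g
    c = cell_level * fade
    if noise_sigma > 0:
        b = np.clip(b * (1.0 + noise_sigma * rng.standard_normal(times.size)), 0, None)
        c = np.clip(c * (1.0 + noise_sigma * rng.standard_normal(times.size)), 1e-9, None)

    rec = FrapRecord(times, b, c, bleach_index=n_pre)
    truth = {
        "kind": "frap",
        "seed": seed,
        "mobile_fraction": mobile_fraction,
        "half_time_s": half_time_s,
        "rate_k": k,
        "noise_sigma": noise_sigma,
        "fading_rate": fading_rate,
        "dt_s": dt_s,
        "bleach_depth": bleach_depth,
    }
    return rec, truth


# --- micropattern adhesion scenes --------------------------------------------


def gen_scene(
    fn_adhesion_fraction: float,
    pattern_coverage: float = 0.5625,
    n_adhesions: int = 500,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.1,
    pitch_um: float = 6.4,
    max_tries: int = 500,
) -> tuple[AdhesionScene, dict[str, BinaryMask], dict]:
    """Micropatterned adhesion scene with a known Fn-area fraction.

    The pattern is a square lattice at ``pattern_coverage`` (square/pitch =
    sqrt(coverage); the study's substrates used 0.75 -> 56% coverage).  The
    default pitch divides the field exactly, so the rasterized coverage equals
    the requested one without partial-period bias.
    Elliptical adhesions are placed entirely on or entirely off the Fn
    squares, greedily steering the painted area fraction toward
    ``fn_adhesion_fraction``.  The talin channel carries cytosolic background
    plus adhesion enrichment; the paxillin channel mirrors the adhesions.
    """
    from skimage.draw import ellipse as draw_ellipse
    from skimage.filters import gaussian

    if not 0 <= fn_adhesion_fraction <= 1:
        raise ValueError("fn_adhesion_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    field_um = shape[0] * pixel_size_um
    square_um = pitch_um * float(np.sqrt(pattern_coverage))
    pattern = make_micropattern(field_um, square_um, pitch_um, pixel_size_um)
    pat = pattern.data

    adh = np.zeros(shape, dtype=bool)
    margin = int(1.0 / pixel_size_um)
    for _ in range(n_adhesions):
        on_px = int((adh & pat).sum())
        total_px = int(adh.sum())
        # steer the painted on-pattern area fraction toward the target; at an
        # exact tie (including the first adhesion) follow the majority side
        if on_px < fn_adhesion_fraction * total_px:
            go_on = True
        elif on_px == fn_adhesion_fraction * total_px:
            go_on = fn_adhesion_fraction > 0.5
        else:
            go_on = False
        for _try in range(max_tries):
            r = rng.uniform(margin, shape[0] - margin)
            c = rng.uniform(margin, shape[1] - margin)
            a_px = rng.uniform(0.4, 0.9) / pixel_size_um
            b_px = rng.uniform(0.2, 0.45) / pixel_size_um
            rot = rng.uniform(0, np.pi)
            rr, cc = draw_ellipse(r, c, a_px, b_px, shape=shape, rotation=rot)
            if rr.size == 0:
                continue
            covered = pat[rr, cc]
            if (go_on and covered.all()) or (not go_on and not covered.any()):
                adh[rr, cc] = True
                break
        else:
            raise RuntimeError(
                f"could not place adhesion {'on' if go_on else 'off'} the pattern "
                f"after {max_tries} tries"
            )

    # cell footprint: central disk covering most of the field
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cy, cx = shape[0] / 2, shape[1] / 2
    cell = ((yy - cy) ** 2 + (xx - cx) ** 2) <= (0.48 * shape[0]) ** 2

    talin = 30.0 * cell + 120.0 * adh + np.clip(
        3.0 * rng.standard_normal(shape), -9, None
    )
    paxillin = gaussian(adh * 100.0, sigma=0.2 / pixel_size_um, preserve_range=True)
    paxillin += 2.0 * np.abs(rng.standard_normal(shape))
    scene = AdhesionScene(
        {
            "talin": np.clip(talin, 0, None),
            "paxillin": np.clip(paxillin, 0, None),
            "pattern": pat * 100.0,
        },
        pixel_size_um,
    )
    masks = {
        "pattern": pattern,
        "adhesion": BinaryMask(adh, "adhesion", pixel_size_um),
        "cell": BinaryMask(cell, "cell", pixel_size_um),
    }
    realized = float((adh & pat).sum() / adh.sum()) if adh.any() else float("nan")
    truth = {
        "kind": "scene",
        "seed": seed,
        "fn_adhesion_fraction": fn_adhesion_fraction,
        "realized_fn_fraction": realized,
        "pattern_coverage": pattern_coverage,
        "n_adhesions": n_adhesions,
        "pixel_size_um": pixel_size_um,
        "pitch_um": pitch_um,
        "square_um": square_um,
    }
    return scene, masks, truth


# --- melts and tracks --------------------------------------------------------


def gen_melt(
    tm_C: float,
    dH_kJ_mol: float = 200.0,
    baseline_folded: tuple[float, float] = (-15000.0, 10.0),
    baseline_unfolded: tuple[float, float] = (-4000.0, 5.0),
    noise: float = 0.0,
    seed: int = 0,
    t_min_C: float = 20.0,
    t_max_C: float = 90.0,
    step_C: float = 2.0,
) -> tuple[MeltCurve, dict]:
    """Model-exact two-state melt curve; ``noise`` is the Gaussian sigma as a
    fraction of the clean signal span.  Defaults mimic a 220 nm CD melt in
    2 degC steps with mildly sloped baselines."""
    rng = np.random.default_rng(seed)
    tC = np.arange(t_min_C, t_max_C + step_C / 2, step_C)
    clean = two_state_signal(tC, tm_C, dH_kJ_mol, *baseline_folded, *baseline_unfolded)
    y = clean + noise * np.ptp(clean) * rng.standard_normal(tC.size)
    truth = {
        "kind": "melt",
        "seed": seed,
        "tm_C": tm_C,
        "dH_kJ_mol": dH_kJ_mol,
        "baseline_folded": baseline_folded,
        "baseline_unfolded": baseline_unfolded,
        "noise": noise,
        "step_C": step_C,
    }
    return MeltCurve(tC, y), truth


def gen_tracks(
    speed_um_per_h: float = 30.0,
    persistence: float = 0.8,
    duration_h: float = 12.0,
    dt_min: float = 2.0,
    n_tracks: int = 100,
    seed: int = 0,
) -> tuple[TrackSet, dict]:
    """Persistent random walks with exact path speed.

    Step length is exactly speed * dt, so the per-track path speed equals the
    generating parameter; ``persistence`` in [0, 1] scales down the per-step
    heading noise (1 -> straight line).  Defaults mirror the study's 12 h
    time-lapse at 2 min intervals.
    """
    if not 0 <= persistence <= 1:
        raise ValueError("persistence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_h * 60 / dt_min))
    step_len = speed_um_per_h * dt_min / 60.0
    turn_sigma = (1.0 - persistence) * 1.0  # rad per step
    tracks = []
    for i in range(n_tracks):
        theta = rng.uniform(0, 2 * np.pi)
        xy = np.zeros((n_steps + 1, 2))
        xy[0] = rng.uniform(0, 500, 2)
        for j in range(n_steps):
            theta += turn_sigma * rng.standard_normal()
            xy[j + 1] = xy[j] + step_len * np.array([np.cos(theta), np.sin(theta)])
        times = np.arange(n_steps + 1) * dt_min
        tracks.append((f"track{i:03d}", times, xy))
    truth = {
        "kind": "tracks",
        "seed": seed,
        "speed_um_per_h": speed_um_per_h,
        "persistence": persistence,
        "duration_h": duration_h,
        "dt_min": dt_min,
        "n_tracks": n_tracks,
    }
    return TrackSet(tracks), truth
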