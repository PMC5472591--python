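"""Talin-1 R3 domain model: helix topology, mutations, conservation, pull plans.

The R3 subdomain of the talin-1 rod (mouse numbering, residues ~795-911) is a
four-helix bundle whose force-induced unfolding exposes cryptic vinculin
binding sites.  This module holds the residue-indexed bundle representation,
the serine-substitution mutant builder (1S-4S), per-column sequence
conservation profiling of an aligned FASTA, and construction of the
constant-force steered-MD pull plan: H1 anchor alpha-carbons fixed, H4 anchor
alpha-carbons pulled along +z after aligning the V808-G896 vector to the z
axis.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

# --- domain constants (mouse talin-1 numbering) ------------------------------

#: Default helix ranges (inclusive). The anchor and mutation residues pin the
#: ranges; exact boundaries are configurable on every entry point.
DEFAULT_HELIX_RANGES: dict[str, tuple[int, int]] = {
    "H1": (796, 815),
    "H2": (824, 849),
    "H3": (856, 880),
    "H4": (886, 909),
}

#: Alpha-carbons held fixed during pulling (H1: Q800, T804, V808, S815).
FIXED_ANCHORS: tuple[int, ...] = (800, 804, 808, 815)
#: Alpha-carbons pulled at constant force (H4: Q888, G896, A900, A904).
PULLED_ANCHORS: tuple[int, ...] = (888, 896, 900, 904)
#: H1-H4 displacement vectors followed during pulling/relaxation.
DISPLACEMENT_VECTORS: dict[str, tuple[int, int]] = {
    "d1": (800, 904),
    "d2": (804, 900),
    "d3": (808, 896),
    "d4": (815, 888),
}
#: Residue pair whose alpha-carbon vector defines the pull axis (d3).
ORIENTATION_PAIR: tuple[int, int] = (808, 896)
#: Simulation box, nm.
DEFAULT_BOX_NM: tuple[float, float, float] = (10.0, 10.0, 30.0)
#: Constant pulling force, pN.
DEFAULT_FORCE_PN: float = 150.0

#: Hydrophobic-core destabilizing substitutions, in the order the cumulative
#: nS constructs add them: 1S = I805S, 2S adds I812S, 3S adds L890S,
#: 4S adds L897S.
MUTATION_LADDER: tuple[tuple[int, str, str], ...] = (
    (805, "I", "S"),
    (812, "I", "S"),
    (890, "L", "S"),
    (897, "L", "S"),
)


# --- types -------------------------------------------------------------------

@dataclass(frozen=True)
class Residue:
    """One residue: author-numbered, with named atom coordinates in nm."""

    number: int
    name: str  # 3-letter code
    atoms: tuple[tuple[str, np.ndarray], ...]

    def atom(self, atom_name: str) -> np.ndarray:
        for name, xyz in self.atoms:
            if name == atom_name:
                return xyz
        raise KeyError(
            f"residue {self.number} ({self.name}) has no atom {atom_name!r}"
        )

    def heavy_atoms(self) -> list[np.ndarray]:
        """Coordinates of non-hydrogen atoms."""
        return [xyz for name, xyz in self.atoms if not name.startswith("H")]


@dataclass
class HelixBundle:
    """Residue-indexed four-helix bundle with per-helix residue ranges.

    ``helix_ranges`` maps H1..H4 to inclusive (first, last) residue numbers;
    the ranges must be disjoint and ascending, and every pull/displacement
    anchor must fall inside its declared helix.
    """

    residues: list[Residue]
    helix_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_HELIX_RANGES)
    )

    def __post_init__(self) -> None:
        self._by_number = {r.number: r for r in self.residues}
        ordered = [self.helix_ranges[h] for h in ("H1", "H2", "H3", "H4")]
        for (a0, a1), (b0, b1) in zip(ordered, ordered[1:]):
            if not (a0 <= a1 < b0 <= b1):
                raise ValueError(
                    f"helix ranges must be disjoint and ascending: {self.helix_ranges}"
                )
        # anchors that exist in the bundle must sit inside their declared helix
        for helix, anchors in (("H1", FIXED_ANCHORS), ("H4", PULLED_ANCHORS)):
            lo, hi = self.helix_ranges[helix]
            for num in anchors:
                if num in self._by_number and not lo <= num <= hi:
                    raise ValueError(
                        f"anchor residue {num} outside declared {helix} range"
                    )
        for res in self.residues:
            for name, xyz in res.atoms:
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(
                        f"non-finite coordinate on residue {res.number} atom {name}"
                    )

    def residue(self, number: int) -> Residue:
        try:
            return self._by_number[number]
        except KeyError:
            raise KeyError(f"bundle has no residue {number}") from None

    def __contains__(self, number: int) -> bool:
        return number in self._by_number

    def alpha_carbon(self, number: int) -> np.ndarray:
        return self.residue(number).atom("CA")

    def helix_residues(self, helix_id: str) -> list[Residue]:
        lo, hi = self.helix_ranges[helix_id]
        return [r for r in self.residues if lo <= r.number <= hi]

    def helix_heavy_coords(self, helix_id: str) -> np.ndarray:
        """(n, 3) heavy-atom coordinates of one helix, nm."""
        coords = [
            xyz for res in self.helix_residues(helix_id) for xyz in res.heavy_atoms()
        ]
        if not coords:
            raise ValueError(f"helix {helix_id} has no heavy atoms")
        return np.asarray(coords, dtype=float)

    def all_coords(self) -> np.ndarray:
        return np.asarray(
            [xyz for res in self.residues for _, xyz in res.atoms], dtype=float
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "HelixBundle":
        """Apply the rigid motion x -> R x + t to every atom."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_res = [
            Residue(
                r.number,
                r.name,
                tuple((name, rotation @ xyz + translation) for name, xyz in r.atoms),
            )
            for r in self.residues
        ]
        return HelixBundle(new_res, dict(self.helix_ranges))


@dataclass(frozen=True)
class MutationSet:
    """A labelled set of point substitutions, e.g. the 4S construct."""

    substitutions: tuple[tuple[int, str, str], ...]
    label: str = ""

    def __post_init__(self) -> None:
        numbers = [n for n, _, _ in self.substitutions]
        if len(numbers) != len(set(numbers)):
            raise ValueError("duplicate residue numbers in mutation set")
        if self.label and self.label != "WT" and self.label.endswith("S"):
            head = self.label[:-1]
            if head.isdigit():
                n = int(head)
                expected = MUTATION_LADDER[:n]
                if tuple(self.substitutions) != expected:
                    raise ValueError(
                        f"label {self.label!r} requires the first {n} ladder "
                        f"substitutions {expected}, got {self.substitutions}"
                    )

    @classmethod
    def from_label(cls, label: str) -> "MutationSet":
        """Build WT or a cumulative nS construct (1S..4S)."""
        if label == "WT":
            return cls((), "WT")
        if label.endswith("S") and label[:-1].isdigit():
            n = int(label[:-1])
            if 1 <= n <= len(MUTATION_LADDER):
                return cls(MUTATION_LADDER[:n], label)
        raise ValueError(f"unknown construct label {label!r}")

    def swapped(self) -> "MutationSet":
        """The inverse set (to/from exchanged); applying both is the identity."""
        return MutationSet(
            tuple((n, to, frm) for n, frm, to in self.substitutions),
            label=f"rev({self.label})" if self.label else "",
        )


@dataclass(frozen=True)
class PullPlan:
    """Declarative constant-force pulling setup (no engine run).

    ``fixed_atoms`` / ``pulled_atoms`` list (residue_number, atom_name) pairs,
    force in pN along the unit ``force_direction`` (+z after orientation),
    inside ``box_nm``; ``orientation_pair`` is the residue pair whose
    alpha-carbon vector is aligned with the pull axis.
    """

    fixed_atoms: tuple[tuple[int, str], ...]
    pulled_atoms: tuple[tuple[int, str], ...]
    force_pN: float
    force_direction: tuple[float, float, float]
    box_nm: tuple[float, float, float]
    orientation_pair: tuple[int, int]

    def __post_init__(self) -> None:
        norm = math.sqrt(sum(c * c for c in self.force_direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("force_direction must be a unit vector")
        if set(self.fixed_atoms) & set(self.pulled_atoms):
            raise ValueError("fixed and pulled atom sets overlap")


@dataclass(frozen=True)
class ConservationColumn:
    alignment_column: int  # 0-based alignment column
    reference_residue: int | None  # author residue number, None at ref gaps
    score: float  # fraction of non-gap rows matching the modal residue
    all_gap: bool = False


@dataclass(frozen=True)
class ConservationProfile:
    columns: tuple[ConservationColumn, ...]

    def scores(self) -> np.ndarray:
        return np.asarray([c.score for c in self.columns])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "alignment_column": [c.alignment_column for c in self.columns],
                "reference_residue": [c.reference_residue for c in self.columns],
                "score": [c.score for c in self.columns],
                "all_gap": [c.all_gap for c in self.columns],
            }
        )


# --- mutations ---------------------------------------------------------------

def apply_mutations(sequence: str, muts: MutationSet, start_number: int) -> str:
    """Apply point substitutions to a 1-letter sequence.

    ``start_number`` is the author residue number of ``sequence[0]``.  Every
    substitution's ``from_aa`` must match the current sequence; mismatches and
    out-of-range residue numbers are rejected naming the offending residue.
    """
    seq = list(sequence)
    last = start_number + len(seq) - 1
    for number, frm, to in muts.substitutions:
        if not start_number <= number <= last:
            raise ValueError(
                f"residue {number} outside sequence range {start_number}-{last}"
            )
        i = number - start_number
        if seq[i] != frm:
            raise ValueError(
                f"residue {number}: expected {frm!r} but sequence has {seq[i]!r}"
            )
        seq[i] = to
    return "".join(seq)


# --- orientation -------------------------------------------------------------

def _minimal_rotation(v: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector v onto unit vector target by the
    smallest angle (Rodrigues)."""
    c = float(np.dot(v, target))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # antiparallel: rotate pi about any axis orthogonal to v
        axis = np.cross(v, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(v, np.array([0.0, 1.0, 0.0]))
        axis /= np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + 2.0 * (K @ K)
    axis = np.cross(v, target)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def orient_to_axis(
    bundle: HelixBundle,
    a: int = ORIENTATION_PAIR[0],
    b: int = ORIENTATION_PAIR[1],
    center: Sequence[float] | None = None,
) -> HelixBundle:
    """Rigidly rotate the bundle so the a->b alpha-carbon vector points along +z.

    The rotation is the minimal rotation taking a->b onto +z, applied about the
    bundle centroid; if ``center`` is given the centroid is then translated
    there (e.g. the box center).  Pairwise distances are preserved exactly up
    to floating point.
    """
    ca_a = bundle.alpha_carbon(a)
    ca_b = bundle.alpha_carbon(b)
    v = ca_b - ca_a
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError(f"degenerate orientation anchors: residues {a} and {b} coincide")
    R = _minimal_rotation(v / norm, np.array([0.0, 0.0, 1.0]))
    centroid = bundle.all_coords().mean(axis=0)
    target = centroid if center is None else np.asarray(center, dtype=float)
    # x -> R (x - centroid) + target
    return bundle.transformed(R, target - R @ centroid)


# --- pull plan ---------------------------------------------------------------

def build_pull_plan(
    bundle: HelixBundle,
    force_pN: float = DEFAULT_FORCE_PN,
    box_nm: tuple[float, float, float] = DEFAULT_BOX_NM,
) -> PullPlan:
    """Construct the constant-force pull plan for a bundle.

    Fixes the four H1 anchor alpha-carbons, pulls the four H4 anchor
    alpha-carbons at ``force_pN`` along +z (the axis the V808-G896 vector is
    oriented to).  ``force_pN`` = 0 is valid (equilibration mode).
    """
    for num in FIXED_ANCHORS + PULLED_ANCHORS:
        if num not in bundle:
            raise ValueError(f"bundle lacks anchor residue {num}")
        bundle.alpha_carbon(num)  # raises KeyError naming the residue if no CA
    if force_pN < 0:
        raise ValueError("force must be >= 0 pN")
    return PullPlan(
        fixed_atoms=tuple((n, "CA") for n in FIXED_ANCHORS),
        pulled_atoms=tuple((n, "CA") for n in PULLED_ANCHORS),
        force_pN=float(force_pN),
        force_direction=(0.0, 0.0, 1.0),
        box_nm=tuple(float(x) for x in box_nm),
        orientation_pair=ORIENTATION_PAIR,
    )


def write_pull_plan(plan: PullPlan, path: str | Path) -> None:
    """Write the plan as a flat key-value text file."""
    lines = [
        "# constant-force pulling plan",
        "fixed_atoms = " + ", ".join(f"{n}:{a}" for n, a in plan.fixed_atoms),
        "pulled_atoms = " + ", ".join(f"{n}:{a}" for n, a in plan.pulled_atoms),
        f"force_pN = {plan.force_pN:g}",
        "force_direction = {:g} {:g} {:g}".format(*plan.force_direction),
        "box_nm = {:g} {:g} {:g}".format(*plan.box_nm),
        f"orientation_pair = {plan.orientation_pair[0]} {plan.orientation_pair[1]}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_index_groups(plan: PullPlan, path: str | Path) -> None:
    """Write fixed/pulled residue groups as a GROMACS-style .ndx listing."""
    lines = [
        "[ fixed_H1 ]",
        " ".join(str(n) for n, _ in plan.fixed_atoms),
        "[ pulled_H4 ]",
        " ".join(str(n) for n, _ in plan.pulled_atoms),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# --- conservation ------------------------------------------------------------

def conservation_profile(
    msa,
    reference_id: str,
    start_number: int = 795,
) -> ConservationProfile:
    """Per-column conservation of an alignment, mapped to reference numbering.

    ``msa`` is a Bio.Align.MultipleSeqAlignment or a path to an aligned FASTA.
    The score of a column is the fraction of non-gap rows carrying the column's
    modal residue; gaps are excluded from the denominator and an all-gap column
    scores 0.  Columns where the reference row is gapped map to no residue
    number; elsewhere the reference residue numbering starts at
    ``start_number``.
    """
    if isinstance(msa, (str, Path)):
        from Bio import AlignIO

        msa = AlignIO.read(str(msa), "fasta")
    rows = [str(rec.seq).upper() for rec in msa]
    ids = [rec.id for rec in msa]
    if not rows:
        raise ValueError("empty alignment")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    try:
        ref_row = rows[ids.index(reference_id)]
    except ValueError:
        raise ValueError(f"reference {reference_id!r} not in alignment") from None

    columns = []
    ref_number = start_number
    for j in range(length):
        col = [r[j] for r in rows]
        non_gap = [c for c in col if c not in "-."]
        if non_gap:
            modal, count = Counter(non_gap).most_common(1)[0]
            score = count / len(non_gap)
            all_gap = False
        else:
            score = 0.0
            all_gap = True
        if ref_row[j] in "-.":
            ref_res = None
        else:
            ref_res = ref_number
            ref_number += 1
        columns.append(ConservationColumn(j, ref_res, score, all_gap))
    return ConservationProfile(tuple(columns))


# --- file readers ------------------------------------------------------------

def load_bundle(
    path: str | Path,
    helix_ranges: Mapping[str, tuple[int, int]] | None = None,
) -> HelixBundle:
    """Read a PDB/GRO structure into a HelixBundle (coordinates in nm).

    Only residues inside the helix ranges are retained; MDAnalysis handles the
    format details, coordinates are converted from Angstrom to nm.
    """
    import warnings

    import MDAnalysis as mda

    ranges = dict(helix_ranges or DEFAULT_HELIX_RANGES)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    wanted = set()
    for lo, hi in ranges.values():
        wanted.update(range(lo, hi + 1))
    residues = []
    for res in u.residues:
        if res.resid not in wanted:
            continue
        atoms = tuple(
            (atom.name, atom.position.astype(float) / 10.0) for atom in res.atoms
        )
        residues.append(Residue(int(res.resid), str(res.resname), atoms))
    if not residues:
        raise ValueError(f"no residues inside helix ranges found in {path}")
    return HelixBundle(residues, ranges)
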