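"""Membrane-helix trajectory descriptors.

Works on multi-frame coordinates of a helix (plus lipid atoms) and extracts
the descriptors used to characterise how an amphipathic helix sits in a
bilayer whose leaflets are horizontal (membrane plane = XY):

* the signed tilt angle α between the helix central axis and the membrane
  plane, positive when the N→C axis points toward +z (C terminus higher);
* residue–lipid contacts, formed when the minimum distance between a
  residue's heavy atoms and lipid phosphate head atoms is strictly below
  a cutoff (0.45 nm by default);
* the maximum persistence time of each contact — its longest unbroken run
  of frames times the frame interval — and the top-k longest-lived
  residue/lipid-class contact pairs;
* the complex "compactness" r: the per-frame minimum heavy-atom distance
  between a reference residue and the helix.

Trajectories are interchanged as multi-model PDB (coordinates stored in Å
on disk, nm in memory) so the analysis needs no binary MD formats.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist

__all__ = [
    "Trajectory",
    "TiltSeries",
    "ContactSummary",
    "read_trajectory",
    "write_trajectory",
    "helix_axis",
    "tilt_angle",
    "min_distance_series",
    "contact_series",
    "max_persistence",
    "top_contacts",
    "compactness_series",
    "align_frames_to_x",
]

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 0.45  # nm, strict '<'

#: Residue names treated as lipids (phosphate pseudo-beads carry the
#: headgroup class directly; common full-lipid names map to their class).
LIPID_CLASS_BY_RESNAME = {
    "PE": "PE", "PC": "PC", "PI": "PI",
    "DOPE": "PE", "DOPC": "PC", "POPE": "PE", "POPC": "PC",
    "SAPI": "PI", "POPI": "PI",
}

_PHOSPHATE_NAME = re.compile(r"^P\d*$|^O\d*P\d*$|^OP\d+$")


def _is_phosphate(atom_name: str) -> bool:
    return bool(_PHOSPHATE_NAME.match(atom_name.strip()))


@dataclass
class Trajectory:
    """Frames × atoms coordinates (nm) with per-atom metadata.

    ``atoms`` columns: atom_name, res_id, res_name, chain ('protein' or
    'lipid'), element, heavy (bool), phosphate (bool). ``dt`` is the time
    per saved frame in ns; ``box`` optional orthorhombic dimensions (nm).
    """

    coords: np.ndarray  # (n_frames, n_atoms, 3), nm
    atoms: pd.DataFrame
    dt: float
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"metadata rows {len(self.atoms)}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if not self.dt > 0:
            raise ValueError("frame interval dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def duration(self) -> float:
        """Total sampled duration in ns (frames × dt)."""
        return self.n_frames * self.dt

    def atom_indices(
        self,
        res_ids: Sequence[int] | None = None,
        chain: str | None = None,
        heavy_only: bool = False,
        phosphate_only: bool = False,
        lipid_class: str | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching all the given criteria."""
        mask = np.ones(len(self.atoms), dtype=bool)
        if res_ids is not None:
            mask &= self.atoms["res_id"].isin(list(res_ids)).to_numpy()
        if chain is not None:
            mask &= (self.atoms["chain"] == chain).to_numpy()
        if heavy_only:
            mask &= self.atoms["heavy"].to_numpy()
        if phosphate_only:
            mask &= self.atoms["phosphate"].to_numpy()
        if lipid_class is not None:
            mask &= (self.atoms["lipid_class"] == lipid_class).to_numpy()
        return np.flatnonzero(mask)

    def ca_indices(self, res_ids: Sequence[int] | None = None) -> np.ndarray:
        """Cα atom indices of the protein chain, ordered by residue number."""
        sel = self.atoms[
            (self.atoms["chain"] == "protein") & (self.atoms["atom_name"] == "CA")
        ]
        if res_ids is not None:
            sel = sel[sel["res_id"].isin(list(res_ids))]
        return sel.sort_values("res_id").index.to_numpy()


@dataclass
class TiltSeries:
    """Per-frame signed tilt angle α in degrees, with summary statistics."""

    alpha: np.ndarray  # degrees, each in [-90, 90]
    dt: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.alpha))

    @property
    def sd(self) -> float:
        return float(np.std(self.alpha, ddof=1)) if len(self.alpha) > 1 else 0.0

    @property
    def sem(self) -> float:
        """Standard error of the mean over frames."""
        return self.sd / np.sqrt(len(self.alpha)) if len(self.alpha) > 1 else 0.0


@dataclass
class ContactSummary:
    """One residue / lipid-class contact: boolean series and persistence."""

    res_id: int
    lipid_class: str
    series: np.ndarray  # per-frame bool
    max_persistence: float  # ns
    cutoff: float  # nm


def _atom_metadata(structure: AtomArray, lipid_resnames: dict[str, str]) -> pd.DataFrame:
    elements = [e.strip().upper() for e in structure.element]
    names = [n.strip() for n in structure.atom_name]
    res_names = [r.strip() for r in structure.res_name]
    lipid_class = [lipid_resnames.get(r, "") for r in res_names]
    return pd.DataFrame(
        {
            "atom_name": names,
            "res_id": structure.res_id.astype(int),
            "res_name": res_names,
            "chain": ["lipid" if c else "protein" for c in lipid_class],
            "lipid_class": lipid_class,
            "element": elements,
            "heavy": [e != "H" for e in elements],
            "phosphate": [_is_phosphate(n) for n in names],
        }
    )


def read_trajectory(
    path: str | Path,
    frame_interval: float,
    lipid_resnames: dict[str, str] | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a trajectory (Å on disk → nm in memory).

    Heavy-atom flags come from the element column (≠ H); phosphate flags
    from atom names (P, P1, O1P, OP1, ...). Residues whose names appear in
    ``lipid_resnames`` (default: PE/PC/PI beads and common phospholipids)
    are tagged as the lipid chain, everything else as protein. Frames with
    differing atom counts are rejected.
    """
    if lipid_resnames is None:
        lipid_resnames = LIPID_CLASS_BY_RESNAME
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent models
        raise ValueError(f"inconsistent models in {path}: {exc}") from exc
    coords = stack.coord
    if coords.ndim == 2:  # single model read as AtomArray
        coords = coords[None, :, :]
        first = stack
    else:
        first = stack[0]
    atoms = _atom_metadata(first, lipid_resnames)
    return Trajectory(coords=np.asarray(coords) / 10.0, atoms=atoms, dt=frame_interval)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB (nm → Å)."""
    n = traj.n_atoms
    template = AtomArray(n)
    template.coord = np.zeros((n, 3), dtype=np.float32)
    template.chain_id = np.where(traj.atoms["chain"] == "lipid", "L", "A").astype("U4")
    template.res_id = traj.atoms["res_id"].to_numpy(dtype=int)
    template.res_name = traj.atoms["res_name"].to_numpy(dtype="U5")
    template.atom_name = traj.atoms["atom_name"].to_numpy(dtype="U6")
    template.element = traj.atoms["element"].to_numpy(dtype="U2")
    template.hetero = (traj.atoms["chain"] == "lipid").to_numpy()
    stack = AtomArrayStack(traj.n_frames, n)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = (traj.coords * 10.0).astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def helix_axis(frame: np.ndarray, ca_indices: Sequence[int]) -> np.ndarray:
    """Central axis of the helix: unit principal axis of its Cα cloud.

    The principal-axis fit is robust to end fraying; orientation is fixed by
    the N→C chord (first to last Cα in the given index order), so reversing
    the index order flips the axis.
    """
    pts = np.asarray(frame)[list(ca_indices)]
    if pts.shape[0] < 3:
        raise ValueError("helix axis needs at least 3 Cα positions")
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("degenerate Cα cloud: all positions coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    chord = pts[-1] - pts[0]
    if axis @ chord < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def tilt_angle(traj: Trajectory, ca_indices: Sequence[int] | None = None) -> TiltSeries:
    """Per-frame signed tilt α = arcsin(axis_z) in degrees.

    α > 0 when the N→C axis points toward +z, i.e. the helix points upward
    from the N to the C terminus; α < 0 when the C terminus dips below the
    membrane plane.
    """
    if ca_indices is None:
        ca_indices = traj.ca_indices()
    alpha = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        axis = helix_axis(traj.coords[t], ca_indices)
        alpha[t] = np.degrees(np.arcsin(np.clip(axis[2], -1.0, 1.0)))
    return TiltSeries(alpha=alpha, dt=traj.dt)


def _min_image(diff: np.ndarray, box: np.ndarray) -> np.ndarray:
    return diff - box * np.round(diff / box)


def min_distance_series(
    traj: Trajectory,
    indices_a: Sequence[int],
    indices_b: Sequence[int],
    use_pbc: bool = False,
) -> np.ndarray:
    """Per-frame minimum pairwise distance (nm) between two atom selections.

    With ``use_pbc`` and an orthorhombic box, distances use the
    minimum-image convention; otherwise plain Euclidean distances.
    """
    ia = np.asarray(list(indices_a), dtype=int)
    ib = np.asarray(list(indices_b), dtype=int)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both atom selections must be non-empty")
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        a = traj.coords[t, ia]
        b = traj.coords[t, ib]
        if use_pbc and traj.box is not None:
            diff = a[:, None, :] - b[None, :, :]
            diff = _min_image(diff, np.asarray(traj.box))
            d = np.sqrt((diff**2).sum(axis=-1))
        else:
            d = cdist(a, b)
        out[t] = d.min()
    return out


def contact_series(
    distances: np.ndarray, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> np.ndarray:
    """Boolean contact series: contact formed when d < cutoff (strict)."""
    d = np.asarray(distances, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("distance series must be finite")
    return d < cutoff


def max_persistence(series: np.ndarray, dt: float) -> float:
    """Longest unbroken run of True frames × dt (ns).

    An empty series returns 0 with a warning.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    s = np.asarray(series, dtype=bool)
    if s.size == 0:
        logger.warning("max_persistence of an empty series is 0")
        return 0.0
    padded = np.concatenate(([False], s, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    if starts.size == 0:
        return 0.0
    return float((ends - starts).max() * dt)


def top_contacts(
    traj: Trajectory,
    protein_res_ids: Sequence[int] | None = None,
    k: int = 10,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    use_pbc: bool = False,
) -> list[ContactSummary]:
    """The k longest-lived residue / lipid-class contacts.

    For each protein residue (heavy atoms) and each lipid headgroup class
    present (phosphate atoms), the minimum-distance series is thresholded
    at ``cutoff`` and the maximum persistence computed; pairs are ranked by
    descending persistence, ties broken by ascending residue number then
    lipid class. Pairs that never form a contact are excluded.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if protein_res_ids is None:
        protein_res_ids = sorted(
            traj.atoms.loc[traj.atoms["chain"] == "protein", "res_id"].unique()
        )
    classes = sorted(
        c for c in traj.atoms.loc[traj.atoms["chain"] == "lipid", "lipid_class"].unique() if c
    )
    summaries: list[ContactSummary] = []
    for res in protein_res_ids:
        res_atoms = traj.atom_indices(res_ids=[res], chain="protein", heavy_only=True)
        if res_atoms.size == 0:
            continue
        for cls in classes:
            lipid_atoms = traj.atom_indices(
                chain="lipid", phosphate_only=True, lipid_class=cls
            )
            if lipid_atoms.size == 0:
                continue
            d = min_distance_series(traj, res_atoms, lipid_atoms, use_pbc=use_pbc)
            series = contact_series(d, cutoff)
            pers = max_persistence(series, traj.dt)
            if pers > 0:
                summaries.append(
                    ContactSummary(
                        res_id=int(res),
                        lipid_class=cls,
                        series=series,
                        max_persistence=pers,
                        cutoff=cutoff,
                    )
                )
    summaries.sort(key=lambda c: (-c.max_persistence, c.res_id, c.lipid_class))
    return summaries[:k]


def compactness_series(
    traj: Trajectory,
    reference_res_id: int,
    ah_res_ids: Sequence[int],
    use_pbc: bool = False,
) -> np.ndarray:
    """Complex compactness r: per-frame minimum heavy-atom distance (nm)
    between a reference residue and the helix residues."""
    ref = traj.atom_indices(res_ids=[reference_res_id], heavy_only=True)
    ah = traj.atom_indices(res_ids=ah_res_ids, chain="protein", heavy_only=True)
    if ref.size == 0 or ah.size == 0:
        raise ValueError("reference and helix selections need ≥ 1 heavy atom")
    return min_distance_series(traj, ref, ah, use_pbc=use_pbc)


def align_frames_to_x(
    traj: Trajectory, ca_indices: Sequence[int] | None = None
) -> Trajectory:
    """Rotate each frame about z so the N→C axis projects onto +x.

    z-coordinates are untouched, so the tilt series is invariant. A frame
    whose axis is (numerically) vertical has no defined projection and is
    left unrotated with a warning.
    """
    if ca_indices is None:
        ca_indices = traj.ca_indices()
    coords = traj.coords.copy()
    for t in range(traj.n_frames):
        axis = helix_axis(coords[t], ca_indices)
        px, py = axis[0], axis[1]
        norm = np.hypot(px, py)
        if norm < 1e-12:
            logger.warning("frame %d: vertical helix axis, left unrotated", t)
            continue
        cos_t, sin_t = px / norm, py / norm
        # rotate by -atan2(py, px) about z
        rot = np.array([[cos_t, sin_t, 0.0], [-sin_t, cos_t, 0.0], [0.0, 0.0, 1.0]])
        coords[t] = coords[t] @ rot.T
    return Trajectory(coords=coords, atoms=traj.atoms.copy(), dt=traj.dt, box=traj.box)
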