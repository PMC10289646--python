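"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all pure functions of (spec, seed):

* **AH sequence families** — each group draws residues face-by-face on the
  helical wheel (a position whose azimuth falls within ±90° of the
  membrane-facing direction samples from the hydrophobic-face profile,
  otherwise from the hydrophilic-face profile), so generated families are
  genuinely amphipathic rather than merely compositionally biased. The
  default ten groups mirror the homolog-family structure of the motivating
  dataset (five ATG3 phyla plus ATG14, ATG2, VPS34, NUP133 and a single
  Spo20 sequence, 1886 sequences in total) and encode only its stated
  contrasts: ATG3-like helices have low hydrophobicity, no bulky W/F and
  little glycine; ATG2-like helices are strongly hydrophobic with W/F;
  the Spo20-like helix carries a large charged face.

* **Rigid-helix membrane trajectories** — an ideal α-helix backbone
  (100°/residue twist, 0.15 nm rise, 0.23 nm Cα ring radius) is placed at a
  per-frame tilt drawn from Normal(μ_α, σ_α), above a planar grid of lipid
  phosphate beads (classes PE/PC/PI). Scripted contact episodes move a
  dedicated bead of the requested class to 0.3 nm from the requested
  residue's Cα, radially outward from the helix axis so neighbouring
  residues stay outside the 0.45 nm cutoff; outside its episodes the bead
  parks far away. Ground truth records the per-frame tilt and the episodes.

* **CD spectra** — a smooth 190–260 nm curve mixing a helical basis
  (fixed to −32640 deg·cm²·dmol⁻¹ at 222 nm, i.e. 100 % helix) and a coil
  basis (−2340 at 222 nm, 0 % helix) in proportion f, plus Gaussian noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cd_helicity import CDSpectrum, HelicityModel
from .physchem import profile_sequence
from .sequence_io import AHRecord, write_fasta
from .trajectory import Trajectory

__all__ = [
    "GroupSpec",
    "TrajectorySpec",
    "default_group_specs",
    "PAPER_GROUP_SIZES",
    "generate_ah_dataset",
    "generate_helix_trajectory",
    "generate_cd_spectrum",
]

#: Per-group sequence counts of the motivating homolog dataset
#: ((family, phylum) -> n); they sum to 1886.
PAPER_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("ATG3", "Chordata"): 195,
    ("ATG3", "Arthropoda"): 129,
    ("ATG3", "Nematoda"): 44,
    ("ATG3", "Streptophyta"): 177,
    ("ATG3", "Ascomycota"): 419,
    ("ATG14", "Chordata"): 157,
    ("ATG2", "Chordata"): 366,
    ("VPS34", "Chordata"): 219,
    ("NUP133", "Chordata"): 179,
    ("Spo20", "Ascomycota"): 1,
}


def _check_profile(profile: Mapping[str, float], label: str) -> None:
    total = float(sum(profile.values()))
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"{label}: face frequencies sum to {total}, expected 1")
    if any(v < 0 for v in profile.values()):
        raise ValueError(f"{label}: negative frequency")


@dataclass(frozen=True)
class GroupSpec:
    """One sequence family/phylum group of the synthetic AH dataset."""

    family: str
    phylum: str
    n: int
    hydrophobic_face: Mapping[str, float]
    hydrophilic_face: Mapping[str, float]
    length_range: tuple[int, int] = (20, 26)
    #: Per-site substitution probability away from the group consensus.
    #: 0.15 puts the mean within-group pairwise identity near
    #: (1-m)^2 + coincidence ~ 75-80%, typical of a conserved functional
    #: helix across one phylum.
    mutation_rate: float = 0.15

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size n must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        lo, hi = self.length_range
        if not (3 <= lo <= hi):
            raise ValueError(f"invalid length range {self.length_range}")
        name = f"{self.family}/{self.phylum}"
        _check_profile(self.hydrophobic_face, f"{name} hydrophobic face")
        _check_profile(self.hydrophilic_face, f"{name} hydrophilic face")


# Face profiles encode the stated family contrasts, not measured frequencies:
# ATG3-like faces carry small hydrophobics only (no W/F, almost no G);
# ATG2-like faces are rich in L/I/F/W; intermediate families sit between;
# the Spo20-like hydrophilic face is predominantly charged.
_ATG3_HYDRO = {"A": 0.20, "L": 0.22, "V": 0.25, "I": 0.12, "M": 0.06,
               "T": 0.08, "P": 0.03, "Y": 0.04}
_ATG3_PHILIC = {"K": 0.20, "E": 0.18, "N": 0.10, "Q": 0.10, "T": 0.10,
                "S": 0.10, "D": 0.06, "R": 0.05, "A": 0.05, "G": 0.03, "H": 0.03}
_ATG2_HYDRO = {"L": 0.24, "I": 0.15, "F": 0.18, "W": 0.12, "V": 0.12,
               "M": 0.08, "A": 0.06, "Y": 0.05}
_ATG2_PHILIC = {"S": 0.14, "T": 0.12, "K": 0.12, "E": 0.12, "N": 0.10,
                "Q": 0.10, "D": 0.08, "R": 0.07, "G": 0.10, "H": 0.05}
_ATG14_HYDRO = {"L": 0.22, "V": 0.18, "I": 0.12, "F": 0.10, "M": 0.08,
                "A": 0.15, "W": 0.03, "Y": 0.07, "C": 0.05}
_ATG14_PHILIC = {"K": 0.15, "R": 0.08, "E": 0.14, "D": 0.08, "S": 0.12,
                 "T": 0.10, "N": 0.10, "Q": 0.10, "G": 0.08, "H": 0.05}
_VPS34_HYDRO = {"L": 0.20, "V": 0.15, "I": 0.15, "F": 0.12, "A": 0.12,
                "M": 0.10, "Y": 0.08, "W": 0.04, "P": 0.04}
_VPS34_PHILIC = {"K": 0.14, "R": 0.10, "E": 0.12, "D": 0.10, "S": 0.12,
                 "T": 0.12, "N": 0.08, "Q": 0.08, "G": 0.09, "H": 0.05}
_NUP133_HYDRO = {"L": 0.25, "V": 0.20, "I": 0.10, "A": 0.15, "F": 0.08,
                 "M": 0.07, "Y": 0.05, "W": 0.02, "G": 0.08}
_NUP133_PHILIC = {"S": 0.15, "T": 0.12, "N": 0.12, "Q": 0.10, "K": 0.12,
                  "E": 0.12, "D": 0.08, "R": 0.06, "G": 0.08, "H": 0.05}
_SPO20_HYDRO = {"L": 0.22, "V": 0.18, "I": 0.15, "M": 0.10, "A": 0.10,
                "F": 0.10, "W": 0.05, "Y": 0.10}
_SPO20_PHILIC = {"K": 0.22, "R": 0.15, "E": 0.20, "D": 0.15, "S": 0.08,
                 "T": 0.06, "N": 0.07, "Q": 0.07}

_FACE_PROFILES = {
    "ATG3": (_ATG3_HYDRO, _ATG3_PHILIC),
    "ATG14": (_ATG14_HYDRO, _ATG14_PHILIC),
    "ATG2": (_ATG2_HYDRO, _ATG2_PHILIC),
    "VPS34": (_VPS34_HYDRO, _VPS34_PHILIC),
    "NUP133": (_NUP133_HYDRO, _NUP133_PHILIC),
    "Spo20": (_SPO20_HYDRO, _SPO20_PHILIC),
}

_LENGTH_RANGES = {
    "Chordata": (20, 26),
    "Arthropoda": (20, 26),
    "Nematoda": (18, 24),
    "Streptophyta": (20, 28),
    "Ascomycota": (18, 26),
}


def default_group_specs(
    sizes: Mapping[tuple[str, str], int] | None = None,
) -> list[GroupSpec]:
    """The ten default groups with the homolog-dataset sizes (1886 total)."""
    if sizes is None:
        sizes = PAPER_GROUP_SIZES
    specs = []
    for (family, phylum), n in sizes.items():
        hydro, philic = _FACE_PROFILES[family]
        specs.append(
            GroupSpec(
                family=family,
                phylum=phylum,
                n=n,
                hydrophobic_face=hydro,
                hydrophilic_face=philic,
                length_range=_LENGTH_RANGES.get(phylum, (20, 26)),
            )
        )
    return specs


def _wheel_face_is_hydrophobic(position: int, delta: float = 100.0) -> bool:
    """Membrane-facing (hydrophobic) face: azimuth within ±90° of 0°."""
    azimuth = (delta * (position - 1)) % 360.0
    wrapped = azimuth if azimuth <= 180.0 else azimuth - 360.0
    return abs(wrapped) < 90.0


def _face_sampler(spec: GroupSpec):
    hydro_aa = list(spec.hydrophobic_face)
    hydro_p = np.array([spec.hydrophobic_face[a] for a in hydro_aa])
    hydro_p = hydro_p / hydro_p.sum()
    philic_aa = list(spec.hydrophilic_face)
    philic_p = np.array([spec.hydrophilic_face[a] for a in philic_aa])
    philic_p = philic_p / philic_p.sum()

    def draw(position: int, rng: np.random.Generator) -> str:
        if _wheel_face_is_hydrophobic(position):
            return str(rng.choice(hydro_aa, p=hydro_p))
        return str(rng.choice(philic_aa, p=philic_p))

    return draw


def _sample_group(spec: GroupSpec, rng: np.random.Generator) -> list[str]:
    """Sample one homolog group: a consensus helix plus point substitutions.

    Homologs of one family/phylum are related by descent, not independent
    draws, and the helix region comes out of a multiple alignment — so the
    group shares a fixed-length consensus (drawn face-by-face from the
    profiles) and each member substitutes every position with probability
    ``mutation_rate``, resampling from the same face profile.
    """
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    draw = _face_sampler(spec)
    consensus = [draw(pos, rng) for pos in range(1, length + 1)]
    sequences = []
    for _ in range(spec.n):
        seq = list(consensus)
        for pos in range(1, length + 1):
            if rng.random() < spec.mutation_rate:
                seq[pos - 1] = draw(pos, rng)
        sequences.append("".join(seq))
    return sequences


def generate_ah_dataset(
    specs: Sequence[GroupSpec] | None = None,
    seed: int = 42,
    out_dir: str | Path | None = None,
) -> tuple[list[AHRecord], pd.DataFrame, dict]:
    """Generate a labeled synthetic AH dataset.

    Returns ``(records, labels, ground_truth)``: records in spec order,
    labels as a DataFrame (family, phylum) indexed by id, and a ground-truth
    summary with realized per-group mean hydrophobicity and bulky counts.
    With ``out_dir``, also writes FASTA, a labels TSV and the summary JSON.
    """
    if specs is None:
        specs = default_group_specs()
    rng = np.random.default_rng(seed)
    records: list[AHRecord] = []
    truth: dict = {"seed": int(seed), "groups": {}}
    for spec in specs:
        sequences = _sample_group(spec, rng)
        group_records = [
            AHRecord(
                id=f"{spec.family}_{spec.phylum}_{i:04d}",
                sequence=seq,
                family=spec.family,
                phylum=spec.phylum,
            )
            for i, seq in enumerate(sequences)
        ]
        records.extend(group_records)
        profs = [profile_sequence(r.id, r.sequence) for r in group_records]
        truth["groups"][f"{spec.family}/{spec.phylum}"] = {
            "n": spec.n,
            "mean_hydrophobicity": float(np.mean([p.hydrophobicity for p in profs])),
            "mean_n_bulky": float(np.mean([p.n_bulky for p in profs])),
            "mean_n_glycine": float(np.mean([p.n_glycine for p in profs])),
        }
    labels = pd.DataFrame(
        {"family": [r.family for r in records], "phylum": [r.phylum for r in records]},
        index=pd.Index([r.id for r in records], name="id"),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out / "ah_dataset.fasta")
        labels.to_csv(out / "labels.tsv", sep="\t")
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return records, labels, truth


# --------------------------------------------------------------------------
# Rigid-helix membrane trajectories


@dataclass(frozen=True)
class TrajectorySpec:
    """Specification of a synthetic rigid-helix membrane trajectory.

    Episodes are (res_id, lipid_class, start_frame, end_frame) with an
    inclusive start and exclusive end, in frame units.
    """

    n_frames: int = 1000
    dt: float = 1.0  # ns per saved frame
    tilt_mean: float = 5.0  # degrees; motivating wild-type mean
    tilt_sd: float = 7.5  # degrees; ~30° dynamic range ≈ ±2σ
    helix_length: int = 24
    twist: float = 100.0  # degrees per residue
    rise: float = 0.15  # nm per residue
    radius: float = 0.23  # nm, Cα ring radius
    helix_z: float = 2.0  # nm, helix centre height above the phosphate plane
    coord_noise: float = 0.02  # nm Gaussian jitter on helix atoms
    lipid_grid: tuple[int, int] = (6, 6)
    lipid_spacing: float = 0.8  # nm
    lipid_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"PE": 0.55, "PC": 0.30, "PI": 0.15}
    )
    contact_episodes: tuple[tuple[int, str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.helix_length < 3:
            raise ValueError("need n_frames >= 1 and helix_length >= 3")
        if self.tilt_sd < 0 or self.coord_noise < 0:
            raise ValueError("sigma values must be >= 0")
        for res, cls, start, end in self.contact_episodes:
            if not (0 <= start < end <= self.n_frames):
                raise ValueError(
                    f"episode ({res}, {cls}, {start}, {end}) outside [0, n_frames)"
                )
            if not (1 <= res <= self.helix_length):
                raise ValueError(f"episode residue {res} outside the helix")


def _ideal_helix(spec: TrajectorySpec) -> np.ndarray:
    """Cα positions of the ideal helix, axis along +x, centred at origin."""
    n = spec.helix_length
    i = np.arange(n)
    x = spec.rise * i
    x -= x.mean()
    phi = np.radians(spec.twist * i)
    return np.column_stack([x, spec.radius * np.cos(phi), spec.radius * np.sin(phi)])


def _tilt_rotation(alpha_deg: float) -> np.ndarray:
    """Rotation about y mapping +x to (cos α, 0, sin α): N→C tips up for α>0."""
    a = np.radians(alpha_deg)
    return np.array(
        [[np.cos(a), 0.0, np.sin(a)], [0.0, 1.0, 0.0], [-np.sin(a), 0.0, np.cos(a)]]
    ).T


def _merge_episodes(
    episodes: Sequence[tuple[int, str, int, int]]
) -> dict[tuple[int, str], list[tuple[int, int]]]:
    by_pair: dict[tuple[int, str], list[tuple[int, int]]] = {}
    for res, cls, start, end in episodes:
        by_pair.setdefault((res, cls), []).append((start, end))
    merged: dict[tuple[int, str], list[tuple[int, int]]] = {}
    for pair, spans in by_pair.items():
        spans.sort()
        out = [spans[0]]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                warnings.warn(
                    f"overlapping contact episodes for {pair}; merging",
                    UserWarning,
                    stacklevel=3,
                )
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[pair] = out
    return merged


def generate_helix_trajectory(
    spec: TrajectorySpec = TrajectorySpec(),
    seed: int = 42,
    out_path: str | Path | None = None,
) -> tuple[Trajectory, dict]:
    """Generate a rigid-helix trajectory above a lipid-bead plane.

    Returns ``(trajectory, ground_truth)`` where the ground truth carries
    the per-frame prescribed tilt and the merged contact episodes. With
    ``out_path``, the trajectory is also written as multi-model PDB.
    """
    rng = np.random.default_rng(seed)
    n_res = spec.helix_length
    base = _ideal_helix(spec)
    alpha = rng.normal(spec.tilt_mean, spec.tilt_sd, size=spec.n_frames)
    if spec.tilt_sd == 0:
        alpha[:] = spec.tilt_mean
    merged = _merge_episodes(spec.contact_episodes)
    pairs = sorted(merged)

    # background phosphate beads on the z=0 plane
    nx, ny = spec.lipid_grid
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    grid = np.column_stack(
        [
            (gx.ravel() - (nx - 1) / 2) * spec.lipid_spacing,
            (gy.ravel() - (ny - 1) / 2) * spec.lipid_spacing,
            np.zeros(nx * ny),
        ]
    )
    classes = list(spec.lipid_fractions)
    fracs = np.array([spec.lipid_fractions[c] for c in classes], dtype=float)
    fracs = fracs / fracs.sum()
    counts = np.floor(fracs * len(grid)).astype(int)
    counts[0] += len(grid) - counts.sum()
    grid_classes = [c for c, k in zip(classes, counts) for _ in range(k)]

    # one dedicated bead per scripted (residue, class) pair; parked far away
    park = np.array([(nx + 4) * spec.lipid_spacing, (ny + 4) * spec.lipid_spacing, 0.0])

    n_lipid = len(grid) + len(pairs)
    n_atoms = n_res + n_lipid
    coords = np.empty((spec.n_frames, n_atoms, 3))
    for t in range(spec.n_frames):
        rot = _tilt_rotation(alpha[t])
        ca = base @ rot.T
        ca[:, 2] += spec.helix_z
        ideal = ca.copy()
        if spec.coord_noise > 0:
            ca = ca + rng.normal(0.0, spec.coord_noise, size=ca.shape)
        coords[t, :n_res] = ca
        coords[t, n_res : n_res + len(grid)] = grid
        # episode beads: 0.3 nm radially outward from the designated residue
        for j, pair in enumerate(pairs):
            res, _cls = pair
            in_episode = any(s <= t < e for s, e in merged[pair])
            if in_episode:
                p = ideal[res - 1]
                axis_point = rot @ np.array([base[res - 1, 0], 0.0, 0.0])
                axis_point[2] += spec.helix_z
                u = p - axis_point
                u /= np.linalg.norm(u)
                coords[t, n_res + len(grid) + j] = p + 0.3 * u
            else:
                coords[t, n_res + len(grid) + j] = park + np.array(
                    [j * spec.lipid_spacing, 0.0, 0.0]
                )

    seq = "MQNVINTVKGKALEVAEYLTPVLK"  # wild-type 24-mer; repeated if longer
    res_names_protein = [
        _THREE_LETTER[seq[i % len(seq)]] for i in range(n_res)
    ]
    atoms = pd.DataFrame(
        {
            "atom_name": ["CA"] * n_res + ["P"] * n_lipid,
            "res_id": (
                list(range(1, n_res + 1))
                + list(range(101, 101 + len(grid)))
                + list(range(901, 901 + len(pairs)))
            ),
            "res_name": res_names_protein + grid_classes + [p[1] for p in pairs],
            "chain": ["protein"] * n_res + ["lipid"] * n_lipid,
            "lipid_class": [""] * n_res + grid_classes + [p[1] for p in pairs],
            "element": ["C"] * n_res + ["P"] * n_lipid,
            "heavy": [True] * n_atoms,
            "phosphate": [False] * n_res + [True] * n_lipid,
        }
    )
    traj = Trajectory(coords=coords, atoms=atoms, dt=spec.dt)
    truth = {
        "seed": int(seed),
        "alpha": alpha.tolist(),
        "episodes": [
            {"res_id": res, "lipid_class": cls, "spans": spans}
            for (res, cls), spans in sorted(merged.items())
        ],
        "dt": spec.dt,
    }
    if out_path is not None:
        from .trajectory import write_trajectory

        write_trajectory(traj, out_path)
        Path(str(out_path) + ".truth.json").write_text(json.dumps(truth, indent=2))
    return traj, truth


_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


# --------------------------------------------------------------------------
# CD spectra


def _gauss(x: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-((x - centre) ** 2) / (2.0 * width**2))


def generate_cd_spectrum(
    helix_fraction: float,
    noise: float = 0.0,
    seed: int = 42,
    model: HelicityModel = HelicityModel(),
    wavelengths: np.ndarray | None = None,
) -> tuple[CDSpectrum, dict]:
    """Synthetic CD spectrum of a peptide with helix fraction f ∈ [0, 1].

    The noiseless MRE at 222 nm is exactly −(baseline + slope·100·f), so the
    forward helicity estimate recovers 100·f. The rest of the curve mixes a
    plausible helical shape (208/222 nm minima, ~192 nm maximum) with a coil
    shape (~198 nm minimum); Gaussian noise of SD ``noise`` is added per
    point.
    """
    if not 0.0 <= helix_fraction <= 1.0:
        raise ValueError(f"helix fraction {helix_fraction} outside [0, 1]")
    if wavelengths is None:
        wavelengths = np.round(np.arange(190.0, 260.0 + 1e-9, 0.2), 1)
    wl = np.asarray(wavelengths, dtype=float)
    helix_shape = (
        -_gauss(wl, 208.0, 6.5) - _gauss(wl, 222.0, 7.5) + 1.6 * _gauss(wl, 192.0, 5.5)
    )
    coil_shape = -_gauss(wl, 198.0, 7.0) - 0.08 * _gauss(wl, 222.0, 20.0)

    def _at222(shape: np.ndarray) -> float:
        return float(np.interp(222.0, wl, shape))

    helix_target = -(model.baseline + model.slope * 100.0)  # = -32640 by default
    coil_target = -model.baseline
    helix_basis = helix_shape * (helix_target / _at222(helix_shape))
    coil_basis = coil_shape * (coil_target / _at222(coil_shape))
    curve = helix_fraction * helix_basis + (1.0 - helix_fraction) * coil_basis
    mre222_true = helix_fraction * helix_target + (1.0 - helix_fraction) * coil_target
    if noise > 0:
        rng = np.random.default_rng(seed)
        curve = curve + rng.normal(0.0, noise, size=curve.shape)
    truth = {
        "helix_fraction": float(helix_fraction),
        "helicity_percent": 100.0 * float(helix_fraction),
        "mre222_true": mre222_true,
        "noise_sd": float(noise),
        "seed": int(seed),
    }
    return CDSpectrum(wl, curve), truth
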