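"""Helical-wheel physicochemical descriptors of amphipathic helices (AHs).

An amphipathic α-helix projected on a helical wheel (100° per residue,
3.6 residues per turn) segregates a hydrophobic from a hydrophilic face.
This module computes the descriptors used to compare AH families:

* mean hydrophobicity ⟨H⟩ on a per-residue scale (default Fauchère–Pliška,
  the scale HeliQuest uses),
* the hydrophobic moment μH — the magnitude of the vector sum of residue
  hydrophobicities placed at their wheel azimuths, normalised by length,
* net charge at neutral pH (K, R → +1; D, E → −1; H neutral, termini
  ignored — the helix is an internal protein segment),
* residue-class counts: polar {S,T,N,H,Q,E,D,K,R}, apolar
  {A,L,V,I,M,Y,W,F,P,C}, charged {E,D,K,R}, bulky-hydrophobic {F,W},
  and glycine counted on its own (G belongs to neither the polar nor the
  apolar class, so polar + apolar + glycine partitions the sequence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "AMINO_ACIDS",
    "FAUCHERE_PLISKA",
    "HydrophobicityScale",
    "PhyschemProfile",
    "WheelLayout",
    "POLAR_RESIDUES",
    "APOLAR_RESIDUES",
    "CHARGED_RESIDUES",
    "BULKY_RESIDUES",
    "mean_hydrophobicity",
    "hydrophobic_moment",
    "net_charge",
    "residue_class_counts",
    "helical_wheel",
    "profile_record",
    "profile_sequence",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Fauchère & Pliška octanol/water transfer free energies (kcal/mol),
#: the per-residue hydrophobicity scale used by HeliQuest. G is 0.
FAUCHERE_PLISKA: dict[str, float] = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

POLAR_RESIDUES = frozenset("STNHQEDKR")
APOLAR_RESIDUES = frozenset("ALVIMYWFPC")
CHARGED_RESIDUES = frozenset("EDKR")
BULKY_RESIDUES = frozenset("FW")

#: Rendering classes of the helical-wheel colour scheme (hydrophobic yellow,
#: K/R dark blue, H light blue, S/T purple, N/Q pink, P green, D/E red,
#: G/A gray). Counting never uses these tags: A is apolar, G is its own class.
_WHEEL_CLASS: dict[str, str] = {}
for _aa in "LVIMFWYC":
    _WHEEL_CLASS[_aa] = "hydrophobic"
for _aa in "KR":
    _WHEEL_CLASS[_aa] = "basic"
_WHEEL_CLASS["H"] = "histidine"
for _aa in "ST":
    _WHEEL_CLASS[_aa] = "ser_thr"
for _aa in "NQ":
    _WHEEL_CLASS[_aa] = "asn_gln"
_WHEEL_CLASS["P"] = "proline"
for _aa in "DE":
    _WHEEL_CLASS[_aa] = "acidic"
for _aa in "GA":
    _WHEEL_CLASS[_aa] = "small"


class UnknownResidueError(ValueError):
    """A residue letter outside the 20 standard amino acids (or the scale)."""


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    for ch in seq:
        if ch not in AMINO_ACIDS:
            raise UnknownResidueError(
                f"non-standard residue {ch!r} in sequence {sequence!r}"
            )
    return seq


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named per-residue hydrophobicity scale with exactly 20 entries."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(AMINO_ACIDS)
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise UnknownResidueError(
                f"residue {residue!r} not in scale {self.name!r}"
            ) from None


DEFAULT_SCALE = HydrophobicityScale("fauchere-pliska", FAUCHERE_PLISKA)

NAMED_SCALES = {"fauchere": DEFAULT_SCALE, "fauchere-pliska": DEFAULT_SCALE}


@dataclass(frozen=True)
class PhyschemProfile:
    """Physicochemical descriptor vector of one AH sequence."""

    id: str
    length: int
    net_charge: int
    hydrophobicity: float
    hydrophobic_moment: float
    n_polar: int
    n_apolar: int
    n_charged: int
    n_bulky: int
    n_glycine: int
    aa_counts: Mapping[str, int] = field(repr=False)

    #: Column order of the summary block in feature tables/matrices.
    SUMMARY_FEATURES = (
        "length", "net_charge", "hydrophobicity", "hydrophobic_moment",
        "n_polar", "n_apolar", "n_charged", "n_bulky",
    )

    def to_dict(self) -> dict[str, float]:
        """Flat feature dict: 8 summary features then 20 per-AA counts."""
        d: dict[str, float] = {k: getattr(self, k) for k in self.SUMMARY_FEATURES}
        for aa in AMINO_ACIDS:
            d[f"count_{aa}"] = self.aa_counts[aa]
        return d


@dataclass(frozen=True)
class WheelLayout:
    """Per-residue helical-wheel geometry: azimuths in [0, 360) degrees."""

    residues: tuple[str, ...]
    azimuths: tuple[float, ...]
    classes: tuple[str, ...]
    delta: float

    def __len__(self) -> int:
        return len(self.residues)


def mean_hydrophobicity(
    sequence: str, scale: HydrophobicityScale = DEFAULT_SCALE
) -> float:
    """Mean per-residue hydrophobicity ⟨H⟩ = (1/N) Σ H_i."""
    seq = _check_sequence(sequence)
    return sum(scale[ch] for ch in seq) / len(seq)


def hydrophobic_moment(
    sequence: str,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    delta: float = 100.0,
    normalize: bool = True,
) -> float:
    """Helical hydrophobic moment μH.

    μH = (1/N) · sqrt[(Σ H_i sin δ(i−1))² + (Σ H_i cos δ(i−1))²] with the
    angular step ``delta`` in degrees (100°/residue for an ideal α-helix).
    ``normalize=False`` returns the unnormalised vector-sum magnitude.
    """
    seq = _check_sequence(sequence)
    s = c = 0.0
    for i, ch in enumerate(seq):
        h = scale[ch]
        theta = math.radians(delta * i)
        s += h * math.sin(theta)
        c += h * math.cos(theta)
    mu = math.hypot(s, c)
    return mu / len(seq) if normalize else mu


def net_charge(sequence: str) -> int:
    """Net charge at neutral pH: +1 per K/R, −1 per D/E; H and termini 0."""
    seq = _check_sequence(sequence)
    return sum(+1 if ch in "KR" else -1 if ch in "DE" else 0 for ch in seq)


def residue_class_counts(sequence: str) -> dict[str, object]:
    """Counts of the polar/apolar/charged/bulky classes, glycine, and per-AA.

    The polar and apolar classes together with glycine partition the 20
    letters, so ``n_polar + n_apolar + n_glycine == len(sequence)``.
    """
    seq = _check_sequence(sequence)
    aa_counts = {aa: seq.count(aa) for aa in AMINO_ACIDS}
    return {
        "n_polar": sum(1 for ch in seq if ch in POLAR_RESIDUES),
        "n_apolar": sum(1 for ch in seq if ch in APOLAR_RESIDUES),
        "n_charged": sum(1 for ch in seq if ch in CHARGED_RESIDUES),
        "n_bulky": sum(1 for ch in seq if ch in BULKY_RESIDUES),
        "n_glycine": aa_counts["G"],
        "aa_counts": aa_counts,
    }


def helical_wheel(sequence: str, delta: float = 100.0) -> WheelLayout:
    """Helical-wheel layout: residue n sits at azimuth (n−1)·delta mod 360."""
    seq = _check_sequence(sequence)
    azimuths = tuple((delta * i) % 360.0 for i in range(len(seq)))
    classes = tuple(_WHEEL_CLASS[ch] for ch in seq)
    return WheelLayout(tuple(seq), azimuths, classes, delta)


def profile_sequence(
    id_: str, sequence: str, scale: HydrophobicityScale = DEFAULT_SCALE
) -> PhyschemProfile:
    """Assemble the full descriptor vector for one sequence."""
    seq = _check_sequence(sequence)
    counts = residue_class_counts(seq)
    return PhyschemProfile(
        id=id_,
        length=len(seq),
        net_charge=net_charge(seq),
        hydrophobicity=mean_hydrophobicity(seq, scale),
        hydrophobic_moment=hydrophobic_moment(seq, scale),
        n_polar=counts["n_polar"],
        n_apolar=counts["n_apolar"],
        n_charged=counts["n_charged"],
        n_bulky=counts["n_bulky"],
        n_glycine=counts["n_glycine"],
        aa_counts=counts["aa_counts"],
    )


def profile_record(record, scale: HydrophobicityScale = DEFAULT_SCALE) -> PhyschemProfile:
    """Profile an :class:`~amphiprof.sequence_io.AHRecord`."""
    return profile_sequence(record.id, record.sequence, scale)
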