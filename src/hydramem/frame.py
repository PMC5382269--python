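"""Configuration data model: atoms, frames, curves and periodic geometry.

A :class:`Frame` holds one snapshot of a hydrated bilayer stack in an
orthorhombic box with periodic boundaries.  The z axis is the membrane
normal; analyses place the origin at the midplane of the water layer
(located as the periodic center of mass of water oxygens).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

LIPID = "lipid"
WATER = "water"
MOLECULE_CLASSES = (LIPID, WATER)
LEAFLETS = ("upper", "lower", "none")


class FrameError(ValueError):
    """Raised for malformed or inconsistent configuration data."""


@dataclass
class AtomRecord:
    """Per-atom annotation.

    ``hb_role`` is a frozenset drawn from {"donor", "acceptor", "hydrogen"};
    an empty set means the atom takes no part in hydrogen bonding.
    ``bonded_heavy`` is the frame index of the parent heavy atom for
    hydrogens (-1 otherwise).
    """

    molecule_id: int
    atom_name: str
    resname: str = ""
    molecule_class: str = WATER
    leaflet: str = "none"
    hb_role: frozenset = field(default_factory=frozenset)
    bonded_heavy: int = -1
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.molecule_class not in MOLECULE_CLASSES:
            raise FrameError(f"unknown molecule_class {self.molecule_class!r}")
        if self.leaflet not in LEAFLETS:
            raise FrameError(f"unknown leaflet {self.leaflet!r}")
        self.hb_role = frozenset(self.hb_role)
        bad = self.hb_role - {"donor", "acceptor", "hydrogen"}
        if bad:
            raise FrameError(f"unknown hb_role entries {sorted(bad)}")


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, box) per axis (idempotent)."""
    wrapped = np.mod(positions, box)
    # np.mod of a tiny negative value rounds up to box itself; fold it back
    return np.where(wrapped < box, wrapped, 0.0)


def minimum_image(vectors: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return vectors - box * np.round(vectors / box)


@dataclass
class Frame:
    """One configuration: coordinates (nm), orthorhombic box (nm), atoms."""

    positions: np.ndarray
    box: np.ndarray
    atoms: list
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise FrameError("positions must be an (N, 3) array")
        if self.box.shape != (3,):
            raise FrameError("box must hold three orthorhombic edge lengths")
        if not np.all(np.isfinite(self.positions)):
            raise FrameError("non-finite coordinates")
        if not np.all(self.box > 0):
            raise FrameError("box lengths must be positive")
        if len(self.atoms) != len(self.positions):
            raise FrameError(
                f"atom list length {len(self.atoms)} does not match "
                f"{len(self.positions)} coordinate rows"
            )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def wrapped(self) -> np.ndarray:
        return wrap_positions(self.positions, self.box)

    # -- annotation-derived arrays -------------------------------------
    def attr_array(self, name: str) -> np.ndarray:
        return np.asarray([getattr(a, name) for a in self.atoms])

    @property
    def molecule_ids(self) -> np.ndarray:
        return self.attr_array("molecule_id").astype(int)

    @property
    def charges(self) -> np.ndarray:
        return self.attr_array("charge").astype(float)

    @property
    def lj_sigmas(self) -> np.ndarray:
        return self.attr_array("lj_sigma").astype(float)

    @property
    def lj_epsilons(self) -> np.ndarray:
        return self.attr_array("lj_epsilon").astype(float)

    def class_mask(self, molecule_class: str) -> np.ndarray:
        return np.asarray([a.molecule_class == molecule_class for a in self.atoms])

    def role_mask(self, role: str) -> np.ndarray:
        return np.asarray([role in a.hb_role for a in self.atoms])

    def name_mask(self, names: Iterable[str]) -> np.ndarray:
        names = set(names)
        return np.asarray([a.atom_name in names for a in self.atoms])

    @property
    def annotated(self) -> bool:
        """True once hydrogen-bond roles have been merged in."""
        return any(a.hb_role for a in self.atoms)

    def require_annotations(self) -> None:
        if not self.annotated:
            raise FrameError(
                "frame carries no hb_role annotations; merge an annotation "
                "table first"
            )

    def water_oxygen_mask(self) -> np.ndarray:
        water = self.class_mask(WATER)
        hydro = self.role_mask("hydrogen")
        return water & ~hydro

    def water_midplane_z(self) -> float:
        """z of the water-layer midplane via a periodic (circular) mean.

        Uses water oxygens when annotated, all atoms otherwise.
        """
        mask = self.water_oxygen_mask()
        if not mask.any():
            mask = np.ones(self.n_atoms, dtype=bool)
        z = self.wrapped()[mask, 2]
        lz = self.box[2]
        angles = 2.0 * np.pi * z / lz
        mean_angle = np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles)))
        return float(np.mod(mean_angle / (2.0 * np.pi) * lz, lz))

    def z_relative(self) -> np.ndarray:
        """z coordinates relative to the water midplane, in [-Lz/2, Lz/2)."""
        lz = self.box[2]
        z = self.wrapped()[:, 2] - self.water_midplane_z()
        return z - lz * np.round(z / lz)

    def copy(self) -> "Frame":
        return Frame(
            positions=self.positions.copy(),
            box=self.box.copy(),
            atoms=[replace(a) for a in self.atoms],
            frame_id=self.frame_id,
        )


@dataclass
class Curve:
    """A 1D series with units: x, y, optional y errors and a label map."""

    x: np.ndarray
    y: np.ndarray
    y_err: np.ndarray | None = None
    x_unit: str = ""
    y_unit: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if self.y_err is not None:
            self.y_err = np.asarray(self.y_err, dtype=float)
            if self.y_err.shape != self.x.shape:
                raise ValueError("y_err length must match x")

    def __len__(self) -> int:
        return len(self.x)

    def require_increasing_x(self) -> None:
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing for this operation")


def molecule_groups(frame: Frame) -> dict:
    """Map molecule_id -> array of atom indices, in frame order."""
    groups: dict[int, list[int]] = {}
    for i, atom in enumerate(frame.atoms):
        groups.setdefault(atom.molecule_id, []).append(i)
    return {mid: np.asarray(idx, dtype=int) for mid, idx in groups.items()}
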