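"""Synthetic input generators with planted ground truth.

Every input the pipeline consumes can be generated here: lamellar
configurations (two headgroup slabs flanking a water layer) with planted
hydrogen-bond geometries and dipole-orientation profiles, bulk-water
reference frames, Gaussian area/volume fluctuation series, exponential
pressure-distance curves and Gaussian Bragg-peak patterns.

The lamellar frames are geometric test fixtures, not physical ensembles.
Planted hydrogen bonds are inserted at donor-acceptor distance 0.29 nm and
hydrogen-donor-acceptor angle 10 degrees (safely inside the detection
criterion); every other donor-acceptor pair is kept at distance > 0.36 nm
or angle > 35 degrees (safely outside), so detection must recover the
planted set exactly.  Guaranteeing that separation bound caps the water
packing at ~18 molecules/nm^3 (about 55% of bulk density); the geometric
water slab is therefore thicker than the nominal D_w implied by
(n_w, A_l, v_w0), which is carried as bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from .constants import DEFAULT_CONSTANTS, Constants, K_B_SI
from .frame import AtomRecord, Curve, Frame

#: planted-bond geometry: safely inside the criterion
PLANT_R_DA = 0.29
PLANT_ANGLE_DEG = 10.0
#: exclusion bound for all non-planted donor-acceptor pairs
EXCLUDE_R = 0.36

_WATER_LATTICE = 0.38     # nm, lattice spacing of slab waters
_WATER_JITTER = 0.005     # nm, per-axis jitter (keeps min distance > 0.36)
_OH_BOND = 0.1            # nm
_HOH_HALF = np.deg2rad(109.47 / 2.0)
_HEAD_GAP = 0.39          # nm, gap between water slab face and headgroup plane
_CLEAR_R = 0.40           # nm, lattice clearing radius around planted atoms

# SPC/E-like water parameters used for annotation of synthetic frames
WATER_Q_O, WATER_Q_H = -0.8476, 0.4238
WATER_SIGMA, WATER_EPS = 0.3166, 0.650
LIPID_Q_O, LIPID_Q_H = -0.548, 0.408
LIPID_SIGMA, LIPID_EPS = 0.310, 0.650


class PackingError(ValueError):
    """Requested density or planted-bond count cannot be packed."""


@dataclass
class LamellarSpec:
    """Specification of one synthetic lamellar configuration.

    ``planted_hb`` lists (class, count) with class in {"ll", "lw", "ww"}.
    ``orientation_amplitude`` scales the planted antisymmetric water
    orientation profile  <cos theta_w>(z) = amplitude * tanh(z / zeta).
    """

    n_lipids_per_leaflet: int = 50
    a_l: float = 0.78
    n_w: float = 20.0
    headgroup_thickness: float = 0.9
    orientation_amplitude: float = 0.0
    orientation_zeta: float = 0.3
    planted_hb: list = field(default_factory=list)
    n_oh: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids_per_leaflet < 1:
            raise ValueError("need at least one lipid per leaflet")
        if self.a_l <= 0 or self.n_w <= 0:
            raise ValueError("a_l and n_w must be positive (D_w must be positive)")
        if not -1.0 <= self.orientation_amplitude <= 1.0:
            raise ValueError("orientation_amplitude must lie in [-1, 1]")
        if not 1 <= self.n_oh <= 8:
            raise ValueError("n_oh must be between 1 and 8")
        if self.headgroup_thickness < 0.5:
            raise ValueError("headgroup_thickness below 0.5 nm cannot hold sites")
        for cls, count in self.planted_hb:
            if cls not in ("ll", "lw", "ww"):
                raise ValueError(f"unknown planted HB class {cls!r}")
            if count < 0:
                raise ValueError("planted HB counts must be non-negative")

    @property
    def d_w(self) -> float:
        """Nominal water-layer thickness 2 n_w v_w0 / A_l (nm)."""
        return 2.0 * self.n_w * DEFAULT_CONSTANTS.v_w0 / self.a_l


@dataclass
class PlantedBond:
    donor: int
    hydrogen: int
    acceptor: int
    hb_class: str
    subtag: str = ""


@dataclass
class GroundTruth:
    """Exact record of what was planted in a synthetic frame."""

    bonds: list
    n_lipids: int
    n_waters: int
    n_w: float
    a_l: float
    d_w_nominal: float
    d_slab: float
    box: tuple
    seed: int

    def counts(self) -> dict:
        out = {"ll": 0, "lw": 0, "ww": 0}
        for b in self.bonds:
            out[b.hb_class] += 1
        return out

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["bonds"] = [PlantedBond(**b) for b in d["bonds"]]
        d["box"] = tuple(d["box"])
        return cls(**d)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perpendicular(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random unit vector perpendicular to u."""
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, u) * u
        n = np.linalg.norm(p)
        if n > 1e-8:
            return p / n


def _tilted(u: np.ndarray, angle_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Unit vector at a fixed angle from u, random azimuth."""
    a = np.deg2rad(angle_deg)
    return np.cos(a) * u + np.sin(a) * _perpendicular(u, rng)


def _water_hydrogens(o_pos, dipole, rng):
    """Two H positions for a rigid 3-site water with the given dipole axis."""
    d = _unit(np.asarray(dipole, dtype=float))
    p = _perpendicular(d, rng)
    h1 = o_pos + _OH_BOND * (np.cos(_HOH_HALF) * d + np.sin(_HOH_HALF) * p)
    h2 = o_pos + _OH_BOND * (np.cos(_HOH_HALF) * d - np.sin(_HOH_HALF) * p)
    return h1, h2


def _sample_dipole(z, amplitude, zeta, rng):
    """Dipole direction whose cos(theta_z) has mean amplitude*tanh(z/zeta)."""
    m = amplitude * np.tanh(z / zeta) if amplitude != 0.0 else 0.0
    w = 1.0 - abs(m)
    c = m + rng.uniform(-w, w)
    c = float(np.clip(c, -1.0, 1.0))
    s = np.sqrt(max(0.0, 1.0 - c * c))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([s * np.cos(phi), s * np.sin(phi), c])


# ---------------------------------------------------------------------------
# molecule assembly buffers
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates molecules and resolves planted-bond atom indices."""

    def __init__(self):
        self.atoms: list[AtomRecord] = []
        self.positions: list[np.ndarray] = []
        self.mol_id = 0

    def add_molecule(self, resname, molecule_class, leaflet, sites):
        """sites: list of (atom_name, pos, roles, bonded_local, charge, sigma, eps).

        Returns the global indices of the molecule's atoms.
        """
        self.mol_id += 1
        base = len(self.atoms)
        idx = []
        for k, (name, pos, roles, bonded_local, q, sig, eps) in enumerate(sites):
            self.atoms.append(
                AtomRecord(
                    molecule_id=self.mol_id,
                    atom_name=name,
                    resname=resname,
                    molecule_class=molecule_class,
                    leaflet=leaflet,
                    hb_role=frozenset(roles),
                    bonded_heavy=base + bonded_local if bonded_local >= 0 else -1,
                    charge=q,
                    lj_sigma=sig,
                    lj_epsilon=eps,
                )
            )
            self.positions.append(np.asarray(pos, dtype=float))
            idx.append(base + k)
        return idx

    def add_water(self, o_pos, h1, h2):
        return self.add_molecule(
            "SOL",
            "water",
            "none",
            [
                ("OW", o_pos, {"donor", "acceptor"}, -1, WATER_Q_O, WATER_SIGMA, WATER_EPS),
                ("HW1", h1, {"hydrogen"}, 0, WATER_Q_H, 0.0, 0.0),
                ("HW2", h2, {"hydrogen"}, 0, WATER_Q_H, 0.0, 0.0),
            ],
        )


def _oh_site(name_o, name_h, o_pos, h_pos):
    return [
        (name_o, o_pos, {"donor", "acceptor"}, -1, LIPID_Q_O, LIPID_SIGMA, LIPID_EPS),
        (name_h, h_pos, {"hydrogen"}, 0, LIPID_Q_H, 0.0, 0.0),
    ]


# ---------------------------------------------------------------------------
# lamellar generator
# ---------------------------------------------------------------------------

def gen_lamellar_frame(spec: LamellarSpec):
    """Generate a lamellar frame plus its planted-bond ground truth.

    Returns (Frame, GroundTruth).  The frame is annotated (roles, charges,
    LJ parameters, leaflets) and centered so that the water midplane sits at
    box_z/2.
    """
    rng = np.random.default_rng(spec.seed)
    n_lip = spec.n_lipids_per_leaflet
    lat = float(np.sqrt(n_lip * spec.a_l))

    n_ll = sum(int(c) for cls, c in spec.planted_hb if cls == "ll")
    n_lw = sum(int(c) for cls, c in spec.planted_hb if cls == "lw")
    n_ww = sum(int(c) for cls, c in spec.planted_hb if cls == "ww")

    # lateral lipid grid; reserved cells host the minimal lipids carrying
    # planted ll / lw bonds
    ncell = int(np.ceil(np.sqrt(n_lip)))
    cell = lat / ncell
    if cell < 0.74:
        raise PackingError(
            f"area per lipid {spec.a_l} nm^2 too small for clean headgroup packing"
        )
    # reserved lipids per leaflet (alternating assignment of bonds)
    ll_per_leaf = [(n_ll + 1) // 2, n_ll // 2]
    lw_per_leaf = [(n_lw + 1) // 2, n_lw // 2]
    for leaf in (0, 1):
        if 2 * ll_per_leaf[leaf] + lw_per_leaf[leaf] > n_lip:
            raise PackingError("too many planted ll/lw bonds for the lipid count")

    n_waters_total = int(round(2 * n_lip * spec.n_w))
    n_planted_waters = n_lw + 2 * n_ww
    if n_planted_waters > n_waters_total:
        raise PackingError("planted bonds require more waters than n_w provides")

    # water lattice: choose enough layers, clear around planted atoms, trim
    nxy = max(1, int(np.floor(lat / _WATER_LATTICE)))
    sxy = lat / nxy
    per_layer = nxy * nxy
    n_lattice_needed = n_waters_total - n_planted_waters
    clearance_budget = 24 * (n_ww + n_lw) + per_layer
    nz = max(1, int(np.ceil((n_lattice_needed + clearance_budget) / per_layer)))
    d_slab = nz * _WATER_LATTICE

    # ww anchors need interior room
    z_ww_max = d_slab / 2.0 - 0.55
    while n_ww > 0 and z_ww_max <= 0.0:
        nz += 1
        d_slab = nz * _WATER_LATTICE
        z_ww_max = d_slab / 2.0 - 0.55

    z_inner = d_slab / 2.0 + _HEAD_GAP
    n_zlev = 1 if spec.n_oh <= 4 else 2
    dz_lev = max(0.45, spec.headgroup_thickness / 2.0)
    z_outer = z_inner + (n_zlev - 1) * dz_lev
    box_z = 2.0 * (z_outer + 0.5)
    box = np.array([lat, lat, box_z])
    center = box_z / 2.0  # water midplane sits here

    b = _Builder()
    bonds: list[PlantedBond] = []

    # --- lipids ------------------------------------------------------------
    cells = [(i, j) for i in range(ncell) for j in range(ncell)][:n_lip]
    # adjacent same-row cell pairs host planted ll bonds; leftover cells host
    # planted lw bonds and regular lipids
    adjacent_pairs: list[tuple] = []
    leftover: list[tuple] = []
    for i in range(ncell):
        row = [c for c in cells if c[0] == i]
        for k in range(0, len(row) - 1, 2):
            adjacent_pairs.append((row[k], row[k + 1]))
        if len(row) % 2:
            leftover.append(row[-1])
    max_ll_per_leaf = max(ll_per_leaf)
    if max_ll_per_leaf > len(adjacent_pairs):
        raise PackingError("could not reserve adjacent cells for planted ll bonds")
    sub_xy = [(-0.25, -0.25), (0.25, -0.25), (-0.25, 0.25), (0.25, 0.25)]

    for leaf, sign, leafname in ((0, 1.0, "upper"), (1, -1.0, "lower")):
        pair_slice = adjacent_pairs[: ll_per_leaf[leaf]]
        used = {c for pr in pair_slice for c in pr}
        free_cells = [c for c in cells if c not in used]
        if lw_per_leaf[leaf] > len(free_cells):
            raise PackingError("too many planted lw bonds for the lipid count")
        # planted ll bonds: pairs of adjacent reserved cells
        for c1, c2 in pair_slice:
            p1 = np.array([(c1[0] + 0.5) * cell, (c1[1] + 0.5) * cell])
            p2 = np.array([(c2[0] + 0.5) * cell, (c2[1] + 0.5) * cell])
            mid = 0.5 * (p1 + p2)
            u2 = _unit(p2 - p1)
            u = np.array([u2[0], u2[1], 0.0])
            z = sign * z_inner
            pd_ = np.array([mid[0], mid[1], z]) - (PLANT_R_DA / 2.0) * u
            pa = pd_ + PLANT_R_DA * u
            hd = pd_ + _OH_BOND * _tilted(u, PLANT_ANGLE_DEG, rng)
            ha = pa + _OH_BOND * u  # points away from donor
            di = b.add_molecule("HGL", "lipid", leafname, _oh_site("O1", "HO1", pd_, hd))
            ai = b.add_molecule("HGL", "lipid", leafname, _oh_site("O1", "HO1", pa, ha))
            bonds.append(PlantedBond(di[0], di[1], ai[0], "ll"))
        # planted lw bonds: one reserved cell each
        for k in range(lw_per_leaf[leaf]):
            c1 = free_cells[k]
            cx, cy = (c1[0] + 0.5) * cell, (c1[1] + 0.5) * cell
            lip_o = np.array([cx, cy, sign * z_inner])
            delta = rng.uniform(-0.25, 0.25, size=2)
            u = _unit(np.array([delta[0], delta[1], -sign]))  # toward midplane
            wat_o = lip_o + PLANT_R_DA * u
            lipid_is_donor = k % 2 == 0
            if lipid_is_donor:
                lip_h = lip_o + _OH_BOND * _tilted(u, PLANT_ANGLE_DEG, rng)
                h1, h2 = _water_hydrogens(wat_o, u, rng)  # dipole away from donor
                li = b.add_molecule(
                    "HGL", "lipid", leafname, _oh_site("O1", "HO1", lip_o, lip_h)
                )
                wi = b.add_water(wat_o, h1, h2)
                bonds.append(
                    PlantedBond(li[0], li[1], wi[0], "lw", subtag="lipid_donor")
                )
            else:
                # water donates; the lipid acceptor's hydroxyl H points back
                # into the headgroup region, 180 deg from the water direction
                lip_h = lip_o - _OH_BOND * u
                hd_dir = _tilted(-u, PLANT_ANGLE_DEG, rng)
                h1 = wat_o + _OH_BOND * hd_dir
                # second H at the tetrahedral angle from the first
                h2 = wat_o + _OH_BOND * _tilted(hd_dir, 109.47, rng)
                li = b.add_molecule(
                    "HGL", "lipid", leafname, _oh_site("O1", "HO1", lip_o, lip_h)
                )
                wi = b.add_water(wat_o, h1, h2)
                bonds.append(
                    PlantedBond(wi[0], wi[1], li[0], "lw", subtag="water_donor")
                )
        # regular lipids
        for c1 in free_cells[lw_per_leaf[leaf]:]:
            cx, cy = (c1[0] + 0.5) * cell, (c1[1] + 0.5) * cell
            sites = []
            for k in range(spec.n_oh):
                ox, oy = sub_xy[k % 4]
                zlev = z_inner + (k // 4) * dz_lev
                pos = np.array([cx + ox * cell, cy + oy * cell, sign * zlev])
                pos[:2] += rng.uniform(-0.005, 0.005, size=2)
                h = pos + np.array([0.0, 0.0, sign * _OH_BOND])
                sites.extend(_oh_site(f"O{k + 1}", f"HO{k + 1}", pos, h))
            # fix bonded_local offsets: each H follows its O
            fixed = []
            for k, s in enumerate(sites):
                s = list(s)
                s[3] = k - 1 if s[0].startswith("HO") else -1
                fixed.append(tuple(s))
            b.add_molecule("HGL", "lipid", leafname, fixed)

    planted_water_os = [
        b.positions[bond.acceptor if bond.subtag == "lipid_donor" else bond.donor]
        for bond in bonds
        if bond.hb_class == "lw"
    ]

    # --- planted ww pairs ---------------------------------------------------
    anchors = []
    for _ in range(n_ww):
        for _try in range(2000):
            pos = np.array(
                [
                    rng.uniform(0, lat),
                    rng.uniform(0, lat),
                    rng.uniform(-z_ww_max, z_ww_max),
                ]
            )
            ok = all(
                _min_image_dist(pos, a, box, lat) > 1.2 for a in anchors
            ) and all(
                _min_image_dist(pos, np.asarray(w), box, lat) > 1.2
                for w in planted_water_os
            )
            if ok:
                anchors.append(pos)
                break
        else:
            raise PackingError("could not place planted ww anchors (density too high)")
    for pos in anchors:
        u = _unit(rng.normal(size=3))
        pd_ = pos - (PLANT_R_DA / 2.0) * u
        pa = pos + (PLANT_R_DA / 2.0) * u
        hd_dir = _tilted(u, PLANT_ANGLE_DEG, rng)
        h1d = pd_ + _OH_BOND * hd_dir
        h2d = pd_ + _OH_BOND * _tilted(hd_dir, 109.47, rng)
        h1a, h2a = _water_hydrogens(pa, u, rng)  # acceptor dipole away from donor
        di = b.add_water(pd_, h1d, h2d)
        ai = b.add_water(pa, h1a, h2a)
        bonds.append(PlantedBond(di[0], di[1], ai[0], "ww"))

    # --- lattice waters ------------------------------------------------------
    planted_os = np.array(
        [b.positions[i] for i, a in enumerate(b.atoms) if "acceptor" in a.hb_role]
    ).reshape(-1, 3)
    sites = []
    for kz in range(nz):
        z = (kz - (nz - 1) / 2.0) * _WATER_LATTICE
        for i in range(nxy):
            for j in range(nxy):
                sites.append([(i + 0.5) * sxy, (j + 0.5) * sxy, z])
    sites = np.asarray(sites)
    sites += rng.uniform(-_WATER_JITTER, _WATER_JITTER, size=sites.shape)
    if len(planted_os):
        keep = np.ones(len(sites), dtype=bool)
        for p in planted_os:
            d = sites - p
            d[:, :2] -= lat * np.round(d[:, :2] / lat)
            keep &= np.einsum("ij,ij->i", d, d) > _CLEAR_R**2
        sites = sites[keep]
    if len(sites) < n_lattice_needed:
        raise PackingError(
            f"water packing infeasible: need {n_lattice_needed} lattice sites, "
            f"have {len(sites)} after clearing"
        )
    chosen = rng.choice(len(sites), size=n_lattice_needed, replace=False)
    for pos in sites[np.sort(chosen)]:
        dipole = _sample_dipole(
            pos[2], spec.orientation_amplitude, spec.orientation_zeta, rng
        )
        h1, h2 = _water_hydrogens(pos, dipole, rng)
        b.add_water(pos, h1, h2)

    positions = np.asarray(b.positions)
    positions[:, 2] += center
    frame = Frame(positions=positions, box=box, atoms=b.atoms, frame_id=0)
    truth = GroundTruth(
        bonds=bonds,
        n_lipids=2 * n_lip,
        n_waters=n_waters_total,
        n_w=spec.n_w,
        a_l=spec.a_l,
        d_w_nominal=spec.d_w,
        d_slab=d_slab,
        box=tuple(box),
        seed=spec.seed,
    )
    return frame, truth


def _min_image_dist(p, q, box, lat):
    d = np.asarray(p) - np.asarray(q)
    d[:2] -= lat * np.round(d[:2] / lat)
    return float(np.linalg.norm(d))


# ---------------------------------------------------------------------------
# bulk water
# ---------------------------------------------------------------------------

def gen_bulk_water_frame(density: float, box, seed: int = 0) -> Frame:
    """Non-overlapping 3-site waters at the requested number density (nm^-3).

    Minimum O-O distance is kept above 0.25 nm; infeasible densities raise
    :class:`PackingError`.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    rng = np.random.default_rng(seed)
    volume = float(np.prod(box))
    n = int(round(density * volume))
    b = _Builder()
    if n == 0:
        return Frame(np.empty((0, 3)), box, [], frame_id=0)
    dims = [max(1, int(np.floor(L / 0.285))) for L in box]
    if n > dims[0] * dims[1] * dims[2]:
        raise PackingError(
            f"density {density} nm^-3 infeasible for non-overlapping packing"
        )
    spacing = box / dims
    sites = np.stack(
        np.meshgrid(
            *[(np.arange(d) + 0.5) * s for d, s in zip(dims, spacing)], indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    chosen = rng.choice(len(sites), size=n, replace=False)
    sites = sites[np.sort(chosen)] + rng.uniform(-0.009, 0.009, size=(n, 3))
    for pos in sites:
        dipole = _unit(rng.normal(size=3))
        h1, h2 = _water_hydrogens(pos, dipole, rng)
        b.add_water(pos, h1, h2)
    return Frame(np.asarray(b.positions), box, b.atoms, frame_id=0)


# ---------------------------------------------------------------------------
# scalar series generators
# ---------------------------------------------------------------------------

def gen_area_series(
    k_a: float, mean_area: float, temperature: float, n: int, seed: int = 0
) -> Curve:
    """I.i.d. Gaussian area series with variance k_B T <A> / K_A.

    k_a in J/m^2, mean_area in nm^2; returned areas in nm^2.
    """
    if k_a <= 0:
        raise ValueError("K_A must be positive")
    var_nm4 = K_B_SI * temperature * mean_area * 1e18 / k_a
    rng = np.random.default_rng(seed)
    areas = rng.normal(mean_area, np.sqrt(var_nm4), size=n)
    return Curve(
        x=np.arange(n, dtype=float),
        y=areas,
        x_unit="frame",
        y_unit="nm^2",
        meta={"k_a_planted": k_a, "T": temperature},
    )


def gen_volume_vs_nw(
    v_w: Callable[[np.ndarray], np.ndarray] | float,
    n_w_grid: Sequence[float],
    v0: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Curve:
    """System volume V(N_w) with planted partial water volume dV/dN_w."""
    n_w_grid = np.asarray(n_w_grid, dtype=float)
    if np.any(np.diff(n_w_grid) <= 0):
        raise ValueError("n_w_grid must be strictly increasing")
    if callable(v_w):
        vw_vals = np.asarray(v_w(n_w_grid), dtype=float)
    else:
        vw_vals = np.full_like(n_w_grid, float(v_w))
    dv = np.concatenate(
        [[0.0], np.cumsum(0.5 * (vw_vals[1:] + vw_vals[:-1]) * np.diff(n_w_grid))]
    )
    vol = v0 + dv
    if noise_sd > 0:
        vol = vol + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(vol))
    return Curve(x=n_w_grid, y=vol, x_unit="waters", y_unit="nm^3")


def gen_area_vs_temperature(
    alpha_a: float,
    a0: float,
    t_grid: Sequence[float],
    t_ref: float = 300.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Curve:
    """Linear area-vs-temperature series with planted expansion coefficient."""
    t_grid = np.asarray(t_grid, dtype=float)
    areas = a0 * (1.0 + alpha_a * (t_grid - t_ref))
    if noise_sd > 0:
        areas = areas + np.random.default_rng(seed).normal(0, noise_sd, len(areas))
    return Curve(x=t_grid, y=areas, x_unit="K", y_unit="nm^2")


def gen_fluctuation_series(kind: str, params: dict, seed: int = 0) -> Curve:
    """Dispatcher over the fluctuation-series generators by kind."""
    if kind == "area":
        return gen_area_series(seed=seed, **params)
    if kind == "volume_vs_nw":
        return gen_volume_vs_nw(seed=seed, **params)
    if kind == "area_vs_T":
        return gen_area_vs_temperature(seed=seed, **params)
    raise ValueError(f"unknown fluctuation series kind {kind!r}")


def gen_pd_curve(
    pi0: float,
    lam: float,
    dw_grid: Sequence[float],
    noise_frac: float = 0.0,
    seed: int = 0,
):
    """Exponential pressure-distance curve with multiplicative noise.

    Pi_i = pi0 exp(-D_i/lam) (1 + eps_i), eps_i ~ N(0, noise_frac^2).
    """
    from .swelling import PDCurve

    if lam <= 0:
        raise ValueError("decay length must be positive")
    dw = np.asarray(dw_grid, dtype=float)
    clean = pi0 * np.exp(-dw / lam)
    rng = np.random.default_rng(seed)
    noisy = clean * (1.0 + rng.normal(0.0, noise_frac, size=len(dw))) \
        if noise_frac > 0 else clean.copy()
    err = clean * noise_frac if noise_frac > 0 else None
    return PDCurve(d_w=dw, pi=noisy, pi_err=err, source="synthetic")


def gen_diffraction(
    d_spacing: float,
    orders: Sequence[int],
    widths=0.002,
    amplitudes=1000.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    q_grid: Sequence[float] | None = None,
    seed: int = 0,
    q_offset: float = 0.0,
):
    """Sum of Gaussian Bragg peaks at q = 2 pi h / D + q_offset (angstrom units)."""
    from .diffraction import DiffPattern

    if d_spacing <= 0:
        raise ValueError("lamellar period must be positive")
    orders = list(orders)
    if not orders:
        raise ValueError("orders must not be empty")
    widths = np.broadcast_to(np.asarray(widths, dtype=float), (len(orders),))
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(orders),))
    if q_grid is None:
        qmax = 2.0 * np.pi * (max(orders) + 0.7) / d_spacing
        q_grid = np.linspace(0.02, qmax, 2000)
    q = np.asarray(q_grid, dtype=float)
    intensity = np.full_like(q, float(background))
    for h, w, a in zip(orders, widths, amplitudes):
        qc = 2.0 * np.pi * h / d_spacing + q_offset
        intensity = intensity + a * np.exp(-((q - qc) ** 2) / (2.0 * w * w))
    if noise_sd > 0:
        intensity = intensity + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=len(q)
        )
    return DiffPattern(q=q, intensity=intensity)
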