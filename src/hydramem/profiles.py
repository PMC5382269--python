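"""z-resolved structure: density, water-orientation and headgroup-angle
profiles along the membrane normal.

All profiles use the water-layer midplane as origin.  The water dipole angle
theta_w is measured between the O -> midpoint(H,H) axis and +z; headgroup
angles theta_l between a named intramolecular vector and +z, with the
histogram divided by sin(theta_l) so a random orientation gives a flat
profile of unit mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frame import Frame, FrameError, minimum_image, molecule_groups


@dataclass
class ZProfile:
    z_centers: np.ndarray
    values: np.ndarray
    errors: np.ndarray
    n_frames: int
    unit: str = ""

    def __post_init__(self) -> None:
        widths = np.diff(self.z_centers)
        if len(widths) and not np.allclose(widths, widths[0]):
            raise ValueError("bins must be uniform")

    @property
    def bin_width(self) -> float:
        return float(self.z_centers[1] - self.z_centers[0])


@dataclass
class AngleDistribution:
    theta_centers: np.ndarray
    weighted_density: np.ndarray
    raw_counts: np.ndarray


def _z_bins(lz: float, bin_width: float):
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = max(1, int(round(lz / bin_width)))
    edges = np.linspace(-lz / 2.0, lz / 2.0, n_bins + 1)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return edges, centers


def _as_frames(frames) -> list:
    if isinstance(frames, Frame):
        return [frames]
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    return frames


def density_profile(frames, selector, bin_width: float = 0.02) -> ZProfile:
    """Number density vs z for a selected atom subset, averaged over frames.

    ``selector`` is "water", "lipid", a callable Frame -> boolean mask, or a
    set of atom names.  The profile integrates (times lateral area) to the
    mean selected-atom count.
    """
    frames = _as_frames(frames)
    lz = frames[0].box[2]
    area = frames[0].box[0] * frames[0].box[1]
    edges, centers = _z_bins(lz, bin_width)
    dz = edges[1] - edges[0]
    counts = np.zeros((len(frames), len(centers)))
    for fi, frame in enumerate(frames):
        if callable(selector):
            mask = np.asarray(selector(frame), dtype=bool)
        elif selector in ("water", "lipid"):
            mask = frame.class_mask(selector)
        else:
            mask = frame.name_mask(selector)
        if not mask.any():
            raise ValueError("empty selection")
        z = frame.z_relative()[mask]
        counts[fi], _ = np.histogram(z, bins=edges)
    dens = counts / (area * dz)
    values = dens.mean(axis=0)
    if len(frames) > 1:
        errors = dens.std(axis=0, ddof=1) / np.sqrt(len(frames))
    else:
        errors = np.sqrt(counts[0]) / (area * dz)
    return ZProfile(
        z_centers=centers,
        values=values,
        errors=errors,
        n_frames=len(frames),
        unit="nm^-3",
    )


def water_dipoles(frame: Frame):
    """(O z-relative, unit dipole vectors) for every water molecule."""
    groups = molecule_groups(frame)
    z_rel = frame.z_relative()
    pos = frame.positions
    box = frame.box
    zs, dips = [], []
    for mid, idx in groups.items():
        if frame.atoms[idx[0]].molecule_class != "water":
            continue
        o = [i for i in idx if "hydrogen" not in frame.atoms[i].hb_role]
        h = [i for i in idx if "hydrogen" in frame.atoms[i].hb_role]
        if len(h) != 2 or len(o) != 1:
            raise FrameError(
                f"water molecule {mid} must have one oxygen and two hydrogens"
            )
        oh1 = minimum_image(pos[h[0]] - pos[o[0]], box)
        oh2 = minimum_image(pos[h[1]] - pos[o[0]], box)
        d = oh1 + oh2  # along O -> midpoint(H,H)
        n = np.linalg.norm(d)
        if n == 0:
            raise FrameError(f"degenerate water geometry in molecule {mid}")
        zs.append(z_rel[o[0]])
        dips.append(d / n)
    return np.asarray(zs), np.asarray(dips)


def orientation_profile(frames, bin_width: float = 0.02) -> ZProfile:
    """Mean cos(theta_w) of the water dipole vs z, with per-bin SE."""
    frames = _as_frames(frames)
    lz = frames[0].box[2]
    edges, centers = _z_bins(lz, bin_width)
    nb = len(centers)
    s = np.zeros(nb)
    s2 = np.zeros(nb)
    n = np.zeros(nb)
    for frame in frames:
        zs, dips = water_dipoles(frame)
        cos_t = dips[:, 2]
        which = np.clip(np.digitize(zs, edges) - 1, 0, nb - 1)
        np.add.at(s, which, cos_t)
        np.add.at(s2, which, cos_t**2)
        np.add.at(n, which, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        var = np.where(n > 1, (s2 - s**2 / np.maximum(n, 1)) / np.maximum(n - 1, 1), np.nan)
        se = np.sqrt(np.maximum(var, 0.0) / np.maximum(n, 1))
    return ZProfile(
        z_centers=centers,
        values=mean,
        errors=se,
        n_frames=len(frames),
        unit="cos(theta_w)",
    )


def headgroup_angle_distribution(
    frames, vector_spec, bin_width: float = 5.0
) -> AngleDistribution:
    """Distribution of the headgroup-vector tilt angle, 1/sin weighted.

    ``vector_spec`` names two atoms per lipid, e.g. ("C1", "C2"); the angle
    is between the intramolecular vector from the first to the second atom
    and the +z axis.
    """
    frames = _as_frames(frames)
    name_a, name_b = vector_spec
    if bin_width <= 0 or bin_width > 180:
        raise ValueError("bin_width must be in (0, 180] degrees")
    thetas = []
    for frame in frames:
        groups = molecule_groups(frame)
        missing = []
        for mid, idx in groups.items():
            if frame.atoms[idx[0]].molecule_class != "lipid":
                continue
            ia = [i for i in idx if frame.atoms[i].atom_name == name_a]
            ib = [i for i in idx if frame.atoms[i].atom_name == name_b]
            if not ia or not ib:
                missing.append(mid)
                continue
            v = minimum_image(
                frame.positions[ib[0]] - frame.positions[ia[0]], frame.box
            )
            n = np.linalg.norm(v)
            if n == 0:
                continue
            thetas.append(np.degrees(np.arccos(np.clip(v[2] / n, -1.0, 1.0))))
        if missing:
            raise ValueError(
                f"atoms {name_a}/{name_b} missing from lipid molecules "
                f"{missing[:10]} (frame {frame.frame_id})"
            )
    thetas = np.asarray(thetas)
    if thetas.size == 0:
        raise ValueError("no lipid vectors found")
    n_bins = int(round(180.0 / bin_width))
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    centers = 0.5 * (edges[1:] + edges[:-1])
    raw, _ = np.histogram(thetas, bins=edges)
    dtheta_rad = np.deg2rad(bin_width)
    # probability density per radian, divided by the isotropic sin(theta)/2
    density = raw / (thetas.size * dtheta_rad)
    weighted = 2.0 * density / np.sin(np.deg2rad(centers))
    return AngleDistribution(
        theta_centers=centers, weighted_density=weighted, raw_counts=raw
    )
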