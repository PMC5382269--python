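"""Hydrogen-bond detection and the per-lipid hydrogen-bond balance.

A bond exists between a donor heavy atom D (with covalent hydrogen H) and an
acceptor heavy atom A when the donor-acceptor distance is strictly below
0.35 nm and the H-D-A angle (measured at the donor) is strictly below 30
degrees — the geometric Luzar-Chandler criterion.  Bonds are classed by the
molecule classes of donor and acceptor: lipid-lipid (ll), lipid-water in
either donation direction (lw), water-water (ww).

The per-lipid balance counts ll, lw and *excess* ww bonds, where the excess
subtracts the bulk-water rate (1.796 bonds per water molecule) times the
number of waters per lipid; their sum is the total bond number whose change
on dehydration tracks the hydration repulsion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import DEFAULT_CONSTANTS, Constants
from .frame import Curve, Frame, FrameError, minimum_image


@dataclass(frozen=True)
class HBRecord:
    donor_atom: int
    hydrogen: int
    acceptor_atom: int
    r_da: float
    angle_hda: float
    hb_class: str
    subtag: str = ""


@dataclass
class HBBalance:
    """Per-lipid hydrogen-bond balance at one hydration level."""

    n_ll: float
    n_lw: float
    n_ww_raw: float
    n_ww_excess: float
    n_tot: float
    n_w: float
    d_w: float

    def __post_init__(self) -> None:
        ident = self.n_ll + self.n_lw + self.n_ww_excess
        if not np.isclose(self.n_tot, ident, rtol=0, atol=1e-9):
            raise ValueError("balance identity n_tot = ll + lw + ww_excess violated")


def detect_hbonds(
    frame: Frame, constants: Constants = DEFAULT_CONSTANTS
) -> list:
    """All hydrogen bonds of one annotated frame under minimum image.

    Neighbor candidates come from a periodic k-d tree on acceptor positions;
    both criterion inequalities are strict.  One record is emitted per
    (donor, hydrogen, acceptor) triple; a donor with two hydrogens can bond
    two acceptors, and one D-H may be recorded against several acceptors if
    several qualify geometrically.
    """
    frame.require_annotations()
    pos = frame.wrapped()
    box = frame.box
    mol = frame.molecule_ids
    classes = np.asarray([a.molecule_class for a in frame.atoms])

    donor_idx = np.flatnonzero(frame.role_mask("donor"))
    acceptor_idx = np.flatnonzero(frame.role_mask("acceptor"))
    hydrogen_idx = np.flatnonzero(frame.role_mask("hydrogen"))
    if donor_idx.size == 0 or acceptor_idx.size == 0:
        return []

    hydrogens_of: dict[int, list[int]] = {}
    for h in hydrogen_idx:
        parent = frame.atoms[h].bonded_heavy
        if parent < 0:
            raise FrameError(f"hydrogen atom {h} lacks a bonded_heavy index")
        hydrogens_of.setdefault(parent, []).append(int(h))

    # periodic KD-tree needs coordinates strictly inside [0, box)
    acc_pos = np.minimum(pos[acceptor_idx], np.nextafter(box, 0.0))
    don_pos = np.minimum(pos[donor_idx], np.nextafter(box, 0.0))
    tree = cKDTree(acc_pos, boxsize=box)
    neighbor_lists = tree.query_ball_point(don_pos, r=constants.r_hb)

    cos_cut = np.cos(np.deg2rad(constants.theta_hb))
    records: list[HBRecord] = []
    for d_local, neighbors in enumerate(neighbor_lists):
        d = int(donor_idx[d_local])
        hs = hydrogens_of.get(d)
        if not hs:
            continue
        for a_local in neighbors:
            a = int(acceptor_idx[a_local])
            if mol[a] == mol[d]:
                continue
            r_vec = minimum_image(pos[a] - pos[d], box)
            r_da = float(np.linalg.norm(r_vec))
            if not r_da < constants.r_hb:
                continue
            for h in hs:
                h_vec = minimum_image(pos[h] - pos[d], box)
                h_norm = np.linalg.norm(h_vec)
                if h_norm == 0 or r_da == 0:
                    continue
                cos_a = float(np.dot(h_vec, r_vec) / (h_norm * r_da))
                cos_a = min(1.0, max(-1.0, cos_a))
                if not cos_a > cos_cut:  # strict: angle < theta_hb
                    continue
                cd, ca = classes[d], classes[a]
                if cd == "lipid" and ca == "lipid":
                    hb_class, subtag = "ll", ""
                elif cd == "water" and ca == "water":
                    hb_class, subtag = "ww", ""
                else:
                    hb_class = "lw"
                    subtag = "lipid_donor" if cd == "lipid" else "water_donor"
                records.append(
                    HBRecord(
                        donor_atom=d,
                        hydrogen=h,
                        acceptor_atom=a,
                        r_da=r_da,
                        angle_hda=float(np.degrees(np.arccos(cos_a))),
                        hb_class=hb_class,
                        subtag=subtag,
                    )
                )
    return records


def hb_balance(
    records: list,
    n_lipids: int,
    n_w: float,
    constants: Constants = DEFAULT_CONSTANTS,
    d_w: float = np.nan,
) -> HBBalance:
    """Reduce a bond list to the per-lipid balance.

    n_w is the number of waters per lipid; the excess ww count subtracts
    n_w times the bulk rate so that an unperturbed water slab contributes
    zero to the total.
    """
    if n_lipids <= 0:
        raise ValueError("n_lipids must be positive")
    if n_w < 0:
        raise ValueError("n_w must be non-negative")
    counts = {"ll": 0, "lw": 0, "ww": 0}
    for rec in records:
        counts[rec.hb_class] += 1
    n_ll = counts["ll"] / n_lipids
    n_lw = counts["lw"] / n_lipids
    n_ww_raw = counts["ww"] / n_lipids
    n_ww_excess = n_ww_raw - n_w * constants.hb_bulk
    return HBBalance(
        n_ll=n_ll,
        n_lw=n_lw,
        n_ww_raw=n_ww_raw,
        n_ww_excess=n_ww_excess,
        n_tot=n_ll + n_lw + n_ww_excess,
        n_w=n_w,
        d_w=d_w,
    )


def bridging_hbonds(records: list, frame: Frame) -> dict:
    """Water-bridged (indirect) headgroup-headgroup contacts.

    For every headgroup (lipid molecule), counts the water molecules that
    are hydrogen-bonded to it and simultaneously to at least one other
    headgroup in the same leaflet.  Each such water is counted once per
    headgroup regardless of how many partners it bridges to.

    Returns {lipid molecule_id: bridge count} covering every lipid.
    """
    mol = frame.molecule_ids
    leaflet_of: dict[int, str] = {}
    lipid_mols = set()
    for atom in frame.atoms:
        if atom.molecule_class == "lipid":
            lipid_mols.add(atom.molecule_id)
            leaflet_of[atom.molecule_id] = atom.leaflet

    # water molecule -> set of bonded lipid molecules
    partners: dict[int, set] = {}
    for rec in records:
        if rec.hb_class != "lw":
            continue
        md, ma = int(mol[rec.donor_atom]), int(mol[rec.acceptor_atom])
        lip, wat = (md, ma) if md in lipid_mols else (ma, md)
        partners.setdefault(wat, set()).add(lip)

    bridges = {lip: 0 for lip in lipid_mols}
    for wat, lips in partners.items():
        for lip in lips:
            others = [
                o for o in lips if o != lip and leaflet_of[o] == leaflet_of[lip]
            ]
            if others:
                bridges[lip] += 1
    return bridges


def delta_hb_curve(balances: list, reference="largest_D_w") -> Curve:
    """Change of the total bond number relative to a reference hydration.

    ``reference`` is either "largest_D_w" (subtract the value at the largest
    separation, emulating the infinite-separation limit) or an explicit
    reference value of n_tot.
    """
    if len(balances) < 2:
        raise ValueError("need at least two hydration levels")
    d_w = np.asarray([b.d_w for b in balances], dtype=float)
    if len(np.unique(d_w)) != len(d_w):
        raise ValueError("duplicate D_w values among balances")
    order = np.argsort(d_w)
    n_tot = np.asarray([b.n_tot for b in balances], dtype=float)[order]
    d_w = d_w[order]
    if reference == "largest_D_w":
        ref = n_tot[-1]
    else:
        ref = float(reference)
    return Curve(
        x=d_w,
        y=n_tot - ref,
        x_unit="nm",
        y_unit="HBs/lipid",
        meta={"reference": ref},
    )
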