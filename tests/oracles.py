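"""Independent reference implementations used only by the tests.

Deliberately slow and explicit: plain Python loops, no neighbor lists, no
vectorized shortcuts shared with the package code.
"""

import numpy as np

COULOMB = 138.935458  # kJ mol^-1 nm e^-2


def _min_image(d, box):
    return d - box * np.round(d / box)


def brute_force_hbonds(frame, r_cut=0.35, angle_cut_deg=30.0):
    """All (donor, hydrogen, acceptor) triples by O(N^2) enumeration."""
    pos = np.mod(frame.positions, frame.box)
    box = frame.box
    donors = [i for i, a in enumerate(frame.atoms) if "donor" in a.hb_role]
    acceptors = [i for i, a in enumerate(frame.atoms) if "acceptor" in a.hb_role]
    hydrogens_of = {}
    for i, a in enumerate(frame.atoms):
        if "hydrogen" in a.hb_role:
            hydrogens_of.setdefault(a.bonded_heavy, []).append(i)
    bonds = set()
    for d in donors:
        for a in acceptors:
            if frame.atoms[d].molecule_id == frame.atoms[a].molecule_id:
                continue
            r_vec = _min_image(pos[a] - pos[d], box)
            r_da = float(np.linalg.norm(r_vec))
            if not r_da < r_cut:
                continue
            for h in hydrogens_of.get(d, []):
                h_vec = _min_image(pos[h] - pos[d], box)
                h_norm = float(np.linalg.norm(h_vec))
                if h_norm == 0.0 or r_da == 0.0:
                    continue
                cos_a = float(np.dot(h_vec, r_vec)) / (h_norm * r_da)
                cos_a = min(1.0, max(-1.0, cos_a))
                if cos_a > np.cos(np.deg2rad(angle_cut_deg)):
                    bonds.add((d, h, int(a)))
    return bonds


def direct_insertion_energy(frame, particle, point, rotation=None, r_lj=0.9):
    """Insertion energy by direct summation over every frame atom."""
    pos = np.mod(frame.positions, frame.box)
    box = frame.box
    energy = 0.0
    for site in particle.sites:
        offset = np.asarray(site.offset, dtype=float)
        if rotation is not None:
            offset = rotation.apply(offset)
        site_pos = np.asarray(point, dtype=float) + offset
        for j in range(len(pos)):
            d = _min_image(site_pos - pos[j], box)
            r2 = float(d @ d)
            if r2 < site.hard_radius**2:
                return np.inf
            if r2 >= r_lj**2:
                continue
            atom = frame.atoms[j]
            eps = np.sqrt(site.epsilon * atom.lj_epsilon)
            if eps > 0:
                sig = 0.5 * (site.sigma + atom.lj_sigma)
                s6 = (sig * sig / r2) ** 3
                sc6 = (sig / r_lj) ** 6
                energy += 4.0 * eps * (s6 * s6 - s6 - (sc6 * sc6 - sc6))
            qq = site.charge * atom.charge
            if qq != 0.0:
                r = np.sqrt(r2)
                energy += COULOMB * qq * (1.0 / r - 1.0 / r_lj)
    return energy


def widom_mu_ex_oracle(frame, particle, n_points, kt, seed, r_lj=0.9):
    """Independent single-bin Widom estimate with its standard error."""
    rng = np.random.default_rng(seed)
    points = rng.uniform(0.0, 1.0, size=(n_points, 3)) * frame.box
    w = np.empty(n_points)
    for i, p in enumerate(points):
        du = direct_insertion_energy(frame, particle, p, r_lj=r_lj)
        w[i] = 0.0 if not np.isfinite(du) else np.exp(-du / kt)
    mean_w = w.mean()
    mu = -kt * np.log(mean_w)
    # delta-method error of -kT ln(mean)
    se_w = w.std(ddof=1) / np.sqrt(n_points)
    return mu, kt * se_w / mean_w


def grid_minimum(fn, lo, hi, n=200001):
    """Location of the minimum of fn on a dense uniform grid."""
    x = np.linspace(lo, hi, n)
    return float(x[np.argmin(fn(x))])
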