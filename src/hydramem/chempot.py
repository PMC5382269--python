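"""Water chemical potential from configurations and its pressure equivalent.

mu = mu_id + mu_ex.  The ideal part follows from the water density profile,
mu_id(z) = kT ln(rho(z)/rho_ref); the excess part from Widom test-particle
insertion, mu_ex(z) = -kT ln < exp(-dU/kT) > over random insertions in each
z bin.  Because both parts vary across the membrane normal while their sum
is flat in equilibrium, they are evaluated on the same z grid and combined
bin-wise before averaging.  The equivalent interaction pressure is
Pi = -(mu - mu0)/v_w0 with mu0 the bulk-water reference.

Insertion energetics: pairwise Lennard-Jones, shifted to zero at the cutoff
r_lj, plus truncated-and-shifted Coulomb at the same cutoff, under the
minimum-image convention.  This truncated electrostatics is a deliberate
approximation suited to the synthetic test systems; the energy routine is
isolated so an Ewald adapter can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .constants import BAR_PER_KJMOL_NM3, COULOMB_KJ_NM_E2, DEFAULT_CONSTANTS, Constants
from .frame import Frame, minimum_image
from .profiles import ZProfile


@dataclass(frozen=True)
class Site:
    """One interaction site of a test particle (offsets in nm, charge in e)."""

    offset: tuple = (0.0, 0.0, 0.0)
    charge: float = 0.0
    sigma: float = 0.0
    epsilon: float = 0.0
    hard_radius: float = 0.0


@dataclass(frozen=True)
class TestParticle:
    sites: tuple

    @property
    def multi_site(self) -> bool:
        return len(self.sites) > 1


def water_test_particle() -> TestParticle:
    """Rigid 3-site water test particle (SPC/E-like geometry and charges)."""
    d = 0.1
    half = np.deg2rad(109.47 / 2.0)
    h1 = (d * np.sin(half), 0.0, d * np.cos(half))
    h2 = (-d * np.sin(half), 0.0, d * np.cos(half))
    return TestParticle(
        sites=(
            Site(offset=(0.0, 0.0, 0.0), charge=-0.8476, sigma=0.3166, epsilon=0.650),
            Site(offset=h1, charge=0.4238),
            Site(offset=h2, charge=0.4238),
        )
    )


def hard_sphere_test_particle(radius: float) -> TestParticle:
    return TestParticle(sites=(Site(hard_radius=radius),))


@dataclass
class MuProfile:
    """Binned chemical-potential profile; mu_tot = mu_id + mu_ex per bin."""

    z_centers: np.ndarray
    mu_id: np.ndarray
    mu_ex: np.ndarray
    mu_ex_err: np.ndarray
    insertions_per_bin: np.ndarray
    acceptance_weight: np.ndarray
    reliable: np.ndarray

    @property
    def mu_tot(self) -> np.ndarray:
        return self.mu_id + self.mu_ex


# ---------------------------------------------------------------------------
# insertion energies
# ---------------------------------------------------------------------------

def _pair_energies(r2, sigma, epsilon, qprod, r_cut):
    """Shifted LJ + truncated-shifted Coulomb for an array of pairs."""
    r2 = np.asarray(r2)
    energy = np.zeros_like(r2, dtype=float)
    lj = epsilon > 0
    if np.any(lj):
        s2 = (sigma[lj] ** 2) / r2[lj]
        s6 = s2**3
        sc6 = (sigma[lj] / r_cut) ** 6
        energy[lj] += 4.0 * epsilon[lj] * (s6 * s6 - s6 - (sc6 * sc6 - sc6))
    coul = qprod != 0
    if np.any(coul):
        r = np.sqrt(r2[coul])
        energy[coul] += COULOMB_KJ_NM_E2 * qprod[coul] * (1.0 / r - 1.0 / r_cut)
    return energy


def insertion_energies(
    frame: Frame,
    particle: TestParticle,
    points: np.ndarray,
    rotations=None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """dU (kJ/mol) for inserting ``particle`` at each point (n, 3).

    ``rotations`` is an optional scipy Rotation of length n applied to the
    site offsets (required only for multi-site particles).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    offsets = np.asarray([s.offset for s in particle.sites])
    n_sites = len(particle.sites)
    if rotations is None:
        site_pos = points[:, None, :] + offsets[None, :, :]
    else:
        mats = rotations.as_matrix()  # (n, 3, 3)
        site_pos = points[:, None, :] + np.einsum("nij,sj->nsi", mats, offsets)
    site_pos = site_pos.reshape(n * n_sites, 3)
    site_pos = np.mod(site_pos, frame.box)

    if frame.n_atoms == 0:
        return np.zeros(n)

    pos = frame.wrapped()
    pos = np.minimum(pos, np.nextafter(frame.box, 0.0))
    site_pos = np.minimum(site_pos, np.nextafter(frame.box, 0.0))
    tree = cKDTree(pos, boxsize=frame.box)
    r_query = max(constants.r_lj, max(s.hard_radius for s in particle.sites))
    lists = tree.query_ball_point(site_pos, r=r_query)
    counts = np.fromiter((len(l) for l in lists), dtype=int, count=len(lists))
    if counts.sum() == 0:
        return np.zeros(n)
    j = np.concatenate([np.asarray(l, dtype=int) for l in lists if l])
    i = np.repeat(np.arange(len(site_pos)), counts)

    d = minimum_image(site_pos[i] - pos[j], frame.box)
    r2 = np.einsum("ij,ij->i", d, d)

    q_frame = frame.charges
    sig_frame = frame.lj_sigmas
    eps_frame = frame.lj_epsilons
    site_of = i % n_sites
    s_sigma = np.asarray([s.sigma for s in particle.sites])[site_of]
    s_eps = np.asarray([s.epsilon for s in particle.sites])[site_of]
    s_q = np.asarray([s.charge for s in particle.sites])[site_of]
    s_hard = np.asarray([s.hard_radius for s in particle.sites])[site_of]

    sigma = 0.5 * (s_sigma + sig_frame[j])
    epsilon = np.sqrt(s_eps * eps_frame[j])
    qprod = s_q * q_frame[j]
    in_cut = r2 < constants.r_lj**2
    e_pair = np.zeros(len(r2))
    e_pair[in_cut] = _pair_energies(
        r2[in_cut], sigma[in_cut], epsilon[in_cut], qprod[in_cut], constants.r_lj
    )
    hard_hit = r2 < s_hard**2
    e_pair[hard_hit] = np.inf

    e_site = np.zeros(len(site_pos))
    np.add.at(e_site, i, e_pair)
    return e_site.reshape(n, n_sites).sum(axis=1)


# ---------------------------------------------------------------------------
# Widom profile
# ---------------------------------------------------------------------------

def widom_mu_ex_profile(
    frames,
    test_particle: TestParticle,
    n_insertions: int = 2000,
    bin_width: float = 0.2,
    constants: Constants = DEFAULT_CONSTANTS,
    seed: int = 0,
    n_blocks: int = 10,
    n_bootstrap: int = 200,
) -> MuProfile:
    """Excess chemical potential per z bin from test-particle insertion.

    ``n_insertions`` insertions are made per bin per frame, uniform in the
    bin slab with random rigid orientations.  Statistical errors come from a
    bootstrap over insertion blocks; bins where every Boltzmann factor
    underflows to zero are flagged unreliable rather than averaged.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    if n_insertions < 1:
        raise ValueError("n_insertions must be positive")
    box = frames[0].box
    lz = box[2]
    n_bins = max(1, int(round(lz / bin_width)))
    edges = np.linspace(0.0, lz, n_bins + 1)  # absolute z; midplane at lz/2
    centers = 0.5 * (edges[1:] + edges[:-1])
    kt = constants.kT
    rng = np.random.default_rng(seed)

    weights = [[] for _ in range(n_bins)]
    for frame in frames:
        z_mid = frame.water_midplane_z()
        shift = z_mid - lz / 2.0  # map bin frame (midplane at lz/2) to box frame
        for b in range(n_bins):
            pts = np.column_stack(
                [
                    rng.uniform(0.0, box[0], n_insertions),
                    rng.uniform(0.0, box[1], n_insertions),
                    np.mod(
                        rng.uniform(edges[b], edges[b + 1], n_insertions) + shift, lz
                    ),
                ]
            )
            rots = (
                Rotation.random(n_insertions, rng=rng)
                if test_particle.multi_site
                else None
            )
            du = insertion_energies(frame, test_particle, pts, rots, constants)
            with np.errstate(over="ignore", under="ignore"):
                w = np.exp(-np.clip(du / kt, -700.0, 700.0))
            w[~np.isfinite(du)] = 0.0
            weights[b].append(w)

    mu_ex = np.full(n_bins, np.nan)
    mu_err = np.full(n_bins, np.nan)
    acc = np.zeros(n_bins)
    n_ins = np.zeros(n_bins, dtype=int)
    reliable = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        w = np.concatenate(weights[b])
        n_ins[b] = len(w)
        mean_w = float(np.mean(w))
        acc[b] = mean_w
        if mean_w <= 0.0:
            continue
        reliable[b] = True
        mu_ex[b] = -kt * np.log(mean_w)
        nb = min(n_blocks, len(w))
        block_means = np.array([bk.mean() for bk in np.array_split(w, nb)])
        idx = rng.integers(0, nb, size=(n_bootstrap, nb))
        boot = block_means[idx].mean(axis=1)
        boot = boot[boot > 0]
        if len(boot) > 1:
            mu_err[b] = float(np.std(-kt * np.log(boot), ddof=1))
        else:
            mu_err[b] = np.nan

    return MuProfile(
        z_centers=centers - lz / 2.0,
        mu_id=np.zeros(n_bins),
        mu_ex=mu_ex,
        mu_ex_err=mu_err,
        insertions_per_bin=n_ins,
        acceptance_weight=acc,
        reliable=reliable,
    )


def mu_id_profile(
    density: ZProfile, rho_ref: float, constants: Constants = DEFAULT_CONSTANTS
) -> MuProfile:
    """Ideal contribution kT ln(rho(z)/rho_ref); empty bins are flagged.

    The thermal-wavelength constant is omitted: it cancels in any difference
    mu - mu0 evaluated with the same convention (asserted by tests).
    """
    if rho_ref <= 0:
        raise ValueError("rho_ref must be positive")
    rho = np.asarray(density.values, dtype=float)
    if np.any(rho < 0):
        raise ValueError("densities must be non-negative")
    ok = rho > 0
    mu = np.full(len(rho), np.nan)
    mu[ok] = constants.kT * np.log(rho[ok] / rho_ref)
    return MuProfile(
        z_centers=np.asarray(density.z_centers, dtype=float),
        mu_id=mu,
        mu_ex=np.zeros(len(rho)),
        mu_ex_err=np.zeros(len(rho)),
        insertions_per_bin=np.zeros(len(rho), dtype=int),
        acceptance_weight=np.zeros(len(rho)),
        reliable=ok,
    )


def combine_mu(mu_id: MuProfile, mu_ex: MuProfile, central_window: float):
    """Combine ideal and excess profiles bin-wise and average centrally.

    Returns (mu, mu_err) in kJ/mol.  The estimate is the acceptance-weighted
    mean of mu(z) = mu_id(z) + mu_ex(z) over reliable bins with
    |z| <= central_window/2; the error is the larger of the weighted SE and
    the RMS deviation of mu(z) from flatness across the window.
    """
    if len(mu_id.z_centers) != len(mu_ex.z_centers) or not np.allclose(
        mu_id.z_centers, mu_ex.z_centers, atol=1e-9
    ):
        raise ValueError("ideal and excess profiles use different bin grids")
    z = mu_id.z_centers
    mu = mu_id.mu_id + mu_ex.mu_ex
    ok = (
        mu_id.reliable
        & mu_ex.reliable
        & np.isfinite(mu)
        & (np.abs(z) <= central_window / 2.0)
    )
    if not ok.any():
        raise ValueError("no reliable bins inside the central window")
    w = mu_ex.acceptance_weight[ok] * np.maximum(mu_ex.insertions_per_bin[ok], 1)
    if np.all(w == 0):
        w = np.ones(ok.sum())
    w = w / w.sum()
    est = float(np.sum(w * mu[ok]))
    err_bins = mu_ex.mu_ex_err[ok]
    err_bins = np.where(np.isfinite(err_bins), err_bins, 0.0)
    weighted_se = float(np.sqrt(np.sum((w * err_bins) ** 2)))
    rms_flat = float(np.sqrt(np.sum(w * (mu[ok] - est) ** 2)))
    return est, max(weighted_se, rms_flat)


def pressure_from_mu(
    mu: float, mu0: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Equivalent interaction pressure Pi = -(mu - mu0)/v_w0, in bar.

    mu below the bulk reference means the membrane stack still takes up
    water: positive Pi, repulsion.
    """
    return -(mu - mu0) / constants.v_w0 * BAR_PER_KJMOL_NM3


def bulk_mu_ex(
    frames,
    test_particle: TestParticle,
    n_insertions: int = 5000,
    constants: Constants = DEFAULT_CONSTANTS,
    seed: int = 0,
):
    """Bulk-reference excess chemical potential (single bin over the box).

    Running the same estimator on a bulk reference makes all conventions
    cancel in mu - mu0.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    frames = list(frames)
    lz = frames[0].box[2]
    prof = widom_mu_ex_profile(
        frames,
        test_particle,
        n_insertions=n_insertions,
        bin_width=lz,
        constants=constants,
        seed=seed,
    )
    if not prof.reliable[0]:
        raise ValueError("bulk reference insertion produced no statistics")
    return float(prof.mu_ex[0]), float(prof.mu_ex_err[0])
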