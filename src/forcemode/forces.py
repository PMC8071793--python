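"""Short-range nonbonded lipid-protein forces and punctual stress.

The force model is the short-range part of a standard membrane force
field: truncated Coulomb plus a Lennard-Jones interaction whose *force*
is switched smoothly to zero between ``r_switch`` and ``r_cut``
(CHARMM-style force switch, as used for membrane simulations). Long-range
reciprocal-space electrostatics and bonded terms are deliberately absent:
only the short-range protein-lipid pair forces enter the punctual stress

    PS_i = sum_j |F_ij|,

where ``F_ij`` is the *vector* sum of all atom-pair forces between
protein residue ``i`` and lipid molecule ``j``, and the outer sum over
lipids is a *scalar* sum of magnitudes. Two lipids pulling a residue in
opposite directions therefore add up rather than cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_CONSTANT, R_CUT, R_SWITCH, STRIDE_PS
from .system import ToySystem, minimum_image


class SingularGeometryError(ValueError):
    """Two interacting atoms coincide (r = 0)."""


@dataclass
class PairForce:
    """Net force of lipid molecule ``lipid_index`` on protein residue
    ``residue_index`` (kJ mol^-1 nm^-1)."""

    residue_index: int
    lipid_index: int
    force: np.ndarray


@dataclass
class PunctualStressSeries:
    """Frames x residues matrix of punctual stress values.

    ``values[f, i]`` is PS of protein residue ``residue_ids[i]`` in frame
    ``f``; ``frame_times`` are in ps.
    """

    values: np.ndarray
    residue_ids: list[str]
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.residue_ids):
            raise ValueError("values must be frames x residues")
        if len(self.frame_times) != self.values.shape[0]:
            raise ValueError("one frame time per row required")


# ---------------------------------------------------------------------------
# radial force kernels (positive = repulsive, along the a-b separation)
# ---------------------------------------------------------------------------

def _coulomb_radial(qq, r, r_cut):
    return np.where(r <= r_cut, COULOMB_CONSTANT * qq / r**2, 0.0)

def _switch_term(c: float, p: int, r, r_switch: float, r_cut: float):
    """Force-switched single power-law term.

    For V = c / r^p the unswitched radial force is a/r^(p+1) with a = p*c.
    Between r_switch and r_cut a cubic in (r - r_switch) is added so that
    both the force and its derivative vanish at r_cut; inside r_switch the
    plain force is used (the added terms vanish at r_switch with zero
    slope, so force and derivative are continuous everywhere).
    """
    a = p * c
    dr = r_cut - r_switch
    A = -a * ((p + 4) * r_cut - (p + 1) * r_switch) / (r_cut ** (p + 2) * dr**2)
    B = a * ((p + 3) * r_cut - (p + 1) * r_switch) / (r_cut ** (p + 2) * dr**3)
    plain = a / r ** (p + 1)
    switched = plain + A * (r - r_switch) ** 2 + B * (r - r_switch) ** 3
    return np.where(r <= r_switch, plain, np.where(r <= r_cut, switched, 0.0))

def _lj_radial(sigma, epsilon, r, r_switch, r_cut):
    c12 = 4.0 * epsilon * sigma**12
    c6 = 4.0 * epsilon * sigma**6
    return (_switch_term(c12, 12, r, r_switch, r_cut)
            + _switch_term(-c6, 6, r, r_switch, r_cut))


def pair_atom_force(pos_a, pos_b, q_a, q_b, sigma, epsilon, box,
                    r_cut=R_CUT, r_switch=R_SWITCH) -> np.ndarray:
    """Force on atom ``a`` due to atom ``b`` (kJ mol^-1 nm^-1).

    ``sigma`` and ``epsilon`` are the *pair* parameters (combination rule
    already applied). The force is computed under the orthorhombic
    minimum-image convention: truncated Coulomb plus force-switched
    Lennard-Jones, identically zero beyond ``r_cut``, and antisymmetric
    under exchange of the two atoms.
    """
    d = minimum_image(np.asarray(pos_a, float) - np.asarray(pos_b, float), box)
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise SingularGeometryError("coincident atoms: pair distance is zero")
    if r > r_cut:
        return np.zeros(3)
    f = float(_coulomb_radial(q_a * q_b, r, r_cut)
              + _lj_radial(sigma, epsilon, r, r_switch, r_cut))
    return (f / r) * d


def combine_lorentz_berthelot(sigma_a, sigma_b, eps_a, eps_b):
    """Arithmetic-sigma / geometric-epsilon combination rule."""
    return 0.5 * (sigma_a + sigma_b), np.sqrt(eps_a * eps_b)


def residue_lipid_force(system: ToySystem, frame_coords, residue_index: int,
                        lipid_index: int, r_cut=R_CUT, r_switch=R_SWITCH) -> PairForce:
    """Vector sum of atom-pair forces between one protein residue and one
    lipid molecule (force on the residue)."""
    coords = np.asarray(frame_coords, dtype=float)
    if residue_index not in system.protein_residue_ids:
        raise IndexError(f"residue {residue_index} is not a protein residue")
    if lipid_index not in system.lipid_molecule_ids:
        raise IndexError(f"molecule {lipid_index} is not a lipid")
    res_atoms = system.residue_atoms(residue_index)
    lip_atoms = system.molecule_atoms(lipid_index)
    total = np.zeros(3)
    for ia in res_atoms:
        for ib in lip_atoms:
            sigma, eps = combine_lorentz_berthelot(
                system.lj_sigma[ia], system.lj_sigma[ib],
                system.lj_epsilon[ia], system.lj_epsilon[ib])
            total += pair_atom_force(coords[ia], coords[ib],
                                     system.charges[ia], system.charges[ib],
                                     sigma, eps, system.box, r_cut, r_switch)
    return PairForce(int(residue_index), int(lipid_index), total)


def punctual_stress(system: ToySystem, frame_coords,
                    r_cut=R_CUT, r_switch=R_SWITCH) -> np.ndarray:
    """Per-residue punctual stress PS_i for one frame.

    Vectorised over all protein-lipid atom pairs: pair forces are
    vector-summed within each (residue, lipid molecule) block, the block
    magnitudes are then scalar-summed over lipids. Returns a length-R
    vector ordered like ``system.protein_residue_ids``; all zeros if the
    system has no lipids.
    """
    coords = np.asarray(frame_coords, dtype=float)
    if coords.shape != (system.n_atoms, 3):
        raise ValueError(f"frame has shape {coords.shape}, expected "
                         f"({system.n_atoms}, 3)")
    res_ids = system.protein_residue_ids
    if len(res_ids) == 0:
        raise ValueError("system has no protein residues")
    pa = np.flatnonzero(system.protein_mask)
    la = np.flatnonzero(system.lipid_mask)
    if len(la) == 0:
        return np.zeros(len(res_ids))

    d = coords[pa][:, None, :] - coords[la][None, :, :]
    d = minimum_image(d, system.box)
    r = np.linalg.norm(d, axis=-1)
    if np.any(r == 0.0):
        raise SingularGeometryError("coincident protein and lipid atoms")
    qq = system.charges[pa][:, None] * system.charges[la][None, :]
    sigma = 0.5 * (system.lj_sigma[pa][:, None] + system.lj_sigma[la][None, :])
    eps = np.sqrt(system.lj_epsilon[pa][:, None] * system.lj_epsilon[la][None, :])
    f = _coulomb_radial(qq, r, r_cut) + _lj_radial(sigma, eps, r, r_switch, r_cut)
    f = np.where(r <= r_cut, f, 0.0)
    fvec = (f / r)[..., None] * d

    lip_ids = system.lipid_molecule_ids
    res_pos = np.searchsorted(res_ids, system.residue_index[pa])
    lip_pos = np.searchsorted(lip_ids, system.molecule_index[la])
    block = np.zeros((len(res_ids), len(lip_ids), 3))
    np.add.at(block,
              (np.broadcast_to(res_pos[:, None], r.shape),
               np.broadcast_to(lip_pos[None, :], r.shape)),
              fvec)
    return np.linalg.norm(block, axis=-1).sum(axis=1)


def stress_trajectory(system: ToySystem, frames, stride_ps: float = STRIDE_PS,
                      r_cut=R_CUT, r_switch=R_SWITCH) -> PunctualStressSeries:
    """Punctual stress for every frame of a trajectory.

    ``frames`` is an iterable of (N, 3) coordinate arrays; frame times are
    ``index * stride_ps`` (default 40 ps between analysed frames).
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if not frames:
        raise ValueError("frames must be nonempty")
    values = np.stack([punctual_stress(system, f, r_cut, r_switch)
                       for f in frames])
    times = np.arange(len(frames), dtype=float) * stride_ps
    return PunctualStressSeries(values, system.residue_labels(), times)


def stress_profile_z(system: ToySystem, stress_values, n_bins: int = 20):
    """Project mean per-residue stress onto the membrane normal (z).

    Residue positions are geometric centres of their atoms. Returns
    ``(bin_centers, mean_stress_per_bin)``; empty bins hold NaN.
    """
    stress_values = np.asarray(stress_values, dtype=float)
    res_ids = system.protein_residue_ids
    if stress_values.shape[-1] != len(res_ids):
        raise ValueError("one stress value per protein residue required")
    mean_stress = stress_values.mean(axis=0) if stress_values.ndim == 2 else stress_values
    z = np.array([system.positions[system.residue_atoms(r), 2].mean()
                  for r in res_ids])
    edges = np.linspace(z.min(), z.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    profile = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            profile[b] = mean_stress[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, profile
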