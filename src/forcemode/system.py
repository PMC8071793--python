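"""In-memory description of a small membrane-protein toy system.

A :class:`ToySystem` carries everything the nonbonded force kernel needs:
atom coordinates, per-atom partial charges and Lennard-Jones parameters,
and the residue / molecule / group bookkeeping that defines which pairs
are protein-lipid pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .constants import R_CUT

PROTEIN = "protein"
LIPID = "lipid"


@dataclass
class ToySystem:
    """Atoms with nonbonded parameters and residue/molecule labels.

    Parameters
    ----------
    positions : (N, 3) float array
        Atom coordinates in nm.
    charges : (N,) float array
        Partial charges in units of e.
    lj_sigma, lj_epsilon : (N,) float arrays
        Per-atom Lennard-Jones parameters (nm, kJ/mol); pair parameters
        are derived with Lorentz-Berthelot combination rules.
    residue_index : (N,) int array
        Residue of each atom. Protein residues come first (0..R-1);
        each lipid molecule is its own residue.
    molecule_index : (N,) int array
        Molecule of each atom; the whole protein is molecule 0, lipid
        molecules are numbered from 1.
    group_tag : (N,) str array
        Either ``"protein"`` or ``"lipid"`` per atom.
    chain_tag : (n_residues,) str array
        ``"A"``/``"B"`` for protein residues, ``"none"`` for lipids.
    box : (3,) float array
        Orthorhombic box lengths in nm; must exceed twice the cutoff so
        the minimum-image convention is unambiguous.
    metadata : dict
        Free-form extras (e.g. the lipid placement plan of the generator).
    """

    positions: np.ndarray
    charges: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    residue_index: np.ndarray
    molecule_index: np.ndarray
    group_tag: np.ndarray
    chain_tag: np.ndarray
    box: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.molecule_index = np.asarray(self.molecule_index, dtype=int)
        self.group_tag = np.asarray(self.group_tag, dtype=object)
        self.chain_tag = np.asarray(self.chain_tag, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        n = self.n_atoms
        for name in ("charges", "lj_sigma", "lj_epsilon", "residue_index",
                     "molecule_index", "group_tag"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, "
                                 f"expected {n}")
        if self.box.shape != (3,):
            raise ValueError("box must be a length-3 vector of orthorhombic "
                             "box lengths; triclinic boxes are not supported")
        if np.any(self.box <= 2.0 * R_CUT):
            raise ValueError(f"box lengths must exceed {2 * R_CUT} nm so the "
                             "minimum image within the cutoff is unambiguous")
        tags = set(self.group_tag.tolist())
        if not tags <= {PROTEIN, LIPID}:
            raise ValueError(f"unknown group tags: {tags - {PROTEIN, LIPID}}")
        if len(self.chain_tag) != self.n_residues:
            raise ValueError("chain_tag must have one entry per residue")

    # -- bookkeeping helpers -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max()) + 1 if self.n_atoms else 0

    @property
    def protein_mask(self) -> np.ndarray:
        return self.group_tag == PROTEIN

    @property
    def lipid_mask(self) -> np.ndarray:
        return self.group_tag == LIPID

    @property
    def protein_residue_ids(self) -> np.ndarray:
        """Sorted residue indices that contain protein atoms."""
        return np.unique(self.residue_index[self.protein_mask])

    @property
    def lipid_molecule_ids(self) -> np.ndarray:
        """Sorted molecule indices that contain lipid atoms."""
        return np.unique(self.molecule_index[self.lipid_mask])

    def residue_atoms(self, residue: int) -> np.ndarray:
        return np.flatnonzero(self.residue_index == residue)

    def molecule_atoms(self, molecule: int) -> np.ndarray:
        return np.flatnonzero(self.molecule_index == molecule)

    def residue_labels(self) -> list[str]:
        """``chain/residue`` identifiers for the protein residues."""
        return [f"{self.chain_tag[r]}/{r}" for r in self.protein_residue_ids]


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the central orthorhombic image."""
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    if box.shape != (3,):
        raise ValueError("only orthorhombic (length-3) boxes are supported")
    return delta - box * np.round(delta / box)
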