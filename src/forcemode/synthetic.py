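"""Synthetic inputs for every stage of the pipeline.

Three generators, all deterministic in their seed:

* :func:`generate_toy_system` — a small membrane-protein toy system with
  known nonbonded parameters, protein residues stacked along the
  membrane normal and lipids placed at controlled distances (alternating
  inside / outside the 1.2 nm cutoff) for force-kernel tests.
* :func:`generate_transition_trajectory` — a down reference, an up
  reference displaced by a rigid-mode-free random field, and frames
  interpolating between them (optionally jittered and pre-transformed by
  random rigid motions to exercise the superposition step).
* :func:`generate_force_ensemble` — replica ensembles of per-frame
  feature vectors and difference-vector observables driven by a latent
  down->up coordinate, mirroring the study design of the real data:
  10 replicas (7 under tension with a transition + 3 controls), 500
  frames each, 521 residue features of which a few "hotspots" carry the
  transition signal with mixed signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from .system import LIPID, PROTEIN, ToySystem

# lipid placement distances (nm): "inside" anchors within the 1.0 nm
# switch radius of a protein atom, "outside" beyond the 1.2 nm cutoff of
# every protein atom even after atom jitter (see generate_toy_system)
_INSIDE_RANGE = (0.4, 0.8)
_OUTSIDE_RANGE = (1.40, 1.70)
_ATOM_JITTER = 0.05
_RESIDUE_SPACING = 0.5


def generate_toy_system(n_protein_residues: int, n_lipids: int,
                        atoms_per_residue: int, seed: int) -> ToySystem:
    """Build a toy membrane-protein system with known parameters.

    Protein residues are stacked along z (the membrane normal) at 0.5 nm
    spacing, first half chain A, second half chain B. Lipid molecules
    alternate between a placement *inside* the cutoff (centre 0.4-0.8 nm
    from a randomly chosen protein atom, same z) and *outside* it
    (radial distance 1.40-1.70 nm, beyond 1.2 nm of every protein atom).
    Charges are drawn uniformly from [-0.5, 0.5] e, sigma from
    [0.25, 0.35] nm, epsilon from [0.2, 0.8] kJ/mol. The placement plan
    is stored in ``metadata["lipid_inside_plan"]``.
    """
    if n_protein_residues < 1 or n_lipids < 1 or atoms_per_residue < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)

    span_z = n_protein_residues * _RESIDUE_SPACING
    box = np.array([6.0, 6.0, max(6.0, span_z + 4.0)])
    center = box / 2.0

    positions, residue_index, molecule_index, group_tag = [], [], [], []
    for r in range(n_protein_residues):
        rc = center + np.array([0.0, 0.0,
                                (r - (n_protein_residues - 1) / 2.0)
                                * _RESIDUE_SPACING])
        for _ in range(atoms_per_residue):
            positions.append(rc + rng.uniform(-_ATOM_JITTER, _ATOM_JITTER, 3))
            residue_index.append(r)
            molecule_index.append(0)
            group_tag.append(PROTEIN)

    n_protein_atoms = len(positions)
    inside_plan = []
    for l in range(n_lipids):
        inside = (l % 2 == 0)
        inside_plan.append(inside)
        anchor = np.asarray(positions[rng.integers(n_protein_atoms)])
        lo, hi = _INSIDE_RANGE if inside else _OUTSIDE_RANGE
        radius = rng.uniform(lo, hi)
        angle = rng.uniform(0.0, 2.0 * np.pi)
        lc = anchor + np.array([radius * np.cos(angle),
                                radius * np.sin(angle), 0.0])
        for _ in range(atoms_per_residue):
            positions.append(lc + rng.uniform(-_ATOM_JITTER, _ATOM_JITTER, 3))
            residue_index.append(n_protein_residues + l)
            molecule_index.append(1 + l)
            group_tag.append(LIPID)

    n_atoms = len(positions)
    chain_tag = (["A"] * (n_protein_residues - n_protein_residues // 2)
                 + ["B"] * (n_protein_residues // 2)
                 + ["none"] * n_lipids)
    return ToySystem(
        positions=np.asarray(positions),
        charges=rng.uniform(-0.5, 0.5, n_atoms),
        lj_sigma=rng.uniform(0.25, 0.35, n_atoms),
        lj_epsilon=rng.uniform(0.2, 0.8, n_atoms),
        residue_index=np.asarray(residue_index),
        molecule_index=np.asarray(molecule_index),
        group_tag=np.asarray(group_tag, dtype=object),
        chain_tag=np.asarray(chain_tag, dtype=object),
        box=box,
        metadata={"lipid_inside_plan": inside_plan, "seed": seed},
    )


@dataclass
class TransitionTrajectory:
    """Interpolated down->up toy trajectory with references.

    ``frames`` are in the reference frame of the down structure;
    ``transformed_frames`` are the same frames after a random rigid
    rotation + translation per frame (to exercise superposition).
    """

    frames: np.ndarray
    transformed_frames: np.ndarray
    r_down: np.ndarray
    r_up: np.ndarray
    selection: np.ndarray
    alphas: np.ndarray


def _remove_rigid_modes(displacement: np.ndarray,
                        coords: np.ndarray) -> np.ndarray:
    """Project net translation and net rotation out of a displacement
    field, so adding any multiple of it to ``coords`` leaves the optimal
    rigid-body fit onto ``coords`` exactly the identity."""
    d = displacement - displacement.mean(axis=0)
    r = coords - coords.mean(axis=0)
    # solve inertia-tensor equation for the angular component
    inertia = np.eye(3) * np.sum(r**2) - r.T @ r
    omega = np.linalg.solve(inertia, np.sum(np.cross(r, d), axis=0))
    return d - np.cross(omega, r)


def generate_transition_trajectory(down: ToySystem,
                                   displacement_magnitude: float,
                                   n_frames: int, seed: int,
                                   jitter_sigma: float = 0.0
                                   ) -> TransitionTrajectory:
    """Interpolate linearly from a down to a displaced up structure.

    The up reference equals the down reference plus a random
    displacement field on the protein atoms, orthogonalised against the
    six rigid-body modes and rescaled to the requested RMS magnitude
    (nm). Frames follow alpha in [0, 1] linearly with optional Gaussian
    jitter of width ``jitter_sigma``; each frame is also returned after
    a random rigid rotation + translation.
    """
    if displacement_magnitude <= 0:
        raise ValueError("displacement_magnitude must be > 0")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    sel = np.flatnonzero(down.protein_mask)
    d = _remove_rigid_modes(rng.normal(size=(len(sel), 3)),
                            down.positions[sel])
    d *= displacement_magnitude / np.sqrt(np.mean(np.sum(d**2, axis=1)))

    r_down = down.positions.copy()
    r_up = r_down.copy()
    r_up[sel] += d

    alphas = np.linspace(0.0, 1.0, n_frames)
    frames = np.repeat(r_down[None], n_frames, axis=0)
    frames[:, sel, :] += alphas[:, None, None] * d
    if jitter_sigma > 0:
        frames[:, sel, :] += rng.normal(0.0, jitter_sigma,
                                        (n_frames, len(sel), 3))

    transformed = np.empty_like(frames)
    for k in range(n_frames):
        quat = rng.normal(size=4)
        rot = Rotation.from_quat(quat / np.linalg.norm(quat))
        shift = rng.uniform(-1.0, 1.0, 3)
        transformed[k] = frames[k] @ rot.as_matrix().T + shift
    return TransitionTrajectory(frames, transformed, r_down, r_up,
                                sel, alphas)


@dataclass
class SyntheticEnsembleSpec:
    """Study design of a synthetic force/observable ensemble.

    Defaults mirror the real study's shape: 10 replicas (7 under tension
    with a down->up transition + 3 tension-free controls), 500 analysed
    frames per replica, 521 per-residue features of which 20 hotspots of
    amplitude 1.0 (mixed signs) carry the transition, with per-frame
    Gaussian feature noise of width 2.0. The latent switch midpoint is
    drawn uniformly within ``transition_window`` and the switch follows
    a logistic ramp about 20 frames wide.
    """

    n_replicas_transition: int = 7
    n_replicas_control: int = 3
    n_frames: int = 500
    n_features: int = 521
    n_hotspots: int = 20
    hotspot_amplitude: float = 1.0
    noise_sigma: float = 2.0
    transition_window: tuple[int, int] = (100, 400)
    observable_scale: float = 1.0
    observable_noise_sigma: float = 0.1
    ramp_width: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_features >= self.n_hotspots >= 1:
            raise ValueError("require n_features >= n_hotspots >= 1")
        if self.noise_sigma < 0 or self.observable_noise_sigma < 0:
            raise ValueError("noise widths must be >= 0")
        if self.n_replicas_transition < 0 or self.n_replicas_control < 0:
            raise ValueError("replica counts must be >= 0")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames per replica")
        lo, hi = self.transition_window
        if not 0 <= lo <= hi < self.n_frames:
            raise ValueError("transition_window must lie within the frames")


@dataclass
class SyntheticEnsemble:
    """Generated replicas with their ground truth.

    ``features[r]`` is frames x n_features, ``observable[r]`` and
    ``state_labels[r]`` are per-frame; ``true_coefficients`` is the
    length-p hotspot vector used to build the features (positive entry:
    the feature grows through the down->up transition; negative: it
    drops).
    """

    spec: SyntheticEnsembleSpec
    features: list[np.ndarray]
    observable: list[np.ndarray]
    state_labels: list[np.ndarray]
    true_coefficients: np.ndarray
    replica_kind: list[str]
    latent: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def n_replicas(self) -> int:
        return len(self.features)

    def replicas(self):
        """View as :class:`forcemode.validation.Replica` objects."""
        from .validation import Replica

        return [Replica(self.features[i], self.observable[i],
                        self.state_labels[i], replica_id=f"rep{i}",
                        kind=self.replica_kind[i])
                for i in range(self.n_replicas)]

    def residue_ids(self) -> list[str]:
        return [f"R{i:03d}" for i in range(self.spec.n_features)]


def generate_force_ensemble(spec: SyntheticEnsembleSpec) -> SyntheticEnsemble:
    """Generate a replica ensemble with a known latent transition.

    The latent coordinate s(t) is -1 (down) throughout control replicas
    and ramps logistically from -1 to +1 in transition replicas, with
    the midpoint drawn uniformly from ``transition_window``. Features
    are ``baseline + true_coefficients * s(t) + noise`` with baselines
    drawn once per ensemble from N(10, 2) (nonzero resting stress the
    PLS mean-centring must absorb); the observable is
    ``observable_scale * s(t) + noise`` and the state label is
    ``1 iff s(t) > 0``.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_features

    hot = rng.choice(p, size=spec.n_hotspots, replace=False)
    signs = np.where(np.arange(spec.n_hotspots) % 2 == 0, 1.0, -1.0)
    coef = np.zeros(p)
    coef[hot] = signs * spec.hotspot_amplitude
    baseline = rng.normal(10.0, 2.0, p)

    t = np.arange(spec.n_frames)
    tau = spec.ramp_width / 4.0  # logistic reaches ~+-0.96 within the width
    features, observable, labels, kinds, latents = [], [], [], [], []
    n_total = spec.n_replicas_transition + spec.n_replicas_control
    for rep in range(n_total):
        if rep < spec.n_replicas_transition:
            lo, hi = spec.transition_window
            t0 = int(rng.integers(lo, hi + 1))
            s = -1.0 + 2.0 / (1.0 + np.exp(-(t - t0) / tau))
            kinds.append("transition")
        else:
            s = np.full(spec.n_frames, -1.0)
            kinds.append("control")
        X = baseline + np.outer(s, coef)
        if spec.noise_sigma > 0:
            X = X + rng.normal(0.0, spec.noise_sigma, (spec.n_frames, p))
        y = spec.observable_scale * s
        if spec.observable_noise_sigma > 0:
            y = y + rng.normal(0.0, spec.observable_noise_sigma, spec.n_frames)
        features.append(X)
        observable.append(y)
        labels.append((s > 0.0).astype(int))
        latents.append(s)
    return SyntheticEnsemble(spec, features, observable, labels, coef,
                             kinds, latents)


def default_chain_pairing(n_features: int) -> dict[str, str]:
    """Synthetic chain pairing: the first half of the features is chain
    A, the second half chain B, paired index-wise; a middle odd feature
    stays unpaired."""
    half = n_features // 2
    return {f"R{i:03d}": f"R{i + half + n_features % 2:03d}"
            for i in range(half)}


def spec_to_dict(spec: SyntheticEnsembleSpec) -> dict:
    d = asdict(spec)
    d["transition_window"] = list(spec.transition_window)
    return d
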