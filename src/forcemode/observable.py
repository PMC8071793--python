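"""Conformational difference-vector observable.

The down->up conformational change is tracked with a single scalar per
frame: after least-squares superposition of the frame onto the *down*
reference over a backbone selection, the deviation from the up/down
midpoint is projected onto the up-minus-down displacement,

    x(t) = sum_i (r_i(t) - r_avg_i) . (r_up_i - r_down_i),
    r_avg_i = (r_up_i + r_down_i) / 2,

summed over the selected backbone atoms (units nm^2). Frames on the
"down" side give negative x, frames on the "up" side positive x; zero is
the natural separatrix between the two states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import STATE_THRESHOLD, STRIDE_PS


class DegenerateGeometryError(ValueError):
    """Superposition selection is too small or collinear."""


@dataclass
class ReferencePair:
    """Up and down reference structures sharing one atom ordering.

    ``r_up``/``r_down`` are full-structure coordinate arrays (nm);
    ``backbone_selection`` indexes the atoms used both for fitting and
    for the projection sum.
    """

    r_up: np.ndarray
    r_down: np.ndarray
    backbone_selection: np.ndarray

    def __post_init__(self) -> None:
        self.r_up = np.asarray(self.r_up, dtype=float)
        self.r_down = np.asarray(self.r_down, dtype=float)
        self.backbone_selection = np.asarray(self.backbone_selection, dtype=int)
        if self.r_up.shape != self.r_down.shape:
            raise ValueError("up and down references must share shape and "
                             "atom ordering")
        if len(self.backbone_selection) < 3:
            raise DegenerateGeometryError("need at least 3 selected atoms")

    @property
    def r_avg(self) -> np.ndarray:
        return 0.5 * (self.r_up + self.r_down)

    @property
    def displacement(self) -> np.ndarray:
        """Up-minus-down displacement over the selection."""
        sel = self.backbone_selection
        return self.r_up[sel] - self.r_down[sel]

    def transition_amplitude(self) -> float:
        """sum_i |r_up_i - r_down_i|^2 over the selection (nm^2).

        x ranges over [-amplitude/2, +amplitude/2] along the straight
        down->up path.
        """
        return float(np.sum(self.displacement**2))


@dataclass
class DifferenceVectorSeries:
    """Per-frame difference-vector values with binary state labels."""

    x: np.ndarray
    labels: np.ndarray
    frame_times: np.ndarray
    threshold: float = STATE_THRESHOLD
    rmsd: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if not (len(self.x) == len(self.labels) == len(self.frame_times)):
            raise ValueError("x, labels and frame_times must share length")


def superpose(mobile_coords, reference_coords, selection):
    """Rigid-body least-squares fit of ``mobile`` onto ``reference``.

    The optimal rotation (proper, no reflection) and translation are
    found over ``selection`` by the Kabsch procedure; the transform is
    applied to all mobile atoms.

    Returns
    -------
    transformed : (N, 3) array
    rmsd : float
        Post-fit RMSD over the selection, nm.
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    reference = np.asarray(reference_coords, dtype=float)
    sel = np.asarray(selection, dtype=int)
    if len(sel) < 3:
        raise DegenerateGeometryError("need at least 3 selected atoms to fit")
    mob_sel = mobile[sel]
    ref_sel = reference[sel]
    cm = mob_sel.mean(axis=0)
    cr = ref_sel.mean(axis=0)
    ref_c = ref_sel - cr
    # collinear selections leave the rotation about the common axis free
    if np.linalg.svd(ref_c, compute_uv=False)[1] < 1e-10:
        raise DegenerateGeometryError("selected reference atoms are collinear")
    rot, _ = Rotation.align_vectors(ref_c, mob_sel - cm)
    transformed = (mobile - cm) @ rot.as_matrix().T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((transformed[sel] - ref_sel) ** 2,
                                        axis=1))))
    return transformed, rmsd


def difference_projection(frame_coords, refs: ReferencePair) -> float:
    """Difference-vector value of one (already superposed) frame, nm^2."""
    coords = np.asarray(frame_coords, dtype=float)
    if coords.shape != refs.r_down.shape:
        raise ValueError(f"frame shape {coords.shape} does not match the "
                         f"references {refs.r_down.shape}")
    sel = refs.backbone_selection
    return float(np.sum((coords[sel] - refs.r_avg[sel]) * refs.displacement))


def label_states(x, threshold: float = STATE_THRESHOLD) -> np.ndarray:
    """Binary state per frame: 1 ("up" side) iff x > threshold."""
    return (np.asarray(x, dtype=float) > threshold).astype(int)


def difference_series(frames, refs: ReferencePair,
                      threshold: float = STATE_THRESHOLD,
                      stride_ps: float = STRIDE_PS) -> DifferenceVectorSeries:
    """Superpose each frame onto the down reference and project.

    The fitting selection equals the projection selection (the backbone
    atoms of the reference pair).
    """
    xs, rmsds = [], []
    for frame in frames:
        fitted, rmsd = superpose(frame, refs.r_down, refs.backbone_selection)
        xs.append(difference_projection(fitted, refs))
        rmsds.append(rmsd)
    xs = np.asarray(xs)
    times = np.arange(len(xs), dtype=float) * stride_ps
    return DifferenceVectorSeries(xs, label_states(xs, threshold), times,
                                  threshold, np.asarray(rmsds))


def plot_difference_trace(series: DifferenceVectorSeries, ax=None, **kwargs):
    """Plot x(t) in ns, colouring by state label (matplotlib required)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t_ns = series.frame_times / 1000.0
    ax.plot(t_ns, series.x, **kwargs)
    ax.axhline(series.threshold, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("time (ns)")
    ax.set_ylabel(r"difference vector $x$ (nm$^2$)")
    return ax
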