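"""Superposition, RMSD and RMSF trajectory metrics.

Backbone atoms are N, CA, C, O (hydrogens excluded everywhere); every other
heavy atom counts as side chain.  RMSF is reported per residue, optionally
averaged over the two chains of the hinge dimer (residue i of chain A paired
with residue i of chain B).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import CVSeries, HingedynError, Trajectory

__all__ = [
    "SuperpositionResult",
    "DegenerateFitError",
    "InsufficientDataError",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd_series",
    "rmsf",
    "superpose_to_mean",
]

BACKBONE_SET = frozenset({"N", "CA", "C", "O"})


class DegenerateFitError(HingedynError):
    """Fit atom set is too small or collinear for a unique superposition."""


class InsufficientDataError(HingedynError):
    """Not enough frames for the requested statistic."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference coordinates.

    ``transform(x) = (x - mobile_centroid) @ rotation.T + ref_centroid``;
    the rotation is proper (det = +1) and rmsd (nm) is evaluated over the
    fit atoms after the transform.
    """

    rotation: np.ndarray      # (3, 3), proper orthogonal
    translation: np.ndarray   # (3,) nm; applied after rotation about origin
    rmsd: float               # nm

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_fit_atoms(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateFitError("need at least 3 fit atoms")
    centered = coords - coords.mean(axis=0)
    # rank < 2 means all fit atoms are collinear (or coincident)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise DegenerateFitError("fit atoms are collinear")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: Sequence[int] | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch) of mobile onto reference.

    Reflections are excluded; the returned rotation always has det = +1.
    RMSD is computed over the fit atoms after the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have equal shapes")
    idx = (np.arange(mobile.shape[0]) if fit_indices is None
           else np.asarray(list(fit_indices), dtype=int))
    m_fit = mobile[idx]
    r_fit = reference[idx]
    _check_fit_atoms(m_fit)
    _check_fit_atoms(r_fit)

    m_centroid = m_fit.mean(axis=0)
    r_centroid = r_fit.mean(axis=0)
    rot, _ = Rotation.align_vectors(r_fit - r_centroid, m_fit - m_centroid)
    rotation = rot.as_matrix()
    translation = r_centroid - rotation @ m_centroid
    moved = m_fit @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - r_fit) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd)


def apply_superposition(result: SuperpositionResult,
                        coords: np.ndarray) -> np.ndarray:
    return result.apply(np.asarray(coords, dtype=float))


def rmsd_series(
    trajectory: Trajectory,
    reference: np.ndarray | int = -1,
    fit_indices: Sequence[int] | None = None,
    fit: bool = True,
) -> CVSeries:
    """Per-frame RMSD (nm) against a reference frame.

    ``reference`` is either explicit coordinates or a frame index into the
    trajectory (default -1: the last frame, the conformation the underlying
    study used as its reference structure).  With ``fit=False`` the raw
    coordinate RMSD over the fit atoms is reported without superposition.
    """
    if isinstance(reference, (int, np.integer)):
        reference = trajectory.coords[int(reference)]
    reference = np.asarray(reference, dtype=float)
    if reference.shape != trajectory.coords.shape[1:]:
        raise ValueError("reference must match the trajectory atom set")
    idx = (np.arange(trajectory.n_atoms) if fit_indices is None
           else np.asarray(list(fit_indices), dtype=int))
    out = np.empty(trajectory.n_frames)
    for f, frame in enumerate(trajectory.coords):
        if fit:
            out[f] = kabsch_superpose(frame, reference, idx).rmsd
        else:
            diff = frame[idx] - reference[idx]
            out[f] = np.sqrt(np.mean(np.sum(diff ** 2, axis=1)))
    return CVSeries(names=["rmsd"], units=["nm"],
                    times=trajectory.times.copy(),
                    values=out.reshape(-1, 1))


def superpose_to_mean(
    trajectory: Trajectory,
    fit_indices: Sequence[int] | None = None,
    n_iter: int = 2,
) -> np.ndarray:
    """Superpose all frames onto their iteratively refined mean structure.

    Returns the fitted coordinate array (n_frames, n_atoms, 3).  Two
    iterations (fit to plain mean, recompute mean, fit again) are enough for
    a stable reference on the trajectories handled here.
    """
    if trajectory.n_frames < 2:
        raise InsufficientDataError("need >= 2 frames to define a mean")
    coords = trajectory.coords.copy()
    idx = (np.arange(trajectory.n_atoms) if fit_indices is None
           else np.asarray(list(fit_indices), dtype=int))
    for _ in range(max(1, n_iter)):
        mean = coords.mean(axis=0)
        for f in range(coords.shape[0]):
            res = kabsch_superpose(coords[f], mean, idx)
            coords[f] = res.apply(coords[f])
    return coords


def rmsf(
    trajectory: Trajectory,
    selection: Sequence[int] | None = None,
    by_residue: bool = True,
    chain_average: bool = True,
    fit_indices: Sequence[int] | None = None,
) -> dict:
    """Root-mean-square fluctuation about the mean structure (nm).

    Frames are first superposed onto the iteratively refined mean structure
    (CA atoms by default via ``fit_indices``).  Per-atom RMSF is
    sqrt(<|x - <x>|^2>) over frames; per-residue values average the selected
    atoms of each residue; ``chain_average`` pairs residue position i of the
    first chain with position i of the second and averages.

    Returns a dict with keys ``atom_rmsf`` (per selected atom),
    ``residue_keys`` and ``residue_rmsf`` (when ``by_residue``).
    """
    if trajectory.n_frames < 2:
        raise InsufficientDataError("RMSF needs >= 2 frames")
    top = trajectory.topology
    if fit_indices is None:
        ca = [i for i, a in enumerate(top.atoms) if a.name == "CA"]
        fit_indices = ca if len(ca) >= 3 else None
    fitted = superpose_to_mean(trajectory, fit_indices)
    sel = (np.arange(trajectory.n_atoms) if selection is None
           else np.asarray(list(selection), dtype=int))
    sub = fitted[:, sel, :]
    mean = sub.mean(axis=0)
    atom_rmsf = np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))
    result: dict = {"selection": sel, "atom_rmsf": atom_rmsf}
    if not by_residue:
        return result

    # residue position within chain (1-based) so chains can be paired
    chains = top.chain_ids()
    pos_of: dict[int, tuple[str, int]] = {}
    for c in chains:
        pos = 0
        last = None
        for i, a in enumerate(top.atoms):
            if a.chain_id != c:
                continue
            if a.res_id != last:
                pos += 1
                last = a.res_id
            pos_of[i] = (c, pos)

    per_res: dict[tuple[str, int], list[float]] = {}
    for j, i in enumerate(sel):
        per_res.setdefault(pos_of[int(i)], []).append(atom_rmsf[j])
    res_vals = {k: float(np.mean(v)) for k, v in per_res.items()}

    if chain_average and len(chains) == 2:
        a, b = chains
        positions = sorted({p for (_, p) in res_vals})
        keys, vals = [], []
        for p in positions:
            parts = [res_vals[k] for k in ((a, p), (b, p)) if k in res_vals]
            keys.append(p)
            vals.append(float(np.mean(parts)))
        result["residue_keys"] = keys
        result["residue_rmsf"] = np.array(vals)
    else:
        keys = sorted(res_vals)
        result["residue_keys"] = keys
        result["residue_rmsf"] = np.array([res_vals[k] for k in keys])
    return result


def backbone_sidechain_split(trajectory: Trajectory) -> tuple[list[int], list[int]]:
    """Indices of backbone (N, CA, C, O) and side-chain heavy atoms."""
    backbone, sidechain = [], []
    for i, atom in enumerate(trajectory.topology.atoms):
        if atom.element.upper() == "H" or atom.name.startswith("H"):
            continue
        if atom.name in BACKBONE_SET:
            backbone.append(i)
        else:
            sidechain.append(i)
    return backbone, sidechain
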