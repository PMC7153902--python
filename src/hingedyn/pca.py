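"""Essential dynamics: Calpha-coordinate covariance analysis.

The positional covariance matrix C = <(x - <x>)(x - <x>)^T> is built over
the selected atoms (population normalization, 1/M) after superposing every
frame onto the mean structure of the same selection, which removes the six
rigid-body modes.  Eigenvectors of C ("essential modes") are sorted by
descending eigenvalue (nm^2); the leading modes carry the large-scale
collective motions (for the hinge dimer: hairpin twisting and the
opening/closing of the hinge).  No mass weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_io import CVSeries, Trajectory
from .structure_metrics import InsufficientDataError, kabsch_superpose

__all__ = ["PCAModel", "fit_pca", "project", "covariance_fraction",
           "mode_trajectory"]


@dataclass
class PCAModel:
    """Result of a positional-covariance eigen-decomposition."""

    mean: np.ndarray          # (3N,) nm, mean of the fitted selection coords
    eigenvalues: np.ndarray   # (3N,) nm^2, descending, clipped at 0
    eigenvectors: np.ndarray  # (3N, 3N), orthonormal columns
    selection: np.ndarray     # atom indices the model was fitted on

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    def fitted_selection_coords(self, trajectory: Trajectory) -> np.ndarray:
        """Selection coordinates of every frame superposed onto the mean."""
        mean3 = self.mean.reshape(-1, 3)
        out = np.empty((trajectory.n_frames, mean3.shape[0], 3))
        for f in range(trajectory.n_frames):
            frame = trajectory.coords[f, self.selection, :]
            res = kabsch_superpose(frame, mean3)
            out[f] = res.apply(frame)
        return out


def _mean_fitted_coords(coords: np.ndarray, tol: float = 1e-13,
                        max_iter: int = 100) -> np.ndarray:
    """Superpose (n_frames, n_sel, 3) coords onto their converged mean.

    Iterates fit-to-mean until the mean structure reaches a fixed point, so
    that the mean of the fitted frames *is* the reference: projections of
    the fitting data are then centered to machine precision.
    """
    fitted = coords.copy()
    prev = None
    for _ in range(max_iter):
        mean = fitted.mean(axis=0)
        if prev is not None and np.max(np.abs(mean - prev)) < tol:
            break
        for f in range(fitted.shape[0]):
            res = kabsch_superpose(fitted[f], mean)
            fitted[f] = res.apply(fitted[f])
        prev = mean
    return fitted


def fit_pca(trajectory: Trajectory, selection: Sequence[int] | None = None) -> PCAModel:
    """Fit the covariance model on a trajectory.

    ``selection`` defaults to the pooled CA atoms of all chains (the
    standard essential-dynamics choice for the hinge: one covariance matrix
    over all 24 CA of the dimer).
    """
    if trajectory.n_frames < 2:
        raise InsufficientDataError("PCA needs >= 2 frames")
    if selection is None:
        selection = [i for i, a in enumerate(trajectory.topology.atoms)
                     if a.name == "CA"]
        if not selection:
            selection = list(range(trajectory.n_atoms))
    sel = np.asarray(list(selection), dtype=int)
    fitted = _mean_fitted_coords(trajectory.coords[:, sel, :])
    flat = fitted.reshape(fitted.shape[0], -1)          # (M, 3N)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / dev.shape[0]                    # population, 1/M
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return PCAModel(mean=mean, eigenvalues=evals, eigenvectors=evecs,
                    selection=sel)


def project(trajectory: Trajectory, model: PCAModel, mode: int) -> CVSeries:
    """Per-frame scalar projection (x_fitted - mean) . v_mode, in nm."""
    if not 0 <= mode < model.n_modes:
        raise ValueError(f"mode {mode} out of range (0..{model.n_modes - 1})")
    fitted = model.fitted_selection_coords(trajectory)
    dev = fitted.reshape(fitted.shape[0], -1) - model.mean
    proj = dev @ model.eigenvectors[:, mode]
    return CVSeries(names=[f"pc{mode + 1}"], units=["nm"],
                    times=trajectory.times.copy(),
                    values=proj.reshape(-1, 1))


def covariance_fraction(model: PCAModel, k: int) -> float:
    """Fraction of total positional covariance in the first k modes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    total = float(model.eigenvalues.sum())
    if total == 0.0:
        return 1.0
    return float(model.eigenvalues[:min(k, model.n_modes)].sum() / total)


def mode_trajectory(
    trajectory: Trajectory,
    model: PCAModel,
    mode: int,
    amplitude: float = 2.0,
    n_frames: int = 20,
) -> Trajectory:
    """Sinusoidal sweep along one essential mode for visualization.

    Frames are ``mean + a(t) * v_mode`` with a(t) sweeping
    +-amplitude*sqrt(eigenvalue) over one period; only selection atoms are
    displaced, all other atoms stay at the first frame's coordinates.
    """
    if not 0 <= mode < model.n_modes:
        raise ValueError(f"mode {mode} out of range")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    lam = float(model.eigenvalues[mode])
    if lam == 0.0:
        import warnings

        warnings.warn("mode has zero eigenvalue; output is flat",
                      stacklevel=2)
    scale = amplitude * np.sqrt(lam)
    phases = (np.sin(2 * np.pi * np.arange(n_frames) / n_frames)
              if n_frames > 1 else np.zeros(1))
    base = trajectory.coords[0].copy()
    frames = np.repeat(base[None, :, :], max(1, n_frames), axis=0)
    mean3 = model.mean.reshape(-1, 3)
    v3 = model.eigenvectors[:, mode].reshape(-1, 3)
    for f, p in enumerate(phases):
        frames[f, model.selection, :] = mean3 + scale * p * v3
    return Trajectory(topology=trajectory.topology, coords=frames,
                      times=np.arange(max(1, n_frames), dtype=float))
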