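"""Rigid-body superposition (Kabsch), RMSD and RMSF.

The Kabsch fit returns the proper rotation (determinant +1, reflections
corrected by flipping the smallest singular direction) and translation that
minimise the RMSD of a mobile point set onto a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ensdyn.ensemble_io import StructuralEnsemble

#: Convergence tolerance (A) for iterative alignment onto the running mean.
MEAN_ITER_TOL = 1e-6
#: Iteration cap for iterative-mean alignment.
MEAN_ITER_MAX = 50


@dataclass
class RigidTransform:
    """A proper rotation plus translation, acting as ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).ravel()
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthogonal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation matrix is not proper (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) coordinate array."""
        return np.asarray(coords) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SuperposedEnsemble:
    """Result of fitting every model of an ensemble onto a reference."""

    ensemble: StructuralEnsemble
    transforms: list[RigidTransform]
    reference_index: int
    rmsd_to_reference: np.ndarray

    def __post_init__(self) -> None:
        self.rmsd_to_reference = np.asarray(self.rmsd_to_reference, dtype=float)
        if np.any(self.rmsd_to_reference < 0):
            raise ValueError("RMSD values must be non-negative")


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square distance between two equally-shaped (N, 3) arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def kabsch(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Optimal proper rotation + translation mapping ``mobile`` onto ``target``.

    Raises
    ------
    ValueError
        For fewer than 3 points, shape mismatch, or degenerate (collinear)
        point sets.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {target.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must have shape (N, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("at least 3 points are required")

    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    p = mobile - mu_m
    q = target - mu_t
    # Degenerate (collinear or coincident) point sets have rank < 2.
    if np.linalg.matrix_rank(p, tol=1e-10) < 2 or np.linalg.matrix_rank(q, tol=1e-10) < 2:
        raise ValueError("degenerate point set: rank < 2 (collinear points)")

    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = mu_t - rotation @ mu_m
    return RigidTransform(rotation, translation)


def superpose_ensemble(
    ensemble: StructuralEnsemble,
    reference_index: int = 0,
    iterate_to_mean: bool = False,
    align_span: tuple[int, int] | None = None,
) -> SuperposedEnsemble:
    """Fit every model onto a reference (or onto the running mean).

    By default each model is fitted onto model ``reference_index``, which is
    left unchanged.  With ``iterate_to_mean`` the models are repeatedly
    fitted onto the running mean structure until the mean moves by less than
    ``MEAN_ITER_TOL`` A (at most ``MEAN_ITER_MAX`` iterations).

    ``align_span`` restricts the *fit* to atoms with resid in the inclusive
    range; the transform is still applied to all atoms.
    """
    if not 0 <= reference_index < ensemble.n_models:
        raise IndexError(
            f"reference_index {reference_index} out of range for {ensemble.n_models} models"
        )
    coords = ensemble.coords.copy()
    m = ensemble.n_models

    if align_span is None:
        fit_idx = np.arange(ensemble.n_atoms)
    else:
        lo, hi = align_span
        resids = ensemble.resids()
        fit_idx = np.where((resids >= lo) & (resids <= hi))[0]
        if fit_idx.size < 3:
            raise ValueError(f"align_span {align_span} selects fewer than 3 atoms")

    transforms = [RigidTransform.identity() for _ in range(m)]

    def _fit_all(target: np.ndarray) -> None:
        for i in range(m):
            t = kabsch(coords[i][fit_idx], target[fit_idx])
            coords[i] = t.apply(coords[i])
            transforms[i] = _compose(t, transforms[i])

    if m == 1:
        pass
    elif not iterate_to_mean:
        target = coords[reference_index].copy()
        for i in range(m):
            if i == reference_index:
                continue
            t = kabsch(coords[i][fit_idx], target[fit_idx])
            coords[i] = t.apply(coords[i])
            transforms[i] = t
    else:
        _fit_all(coords[reference_index].copy())
        prev_mean = coords.mean(axis=0)
        for _ in range(MEAN_ITER_MAX):
            _fit_all(prev_mean)
            mean = coords.mean(axis=0)
            if rmsd(mean, prev_mean) < MEAN_ITER_TOL:
                break
            prev_mean = mean

    ref = coords[reference_index]
    rmsds = np.array([rmsd(coords[i], ref) for i in range(m)])
    out = StructuralEnsemble(
        coords=coords,
        atoms=list(ensemble.atoms),
        source_id=ensemble.source_id,
        model_ids=list(ensemble.model_ids),
    )
    return SuperposedEnsemble(
        ensemble=out,
        transforms=transforms,
        reference_index=reference_index,
        rmsd_to_reference=rmsds,
    )


def _compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``inner`` then ``outer``."""
    return RigidTransform(
        outer.rotation @ inner.rotation,
        outer.rotation @ inner.translation + outer.translation,
    )


def rmsf(sup: SuperposedEnsemble) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the ensemble mean (A)."""
    coords = sup.ensemble.coords
    if coords.shape[0] < 2:
        raise ValueError("RMSF requires at least 2 models")
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=-1), axis=0))
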