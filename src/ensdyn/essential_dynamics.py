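"""Coordinate PCA of superposed ensembles: principal displacement modes.

Rows of the conformation matrix are flattened model coordinates; columns
are mean-centred (optionally scaled to unit variance).  Modes are the top
eigenvectors of the column covariance (divisor M-1), computed through an
SVD of the centred matrix.  A deterministic sign convention (largest-
magnitude element positive) makes outputs backend-independent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ensdyn.ensemble_io import NmdDocument, StructuralEnsemble
from ensdyn.superpose import SuperposedEnsemble

logger = logging.getLogger(__name__)


class Scaling(str, Enum):
    none = "none"
    unit_variance = "unit_variance"


@dataclass
class ConformationMatrix:
    """Centred (optionally scaled) M x 3N coordinate matrix."""

    data: np.ndarray
    atom_index: list[tuple[str, int]]  # per column triplet: (chain, resid)
    col_mean: np.ndarray
    centered: bool = True
    scaling: Scaling = Scaling.none
    col_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.col_mean = np.asarray(self.col_mean, dtype=float).ravel()
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D")
        if self.data.shape[1] != 3 * len(self.atom_index):
            raise ValueError("data must have 3 columns per atom")
        if self.col_mean.size != self.data.shape[1]:
            raise ValueError("col_mean length must match number of columns")

    @property
    def n_models(self) -> int:
        return self.data.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_index)


@dataclass
class ModeSet:
    """Orthonormal displacement modes with eigenvalues (A^2)."""

    mean_coords: np.ndarray
    vectors: np.ndarray  # k x 3N, rows orthonormal
    eigenvalues: np.ndarray  # k, non-negative, non-increasing
    total_variance: float
    scaling: Scaling = Scaling.none

    def __post_init__(self) -> None:
        self.mean_coords = np.asarray(self.mean_coords, dtype=float).ravel()
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).ravel()
        if self.vectors.shape[0] != self.eigenvalues.size:
            raise ValueError("one eigenvalue per mode vector required")
        if self.vectors.shape[1] != self.mean_coords.size:
            raise ValueError("mode length must equal 3N")
        if np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be non-negative")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def k(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.mean_coords.size // 3


@dataclass
class ConformerLabels:
    """Open/closed labels of ensemble models."""

    labels: list[str]
    criterion: str
    threshold: float
    domain_split: int
    values: np.ndarray = field(default_factory=lambda: np.array([]))
    warning: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.labels) - {"open", "closed"}
        if bad:
            raise ValueError(f"labels must be 'open'/'closed', got {bad}")
        self.values = np.asarray(self.values, dtype=float)


def build_matrix(
    sup: SuperposedEnsemble, scaling: Scaling | str = Scaling.none
) -> ConformationMatrix:
    """Flatten a superposed ensemble into a centred conformation matrix.

    Row i is ``(x1, y1, z1, ..., xN, yN, zN)`` of model i.  Columns are
    mean-centred; with ``unit_variance`` scaling they are also divided by
    their standard deviation (zero-variance columns stay 0).
    """
    scaling = Scaling(scaling)
    ens = sup.ensemble
    if ens.n_models < 2:
        raise ValueError("need at least 2 models to analyse variation")
    x = ens.coords.reshape(ens.n_models, 3 * ens.n_atoms)
    mean = x.mean(axis=0)
    data = x - mean
    col_scale = None
    if scaling is Scaling.unit_variance:
        sd = x.std(axis=0, ddof=1)
        col_scale = np.where(sd > 0, sd, 1.0)
        data = np.where(sd > 0, data / col_scale, 0.0)
    atom_index = [(a.chain, a.resid) for a in ens.atoms]
    return ConformationMatrix(
        data=data,
        atom_index=atom_index,
        col_mean=mean,
        centered=True,
        scaling=scaling,
        col_scale=col_scale,
    )


def compute_modes(matrix: ConformationMatrix, k: int | None = None) -> ModeSet:
    """Top-k principal displacement modes of a centred conformation matrix.

    Eigen-decomposition of the column covariance (divisor M-1) via SVD of
    the centred data.  Sign convention: each mode's largest-magnitude
    element is positive.
    """
    if not matrix.centered:
        raise ValueError("matrix must be centred")
    m, cols = matrix.data.shape
    kmax = min(m - 1, cols)
    if k is None:
        k = min(kmax, 20)
    if not 1 <= k <= kmax:
        raise ValueError(f"k={k} out of range [1, {kmax}]")

    _, s, vt = np.linalg.svd(matrix.data, full_matrices=False)
    eigenvalues = s**2 / (m - 1)
    total_variance = float(eigenvalues.sum())
    vectors = vt[:k].copy()
    for row in vectors:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return ModeSet(
        mean_coords=matrix.col_mean,
        vectors=vectors,
        eigenvalues=eigenvalues[:k],
        total_variance=total_variance,
        scaling=matrix.scaling,
    )


def variance_fractions(modes: ModeSet) -> np.ndarray:
    """Per-mode fraction of the total coordinate variance, in [0, 1]."""
    if modes.total_variance <= 0:
        raise ValueError("total variance is zero; no variation to apportion")
    return modes.eigenvalues / modes.total_variance


def project(matrix: ConformationMatrix, modes: ModeSet) -> np.ndarray:
    """Project each centred row onto the mode vectors -> (M, k) array."""
    if matrix.data.shape[1] != modes.vectors.shape[1]:
        raise ValueError(
            f"dimension mismatch: matrix has {matrix.data.shape[1]} columns, "
            f"modes have {modes.vectors.shape[1]}"
        )
    return matrix.data @ modes.vectors.T


def mode_overlap(v1: np.ndarray, v2: np.ndarray) -> float:
    """Absolute normalised dot product of two displacement vectors."""
    v1 = np.asarray(v1, dtype=float).ravel()
    v2 = np.asarray(v2, dtype=float).ravel()
    if v1.size != v2.size:
        raise ValueError(f"length mismatch: {v1.size} vs {v2.size}")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("overlap with a zero vector is undefined")
    return float(min(1.0, abs(v1 @ v2) / (n1 * n2)))


def residue_mode_amplitude(modes: ModeSet, mode_index: int) -> np.ndarray:
    """Per-atom displacement amplitude of one mode, scaled by sqrt(eigenvalue).

    The squared amplitudes sum to the mode's eigenvalue because the mode
    vector has unit norm.
    """
    if not 0 <= mode_index < modes.k:
        raise IndexError(f"mode_index {mode_index} out of range [0, {modes.k})")
    triplets = modes.vectors[mode_index].reshape(-1, 3)
    return np.linalg.norm(triplets, axis=1) * np.sqrt(modes.eigenvalues[mode_index])


def interdomain_distances(sup: SuperposedEnsemble, domain_split: int) -> np.ndarray:
    """Per-model distance between the two domains' CA geometric centres."""
    ens = sup.ensemble
    resids = ens.resids()
    ca = np.array([a.name == "CA" for a in ens.atoms])
    d1 = ca & (resids <= domain_split)
    d2 = ca & (resids > domain_split)
    if not d1.any() or not d2.any():
        raise ValueError(
            f"domain_split {domain_split} must lie strictly inside the modeled residue range"
        )
    c1 = ens.coords[:, d1, :].mean(axis=1)
    c2 = ens.coords[:, d2, :].mean(axis=1)
    return np.linalg.norm(c1 - c2, axis=1)


def classify_conformers(
    sup: SuperposedEnsemble,
    domain_split: int,
    criterion: str = "interdomain_distance",
    threshold: float | None = None,
    mode_index: int = 0,
    modes: ModeSet | None = None,
    matrix: ConformationMatrix | None = None,
) -> ConformerLabels:
    """Two-way open/closed split of the models.

    With the default ``interdomain_distance`` criterion the per-model value
    is the distance between the geometric centres of the two domains' CA
    atoms; with ``mode_projection`` it is the projection on mode
    ``mode_index`` (modes/matrix computed on the fly when not supplied).
    Models at or below the threshold (default: median of the values) are
    labelled closed.
    """
    if criterion == "interdomain_distance":
        values = interdomain_distances(sup, domain_split)
    elif criterion == "mode_projection":
        if matrix is None:
            matrix = build_matrix(sup)
        if modes is None:
            modes = compute_modes(matrix, k=mode_index + 1)
        values = project(matrix, modes)[:, mode_index]
    else:
        raise ValueError(f"unknown criterion: {criterion!r}")

    warning = None
    if np.ptp(values) == 0:
        warning = "all per-model values identical; labelling every model open"
        logger.warning(warning)
        labels = ["open"] * len(values)
        thr = float(values[0]) if threshold is None else float(threshold)
    else:
        thr = float(np.median(values)) if threshold is None else float(threshold)
        labels = ["closed" if v <= thr else "open" for v in values]
        if len(set(labels)) < 2 and len(values) >= 2:
            warning = "classification produced a single class"
            logger.warning(warning)
    return ConformerLabels(
        labels=labels,
        criterion=criterion,
        threshold=thr,
        domain_split=domain_split,
        values=values,
        warning=warning,
    )


def to_nmd_document(
    modes: ModeSet,
    ensemble: StructuralEnsemble,
    title: str = "ensdyn modes",
    n_modes: int | None = None,
) -> NmdDocument:
    """Package a ModeSet as an NMD document (mode scale = sqrt(eigenvalue))."""
    if n_modes is None:
        n_modes = modes.k
    n_modes = min(n_modes, modes.k)
    atoms = ensemble.atoms
    if len(atoms) != modes.n_atoms:
        raise ValueError("ensemble and modes disagree on atom count")
    return NmdDocument(
        title=title,
        atomnames=[a.name for a in atoms],
        resnames=[a.resname for a in atoms],
        resids=[a.resid for a in atoms],
        chainids=[a.chain or "A" for a in atoms],
        coordinates=modes.mean_coords,
        modes=[
            (i + 1, float(np.sqrt(modes.eigenvalues[i])), modes.vectors[i])
            for i in range(n_modes)
        ],
    )
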