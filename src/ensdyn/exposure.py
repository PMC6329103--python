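"""Solvent exposure of annotated regions across ensemble conformers.

SASA is computed with a deterministic Shrake-Rupley scheme (golden-spiral
sphere quadrature), so results are reproducible bit-for-bit at a fixed
point count.  For CA-only ensembles a burial proxy is used instead: the
(negated) count of foreign-domain CA atoms within 10 A of the span.

``masking_test`` formalises "region X is less exposed in closed
conformers" as a one-sided permutation test on open-minus-closed mean
exposure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from ensdyn.ensemble_io import StructuralEnsemble
from ensdyn.essential_dynamics import ConformerLabels
from ensdyn.sequence_features import SequenceFeature

logger = logging.getLogger(__name__)

#: Default permutation RNG seed.
DEFAULT_PERMUTATION_SEED = 20190111
#: Cutoff (A) for the CA-only burial proxy.
PROXY_CONTACT_CUTOFF = 10.0

_DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


@dataclass
class SasaParams:
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RADII))
    default_radius: float = 1.70
    strict: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 60:
            raise ValueError("n_sphere_points must be at least 60")

    def radius_of(self, element: str) -> float:
        el = element.capitalize()
        if el in self.radii:
            return self.radii[el]
        if self.strict:
            raise ValueError(f"unknown element {element!r} and strict radii requested")
        return self.default_radius


@dataclass
class RegionExposure:
    """Per-model exposure of a residue span, with conformer labels."""

    span: SequenceFeature
    per_model_sasa: np.ndarray
    labels: ConformerLabels
    per_model_relative: np.ndarray | None = None
    proxy: bool = False

    def __post_init__(self) -> None:
        self.per_model_sasa = np.asarray(self.per_model_sasa, dtype=float)
        if len(self.labels.labels) != self.per_model_sasa.size:
            raise ValueError("labels and per-model values must have equal length")
        if not self.proxy and np.any(self.per_model_sasa < 0):
            raise ValueError("SASA values must be non-negative")


def golden_spiral_points(n: int) -> np.ndarray:
    """n approximately uniform points on the unit sphere (deterministic)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden_angle = math.pi * (3.0 - math.sqrt(5.0))
    phi = golden_angle * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    model: StructuralEnsemble, params: SasaParams | None = None
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2) of a single model.

    Points on each atom's probe-expanded sphere are tested against every
    neighbour's expanded sphere; the unburied fraction scales the sphere
    area.
    """
    if params is None:
        params = SasaParams()
    if model.n_models != 1:
        raise ValueError("shrake_rupley expects a single-model ensemble")
    coords = model.coords[0]
    n = coords.shape[0]
    radii = np.array([params.radius_of(a.element or a.name[:1]) for a in model.atoms])
    expanded = radii + params.probe_radius
    sphere = golden_spiral_points(params.n_sphere_points)

    tree = cKDTree(coords)
    rmax = float(expanded.max())
    areas = np.empty(n)
    for i in range(n):
        ri = expanded[i]
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], ri + rmax)
            if j != i and np.linalg.norm(coords[j] - coords[i]) < ri + expanded[j]
        ]
        pts = coords[i] + ri * sphere
        buried = np.zeros(params.n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            buried |= d2 < expanded[j] ** 2
        frac = 1.0 - buried.mean()
        areas[i] = 4.0 * math.pi * ri * ri * frac
    return areas


def region_exposure(
    ensemble: StructuralEnsemble,
    span: SequenceFeature,
    labels: ConformerLabels,
    params: SasaParams | None = None,
    chain: str | None = None,
) -> RegionExposure:
    """Per-model exposure of the residues in ``span``.

    Full-atom models: summed Shrake-Rupley SASA over the span's residues.
    CA-only models: burial proxy = -(count of foreign-domain CA within
    10 A of any span CA); larger still means more exposed.
    """
    if params is None:
        params = SasaParams()
    if len(labels.labels) != ensemble.n_models:
        raise ValueError("labels must cover every model")
    resids = ensemble.resids()
    in_span = np.array(
        [
            span.start <= a.resid <= span.end and (chain is None or a.chain == chain)
            for a in ensemble.atoms
        ]
    )
    if not in_span.any():
        raise ValueError(f"span {span.start}..{span.end} resolves to zero modeled residues")

    if ensemble.is_calpha_only():
        split = labels.domain_split
        span_domain_n = (resids[in_span] <= split).mean() >= 0.5
        foreign = (resids > split) if span_domain_n else (resids <= split)
        foreign &= ~in_span
        values = np.empty(ensemble.n_models)
        for mi in range(ensemble.n_models):
            span_xyz = ensemble.coords[mi][in_span]
            foreign_xyz = ensemble.coords[mi][foreign]
            if foreign_xyz.size == 0:
                values[mi] = 0.0
                continue
            tree = cKDTree(foreign_xyz)
            counts = tree.query_ball_point(span_xyz, PROXY_CONTACT_CUTOFF)
            values[mi] = -float(sum(len(c) for c in counts))
        logger.info("CA-only ensemble: using burial proxy for span exposure")
        return RegionExposure(
            span=span, per_model_sasa=values, labels=labels, proxy=True
        )

    values = np.empty(ensemble.n_models)
    for mi in range(ensemble.n_models):
        areas = shrake_rupley(ensemble.single_model(mi), params)
        values[mi] = float(areas[in_span].sum())
    return RegionExposure(span=span, per_model_sasa=values, labels=labels, proxy=False)


def masking_test(
    exposure: RegionExposure,
    seed: int = DEFAULT_PERMUTATION_SEED,
    max_exhaustive: int = 10_000,
    n_draws: int = 10_000,
) -> tuple[float, float]:
    """One-sided permutation test of open-minus-closed mean exposure.

    Returns ``(delta, p)`` with ``delta = mean(open) - mean(closed)`` and
    ``p`` the fraction of label permutations whose delta is at least the
    observed one (exhaustive when the number of assignments is at most
    ``max_exhaustive``, else ``n_draws`` seeded random draws with the
    add-one correction).
    """
    values = exposure.per_model_sasa
    lab = np.array([l == "open" for l in exposure.labels.labels])
    n_open = int(lab.sum())
    n_closed = lab.size - n_open
    if n_open == 0 or n_closed == 0:
        raise ValueError("both open and closed classes must be non-empty")

    delta = float(values[lab].mean() - values[~lab].mean())
    total = values.sum()
    m = values.size

    def delta_of_open_sum(open_sum: float) -> float:
        return open_sum / n_open - (total - open_sum) / n_closed

    n_assign = math.comb(m, n_open)
    eps = 1e-12
    if n_assign <= max_exhaustive:
        count = 0
        for idx in combinations(range(m), n_open):
            if delta_of_open_sum(values[list(idx)].sum()) >= delta - eps:
                count += 1
        p = count / n_assign
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_draws):
            perm = rng.permutation(m)
            if delta_of_open_sum(values[perm[:n_open]].sum()) >= delta - eps:
                count += 1
        p = (count + 1) / (n_draws + 1)
    return delta, float(p)
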