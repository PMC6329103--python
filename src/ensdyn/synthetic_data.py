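"""Ground-truth-bearing synthetic inputs for every pipeline stage.

Structural fixtures are two-domain CA traces (idealised helical spirals,
3.8 A consecutive spacing) whose inter-model variation is generated by two
rigid-body rotations of the second domain about axes through the hinge:

* twist — rotation about the inter-domain axis;
* bend  — rotation about a perpendicular hinge axis, which moves the two
  domains towards / away from each other (optionally bimodal, yielding
  planted open/closed groups).

The planted displacement-mode vectors are the first-order fields of those
rotations with global rigid-body components projected out (superposition
and PCA both operate in the rigid-motion quotient space), normalised to
unit length.

Sequence fixtures plant NLS/NES motifs in backgrounds that cannot fire the
scanners spuriously; PCR fixtures plant primer annealing sites around an
insert of known length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ensdyn.ensemble_io import Atom, StructuralEnsemble
from ensdyn.sequence_features import (
    FeatureKind,
    SequenceFeature,
    revcomp,
)
from ensdyn.superpose import kabsch

#: Background alphabet free of basic and scanner-hydrophobic residues.
NEUTRAL_ALPHABET = "AGSTPQNED"

HELIX_RADIUS = 2.3  # A
HELIX_RISE = 1.5  # A per residue
HELIX_TURN = math.radians(100.0)
#: Angle between the two domain axes in the base structure.
DOMAIN_TILT = math.radians(50.0)


@dataclass
class SyntheticEnsembleSpec:
    """Parameters of a planted two-domain ensemble."""

    n_models: int = 50
    n_res_domain1: int = 60
    n_res_domain2: int = 80
    twist_amplitude_sd: float = 0.15  # radians
    bend_amplitude_sd: float = 0.08  # radians; mixture centre when bimodal
    noise_sd: float = 0.1  # A
    hinge_resid: int | None = None  # defaults to the domain boundary
    bimodal_bend: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.n_res_domain1 < 3 or self.n_res_domain2 < 3:
            raise ValueError("each domain needs at least 3 residues")
        if self.twist_amplitude_sd < 0 or self.bend_amplitude_sd < 0 or self.noise_sd < 0:
            raise ValueError("amplitude/noise sds must be non-negative")
        if self.hinge_resid is None:
            self.hinge_resid = self.n_res_domain1
        elif self.hinge_resid != self.n_res_domain1:
            raise ValueError("hinge_resid must sit at the domain boundary")

    @property
    def n_res(self) -> int:
        return self.n_res_domain1 + self.n_res_domain2


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated ensemble."""

    planted_mode_vectors: np.ndarray  # 2 x 3N (twist, bend), unit norm
    per_model_amplitudes: np.ndarray  # M x 2, displacement A along each mode
    base_coords: np.ndarray  # N x 3 base structure
    twist_axis: np.ndarray
    bend_axis: np.ndarray
    hinge_point: np.ndarray
    labels: list[str] | None = None  # open/closed when bimodal

    def __post_init__(self) -> None:
        self.planted_mode_vectors = np.asarray(self.planted_mode_vectors, dtype=float)
        norms = np.linalg.norm(self.planted_mode_vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("planted mode vectors must have unit norm")

    def aligned_mode_vectors(self, target_coords: np.ndarray) -> np.ndarray:
        """Planted vectors rotated into the frame of ``target_coords``.

        Mode vectors are frame-dependent; to compare against modes computed
        from a superposed ensemble, rotate them by the rigid fit of the
        base structure onto the analysis reference (e.g. the superposed
        ensemble's mean structure).
        """
        t = kabsch(self.base_coords, np.asarray(target_coords, dtype=float))
        rotated = self.planted_mode_vectors.reshape(2, -1, 3) @ t.rotation.T
        return rotated.reshape(2, -1)


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _helix(n: int, start: np.ndarray, direction: np.ndarray, phase: float = 0.0) -> np.ndarray:
    """Idealised CA helix of ``n`` residues along ``direction`` from ``start``."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    # Orthonormal frame around the axis.
    ref = np.array([0.0, 1.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(direction, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    k = np.arange(n)
    angles = phase + HELIX_TURN * k
    return (
        start
        + np.outer(HELIX_RISE * k, direction)
        + HELIX_RADIUS * (np.outer(np.cos(angles), e1) + np.outer(np.sin(angles), e2))
    )


def _base_structure(spec: SyntheticEnsembleSpec) -> tuple[np.ndarray, np.ndarray]:
    """Base coordinates (N, 3) and the hinge point."""
    n1, n2 = spec.n_res_domain1, spec.n_res_domain2
    a1 = np.array([0.0, 0.0, 1.0])
    start1 = np.array([0.0, 0.0, -HELIX_RISE * (n1 - 1)])
    dom1 = _helix(n1, start1, a1)
    hinge = dom1[-1]
    a2 = np.array([math.sin(DOMAIN_TILT), 0.0, math.cos(DOMAIN_TILT)])
    dom2 = _helix(n2, hinge + 3.8 * a2, a2)
    return np.vstack([dom1, dom2]), hinge


def _rigid_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6 x 3N) of global rigid-body displacement fields."""
    n = coords.shape[0]
    centred = coords - coords.mean(axis=0)
    fields = []
    for ax in np.eye(3):
        fields.append(np.tile(ax, n))  # translation
    for ax in np.eye(3):
        fields.append(np.cross(np.tile(ax, (n, 1)), centred).ravel())  # rotation
    q, _ = np.linalg.qr(np.array(fields).T)
    return q.T  # 6 x 3N


def _project_out_rigid(field_vec: np.ndarray, rigid: np.ndarray) -> np.ndarray:
    return field_vec - rigid.T @ (rigid @ field_vec)


def generate_two_domain_ensemble(
    spec: SyntheticEnsembleSpec,
) -> tuple[StructuralEnsemble, SyntheticTruth]:
    """Generate a two-domain CA ensemble with planted twist/bend motions.

    Model m applies ``R_twist(theta_m) R_bend(phi_m)`` to the second domain
    about the hinge, plus iid Gaussian coordinate noise.  Fully
    deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    base, hinge = _base_structure(spec)
    n = base.shape[0]
    n1 = spec.n_res_domain1
    dom2 = np.zeros(n, dtype=bool)
    dom2[n1:] = True

    c1 = base[~dom2].mean(axis=0)
    c2 = base[dom2].mean(axis=0)
    twist_axis = (c2 - c1) / np.linalg.norm(c2 - c1)
    bend_axis = np.array([0.0, 1.0, 0.0])
    bend_axis -= (bend_axis @ twist_axis) * twist_axis
    bend_axis /= np.linalg.norm(bend_axis)

    # First-order displacement fields of the two rotations, rigid-projected.
    rel = base - hinge
    raw_twist = np.where(dom2[:, None], np.cross(twist_axis, rel), 0.0).ravel()
    raw_bend = np.where(dom2[:, None], np.cross(bend_axis, rel), 0.0).ravel()
    rigid = _rigid_basis(base)
    proj_twist = _project_out_rigid(raw_twist, rigid)
    proj_bend = _project_out_rigid(raw_bend, rigid)
    norm_twist = np.linalg.norm(proj_twist)
    norm_bend = np.linalg.norm(proj_bend)
    planted = np.vstack([proj_twist / norm_twist, proj_bend / norm_bend])

    thetas = rng.normal(0.0, spec.twist_amplitude_sd, size=spec.n_models)
    labels: list[str] | None = None
    if spec.bimodal_bend:
        # Balanced two-component mixture: half the models bend one way.
        signs = np.ones(spec.n_models)
        signs[: spec.n_models // 2] = -1.0
        if spec.n_models % 2:
            signs[spec.n_models // 2] = rng.choice([-1.0, 1.0])
        rng.shuffle(signs)
        phis = signs * spec.bend_amplitude_sd
        # Which bend sign brings the domain centres together?
        def _dist_at(phi: float) -> float:
            r = _rotation_about_axis(bend_axis, phi)
            moved = np.where(dom2[:, None], (base - hinge) @ r.T + hinge, base)
            return float(
                np.linalg.norm(moved[~dom2].mean(axis=0) - moved[dom2].mean(axis=0))
            )

        closed_sign = 1.0 if _dist_at(spec.bend_amplitude_sd) < _dist_at(-spec.bend_amplitude_sd) else -1.0
        labels = ["closed" if s == closed_sign else "open" for s in signs]
    else:
        phis = rng.normal(0.0, spec.bend_amplitude_sd, size=spec.n_models)

    coords = np.empty((spec.n_models, n, 3))
    for m in range(spec.n_models):
        r = _rotation_about_axis(twist_axis, thetas[m]) @ _rotation_about_axis(
            bend_axis, phis[m]
        )
        moved = base.copy()
        moved[dom2] = (base[dom2] - hinge) @ r.T + hinge
        if spec.noise_sd > 0:
            moved = moved + rng.normal(0.0, spec.noise_sd, size=moved.shape)
        coords[m] = moved

    atoms = [
        Atom(serial=i + 1, name="CA", resname="ALA", chain="A", resid=i + 1, element="C")
        for i in range(n)
    ]
    ensemble = StructuralEnsemble(
        coords=coords, atoms=atoms, source_id=f"SYNTH-{spec.seed}"
    )
    amplitudes = np.column_stack([thetas * norm_twist, phis * norm_bend])
    truth = SyntheticTruth(
        planted_mode_vectors=planted,
        per_model_amplitudes=amplitudes,
        base_coords=base,
        twist_axis=twist_axis,
        bend_axis=bend_axis,
        hinge_point=hinge,
        labels=labels,
    )
    return ensemble, truth


# ---------------------------------------------------------------------------
# Sequence fixtures


def _neutral_background(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(NEUTRAL_ALPHABET), size=length))


def generate_motif_sequence(
    kind: FeatureKind | str,
    background_len: int = 100,
    insert_pos: int = 40,
    seed: int = 0,
) -> tuple[str, SequenceFeature]:
    """A neutral-background protein sequence with one planted motif.

    The background alphabet contains no basic (K/R) and no scanner-class
    hydrophobic (L/I/V/F/M) residues, so the scanners can only fire on the
    planted instance.  Returns the sequence and the ground-truth feature
    (1-based span; for NES the span starts at the planted Phi1).
    """
    kind = FeatureKind(kind)
    rng = np.random.default_rng(seed)
    bg = _neutral_background(background_len, rng)
    if kind is FeatureKind.NLS_bipartite:
        spacer = _neutral_background(10, rng)
        motif = "KR" + spacer + "KRKKA"
        # Last basic of the second cluster is 4 residues before the motif end.
        truth_len = len(motif) - 1
    elif kind is FeatureKind.NES:
        motif = "L" + "AA" + "L" + "AA" + "L" + "A" + "L"  # Phi1-x2-Phi2-x2-Phi3-x-Phi4
        truth_len = len(motif)
    else:
        raise ValueError(f"no motif generator for kind {kind}")
    if insert_pos < 1 or insert_pos - 1 + len(motif) > background_len:
        raise ValueError("insert does not fit within the background")
    i = insert_pos - 1
    seq = bg[:i] + motif + bg[i + len(motif) :]
    feature = SequenceFeature(kind, start=insert_pos, end=insert_pos + truth_len - 1)
    return seq, feature


def generate_pcr_template(
    fwd: str,
    rev: str,
    insert_len: int = 100,
    tail_lens: tuple[int, int] = (0, 0),
    seed: int = 0,
    pad_len: int = 30,
    min_anneal: int = 12,
) -> tuple[str, int]:
    """A template with planted annealing sites around a random insert.

    ``tail_lens`` gives the number of 5' primer bases left out of the
    template (unannealed tails).  The expected full product length is
    ``insert_len + len(fwd) + len(rev)`` regardless of tails.  Pads and
    insert are redrawn until they contain no spurious annealing seed.
    """
    fwd = fwd.upper()
    rev = rev.upper()
    tf, tr = tail_lens
    if tf >= len(fwd) or tr >= len(rev):
        raise ValueError("tail lengths must be shorter than the primers")
    if len(fwd) - tf < min_anneal or len(rev) - tr < min_anneal:
        raise ValueError("annealing regions must be at least min_anneal long")
    rng = np.random.default_rng(seed)
    fwd_anneal = fwd[tf:]
    rev_anneal_rc = revcomp(rev[tr:])
    fwd_seed = fwd[-min_anneal:]
    rev_seed = revcomp(rev)[:min_anneal]
    rc_full_rev = revcomp(rev)
    for _ in range(100):
        pad5 = "".join(rng.choice(list("ACGT"), size=pad_len))
        pad3 = "".join(rng.choice(list("ACGT"), size=pad_len))
        insert = "".join(rng.choice(list("ACGT"), size=insert_len))
        # Pad bases adjacent to the planted sites must not extend annealing
        # into the primer tails by coincidence.
        if tf > 0 and pad5 and pad5[-1] == fwd[tf - 1]:
            continue
        if tr > 0 and pad3 and pad3[0] == rc_full_rev[len(rev) - tr]:
            continue
        template = pad5 + fwd_anneal + insert + rev_anneal_rc + pad3
        if template.count(fwd_seed) == 1 and template.count(rev_seed) == 1:
            return template, insert_len + len(fwd) + len(rev)
    raise RuntimeError("could not build a template free of spurious primer sites")
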