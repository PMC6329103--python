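"""End-to-end orchestration: ensemble -> superpose -> modes -> NMD/report -> masking.

``run`` executes the whole analysis from a single :class:`PipelineConfig`
(loadable from a YAML key-value file) and writes a deterministic report
bundle:

* ``superposed.pdb``   — CA ensemble after superposition
* ``modes.nmd``        — top displacement modes (NMWiz layout)
* ``report.tsv``       — eigenvalues, variance fractions, projections,
  open/closed labels, RMSF
* ``masking_<label>.tsv`` — per annotated span: model, label, exposure,
  with the open-minus-closed delta and permutation p in the footer
* ``run.log``          — versions, parameters and seeds

Any stage failure is re-raised as :class:`PipelineError` naming the stage,
and partially written outputs are removed.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

import ensdyn
from ensdyn.ensemble_io import (
    StructuralEnsemble,
    extract_calpha,
    read_multi_model_pdb,
    write_nmd,
    write_pdb,
)
from ensdyn.essential_dynamics import (
    Scaling,
    build_matrix,
    classify_conformers,
    compute_modes,
    project,
    to_nmd_document,
    variance_fractions,
)
from ensdyn.exposure import (
    DEFAULT_PERMUTATION_SEED,
    SasaParams,
    masking_test,
    region_exposure,
)
from ensdyn.sequence_features import (
    SequenceFeature,
    builtin_features,
    read_feature_table,
)
from ensdyn.superpose import rmsf, superpose_ensemble

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    pdb: str
    outdir: str = "ensdyn_out"
    chain: str | None = None
    reference_index: int = 0
    iterate_to_mean: bool = False
    align_span: tuple[int, int] | None = None
    scaling: str = "none"
    n_modes: int | None = None
    domain_split: int = 60
    feature_table: str | None = None  # None -> bundled annotations
    s1_span: tuple[int, int] | None = None
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    permutation_seed: int = DEFAULT_PERMUTATION_SEED
    title: str = "ensdyn modes"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat YAML mapping; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("align_span", "s1_span"):
            if isinstance(raw.get(key), (list, str)):
                raw[key] = parse_span(raw[key])
        return cls(**raw)


def parse_span(value) -> tuple[int, int]:
    """Parse '182:216' / [182, 216] into an inclusive residue span."""
    if isinstance(value, str):
        lo, _, hi = value.partition(":")
        return int(lo), int(hi)
    lo, hi = value
    return int(lo), int(hi)


@dataclass
class RunResult:
    outputs: dict[str, Path]
    mode_eigenvalues: np.ndarray
    labels: list[str]


def _stage(name: str):
    """Decorator-free stage wrapper: call fn, re-raise with stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run(config: PipelineConfig) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_inner(config, outdir, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run_inner(config: PipelineConfig, outdir: Path, written: list[Path]) -> RunResult:
    with _stage("read"):
        full = read_multi_model_pdb(config.pdb, chain=config.chain)
        ca = extract_calpha(full)

    with _stage("superpose"):
        sup = superpose_ensemble(
            ca,
            reference_index=config.reference_index,
            iterate_to_mean=config.iterate_to_mean,
            align_span=config.align_span,
        )

    with _stage("build_matrix"):
        matrix = build_matrix(sup, scaling=Scaling(config.scaling))

    with _stage("compute_modes"):
        modes = compute_modes(matrix, k=config.n_modes)
        fractions = variance_fractions(modes)
        projections = project(matrix, modes)
        fluct = rmsf(sup)

    with _stage("classify"):
        labels = classify_conformers(sup, domain_split=config.domain_split)

    with _stage("write_pdb"):
        p = outdir / "superposed.pdb"
        write_pdb(sup.ensemble, p)
        written.append(p)

    with _stage("write_nmd"):
        doc = to_nmd_document(modes, sup.ensemble, title=config.title)
        p_nmd = outdir / "modes.nmd"
        write_nmd(doc, p_nmd)
        written.append(p_nmd)

    with _stage("report"):
        p_report = outdir / "report.tsv"
        _write_report(p_report, sup, modes.eigenvalues, fractions, projections, labels, fluct)
        written.append(p_report)

    masking_paths: dict[str, Path] = {}
    with _stage("masking"):
        if config.feature_table:
            features = read_feature_table(config.feature_table)
        else:
            features = builtin_features(s1_span=config.s1_span)
        span_features = [f for f in features if f.length > 1]
        params = SasaParams(
            probe_radius=config.probe_radius, n_sphere_points=config.n_sphere_points
        )
        for feat in span_features:
            tag = feat.kind.value.lower()
            p_mask = outdir / f"masking_{tag}_{feat.start}_{feat.end}.tsv"
            try:
                expo = region_exposure(full, feat, labels, params, chain=config.chain)
            except ValueError as e:
                logger.warning("masking skipped for %s: %s", tag, e)
                continue
            delta, pval = masking_test(expo, seed=config.permutation_seed)
            _write_masking(p_mask, expo, delta, pval)
            written.append(p_mask)
            masking_paths[tag] = p_mask

    with _stage("log"):
        p_log = outdir / "run.log"
        _write_log(p_log, config)
        written.append(p_log)

    outputs = {
        "superposed_pdb": outdir / "superposed.pdb",
        "nmd": outdir / "modes.nmd",
        "report": outdir / "report.tsv",
        "log": p_log,
    }
    outputs.update({f"masking_{k}": v for k, v in masking_paths.items()})
    return RunResult(
        outputs=outputs, mode_eigenvalues=modes.eigenvalues, labels=labels.labels
    )


def _write_report(path, sup, eigenvalues, fractions, projections, labels, fluct) -> None:
    lines = ["# modes", "mode\teigenvalue\tvariance_fraction"]
    for i, (ev, fr) in enumerate(zip(eigenvalues, fractions), start=1):
        lines.append(f"{i}\t{ev:.8g}\t{fr:.8g}")
    k = projections.shape[1]
    header = "model\tlabel\tvalue\trmsd_to_ref\t" + "\t".join(
        f"proj_{i + 1}" for i in range(k)
    )
    lines += ["", "# models", header]
    for mi, mid in enumerate(sup.ensemble.model_ids):
        projs = "\t".join(f"{projections[mi, j]:.8g}" for j in range(k))
        lines.append(
            f"{mid}\t{labels.labels[mi]}\t{labels.values[mi]:.8g}"
            f"\t{sup.rmsd_to_reference[mi]:.8g}\t{projs}"
        )
    lines += ["", "# rmsf", "chain\tresid\trmsf"]
    for a, v in zip(sup.ensemble.atoms, fluct):
        lines.append(f"{a.chain}\t{a.resid}\t{v:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_masking(path, expo, delta, pval) -> None:
    lines = ["model\tlabel\tspan_exposure\tproxy"]
    for mid, lab, v in zip(
        range(1, expo.per_model_sasa.size + 1), expo.labels.labels, expo.per_model_sasa
    ):
        lines.append(f"{mid}\t{lab}\t{v:.8g}\t{int(expo.proxy)}")
    lines.append(f"# delta\t{delta:.8g}")
    lines.append(f"# p\t{pval:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_log(path, config: PipelineConfig) -> None:
    import scipy

    lines = [
        f"ensdyn {ensdyn.__version__}",
        f"python {sys.version.split()[0]}",
        f"numpy {np.__version__}",
        f"scipy {scipy.__version__}",
        "parameters:",
    ]
    for f in dataclasses.fields(config):
        lines.append(f"  {f.name}: {getattr(config, f.name)}")
    Path(path).write_text("\n".join(lines) + "\n")
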