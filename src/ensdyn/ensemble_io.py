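"""Reading and writing of multi-model PDB ensembles and NMD mode files.

A :class:`StructuralEnsemble` stores the coordinates of M models over a
shared list of N atoms.  Atom metadata is guaranteed identical (and in the
same order) across models: on input, atoms are matched across models by
``(chain, resid, insertion code, atom name)`` after alternate-location
filtering, and only the intersection is kept.

The NMD dialect written here is the plain-text layout loadable by the
NMWiz VMD plug-in: per-atom metadata records followed by one ``mode`` line
per displacement mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Three-letter codes of the 20 standard amino acids.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class PdbFormatError(ValueError):
    """Raised when a PDB file cannot be parsed or written."""


@dataclass(frozen=True)
class Atom:
    """Metadata of a single atom (coordinates live in the ensemble)."""

    serial: int
    name: str
    resname: str
    chain: str
    resid: int
    element: str = ""
    icode: str = ""
    altloc: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")

    @property
    def key(self) -> tuple:
        """Identity used to match atoms across models."""
        return (self.chain, self.resid, self.icode, self.name)


@dataclass
class StructuralEnsemble:
    """M models x N atoms with shared per-atom metadata.

    Parameters
    ----------
    coords:
        Array of shape (M, N, 3), Angstrom.
    atoms:
        Shared metadata, length N, identical order for every model.
    source_id:
        Free-form origin tag (e.g. a PDB id).
    model_ids:
        The MODEL record numbers, length M.
    """

    coords: np.ndarray
    atoms: list[Atom]
    source_id: str = ""
    model_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (M, N, 3)")
        if self.coords.shape[0] < 1 or self.coords.shape[1] < 1:
            raise ValueError("need at least one model and one atom")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coords have {self.coords.shape[1]} atoms but metadata has {len(self.atoms)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.model_ids:
            self.model_ids = list(range(1, self.coords.shape[0] + 1))
        if len(self.model_ids) != self.coords.shape[0]:
            raise ValueError("model_ids length must equal number of models")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def model(self, i: int) -> np.ndarray:
        """Coordinates of model ``i`` as an (N, 3) array."""
        return self.coords[i]

    def single_model(self, i: int) -> "StructuralEnsemble":
        """A one-model ensemble holding model ``i``."""
        return StructuralEnsemble(
            coords=self.coords[i : i + 1].copy(),
            atoms=list(self.atoms),
            source_id=self.source_id,
            model_ids=[self.model_ids[i]],
        )

    def copy(self) -> "StructuralEnsemble":
        return StructuralEnsemble(
            coords=self.coords.copy(),
            atoms=list(self.atoms),
            source_id=self.source_id,
            model_ids=list(self.model_ids),
        )

    def resids(self) -> np.ndarray:
        return np.array([a.resid for a in self.atoms], dtype=int)

    def is_calpha_only(self) -> bool:
        return all(a.name == "CA" for a in self.atoms)


@dataclass
class NmdDocument:
    """In-memory form of an NMD (NMWiz) file."""

    title: str
    atomnames: list[str]
    resnames: list[str]
    resids: list[int]
    chainids: list[str]
    coordinates: np.ndarray  # flat, length 3N
    modes: list[tuple[int, float, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).ravel()
        n = len(self.atomnames)
        for name, lst in (
            ("resnames", self.resnames),
            ("resids", self.resids),
            ("chainids", self.chainids),
        ):
            if len(lst) != n:
                raise ValueError(f"{name} has length {len(lst)}, expected {n}")
        if self.coordinates.size != 3 * n:
            raise ValueError(
                f"coordinates have {self.coordinates.size} values, expected {3 * n}"
            )
        indices = [m[0] for m in self.modes]
        if len(set(indices)) != len(indices) or sorted(indices) != indices:
            raise ValueError("mode indices must be unique and ascending")
        norm_modes = []
        for idx, scale, vec in self.modes:
            vec = np.asarray(vec, dtype=float).ravel()
            if vec.size != 3 * n:
                raise ValueError(
                    f"mode {idx} has length {vec.size}, expected {3 * n}"
                )
            norm_modes.append((int(idx), float(scale), vec))
        self.modes = norm_modes

    @property
    def n_atoms(self) -> int:
        return len(self.atomnames)

    def allclose(self, other: "NmdDocument", atol: float = 1e-6) -> bool:
        if (
            self.title != other.title
            or self.atomnames != other.atomnames
            or self.resnames != other.resnames
            or self.resids != other.resids
            or self.chainids != other.chainids
            or len(self.modes) != len(other.modes)
        ):
            return False
        if not np.allclose(self.coordinates, other.coordinates, atol=atol):
            return False
        for (i1, s1, v1), (i2, s2, v2) in zip(self.modes, other.modes):
            if i1 != i2 or abs(s1 - s2) > atol or not np.allclose(v1, v2, atol=atol):
                return False
        return True


# ---------------------------------------------------------------------------
# PDB parsing


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "MN", "NA"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str) -> tuple[Atom, np.ndarray]:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0
    name = line[12:16].strip()
    altloc = line[16].strip()
    resname = line[17:20].strip()
    chain = line[21].strip() or " "
    resid = int(line[22:26])
    icode = line[26].strip()
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    atom = Atom(
        serial=serial,
        name=name,
        resname=resname,
        chain=chain,
        resid=resid,
        element=element,
        icode=icode,
        altloc=altloc,
    )
    return atom, np.array([x, y, z])


def read_multi_model_pdb(
    path: str | Path,
    chain: str | None = None,
    keep_hydrogens: bool = False,
) -> StructuralEnsemble:
    """Read a (possibly multi-model) PDB file into a StructuralEnsemble.

    Models are ordered by their MODEL record number; a file without MODEL
    records yields a single model.  Atoms are matched across models by
    ``(chain, resid, icode, name)``; atoms present in only some models are
    dropped with a warning.  Alternate locations: blank or "A" kept, others
    dropped.  Hydrogens are dropped unless ``keep_hydrogens``.

    Raises
    ------
    PdbFormatError
        On an empty file or when the cross-model atom intersection is empty.
    """
    path = Path(path)
    text = path.read_text()
    models: list[tuple[int, list[Atom], list[np.ndarray]]] = []
    cur_atoms: list[Atom] | None = None
    cur_coords: list[np.ndarray] | None = None
    cur_id: int | None = None
    saw_model_record = False

    def _flush() -> None:
        nonlocal cur_atoms, cur_coords, cur_id
        if cur_atoms:
            models.append((cur_id if cur_id is not None else len(models) + 1, cur_atoms, cur_coords))
        cur_atoms, cur_coords, cur_id = None, None, None

    for line in text.splitlines():
        rec = line[:6]
        if rec.startswith("MODEL"):
            _flush()
            saw_model_record = True
            try:
                cur_id = int(line.split()[1])
            except (IndexError, ValueError):
                cur_id = len(models) + 1
            cur_atoms, cur_coords = [], []
        elif rec.startswith("ENDMDL"):
            _flush()
        elif rec.startswith(("ATOM  ", "HETATM")):
            if cur_atoms is None:
                cur_atoms, cur_coords = [], []
            atom, xyz = _parse_atom_line(line)
            if atom.altloc not in ("", "A"):
                continue
            if not keep_hydrogens and atom.element in ("H", "D"):
                continue
            if chain is not None and atom.chain != chain:
                continue
            cur_atoms.append(atom)
            cur_coords.append(xyz)
    _flush()

    if not models:
        raise PdbFormatError(f"no ATOM records found in {path}")
    models.sort(key=lambda m: m[0])

    # Intersect atoms across models by identity key, first-model order.
    keysets = [
        {a.key for a in atoms} for _, atoms, _ in models
    ]
    common = set.intersection(*keysets)
    first_atoms = models[0][1]
    if not common:
        raise PdbFormatError(
            f"no atom is present in all {len(models)} models; first offending atom: "
            f"{first_atoms[0].key if first_atoms else 'none'}"
        )
    kept_keys = [a.key for a in first_atoms if a.key in common]
    n_dropped = sum(len(atoms) - len(kept_keys) for _, atoms, _ in models)
    if n_dropped:
        logger.warning(
            "%s: dropped %d atom records not shared by all models", path.name, n_dropped
        )

    atoms_out = [a for a in first_atoms if a.key in common]
    coords = np.empty((len(models), len(kept_keys), 3))
    for mi, (_, atoms, xyzs) in enumerate(models):
        lookup = {}
        for a, xyz in zip(atoms, xyzs):
            lookup.setdefault(a.key, xyz)  # first wins (altloc "A" precedes)
        for ai, key in enumerate(kept_keys):
            coords[mi, ai] = lookup[key]

    return StructuralEnsemble(
        coords=coords,
        atoms=atoms_out,
        source_id=path.stem,
        model_ids=[m[0] for m in models],
    )


def extract_calpha(ensemble: StructuralEnsemble) -> StructuralEnsemble:
    """Keep only alpha-carbon atoms of standard amino acids.

    Idempotent.  Rejects duplicate CA atoms for one residue; raises if no
    CA atom survives the filter (e.g. a calcium ion has resname "CA" and is
    excluded by the standard-residue filter).
    """
    idx = [
        i
        for i, a in enumerate(ensemble.atoms)
        if a.name == "CA" and a.resname in STANDARD_AA
    ]
    if not idx:
        raise ValueError("ensemble contains no alpha-carbon atoms of standard residues")
    seen: set[tuple] = set()
    for i in idx:
        a = ensemble.atoms[i]
        rkey = (a.chain, a.resid, a.icode)
        if rkey in seen:
            raise ValueError(f"duplicate CA atom for residue {rkey}")
        seen.add(rkey)
    return StructuralEnsemble(
        coords=ensemble.coords[:, idx, :].copy(),
        atoms=[ensemble.atoms[i] for i in idx],
        source_id=ensemble.source_id,
        model_ids=list(ensemble.model_ids),
    )


# ---------------------------------------------------------------------------
# PDB writing

_PDB_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resid:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}"
)


def _format_atom_name(name: str) -> str:
    # Standard convention: names shorter than 4 chars start in column 14.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb(ensemble: StructuralEnsemble, path: str | Path) -> Path:
    """Write an ensemble as fixed-column PDB ATOM records.

    Multi-model ensembles are wrapped in MODEL/ENDMDL blocks.  Coordinates
    with magnitude >= 10000 A or residue ids above 9999 overflow the fixed
    columns and raise :class:`PdbFormatError`.
    """
    path = Path(path)
    if np.any(np.abs(ensemble.coords) >= 10000.0):
        raise PdbFormatError("coordinate magnitude >= 10000 A does not fit PDB columns")
    for a in ensemble.atoms:
        if a.resid > 9999 or a.resid < -999:
            raise PdbFormatError(f"residue id {a.resid} does not fit PDB columns")
    lines: list[str] = []
    multi = ensemble.n_models > 1
    for mi in range(ensemble.n_models):
        if multi:
            lines.append(f"MODEL     {ensemble.model_ids[mi]:>4d}")
        for ai, a in enumerate(ensemble.atoms):
            x, y, z = ensemble.coords[mi, ai]
            lines.append(
                _PDB_ATOM_FMT.format(
                    serial=min(ai + 1, 99999),
                    name=_format_atom_name(a.name),
                    altloc=a.altloc or " ",
                    resname=a.resname,
                    chain=a.chain,
                    resid=a.resid,
                    icode=a.icode or " ",
                    x=x,
                    y=y,
                    z=z,
                    occ=1.0,
                    b=0.0,
                    element=a.element[:2],
                )
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# NMD dialect


def write_nmd(doc: NmdDocument, path: str | Path) -> Path:
    """Write an NMD document in the NMWiz-loadable plain-text layout."""
    path = Path(path)

    def fmt(values: Iterable[float]) -> str:
        return " ".join(f"{v:.10g}" for v in values)

    lines = [
        f"name {doc.title}",
        "atomnames " + " ".join(doc.atomnames),
        "resnames " + " ".join(doc.resnames),
        "resids " + " ".join(str(r) for r in doc.resids),
        "chainids " + " ".join(doc.chainids),
        "coordinates " + fmt(doc.coordinates),
    ]
    for idx, scale, vec in doc.modes:
        lines.append(f"mode {idx} {scale:.10g} " + fmt(vec))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_nmd(path: str | Path) -> NmdDocument:
    """Parse a file written by :func:`write_nmd`."""
    path = Path(path)
    title = ""
    atomnames: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    chainids: list[str] = []
    coordinates: np.ndarray | None = None
    modes: list[tuple[int, float, np.ndarray]] = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        record, _, rest = line.partition(" ")
        if record == "name":
            title = rest.strip()
        elif record == "atomnames":
            atomnames = rest.split()
        elif record == "resnames":
            resnames = rest.split()
        elif record == "resids":
            resids = [int(t) for t in rest.split()]
        elif record == "chainids":
            chainids = rest.split()
        elif record == "coordinates":
            coordinates = np.array([float(t) for t in rest.split()])
        elif record == "mode":
            tokens = rest.split()
            modes.append(
                (int(tokens[0]), float(tokens[1]), np.array([float(t) for t in tokens[2:]]))
            )
    if coordinates is None:
        raise ValueError(f"{path}: no coordinates record")
    return NmdDocument(
        title=title,
        atomnames=atomnames,
        resnames=resnames,
        resids=resids,
        chainids=chainids,
        coordinates=coordinates,
        modes=modes,
    )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as (id, sequence) pairs; id = first header word."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [(rec.id, str(rec.seq).upper()) for rec in records]


def write_fasta(entries: Sequence[tuple[str, str]], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    chunks = []
    for name, seq in entries:
        chunks.append(f">{name}")
        chunks.extend(seq[i : i + width] for i in range(0, len(seq), width))
    path.write_text("\n".join(chunks) + "\n")
    return path
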