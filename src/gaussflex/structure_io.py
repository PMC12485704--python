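"""Reading macromolecular structures and tabular artifacts.

Structures are parsed with biotite into an :class:`~biotite.structure.AtomArrayStack`
(models x atoms).  From a stack we extract per-chain C-alpha traces — the open
polygonal curves whose Gauss-integral descriptors the rest of the package
computes — plus per-residue secondary-structure annotations from TSV tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io import pdb as _pdb
from biotite.structure.io import pdbx as _pdbx

from .errors import DegenerateInputError, FormatError, ParseError, SchemaError

logger = logging.getLogger(__name__)

#: Consecutive C-alpha atoms farther apart than this are flagged as a chain break.
CHAIN_BREAK_DISTANCE = 4.5

SS_CLASSES = ("helix", "sheet", "coil")


@dataclass
class CaTrace:
    """Ordered C-alpha coordinates of one chain, treated as an open polygonal curve.

    Parameters
    ----------
    chain_id : str
        Chain identifier as given in the source file.
    residue_ids : ndarray of int
        Author residue numbering, one entry per point.
    coords : ndarray, shape (n, 3)
        C-alpha coordinates in Angstrom, in file order.
    ins_codes : list of str
        Insertion codes aligned to ``residue_ids`` (empty string when absent).
    breaks : list of int
        Indices ``i`` such that the distance between points ``i`` and ``i+1``
        exceeds :data:`CHAIN_BREAK_DISTANCE`.  The curve is still treated as a
        single connected polygon; the flags let callers exclude fragmented
        chains.
    """

    chain_id: str
    residue_ids: np.ndarray
    coords: np.ndarray
    ins_codes: list = field(default_factory=list)
    breaks: list = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DegenerateInputError(
                f"coords must be (n, 3), got {self.coords.shape}"
            )
        n = self.coords.shape[0]
        if n < 3:
            raise DegenerateInputError(f"trace needs >= 3 points, got {n}")
        if len(self.residue_ids) != n:
            raise DegenerateInputError("residue_ids and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise DegenerateInputError("non-finite coordinate in trace")
        steps = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise DegenerateInputError("consecutive trace points coincide")
        if not self.ins_codes:
            self.ins_codes = [""] * n

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def n_segments(self) -> int:
        return self.coords.shape[0] - 1


@dataclass
class SecondaryStructureAnnotation:
    """Per-residue secondary-structure classes for one chain."""

    chain_id: str
    residue_ids: np.ndarray
    classes: list

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if len(self.classes) != len(self.residue_ids):
            raise SchemaError("classes and residue_ids length mismatch")
        bad = sorted({c for c in self.classes} - set(SS_CLASSES))
        if bad:
            raise SchemaError(f"unknown secondary-structure class tokens: {bad}")
        if len(self.classes) == 0:
            raise SchemaError("annotation table contains no residues")

    def __len__(self) -> int:
        return len(self.classes)


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif", ".pdbx"):
        return "mmcif"
    raise FormatError(f"cannot infer format from suffix {suffix!r} of {path}")


def read_structure(path, format: str = "auto") -> struc.AtomArrayStack:
    """Read a PDB or mmCIF file into an AtomArrayStack (models x atoms).

    All models and chains are kept; altloc codes and occupancies are preserved
    as annotations so that altloc resolution can be done downstream.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if format == "auto":
        format = _detect_format(path)
    if format not in ("pdb", "mmcif"):
        raise FormatError(f"unknown structure format {format!r}")
    try:
        if format == "pdb":
            pdb_file = _pdb.PDBFile.read(str(path))
            stack = _pdb.get_structure(
                pdb_file, model=None, altloc="all", extra_fields=["occupancy"]
            )
        else:
            cif_file = _pdbx.CIFFile.read(str(path))
            stack = _pdbx.get_structure(
                cif_file, model=None, altloc="all", extra_fields=["occupancy"]
            )
    except (FormatError, ParseError):
        raise
    except Exception as exc:  # parser-level failure: re-tag with file context
        raise ParseError(f"failed to parse {path} as {format}: {exc}") from exc
    return stack


def extract_ca_trace(
    model: struc.AtomArrayStack | struc.AtomArray,
    chain_id: str,
    model_index: int = 0,
) -> CaTrace:
    """Extract the C-alpha trace of one chain from one model.

    Altlocs are resolved to the highest-occupancy location (ties broken
    alphabetically by altloc id).  Residues without a C-alpha atom are skipped
    with a warning.  Chain breaks (consecutive distance > 4.5 A) are flagged
    on the returned trace but the curve remains a single polygon.
    """
    if isinstance(model, struc.AtomArrayStack):
        if not 0 <= model_index < model.stack_depth():
            raise LookupError(
                f"model index {model_index} out of range "
                f"(file has {model.stack_depth()} models)"
            )
        atoms = model[model_index]
    else:
        atoms = model
    chains = np.unique(atoms.chain_id)
    if chain_id not in chains:
        raise LookupError(
            f"chain {chain_id!r} not found; available: {sorted(chains)}"
        )
    mask = (
        (atoms.chain_id == chain_id)
        & (atoms.atom_name == "CA")
        & (atoms.element == "C")
        & (~atoms.hetero)
    )
    ca = atoms[mask]

    occupancy = (
        ca.occupancy
        if "occupancy" in ca.get_annotation_categories()
        else np.ones(ca.array_length())
    )
    altloc = (
        ca.altloc_id
        if "altloc_id" in ca.get_annotation_categories()
        else np.array([""] * ca.array_length())
    )

    # group by (res_id, ins_code) preserving file order
    coords, res_ids, ins_codes = [], [], []
    seen = {}
    order = []
    for idx in range(ca.array_length()):
        key = (int(ca.res_id[idx]), str(ca.ins_code[idx]))
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(idx)
    for key in order:
        members = seen[key]
        # highest occupancy first, ties alphabetical by altloc id
        best = min(members, key=lambda i: (-float(occupancy[i]), str(altloc[i])))
        res_ids.append(key[0])
        ins_codes.append(key[1])
        coords.append(ca.coord[best])

    # warn about residues of this chain lacking a C-alpha
    chain_atoms = atoms[(atoms.chain_id == chain_id) & (~atoms.hetero)]
    all_res = {
        (int(r), str(i))
        for r, i in zip(chain_atoms.res_id, chain_atoms.ins_code)
    }
    missing = all_res - set(order)
    if missing:
        warnings.warn(
            f"chain {chain_id}: {len(missing)} residue(s) without C-alpha "
            f"skipped: {sorted(missing)[:5]}",
            stacklevel=2,
        )

    if len(coords) < 3:
        raise DegenerateInputError(
            f"chain {chain_id} has only {len(coords)} C-alpha atoms (need >= 3)"
        )
    coords = np.asarray(coords, dtype=float)
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    breaks = [int(i) for i in np.nonzero(steps > CHAIN_BREAK_DISTANCE)[0]]
    if breaks:
        logger.warning(
            "chain %s: %d chain break(s) at trace indices %s; "
            "curve kept as a single polygon",
            chain_id, len(breaks), breaks,
        )
    return CaTrace(
        chain_id=chain_id,
        residue_ids=np.asarray(res_ids, dtype=int),
        coords=coords,
        ins_codes=ins_codes,
        breaks=breaks,
    )


def _trace_atom_array(trace: CaTrace, coords=None) -> struc.AtomArray:
    n = trace.n_residues
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(coords if coords is not None else trace.coords, dtype=float)
    atoms.chain_id = np.full(n, trace.chain_id)
    atoms.res_id = trace.residue_ids.copy()
    atoms.ins_code = np.array(trace.ins_codes)
    atoms.res_name = np.full(n, "GLY")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    return atoms


def write_trace_pdb(trace: CaTrace, path) -> None:
    """Write a C-alpha trace as a single-model PDB file (glycine CA atoms)."""
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(_trace_atom_array(trace))
    pdb_file.write(str(path))


def write_trace_cif(trace: CaTrace, path) -> None:
    """Write a C-alpha trace as an mmCIF file."""
    cif_file = _pdbx.CIFFile()
    _pdbx.set_structure(cif_file, _trace_atom_array(trace))
    cif_file.write(str(path))


def write_ensemble_pdb(trace: CaTrace, frames, path) -> None:
    """Write frames (n_frames, n_residues, 3) as a multi-model PDB file."""
    frames = np.asarray(frames, dtype=float)
    template = _trace_atom_array(trace)
    stack = struc.stack([template] * frames.shape[0])
    stack.coord = frames.copy()
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_ensemble_frames(path, chain_id: str | None = None) -> np.ndarray:
    """Read all models of a multi-model PDB/mmCIF as C-alpha frames."""
    stack = read_structure(path)
    if chain_id is None:
        chain_id = str(stack.chain_id[0])
    frames = []
    for m in range(stack.stack_depth()):
        frames.append(extract_ca_trace(stack, chain_id, model_index=m).coords)
    return np.asarray(frames)


_ANNOTATION_COLUMNS = ["chain_id", "residue_id", "ss"]


def read_annotation_table(path) -> SecondaryStructureAnnotation:
    """Read a per-residue secondary-structure TSV (columns chain_id, residue_id, ss)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"cannot read annotation table {path}: {exc}") from exc
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table {path} lacks columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"annotation table {path} is empty")
    chains = df["chain_id"].astype(str).unique()
    if len(chains) != 1:
        raise SchemaError(
            f"annotation table must describe one chain, found {list(chains)}"
        )
    return SecondaryStructureAnnotation(
        chain_id=str(chains[0]),
        residue_ids=df["residue_id"].to_numpy(dtype=int),
        classes=[str(c) for c in df["ss"]],
    )


def write_annotation_table(ann: SecondaryStructureAnnotation, path) -> None:
    df = pd.DataFrame(
        {
            "chain_id": ann.chain_id,
            "residue_id": ann.residue_ids,
            "ss": ann.classes,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a DataFrame as TSV (UTF-8, header row), optionally with a # comment line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comment lines skipped)."""
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"cannot read table {path}: {exc}") from exc
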