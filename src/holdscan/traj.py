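"""Trajectory I/O: multi-model PDB reading/writing, atom selection, tables.

A :class:`Trajectory` is a topology plus an ``F x N x 3`` coordinate array in
angstrom with strictly increasing frame times (ps).  MODEL/ENDMDL blocks of a
PDB file become frames; a file without MODEL records yields a single frame.

Atom selection uses a small expression language::

    name CA and chain A
    resid 145 192 200
    resname LIG or water
    not (water or ligand)
    resid 1:50 and name CA

Keywords: ``chain``, ``resid`` (integers and ``lo:hi`` ranges), ``resname``,
``name``, ``element``, and the flags ``water``, ``ligand``, ``protein``,
``all``; combined with ``and``/``or``/``not`` and parentheses.  Selections
always resolve to a deterministic sorted index list.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

__all__ = [
    "WATER_RESNAMES",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "Topology",
    "Trajectory",
    "Selection",
    "SelectionError",
    "read_structure",
    "write_structure",
    "select",
    "write_table",
    "read_table",
]

#: Residue names recognized as water.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3"})

#: Default van der Waals radii by element (angstrom), used by the pocket grid.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_VDW_RADIUS = 1.70

#: Default spacing between recorded frames (ps) when the source format
#: carries no time axis (PDB does not).
DEFAULT_FRAME_DT_PS = 20.0


@dataclass
class Topology:
    """Per-atom metadata stored as parallel arrays."""

    serial: np.ndarray
    name: np.ndarray
    resname: np.ndarray
    chain: np.ndarray
    resid: np.ndarray
    element: np.ndarray
    vdw_radius: np.ndarray
    charge: np.ndarray
    is_water: np.ndarray
    is_ligand: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.serial)
        for f in (
            "name", "resname", "chain", "resid", "element",
            "vdw_radius", "charge", "is_water", "is_ligand",
        ):
            if len(getattr(self, f)) != n:
                raise ValueError(f"topology field {f!r} has inconsistent length")
        if len(np.unique(self.serial)) != n:
            raise ValueError("atom serial numbers are not unique")
        if np.any(self.vdw_radius <= 0):
            raise ValueError("van der Waals radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def is_heavy(self) -> np.ndarray:
        return self.element != "H"


@dataclass
class Trajectory:
    """Topology plus coordinates (F x N x 3, angstrom) and frame times (ps)."""

    topology: Topology
    coords: np.ndarray
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be F x N x 3, got {self.coords.shape}")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate array has {self.coords.shape[1]} atoms but "
                f"topology has {self.topology.n_atoms}"
            )
        if self.n_frames < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.times is None:
            self.times = np.arange(self.n_frames) * DEFAULT_FRAME_DT_PS
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.n_frames:
            raise ValueError("times length does not match frame count")
        if self.n_frames > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, expression: str) -> np.ndarray:
        return select(self.topology, expression)

    def slice_frames(self, frames) -> "Trajectory":
        idx = np.asarray(frames)
        return Trajectory(self.topology, self.coords[idx], self.times[idx])


# ---------------------------------------------------------------------------
# PDB reading / writing (Biotite-backed)
# ---------------------------------------------------------------------------

def _infer_element(name: str) -> str:
    """Element from an atom name when the element column is blank.

    Strips leading digits (e.g. ``1HB``) and takes the first letter; two-letter
    elements in the supported radius table are not distinguished here because
    protein/ligand/water atoms in this pipeline are C/N/O/S/P/H.
    """
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else ""


def _prescan_pdb(path: Path) -> None:
    """Validate MODEL atom-count consistency and fixed-width numeric fields."""
    counts: list[tuple[int, int]] = []  # (model number, atom count)
    current_model = None
    current_count = 0
    saw_model = False
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                current_model = int(line[6:].split()[0]) if line[6:].split() else len(counts) + 1
                current_count = 0
            elif rec == "ENDMDL":
                counts.append((current_model if current_model is not None else len(counts) + 1,
                               current_count))
                current_model = None
            elif rec in ("ATOM", "HETATM"):
                n_records += 1
                current_count += 1
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: unparseable coordinate field on line {lineno}: "
                        f"{line.rstrip()!r}"
                    ) from exc
    if n_records == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    if saw_model and current_model is not None:  # MODEL without ENDMDL
        counts.append((current_model, current_count))
    if counts:
        ref_model, ref_count = counts[0]
        for model, count in counts[1:]:
            if count != ref_count:
                raise ValueError(
                    f"{path}: MODEL {model} has {count} atoms but MODEL "
                    f"{ref_model} has {ref_count}"
                )


def read_structure(path: str | Path, dt_ps: float = DEFAULT_FRAME_DT_PS) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    MODEL/ENDMDL blocks become frames; frame times are assigned on a uniform
    ``dt_ps`` grid since PDB stores no time axis.  Alternate locations other
    than blank/'A' are dropped; elements are inferred from atom names when the
    element column is blank.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    pdb_file = pdbio.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None, altloc="first")
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])

    n = stack.array_length()
    element = np.array(
        [el if el else _infer_element(nm)
         for el, nm in zip(stack.element, stack.atom_name)],
        dtype="U2",
    )
    unknown = sorted({el for el in element if el not in VDW_RADII})
    if unknown:
        warnings.warn(
            f"unknown element(s) {unknown}: assigning default vdW radius "
            f"{DEFAULT_VDW_RADIUS} A",
            stacklevel=2,
        )
    vdw = np.array([VDW_RADII.get(el, DEFAULT_VDW_RADIUS) for el in element])
    resname = stack.res_name.astype("U5")
    is_water = np.isin(resname, sorted(WATER_RESNAMES))
    is_ligand = stack.hetero & ~is_water
    top = Topology(
        serial=np.arange(1, n + 1),
        name=stack.atom_name.astype("U5"),
        resname=resname,
        chain=stack.chain_id.astype("U4"),
        resid=stack.res_id.astype(int),
        element=element,
        vdw_radius=vdw,
        charge=np.zeros(n),
        is_water=is_water,
        is_ligand=is_ligand,
    )
    times = np.arange(stack.stack_depth()) * dt_ps
    return Trajectory(top, stack.coord.astype(float), times)


def write_structure(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (one MODEL per frame)."""
    top = traj.topology
    atoms = struc.AtomArray(top.n_atoms)
    atoms.coord = traj.coords[0]
    atoms.chain_id = top.chain
    atoms.res_id = top.resid
    atoms.res_name = top.resname
    atoms.atom_name = top.name
    atoms.element = top.element
    atoms.hetero = top.is_water | top.is_ligand
    stack = struc.AtomArrayStack(traj.n_frames, top.n_atoms)
    for cat in atoms.get_annotation_categories():
        stack.set_annotation(cat, atoms.get_annotation(cat))
    stack.coord = traj.coords
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------

class SelectionError(ValueError):
    """Raised on a selection syntax error; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


_KEYWORDS = {"chain", "resid", "resname", "name", "element"}
_FLAGS = {"water", "ligand", "protein", "all"}
_OPERATORS = {"and", "or", "not"}


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expression):
        c = expression[i]
        if c.isspace():
            i += 1
        elif c in "()":
            tokens.append((c, i))
            i += 1
        else:
            j = i
            while j < len(expression) and not expression[j].isspace() and expression[j] not in "()":
                j += 1
            tokens.append((expression[i:j], i))
            i = j
    return tokens


@dataclass(frozen=True)
class Selection:
    """A parsed, reusable selection expression."""

    expression: str

    def indices(self, top: Topology) -> np.ndarray:
        return select(top, self.expression)


class _Parser:
    def __init__(self, expression: str, top: Topology):
        self.tokens = _tokenize(expression)
        self.pos = 0
        self.top = top
        self.expression = expression

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expression))

    def parse(self) -> np.ndarray:
        mask = self._or_expr()
        tok, at = self._peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok!r}", at)
        return mask

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self._peek()[0] == "or":
            self.pos += 1
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._not_expr()
        while self._peek()[0] == "and":
            self.pos += 1
            mask = mask & self._not_expr()
        return mask

    def _not_expr(self) -> np.ndarray:
        if self._peek()[0] == "not":
            self.pos += 1
            return ~self._not_expr()
        return self._primary()

    def _primary(self) -> np.ndarray:
        tok, at = self._peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", at)
        if tok == "(":
            self.pos += 1
            mask = self._or_expr()
            tok, at = self._peek()
            if tok != ")":
                raise SelectionError("expected ')'", at)
            self.pos += 1
            return mask
        if tok in _FLAGS:
            self.pos += 1
            return self._flag_mask(tok)
        if tok in _KEYWORDS:
            self.pos += 1
            values = self._collect_values(tok, at)
            return self._keyword_mask(tok, values, at)
        raise SelectionError(f"unknown token {tok!r}", at)

    def _collect_values(self, keyword: str, at: int) -> list[str]:
        values: list[str] = []
        while True:
            tok, _ = self._peek()
            if tok is None or tok in _OPERATORS or tok in _KEYWORDS or tok in _FLAGS or tok in "()":
                break
            values.append(tok)
            self.pos += 1
        if not values:
            raise SelectionError(f"keyword {keyword!r} expects at least one value", at)
        return values

    def _flag_mask(self, flag: str) -> np.ndarray:
        top = self.top
        if flag == "water":
            return top.is_water.copy()
        if flag == "ligand":
            return top.is_ligand.copy()
        if flag == "protein":
            return ~(top.is_water | top.is_ligand)
        return np.ones(top.n_atoms, dtype=bool)  # all

    def _keyword_mask(self, keyword: str, values: list[str], at: int) -> np.ndarray:
        top = self.top
        if keyword == "resid":
            mask = np.zeros(top.n_atoms, dtype=bool)
            for v in values:
                if ":" in v or "-" in v.lstrip("-") and ":" not in v:
                    sep = ":" if ":" in v else "-"
                    lo_s, _, hi_s = v.partition(sep)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        raise SelectionError(f"bad resid range {v!r}", at) from None
                    mask |= (top.resid >= lo) & (top.resid <= hi)
                else:
                    try:
                        mask |= top.resid == int(v)
                    except ValueError:
                        raise SelectionError(f"bad resid {v!r}", at) from None
            return mask
        column = {
            "chain": top.chain,
            "resname": top.resname,
            "name": top.name,
            "element": top.element,
        }[keyword]
        return np.isin(column, values)


def select(top: Topology, expression: str) -> np.ndarray:
    """Evaluate a selection expression to a sorted array of atom indices."""
    mask = _Parser(expression, top).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return idx


# ---------------------------------------------------------------------------
# Tabular reports
# ---------------------------------------------------------------------------

def write_table(records, path: str | Path, format: str = "csv") -> None:
    """Write records (list of dicts or DataFrame) as CSV or JSON.

    Numeric fields keep 6 significant digits, which round-trips losslessly for
    the report quantities produced here.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.6g")
    elif format == "json":
        cleaned = json.loads(df.to_json(orient="records", double_precision=10))
        with open(path, "w") as fh:
            json.dump(cleaned, fh, indent=2)
    else:
        raise ValueError(f"unknown table format {format!r}")


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        return pd.read_json(path)
    return pd.read_csv(path)
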