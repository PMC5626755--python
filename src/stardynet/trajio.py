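"""Structure/trajectory IO and the atom-selection mini-language.

Internal atom indexing is 0-based and dense; author residue numbering from the
PDB file (e.g. 69-204 for a KH-QUA2 construct) is preserved as data and never
used as an array index.  Distances are computed without periodic-boundary
handling: analyses assume a whole, already-imaged solute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import AMINO_ACIDS_3, ATOMIC_MASSES, NUCLEOTIDES

logger = logging.getLogger("stardynet")

__all__ = [
    "Structure",
    "Trajectory",
    "AtomSelection",
    "PDBParseError",
    "SelectionError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select",
]


class PDBParseError(ValueError):
    """Raised for malformed PDB records; the message names the line number."""


class SelectionError(ValueError):
    """Raised for syntax errors in the selection mini-language."""


@dataclass
class Structure:
    """A molecular topology with one set of coordinates.

    All fields are per-atom arrays of equal length; ``coords`` is (n, 3) in
    Angstrom, ``bfactors`` in A^2, ``masses`` in amu.
    """

    atom_names: np.ndarray
    residue_seqs: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    bfactors: np.ndarray
    occupancies: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.residue_seqs = np.asarray(self.residue_seqs, dtype=int)
        for name in ("atom_names", "residue_names", "chain_ids", "elements"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.bfactors = np.asarray(self.bfactors, dtype=float)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in Structure")
        if np.any(self.masses <= 0):
            raise ValueError("all atom masses must be > 0")
        keys = list(zip(self.chain_ids, self.residue_seqs, self.atom_names))
        if len(set(keys)) != len(keys):
            raise ValueError(
                "(chain_id, residue_seq, atom_name) must be unique per model"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def subset(self, atom_ids: np.ndarray) -> "Structure":
        """New Structure restricted to the given 0-based atom indices."""
        ids = np.asarray(atom_ids, dtype=int)
        return Structure(
            atom_names=self.atom_names[ids],
            residue_seqs=self.residue_seqs[ids],
            residue_names=self.residue_names[ids],
            chain_ids=self.chain_ids[ids],
            elements=self.elements[ids],
            coords=self.coords[ids],
            bfactors=self.bfactors[ids],
            occupancies=self.occupancies[ids],
            masses=self.masses[ids],
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.subset(np.arange(self.n_atoms))
        out.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        return out


@dataclass
class Trajectory:
    """Frame stack (n_frames, n_atoms, 3) in Angstrom over a fixed topology.

    ``timestep`` is the time between stored frames in ps (the source data is
    typically saved every 1-2 ps of simulation).
    """

    topology: Structure
    frames: np.ndarray
    timestep: float = 2.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must have at least one frame")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.timestep


@dataclass
class AtomSelection:
    """A resolved selection: the expression plus sorted, unique atom ids."""

    expression: str
    resolved_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        ids = np.asarray(self.resolved_ids, dtype=int)
        self.resolved_ids = np.unique(ids)

    def __len__(self) -> int:
        return len(self.resolved_ids)


# --------------------------------------------------------------------------
# PDB reading/writing (ATOM/HETATM/MODEL/ENDMDL subset)
# --------------------------------------------------------------------------

_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN"}


def _infer_element(atom_name: str) -> str:
    """Element from a PDB atom name: first alphabetic character, with a check
    for common two-letter elements (CL, MG, ...) occupying the full field."""
    stripped = atom_name.strip().upper()
    if stripped[:2] in _TWO_LETTER_ELEMENTS and not stripped[2:3].isalpha():
        return stripped[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def _element_mass(element: str, atom_name: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise ValueError(
            f"no mass for element {element!r} (atom {atom_name!r})"
        ) from None


def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        rec = {
            "name": line[12:16].strip(),
            "altloc": line[16:17].strip(),
            "resname": line[17:20].strip() or line[17:21].strip(),
            "chain": line[21:22].strip() or "A",
            "resseq": int(line[22:26]),
            "icode": line[26:27].strip(),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
        }
    except (ValueError, IndexError) as exc:
        raise PDBParseError(
            f"malformed ATOM/HETATM record at line {lineno}: {exc}"
        ) from None
    occ = line[54:60].strip()
    bf = line[60:66].strip()
    elem = line[76:78].strip()
    try:
        rec["occupancy"] = float(occ) if occ else 1.0
        rec["bfactor"] = float(bf) if bf else 0.0
    except ValueError:
        raise PDBParseError(
            f"malformed occupancy/bfactor at line {lineno}"
        ) from None
    rec["element"] = elem.capitalize() if elem else _infer_element(rec["name"])
    return rec


def read_structure(path, model: int = 1) -> Structure:
    """Read one MODEL of a PDB file into a Structure.

    Missing bfactor/occupancy default to 0.0/1.0; the element is inferred from
    the atom name when columns 77-78 are blank; masses come from a standard
    element table.  Alternate locations keep the highest-occupancy record
    (ties: first encountered).
    """
    models = _read_pdb_models(path)
    if model < 1 or model > len(models):
        raise ValueError(
            f"requested model {model} but file has {len(models)} model(s)"
        )
    return _records_to_structure(models[model - 1])


def _read_pdb_models(path) -> list[list[dict]]:
    models: list[list[dict]] = []
    current: list[dict] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec6 = line[:6].strip()
            if rec6 == "MODEL":
                if current:
                    models.append(current)
                    current = []
                in_model = True
            elif rec6 == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec6 in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
    if current or not models:
        if not current and not models:
            raise PDBParseError(f"no ATOM/HETATM records in {path}")
        if current:
            models.append(current)
    del in_model
    return models


def _records_to_structure(records: list[dict]) -> Structure:
    # altloc resolution: keep highest occupancy, tie -> first seen
    chosen: dict[tuple, dict] = {}
    order: list[tuple] = []
    for rec in records:
        key = (rec["chain"], rec["resseq"], rec["icode"], rec["name"])
        if key not in chosen:
            chosen[key] = rec
            order.append(key)
        elif rec["altloc"] and rec["occupancy"] > chosen[key]["occupancy"]:
            chosen[key] = rec
    recs = [chosen[k] for k in order]
    return Structure(
        atom_names=[r["name"] for r in recs],
        residue_seqs=[r["resseq"] for r in recs],
        residue_names=[r["resname"] for r in recs],
        chain_ids=[r["chain"] for r in recs],
        elements=[r["element"] for r in recs],
        coords=[(r["x"], r["y"], r["z"]) for r in recs],
        bfactors=[r["bfactor"] for r in recs],
        occupancies=[r["occupancy"] for r in recs],
        masses=[_element_mass(r["element"], r["name"]) for r in recs],
    )


def _format_atom_line(structure: Structure, i: int, serial: int) -> str:
    name = str(structure.atom_names[i])
    # PDB convention: 1-3 char names start in column 14 unless 4 chars
    fname = name if len(name) >= 4 else f" {name:<3s}"
    elem = str(structure.elements[i]).upper()
    return (
        f"ATOM  {serial:5d} {fname:<4s}{'':1s}{str(structure.residue_names[i]):>3s} "
        f"{str(structure.chain_ids[i]):1s}{int(structure.residue_seqs[i]):4d}    "
        f"{structure.coords[i, 0]:8.3f}{structure.coords[i, 1]:8.3f}"
        f"{structure.coords[i, 2]:8.3f}{structure.occupancies[i]:6.2f}"
        f"{structure.bfactors[i]:6.2f}          {elem:>2s}\n"
    )


def write_structure(structure: Structure, path) -> None:
    """Write a Structure as a single-model PDB file."""
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            fh.write(_format_atom_line(structure, i, i + 1))
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a Trajectory as multi-model PDB (.pdb) or DCD (.dcd)."""
    path = str(path)
    if path.endswith(".dcd"):
        _write_dcd(traj, path)
        return
    with open(path, "w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            frame_struct = traj.topology.with_coords(traj.frames[m])
            for i in range(frame_struct.n_atoms):
                fh.write(_format_atom_line(frame_struct, i, i + 1))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_dcd(traj: Trajectory, path: str) -> None:
    import MDAnalysis as mda

    u = mda.Universe.empty(traj.topology.n_atoms, trajectory=True)
    with mda.coordinates.DCD.DCDWriter(path, traj.topology.n_atoms) as w:
        for frame in traj.frames:
            u.atoms.positions = frame.astype(np.float32)
            w.write(u.atoms)


def read_trajectory(
    path,
    topology: Structure,
    timestep: float | None = None,
    on_truncation: str = "error",
) -> Trajectory:
    """Read a DCD or multi-model PDB trajectory against a topology.

    ``timestep`` (ps between stored frames) overrides any header value;
    ``on_truncation`` is "error" or "skip" for a truncated final DCD frame.
    """
    path = str(path)
    if path.endswith(".dcd"):
        frames, header_dt = _read_dcd(path, topology.n_atoms, on_truncation)
    else:
        models = _read_pdb_models(path)
        frames = []
        for m, recs in enumerate(models):
            if len(recs) != topology.n_atoms:
                raise ValueError(
                    f"trajectory frame {m} has {len(recs)} atoms but topology "
                    f"has {topology.n_atoms}"
                )
            frames.append([(r["x"], r["y"], r["z"]) for r in recs])
        frames = np.asarray(frames, dtype=float)
        header_dt = None
    dt = timestep if timestep is not None else (header_dt or 2.0)
    return Trajectory(topology=topology, frames=frames, timestep=dt)


def _read_dcd(path: str, n_atoms: int, on_truncation: str):
    from MDAnalysis.coordinates.DCD import DCDReader

    reader = DCDReader(path)
    if reader.n_atoms != n_atoms:
        raise ValueError(
            f"trajectory has {reader.n_atoms} atoms but topology has {n_atoms}"
        )
    frames = []
    try:
        for ts in reader:
            frames.append(np.array(ts.positions, dtype=float))
    except (EOFError, OSError) as exc:
        if on_truncation == "skip":
            logger.warning("truncated final DCD frame skipped: %s", exc)
        else:
            raise
    finally:
        dt = getattr(reader, "dt", None)
        reader.close()
    return np.asarray(frames), dt


# --------------------------------------------------------------------------
# Selection mini-language
# --------------------------------------------------------------------------
#
# Grammar (keywords case-sensitive, whitespace separated):
#   expr     := and_expr ( "or" and_expr )*
#   and_expr := unary ( "and" unary )*
#   unary    := "not" unary | primary
#   primary  := "(" expr ")"
#             | "all" | "protein" | "nucleic"
#             | "name" NAME+ | "resname" NAME+ | "chain" ID+ | "element" SYM+
#             | "resid" range+            range := INT [ "to" INT ]
#             | "within" FLOAT "of" unary
#
# "within R of S" selects atoms whose distance to any atom of S is <= R (a
# closed ball), evaluated on the designated reference frame (by default the
# structure's own coordinates, i.e. the crystal structure).

_KEYWORDS = {
    "and", "or", "not", "name", "resname", "chain", "element", "resid",
    "within", "of", "to", "all", "protein", "nucleic", "(", ")",
}


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], structure: Structure,
                 reference_coords: np.ndarray):
        self.tokens = tokens
        self.pos = 0
        self.s = structure
        self.ref = reference_coords

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def expect(self, token: str) -> None:
        tok = self.next()
        if tok != token:
            raise SelectionError(f"expected {token!r} but found {tok!r}")

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        if self.peek() == "not":
            self.next()
            return ~self.unary()
        return self.primary()

    def _values(self) -> list[str]:
        vals: list[str] = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.next())
        if not vals:
            raise SelectionError(
                f"expected at least one value before {self.peek()!r}"
            )
        return vals

    def primary(self) -> np.ndarray:
        tok = self.next()
        n = self.s.n_atoms
        if tok == "(":
            mask = self.expr()
            self.expect(")")
            return mask
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "protein":
            return np.isin(self.s.residue_names.astype(str),
                           list(AMINO_ACIDS_3))
        if tok == "nucleic":
            return np.isin(self.s.residue_names.astype(str),
                           list(NUCLEOTIDES))
        if tok == "name":
            return np.isin(self.s.atom_names.astype(str), self._values())
        if tok == "resname":
            return np.isin(self.s.residue_names.astype(str), self._values())
        if tok == "chain":
            return np.isin(self.s.chain_ids.astype(str), self._values())
        if tok == "element":
            vals = [v.capitalize() for v in self._values()]
            return np.isin(self.s.elements.astype(str), vals)
        if tok == "resid":
            return self._resid_mask()
        if tok == "within":
            try:
                radius = float(self.next())
            except ValueError:
                raise SelectionError("'within' requires a numeric radius")
            self.expect("of")
            inner = self.unary()
            return self._within(radius, inner)
        raise SelectionError(f"syntax error at token {tok!r}")

    def _resid_mask(self) -> np.ndarray:
        mask = np.zeros(self.s.n_atoms, dtype=bool)
        got_any = False
        while True:
            tok = self.peek()
            if tok is None or tok in _KEYWORDS:
                break
            start = int(self.next())
            if self.peek() == "to":
                self.next()
                stop_tok = self.next()
                stop = int(stop_tok)
                mask |= (self.s.residue_seqs >= start) & (
                    self.s.residue_seqs <= stop)
            else:
                mask |= self.s.residue_seqs == start
            got_any = True
        if not got_any:
            raise SelectionError("'resid' requires at least one residue number")
        return mask

    def _within(self, radius: float, inner: np.ndarray) -> np.ndarray:
        if radius < 0:
            raise SelectionError("'within' radius must be >= 0")
        if not inner.any():
            return np.zeros(self.s.n_atoms, dtype=bool)
        tree = cKDTree(self.ref[inner])
        dmin, _ = tree.query(self.ref, k=1)
        return dmin <= radius


def select(
    structure: Structure,
    expression: str,
    reference_coords: np.ndarray | None = None,
) -> AtomSelection:
    """Resolve a selection expression against a structure.

    ``reference_coords`` is the frame on which "within" distances are
    evaluated (default: the structure's own coordinates).  An empty result is
    not an error; a warning is logged.
    """
    ref = (structure.coords if reference_coords is None
           else np.asarray(reference_coords, dtype=float).reshape(-1, 3))
    if ref.shape[0] != structure.n_atoms:
        raise ValueError("reference frame atom count mismatch")
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, structure, ref).parse()
    ids = np.flatnonzero(mask)
    if len(ids) == 0:
        logger.warning("selection %r resolved to zero atoms", expression)
    return AtomSelection(expression=expression, resolved_ids=ids)
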