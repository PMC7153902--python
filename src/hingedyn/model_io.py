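"""Data model and text I/O for hinge-dynamics analyses.

Internal conventions
--------------------
* lengths in nm, times in ps, energies in kJ/mol (PDB files are converted
  from/to Angstrom at the boundary, factor 0.1 exactly);
* residue numbering is 1-based (C1...C12 of the hinge sequence), atom
  indices are 0-based positions into ``Topology.atoms``;
* numeric text output uses ``%.9g`` so that write -> read round-trips are
  value-identical at the written precision.

Supported formats: multi-model PDB (via biotite), a plain XYZ-with-time
table (one row per frame: time then x y z per atom, nm), and PLUMED-style
COLVAR / HILLS files with ``#! FIELDS`` headers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HingedynError",
    "FileFormatError",
    "PDBParseError",
    "StructureError",
    "SelectionError",
    "Atom",
    "Topology",
    "Trajectory",
    "CVSeries",
    "Hill",
    "HINGE_SEQUENCE",
    "read_pdb",
    "write_pdb",
    "read_xyzt",
    "write_xyzt",
    "read_colvar",
    "write_colvar",
    "read_hills",
    "write_hills",
    "hills_cv_names",
    "resolve_selection",
    "standard_hinge_groups",
]

NUMERIC_FMT = "%.9g"

#: the dimeric hinge peptide sequence (one chain); the dimer is two copies
#: stapled by the C1-C12'/C1'-C12 disulfide cluster.
HINGE_SEQUENCE = "CHWECRGCRLVC"

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: atom names counted as backbone; everything else in a residue is side chain.
BACKBONE_NAMES = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "HN", "HA", "H1", "H2", "H3",
     "HA2", "HA3", "OT1", "OT2"}
)


class HingedynError(Exception):
    """Base class for errors raised by hingedyn."""


class FileFormatError(HingedynError):
    """A text file violates the expected COLVAR/HILLS/XYZ layout."""


class PDBParseError(FileFormatError):
    """A PDB record could not be parsed."""


class StructureError(HingedynError):
    """Models/frames are structurally inconsistent."""


class SelectionError(HingedynError):
    """Atom-selection expression is invalid or matches nothing."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    res_name: str
    res_id: int          # 1-based residue number within its chain
    chain_id: str


@dataclass
class Topology:
    """Atom labels plus named selection groups (0-based atom indices)."""

    atoms: list[Atom]
    groups: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("a topology needs at least one atom")
        seen: dict[str, int] = {}
        for atom in self.atoms:
            prev = seen.get(atom.chain_id)
            if prev is not None and atom.res_id < prev:
                raise StructureError(
                    f"residue ids decrease within chain {atom.chain_id!r}"
                )
            seen[atom.chain_id] = atom.res_id
        n = len(self.atoms)
        for name, idx in self.groups.items():
            if not idx:
                raise StructureError(f"group {name!r} is empty")
            if len(set(idx)) != len(idx):
                raise StructureError(f"group {name!r} has duplicate indices")
            if min(idx) < 0 or max(idx) >= n:
                raise StructureError(f"group {name!r} has out-of-range indices")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def chain_ids(self) -> list[str]:
        """Chain ids in order of first appearance."""
        out: list[str] = []
        for atom in self.atoms:
            if atom.chain_id not in out:
                out.append(atom.chain_id)
        return out

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain ('X' for non-standard residues)."""
        letters = []
        last = None
        for atom in self.atoms:
            if atom.chain_id != chain_id:
                continue
            if atom.res_id != last:
                letters.append(_THREE_TO_ONE.get(atom.res_name.upper(), "X"))
                last = atom.res_id
        return "".join(letters)

    def select(self, expression: str) -> list[int]:
        return resolve_selection(self, expression)


@dataclass
class Trajectory:
    """Time-stamped Cartesian frames (nm, ps) over a fixed atom set."""

    topology: Topology
    coords: np.ndarray   # (n_frames, n_atoms, 3) nm
    times: np.ndarray    # (n_frames,) ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise StructureError("a trajectory needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"frame atom count {self.coords.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if self.times.shape != (self.coords.shape[0],):
            raise StructureError("one time stamp per frame is required")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class CVSeries:
    """Named time series of collective-variable values with units."""

    names: list[str]
    units: list[str]
    times: np.ndarray        # (n,) ps
    values: np.ndarray       # (n, n_cv)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.times), -1)
        if self.values.shape[0] != self.times.shape[0]:
            raise StructureError("one row of CV values per time stamp")
        if self.values.shape[1] != len(self.names):
            raise StructureError("CV tuple arity must equal the name count")
        if len(self.units) != len(self.names):
            raise StructureError("one unit per CV name")

    @property
    def n_rows(self) -> int:
        return self.times.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"no CV named {name!r}; have {self.names}") from None
        return self.values[:, j]


@dataclass(frozen=True)
class Hill:
    """One deposited metadynamics Gaussian."""

    time: float                  # ps
    centers: tuple[float, ...]   # CV units
    widths: tuple[float, ...]    # Gaussian sigma, CV units
    height: float                # kJ/mol
    bias_factor: float           # gamma, dimensionless

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.widths):
            raise ValueError("hill widths must be > 0")
        if self.height < 0:
            raise ValueError("hill height must be >= 0")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must be > 1")
        if len(self.centers) != len(self.widths):
            raise ValueError("one width per CV center")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _prevalidate_pdb_text(path: str) -> None:
    """Cheap scan giving line-numbered diagnostics before biotite parses."""
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(
                        f"{path}:{lineno}: truncated {rec} record"
                    )
                for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise PDBParseError(
                            f"{path}:{lineno}: malformed {what} coordinate "
                            f"{fieldtxt!r} in {rec} record"
                        ) from None
                current += 1
                in_model = True
            elif rec == "ENDMDL":
                counts.append(current)
                current = 0
                in_model = False
    if in_model:
        counts.append(current)
    if not counts or counts[0] == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    if len(set(counts)) > 1:
        raise StructureError(
            f"{path}: inconsistent atom count across MODELs: {sorted(set(counts))}"
        )


def read_pdb(path: str, times: np.ndarray | None = None) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory.

    Coordinates are converted Angstrom -> nm.  When ``times`` is not given,
    frames are stamped 0, 1, 2, ... ps.  If the file's sequence matches the
    dimeric hinge (CHWECRGCRLVC)2 the standard selection groups
    (``ca_chainA``, ``sulfur_cluster``, ``c5c8_A``, ``g7_A``, ``trpA``, ...)
    are attached automatically.
    """
    from biotite.structure.io.pdb import PDBFile

    _prevalidate_pdb_text(path)
    try:
        pdb_file = PDBFile.read(path)
        stack = pdb_file.get_structure()  # AtomArrayStack, Angstrom
    except Exception as exc:  # noqa: BLE001 - rewrap third-party parse errors
        raise PDBParseError(f"{path}: {exc}") from exc

    atoms = [
        Atom(
            name=str(stack.atom_name[i]),
            element=str(stack.element[i]),
            res_name=str(stack.res_name[i]),
            res_id=int(stack.res_id[i]),
            chain_id=str(stack.chain_id[i]),
        )
        for i in range(stack.array_length())
    ]
    topology = Topology(atoms=atoms)
    topology.groups.update(standard_hinge_groups(topology))

    coords = np.asarray(stack.coord, dtype=float) * 0.1  # A -> nm
    n_frames = coords.shape[0]
    if times is None:
        times = np.arange(n_frames, dtype=float)
    return Trajectory(topology=topology, coords=coords, times=times)


def write_pdb(trajectory: Trajectory, path: str) -> None:
    """Write a Trajectory as a multi-model PDB (nm -> Angstrom)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    top = trajectory.topology
    n = top.n_atoms
    array = struc.AtomArray(n)
    array.coord = np.zeros((n, 3))
    array.chain_id = np.array([a.chain_id for a in top.atoms], dtype="U4")
    array.res_id = np.array([a.res_id for a in top.atoms], dtype=int)
    array.res_name = np.array([a.res_name for a in top.atoms], dtype="U5")
    array.atom_name = np.array([a.name for a in top.atoms], dtype="U6")
    array.element = np.array([a.element for a in top.atoms], dtype="U2")
    stack = struc.stack([array] * trajectory.n_frames)
    stack.coord = np.asarray(trajectory.coords, dtype=float) * 10.0  # nm -> A
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)


def standard_hinge_groups(topology: Topology) -> dict[str, list[int]]:
    """Auto-build the named hinge selections if the sequence matches.

    Returns an empty dict for anything that is not the dimeric 12-mer
    (CHWECRGCRLVC)2.  Residues are addressed by their 1-based *position*
    within each chain so that numbering offsets in the file do not matter.
    """
    chains = topology.chain_ids()
    if len(chains) != 2:
        return {}
    if any(topology.chain_sequence(c) != HINGE_SEQUENCE for c in chains):
        return {}

    # per-chain map: residue position (1-based) -> atom indices
    pos_atoms: dict[str, dict[int, list[int]]] = {c: {} for c in chains}
    for c in chains:
        last_rid = None
        pos = 0
        for i, atom in enumerate(topology.atoms):
            if atom.chain_id != c:
                continue
            if atom.res_id != last_rid:
                pos += 1
                last_rid = atom.res_id
            pos_atoms[c].setdefault(pos, []).append(i)

    def named(chain: str, pos: int, name: str) -> list[int]:
        return [i for i in pos_atoms[chain].get(pos, [])
                if topology.atoms[i].name == name]

    def sidechain(chain: str, pos: int) -> list[int]:
        return [i for i in pos_atoms[chain].get(pos, [])
                if topology.atoms[i].name not in BACKBONE_NAMES]

    a, b = chains
    groups = {
        "ca_chainA": [i for p in range(1, 13) for i in named(a, p, "CA")],
        "ca_chainB": [i for p in range(1, 13) for i in named(b, p, "CA")],
        "sulfur_cluster": (named(a, 1, "SG") + named(a, 12, "SG")
                           + named(b, 1, "SG") + named(b, 12, "SG")),
        "c5c8_A": named(a, 5, "CA") + named(a, 8, "CA"),
        "c5c8_B": named(b, 5, "CA") + named(b, 8, "CA"),
        "g7_A": named(a, 7, "CA"),
        "g7_B": named(b, 7, "CA"),
        "trpA": sidechain(a, 3),
        "trpB": sidechain(b, 3),
    }
    return {k: v for k, v in groups.items() if v}


# ---------------------------------------------------------------------------
# XYZ-with-time
# ---------------------------------------------------------------------------

def write_xyzt(trajectory: Trajectory, path: str) -> None:
    """Plain-text frames: ``time x1 y1 z1 x2 y2 z2 ...`` (ps, nm)."""
    n = trajectory.n_atoms
    with open(path, "w") as fh:
        fh.write(f"# xyzt n_atoms={n} units=nm,ps\n")
        for t, frame in zip(trajectory.times, trajectory.coords):
            row = np.concatenate([[t], frame.reshape(-1)])
            fh.write(" ".join(NUMERIC_FMT % v for v in row) + "\n")


def read_xyzt(path: str, topology: Topology) -> Trajectory:
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        raise FileFormatError(f"{path}: no frames")
    if (data.shape[1] - 1) % 3 != 0:
        raise FileFormatError(f"{path}: row width {data.shape[1]} is not 1+3N")
    n = (data.shape[1] - 1) // 3
    if n != topology.n_atoms:
        raise StructureError(
            f"{path}: {n} atoms per frame but topology has {topology.n_atoms}"
        )
    coords = data[:, 1:].reshape(-1, n, 3)
    return Trajectory(topology=topology, coords=coords, times=data[:, 0])


# ---------------------------------------------------------------------------
# COLVAR / HILLS (PLUMED dialect)
# ---------------------------------------------------------------------------

def _read_fields_header(path: str) -> list[str]:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#! FIELDS"):
        raise FileFormatError(
            f"{path}: missing '#! FIELDS' header (got {first[:40]!r})"
        )
    fields = first.split()[2:]
    if not fields or fields[0] != "time":
        raise FileFormatError(f"{path}: first field must be 'time'")
    return fields


def _read_table(path: str, n_fields: int) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != n_fields:
                raise FileFormatError(
                    f"{path}:{lineno}: expected {n_fields} columns, "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise FileFormatError(
                    f"{path}:{lineno}: non-numeric value in row"
                ) from None
    return np.array(rows, dtype=float).reshape(len(rows), n_fields)


def read_colvar(path: str) -> CVSeries:
    """Read a PLUMED-style COLVAR file.

    Units are taken from optional ``#! SET unit_<name> <unit>`` lines and
    default to "dimensionless".
    """
    fields = _read_fields_header(path)
    names = fields[1:]
    units = {n: "dimensionless" for n in names}
    with open(path) as fh:
        for line in fh:
            m = re.match(r"#!\s+SET\s+unit_(\S+)\s+(\S+)", line)
            if m and m.group(1) in units:
                units[m.group(1)] = m.group(2)
    data = _read_table(path, len(fields))
    return CVSeries(
        names=names,
        units=[units[n] for n in names],
        times=data[:, 0],
        values=data[:, 1:],
    )


def write_colvar(series: CVSeries, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#! FIELDS time " + " ".join(series.names) + "\n")
        for name, unit in zip(series.names, series.units):
            fh.write(f"#! SET unit_{name} {unit}\n")
        for t, row in zip(series.times, series.values):
            vals = np.concatenate([[t], row])
            fh.write(" ".join(NUMERIC_FMT % v for v in vals) + "\n")


def hills_cv_names(path: str) -> list[str]:
    """CV names declared in a HILLS header."""
    fields = _read_fields_header(path)
    body = fields[1:]
    n_cv = sum(1 for f in body if f.startswith("sigma_"))
    names = body[:n_cv]
    expected = names + [f"sigma_{n}" for n in names] + ["height", "biasf"]
    if body != expected:
        raise FileFormatError(
            f"{path}: HILLS header must read 'time <cv..> sigma_<cv..> "
            f"height biasf', got {body}"
        )
    return names


def read_hills(path: str) -> list[Hill]:
    """Read a PLUMED-style HILLS file into Hill records."""
    names = hills_cv_names(path)
    n_cv = len(names)
    data = _read_table(path, 2 * n_cv + 3)
    hills = []
    for r, row in enumerate(data):
        height = row[2 * n_cv + 1]
        sigmas = row[n_cv + 1:2 * n_cv + 1]
        if height < 0 or np.any(sigmas <= 0):
            raise FileFormatError(
                f"{path}: invalid hill in data row {r + 1} "
                f"(height={height}, sigma={sigmas})"
            )
        hills.append(
            Hill(
                time=row[0],
                centers=tuple(row[1:n_cv + 1]),
                widths=tuple(sigmas),
                height=height,
                bias_factor=row[2 * n_cv + 2],
            )
        )
    return hills


def write_hills(hills: list[Hill], path: str, names: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write(_hills_header(names))
        for hill in hills:
            fh.write(format_hill_row(hill))


def _hills_header(names: list[str]) -> str:
    return ("#! FIELDS time " + " ".join(names) + " "
            + " ".join(f"sigma_{n}" for n in names) + " height biasf\n")


def format_hill_row(hill: Hill) -> str:
    vals = ((hill.time,) + hill.centers + hill.widths
            + (hill.height, hill.bias_factor))
    return " ".join(NUMERIC_FMT % v for v in vals) + "\n"


# ---------------------------------------------------------------------------
# selection mini-grammar
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = ("chain", "resid", "resname", "name")


def resolve_selection(topology: Topology, expression: str) -> list[int]:
    """Resolve ``chain A and resid 7 and name CA``-style expressions.

    Grammar: primitives ``chain <id>``, ``resid <n>``, ``resname <X>``,
    ``name <X>`` combined with ``and`` / ``or`` and parentheses (``and``
    binds tighter).  The result is an order-preserving 0-based index list;
    an empty match raises :class:`SelectionError`.
    """
    tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]
    if not tokens:
        raise SelectionError("empty selection expression")
    pos = 0

    def peek() -> str | None:
        return tokens[pos][0] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos][0]
        pos += 1
        return tok

    def fail(msg: str) -> SelectionError:
        at = tokens[pos][1] if pos < len(tokens) else len(expression)
        return SelectionError(f"{msg} at position {at} in {expression!r}")

    n = topology.n_atoms

    def primitive() -> np.ndarray:
        tok = peek()
        if tok == "(":
            take()
            mask = expr()
            if peek() != ")":
                raise fail("expected ')'")
            take()
            return mask
        if tok not in _KEYWORDS:
            raise fail(f"expected one of {_KEYWORDS} or '('")
        key = take()
        if peek() is None or peek() in ("and", "or", ")", "("):
            raise fail(f"keyword {key!r} needs a value")
        value = take()
        mask = np.zeros(n, dtype=bool)
        if key == "chain":
            for i, a in enumerate(topology.atoms):
                mask[i] = a.chain_id == value
        elif key == "resid":
            try:
                rid = int(value)
            except ValueError:
                raise fail(f"resid needs an integer, got {value!r}") from None
            for i, a in enumerate(topology.atoms):
                mask[i] = a.res_id == rid
        elif key == "resname":
            for i, a in enumerate(topology.atoms):
                mask[i] = a.res_name.upper() == value.upper()
        else:  # name
            for i, a in enumerate(topology.atoms):
                mask[i] = a.name.upper() == value.upper()
        return mask

    def term() -> np.ndarray:
        mask = primitive()
        while peek() == "and":
            take()
            mask = mask & primitive()
        return mask

    def expr() -> np.ndarray:
        mask = term()
        while peek() == "or":
            take()
            mask = mask | term()
        return mask

    mask = expr()
    if pos != len(tokens):
        raise fail("unexpected trailing token")
    indices = [int(i) for i in np.nonzero(mask)[0]]
    if not indices:
        raise SelectionError(
            f"selection {expression!r} matches no atoms"
        )
    return indices
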