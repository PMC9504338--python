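"""Topology and trajectory I/O plus atom selection.

Conventions
-----------
* Residue and atom serial numbers are 1-based, exactly as printed in PDB
  files.  Every array index handed to the rest of the package is 0-based;
  the 1-based/0-based boundary is crossed only inside this module.
* Coordinates are always in Angstrom.  ``frame_spacing`` is in ns per frame
  and defaults to 1.0 when the stored format carries no time information.

Formats
-------
* Topology: PDB (``ATOM``/``HETATM`` records, fixed-width columns).
* Trajectory: multi-model PDB (``MODEL``/``ENDMDL``) or the plain-matrix
  text format::

      n_frames n_atoms frame_spacing
      x y z          # atom 0, frame 0
      x y z          # atom 1, frame 0
      ...            # one line per atom, frames concatenated

Readers reject inconsistent input rather than repairing it; every error
message carries file/line context.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# Default atomic masses (amu) used when a PDB provides no mass information.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "MN": 54.938, "CU": 63.546, "SE": 78.971,
}
_DEFAULT_MASS = 12.011  # fall back to carbon for unknown elements


@dataclass
class Topology:
    """Static atom metadata: one entry per atom, in file order."""

    names: list[str]
    resids: np.ndarray          # 1-based residue numbers
    resnames: list[str]
    chains: list[str]
    masses: np.ndarray          # amu
    elements: list[str]
    record_types: list[str] = field(default_factory=list)   # ATOM / HETATM
    # named residue ranges: name -> (chain_id or None, first_resid, last_resid)
    segments: dict[str, tuple[str | None, int, int]] = field(default_factory=dict)
    # free-form residue annotations, e.g. {"TM6": [201, ..., 215]}
    annotations: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        self.resids = np.asarray(self.resids, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        if not self.record_types:
            self.record_types = ["ATOM"] * len(self.names)
        if np.any(self.masses <= 0):
            raise ValueError("atom masses must be positive")
        for chain in set(self.chains):
            r = self.resids[[c == chain for c in self.chains]]
            if np.any(np.diff(r) < 0):
                raise ValueError(f"residue indices decrease within chain {chain!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def add_segment(self, name: str, first_resid: int, last_resid: int,
                    chain: str | None = None) -> None:
        for other, (ch, a, b) in self.segments.items():
            if (chain is None or ch is None or chain == ch) and not (last_resid < a or first_resid > b):
                raise ValueError(f"segment {name!r} overlaps existing segment {other!r}")
        self.segments[name] = (chain, int(first_resid), int(last_resid))


@dataclass
class Trajectory:
    """Coordinates over time for a fixed topology.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in Angstrom.
    """

    topology: Topology
    coordinates: np.ndarray
    frame_spacing: float = 1.0   # ns per frame

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(f"coordinates must be (frames, atoms, 3), got {self.coordinates.shape}")
        if self.coordinates.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class AtomSelection:
    """A sorted, duplicate-free list of 0-based atom indices."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and (np.any(np.diff(idx) <= 0)):
            raise ValueError("selection indices must be unique and sorted")
        self.indices = idx

    def __len__(self) -> int:
        return int(self.indices.size)


# --------------------------------------------------------------------------
# PDB reading / writing
# --------------------------------------------------------------------------

def _parse_float(text: str, what: str, path: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed {what} field {text!r}") from None


def _parse_atom_line(line: str, path: str, lineno: int):
    if len(line.rstrip("\n")) < 54:
        raise ValueError(f"{path}:{lineno}: ATOM/HETATM record shorter than 54 columns")
    record = line[:6].strip()
    try:
        serial = int(line[6:11])
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed atom serial {line[6:11]!r}") from None
    name = line[12:16].strip()
    resname = line[17:20].strip()
    chain = line[21].strip() or "A"
    try:
        resid = int(line[22:26])
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed residue number {line[22:26]!r}") from None
    x = _parse_float(line[30:38], "x coordinate", path, lineno)
    y = _parse_float(line[38:46], "y coordinate", path, lineno)
    z = _parse_float(line[46:54], "z coordinate", path, lineno)
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        # infer from the atom name: leading digits stripped, first letter(s)
        stripped = name.lstrip("0123456789")
        element = stripped[:2].upper() if stripped[:2].upper() in ELEMENT_MASSES else stripped[:1].upper()
    return record, serial, name, resname, chain, resid, (x, y, z), element


def read_topology(path: str) -> tuple[Topology, np.ndarray]:
    """Read a PDB topology; returns (Topology, first-model coordinates).

    One atom per ATOM/HETATM record of the first model; chain and residue
    numbering preserved exactly as printed.
    """
    names, resids, resnames, chains, masses, elements, records = [], [], [], [], [], [], []
    coords = []
    seen_serials: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag == "ENDMDL":
                break
            if tag not in ("ATOM", "HETATM"):
                continue
            record, serial, name, resname, chain, resid, xyz, element = _parse_atom_line(
                line, str(path), lineno)
            if serial in seen_serials:
                warnings.warn(f"{path}:{lineno}: duplicate atom serial {serial}")
            seen_serials.add(serial)
            names.append(name)
            resids.append(resid)
            resnames.append(resname)
            chains.append(chain)
            masses.append(ELEMENT_MASSES.get(element, _DEFAULT_MASS))
            elements.append(element)
            records.append(record)
            coords.append(xyz)
    if not names:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    top = Topology(names, np.array(resids), resnames, chains,
                   np.array(masses), elements, record_types=records)
    return top, np.asarray(coords, dtype=float)


def write_topology(path: str, topology: Topology, coordinates: np.ndarray) -> None:
    """Write a single-model PDB for the topology at the given coordinates."""
    with open(path, "w") as fh:
        _write_model(fh, topology, np.asarray(coordinates, dtype=float))
        fh.write("END\n")


def _write_model(fh, top: Topology, xyz: np.ndarray) -> None:
    for i in range(top.n_atoms):
        name = top.names[i]
        # PDB convention: 1-3 character names start in column 14
        padded = f" {name:<3s}" if len(name) < 4 else name[:4]
        fh.write(
            f"{top.record_types[i]:<6s}{(i + 1) % 100000:5d} {padded:<4s} "
            f"{top.resnames[i]:>3s} {top.chains[i]:1s}{top.resids[i]:4d}    "
            f"{xyz[i, 0]:8.3f}{xyz[i, 1]:8.3f}{xyz[i, 2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {top.elements[i]:>2s}\n")


def read_trajectory(path: str, topology: Topology, fmt: str = "plain-matrix",
                    frame_spacing: float | None = None) -> Trajectory:
    """Read a trajectory in ``plain-matrix`` or ``multi-model-pdb`` format."""
    if fmt == "plain-matrix":
        return _read_plain_matrix(path, topology)
    if fmt == "multi-model-pdb":
        return _read_multimodel_pdb(path, topology, frame_spacing or 1.0)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def _read_plain_matrix(path: str, topology: Topology) -> Trajectory:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3:
            raise ValueError(f"{path}:1: header must be 'n_frames n_atoms frame_spacing'")
        n_frames, n_atoms = int(header[0]), int(header[1])
        frame_spacing = float(header[2])
        if n_atoms != topology.n_atoms:
            raise ValueError(
                f"{path}: file declares {n_atoms} atoms but topology has {topology.n_atoms}")
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    if data.shape != (n_frames * n_atoms, 3):
        frame = data.shape[0] // max(n_atoms, 1)
        raise ValueError(
            f"{path}: expected {n_frames * n_atoms} coordinate rows, got {data.shape[0]} "
            f"(truncated near frame {frame})")
    return Trajectory(topology, data.reshape(n_frames, n_atoms, 3), frame_spacing)


def write_trajectory(path: str, traj: Trajectory, fmt: str = "plain-matrix") -> None:
    if fmt == "plain-matrix":
        with open(path, "w") as fh:
            fh.write(f"{traj.n_frames} {traj.n_atoms} {traj.frame_spacing:.10g}\n")
            flat = traj.coordinates.reshape(-1, 3)
            np.savetxt(fh, flat, fmt="%.8f")
    elif fmt == "multi-model-pdb":
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"MODEL     {f + 1:4d}\n")
                _write_model(fh, traj.topology, traj.coordinates[f])
                fh.write("ENDMDL\n")
            fh.write("END\n")
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def _read_multimodel_pdb(path: str, topology: Topology, frame_spacing: float) -> Trajectory:
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag == "MODEL":
                current = []
            elif tag == "ENDMDL":
                if current is None:
                    raise ValueError(f"{path}:{lineno}: ENDMDL without MODEL")
                if len(current) != topology.n_atoms:
                    raise ValueError(
                        f"{path}:{lineno}: frame {len(frames)} has {len(current)} atoms, "
                        f"topology has {topology.n_atoms}")
                frames.append(current)
                current = None
            elif tag in ("ATOM", "HETATM"):
                *_, xyz, _el = _parse_atom_line(line, str(path), lineno)
                if current is None:   # single-model file without MODEL records
                    current = []
                current.append(xyz)
    if current:
        if len(current) != topology.n_atoms:
            raise ValueError(f"{path}: truncated final frame ({len(current)} atoms)")
        frames.append(current)
    if not frames:
        raise ValueError(f"{path}: no coordinate frames found")
    return Trajectory(topology, np.asarray(frames, dtype=float), frame_spacing)


# --------------------------------------------------------------------------
# Atom selection
# --------------------------------------------------------------------------

def _parse_resid_values(text: str) -> list[tuple[int, int]]:
    ranges = []
    for part in text.split(","):
        if ":" in part:
            a, b = part.split(":")
            ranges.append((int(a), int(b)))
        else:
            ranges.append((int(part), int(part)))
    return ranges


def select_atoms(topology: Topology, query: str, label: str | None = None,
                 invert: bool = False) -> AtomSelection:
    """Resolve a selection query to a sorted AtomSelection.

    Grammar: clauses joined by ``and``; each clause optionally prefixed by
    ``not``.  Clauses::

        all
        name CA[,CB,...]
        resname ALA[,GLY]
        resid 10:50[,60,70:80]     (1-based, inclusive)
        chain A[,B]
        element C[,N]
        segment receptor
        record ATOM|HETATM

    An empty result raises, never returns silently.
    """
    n = topology.n_atoms
    mask = np.ones(n, dtype=bool)
    tokens = query.split()
    i = 0
    while i < len(tokens):
        negate = False
        if tokens[i] == "and":
            i += 1
            continue
        if tokens[i] == "not":
            negate = True
            i += 1
        if i >= len(tokens):
            raise ValueError(f"selection query ends unexpectedly: {query!r}")
        key = tokens[i]
        if key == "all":
            clause = np.ones(n, dtype=bool)
            i += 1
        else:
            if i + 1 >= len(tokens):
                raise ValueError(f"selection clause {key!r} missing its value in {query!r}")
            value = tokens[i + 1]
            i += 2
            if key == "name":
                wanted = set(value.split(","))
                clause = np.array([nm in wanted for nm in topology.names])
            elif key == "resname":
                wanted = set(value.split(","))
                clause = np.array([rn in wanted for rn in topology.resnames])
            elif key == "chain":
                wanted = set(value.split(","))
                clause = np.array([c in wanted for c in topology.chains])
            elif key == "element":
                wanted = {v.upper() for v in value.split(",")}
                clause = np.array([e.upper() in wanted for e in topology.elements])
            elif key == "record":
                clause = np.array([r == value for r in topology.record_types])
            elif key == "resid":
                clause = np.zeros(n, dtype=bool)
                for a, b in _parse_resid_values(value):
                    clause |= (topology.resids >= a) & (topology.resids <= b)
            elif key == "segment":
                if value not in topology.segments:
                    raise ValueError(f"unknown segment {value!r}; known: {sorted(topology.segments)}")
                chain, a, b = topology.segments[value]
                clause = (topology.resids >= a) & (topology.resids <= b)
                if chain is not None:
                    clause &= np.array([c == chain for c in topology.chains])
            else:
                raise ValueError(f"unknown selection keyword {key!r} in {query!r}")
        mask &= ~clause if negate else clause
    if invert:
        mask = ~mask
    idx = np.where(mask)[0]
    if idx.size == 0:
        raise ValueError(f"selection {query!r} matched no atoms")
    return AtomSelection(idx, label if label is not None else query)


def residue_index_of(topology: Topology, selection: AtomSelection) -> np.ndarray:
    """1-based residue number for each selected atom."""
    return topology.resids[selection.indices]
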