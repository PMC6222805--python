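"""Trajectory, structure and topology I/O.

Length unit is the nanometre and time unit the picosecond throughout the
package.  Trajectories are multi-frame XYZ files (which carry no box
information: the cubic box edge comes from the companion ``.gro`` structure
file or from the topology config and is assumed constant over the
trajectory).  The system composition is described by a plain-text topology
config that lists molecule templates -- element sequence, internal bonds and
named interaction sites -- plus the instance layout of one frame.

Atom serials are 1-based in files and 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .errors import GeometryError, ParseError, TopologyError

_KNOWN_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Br", "I", "Fe", "Zn", "Cu", "Mn",
}


class Atom(NamedTuple):
    """One atom: chemical symbol, 1-based serial within the frame, position in nm."""

    element: str
    serial: int
    position: np.ndarray


@dataclass
class Frame:
    """One trajectory snapshot.

    Parameters
    ----------
    elements
        Chemical symbols, one per atom, in file order.
    coords
        ``(n_atoms, 3)`` Cartesian coordinates in nm.
    box_edge
        Cubic box edge length in nm, or ``None`` when unknown (plain XYZ).
    index
        0-based frame number within its trajectory.
    time
        Time stamp in ps (``index * frame_interval``).
    """

    elements: list[str]
    coords: np.ndarray
    box_edge: float | None = None
    index: int = 0
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinate")
        if self.box_edge is not None and self.box_edge <= 0:
            raise ValueError("box_edge must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atoms(self) -> Iterator[Atom]:
        for i, (el, xyz) in enumerate(zip(self.elements, self.coords)):
            yield Atom(el, i + 1, xyz)


@dataclass
class MoleculeTemplate:
    """A molecule blueprint: elements, internal bonds and named sites.

    Bond indices and site indices are 0-based local atom indices (the config
    file uses 1-based indices, converted on parse).
    """

    name: str
    elements: list[str]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    sites: dict[str, int] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def validate(self) -> None:
        n = self.n_atoms
        if n == 0:
            raise TopologyError(f"template {self.name!r} has no atoms")
        for el in self.elements:
            if el not in _KNOWN_ELEMENTS:
                raise TopologyError(
                    f"template {self.name!r}: unrecognized element {el!r}")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise TopologyError(
                    f"template {self.name!r}: bond ({i + 1}, {j + 1}) references "
                    f"an unknown atom (template has {n} atoms)")
        for label, idx in self.sites.items():
            if not 0 <= idx < n:
                raise TopologyError(
                    f"template {self.name!r}: site {label!r} index {idx + 1} "
                    f"out of range (template has {n} atoms)")

    def bonded_to(self, local_index: int) -> list[int]:
        out = [j for i, j in self.bonds if i == local_index]
        out += [i for i, j in self.bonds if j == local_index]
        return sorted(out)


class MoleculeInstance(NamedTuple):
    """One concrete molecule in a frame: its template, global index and atom offset."""

    template: MoleculeTemplate
    mol_index: int
    atom_offset: int


@dataclass
class SystemTopology:
    """Templates plus the per-frame instance layout.

    ``layout`` is an ordered list of ``(template_name, count)`` pairs; frames
    are partitioned positionally, templates consumed in declared order.
    """

    templates: dict[str, MoleculeTemplate]
    layout: list[tuple[str, int]]
    box_edge: float | None = None

    def __post_init__(self) -> None:
        for tpl in self.templates.values():
            tpl.validate()
        for name, count in self.layout:
            if name not in self.templates:
                raise TopologyError(f"layout references unknown template {name!r}")
            if count < 0:
                raise TopologyError(f"negative instance count for {name!r}")

    @property
    def n_atoms(self) -> int:
        return sum(self.templates[name].n_atoms * count for name, count in self.layout)

    @property
    def n_molecules(self) -> int:
        return sum(count for _, count in self.layout)

    def instances(self) -> Iterator[MoleculeInstance]:
        """Yield every molecule instance with its global index and atom offset."""
        mol = 0
        offset = 0
        for name, count in self.layout:
            tpl = self.templates[name]
            for _ in range(count):
                yield MoleculeInstance(tpl, mol, offset)
                mol += 1
                offset += tpl.n_atoms
        assert offset == self.n_atoms

    def instances_of(self, template_name: str) -> list[MoleculeInstance]:
        return [mi for mi in self.instances() if mi.template.name == template_name]

    def check_frame(self, frame: Frame) -> None:
        """Raise TopologyError if the frame does not match the layout."""
        if frame.n_atoms != self.n_atoms:
            raise TopologyError(
                f"frame {frame.index}: {frame.n_atoms} atoms but topology "
                f"layout defines {self.n_atoms}")
        pos = 0
        for name, count in self.layout:
            tpl = self.templates[name]
            for k in range(count):
                got = frame.elements[pos:pos + tpl.n_atoms]
                if got != tpl.elements:
                    raise TopologyError(
                        f"frame {frame.index}: elements of molecule {k} of "
                        f"template {name!r} are {got}, expected {tpl.elements}")
                pos += tpl.n_atoms


# ---------------------------------------------------------------------------
# XYZ trajectories

def read_xyz_trajectory(path: str | Path, frame_interval: float = 0.5,
                        box_edge: float | None = None) -> list[Frame]:
    """Read a multi-frame XYZ file (coordinates in nm).

    Time stamps are assigned as ``index * frame_interval`` (ps).  A constant
    atom count across frames is enforced.  An empty file yields an empty list.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    ln = 0
    n_expected: int | None = None
    while ln < len(lines):
        if not lines[ln].strip():  # tolerate trailing blank lines
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise ParseError(
                f"{path}:{ln + 1}: malformed atom-count line {lines[ln]!r}")
        if natoms < 0 or ln + 2 + natoms > len(lines):
            raise ParseError(
                f"{path}:{ln + 1}: frame truncated ({natoms} atoms declared)")
        idx = len(frames)
        if n_expected is None:
            n_expected = natoms
        elif natoms != n_expected:
            raise ParseError(
                f"{path}: atom count changed from {n_expected} to {natoms} "
                f"at frame {idx}")
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for a in range(natoms):
            row = lines[ln + 2 + a].split()
            if len(row) < 4:
                raise ParseError(
                    f"{path}:{ln + 3 + a}: malformed atom line {lines[ln + 2 + a]!r}")
            elements.append(row[0])
            try:
                coords[a] = [float(x) for x in row[1:4]]
            except ValueError:
                raise ParseError(
                    f"{path}:{ln + 3 + a}: non-numeric coordinate in "
                    f"{lines[ln + 2 + a]!r}")
        frames.append(Frame(elements, coords, box_edge=box_edge, index=idx,
                            time=idx * frame_interval))
        ln += 2 + natoms
    return frames


def write_xyz_trajectory(frames: Sequence[Frame], path: str | Path,
                         precision: int = 6) -> None:
    """Write frames as multi-frame XYZ, coordinates in nm."""
    path = Path(path)
    fmt = f"%-2s %.{precision}f %.{precision}f %.{precision}f"
    out: list[str] = []
    for fr in frames:
        out.append(str(fr.n_atoms))
        out.append(f"frame {fr.index} t= {fr.time:.4f} ps")
        for el, (x, y, z) in zip(fr.elements, fr.coords):
            out.append(fmt % (el, x, y, z))
    path.write_text("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# GRO structures

_CUBIC_TOL = 1e-4  # nm; box components must agree within this to count as cubic


def read_gro_structure(path: str | Path) -> Frame:
    """Read a single-frame fixed-column .gro structure file (nm units).

    Only cubic boxes are supported: the box line's first three components
    must be equal (within a small tolerance) and any off-diagonal components
    must vanish.  Velocity columns, if present, are ignored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: too short to be a .gro file")
    try:
        natoms = int(lines[1].strip())
    except ValueError:
        raise ParseError(f"{path}:2: malformed atom-count line {lines[1]!r}")
    if len(lines) < 2 + natoms + 1:
        raise ParseError(f"{path}: expected {natoms} atom lines plus a box line")
    elements: list[str] = []
    coords = np.empty((natoms, 3))
    for a in range(natoms):
        line = lines[2 + a]
        if len(line) < 44:
            raise ParseError(f"{path}:{3 + a}: atom line too short {line!r}")
        name = line[10:15].strip()
        # element = leading alphabetic part of the atom name
        el = "".join(c for c in name if c.isalpha())[:2]
        if el[:1].upper() + el[1:].lower() in _KNOWN_ELEMENTS:
            el = el[:1].upper() + el[1:].lower()
        else:
            el = name[:1].upper()
        elements.append(el)
        try:
            coords[a] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        except ValueError:
            raise ParseError(f"{path}:{3 + a}: malformed coordinates in {line!r}")
    box_fields = lines[2 + natoms].split()
    try:
        box = [float(x) for x in box_fields]
    except ValueError:
        raise ParseError(f"{path}: malformed box line {lines[2 + natoms]!r}")
    if len(box) < 3:
        raise ParseError(f"{path}: box line needs at least 3 components")
    if any(abs(v) > _CUBIC_TOL for v in box[3:]):
        raise GeometryError(f"{path}: triclinic box not supported: {box}")
    if abs(box[0] - box[1]) > _CUBIC_TOL or abs(box[0] - box[2]) > _CUBIC_TOL:
        raise GeometryError(f"{path}: non-cubic box not supported: {box[:3]}")
    return Frame(elements, coords, box_edge=box[0])


def write_gro_structure(frame: Frame, topology: SystemTopology,
                        path: str | Path, title: str = "solvgraph") -> None:
    """Write a frame in fixed-column .gro format (nm, %8.3f precision).

    Residue names come from the topology templates; atom names are the
    element symbol plus the 1-based local index.
    """
    if frame.box_edge is None:
        raise GeometryError("cannot write .gro without a box edge")
    topology.check_frame(frame)
    lines = [title, f"{frame.n_atoms:5d}"]
    serial = 0
    for mi in topology.instances():
        resid = (mi.mol_index + 1) % 100000
        for local in range(mi.template.n_atoms):
            x, y, z = frame.coords[serial]
            name = f"{mi.template.elements[local]}{local + 1}"
            lines.append(
                f"{resid:5d}{mi.template.name[:5]:<5s}{name[:5]:>5s}"
                f"{(serial + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
            serial += 1
    e = frame.box_edge
    lines.append(f"{e:10.5f}{e:10.5f}{e:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Topology config

def parse_topology(path: str | Path) -> SystemTopology:
    """Parse the plain-text topology config.

    Grammar (one directive per line, ``#`` starts a comment)::

        molecule NAME          # open a template block
          atoms El El El ...   # element sequence
          bond I J             # internal bond, 1-based local indices
          site LABEL I         # named interaction site, 1-based local index
        end
        layout NAME COUNT      # instance layout, declared order = frame order
        box EDGE               # optional cubic box edge, nm
    """
    path = Path(path)
    templates: dict[str, MoleculeTemplate] = {}
    layout: list[tuple[str, int]] = []
    box_edge: float | None = None
    current: MoleculeTemplate | None = None
    for n, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        kw = tok[0].lower()
        try:
            if kw == "molecule":
                if current is not None:
                    raise ParseError(f"{path}:{n}: nested molecule block")
                if tok[1] in templates:
                    raise ParseError(f"{path}:{n}: duplicate template {tok[1]!r}")
                current = MoleculeTemplate(tok[1], [])
            elif kw == "atoms":
                if current is None:
                    raise ParseError(f"{path}:{n}: 'atoms' outside molecule block")
                current.elements.extend(tok[1:])
            elif kw == "bond":
                if current is None:
                    raise ParseError(f"{path}:{n}: 'bond' outside molecule block")
                current.bonds.append((int(tok[1]) - 1, int(tok[2]) - 1))
            elif kw == "site":
                if current is None:
                    raise ParseError(f"{path}:{n}: 'site' outside molecule block")
                if tok[1] in current.sites:
                    raise ParseError(
                        f"{path}:{n}: duplicate site label {tok[1]!r} in "
                        f"template {current.name!r}")
                current.sites[tok[1]] = int(tok[2]) - 1
            elif kw == "end":
                if current is None:
                    raise ParseError(f"{path}:{n}: 'end' without molecule block")
                templates[current.name] = current
                current = None
            elif kw == "layout":
                layout.append((tok[1], int(tok[2])))
            elif kw == "box":
                box_edge = float(tok[1])
            else:
                raise ParseError(f"{path}:{n}: unknown directive {tok[0]!r}")
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{n}: malformed directive {raw!r}") from exc
    if current is not None:
        raise ParseError(f"{path}: unterminated molecule block {current.name!r}")
    return SystemTopology(templates, layout, box_edge=box_edge)


def write_topology(topology: SystemTopology, path: str | Path) -> None:
    """Write a topology config in the grammar accepted by :func:`parse_topology`."""
    lines: list[str] = []
    for tpl in topology.templates.values():
        lines.append(f"molecule {tpl.name}")
        lines.append("  atoms " + " ".join(tpl.elements))
        for i, j in tpl.bonds:
            lines.append(f"  bond {i + 1} {j + 1}")
        for label, idx in tpl.sites.items():
            lines.append(f"  site {label} {idx + 1}")
        lines.append("end")
    for name, count in topology.layout:
        lines.append(f"layout {name} {count}")
    if topology.box_edge is not None:
        lines.append(f"box {topology.box_edge}")
    Path(path).write_text("\n".join(lines) + "\n")
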