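"""Molecular system containers and plain-text persistence.

A :class:`Topology` holds per-atom metadata (name, element, mass,
residue, and role labels: ligand, nucleobase with signed position and
strand, protein residue) plus hydrogen-bond donor/acceptor annotations.
A :class:`Trajectory` is a time-ordered coordinate array in nm with a
time stamp per frame in ps.

Topologies are written as PDB through MDAnalysis (coordinates converted
nm <-> Angstrom) with a sidecar TSV carrying the exact masses and role
labels that PDB columns cannot hold.  Trajectories are written as
multi-frame XYZ (Angstrom, per convention) whose comment line carries
the frame time in ps; the XYZ round-trip is handled in-package because
the time stamp is load-bearing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "write_topology",
    "read_topology",
    "write_xyz",
    "read_xyz",
]

# role kinds
LIGAND = "ligand"
BASE = "base"
RESIDUE = "residue"


@dataclass
class Atom:
    name: str
    element: str
    mass: float  # amu
    resid: int
    resname: str
    kind: str = RESIDUE  # ligand | base | residue
    base_position: int | None = None  # signed position relative to the nick
    strand: str | None = None  # intact | scissile
    backbone: bool = False


@dataclass
class Topology:
    atoms: list[Atom]
    donors: list[tuple[int, int]] = field(default_factory=list)  # (donor, hydrogen)
    acceptors: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("topology has no atoms")
        self.donors = sorted(self.donors)
        self.acceptors = sorted(self.acceptors)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def indices(self, predicate) -> tuple[int, ...]:
        return tuple(i for i, a in enumerate(self.atoms) if predicate(a))

    def ligand_indices(self) -> tuple[int, ...]:
        return self.indices(lambda a: a.kind == LIGAND)

    def base_indices(
        self, position: int, strand: str | None = None
    ) -> tuple[int, ...]:
        return self.indices(
            lambda a: a.kind == BASE
            and a.base_position == position
            and (strand is None or a.strand == strand)
        )

    def residue_groups(self) -> dict[tuple[int, str], tuple[int, ...]]:
        """Atoms grouped by (resid, resname), in topology order."""
        groups: dict[tuple[int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            groups.setdefault((a.resid, a.resname), []).append(i)
        return {k: tuple(v) for k, v in groups.items()}


@dataclass
class Trajectory:
    coords: np.ndarray  # (n_frames, n_atoms, 3) nm
    times: np.ndarray  # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.times.shape[0] != self.coords.shape[0]:
            raise ValueError("one time stamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# --- PDB topology + sidecar ---------------------------------------------

_SIDECAR_COLS = [
    "index", "name", "element", "mass", "resid", "resname",
    "kind", "base_position", "strand", "backbone", "donor_h", "acceptor",
]


def _sidecar_path(pdb_path) -> Path:
    p = Path(pdb_path)
    return p.with_suffix(p.suffix + ".labels.tsv")


def write_topology(top: Topology, path, frame: np.ndarray | None = None) -> None:
    """Write a PDB (via MDAnalysis) plus a ``<path>.labels.tsv`` sidecar."""
    import MDAnalysis as mda

    n = len(top)
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("names", [a.name[:4] for a in top.atoms])
    u.add_TopologyAttr("elements", [a.element for a in top.atoms])
    u.add_TopologyAttr("masses", [a.mass for a in top.atoms])
    u.add_TopologyAttr("resids", [a.resid for a in top.atoms])
    u.add_TopologyAttr("resnames", [a.resname[:4] for a in top.atoms])
    if frame is None:
        frame = np.zeros((n, 3))
    u.atoms.positions = np.asarray(frame) * 10.0  # nm -> Angstrom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))

    h_of = {d: h for d, h in top.donors}
    acc = set(top.acceptors)
    with open(_sidecar_path(path), "w") as fh:
        fh.write("\t".join(_SIDECAR_COLS) + "\n")
        for i, a in enumerate(top.atoms):
            fh.write(
                "\t".join(
                    str(v)
                    for v in [
                        i, a.name, a.element, repr(a.mass), a.resid, a.resname,
                        a.kind,
                        "" if a.base_position is None else a.base_position,
                        "" if a.strand is None else a.strand,
                        int(a.backbone),
                        h_of.get(i, ""),
                        int(i in acc),
                    ]
                )
                + "\n"
            )


def read_topology(path) -> Topology:
    """Read a topology written by :func:`write_topology`.

    The sidecar supplies exact masses and labels; without it the PDB
    alone is read and masses are inferred from the element.
    """
    import MDAnalysis as mda

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        atoms: list[Atom] = []
        donors: list[tuple[int, int]] = []
        acceptors: list[int] = []
        with open(sidecar) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                rec = dict(zip(header, line.rstrip("\n").split("\t")))
                i = int(rec["index"])
                atoms.append(
                    Atom(
                        name=rec["name"],
                        element=rec["element"],
                        mass=float(rec["mass"]),
                        resid=int(rec["resid"]),
                        resname=rec["resname"],
                        kind=rec["kind"],
                        base_position=(
                            int(rec["base_position"]) if rec["base_position"] else None
                        ),
                        strand=rec["strand"] or None,
                        backbone=bool(int(rec["backbone"])),
                    )
                )
                if rec["donor_h"]:
                    donors.append((i, int(rec["donor_h"])))
                if int(rec["acceptor"]):
                    acceptors.append(i)
        return Topology(atoms=atoms, donors=donors, acceptors=acceptors)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = [
        Atom(
            name=str(a.name),
            element=str(getattr(a, "element", a.name[0])),
            mass=float(a.mass),
            resid=int(a.resid),
            resname=str(a.resname),
        )
        for a in u.atoms
    ]
    return Topology(atoms=atoms)


# --- multi-frame XYZ -----------------------------------------------------


def write_xyz(top: Topology, traj: Trajectory, path) -> None:
    """Multi-frame XYZ in Angstrom; comment line ``t= <time> ps``."""
    names = top.names
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t= {traj.times[f]:.6f} ps\n")
            for name, (x, y, z) in zip(names, traj.coords[f] * 10.0):
                fh.write(f"{name} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path) -> Trajectory:
    frames: list[np.ndarray] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        t = 0.0
        toks = comment.replace("=", "= ").split()
        if "t=" in toks:
            t = float(toks[toks.index("t=") + 1])
        block = lines[i + 2 : i + 2 + n]
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block], dtype=float
        )
        frames.append(coords / 10.0)  # Angstrom -> nm
        times.append(t)
        i += 2 + n
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return Trajectory(coords=np.stack(frames), times=np.array(times))
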