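"""Synthetic test systems: analytic toy potentials and mock complexes.

The all-atom trajectories behind a protein--DNA--drug unbinding study
are far too expensive to regenerate, so every stage of this package is
exercised on synthetic stand-ins with known ground truth:

* analytic CV-space potentials for the sampling engine -- a 1-D double
  well with an exact barrier, and a 2-D "unbinding" landscape with a
  bound basin (B), one intermediate basin (I), a saddle (Ts) whose
  height above B is prescribed, and an open exit channel at large
  distance;
* mock ternary-complex trajectories (<= ~100 pseudo-atoms) with
  prescribed per-state hydrogen-bond occupancies and per-atom Gaussian
  fluctuation amplitudes, written at a fixed 0.5 ps frame stride.

Units: nm, kJ/mol, ps, amu throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator

from .system import Atom, BASE, LIGAND, RESIDUE, Topology, Trajectory

__all__ = [
    "ToyPotential",
    "make_double_well",
    "make_harmonic_well",
    "make_unbinding_landscape",
    "MockComplexSpec",
    "default_mock_spec",
    "generate_mock_trajectory",
    "spec_to_yaml",
    "spec_from_yaml",
]

FRAME_STRIDE_PS = 0.5  # trajectory saving stride


@dataclass
class ToyPotential:
    """Analytic potential on a rectangular CV-space domain.

    ``energy`` and ``gradient`` accept arrays of shape (..., ndim) and
    return shapes (...) and (..., ndim) respectively (kJ/mol and
    kJ/mol per CV unit).
    """

    name: str
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    domain: tuple[tuple[float, float], ...]
    info: dict = field(default_factory=dict)

    @property
    def ndim(self) -> int:
        return len(self.domain)


def make_double_well(barrier: float, well_separation: float) -> ToyPotential:
    """Symmetric quartic double well U = barrier * ((x/a)^2 - 1)^2, a = sep/2.

    Minima at x = -a and +a with U = 0; the midpoint barrier is exactly
    ``barrier`` kJ/mol.
    """
    if barrier <= 0 or well_separation <= 0:
        raise ValueError("barrier and well_separation must be positive")
    a = well_separation / 2.0

    def energy(pts):
        x = np.asarray(pts, dtype=float)[..., 0]
        return barrier * ((x / a) ** 2 - 1.0) ** 2

    def gradient(pts):
        x = np.asarray(pts, dtype=float)[..., 0]
        g = 4.0 * barrier * x * ((x / a) ** 2 - 1.0) / a**2
        return g[..., None]

    return ToyPotential(
        name="double_well",
        energy=energy,
        gradient=gradient,
        domain=((-2.0 * a, 2.0 * a),),
        info={"barrier": barrier, "minima": (-a, a), "saddle": 0.0},
    )


def make_harmonic_well(k: float, ndim: int = 1, half_width: float = 5.0) -> ToyPotential:
    """Isotropic harmonic well U = 0.5 k |x|^2 (equipartition reference)."""
    if k <= 0:
        raise ValueError("spring constant must be positive")

    def energy(pts):
        x = np.asarray(pts, dtype=float)
        return 0.5 * k * np.sum(x**2, axis=-1)

    def gradient(pts):
        return k * np.asarray(pts, dtype=float)

    return ToyPotential(
        name="harmonic",
        energy=energy,
        gradient=gradient,
        domain=tuple(((-half_width, half_width),) * ndim),
        info={"k": k},
    )


# --- 2-D unbinding landscape --------------------------------------------

# geometry of the 1-D spine along the distance CV (nm)
_D_WALL, _D_B, _D_TS, _D_I, _D_OUT, _D_FLAT, _D_END = 0.0, 0.25, 0.9, 1.6, 2.3, 3.0, 4.5
_D_CUT = 2.6  # valley center line is exactly 0 beyond this distance
CONTACT_MAX = 400.0


def make_unbinding_landscape(
    depths: dict[str, float],
    barrier_BTs: float,
    barrier_out: float = 12.0,
    kc: float = 0.002,
    contact_scale: float = 300.0,
) -> ToyPotential:
    """2-D unbinding landscape over (distance in [0, 4.5] nm, contacts in [0, 400]).

    A monotone-cubic (PCHIP) spine U(d) through fixed knots carries the
    basin topology -- bound minimum B at d = 0.25 (energy -depths[B]),
    saddle Ts at d = 0.9 (energy -depths[B] + barrier_BTs), intermediate
    minimum I at d = 1.6 (energy -depths[I]), exit saddle, then a flat
    plateau out to d = 4.5 below the Ts energy.  A harmonic transverse
    term 0.5*kc*(c - c*(d))^2 confines the contact CV to a valley center
    line c*(d) that decays from ``contact_scale`` at B to exactly zero
    for d >= 2.6 nm.  Because PCHIP is monotone between knots and the
    transverse term is nonnegative, the surface has exactly two local
    minima and the minimax saddle between them sits exactly at the Ts
    knot, so the B->Ts activation energy equals ``barrier_BTs`` by
    construction.
    """
    try:
        depth_b = float(depths["B"])
        depth_i = float(depths["I"])
    except KeyError as e:
        raise ValueError("depths must provide 'B' and 'I'") from e
    if depth_b <= 0 or depth_i <= 0 or barrier_BTs <= 0:
        raise ValueError("depths and barrier must be positive")
    if barrier_out <= 0:
        raise ValueError("exit barrier must be positive")
    if barrier_BTs <= depth_b - depth_i:
        raise ValueError(
            "degenerate geometry: saddle would not separate B and I "
            f"(need barrier > depth_B - depth_I = {depth_b - depth_i:g})"
        )

    e_saddle = -depth_b + barrier_BTs
    e_out = -depth_i + barrier_out
    e_flat = min(e_saddle, e_out) - 3.0
    knots_d = [_D_WALL, _D_B, _D_TS, _D_I, _D_OUT, _D_FLAT, _D_END]
    knots_e = [e_saddle + 15.0, -depth_b, e_saddle, -depth_i, e_out, e_flat, e_flat]
    spine = PchipInterpolator(knots_d, knots_e)
    dspine = spine.derivative()

    span = _D_CUT - _D_B

    def _cstar(d):
        z = np.clip((_D_CUT - d) / span, 0.0, None)
        return contact_scale * z**2

    def _dcstar(d):
        z = np.clip((_D_CUT - d) / span, 0.0, None)
        return -2.0 * contact_scale * z / span

    def energy(pts):
        pts = np.asarray(pts, dtype=float)
        d, c = pts[..., 0], pts[..., 1]
        return spine(d) + 0.5 * kc * (c - _cstar(d)) ** 2

    def gradient(pts):
        pts = np.asarray(pts, dtype=float)
        d, c = pts[..., 0], pts[..., 1]
        dc = c - _cstar(d)
        gd = dspine(d) - kc * dc * _dcstar(d)
        gc = kc * dc
        return np.stack([gd, gc], axis=-1)

    return ToyPotential(
        name="unbinding_landscape",
        energy=energy,
        gradient=gradient,
        domain=((0.0, _D_END), (0.0, CONTACT_MAX)),
        info={
            "barrier_BTs": barrier_BTs,
            "minimum_B": (_D_B, float(_cstar(_D_B))),
            "minimum_I": (_D_I, float(_cstar(_D_I))),
            "saddle_Ts": (_D_TS, float(_cstar(_D_TS))),
            "energy_B": -depth_b,
            "energy_I": -depth_i,
            "energy_Ts": e_saddle,
            "kc": kc,
        },
    )


# --- mock ternary-complex trajectories ----------------------------------


@dataclass
class MockComplexSpec:
    """Specification of a mock complex with known statistical structure.

    ``occupancy`` maps (donor atom name, acceptor atom name, state) to
    the Bernoulli probability that the H-bond exists in a frame of that
    state.  ``sigma`` maps atom name to the isotropic Gaussian jitter
    (nm) around the atom's mean position.  ``state_sequence`` gives the
    state label of each frame.
    """

    atoms: list[Atom]
    states: list[str]
    occupancy: dict[tuple[str, str, str], float]
    sigma: dict[str, float]
    state_sequence: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("mock spec has no atoms")
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValueError("atom names must be unique")
        for (d, a, s), p in self.occupancy.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"occupancy for ({d},{a},{s}) outside [0,1]: {p}")
            if s not in self.states:
                raise ValueError(f"occupancy references unknown state {s!r}")
        for name, sig in self.sigma.items():
            if sig < 0:
                raise ValueError(f"negative sigma for {name}")
        for s in self.state_sequence:
            if s not in self.states:
                raise ValueError(f"state sequence contains unknown state {s!r}")
        pairs = sorted({(d, a) for d, a, _ in self.occupancy})
        for side in (0, 1):
            seen: set[str] = set()
            for p in pairs:
                if p[side] in seen:
                    raise ValueError(
                        f"atom {p[side]!r} participates in more than one H-bond pair"
                    )
                seen.add(p[side])
        self.pairs = pairs

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.atoms]


# geometry realizing "H-bond present/absent": donor-acceptor distance
# well inside / outside any sensible cutoff, perfectly colinear D-H-A
HB_PRESENT_NM = 0.30
HB_ABSENT_NM = 0.60
HB_DH_NM = 0.10


def _layout(atoms: list[Atom]) -> np.ndarray:
    """Deterministic mean positions: residues on a 2 nm lattice,
    atoms within a residue offset by 0.15 nm steps."""
    resids = sorted({a.resid for a in atoms})
    centers = {}
    for j, r in enumerate(resids):
        centers[r] = np.array(
            [2.0 * (j % 4), 2.0 * ((j // 4) % 4), 2.0 * (j // 16)], dtype=float
        )
    offsets = [
        np.array([0.0, 0.0, 0.0]),
        np.array([0.15, 0.0, 0.0]),
        np.array([0.0, 0.15, 0.0]),
        np.array([0.0, 0.0, 0.15]),
        np.array([0.15, 0.15, 0.0]),
        np.array([0.0, 0.15, 0.15]),
        np.array([0.15, 0.0, 0.15]),
        np.array([0.15, 0.15, 0.15]),
    ]
    within: dict[int, int] = {}
    means = np.zeros((len(atoms), 3))
    for i, a in enumerate(atoms):
        k = within.get(a.resid, 0)
        within[a.resid] = k + 1
        means[i] = centers[a.resid] + offsets[k % len(offsets)]
    return means


def generate_mock_trajectory(
    spec: MockComplexSpec, n_frames: int
) -> tuple[Topology, Trajectory]:
    """Generate a seeded mock trajectory realizing the spec's statistics.

    Per frame, every specified H-bond pair is placed in colinear
    D-H...A geometry at 0.30 nm (present, Bernoulli with the state's
    occupancy) or 0.60 nm (absent); every other coordinate jitters
    isotropically around its mean with the atom's sigma.  A hydrogen is
    added after each donor.  Bitwise deterministic for a fixed seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_frames > len(spec.state_sequence):
        raise ValueError(
            f"state sequence has {len(spec.state_sequence)} frames, "
            f"{n_frames} requested"
        )

    atoms = [Atom(**vars(a)) for a in spec.atoms]
    name_to_idx = {a.name: i for i, a in enumerate(atoms)}
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    h_index: dict[str, int] = {}
    for d_name, a_name in spec.pairs:
        if d_name not in name_to_idx:
            raise ValueError(f"unknown donor atom {d_name!r}")
        if a_name not in name_to_idx:
            raise ValueError(f"unknown acceptor atom {a_name!r}")
        d = atoms[name_to_idx[d_name]]
        atoms.append(
            Atom(
                name="H" + d_name,
                element="H",
                mass=1.008,
                resid=d.resid,
                resname=d.resname,
                kind=d.kind,
                base_position=d.base_position,
                strand=d.strand,
            )
        )
        h_index[d_name] = len(atoms) - 1
        donors.append((name_to_idx[d_name], h_index[d_name]))
        acceptors.append(name_to_idx[a_name])
    top = Topology(atoms=atoms, donors=donors, acceptors=acceptors)

    means = np.zeros((len(atoms), 3))
    means[: len(spec.atoms)] = _layout(spec.atoms)
    sigmas = np.array(
        [spec.sigma.get(a.name, spec.sigma.get(a.name.lstrip("H"), 0.02))
         for a in atoms],
        dtype=float,
    )

    # fixed unit direction per pair, from donor mean toward acceptor mean
    pair_dirs = {}
    for d_name, a_name in spec.pairs:
        v = means[name_to_idx[a_name]] - means[name_to_idx[d_name]]
        nrm = np.linalg.norm(v)
        pair_dirs[(d_name, a_name)] = v / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])

    rng = np.random.default_rng(spec.seed)
    coords = np.empty((n_frames, len(atoms), 3))
    for f in range(n_frames):
        state = spec.state_sequence[f]
        frame = means + rng.normal(0.0, 1.0, means.shape) * sigmas[:, None]
        for d_name, a_name in spec.pairs:
            p = spec.occupancy.get((d_name, a_name, state), 0.0)
            present = rng.random() < p
            di = name_to_idx[d_name]
            u = pair_dirs[(d_name, a_name)]
            da = HB_PRESENT_NM if present else HB_ABSENT_NM
            frame[name_to_idx[a_name]] = frame[di] + da * u
            frame[h_index[d_name]] = frame[di] + HB_DH_NM * u
        coords[f] = frame
    times = np.arange(n_frames) * FRAME_STRIDE_PS
    return top, Trajectory(coords=coords, times=times)


def default_mock_spec(
    seed: int = 0,
    occupancy_b: float = 0.49,
    state_counts: dict[str, int] | None = None,
) -> MockComplexSpec:
    """The standard mock ternary complex used in tests and the pipeline.

    ~40 pseudo-atoms: a 4-atom ligand, nucleobases at positions -2, -1,
    +1, +2 on both strands, and three protein-like residues.  The
    hallmark pair LYSN -> ligand carbonyl carries occupancy
    ``occupancy_b`` in the bound state and 0 elsewhere; two further
    pairs have high occupancies across states.  The default state
    sequence holds 7512 B, 22 Ts and 631 I frames (0.5 ps apart).
    """
    atoms: list[Atom] = []
    rid = 0
    for nm, el in [("LIG1", "C"), ("LIG2", "C"), ("LIG3", "N"), ("LIGO", "O")]:
        atoms.append(Atom(nm, el, 12.011 if el == "C" else (14.007 if el == "N" else 15.999),
                          rid, "LIG", kind=LIGAND))
    masses = {"C": 12.011, "N": 14.007, "O": 15.999}
    for pos in (-2, -1, 1, 2):
        for strand in ("intact", "scissile"):
            rid += 1
            tag = f"{'I' if strand == 'intact' else 'S'}{pos:+d}".replace("+", "p").replace("-", "m")
            for j, el in enumerate(["C", "N", "O"]):
                atoms.append(
                    Atom(f"B{tag}{j}", el, masses[el], rid, "DB",
                         kind=BASE, base_position=pos, strand=strand,
                         backbone=(j == 2))
                )
    for resname, donor_el in [("LYS", "N"), ("ASN", "N"), ("THR", "O")]:
        rid += 1
        atoms.append(Atom(f"{resname}D", donor_el, masses[donor_el], rid, resname,
                          kind=RESIDUE))
        atoms.append(Atom(f"{resname}C1", "C", masses["C"], rid, resname, kind=RESIDUE))
        atoms.append(Atom(f"{resname}C2", "C", masses["C"], rid, resname, kind=RESIDUE))

    states = ["B", "Ts", "I"]
    occupancy = {
        # hallmark bound-state-only contact (0.49 in B, absent elsewhere)
        ("LYSD", "LIGO", "B"): occupancy_b,
        ("LYSD", "LIGO", "Ts"): 0.0,
        ("LYSD", "LIGO", "I"): 0.0,
        # stable protein-DNA contacts persisting across states
        ("ASND", "BSm11", "B"): 0.86,
        ("ASND", "BSm11", "Ts"): 0.91,
        ("ASND", "BSm11", "I"): 0.85,
        ("THRD", "BSp21", "B"): 0.99,
        ("THRD", "BSp21", "Ts"): 0.0,
        ("THRD", "BSp21", "I"): 0.99,
    }
    sigma = {a.name: 0.02 for a in atoms}
    for a in atoms:
        if a.kind == BASE and a.base_position in (1, -1):
            sigma[a.name] = 0.05  # nick-flanking bases fluctuate more
    if state_counts is None:
        state_counts = {"B": 7512, "Ts": 22, "I": 631}
    sequence = [s for s in states for _ in range(int(state_counts.get(s, 0)))]
    return MockComplexSpec(
        atoms=atoms,
        states=states,
        occupancy=occupancy,
        sigma=sigma,
        state_sequence=sequence,
        seed=seed,
    )


# --- MockComplexSpec persistence ----------------------------------------


def spec_to_yaml(spec: MockComplexSpec, path) -> None:
    """Write a mock-complex specification as a YAML configuration."""
    import yaml

    doc = {
        "seed": spec.seed,
        "states": list(spec.states),
        "atoms": [
            {k: v for k, v in vars(a).items()
             if v is not None and v is not False}
            for a in spec.atoms
        ],
        "occupancy": [
            {"donor": d, "acceptor": a, "state": s, "p": float(p)}
            for (d, a, s), p in sorted(spec.occupancy.items())
        ],
        "sigma": {k: float(v) for k, v in sorted(spec.sigma.items())},
        "state_sequence": "".join(
            f"{lab}:{len(list(grp))};"
            for lab, grp in __import__("itertools").groupby(spec.state_sequence)
        ),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path) -> MockComplexSpec:
    """Read back a specification written by :func:`spec_to_yaml`."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    atoms = [Atom(**rec) for rec in doc["atoms"]]
    occupancy = {
        (r["donor"], r["acceptor"], r["state"]): float(r["p"])
        for r in doc["occupancy"]
    }
    sequence: list[str] = []
    for run in filter(None, doc["state_sequence"].split(";")):
        lab, n = run.rsplit(":", 1)
        sequence.extend([lab] * int(n))
    return MockComplexSpec(
        atoms=atoms,
        states=list(doc["states"]),
        occupancy=occupancy,
        sigma={k: float(v) for k, v in doc["sigma"].items()},
        state_sequence=sequence,
        seed=int(doc["seed"]),
    )
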