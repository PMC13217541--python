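"""Readers and writers for the plain-text formats the toolkit consumes.

Four formats are supported: a column-strict PDB subset (ATOM/HETATM/MODEL/
ENDMDL/TER/CONECT/SSBOND) whose multi-model variant doubles as the trajectory
format, a TRIPOS MOL2 subset for ligands and docking poses, FASTA sequence
files, and a flat whitespace-delimited per-atom parameter file carrying
charges, Lennard-Jones parameters, intrinsic generalized-Born radii and
descreening scales, with optional bonded-term blocks.

Coordinates are Ångström throughout; energies elsewhere in the package are
kcal/mol with a report-time conversion to kJ/mol.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "Atom",
    "MolecularSystem",
    "Trajectory",
    "BondedTerms",
    "ParameterSet",
    "ParseError",
    "EmptyInputError",
    "ConsistencyError",
    "read_pdb",
    "write_pdb",
    "read_mol2",
    "write_mol2",
    "read_parameters",
    "write_parameters",
    "read_fasta",
    "write_fasta",
]

KCAL_TO_KJ = 4.184

#: Fallback intrinsic GB radii (Å) and descreening scales per element, used
#: when a parameter file omits them (e.g. the provisional MOL2 parameter set).
DEFAULT_GB_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.5, "S": 1.8}
DEFAULT_GB_SCALES = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "S": 0.96}
FALLBACK_GB_RADIUS = 1.5
FALLBACK_GB_SCALE = 0.80


class ParseError(ValueError):
    """Malformed input text; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyInputError(ValueError):
    """Input contained no usable records."""


class ConsistencyError(ValueError):
    """Companion files disagree (e.g. parameter count vs atom count)."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    resname: str
    chain: str
    resid: int
    coords: np.ndarray  # (3,) Å
    record_kind: str = "standard-residue"  # or "hetero"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")


@dataclass
class MolecularSystem:
    """An ordered set of atoms with a receptor/ligand partition.

    ``receptor_selection`` and ``ligand_selection`` are disjoint index arrays
    into ``atoms``; both must be non-empty before the system is used for
    binding free energy evaluation.
    """

    atoms: list[Atom]
    receptor_selection: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    ligand_selection: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.receptor_selection = np.asarray(self.receptor_selection, dtype=int)
        self.ligand_selection = np.asarray(self.ligand_selection, dtype=int)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a system")
        if np.intersect1d(self.receptor_selection, self.ligand_selection).size:
            raise ValueError("receptor and ligand selections must be disjoint")
        n = len(self.atoms)
        for sel in (self.receptor_selection, self.ligand_selection):
            if sel.size and (sel.min() < 0 or sel.max() >= n):
                raise ValueError("selection index out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, frame: np.ndarray) -> "MolecularSystem":
        """Copy of the system with coordinates replaced by ``frame``."""
        frame = np.asarray(frame, dtype=float)
        if frame.shape != (self.n_atoms, 3):
            raise ValueError("frame shape does not match atom count")
        atoms = [
            Atom(a.serial, a.name, a.element, a.resname, a.chain, a.resid,
                 frame[i], a.record_kind)
            for i, a in enumerate(self.atoms)
        ]
        return MolecularSystem(atoms, self.receptor_selection.copy(),
                               self.ligand_selection.copy(), dict(self.metadata))


@dataclass
class Trajectory:
    """Ordered coordinate frames (n_frames × n_atoms × 3, Å) for one replica."""

    frames: np.ndarray
    spacing_ps: float
    replica_id: int = 0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.spacing_ps <= 0:
            raise ValueError("spacing_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def check_compatible(self, system: MolecularSystem) -> None:
        if self.n_atoms != system.n_atoms:
            raise ConsistencyError(
                f"trajectory has {self.n_atoms} atoms but system has {system.n_atoms}")


@dataclass
class BondedTerms:
    bonds: list = field(default_factory=list)      # (i, j, k_b, r0)
    angles: list = field(default_factory=list)     # (i, j, k, k_theta, theta0_deg)
    dihedrals: list = field(default_factory=list)  # (i, j, k, l, k_phi, n, phi0_deg)


@dataclass
class ParameterSet:
    """Per-atom force-field parameters aligned with a companion system.

    charge: elementary charges; lj_sigma: Å; lj_epsilon: kcal/mol;
    gb_radius: intrinsic GB radius ρ_i, Å; gb_scale: descreening scale S_i.
    """

    charge: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    gb_radius: np.ndarray
    gb_scale: np.ndarray
    bonded: BondedTerms | None = None

    def __post_init__(self):
        for name in ("charge", "lj_sigma", "lj_epsilon", "gb_radius", "gb_scale"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.charge.size
        for name in ("lj_sigma", "lj_epsilon", "gb_radius", "gb_scale"):
            if getattr(self, name).size != n:
                raise ConsistencyError("parameter vectors must have equal length")
        if np.any(self.lj_sigma <= 0):
            raise ValueError("lj_sigma must be positive")
        if np.any(self.lj_epsilon < 0):
            raise ValueError("lj_epsilon must be non-negative")
        if np.any(self.gb_radius <= 0):
            raise ValueError("gb_radius must be positive")
        if np.any((self.gb_scale <= 0) | (self.gb_scale > 1)):
            raise ValueError("gb_scale must lie in (0, 1]")

    @property
    def n_atoms(self) -> int:
        return self.charge.size

    def check_compatible(self, system: MolecularSystem) -> None:
        if self.n_atoms != system.n_atoms:
            raise ConsistencyError(
                f"parameter set has {self.n_atoms} entries but system has "
                f"{system.n_atoms} atoms")

    def subset(self, indices: np.ndarray) -> "ParameterSet":
        idx = np.asarray(indices, dtype=int)
        return ParameterSet(self.charge[idx], self.lj_sigma[idx],
                            self.lj_epsilon[idx], self.gb_radius[idx],
                            self.gb_scale[idx])


def default_gb_params(elements: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Element-table intrinsic radii and descreening scales."""
    radii = np.array([DEFAULT_GB_RADII.get(e.upper(), FALLBACK_GB_RADIUS)
                      for e in elements])
    scales = np.array([DEFAULT_GB_SCALES.get(e.upper(), FALLBACK_GB_SCALE)
                       for e in elements])
    return radii, scales


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _infer_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_pdb_atom(line: str, lineno: int) -> tuple[Atom, str, bool]:
    """Parse one ATOM/HETATM line. Returns (atom, altloc, element_inferred)."""
    if len(line) < 54:
        raise ParseError("ATOM/HETATM record shorter than coordinate columns", lineno)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(f"malformed fixed-width field ({exc})", lineno) from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    inferred = False
    if not element:
        element = _infer_element(name)
        inferred = True
        if not element:
            raise ParseError("cannot infer element from atom name", lineno)
    kind = "hetero" if line.startswith("HETATM") else "standard-residue"
    atom = Atom(serial, name, element, resname, chain, resid,
                np.array([x, y, z]), kind)
    return atom, altloc, inferred


def read_pdb(text: str) -> tuple[MolecularSystem, Trajectory | None]:
    """Parse a (possibly multi-model) PDB subset.

    Each MODEL block becomes one trajectory frame; a single-model or
    model-free file returns ``(system, None)``. Alternate locations: blank or
    'A' kept, others dropped with a note. CONECT and SSBOND records are
    retained in ``system.metadata``.
    """
    atoms: list[Atom] = []
    notes: list[str] = []
    conect: list[list[int]] = []
    ssbond: list[tuple[tuple[str, int], tuple[str, int]]] = []
    model_frames: list[list[np.ndarray]] = []
    current_model: list[np.ndarray] | None = None
    n_models = 0
    first_model_atoms = True

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            atom, altloc, inferred = _parse_pdb_atom(line, lineno)
            if altloc not in ("", "A"):
                notes.append(f"dropped altloc '{altloc}' atom serial {atom.serial}")
                continue
            if inferred:
                notes.append(
                    f"element inferred from atom name for serial {atom.serial}")
            if current_model is None or first_model_atoms:
                atoms.append(atom)
            if current_model is not None:
                current_model.append(atom.coords)
        elif rec == "MODEL ":
            n_models += 1
            current_model = []
            first_model_atoms = n_models == 1
        elif rec == "ENDMDL":
            if current_model is not None:
                model_frames.append(current_model)
            current_model = None
            first_model_atoms = False
        elif rec == "CONECT":
            try:
                serials = [int(line[k:k + 5]) for k in range(6, min(len(line), 31), 5)
                           if line[k:k + 5].strip()]
            except ValueError:
                raise ParseError("malformed CONECT record", lineno) from None
            if serials:
                conect.append(serials)
        elif rec == "SSBOND":
            try:
                pair = (
                    (line[15].strip() or " ", int(line[17:21])),
                    (line[29].strip() or " ", int(line[31:35])),
                )
            except (ValueError, IndexError):
                raise ParseError("malformed SSBOND record", lineno) from None
            ssbond.append(pair)

    if current_model is not None and current_model:
        model_frames.append(current_model)
    if not atoms:
        raise EmptyInputError("PDB text contains no ATOM/HETATM records")

    metadata: dict = {}
    if notes:
        metadata["notes"] = notes
    if conect:
        metadata["conect"] = conect
    if ssbond:
        metadata["ssbond"] = ssbond
    system = MolecularSystem(atoms, metadata=metadata)

    trajectory = None
    if len(model_frames) > 1:
        n = system.n_atoms
        for i, fr in enumerate(model_frames):
            if len(fr) != n:
                raise ConsistencyError(
                    f"model {i + 1} has {len(fr)} atoms, expected {n}")
        trajectory = Trajectory(np.array(model_frames), spacing_ps=1.0)
    return system, trajectory


def write_pdb(system: MolecularSystem, trajectory: Trajectory | None = None) -> str:
    """Serialize a system (optionally with a multi-model trajectory)."""
    out = io.StringIO()
    for (c1, r1), (c2, r2) in system.metadata.get("ssbond", []):
        out.write(
            f"SSBOND   1 CYS {c1}{r1:5d}    CYS {c2}{r2:5d}"
            f"{'':>23}1555   1555  2.04\n")

    def write_atoms(coords):
        for i, a in enumerate(system.atoms):
            rec = "HETATM" if a.record_kind == "hetero" else "ATOM  "
            name = a.name if len(a.name) >= 4 else f" {a.name:<3}"
            x, y, z = coords[i]
            out.write(
                f"{rec}{a.serial:5d} {name:<4.4}{'':1}{a.resname:<3} "
                f"{a.chain:1}{a.resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2}\n")

    if trajectory is not None and trajectory.n_frames > 1:
        trajectory.check_compatible(system)
        for m in range(trajectory.n_frames):
            out.write(f"MODEL     {m + 1:4d}\n")
            write_atoms(trajectory.frames[m])
            out.write("ENDMDL\n")
    else:
        coords = (trajectory.frames[0] if trajectory is not None
                  else system.coords)
        write_atoms(coords)
    for serials in system.metadata.get("conect", []):
        out.write("CONECT" + "".join(f"{s:5d}" for s in serials) + "\n")
    out.write("END\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# TRIPOS MOL2
# ---------------------------------------------------------------------------

def read_mol2(text: str) -> tuple[MolecularSystem, ParameterSet]:
    """Parse a TRIPOS MOL2 subset (MOLECULE/ATOM/BOND sections).

    SYBYL atom types and bonds are kept in ``system.metadata``; the
    partial-charge column populates a provisional :class:`ParameterSet` with
    element-table LJ/GB defaults.
    """
    section = None
    mol_name = "LIG"
    atoms: list[Atom] = []
    sybyl: list[str] = []
    charges: list[float] = []
    bonds: list[tuple[int, int, str]] = []
    saw_atom_section = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            if section == "ATOM":
                saw_atom_section = True
            continue
        if not line or line.startswith("#") or section is None:
            continue
        if section == "MOLECULE":
            if mol_name == "LIG":
                mol_name = line.split()[0][:3].upper() or "LIG"
        elif section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise ParseError("ATOM record needs at least 6 fields", lineno)
            try:
                serial = int(parts[0])
                xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
            except ValueError:
                raise ParseError("non-numeric atom id or coordinate", lineno) from None
            atype = parts[5]
            charge = 0.0
            if len(parts) >= 9:
                try:
                    charge = float(parts[8])
                except ValueError:
                    raise ParseError("non-numeric partial charge", lineno) from None
            element = atype.split(".")[0]
            if not element[:1].isalpha():
                raise ParseError(f"cannot derive element from type '{atype}'", lineno)
            atoms.append(Atom(serial, parts[1], element, mol_name, "L",
                              1, xyz, "hetero"))
            sybyl.append(atype)
            charges.append(charge)
        elif section == "BOND":
            parts = line.split()
            if len(parts) < 4:
                raise ParseError("BOND record needs 4 fields", lineno)
            try:
                bonds.append((int(parts[1]), int(parts[2]), parts[3]))
            except ValueError:
                raise ParseError("non-numeric bond atom id", lineno) from None

    if not saw_atom_section:
        raise ParseError("missing @<TRIPOS>ATOM section")
    if not atoms:
        raise EmptyInputError("MOL2 text contains no atoms")

    system = MolecularSystem(
        atoms, metadata={"sybyl_types": sybyl, "bonds": bonds})
    radii, scales = default_gb_params([a.element for a in atoms])
    params = ParameterSet(
        charge=np.array(charges),
        lj_sigma=np.full(len(atoms), 3.4),
        lj_epsilon=np.full(len(atoms), 0.1),
        gb_radius=radii,
        gb_scale=scales,
    )
    return system, params


def write_mol2(system: MolecularSystem, charges: np.ndarray | None = None,
               name: str = "LIG") -> str:
    sybyl = system.metadata.get(
        "sybyl_types", [f"{a.element}.3" for a in system.atoms])
    bonds = system.metadata.get("bonds", [])
    if charges is None:
        charges = np.zeros(system.n_atoms)
    out = io.StringIO()
    out.write("@<TRIPOS>MOLECULE\n")
    out.write(f"{name}\n{system.n_atoms} {len(bonds)} 0 0 0\nSMALL\nUSER_CHARGES\n")
    out.write("@<TRIPOS>ATOM\n")
    for i, a in enumerate(system.atoms):
        x, y, z = a.coords
        out.write(f"{a.serial:>7d} {a.name:<8} {x:10.4f} {y:10.4f} {z:10.4f} "
                  f"{sybyl[i]:<8} 1 {name:<8} {charges[i]:10.6f}\n")
    out.write("@<TRIPOS>BOND\n")
    for k, (i, j, order) in enumerate(bonds, start=1):
        out.write(f"{k:>6d} {i:>5d} {j:>5d} {order:>4}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Flat parameter file
# ---------------------------------------------------------------------------

def read_parameters(text: str, n_atoms: int | None = None) -> ParameterSet:
    """Read the flat per-atom parameter format.

    One record per atom: ``serial charge sigma epsilon gb_radius gb_scale``,
    followed by optional ``BOND i j k_b r0``, ``ANGLE i j k k_theta theta0``
    and ``DIHEDRAL i j k l k_phi n phi0`` lines (angles in degrees, indices
    0-based).
    """
    rows: list[tuple] = []
    bonded = BondedTerms()
    have_bonded = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        tag = parts[0].upper()
        try:
            if tag == "BOND":
                bonded.bonds.append((int(parts[1]), int(parts[2]),
                                     float(parts[3]), float(parts[4])))
                have_bonded = True
            elif tag == "ANGLE":
                bonded.angles.append((int(parts[1]), int(parts[2]), int(parts[3]),
                                      float(parts[4]), float(parts[5])))
                have_bonded = True
            elif tag == "DIHEDRAL":
                bonded.dihedrals.append(
                    (int(parts[1]), int(parts[2]), int(parts[3]), int(parts[4]),
                     float(parts[5]), int(parts[6]), float(parts[7])))
                have_bonded = True
            else:
                if len(parts) != 6:
                    raise ParseError("atom record needs 6 fields", lineno)
                rows.append((int(parts[0]), float(parts[1]), float(parts[2]),
                             float(parts[3]), float(parts[4]), float(parts[5])))
        except (ValueError, IndexError):
            raise ParseError("malformed parameter record", lineno) from None
    if not rows:
        raise EmptyInputError("parameter text contains no atom records")
    rows.sort(key=lambda r: r[0])
    arr = np.array([r[1:] for r in rows])
    params = ParameterSet(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4],
                          bonded if have_bonded else None)
    if n_atoms is not None and params.n_atoms != n_atoms:
        raise ConsistencyError(
            f"parameter file has {params.n_atoms} atoms, system has {n_atoms}")
    return params


def write_parameters(params: ParameterSet) -> str:
    out = io.StringIO()
    out.write("# serial charge sigma epsilon gb_radius gb_scale\n")
    for i in range(params.n_atoms):
        out.write(f"{i + 1} {params.charge[i]:.6g} {params.lj_sigma[i]:.6g} "
                  f"{params.lj_epsilon[i]:.6g} {params.gb_radius[i]:.6g} "
                  f"{params.gb_scale[i]:.6g}\n")
    if params.bonded is not None:
        for i, j, kb, r0 in params.bonded.bonds:
            out.write(f"BOND {i} {j} {kb:.6g} {r0:.6g}\n")
        for i, j, k, kt, t0 in params.bonded.angles:
            out.write(f"ANGLE {i} {j} {k} {kt:.6g} {t0:.6g}\n")
        for i, j, k, l, kp, n, p0 in params.bonded.dihedrals:
            out.write(f"DIHEDRAL {i} {j} {k} {l} {kp:.6g} {n} {p0:.6g}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def assign_selections(system: MolecularSystem,
                      ligand_resname: str | None = None,
                      water_names: tuple[str, ...] = ("HOH", "WAT", "SOL"),
                      in_place: bool = True) -> MolecularSystem:
    """Set receptor/ligand selections from record kinds.

    Receptor: standard-residue records.  Ligand: hetero atoms with the given
    residue name, or — when none is given — every polyatomic non-water
    hetero group.  Monatomic hetero species (ions) join neither selection.
    """
    receptor = [i for i, a in enumerate(system.atoms)
                if a.record_kind == "standard-residue"]
    groups: dict[tuple, list[int]] = {}
    for i, a in enumerate(system.atoms):
        if a.record_kind == "hetero" and a.resname not in water_names:
            groups.setdefault((a.chain, a.resid, a.resname), []).append(i)
    ligand: list[int] = []
    for (chain, resid, resname), idx in groups.items():
        if ligand_resname is not None:
            if resname == ligand_resname:
                ligand.extend(idx)
        elif len(idx) > 1:
            ligand.extend(idx)
    target = system if in_place else MolecularSystem(
        system.atoms, metadata=dict(system.metadata))
    target.receptor_selection = np.asarray(sorted(receptor), dtype=int)
    target.ligand_selection = np.asarray(sorted(ligand), dtype=int)
    return target


def read_fasta(text: str) -> dict[str, str]:
    """FASTA records keyed by the first header token (chain id).

    Sequences are uppercased; unknown residues stay ``X``.
    """
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise EmptyInputError("FASTA text contains no records")
    out: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"empty FASTA record '{rec.id}'")
        out[rec.id] = seq
    return out


def write_fasta(sequences: dict[str, str]) -> str:
    return "".join(f">{cid}\n{seq}\n" for cid, seq in sequences.items())
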