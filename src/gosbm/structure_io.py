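"""Structure input/output and synthetic test structures.

Coordinates are stored internally in nanometers (GROMACS convention); the
PDB reader converts from Angstrom exactly once at parse time.  Chain breaks
are recorded where a TER record appears or the chain identifier changes; a
further numbering-gap heuristic is applied at bond-graph construction time
(see :mod:`gosbm.topology_builder`).

The fixture generators produce small deterministic structures used
throughout the test suite, plus ``synthetic_ci2``: a *synthetic* 64-residue
alpha/beta fold of CI2-like size and architecture (one N-terminal strand, a
helix packed against a four-stranded sheet, a long active-site-like loop)
used for desk-scale folding experiments.  It is a constructed stand-in, not
experimental coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .templates import TemplateSet

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "write_gro",
    "read_gro",
    "adjust_names",
    "make_fixture",
    "FIXTURE_KINDS",
    "DEFAULT_ALIASES",
]

logger = logging.getLogger("gosbm.structure_io")

ANGSTROM_TO_NM = 0.1
NM_TO_ANGSTROM = 10.0


class StructureError(ValueError):
    """Malformed or inconsistent structural input."""


@dataclass
class Atom:
    """One atom of a parsed structure; position in nm."""

    serial: int
    name: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    icode: str = ""

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.icode)


@dataclass(frozen=True)
class Residue:
    """A view of one residue: contiguous atoms sharing a residue identity."""

    chain_index: int
    chain_id: str
    residue_seq: int
    icode: str
    residue_name: str
    atom_indices: tuple[int, ...]


@dataclass
class Structure:
    """An ordered atomic model with chain-break bookkeeping.

    ``chain_breaks`` holds atom indices (> 0, strictly increasing) at which a
    new physical chain starts.  ``extra_bonds`` holds user-supplied covalent
    bonds as atom-index pairs, used for irregular chains.
    """

    atoms: list[Atom] = field(default_factory=list)
    chain_breaks: list[int] = field(default_factory=list)
    extra_bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic views -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """All positions as an (n_atoms, 3) array in nm."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise StructureError(
                f"coordinate array shape {xyz.shape} does not match "
                f"{self.n_atoms} atoms"
            )
        for a, row in zip(self.atoms, xyz):
            a.position = row.copy()

    def chain_of_atom(self) -> np.ndarray:
        """Physical chain index for every atom."""
        out = np.zeros(self.n_atoms, dtype=int)
        c = 0
        breaks = set(self.chain_breaks)
        for i in range(self.n_atoms):
            if i in breaks:
                c += 1
            out[i] = c
        return out

    def residues(self) -> list[Residue]:
        """Group consecutive atoms into residues (icode-aware)."""
        out: list[Residue] = []
        chain_idx = self.chain_of_atom()
        cur_key: Optional[tuple] = None
        cur: list[int] = []
        for i, a in enumerate(self.atoms):
            key = (chain_idx[i],) + a.residue_key()
            if key != cur_key:
                if cur:
                    a0 = self.atoms[cur[0]]
                    out.append(
                        Residue(
                            chain_index=int(chain_idx[cur[0]]),
                            chain_id=a0.chain_id,
                            residue_seq=a0.residue_seq,
                            icode=a0.icode,
                            residue_name=a0.residue_name,
                            atom_indices=tuple(cur),
                        )
                    )
                cur_key, cur = key, []
            cur.append(i)
        if cur:
            a0 = self.atoms[cur[0]]
            out.append(
                Residue(
                    chain_index=int(chain_idx[cur[0]]),
                    chain_id=a0.chain_id,
                    residue_seq=a0.residue_seq,
                    icode=a0.icode,
                    residue_name=a0.residue_name,
                    atom_indices=tuple(cur),
                )
            )
        return out

    def residue_index_of_atom(self) -> np.ndarray:
        out = np.zeros(self.n_atoms, dtype=int)
        for ri, res in enumerate(self.residues()):
            for ai in res.atom_indices:
                out[ai] = ri
        return out

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            if not np.all(np.isfinite(a.position)):
                raise StructureError(
                    f"non-finite position for atom {a.name} "
                    f"{a.chain_id}/{a.residue_seq}"
                )
            key = (a.chain_id, a.residue_seq, a.icode, a.name)
            if key in seen:
                raise StructureError(f"duplicate atom {key}")
            seen.add(key)
        last = 0
        for b in self.chain_breaks:
            if not (0 < b <= self.n_atoms and b > last):
                raise StructureError(
                    f"chain_breaks must be strictly increasing indices in "
                    f"(0, n_atoms]; got {self.chain_breaks}"
                )
            last = b
        for i, j in self.extra_bonds:
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise StructureError(f"extra bond ({i}, {j}) references missing atom")

    def copy(self) -> "Structure":
        return Structure(
            atoms=[replace(a, position=a.position.copy()) for a in self.atoms],
            chain_breaks=list(self.chain_breaks),
            extra_bonds=list(self.extra_bonds),
        )


# ---------------------------------------------------------------------------
# PDB reading / writing (fixed-column v3.3 ATOM/HETATM/TER/MODEL/END)
# ---------------------------------------------------------------------------


def _parse_float(line: str, lo: int, hi: int, what: str, lineno: int) -> float:
    text = line[lo:hi].strip()
    try:
        return float(text)
    except ValueError as exc:
        raise StructureError(
            f"line {lineno}: malformed {what} field {text!r}"
        ) from exc


def read_pdb(path: Union[str, Path]) -> Structure:
    """Read fixed-column PDB ATOM/HETATM records into a :class:`Structure`.

    Coordinates are converted A -> nm.  TER records and chain-id changes
    both start a new chain.  Alternate locations other than blank/'A' are
    dropped with a warning; models after the first are ignored with a
    warning.
    """
    path = Path(path)
    atoms: list[Atom] = []
    chain_breaks: list[int] = []
    pending_break = False
    last_chain: Optional[str] = None
    model_seen = 0
    dropped_altloc = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                model_seen += 1
                if model_seen > 1:
                    logger.warning(
                        "%s: multiple MODEL records; keeping model 1 only", path
                    )
                    break
            elif rec == "TER   " or line.strip() == "TER":
                pending_break = True
            elif rec in ("ATOM  ", "HETATM"):
                altloc = line[16]
                if altloc not in (" ", "A"):
                    dropped_altloc += 1
                    continue
                serial_text = line[6:11].strip()
                serial = int(serial_text) if serial_text else len(atoms) + 1
                name = line[12:16].strip()
                resname = line[17:20].strip() or line[17:21].strip()
                chain = line[21].strip() or "A"
                resseq = int(line[22:26].strip() or "0")
                icode = line[26].strip()
                x = _parse_float(line, 30, 38, "x coordinate", lineno)
                y = _parse_float(line, 38, 46, "y coordinate", lineno)
                z = _parse_float(line, 46, 54, "z coordinate", lineno)
                if last_chain is not None and chain != last_chain:
                    pending_break = True
                if pending_break and atoms:
                    if not chain_breaks or chain_breaks[-1] != len(atoms):
                        chain_breaks.append(len(atoms))
                pending_break = False
                last_chain = chain
                atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        residue_name=resname,
                        residue_seq=resseq,
                        chain_id=chain,
                        icode=icode,
                        position=np.array([x, y, z]) * ANGSTROM_TO_NM,
                    )
                )
            elif rec.startswith("END"):
                break
    if dropped_altloc:
        logger.warning(
            "%s: dropped %d alternate-location atoms (kept blank/'A')",
            path, dropped_altloc,
        )
    return Structure(atoms=atoms, chain_breaks=chain_breaks)


def write_pdb(structure: Structure, path: Union[str, Path]) -> None:
    """Minimal fixed-column PDB writer (fixture/round-trip support)."""
    path = Path(path)
    breaks = set(structure.chain_breaks)
    with open(path, "w") as fh:
        for i, a in enumerate(structure.atoms):
            if i in breaks:
                fh.write("TER\n")
            pos = a.position * NM_TO_ANGSTROM
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {(a.serial % 100000):5d} {name:<4s} {a.residue_name:<3s} "
                f"{a.chain_id[:1]}{a.residue_seq:4d}{a.icode or ' '}   "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00\n"
            )
        fh.write("TER\nEND\n")


# ---------------------------------------------------------------------------
# GRO writing / reading
# ---------------------------------------------------------------------------


def write_gro(
    structure: Structure,
    path: Union[str, Path],
    *,
    title: str = "generated by gosbm",
    box_padding: float = 1.0,
) -> None:
    """Write a fixed-format GRO coordinate file (positions in nm, 3 decimals).

    The box line is the axis-aligned bounding box plus ``box_padding`` nm on
    each side.  Serial numbers wrap modulo 100000 per the GRO convention.
    """
    if structure.n_atoms == 0:
        raise StructureError("refusing to write a GRO file for an empty structure")
    xyz = structure.coords()
    box = xyz.max(axis=0) - xyz.min(axis=0) + 2.0 * box_padding
    with open(path, "w") as fh:
        fh.write(f"{title}\n{structure.n_atoms:d}\n")
        for i, a in enumerate(structure.atoms):
            fh.write(
                f"{(a.residue_seq % 100000):5d}{a.residue_name[:5]:<5s}"
                f"{a.name[:5]:>5s}{((i + 1) % 100000):5d}"
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}\n"
            )
        fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


def read_gro(path: Union[str, Path]) -> Structure:
    """Read a GRO file written by :func:`write_gro` (or compatible)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise StructureError(f"{path}: truncated GRO file")
    n = int(lines[1].strip())
    atoms: list[Atom] = []
    for i in range(n):
        line = lines[2 + i]
        resseq = int(line[0:5])
        resname = line[5:10].strip()
        name = line[10:15].strip()
        serial = int(line[15:20])
        x, y, z = float(line[20:28]), float(line[28:36]), float(line[36:44])
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                residue_name=resname,
                residue_seq=resseq,
                chain_id="A",
                position=np.array([x, y, z]),
            )
        )
    return Structure(atoms=atoms)


# ---------------------------------------------------------------------------
# Name normalization against a template set
# ---------------------------------------------------------------------------

#: Common PDB naming variants -> template vocabulary.
DEFAULT_ALIASES: dict[str, str] = {
    # atom aliases
    "OT1": "O",
    "OT2": "OXT",
    "O1": "O",
    "O2": "OXT",
    "OCT1": "O",
    "OCT2": "OXT",
    "CD": "CD1",  # ILE delta carbon variant (applied only if CD undeclared)
}

#: Residue-name aliases (protonation variants, selenomethionine, ...).
DEFAULT_RESIDUE_ALIASES: dict[str, str] = {
    "HSD": "HIS",
    "HSE": "HIS",
    "HSP": "HIS",
    "HID": "HIS",
    "HIE": "HIS",
    "HIP": "HIS",
    "MSE": "MET",
    "CYX": "CYS",
}


def _is_hydrogen(name: str) -> bool:
    stripped = name.lstrip("0123456789")
    return stripped.startswith("H")


def adjust_names(
    structure: Structure,
    template_set: TemplateSet,
    *,
    atom_aliases: Optional[dict[str, str]] = None,
    residue_aliases: Optional[dict[str, str]] = None,
    drop_unmatched_atoms: bool = True,
) -> Structure:
    """Normalize residue and atom names to the template vocabulary.

    Aliases (terminal oxygen variants, protonation-state residue names, ...)
    are rewritten; hydrogens and other atoms the template does not declare
    are dropped with a warning when ``drop_unmatched_atoms`` is true,
    otherwise reported as an error.  A residue name with no template entry
    and no alias raises :class:`StructureError` naming the residue.
    """
    atom_aliases = DEFAULT_ALIASES if atom_aliases is None else atom_aliases
    residue_aliases = (
        DEFAULT_RESIDUE_ALIASES if residue_aliases is None else residue_aliases
    )
    new_atoms: list[Atom] = []
    new_breaks: list[int] = []
    old_breaks = set(structure.chain_breaks)
    dropped: list[str] = []
    for i, a in enumerate(structure.atoms):
        if i in old_breaks:
            if new_atoms and (not new_breaks or new_breaks[-1] != len(new_atoms)):
                new_breaks.append(len(new_atoms))
        resname = a.residue_name
        if resname not in template_set.residues:
            resname = residue_aliases.get(resname, resname)
        if resname not in template_set.residues:
            raise StructureError(
                f"residue {a.residue_name!r} at {a.chain_id}/{a.residue_seq} "
                f"has no entry in template set {template_set.name!r} and no alias"
            )
        rdef = template_set.residues[resname]
        declared = set(rdef.atom_names)
        name = a.name
        if name not in declared and name in atom_aliases:
            alias = atom_aliases[name]
            if alias in declared:
                name = alias
        if name not in declared:
            if _is_hydrogen(name) or drop_unmatched_atoms:
                dropped.append(f"{a.chain_id}/{a.residue_seq}:{a.name}")
                continue
            raise StructureError(
                f"atom {a.name!r} in residue {a.chain_id}/{a.residue_seq} "
                f"({resname}) is not declared by template {template_set.name!r}"
            )
        new_atoms.append(replace(a, name=name, residue_name=resname,
                                 position=a.position.copy()))
    if dropped:
        logger.warning(
            "adjust_names: dropped %d atoms not declared by template %s (%s%s)",
            len(dropped), template_set.name, ", ".join(dropped[:8]),
            ", ..." if len(dropped) > 8 else "",
        )
    return Structure(atoms=new_atoms, chain_breaks=new_breaks,
                     extra_bonds=list(structure.extra_bonds))


# ---------------------------------------------------------------------------
# Fixture generators
# ---------------------------------------------------------------------------

FIXTURE_KINDS = (
    "dimer",
    "triatomic_bent",
    "planar_four",
    "ca_helix",
    "ca_hairpin",
    "two_chain",
    "aa_peptide",
    "synthetic_ci2",
)

_CA_SPACING = 0.38  # nm, consecutive C-alpha distance

#: Synthetic sequence pattern: residues whose side chains all contain CB and
#: CG so the decorated synthetic structures stay within the all-atom
#: template vocabulary.
_SYNTH_SEQ_CYCLE = ("LEU", "GLU", "LYS", "PHE", "ARG", "GLN", "MET", "HIS")


def _ca_structure(
    positions: np.ndarray,
    *,
    chain_breaks: Sequence[int] = (),
    resnames: Optional[Sequence[str]] = None,
    chain_ids: Optional[Sequence[str]] = None,
) -> Structure:
    atoms = []
    for i, pos in enumerate(positions):
        atoms.append(
            Atom(
                serial=i + 1,
                name="CA",
                residue_name=resnames[i] if resnames else "GLY",
                residue_seq=i + 1,
                chain_id=chain_ids[i] if chain_ids else "A",
                position=np.asarray(pos, dtype=float),
            )
        )
    return Structure(atoms=atoms, chain_breaks=list(chain_breaks))


def _helix_trace(n: int, *, origin=(0.0, 0.0, 0.0), axis_dir=1.0) -> np.ndarray:
    """Ideal alpha-helix C-alpha trace with exactly 0.38 nm spacing.

    Radius 0.23 nm and 100 degrees per residue; the rise per residue is
    solved so consecutive spacing is exactly ``_CA_SPACING``.
    """
    radius = 0.23
    dphi = math.radians(100.0)
    chord = 2.0 * radius * math.sin(dphi / 2.0)
    rise = math.sqrt(_CA_SPACING**2 - chord**2)
    i = np.arange(n)
    pts = np.stack(
        [
            axis_dir * rise * i,
            radius * np.cos(dphi * i),
            radius * np.sin(dphi * i),
        ],
        axis=1,
    )
    return pts + np.asarray(origin, dtype=float)


def _arc_loop(p0: np.ndarray, p1: np.ndarray, n: int, bulge: np.ndarray) -> np.ndarray:
    """``n`` intermediate points from p0 to p1 bulging along ``bulge``.

    The bulge amplitude is chosen so the mean step length is close to the
    C-alpha spacing, keeping loops walkable without clashes.
    """
    t = np.linspace(0.0, 1.0, n + 2)[1:-1]
    straight = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    d = float(np.linalg.norm(p1 - p0))
    needed = _CA_SPACING * (n + 1)
    # circular-arc approximation: arc length ~ d * (1 + 8/3 * (a/d)^2)
    if needed > d > 1e-9:
        amp = d * math.sqrt(max(0.0, 3.0 / 8.0 * (needed / d - 1.0)))
    else:
        amp = 0.05
    return straight + (amp * np.sin(math.pi * t))[:, None] * bulge[None, :]


def _synthetic_ci2_trace() -> np.ndarray:
    """C-alpha trace of the synthetic 64-residue alpha/beta fold.

    Architecture (1-based residue ranges): N-tail 1-2, beta1 3-9, helix
    12-24 packed over the sheet, beta2 28-34, long loop 35-44, beta3 45-52,
    beta4 56-63, C-tail 64.  Sheet strands sit 0.5 nm apart; the helix axis
    lies ~0.85 nm above the sheet plane.
    """
    s = _CA_SPACING
    pts: dict[int, np.ndarray] = {}

    def strand(r0: int, r1: int, start: np.ndarray, direction: np.ndarray) -> None:
        direction = direction / np.linalg.norm(direction)
        for k, r in enumerate(range(r0, r1 + 1)):
            # small alternating pleat keeps strands from being collinear
            pleat = 0.04 * (1 if (r % 2) else -1)
            pts[r] = start + k * s * direction + np.array([0.0, pleat, 0.0])

    # beta1: residues 3-9 along +x at z=0.50
    strand(3, 9, np.array([0.0, 0.0, 0.50]), np.array([1.0, 0.0, 0.0]))
    # helix 12-24, axis along -x, above the sheet
    helix = _helix_trace(13, origin=(2.35, 0.85, 0.75), axis_dir=-1.0)
    for k, r in enumerate(range(12, 25)):
        pts[r] = helix[k]
    # beta2: 28-34 along +x at z=1.00
    strand(28, 34, np.array([0.05, 0.0, 1.00]), np.array([1.0, 0.0, 0.0]))
    # beta3: 45-52 along -x at z=0.0
    strand(45, 52, np.array([2.55, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0]))
    # beta4: 56-63 along +x at z=1.50
    strand(56, 63, np.array([0.05, 0.0, 1.50]), np.array([1.0, 0.0, 0.0]))

    # tails and loops
    pts[2] = pts[3] + np.array([-0.30, 0.18, -0.12])
    pts[1] = pts[2] + np.array([-0.30, 0.20, -0.10])
    for i, p in zip((10, 11), _arc_loop(pts[9], pts[12], 2, np.array([0.2, 1.0, 0.0]))):
        pts[i] = p
    for i, p in zip(
        (25, 26, 27), _arc_loop(pts[24], pts[28], 3, np.array([-0.6, 0.6, 0.4]))
    ):
        pts[i] = p
    # long "active-site" loop 35-44 swinging below the sheet plane
    for i, p in zip(
        range(35, 45), _arc_loop(pts[34], pts[45], 10, np.array([0.55, -0.83, 0.0]))
    ):
        pts[i] = p
    for i, p in zip(
        (53, 54, 55), _arc_loop(pts[52], pts[56], 3, np.array([-0.5, 0.5, 0.5]))
    ):
        pts[i] = p
    pts[64] = pts[63] + np.array([0.28, 0.20, 0.14])

    return np.stack([pts[r] for r in range(1, 65)], axis=0)


def _relax_trace(
    trace: np.ndarray,
    *,
    spacing: float = _CA_SPACING,
    repulsion_dist: float = 0.46,
    n_steps: int = 800,
    lr: float = 5e-3,
) -> np.ndarray:
    """Deterministic gradient relaxation of a CA trace.

    Enforces uniform consecutive spacing and a soft minimum distance between
    non-neighbouring residues while weakly restraining the points to their
    initial layout, so the designed architecture is preserved but hand-laid
    loops become clash-free and evenly spaced.
    """
    x = trace.copy()
    ref = trace.copy()
    n = len(x)
    iu, ju = np.triu_indices(n, k=2)
    for _ in range(n_steps):
        grad = 0.10 * (x - ref)  # weak positional restraint
        # bond springs
        dvec = x[1:] - x[:-1]
        d = np.linalg.norm(dvec, axis=1, keepdims=True)
        g = 40.0 * (d - spacing) * dvec / np.maximum(d, 1e-9)
        grad[1:] += g
        grad[:-1] -= g
        # soft repulsion between non-neighbours
        rvec = x[iu] - x[ju]
        r = np.linalg.norm(rvec, axis=1)
        close = r < repulsion_dist
        if np.any(close):
            rv = rvec[close]
            rr = r[close][:, None]
            g = 40.0 * (rr - repulsion_dist) * rv / np.maximum(rr, 1e-9)
            np.add.at(grad, iu[close], g)
            np.add.at(grad, ju[close], -g)
        x -= lr * grad
    return x


def _declash_decorated(structure: Structure, min_dist: float = 0.27) -> Structure:
    """Shrink atom offsets toward their own CA until inter-residue clashes clear.

    Keeps every decorated atom on the ray from its C-alpha, so the local
    geometry stays well-defined while overlaps between residues are removed.
    Deterministic fixed-point iteration.
    """
    ridx = structure.residue_index_of_atom()
    # map residue index -> CA position
    ca_pos: dict[int, np.ndarray] = {}
    for ri, res in enumerate(structure.residues()):
        for ai in res.atom_indices:
            if structure.atoms[ai].name == "CA":
                ca_pos[ri] = structure.atoms[ai].position.copy()
    xyz = structure.coords()
    names = [a.name for a in structure.atoms]
    for _ in range(40):
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
        ii, jj = np.where(d < min_dist)
        moved = False
        for i, j in zip(ii, jj):
            if i >= j or ridx[i] == ridx[j]:
                continue
            for k in (i, j):
                if names[k] == "CA":
                    continue
                ca = ca_pos[int(ridx[k])]
                xyz[k] = ca + 0.85 * (xyz[k] - ca)
                moved = True
        if not moved:
            break
    out = structure.copy()
    out.set_coords(xyz)
    return out


def _decorate_backbone(
    trace: np.ndarray, resnames: Sequence[str], *, with_cg: bool = True
) -> Structure:
    """Build an approximate heavy-atom backbone (+CB/CG) around a CA trace.

    N and C are placed along the local chain tangent, CB points toward the
    structure centroid (packing side chains into the core) and CG extends
    the same direction.  Geometry is approximate by design: structure-based
    parameterization measures whatever geometry the input has.
    """
    n = len(trace)
    centroid = trace.mean(axis=0)
    atoms: list[Atom] = []
    serial = 1
    for i in range(n):
        prev_i = max(i - 1, 0)
        next_i = min(i + 1, n - 1)
        t = trace[next_i] - trace[prev_i]
        t = t / (np.linalg.norm(t) + 1e-12)
        inward = centroid - trace[i]
        inward = inward - np.dot(inward, t) * t
        nrm = np.linalg.norm(inward)
        if nrm < 1e-6:
            inward = np.array([0.0, 0.0, 1.0]) - t[2] * t
            nrm = np.linalg.norm(inward)
        inward = inward / nrm
        side = np.cross(t, inward)
        ca = trace[i]
        placements = [
            ("N", ca - 0.125 * t + 0.02 * side),
            ("CA", ca),
            ("C", ca + 0.125 * t + 0.02 * side),
            ("O", ca + 0.145 * t - 0.10 * inward + 0.05 * side),
            ("CB", ca + 0.153 * inward),
        ]
        if with_cg:
            placements.append(("CG", ca + 0.29 * inward + 0.03 * side))
        for name, pos in placements:
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    residue_name=resnames[i],
                    residue_seq=i + 1,
                    chain_id="A",
                    position=np.asarray(pos, dtype=float),
                )
            )
            serial += 1
    return Structure(atoms=atoms)


def make_fixture(kind: str, n_residues: int = 10, seed: int = 0) -> Structure:
    """Generate a deterministic toy structure.

    Kinds
    -----
    ``dimer``            two CA beads 0.38 nm apart
    ``triatomic_bent``   three CA beads with a 100-degree interior angle
    ``planar_four``      four coplanar beads in trans (dihedral pi)
    ``ca_helix``         ideal alpha-helix CA trace, exact 0.38 nm spacing
    ``ca_hairpin``       two-stranded antiparallel hairpin CA trace
    ``two_chain``        two separate short CA chains (chain break)
    ``aa_peptide``       extended peptide with N/CA/C/O/CB/CG heavy atoms
    ``synthetic_ci2``    synthetic 64-residue alpha/beta fold, heavy-atom
                         decorated; a constructed CI2-scale stand-in

    ``seed`` only affects kinds that add stochastic jitter (currently none
    add jitter by default; the parameter is part of the determinism
    contract: identical inputs give bit-identical structures).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)  # noqa: F841  (reserved for jittered kinds)

    if kind == "dimer":
        return _ca_structure(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, _CA_SPACING]]))

    if kind == "triatomic_bent":
        theta = math.radians(100.0)
        p = np.array(
            [
                [_CA_SPACING, 0.0, 0.0],
                [0.0, 0.0, 0.0],
                [_CA_SPACING * math.cos(theta), _CA_SPACING * math.sin(theta), 0.0],
            ]
        )
        return _ca_structure(p)

    if kind == "planar_four":
        # planar zig-zag: trans arrangement, dihedral exactly pi
        p = np.array(
            [
                [0.0, 0.3, 0.0],
                [0.3, 0.0, 0.0],
                [0.6, 0.3, 0.0],
                [0.9, 0.0, 0.0],
            ]
        )
        return _ca_structure(p)

    if kind == "ca_helix":
        return _ca_structure(_helix_trace(n_residues))

    if kind == "ca_hairpin":
        if n_residues < 6:
            raise ValueError("ca_hairpin needs at least 6 residues")
        n_turn = 2
        n1 = (n_residues - n_turn + 1) // 2
        n2 = n_residues - n_turn - n1
        pts = []
        for i in range(n1):  # strand 1 along +x
            pts.append([i * _CA_SPACING, 0.04 * (-1) ** i, 0.0])
        xe = (n1 - 1) * _CA_SPACING
        pts.append([xe + 0.30, 0.10, 0.05])
        pts.append([xe + 0.30, 0.40, 0.05])
        for i in range(n2):  # strand 2 along -x, 0.5 nm away
            pts.append([xe - i * _CA_SPACING, 0.50 + 0.04 * (-1) ** i, 0.0])
        return _ca_structure(np.array(pts))

    if kind == "two_chain":
        n1 = max(n_residues // 2, 2)
        n2 = max(n_residues - n1, 2)
        a = _helix_trace(n1)
        b = _helix_trace(n2, origin=(0.0, 2.0, 0.0))
        pos = np.vstack([a, b])
        chain_ids = ["A"] * n1 + ["B"] * n2
        st = _ca_structure(pos, chain_breaks=[n1], chain_ids=chain_ids)
        # residue numbering restarts on the second chain
        for i, atom in enumerate(st.atoms[n1:]):
            atom.residue_seq = i + 1
        return st

    if kind == "aa_peptide":
        # extended poly-alanine, tangent along +x with out-of-plane pucker;
        # ALA's full heavy-atom set is N/CA/C/O/CB, so the chain is complete
        # against the all-atom template (usable for bonded assembly)
        trace = np.stack(
            [
                0.36 * np.arange(n_residues),
                0.05 * (-1.0) ** np.arange(n_residues),
                0.02 * (-1.0) ** (np.arange(n_residues) // 2),
            ],
            axis=1,
        )
        return _decorate_backbone(trace, ["ALA"] * n_residues, with_cg=False)

    if kind == "synthetic_ci2":
        trace = _relax_trace(_synthetic_ci2_trace())
        resnames = [_SYNTH_SEQ_CYCLE[i % len(_SYNTH_SEQ_CYCLE)] for i in range(64)]
        return _declash_decorated(_decorate_backbone(trace, resnames))

    raise AssertionError("unreachable")
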