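"""Build fully parameterized structure-based topologies.

The covalent bond graph is instantiated from per-residue template bonds plus
connect-atom links between consecutive residues of a chain; angles and
dihedrals are enumerated from the graph; native values (r0, theta0, phi0)
are measured from the input coordinates; and every term is parameterized by
matching typed template rules, with ``?`` placeholders resolved to the
measured native values.  The result is the standard structure-based
Hamiltonian:

    V = sum_bonds  eps_b/2 (r - r0)^2
      + sum_angles eps_th/2 (theta - theta0)^2
      + sum_dihedrals eps_D F_D(phi - phi0)
      + sum_contacts  eps_C [5 (r0/r)^12 - 6 (r0/r)^10]          (12-10 form)
      + sum_noncontacts eps_NC (sigma_NC / r)^12

with F_D(d) = [1 - cos d] + 1/2 [1 - cos 3d], so each dihedral record
expands into periodic terms of multiplicity 1 (weight 1) and 3 (weight 1/2).
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

from .structure_io import Atom, Structure, StructureError
from .templates import (
    NonbondedSettings,
    PhysicalForm,
    Rule,
    TemplateError,
    TemplateSet,
    match_rule,
    resolve_placeholders,
)

__all__ = [
    "EdgeProvenance",
    "BondGraph",
    "BondRecord",
    "AngleRecord",
    "DihedralRecord",
    "ContactRecord",
    "TopAtom",
    "Topology",
    "TopologyError",
    "build_bond_graph",
    "enumerate_angles",
    "enumerate_dihedrals",
    "measure_geometry",
    "measure_distance",
    "measure_angle",
    "measure_dihedral",
    "coarse_grain",
    "CoarseGrainResult",
    "assemble_topology",
    "normalize_energies",
]

logger = logging.getLogger("gosbm.topology_builder")

#: Numbering-gap bondability threshold between connect atoms (nm): residues
#: with a gap in numbering are only joined if their connect atoms are this
#: close (catches missing loops in crystal structures).
BONDABILITY_THRESHOLD = 0.3


class TopologyError(ValueError):
    pass


class EdgeProvenance(Enum):
    RESIDUE_INTERNAL = "residue_internal"
    INTER_RESIDUE = "inter_residue"
    USER_EXTRA = "user_extra"


@dataclass
class BondGraph:
    """Symmetric covalent adjacency over atom indices."""

    n_atoms: int
    adjacency: list[set[int]] = field(default_factory=list)
    provenance: dict[tuple[int, int], EdgeProvenance] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.adjacency:
            self.adjacency = [set() for _ in range(self.n_atoms)]

    def add_edge(self, i: int, j: int, provenance: EdgeProvenance) -> None:
        if i == j:
            raise TopologyError(f"self-edge on atom {i}")
        if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
            raise TopologyError(f"edge ({i}, {j}) outside atom range")
        self.adjacency[i].add(j)
        self.adjacency[j].add(i)
        self.provenance[(min(i, j), max(i, j))] = provenance

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.provenance.keys())

    def n_components(self) -> int:
        seen = [False] * self.n_atoms
        n = 0
        for start in range(self.n_atoms):
            if seen[start]:
                continue
            n += 1
            stack = [start]
            seen[start] = True
            while stack:
                u = stack.pop()
                for v in self.adjacency[u]:
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
        return n

    def pairs_within(self, depth: int) -> set[tuple[int, int]]:
        """All atom pairs at bond-graph distance <= depth (i < j)."""
        out: set[tuple[int, int]] = set()
        for start in range(self.n_atoms):
            dist = {start: 0}
            q = deque([start])
            while q:
                u = q.popleft()
                if dist[u] == depth:
                    continue
                for v in self.adjacency[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        q.append(v)
            for v, d in dist.items():
                if v > start and d >= 1:
                    out.add((start, v))
        return out


# ---------------------------------------------------------------------------
# Bond graph construction
# ---------------------------------------------------------------------------


def build_bond_graph(
    structure: Structure,
    template_set: TemplateSet,
    *,
    bondability_threshold: float = BONDABILITY_THRESHOLD,
) -> BondGraph:
    """Instantiate the covalent bond graph from templates and chain layout.

    Per-residue internal bonds come from the residue definitions;
    consecutive residues within a physical chain are joined through their
    connect atoms.  Residues separated by a numbering gap are joined only if
    the connect atoms are within ``bondability_threshold`` nm.  User
    ``extra_bonds`` are added last; no other inter-chain bonds are created.
    """
    graph = BondGraph(structure.n_atoms)
    residues = structure.residues()
    index_of: list[dict[str, int]] = []
    for res in residues:
        lookup = {structure.atoms[ai].name: ai for ai in res.atom_indices}
        index_of.append(lookup)

    for ri, res in enumerate(residues):
        try:
            rdef = template_set.residues[res.residue_name]
        except KeyError as exc:
            raise TopologyError(
                f"residue {res.residue_name!r} at {res.chain_id}/{res.residue_seq} "
                f"not in template set {template_set.name!r} (run adjust_names first)"
            ) from exc
        present = index_of[ri]
        for a1, a2 in rdef.internal_bonds:
            if a1 not in present or a2 not in present:
                missing = a1 if a1 not in present else a2
                raise TopologyError(
                    f"declared bond atom {missing!r} missing from residue "
                    f"{res.chain_id}/{res.residue_seq} ({res.residue_name})"
                )
            graph.add_edge(present[a1], present[a2], EdgeProvenance.RESIDUE_INTERNAL)

    for ri in range(len(residues) - 1):
        r1, r2 = residues[ri], residues[ri + 1]
        if r1.chain_index != r2.chain_index:
            continue
        d1 = template_set.residues[r1.residue_name]
        d2 = template_set.residues[r2.residue_name]
        if d1.connect_out is None or d2.connect_in is None:
            continue
        if d1.connect_out not in index_of[ri]:
            raise TopologyError(
                f"connect atom {d1.connect_out!r} missing from residue "
                f"{r1.chain_id}/{r1.residue_seq} at a chain junction"
            )
        if d2.connect_in not in index_of[ri + 1]:
            raise TopologyError(
                f"connect atom {d2.connect_in!r} missing from residue "
                f"{r2.chain_id}/{r2.residue_seq} at a chain junction"
            )
        i = index_of[ri][d1.connect_out]
        j = index_of[ri + 1][d2.connect_in]
        gap = (r2.residue_seq - r1.residue_seq) > 1 and r1.icode == r2.icode
        if gap:
            dist = float(
                np.linalg.norm(structure.atoms[i].position - structure.atoms[j].position)
            )
            if dist > bondability_threshold:
                logger.info(
                    "numbering gap %s/%d -> %d with connect distance %.3f nm "
                    "> %.2f nm: treated as chain break",
                    r1.chain_id, r1.residue_seq, r2.residue_seq, dist,
                    bondability_threshold,
                )
                continue
        graph.add_edge(i, j, EdgeProvenance.INTER_RESIDUE)

    for i, j in structure.extra_bonds:
        graph.add_edge(i, j, EdgeProvenance.USER_EXTRA)
    return graph


# ---------------------------------------------------------------------------
# Angle / dihedral enumeration
# ---------------------------------------------------------------------------


def enumerate_angles(graph: BondGraph) -> list[tuple[int, int, int]]:
    """All simple paths i-j-k, canonicalized with i < k, each listed once."""
    out: list[tuple[int, int, int]] = []
    for j in range(graph.n_atoms):
        nbrs = sorted(graph.adjacency[j])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                out.append((nbrs[a], j, nbrs[b]))
    out.sort()
    return out


def enumerate_dihedrals(graph: BondGraph) -> list[tuple[int, int, int, int]]:
    """All simple paths i-j-k-l over central bonds (j, k), with i < l.

    Every flanking combination of each central bond is listed once; paths
    revisiting an atom (i == l, i == k, l == j) are excluded.
    """
    out: list[tuple[int, int, int, int]] = []
    for j, k in graph.edges:
        for i in graph.adjacency[j]:
            if i == k:
                continue
            for l in graph.adjacency[k]:
                if l == j or l == i:
                    continue
                quad = (i, j, k, l) if i < l else (l, k, j, i)
                out.append(quad)
    out = sorted(set(out))
    return out


# ---------------------------------------------------------------------------
# Native geometry measurement
# ---------------------------------------------------------------------------


def measure_distance(xyz: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(xyz[j] - xyz[i]))


def measure_angle(xyz: np.ndarray, i: int, j: int, k: int) -> float:
    """Interior angle at j, radians in [0, pi]."""
    u = xyz[i] - xyz[j]
    v = xyz[k] - xyz[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise TopologyError(f"coincident points in angle ({i}, {j}, {k})")
    c = float(np.dot(u, v) / (nu * nv))
    return math.acos(max(-1.0, min(1.0, c)))


def measure_dihedral(xyz: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral (atan2 convention), right-handed about j->k, (-pi, pi]."""
    b1 = xyz[j] - xyz[i]
    b2 = xyz[k] - xyz[j]
    b3 = xyz[l] - xyz[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise TopologyError(
            f"degenerate geometry: collinear atoms in dihedral ({i}, {j}, {k}, {l})"
        )
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    phi = math.atan2(y, x)
    if phi <= -math.pi:
        phi += 2.0 * math.pi
    return phi


def measure_geometry(structure: Structure, indices: Sequence[int]) -> float:
    """Native distance (nm) / angle / dihedral (rad) for 2/3/4 atom indices."""
    xyz = structure.coords()
    idx = tuple(int(i) for i in indices)
    if len(idx) == 2:
        return measure_distance(xyz, *idx)
    if len(idx) == 3:
        return measure_angle(xyz, *idx)
    if len(idx) == 4:
        return measure_dihedral(xyz, *idx)
    raise TopologyError(f"measure_geometry takes 2-4 indices, got {len(idx)}")


# ---------------------------------------------------------------------------
# Coarse-graining
# ---------------------------------------------------------------------------


class CoarseGrainResult(NamedTuple):
    structure: Structure
    kept_atom_index: np.ndarray  # residue index -> atom index in the input


def coarse_grain(structure: Structure, cg_template: TemplateSet) -> CoarseGrainResult:
    """Map each residue to its single designated bead.

    The coarse-grained template declares exactly one atom per residue; the
    output keeps that atom (at its input position) for every residue, with
    chain breaks preserved.  The returned mapping table (residue index ->
    input atom index) supports contact-map coarse-graining.
    """
    if not cg_template.is_cg_mapping():
        raise TopologyError(
            f"template {cg_template.name!r} is not a single-bead-per-residue "
            "coarse-graining template"
        )
    residues = structure.residues()
    kept: list[int] = []
    atoms: list[Atom] = []
    breaks: list[int] = []
    last_chain: Optional[int] = None
    for res in residues:
        try:
            rdef = cg_template.residues[res.residue_name]
        except KeyError as exc:
            raise TopologyError(
                f"residue {res.residue_name!r} at {res.chain_id}/{res.residue_seq} "
                f"not present in CG template {cg_template.name!r}"
            ) from exc
        keep_name = rdef.atoms[0].name
        match = [
            ai for ai in res.atom_indices if structure.atoms[ai].name == keep_name
        ]
        if not match:
            raise TopologyError(
                f"residue {res.chain_id}/{res.residue_seq} ({res.residue_name}) "
                f"lacks its designated coarse-grained atom {keep_name!r}"
            )
        ai = match[0]
        if last_chain is not None and res.chain_index != last_chain:
            breaks.append(len(atoms))
        last_chain = res.chain_index
        kept.append(ai)
        src = structure.atoms[ai]
        atoms.append(
            Atom(
                serial=len(atoms) + 1,
                name=keep_name,
                residue_name=res.residue_name,
                residue_seq=res.residue_seq,
                chain_id=res.chain_id,
                icode=res.icode,
                position=src.position.copy(),
            )
        )
    return CoarseGrainResult(
        structure=Structure(atoms=atoms, chain_breaks=breaks),
        kept_atom_index=np.array(kept, dtype=int),
    )


# ---------------------------------------------------------------------------
# Parameterized records and the assembled topology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BondRecord:
    i: int
    j: int
    r0: float          # nm
    eps: float         # eps / nm^2 curvature scale (V = eps/2 (r - r0)^2)


@dataclass(frozen=True)
class AngleRecord:
    i: int
    j: int
    k: int
    theta0: float      # rad, in [0, pi]
    eps: float         # eps / rad^2


@dataclass(frozen=True)
class DihedralRecord:
    i: int
    j: int
    k: int
    l: int
    phi0: float        # rad, in (-pi, pi]
    eps: float         # eps (F_D prefactor; expands to n=1 and n=3 terms)


class ContactForm(str, Enum):
    LJ_12_10 = "lj_12_10"
    GAUSSIAN = "gaussian"
    HARMONIC = "harmonic"


_FORM_FROM_PHYSICAL = {
    PhysicalForm.CONTACT_12_10: ContactForm.LJ_12_10,
    PhysicalForm.CONTACT_GAUSSIAN: ContactForm.GAUSSIAN,
    PhysicalForm.CONTACT_HARMONIC: ContactForm.HARMONIC,
}


@dataclass(frozen=True)
class ContactRecord:
    i: int
    j: int
    r0: float                      # nm, > 0
    eps: float                     # eps (well depth or spring constant)
    form: ContactForm = ContactForm.LJ_12_10
    width: float = 0.05            # nm, gaussian well width (gaussian form only)

    def __post_init__(self) -> None:
        if not self.i < self.j:
            raise TopologyError(f"contact indices must satisfy i < j: ({self.i}, {self.j})")
        if not self.r0 > 0:
            raise TopologyError(f"contact ({self.i}, {self.j}) has r0 <= 0")


@dataclass(frozen=True)
class TopAtom:
    name: str
    nonbonded_type: str
    residue_name: str
    residue_seq: int
    chain_id: str
    mass: float = 1.0
    charge: float = 0.0


@dataclass
class Topology:
    """A fully parameterized structure-based Hamiltonian."""

    atoms: list[TopAtom]
    bonds: list[BondRecord]
    angles: list[AngleRecord]
    dihedrals: list[DihedralRecord]
    contacts: list[ContactRecord]
    exclusions: set[tuple[int, int]]
    settings: NonbondedSettings
    atomtypes: dict[str, tuple[float, float]] = field(default_factory=dict)
    # atomtypes: nonbonded type -> (sigma nm, eps); excluded volume is
    # sqrt(c12_i c12_j) / r^12 with c12 = eps * sigma^12
    name: str = "system"
    template_name: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def atom_c12(self) -> np.ndarray:
        out = np.empty(self.n_atoms)
        default = self.settings.epsilon_nc * self.settings.sigma_nc**12
        for idx, a in enumerate(self.atoms):
            sig_eps = self.atomtypes.get(a.nonbonded_type)
            out[idx] = (
                sig_eps[1] * sig_eps[0] ** 12 if sig_eps is not None else default
            )
        return out

    def validate(self) -> None:
        n = self.n_atoms
        bonded_pairs = {(min(b.i, b.j), max(b.i, b.j)) for b in self.bonds}
        for c in self.contacts:
            pair = (c.i, c.j)
            if pair not in self.exclusions:
                raise TopologyError(f"contact {pair} missing from exclusions")
            if pair in bonded_pairs:
                raise TopologyError(f"pair {pair} is both contact and bond")
        for rec in self.angles:
            if not 0.0 <= rec.theta0 <= math.pi:
                raise TopologyError(f"native angle out of [0, pi]: {rec}")
        for rec in self.dihedrals:
            if not -math.pi < rec.phi0 <= math.pi + 1e-12:
                raise TopologyError(f"native dihedral out of (-pi, pi]: {rec}")
        for group in (self.bonds, self.angles, self.dihedrals, self.contacts):
            for rec in group:
                idx = [getattr(rec, f) for f in "ijkl" if hasattr(rec, f)]
                if len(set(idx)) != len(idx):
                    raise TopologyError(f"repeated atom index in record {rec}")
                if any(not 0 <= x < n for x in idx):
                    raise TopologyError(f"atom index out of range in record {rec}")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _template_atom(template_set: TemplateSet, atom: Atom):
    rdef = template_set.residues[atom.residue_name]
    try:
        return rdef.atom(atom.name)
    except KeyError as exc:
        raise TopologyError(
            f"atom {atom.name!r} of residue {atom.chain_id}/{atom.residue_seq} "
            f"({atom.residue_name}) is not declared by template "
            f"{template_set.name!r}"
        ) from exc


def assemble_topology(
    structure: Structure,
    template_set: TemplateSet,
    contact_list=None,
    *,
    name: str = "system",
) -> Topology:
    """Assemble the parameterized topology for a structure.

    ``contact_list`` is a :class:`gosbm.contacts.ContactList` (or ``None``
    for a contact-free topology).  Contact entries that fall within the
    bonded exclusion depth of the covalent graph are dropped with a log
    message — they are already parameterized as bonded terms.
    """
    graph = build_bond_graph(structure, template_set)
    xyz = structure.coords()
    t_atoms = [_template_atom(template_set, a) for a in structure.atoms]

    atoms = [
        TopAtom(
            name=a.name,
            nonbonded_type=ta.nonbonded_type,
            residue_name=a.residue_name,
            residue_seq=a.residue_seq,
            chain_id=a.chain_id,
            mass=ta.mass,
            charge=ta.charge,
        )
        for a, ta in zip(structure.atoms, t_atoms)
    ]

    bonds: list[BondRecord] = []
    for i, j in graph.edges:
        rule = match_rule(
            template_set.bond_rules, (t_atoms[i].bonded_type, t_atoms[j].bonded_type)
        )
        decl = template_set.declaration_for(rule)
        if decl.physical_form is not PhysicalForm.HARMONIC_BOND:
            raise TopologyError(
                f"bond rule {rule.function!r} has non-bond form {decl.physical_form}"
            )
        params = resolve_placeholders(rule, measure_distance(xyz, i, j))
        bonds.append(BondRecord(i=i, j=j, r0=params[0], eps=params[1]))

    angles: list[AngleRecord] = []
    if template_set.enumerate_angles:
        for i, j, k in enumerate_angles(graph):
            rule = match_rule(
                template_set.angle_rules,
                (t_atoms[i].bonded_type, t_atoms[j].bonded_type, t_atoms[k].bonded_type),
            )
            params = resolve_placeholders(rule, measure_angle(xyz, i, j, k))
            angles.append(AngleRecord(i=i, j=j, k=k, theta0=params[0], eps=params[1]))

    dihedrals: list[DihedralRecord] = []
    if template_set.enumerate_dihedrals:
        for i, j, k, l in enumerate_dihedrals(graph):
            rule = match_rule(
                template_set.dihedral_rules,
                (
                    t_atoms[i].bonded_type,
                    t_atoms[j].bonded_type,
                    t_atoms[k].bonded_type,
                    t_atoms[l].bonded_type,
                ),
            )
            params = resolve_placeholders(rule, measure_dihedral(xyz, i, j, k, l))
            dihedrals.append(
                DihedralRecord(i=i, j=j, k=k, l=l, phi0=params[0], eps=params[1])
            )

    depth = template_set.settings.exclusion_depth
    exclusions = graph.pairs_within(depth)

    contacts: list[ContactRecord] = []
    dropped_bonded = 0
    if contact_list is not None:
        for i, j, r0 in contact_list.entries:
            i, j = int(i), int(j)
            if (i, j) in exclusions:
                dropped_bonded += 1
                continue
            rule = match_rule(
                template_set.pair_rules, (t_atoms[i].pair_type, t_atoms[j].pair_type)
            )
            decl = template_set.declaration_for(rule)
            form = _FORM_FROM_PHYSICAL.get(decl.physical_form)
            if form is None:
                raise TopologyError(
                    f"pair rule {rule.function!r} has non-contact form "
                    f"{decl.physical_form}"
                )
            params = resolve_placeholders(rule, float(r0))
            width = params[2] if len(params) > 2 else 0.05
            contacts.append(
                ContactRecord(i=i, j=j, r0=params[0], eps=params[1], form=form,
                              width=width)
            )
            exclusions.add((i, j))
    if dropped_bonded:
        logger.info(
            "dropped %d contact entries within the bonded exclusion depth",
            dropped_bonded,
        )

    atomtypes: dict[str, tuple[float, float]] = {}
    for ta in t_atoms:
        if ta.nonbonded_type in atomtypes:
            continue
        try:
            rule = match_rule(template_set.nonbond_rules, (ta.nonbonded_type,))
        except TemplateError:
            sigma, eps = template_set.settings.sigma_nc, template_set.settings.epsilon_nc
        else:
            params = resolve_placeholders(rule)
            sigma, eps = params[0], params[1]
        atomtypes[ta.nonbonded_type] = (sigma, eps)

    top = Topology(
        atoms=atoms,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        contacts=contacts,
        exclusions=exclusions,
        settings=template_set.settings,
        atomtypes=atomtypes,
        name=name,
        template_name=template_set.name,
    )
    top.validate()
    return top


def normalize_energies(
    topology: Topology,
    *,
    contact_dihedral_ratio: float = 2.0,
    total_stabilizing_energy: Optional[float] = None,
) -> Topology:
    """Rescale contact and dihedral strengths to a stabilizing-energy budget.

    Uniformly rescales eps_C and eps_D so that (sum eps_C)/(sum eps_D)
    equals ``contact_dihedral_ratio`` and their sum equals
    ``total_stabilizing_energy`` (default: the number of atoms, in reduced
    eps).  This is the conventional normalization for all-atom
    structure-based models; the constants are provisional defaults and both
    are configurable.
    """
    if not topology.contacts or not topology.dihedrals:
        raise TopologyError("normalization needs both contacts and dihedrals")
    total = (
        float(topology.n_atoms)
        if total_stabilizing_energy is None
        else float(total_stabilizing_energy)
    )
    r = contact_dihedral_ratio
    target_c = total * r / (1.0 + r)
    target_d = total / (1.0 + r)
    sum_c = sum(c.eps for c in topology.contacts)
    sum_d = sum(d.eps for d in topology.dihedrals)
    fc, fd = target_c / sum_c, target_d / sum_d
    new = replace(
        topology,
        contacts=[replace(c, eps=c.eps * fc) for c in topology.contacts],
        dihedrals=[replace(d, eps=d.eps * fd) for d in topology.dihedrals],
    )
    new.validate()
    return new
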