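"""GROMACS-dialect topology (.top) serialization.

Conventions of this dialect (stated in every file header):

* harmonic stiffness is stored as ``k`` with V = (k/2) dx^2, so ``k``
  equals the Hamiltonian prefactor eps exactly — no factor-of-two
  conversion;
* angles are degrees in the file, radians in memory;
* each dihedral is two periodic (function type 1) lines sharing atoms:
  multiplicity 1 with phase phi0 + 180 deg and strength eps_D, and
  multiplicity 3 with phase 3 phi0 + 180 deg and strength eps_D / 2 —
  together they realize F_D(phi - phi0);
* native 12-10 contacts are [pairs] function 1 with explicit coefficients
  C10 = 6 eps r0^10 and C12 = 5 eps r0^12 (V = C12/r^12 - C10/r^10);
  gaussian contacts use dialect function 5 (eps, r0, width) and harmonic
  contacts function 6 (r0, k).  Stock GROMACS interprets [pairs] type 1 as
  6-12 coefficients; files with 12-10/gaussian/harmonic pairs are meant
  for the bundled simulator or an SBM-enhanced MD build;
* excluded volume is carried per atom type as c12 = eps_NC * sigma_NC^12
  with geometric-mean combination;
* every contact pair is also listed under [exclusions]; bonded exclusions
  are implied by ``nrexcl``.

Floats are written as repeatable 9-significant-digit values so emitted
files are byte-stable for regression fixtures.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .templates import NonbondedSettings
from .topology_builder import (
    AngleRecord,
    BondGraph,
    BondRecord,
    EdgeProvenance,
    ContactForm,
    ContactRecord,
    DihedralRecord,
    TopAtom,
    Topology,
    TopologyError,
)

__all__ = ["write_top", "read_top", "TopParseError"]

_PAIR_FUNC = {ContactForm.LJ_12_10: 1, ContactForm.GAUSSIAN: 5, ContactForm.HARMONIC: 6}
_PAIR_FORM = {v: k for k, v in _PAIR_FUNC.items()}


class TopParseError(ValueError):
    pass


def _f(x: float) -> str:
    return f"{x:.9g}"


def _wrap_deg(x: float) -> float:
    """Wrap degrees to (-180, 180]."""
    y = math.fmod(x, 360.0)
    if y <= -180.0:
        y += 360.0
    elif y > 180.0:
        y -= 360.0
    return y


def write_top(topology: Topology, path: Union[str, Path]) -> None:
    """Serialize a topology to the dialect described in the module docstring."""
    topology.validate()
    s = topology.settings
    lines: list[str] = []
    w = lines.append
    w(f"; generated by gosbm {__version__}, template set "
      f"{topology.template_name or 'unknown'}")
    w("; conventions: V_bond = k/2 (r-r0)^2 (k = eps_b exactly); angles in degrees;")
    w("; dihedrals: two periodic type-1 lines, phase phi0+180 (n=1) and "
      "3*phi0+180 (n=3, half strength);")
    w("; pairs: func 1 -> V = C12/r^12 - C10/r^10 with C10 = 6 eps r0^10, "
      "C12 = 5 eps r0^12;")
    w(";        func 5 -> gaussian (eps, r0, width); func 6 -> harmonic (r0, k)")
    w(f"; settings sigma_NC={_f(s.sigma_nc)} epsilon_NC={_f(s.epsilon_nc)} "
      f"exclusion_depth={s.exclusion_depth}")
    w("")
    w("[ defaults ]")
    w("; nbfunc comb-rule gen-pairs")
    w("1 1 no")
    w("")
    w("[ atomtypes ]")
    w("; name mass charge ptype c6 c12")
    for name, (sigma, eps) in sorted(topology.atomtypes.items()):
        w(f"{name} 1.0 0.0 A 0.0 {_f(eps * sigma ** 12)}")
    if not topology.atomtypes:
        w(f"NB 1.0 0.0 A 0.0 {_f(s.epsilon_nc * s.sigma_nc ** 12)}")
    w("")
    w("[ moleculetype ]")
    w("; name nrexcl")
    w(f"{topology.name} {s.exclusion_depth}")
    w("")
    w("[ atoms ]")
    w("; nr type resnr residue atom cgnr charge mass")
    for idx, a in enumerate(topology.atoms, start=1):
        w(f"{idx} {a.nonbonded_type} {a.residue_seq} {a.residue_name} "
          f"{a.name} {idx} {_f(a.charge)} {_f(a.mass)}")
    w("")
    w("[ bonds ]")
    w("; i j func r0(nm) k")
    for b in topology.bonds:
        w(f"{b.i + 1} {b.j + 1} 1 {_f(b.r0)} {_f(b.eps)}")
    w("")
    w("[ angles ]")
    w("; i j k func theta0(deg) k")
    for a in topology.angles:
        w(f"{a.i + 1} {a.j + 1} {a.k + 1} 1 {_f(math.degrees(a.theta0))} "
          f"{_f(a.eps)}")
    w("")
    w("[ dihedrals ]")
    w("; i j k l func phase(deg) k mult")
    for d in topology.dihedrals:
        phi0_deg = math.degrees(d.phi0)
        w(f"{d.i + 1} {d.j + 1} {d.k + 1} {d.l + 1} 1 "
          f"{_f(_wrap_deg(phi0_deg + 180.0))} {_f(d.eps)} 1")
        w(f"{d.i + 1} {d.j + 1} {d.k + 1} {d.l + 1} 1 "
          f"{_f(_wrap_deg(3.0 * phi0_deg + 180.0))} {_f(d.eps / 2.0)} 3")
    w("")
    w("[ pairs ]")
    w("; i j func params")
    for c in topology.contacts:
        func = _PAIR_FUNC[c.form]
        if c.form is ContactForm.LJ_12_10:
            c10 = 6.0 * c.eps * c.r0**10
            c12 = 5.0 * c.eps * c.r0**12
            w(f"{c.i + 1} {c.j + 1} 1 {_f(c10)} {_f(c12)}")
        elif c.form is ContactForm.GAUSSIAN:
            w(f"{c.i + 1} {c.j + 1} 5 {_f(c.eps)} {_f(c.r0)} {_f(c.width)}")
        else:
            w(f"{c.i + 1} {c.j + 1} 6 {_f(c.r0)} {_f(c.eps)}")
    w("")
    w("[ exclusions ]")
    w("; contact pairs (bonded exclusions implied by nrexcl)")
    for c in topology.contacts:
        w(f"{c.i + 1} {c.j + 1}")
    w("")
    w("[ system ]")
    w(topology.name)
    w("")
    w("[ molecules ]")
    w(f"{topology.name} 1")
    Path(path).write_text("\n".join(lines) + "\n")


_SECTION_RE = re.compile(r"^\[\s*(\w+)\s*\]$")
_SETTINGS_RE = re.compile(
    r"settings sigma_NC=([\d.eE+-]+) epsilon_NC=([\d.eE+-]+) exclusion_depth=(\d+)"
)


def _index(token: str, n_atoms: Optional[int], what: str, lineno: int) -> int:
    v = int(token)
    if v < 1:
        raise TopParseError(f"line {lineno}: {what} index {v} (file indices are 1-based)")
    if n_atoms is not None and v > n_atoms:
        raise TopParseError(
            f"line {lineno}: {what} index {v} exceeds atom count {n_atoms}"
        )
    return v - 1


def read_top(path: Union[str, Path]) -> Topology:
    """Parse a dialect-compatible .top back into a :class:`Topology`.

    Consecutive dihedral lines with multiplicities 1 and 3 are merged into
    one record; an n=3 line without its n=1 partner is an error.
    """
    path = Path(path)
    section = None
    template_name = ""
    settings = NonbondedSettings()
    atomtypes_c12: dict[str, float] = {}
    atoms: list[TopAtom] = []
    bonds: list[BondRecord] = []
    angles: list[AngleRecord] = []
    dihedrals: list[DihedralRecord] = []
    pending_dihedral: Optional[tuple] = None
    contacts: list[ContactRecord] = []
    explicit_excl: set[tuple[int, int]] = set()
    nrexcl = settings.exclusion_depth
    name = "system"

    def n_at() -> Optional[int]:
        return len(atoms) if atoms else None

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if raw.startswith(";"):
            m = _SETTINGS_RE.search(raw)
            if m:
                settings = NonbondedSettings(
                    sigma_nc=float(m.group(1)),
                    epsilon_nc=float(m.group(2)),
                    exclusion_depth=int(m.group(3)),
                )
                nrexcl = settings.exclusion_depth
            if "template set" in raw:
                template_name = raw.rsplit("template set", 1)[1].strip()
            continue
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        m = _SECTION_RE.match(line)
        if m:
            if pending_dihedral is not None:
                raise TopParseError(
                    f"line {lineno}: dihedral block ended with an unpaired "
                    "multiplicity-1 line"
                )
            section = m.group(1)
            continue
        fields = line.split()
        if section == "atomtypes":
            atomtypes_c12[fields[0]] = float(fields[5])
        elif section == "moleculetype":
            name = fields[0]
            nrexcl = int(fields[1])
        elif section == "atoms":
            atoms.append(
                TopAtom(
                    name=fields[4],
                    nonbonded_type=fields[1],
                    residue_name=fields[3],
                    residue_seq=int(fields[2]),
                    chain_id="A",
                    charge=float(fields[6]),
                    mass=float(fields[7]),
                )
            )
        elif section == "bonds":
            i = _index(fields[0], n_at(), "bond", lineno)
            j = _index(fields[1], n_at(), "bond", lineno)
            if int(fields[2]) != 1:
                raise TopParseError(f"line {lineno}: unknown bond function {fields[2]}")
            bonds.append(BondRecord(i=i, j=j, r0=float(fields[3]), eps=float(fields[4])))
        elif section == "angles":
            i, j, k = (_index(f, n_at(), "angle", lineno) for f in fields[:3])
            if int(fields[3]) != 1:
                raise TopParseError(f"line {lineno}: unknown angle function {fields[3]}")
            angles.append(
                AngleRecord(i=i, j=j, k=k, theta0=math.radians(float(fields[4])),
                            eps=float(fields[5]))
            )
        elif section == "dihedrals":
            i, j, k, l = (_index(f, n_at(), "dihedral", lineno) for f in fields[:4])
            if int(fields[4]) != 1:
                raise TopParseError(
                    f"line {lineno}: unknown dihedral function {fields[4]}"
                )
            phase, strength, mult = float(fields[5]), float(fields[6]), int(fields[7])
            if mult == 1:
                if pending_dihedral is not None:
                    raise TopParseError(
                        f"line {lineno}: two consecutive multiplicity-1 dihedral lines"
                    )
                pending_dihedral = (i, j, k, l, phase, strength, lineno)
            elif mult == 3:
                if pending_dihedral is None or pending_dihedral[:4] != (i, j, k, l):
                    raise TopParseError(
                        f"line {lineno}: unpaired multiplicity-3 dihedral line"
                    )
                _, _, _, _, phase1, k1, _ = pending_dihedral
                if not math.isclose(strength, k1 / 2.0, rel_tol=1e-6, abs_tol=1e-12):
                    raise TopParseError(
                        f"line {lineno}: multiplicity-3 strength {strength} is not "
                        f"half of the n=1 strength {k1}"
                    )
                phi0 = math.radians(_wrap_deg(phase1 - 180.0))
                if phi0 <= -math.pi:
                    phi0 += 2 * math.pi
                dihedrals.append(DihedralRecord(i=i, j=j, k=k, l=l, phi0=phi0, eps=k1))
                pending_dihedral = None
            else:
                raise TopParseError(
                    f"line {lineno}: unsupported dihedral multiplicity {mult}"
                )
        elif section == "pairs":
            i = _index(fields[0], n_at(), "pair", lineno)
            j = _index(fields[1], n_at(), "pair", lineno)
            func = int(fields[2])
            form = _PAIR_FORM.get(func)
            if form is None:
                raise TopParseError(f"line {lineno}: unknown pair function {func}")
            if form is ContactForm.LJ_12_10:
                c10, c12 = float(fields[3]), float(fields[4])
                # invert C10 = 6 eps r0^10, C12 = 5 eps r0^12
                r0 = math.sqrt(6.0 * c12 / (5.0 * c10))
                eps = c10 / (6.0 * r0**10)
                contacts.append(ContactRecord(i=i, j=j, r0=r0, eps=eps, form=form))
            elif form is ContactForm.GAUSSIAN:
                contacts.append(
                    ContactRecord(i=i, j=j, r0=float(fields[4]), eps=float(fields[3]),
                                  form=form, width=float(fields[5]))
                )
            else:
                contacts.append(
                    ContactRecord(i=i, j=j, r0=float(fields[3]), eps=float(fields[4]),
                                  form=form)
                )
        elif section == "exclusions":
            i = _index(fields[0], n_at(), "exclusion", lineno)
            j = _index(fields[1], n_at(), "exclusion", lineno)
            explicit_excl.add((min(i, j), max(i, j)))

    if pending_dihedral is not None:
        raise TopParseError(
            f"line {pending_dihedral[6]}: multiplicity-1 dihedral line never paired"
        )
    if not atoms:
        raise TopParseError(f"{path}: no [ atoms ] section")

    settings = NonbondedSettings(
        sigma_nc=settings.sigma_nc,
        epsilon_nc=settings.epsilon_nc,
        exclusion_depth=nrexcl,
    )
    # reconstruct per-type sigma from c12 and the global epsilon
    atomtypes: dict[str, tuple[float, float]] = {}
    for tname, c12 in atomtypes_c12.items():
        if settings.epsilon_nc > 0:
            sigma = (c12 / settings.epsilon_nc) ** (1.0 / 12.0)
            atomtypes[tname] = (sigma, settings.epsilon_nc)

    graph = BondGraph(len(atoms))
    for b in bonds:
        graph.add_edge(b.i, b.j, EdgeProvenance.RESIDUE_INTERNAL)
    exclusions = graph.pairs_within(nrexcl) | explicit_excl

    top = Topology(
        atoms=atoms,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        contacts=contacts,
        exclusions=exclusions,
        settings=settings,
        atomtypes=atomtypes,
        name=name,
        template_name=template_name,
    )
    top.validate()
    return top
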