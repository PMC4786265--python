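"""Forcefield template sets for structure-based models.

A template set is a directory of four XML documents that together define a
structure-based forcefield grammar:

``residues.xml``
    The atoms and covalent bonds of every residue the forcefield knows,
    including the connection atoms that link consecutive residues.
``settings.xml``
    Declared interaction functions (name, physical form), system-wide
    nonbonded settings, and optional coarse-graining metadata.
``bonded.xml``
    Typed rules mapping tuples of *bonded types* to bond / angle / dihedral
    functions.
``nonbonded.xml``
    Typed rules for excluded volume (per nonbonded type) and for native
    contact ("pair") interactions (per pair-type tuple).

Rule parameters may use the special placeholder ``?`` to request that the
value be measured from the native structure (e.g. the native bond length
r0).  Type tokens may be the whole-token wildcard ``*``; the most specific
matching rule wins and ties between distinct equally-specific rules are an
error.  The full schema is documented in ``docs/template_schema.md``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from lxml import etree

__all__ = [
    "PLACEHOLDER",
    "Placeholder",
    "PhysicalForm",
    "ResidueClass",
    "ResidueDefinition",
    "TemplateAtom",
    "FunctionDeclaration",
    "Rule",
    "NonbondedSettings",
    "TemplateSet",
    "TemplateError",
    "AmbiguousRuleError",
    "UnparameterizedInteractionError",
    "parse_template_set",
    "write_template_set",
    "match_rule",
    "resolve_placeholders",
    "bundled_template_dir",
]

TEMPLATE_FILES = ("residues.xml", "settings.xml", "bonded.xml", "nonbonded.xml")


class TemplateError(ValueError):
    """A template document failed validation.

    The message carries the file and, where available, the source line of the
    offending element.
    """


class AmbiguousRuleError(TemplateError):
    """Two distinct rules match a type tuple with equal specificity."""


class UnparameterizedInteractionError(TemplateError):
    """No rule matches a type tuple."""


class Placeholder:
    """Singleton marker for a structure-derived parameter slot (``?``)."""

    _instance: Optional["Placeholder"] = None

    def __new__(cls) -> "Placeholder":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "?"


#: The placeholder singleton used in rule parameter lists.
PLACEHOLDER = Placeholder()

Param = Union[float, Placeholder]


class PhysicalForm(str, Enum):
    """Supported interaction functional forms."""

    HARMONIC_BOND = "harmonic_bond"            # (r0 [nm], eps_b)
    HARMONIC_ANGLE = "harmonic_angle"          # (theta0 [rad], eps_theta)
    PERIODIC_DIHEDRAL_1_3 = "periodic_dihedral_1_3"  # (phi0 [rad], eps_D)
    CONTACT_12_10 = "contact_12_10"            # (r0 [nm], eps_C)
    CONTACT_GAUSSIAN = "contact_gaussian"      # (r0 [nm], eps_C, width [nm])
    CONTACT_HARMONIC = "contact_harmonic"      # (r0 [nm], k [eps/nm^2])
    EXCLUDED_12 = "excluded_12"                # (sigma [nm], eps)


#: arity, indices of structure-derivable slots, and emitted topology section
FORM_INFO: Mapping[PhysicalForm, tuple[int, tuple[int, ...], str]] = {
    PhysicalForm.HARMONIC_BOND: (2, (0,), "bonds"),
    PhysicalForm.HARMONIC_ANGLE: (2, (0,), "angles"),
    PhysicalForm.PERIODIC_DIHEDRAL_1_3: (2, (0,), "dihedrals"),
    PhysicalForm.CONTACT_12_10: (2, (0,), "pairs"),
    PhysicalForm.CONTACT_GAUSSIAN: (3, (0,), "pairs"),
    PhysicalForm.CONTACT_HARMONIC: (2, (0,), "pairs"),
    PhysicalForm.EXCLUDED_12: (2, (), "atomtypes"),
}


class ResidueClass(str, Enum):
    AMINO = "amino"
    NUCLEIC = "nucleic"
    LIGAND = "ligand"


@dataclass(frozen=True)
class TemplateAtom:
    """One atom slot in a residue definition.

    Charges are in elementary charge units, masses in reduced units; both
    default to the charge-free, mass-uniform conventions of plain
    structure-based Hamiltonians.
    """

    name: str
    bonded_type: str
    nonbonded_type: str
    pair_type: str
    charge: float = 0.0
    mass: float = 1.0


@dataclass(frozen=True)
class ResidueDefinition:
    """Covalent blueprint of one residue type."""

    residue_name: str
    atoms: tuple[TemplateAtom, ...]
    internal_bonds: tuple[tuple[str, str], ...] = ()
    connect_out: Optional[str] = None
    connect_in: Optional[str] = None
    residue_class: ResidueClass = ResidueClass.AMINO

    def atom(self, name: str) -> TemplateAtom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def atom_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.atoms)

    def validate(self, source: str = "") -> None:
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise TemplateError(
                f"{source}: residue {self.residue_name!r} declares duplicate atom names"
            )
        declared = set(names)
        for a1, a2 in self.internal_bonds:
            for nm in (a1, a2):
                if nm not in declared:
                    raise TemplateError(
                        f"{source}: residue {self.residue_name!r} bond references "
                        f"undeclared atom {nm!r}"
                    )
        for nm in (self.connect_in, self.connect_out):
            if nm is not None and nm not in declared:
                raise TemplateError(
                    f"{source}: residue {self.residue_name!r} connect atom {nm!r} "
                    "is not a declared atom"
                )


@dataclass(frozen=True)
class FunctionDeclaration:
    """A named interaction function, tied to a physical form."""

    name: str
    physical_form: PhysicalForm

    @property
    def arity(self) -> int:
        return FORM_INFO[self.physical_form][0]

    @property
    def derivable_slots(self) -> tuple[int, ...]:
        return FORM_INFO[self.physical_form][1]

    @property
    def directive(self) -> str:
        return FORM_INFO[self.physical_form][2]


@dataclass(frozen=True)
class Rule:
    """A typed interaction rule: pattern of type tokens -> function(params).

    ``type_pattern`` tokens are literals or the whole-token wildcard ``"*"``.
    ``params`` entries are numbers or :data:`PLACEHOLDER`.
    """

    type_pattern: tuple[str, ...]
    function: str
    params: tuple[Param, ...]

    def specificity(self) -> int:
        return sum(1 for t in self.type_pattern if t != "*")

    def matches(self, type_tuple: Sequence[str]) -> bool:
        if len(type_tuple) != len(self.type_pattern):
            return False
        fwd = all(p == "*" or p == t for p, t in zip(self.type_pattern, type_tuple))
        if fwd:
            return True
        rev = all(
            p == "*" or p == t
            for p, t in zip(self.type_pattern, reversed(type_tuple))
        )
        return rev


@dataclass(frozen=True)
class NonbondedSettings:
    """System-wide nonbonded parameters.

    sigma_nc is the excluded-volume length scale (nm), epsilon_nc its energy
    prefactor (reduced epsilon), exclusion_depth the bond-graph distance
    within which pairs are excluded from the generic nonbonded sum
    (GROMACS ``nrexcl`` semantics).
    """

    sigma_nc: float = 0.4
    epsilon_nc: float = 1.0
    exclusion_depth: int = 3

    def __post_init__(self) -> None:
        if not self.sigma_nc > 0:
            raise TemplateError(f"sigma_NC must be positive, got {self.sigma_nc}")
        if self.epsilon_nc < 0:
            raise TemplateError(f"epsilon_NC must be >= 0, got {self.epsilon_nc}")
        if self.exclusion_depth < 1:
            raise TemplateError(
                f"exclusion_depth must be >= 1, got {self.exclusion_depth}"
            )


@dataclass
class TemplateSet:
    """A fully validated, compiled forcefield template set."""

    name: str
    residues: dict[str, ResidueDefinition]
    declarations: dict[str, FunctionDeclaration]
    bond_rules: list[Rule]
    angle_rules: list[Rule]
    dihedral_rules: list[Rule]
    nonbond_rules: list[Rule] = field(default_factory=list)
    pair_rules: list[Rule] = field(default_factory=list)
    settings: NonbondedSettings = field(default_factory=NonbondedSettings)
    enumerate_angles: bool = True
    enumerate_dihedrals: bool = True
    cg_partner: Optional[str] = None

    # -- queries ---------------------------------------------------------

    def declaration_for(self, rule: Rule) -> FunctionDeclaration:
        return self.declarations[rule.function]

    def is_cg_mapping(self) -> bool:
        """True when every residue keeps exactly one atom (bead mapping)."""
        return all(len(r.atoms) == 1 for r in self.residues.values())

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        for res in self.residues.values():
            res.validate(self.name)
        token_universe = {
            "bonded": {a.bonded_type for r in self.residues.values() for a in r.atoms},
            "nonbonded": {
                a.nonbonded_type for r in self.residues.values() for a in r.atoms
            },
            "pair": {a.pair_type for r in self.residues.values() for a in r.atoms},
        }
        groups = [
            (self.bond_rules, 2, "bonded", "bond"),
            (self.angle_rules, 3, "bonded", "angle"),
            (self.dihedral_rules, 4, "bonded", "dihedral"),
            (self.nonbond_rules, 1, "nonbonded", "nonbond"),
            (self.pair_rules, 2, "pair", "pair"),
        ]
        for rules, arity, token_kind, label in groups:
            seen: set[tuple[str, ...]] = set()
            for rule in rules:
                if len(rule.type_pattern) != arity:
                    raise TemplateError(
                        f"{self.name}: {label} rule {rule.type_pattern} has "
                        f"{len(rule.type_pattern)} type tokens, expected {arity}"
                    )
                key = min(rule.type_pattern, tuple(reversed(rule.type_pattern)))
                if key in seen:
                    raise TemplateError(
                        f"{self.name}: duplicate {label} rule for pattern "
                        f"{rule.type_pattern}"
                    )
                seen.add(key)
                if rule.function not in self.declarations:
                    raise TemplateError(
                        f"{self.name}: {label} rule {rule.type_pattern} references "
                        f"undeclared function {rule.function!r}"
                    )
                decl = self.declarations[rule.function]
                if len(rule.params) != decl.arity:
                    raise TemplateError(
                        f"{self.name}: function {rule.function!r} expects "
                        f"{decl.arity} parameters, rule gives {len(rule.params)}"
                    )
                for i, p in enumerate(rule.params):
                    if isinstance(p, Placeholder) and i not in decl.derivable_slots:
                        raise TemplateError(
                            f"{self.name}: '?' in slot {i} of {rule.function!r} "
                            "is not structure-derivable for this form"
                        )
                for token in rule.type_pattern:
                    if token != "*" and token not in token_universe[token_kind]:
                        raise TemplateError(
                            f"{self.name}: {label} rule uses type {token!r} which "
                            "appears on no declared atom"
                        )


# ---------------------------------------------------------------------------
# Rule matching and placeholder resolution
# ---------------------------------------------------------------------------


def match_rule(rules: Sequence[Rule], type_tuple: Sequence[str]) -> Rule:
    """Return the most specific rule matching ``type_tuple``.

    Specificity is the number of literal (non-wildcard) tokens; matching is
    symmetric under tuple reversal so bonded interactions need only be
    declared once.  A tie between *distinct* equally-specific rules raises
    :class:`AmbiguousRuleError` — the template should declare an exact rule.
    """
    tt = tuple(type_tuple)
    best: list[Rule] = []
    best_score = -1
    for rule in rules:
        if rule.matches(tt):
            score = rule.specificity()
            if score > best_score:
                best, best_score = [rule], score
            elif score == best_score:
                best.append(rule)
    if not best:
        raise UnparameterizedInteractionError(
            f"unparameterized interaction: no rule matches type tuple {tt}"
        )
    if len(best) > 1:
        raise AmbiguousRuleError(
            f"ambiguous rules for type tuple {tt}: "
            + ", ".join(str(r.type_pattern) for r in best)
            + " have equal specificity; declare an exact rule"
        )
    return best[0]


def resolve_placeholders(
    rule: Rule,
    measured_value: Optional[float] = None,
    *,
    warn: Optional[list[str]] = None,
) -> list[float]:
    """Fill the ``?`` slots of a rule from a structure measurement.

    The measurement is interpreted in the slot's native units (nm for
    distances, radians for angles/dihedrals).  Supplying a measurement for a
    fully numeric rule is tolerated with a warning appended to ``warn``.
    """
    has_placeholder = any(isinstance(p, Placeholder) for p in rule.params)
    if has_placeholder and measured_value is None:
        raise TemplateError(
            f"rule {rule.function}{rule.type_pattern} contains '?' but no "
            "measured value was supplied"
        )
    if not has_placeholder and measured_value is not None and warn is not None:
        warn.append(
            f"measurement supplied for fully numeric rule {rule.function}"
            f"{rule.type_pattern}; ignored"
        )
    out: list[float] = []
    for p in rule.params:
        if isinstance(p, Placeholder):
            out.append(float(measured_value))  # type: ignore[arg-type]
        else:
            out.append(float(p))
    return out


# ---------------------------------------------------------------------------
# XML parsing
# ---------------------------------------------------------------------------

_FUNC_RE = re.compile(r"^\s*([A-Za-z_][\w]*)\s*\(\s*(.*?)\s*\)\s*$")


def _parse_func_string(text: str, ctx: str) -> tuple[str, tuple[Param, ...]]:
    m = _FUNC_RE.match(text)
    if not m:
        raise TemplateError(f"{ctx}: cannot parse function string {text!r}")
    name = m.group(1)
    body = m.group(2)
    params: list[Param] = []
    if body:
        for tok in (t.strip() for t in body.split(",")):
            if tok == "?":
                params.append(PLACEHOLDER)
            else:
                try:
                    params.append(float(tok))
                except ValueError as exc:
                    raise TemplateError(
                        f"{ctx}: bad parameter {tok!r} in {text!r}"
                    ) from exc
    return name, tuple(params)


def _root(path: Path, expected_tag: str) -> etree._Element:
    if not path.is_file():
        raise TemplateError(f"missing template file: {path}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise TemplateError(f"{path}: XML syntax error: {exc}") from exc
    root = tree.getroot()
    if root.tag != expected_tag:
        raise TemplateError(
            f"{path}: expected root element <{expected_tag}>, got <{root.tag}>"
        )
    return root


def _ctx(path: Path, elem: etree._Element) -> str:
    return f"{path.name}:{elem.sourceline}"


def _parse_residues(path: Path) -> dict[str, ResidueDefinition]:
    root = _root(path, "residues")
    residues: dict[str, ResidueDefinition] = {}
    for relem in root.iterchildren("residue"):
        name = relem.get("name")
        if not name:
            raise TemplateError(f"{_ctx(path, relem)}: residue without name")
        if name in residues:
            raise TemplateError(f"{_ctx(path, relem)}: duplicate residue {name!r}")
        cls = ResidueClass(relem.get("class", "amino"))
        atoms: list[TemplateAtom] = []
        bonds: list[tuple[str, str]] = []
        connect_in = connect_out = None
        for child in relem.iterchildren():
            if child.tag == "atom":
                aname = child.get("name")
                if not aname:
                    raise TemplateError(f"{_ctx(path, child)}: atom without name")
                atoms.append(
                    TemplateAtom(
                        name=aname,
                        bonded_type=child.get("bType", aname),
                        nonbonded_type=child.get("nbType", aname),
                        pair_type=child.get("pType", aname),
                        charge=float(child.get("charge", "0")),
                        mass=float(child.get("mass", "1")),
                    )
                )
            elif child.tag == "bond":
                a1, a2 = child.get("a1"), child.get("a2")
                if not a1 or not a2:
                    raise TemplateError(
                        f"{_ctx(path, child)}: bond needs a1 and a2 attributes"
                    )
                bonds.append((a1, a2))
            elif child.tag == "connect":
                connect_in = child.get("in")
                connect_out = child.get("out")
        rd = ResidueDefinition(
            residue_name=name,
            atoms=tuple(atoms),
            internal_bonds=tuple(bonds),
            connect_in=connect_in,
            connect_out=connect_out,
            residue_class=cls,
        )
        rd.validate(f"{path.name}:{relem.sourceline}")
        residues[name] = rd
    if not residues:
        raise TemplateError(f"{path}: no residues declared")
    return residues


def _parse_settings(
    path: Path,
) -> tuple[dict[str, FunctionDeclaration], NonbondedSettings, bool, bool, Optional[str]]:
    root = _root(path, "settings")
    decls: dict[str, FunctionDeclaration] = {}
    settings = NonbondedSettings()
    enum_angles = enum_dihedrals = True
    cg_partner: Optional[str] = None
    for child in root.iterchildren():
        if child.tag == "functions":
            for f in child.iterchildren("function"):
                fname, form = f.get("name"), f.get("form")
                if not fname or not form:
                    raise TemplateError(
                        f"{_ctx(path, f)}: function needs name and form attributes"
                    )
                try:
                    pform = PhysicalForm(form)
                except ValueError as exc:
                    raise TemplateError(
                        f"{_ctx(path, f)}: unknown physical form {form!r}"
                    ) from exc
                if fname in decls:
                    raise TemplateError(
                        f"{_ctx(path, f)}: duplicate function {fname!r}"
                    )
                decls[fname] = FunctionDeclaration(fname, pform)
        elif child.tag == "nonbonded":
            settings = NonbondedSettings(
                sigma_nc=float(child.get("sigma_NC", "0.4")),
                epsilon_nc=float(child.get("epsilon_NC", "1.0")),
                exclusion_depth=int(child.get("exclusion_depth", "3")),
            )
        elif child.tag == "enumerate":
            enum_angles = child.get("angles", "true").lower() != "false"
            enum_dihedrals = child.get("dihedrals", "true").lower() != "false"
        elif child.tag == "coarse_graining":
            cg_partner = child.get("partner")
    return decls, settings, enum_angles, enum_dihedrals, cg_partner


_BONDED_TAGS = {"bond": 2, "angle": 3, "dihedral": 4}


def _parse_rule(elem: etree._Element, path: Path, token_tag: str, arity: int) -> Rule:
    func = elem.get("func")
    if not func:
        raise TemplateError(f"{_ctx(path, elem)}: rule without func attribute")
    name, params = _parse_func_string(func, _ctx(path, elem))
    tokens = [t.text.strip() if t.text else "" for t in elem.iterchildren(token_tag)]
    if len(tokens) != arity:
        raise TemplateError(
            f"{_ctx(path, elem)}: expected {arity} <{token_tag}> tokens, "
            f"got {len(tokens)}"
        )
    return Rule(type_pattern=tuple(tokens), function=name, params=params)


def _parse_bonded(path: Path) -> tuple[list[Rule], list[Rule], list[Rule]]:
    root = _root(path, "bonded")
    out: dict[str, list[Rule]] = {"bond": [], "angle": [], "dihedral": []}
    for child in root.iterchildren(*_BONDED_TAGS):
        out[child.tag].append(_parse_rule(child, path, "bType", _BONDED_TAGS[child.tag]))
    return out["bond"], out["angle"], out["dihedral"]


def _parse_nonbonded(path: Path) -> tuple[list[Rule], list[Rule]]:
    root = _root(path, "nonbonded")
    nonbond: list[Rule] = []
    pairs: list[Rule] = []
    for child in root.iterchildren():
        if child.tag == "nonbond":
            nonbond.append(_parse_rule(child, path, "nbType", 1))
        elif child.tag == "pair":
            pairs.append(_parse_rule(child, path, "pType", 2))
    return nonbond, pairs


def parse_template_set(directory_path: Union[str, Path]) -> TemplateSet:
    """Parse and validate the four-document template set in a directory.

    Raises :class:`TemplateError` with file/element context on any missing
    file, undeclared function, duplicate rule pattern, or undeclared atom.
    """
    d = Path(directory_path)
    if not d.is_dir():
        raise TemplateError(f"template directory not found: {d}")
    residues = _parse_residues(d / "residues.xml")
    decls, settings, enum_a, enum_d, cg_partner = _parse_settings(d / "settings.xml")
    bond_rules, angle_rules, dihedral_rules = _parse_bonded(d / "bonded.xml")
    nonbond_rules, pair_rules = _parse_nonbonded(d / "nonbonded.xml")
    ts = TemplateSet(
        name=d.name,
        residues=residues,
        declarations=decls,
        bond_rules=bond_rules,
        angle_rules=angle_rules,
        dihedral_rules=dihedral_rules,
        nonbond_rules=nonbond_rules,
        pair_rules=pair_rules,
        settings=settings,
        enumerate_angles=enum_a,
        enumerate_dihedrals=enum_d,
        cg_partner=cg_partner,
    )
    ts.validate()
    return ts


# ---------------------------------------------------------------------------
# Serialization (round-trip support)
# ---------------------------------------------------------------------------


def _fmt_param(p: Param) -> str:
    if isinstance(p, Placeholder):
        return "?"
    if float(p) == int(p) and abs(p) < 1e15:
        return str(int(p))
    return repr(float(p))


def _rule_elem(tag: str, rule: Rule, token_tag: str) -> etree._Element:
    e = etree.Element(tag)
    e.set("func", f"{rule.function}({','.join(_fmt_param(p) for p in rule.params)})")
    for token in rule.type_pattern:
        t = etree.SubElement(e, token_tag)
        t.text = token
    return e


def write_template_set(ts: TemplateSet, directory_path: Union[str, Path]) -> None:
    """Serialize a template set back to the four-document XML layout."""
    d = Path(directory_path)
    d.mkdir(parents=True, exist_ok=True)

    res_root = etree.Element("residues")
    for res in ts.residues.values():
        r = etree.SubElement(res_root, "residue")
        r.set("name", res.residue_name)
        r.set("class", res.residue_class.value)
        for a in res.atoms:
            ae = etree.SubElement(r, "atom")
            ae.set("name", a.name)
            ae.set("bType", a.bonded_type)
            ae.set("nbType", a.nonbonded_type)
            ae.set("pType", a.pair_type)
            if a.charge != 0.0:
                ae.set("charge", repr(a.charge))
            if a.mass != 1.0:
                ae.set("mass", repr(a.mass))
        for a1, a2 in res.internal_bonds:
            be = etree.SubElement(r, "bond")
            be.set("a1", a1)
            be.set("a2", a2)
        if res.connect_in is not None or res.connect_out is not None:
            ce = etree.SubElement(r, "connect")
            if res.connect_in is not None:
                ce.set("in", res.connect_in)
            if res.connect_out is not None:
                ce.set("out", res.connect_out)

    set_root = etree.Element("settings")
    fs = etree.SubElement(set_root, "functions")
    for decl in ts.declarations.values():
        fe = etree.SubElement(fs, "function")
        fe.set("name", decl.name)
        fe.set("form", decl.physical_form.value)
    nb = etree.SubElement(set_root, "nonbonded")
    nb.set("sigma_NC", repr(ts.settings.sigma_nc))
    nb.set("epsilon_NC", repr(ts.settings.epsilon_nc))
    nb.set("exclusion_depth", str(ts.settings.exclusion_depth))
    if not (ts.enumerate_angles and ts.enumerate_dihedrals):
        en = etree.SubElement(set_root, "enumerate")
        en.set("angles", "true" if ts.enumerate_angles else "false")
        en.set("dihedrals", "true" if ts.enumerate_dihedrals else "false")
    if ts.cg_partner:
        cg = etree.SubElement(set_root, "coarse_graining")
        cg.set("partner", ts.cg_partner)

    bonded_root = etree.Element("bonded")
    for tag, rules in (
        ("bond", ts.bond_rules),
        ("angle", ts.angle_rules),
        ("dihedral", ts.dihedral_rules),
    ):
        for rule in rules:
            bonded_root.append(_rule_elem(tag, rule, "bType"))

    nonbonded_root = etree.Element("nonbonded")
    for rule in ts.nonbond_rules:
        nonbonded_root.append(_rule_elem("nonbond", rule, "nbType"))
    for rule in ts.pair_rules:
        nonbonded_root.append(_rule_elem("pair", rule, "pType"))

    for fname, root in (
        ("residues.xml", res_root),
        ("settings.xml", set_root),
        ("bonded.xml", bonded_root),
        ("nonbonded.xml", nonbonded_root),
    ):
        (d / fname).write_bytes(
            etree.tostring(root, pretty_print=True, xml_declaration=True,
                           encoding="UTF-8")
        )


def bundled_template_dir(name: str) -> Path:
    """Path to one of the template sets shipped with the package.

    Available: ``SBM_CA``, ``SBM_CA_gaussian``, ``SBM_AA``, ``ENM``.
    """
    d = Path(__file__).parent / "template_sets" / name
    if not d.is_dir():
        available = sorted(
            p.name for p in (Path(__file__).parent / "template_sets").iterdir()
            if p.is_dir()
        )
        raise TemplateError(
            f"no bundled template set {name!r}; available: {available}"
        )
    return d
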