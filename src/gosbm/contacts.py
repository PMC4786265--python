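"""Native contact map generation, coarse-grain mapping, and contact files.

A native contact is an atom (or bead) pair in spatial proximity in the
input structure; the generator here is a distance cutoff (default 0.6 nm)
with a residue-separation filter, optionally post-processed by a simple
line-of-sight occlusion filter that removes pairs whose connecting segment
passes close to a third atom.  The occlusion filter is a deliberately
simplified screening criterion in the spirit of shadow-style contact map
generators, not a reimplementation of one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure, StructureError

__all__ = [
    "ContactLevel",
    "ContactProvenance",
    "ContactList",
    "cutoff_contact_map",
    "occlusion_filter",
    "map_contacts_to_cg",
    "read_contact_file",
    "write_contact_file",
    "DEFAULT_ATOMIC_CUTOFF",
    "DEFAULT_SCREENING_RADIUS",
]

logger = logging.getLogger("gosbm.contacts")

DEFAULT_ATOMIC_CUTOFF = 0.6       # nm
DEFAULT_SCREENING_RADIUS = 0.1    # nm
DEFAULT_CG_MIN_SEQ_SEPARATION = 4
DEFAULT_ATOMIC_MIN_SEQ_SEPARATION = 1


class ContactLevel(Enum):
    ATOMIC = "atomic"
    RESIDUE = "residue"


class ContactProvenance(Enum):
    CUTOFF = "cutoff"
    OCCLUSION_FILTERED = "occlusion_filtered"
    USER_SUPPLIED = "user_supplied"


@dataclass
class ContactList:
    """Native pairs (i, j, r0) with i < j, r0 in nm."""

    entries: list[tuple[int, int, float]] = field(default_factory=list)
    level: ContactLevel = ContactLevel.ATOMIC
    provenance: ContactProvenance = ContactProvenance.CUTOFF

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        norm: list[tuple[int, int, float]] = []
        for i, j, r0 in self.entries:
            i, j = int(i), int(j)
            if i == j:
                raise StructureError(f"self-contact ({i}, {j})")
            if i > j:
                i, j = j, i
            if (i, j) in seen:
                raise StructureError(f"duplicate contact ({i}, {j})")
            seen.add((i, j))
            norm.append((i, j, float(r0)))
        self.entries = sorted(norm)

    def __len__(self) -> int:
        return len(self.entries)

    def pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.entries}

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self.entries:
            return (np.zeros(0, int), np.zeros(0, int), np.zeros(0))
        arr = np.array(self.entries, dtype=float)
        return arr[:, 0].astype(int), arr[:, 1].astype(int), arr[:, 2]


def _residue_metadata(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """(residue index per atom, chain index per residue)."""
    ridx = structure.residue_index_of_atom()
    chain_of_res = np.array([r.chain_index for r in structure.residues()], dtype=int)
    return ridx, chain_of_res


def cutoff_contact_map(
    structure: Structure,
    cutoff: float = DEFAULT_ATOMIC_CUTOFF,
    min_seq_separation: int = DEFAULT_ATOMIC_MIN_SEQ_SEPARATION,
) -> ContactList:
    """All atom pairs within ``cutoff`` nm, filtered by residue separation.

    Pairs whose residues are separated by fewer than ``min_seq_separation``
    positions along the same chain are skipped; pairs on different chains
    are always eligible.
    """
    if not cutoff > 0:
        raise StructureError(f"cutoff must be positive, got {cutoff}")
    xyz = structure.coords()
    ridx, chain_of_res = _residue_metadata(structure)
    tree = cKDTree(xyz)
    entries: list[tuple[int, int, float]] = []
    for i, j in tree.query_pairs(cutoff):
        ri, rj = int(ridx[i]), int(ridx[j])
        if chain_of_res[ri] == chain_of_res[rj] and abs(ri - rj) < min_seq_separation:
            continue
        entries.append((i, j, float(np.linalg.norm(xyz[j] - xyz[i]))))
    return ContactList(entries=entries, level=ContactLevel.ATOMIC,
                       provenance=ContactProvenance.CUTOFF)


def occlusion_filter(
    structure: Structure,
    contact_list: ContactList,
    screening_radius: float = DEFAULT_SCREENING_RADIUS,
) -> ContactList:
    """Drop contacts whose line of sight is occluded by a third atom.

    A contact (i, j) is removed when any third atom's center lies within
    ``screening_radius`` nm of the i-j segment (point-to-segment distance).
    Output is always a subset of the input and shrinks monotonically with
    the screening radius.
    """
    if contact_list.level is not ContactLevel.ATOMIC:
        raise StructureError("occlusion filter operates on atomic contact lists")
    xyz = structure.coords()
    n = len(xyz)
    kept: list[tuple[int, int, float]] = []
    for i, j, r0 in contact_list.entries:
        a, b = xyz[i], xyz[j]
        ab = b - a
        denom = float(np.dot(ab, ab))
        rel = xyz - a
        t = np.clip(rel @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(n)
        closest = a + t[:, None] * ab
        dist = np.linalg.norm(xyz - closest, axis=1)
        dist[i] = dist[j] = np.inf
        if float(dist.min()) >= screening_radius:
            kept.append((i, j, r0))
    return ContactList(entries=kept, level=ContactLevel.ATOMIC,
                       provenance=ContactProvenance.OCCLUSION_FILTERED)


def map_contacts_to_cg(
    contact_list: ContactList,
    atomic_structure: Structure,
    cg_structure: Structure,
    *,
    min_seq_separation: int = DEFAULT_CG_MIN_SEQ_SEPARATION,
) -> ContactList:
    """Project an atomic contact list onto coarse-grained beads.

    Residue pair (I, J) becomes a coarse-grained contact iff at least one
    atomic contact joins residues I and J; its native distance is the
    bead-bead distance in ``cg_structure`` (one bead per residue, residue
    order matching ``atomic_structure``).  Same-residue pairs and pairs
    closer than ``min_seq_separation`` along a chain are dropped.
    """
    ridx, chain_of_res = _residue_metadata(atomic_structure)
    cg_xyz = cg_structure.coords()
    if len(cg_xyz) != len(chain_of_res):
        raise StructureError(
            f"CG structure has {len(cg_xyz)} beads but the atomic structure "
            f"has {len(chain_of_res)} residues"
        )
    pairs: set[tuple[int, int]] = set()
    for i, j, _ in contact_list.entries:
        ri, rj = int(ridx[i]), int(ridx[j])
        if ri == rj:
            continue
        if ri > rj:
            ri, rj = rj, ri
        if chain_of_res[ri] == chain_of_res[rj] and rj - ri < min_seq_separation:
            continue
        pairs.add((ri, rj))
    entries = [
        (ri, rj, float(np.linalg.norm(cg_xyz[rj] - cg_xyz[ri])))
        for ri, rj in sorted(pairs)
    ]
    return ContactList(entries=entries, level=ContactLevel.RESIDUE,
                       provenance=contact_list.provenance)


# ---------------------------------------------------------------------------
# Contact files: whitespace-delimited "chain_i atom_i chain_j atom_j"
# (1-based atom numbering within each chain), "#" comments.
# ---------------------------------------------------------------------------


def _chain_local_numbering(structure: Structure) -> tuple[np.ndarray, list[list[int]]]:
    """(chain index, 1-based within-chain number) per atom and the inverse."""
    chain_of_atom = structure.chain_of_atom()
    n_chains = int(chain_of_atom.max()) + 1 if structure.n_atoms else 0
    per_chain: list[list[int]] = [[] for _ in range(n_chains)]
    local = np.zeros(structure.n_atoms, dtype=int)
    for i in range(structure.n_atoms):
        c = int(chain_of_atom[i])
        per_chain[c].append(i)
        local[i] = len(per_chain[c])
    return np.stack([chain_of_atom, local], axis=1), per_chain


def write_contact_file(
    contact_list: ContactList, path: Union[str, Path], structure: Structure
) -> None:
    """Write the four-column contact file for ``structure``."""
    chain_local, _ = _chain_local_numbering(structure)
    with open(path, "w") as fh:
        fh.write("# chain_i atom_i chain_j atom_j  (1-based within chain)\n")
        for i, j, _ in contact_list.entries:
            ci, li = chain_local[i]
            cj, lj = chain_local[j]
            fh.write(f"{ci + 1} {li} {cj + 1} {lj}\n")


def read_contact_file(
    path: Union[str, Path],
    structure: Structure,
    *,
    level: ContactLevel = ContactLevel.ATOMIC,
) -> ContactList:
    """Read a four-column contact file; native distances come from the
    structure's current coordinates.  Pairs are normalized to i < j."""
    _, per_chain = _chain_local_numbering(structure)
    xyz = structure.coords()
    entries: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 4:
                raise StructureError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            try:
                ci, li, cj, lj = (int(f) for f in fields)
            except ValueError as exc:
                raise StructureError(
                    f"{path}:{lineno}: non-integer contact field"
                ) from exc
            for c, l in ((ci, li), (cj, lj)):
                if not 1 <= c <= len(per_chain):
                    raise StructureError(
                        f"{path}:{lineno}: chain index {c} out of range "
                        f"(structure has {len(per_chain)} chains)"
                    )
                if not 1 <= l <= len(per_chain[c - 1]):
                    raise StructureError(
                        f"{path}:{lineno}: atom index {l} beyond chain length "
                        f"{len(per_chain[c - 1])}"
                    )
            i = per_chain[ci - 1][li - 1]
            j = per_chain[cj - 1][lj - 1]
            if i > j:
                i, j = j, i
            entries.append((i, j, float(np.linalg.norm(xyz[j] - xyz[i]))))
    try:
        return ContactList(entries=entries, level=level,
                           provenance=ContactProvenance.USER_SUPPLIED)
    except StructureError as exc:
        raise StructureError(f"{path}: {exc}") from exc
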