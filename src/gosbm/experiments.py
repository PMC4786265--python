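"""Canned desk-scale experiments: model builders and folding scans.

These drivers wire the full pipeline together for the bundled synthetic
CI2-scale test protein: build the C-alpha structure-based model, run a
temperature ladder of Langevin simulations around the folding transition,
and estimate the folding temperature T_F from both folded/unfolded
population balance and the specific-heat peak.

Default scan conditions (seven temperatures spanning 1.0-1.3 reduced units,
1.5e6 steps each at dt = 5e-4) are sized for a desktop CPU; they yield
multiple folding/unfolding transitions per trajectory for this 64-residue
model.  All-atom folding thermodynamics needs far longer sampling and is
only meaningful in an extended-run configuration (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .analysis import (
    AnalysisError,
    compute_q,
    estimate_tf_from_profiles,
    free_energy_profile,
    specific_heat,
)
from .contacts import ContactList, cutoff_contact_map, map_contacts_to_cg
from .simulator import SimParams, run_langevin
from .structure_io import Structure, make_fixture
from .templates import bundled_template_dir, parse_template_set
from .topology_builder import Topology, assemble_topology, coarse_grain, normalize_energies

__all__ = [
    "CaModel",
    "build_synthetic_ci2_ca_model",
    "build_all_atom_model",
    "FoldingScan",
    "folding_temperature_scan",
    "DEFAULT_SCAN_TEMPERATURES",
]

DEFAULT_SCAN_TEMPERATURES = (1.00, 1.05, 1.10, 1.15, 1.20, 1.25, 1.30)


class CaModel(NamedTuple):
    atomistic: Structure
    structure: Structure          # one bead per residue
    contacts: ContactList         # residue-level native map
    topology: Topology


def build_synthetic_ci2_ca_model() -> CaModel:
    """C-alpha structure-based model of the synthetic CI2-scale fold.

    Pipeline: all-atom-style synthetic structure -> atomic cutoff contact
    map (0.6 nm) -> coarse-grain to C-alpha beads -> residue contact map
    (sequence separation >= 4) -> parameterized topology with the bundled
    SBM_CA template.
    """
    ca = parse_template_set(bundled_template_dir("SBM_CA"))
    atomistic = make_fixture("synthetic_ci2")
    cg = coarse_grain(atomistic, ca)
    atomic_contacts = cutoff_contact_map(atomistic)
    contacts = map_contacts_to_cg(atomic_contacts, atomistic, cg.structure)
    topology = assemble_topology(cg.structure, ca, contacts, name="ci2_ca")
    return CaModel(atomistic=atomistic, structure=cg.structure,
                   contacts=contacts, topology=topology)


def build_all_atom_model(
    structure: Optional[Structure] = None,
    *,
    normalize: bool = True,
) -> tuple[Structure, Topology]:
    """All-heavy-atom structure-based model with the bundled SBM_AA template.

    The stabilizing energies are normalized to the conventional budget
    (contacts:dihedrals 2:1, total equal to the atom count) unless
    ``normalize`` is false.  Defaults to the extended poly-alanine fixture.
    """
    aa = parse_template_set(bundled_template_dir("SBM_AA"))
    st = structure if structure is not None else make_fixture("aa_peptide", 8)
    contacts = cutoff_contact_map(st, min_seq_separation=2)
    top = assemble_topology(st, aa, contacts, name="aa_model")
    if normalize and top.contacts and top.dihedrals:
        top = normalize_energies(top)
    return st, top


@dataclass
class FoldingScan:
    """Results of a folding temperature ladder."""

    temperatures: np.ndarray
    q_series: dict[float, np.ndarray]          # burn-in removed
    energy_series: dict[float, np.ndarray]     # potential energy, burn-in removed
    tf_population: float
    tf_cv: float
    bimodal_temperature: Optional[float]       # a T with bimodal F(Q), if any

    @property
    def has_bimodal_profile(self) -> bool:
        return self.bimodal_temperature is not None


def folding_temperature_scan(
    model: CaModel,
    *,
    temperatures: Sequence[float] = DEFAULT_SCAN_TEMPERATURES,
    n_steps: int = 2_000_000,
    save_every: int = 2_000,
    n_replicas: int = 2,
    seed: int = 0,
    friction: float = 0.5,
    burn_in_fraction: float = 0.2,
    n_bins: int = 40,
) -> FoldingScan:
    """Simulate a temperature ladder and locate the folding transition.

    Each temperature runs ``n_replicas`` independent trajectories from the
    native state (per-run seeds derived from ``seed``); pooling replicas
    reduces the hysteresis noise of rare folding/unfolding transitions.
    The light default friction (0.5 inverse reduced time) speeds diffusion
    across the folding barrier without changing the sampled ensemble.
    After discarding the burn-in, Q histograms give the population-balance
    T_F and potential-energy fluctuations the Cv-peak T_F.
    """
    q_series: dict[float, np.ndarray] = {}
    energy_series: dict[float, np.ndarray] = {}
    x0 = model.structure.coords()
    for idx, t in enumerate(temperatures):
        q_parts, e_parts = [], []
        for rep in range(n_replicas):
            params = SimParams(
                n_steps=n_steps,
                save_every=save_every,
                temperature=float(t),
                friction=friction,
                seed=(seed * 10_000 + idx * 100 + rep) % (2**31 - 1),
            )
            traj = run_langevin(model.topology, x0, params)
            burn = int(burn_in_fraction * traj.n_frames)
            q = compute_q(traj.frames[burn:], model.contacts, ratio=1.5)
            q_parts.append(q.values)
            e_parts.append(np.array([e.total for e in traj.energies[burn:]]))
        q_series[float(t)] = np.concatenate(q_parts)
        energy_series[float(t)] = np.concatenate(e_parts)

    tf_pop = estimate_tf_from_profiles(q_series, n_bins=n_bins)
    tf_cv = specific_heat(energy_series).t_f

    bimodal_t: Optional[float] = None
    best_gap = np.inf
    for t, q in q_series.items():
        try:
            prof = free_energy_profile(q, n_bins=n_bins)
        except AnalysisError:
            continue
        if prof.is_bimodal() and abs(t - tf_pop) < best_gap:
            best_gap = abs(t - tf_pop)
            bimodal_t = t

    return FoldingScan(
        temperatures=np.asarray(temperatures, dtype=float),
        q_series=q_series,
        energy_series=energy_series,
        tf_population=tf_pop,
        tf_cv=tf_cv,
        bimodal_temperature=bimodal_t,
    )
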