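"""Folding-landscape observables: Q, F(Q), specific heat, T_F, contact maps,
domain-COM principal components.

Q is the fraction of native contacts formed: a native pair counts as formed
in a frame when its distance is within ``ratio`` times the native distance
(default ratio 1.5; 1.2 is the common alternative for atomic contact
counting).  Free-energy profiles are F(Q) = -ln P(Q) in units of k_B T with
the minimum shifted to zero.  The specific heat is computed from energy
fluctuations, Cv(T) = (<E^2> - <E>^2) / T^2 with k_B = 1, and the folding
temperature T_F is located either at the Cv peak (quadratic interpolation)
or where folded/unfolded basin populations balance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .contacts import ContactList
from .simulator import Trajectory

logger = logging.getLogger("gosbm.analysis")

__all__ = [
    "AnalysisError",
    "QSeries",
    "FreeEnergyProfile",
    "CvCurve",
    "compute_q",
    "free_energy_profile",
    "specific_heat",
    "contact_formation_map",
    "compute_com_pca",
    "estimate_tf_from_profiles",
    "DEFAULT_Q_RATIO",
]

DEFAULT_Q_RATIO = 1.5
DEFAULT_N_BINS = 40


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Q
# ---------------------------------------------------------------------------


@dataclass
class QSeries:
    """Per-frame fraction of native contacts, in [0, 1]."""

    values: np.ndarray
    threshold_ratio: float
    contacts: ContactList

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise AnalysisError("Q values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def tsv(self) -> str:
        lines = ["frame\tQ"]
        lines += [f"{i}\t{v:.6f}" for i, v in enumerate(self.values)]
        return "\n".join(lines) + "\n"


def _formed_matrix(
    frames: np.ndarray, contacts: ContactList, ratio: float
) -> np.ndarray:
    """(n_frames, n_contacts) boolean matrix of formed contacts."""
    ci, cj, r0 = contacts.index_arrays()
    d = np.linalg.norm(frames[:, cj, :] - frames[:, ci, :], axis=2)
    return d <= ratio * r0


def compute_q(
    trajectory: Union[Trajectory, np.ndarray],
    contacts: ContactList,
    ratio: float = DEFAULT_Q_RATIO,
) -> QSeries:
    """Fraction of native pairs within ``ratio`` x native distance, per frame.

    Invariant under rigid rotations/translations of the frames.  Accepts a
    Trajectory or a raw (n_frames, n_atoms, 3) array.
    """
    if len(contacts) == 0:
        raise AnalysisError("cannot compute Q with an empty contact list")
    if ratio <= 1.0:
        raise AnalysisError(f"threshold ratio must exceed 1, got {ratio}")
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else np.asarray(trajectory)
    formed = _formed_matrix(frames, contacts, ratio)
    return QSeries(values=formed.mean(axis=1), threshold_ratio=ratio,
                   contacts=contacts)


# ---------------------------------------------------------------------------
# F(Q)
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergyProfile:
    """F(Q) = -ln P(Q) in k_B T, minimum shifted to 0.

    Defined only on visited bins; ``bin_indices`` records each entry's
    position in the original uniform binning so that unvisited gaps — which
    act as effectively infinite barriers — are recognized as such.
    """

    bin_centers: np.ndarray
    values: np.ndarray
    bin_indices: Optional[np.ndarray] = None

    def _indices(self) -> np.ndarray:
        if self.bin_indices is not None:
            return np.asarray(self.bin_indices)
        return np.arange(len(self.values))

    def minima(self) -> list[int]:
        """Local minima over visited bins; an unvisited gap counts as an
        infinitely high neighbour."""
        v = self.values
        idx = self._indices()
        out = []
        for i in range(len(v)):
            left = v[i - 1] if i > 0 and idx[i - 1] == idx[i] - 1 else np.inf
            right = (
                v[i + 1] if i < len(v) - 1 and idx[i + 1] == idx[i] + 1 else np.inf
            )
            if v[i] < left and v[i] <= right:
                out.append(i)
        return out

    def _barrier_between(self, i: int, j: int) -> tuple[float, float]:
        """(barrier height, barrier Q) between visited entries i < j; an
        unvisited gap is an infinite barrier located at the gap centre
        (ties resolved toward lower Q: the first maximum wins)."""
        idx = self._indices()
        best_val, best_q = -np.inf, float(self.bin_centers[i])
        for k in range(i, j):
            if self.values[k] > best_val:
                best_val = float(self.values[k])
                best_q = float(self.bin_centers[k])
            if idx[k + 1] != idx[k] + 1 and np.isfinite(best_val):
                gap_q = 0.5 * float(self.bin_centers[k] + self.bin_centers[k + 1])
                return np.inf, gap_q
        if self.values[j] > best_val:
            best_val = float(self.values[j])
            best_q = float(self.bin_centers[j])
        return best_val, best_q

    def is_bimodal(self, min_barrier: float = 0.3,
                   min_separation: float = 0.25) -> bool:
        """Two well-separated local minima (at least ``min_separation``
        apart in Q — folded vs unfolded basins, not sub-basins of one
        state) divided by a barrier of at least ``min_barrier`` k_B T
        measured from the shallower minimum."""
        mins = self.minima()
        best = 0.0
        for a in range(len(mins)):
            for b in range(a + 1, len(mins)):
                i, j = mins[a], mins[b]
                if abs(self.bin_centers[j] - self.bin_centers[i]) < min_separation:
                    continue
                barrier, _ = self._barrier_between(i, j)
                depth = barrier - max(self.values[i], self.values[j])
                best = max(best, depth)
        return best >= min_barrier

    def deepest_separated_minima(self, min_separation: float = 0.25) -> tuple[int, int]:
        """The deepest pair of local minima at least ``min_separation``
        apart in Q: the global minimum plus the deepest minimum of the
        other basin."""
        mins = self.minima()
        if len(mins) < 2:
            raise AnalysisError("profile has fewer than two minima")
        by_depth = sorted(mins, key=lambda i: self.values[i])
        first = by_depth[0]
        for cand in by_depth[1:]:
            if abs(self.bin_centers[cand] - self.bin_centers[first]) >= min_separation:
                return tuple(sorted((first, cand)))  # type: ignore[return-value]
        raise AnalysisError(
            "no pair of well-separated minima (single-basin profile)"
        )

    def barrier_top_between_deepest_minima(
        self, min_separation: float = 0.25
    ) -> float:
        """Q at the F maximum between the deepest well-separated minima
        (ties toward lower Q)."""
        i, j = self.deepest_separated_minima(min_separation)
        _, q = self._barrier_between(i, j)
        return q

    def tsv(self) -> str:
        lines = ["Q\tF_kT"]
        lines += [f"{q:.4f}\t{f:.6f}" for q, f in zip(self.bin_centers, self.values)]
        return "\n".join(lines) + "\n"


def free_energy_profile(
    q_series: Union[QSeries, np.ndarray],
    n_bins: int = DEFAULT_N_BINS,
) -> FreeEnergyProfile:
    """Histogram a Q series into F(Q) = -ln P(Q), min-shifted to zero.

    Only visited bins appear in the output; normalization cancels, so the
    profile is invariant under rescaling of P.
    """
    values = q_series.values if isinstance(q_series, QSeries) else np.asarray(q_series)
    if len(values) == 0:
        raise AnalysisError("empty Q series")
    if len(values) < n_bins:
        raise AnalysisError(
            f"series length {len(values)} is smaller than n_bins={n_bins}"
        )
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0 + 1e-12))
    centers = 0.5 * (edges[:-1] + edges[1:])
    visited = counts > 0
    f = -np.log(counts[visited].astype(float))
    f -= f.min()
    return FreeEnergyProfile(bin_centers=centers[visited], values=f,
                             bin_indices=np.where(visited)[0])


# ---------------------------------------------------------------------------
# Specific heat and T_F
# ---------------------------------------------------------------------------


@dataclass
class CvCurve:
    """Cv(T) from energy fluctuations; T_F at the interpolated peak."""

    temperatures: np.ndarray
    cv: np.ndarray
    t_f: float

    def tsv(self) -> str:
        lines = ["T\tCv"]
        lines += [f"{t:.6g}\t{c:.6g}" for t, c in zip(self.temperatures, self.cv)]
        return "\n".join(lines) + "\n"


def _quadratic_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Peak position by quadratic interpolation around the maximum sample."""
    k = int(np.argmax(y))
    if k == 0 or k == len(x) - 1:
        return float(x[k])
    a, b, _ = np.polyfit(x[k - 1:k + 2], y[k - 1:k + 2], 2)
    if a >= 0:
        return float(x[k])
    vertex = -b / (2.0 * a)
    # keep the interpolated peak inside the bracketing interval
    return float(min(max(vertex, x[k - 1]), x[k + 1]))


def specific_heat(
    energy_series_by_temperature: dict[float, np.ndarray],
    *,
    equal_area: bool = False,
) -> CvCurve:
    """Cv(T) = var(E) / T^2 per temperature (k_B = 1).

    ``equal_area`` rescales the curve to unit area (used when overlaying
    models of different sizes).  T_F is the quadratically interpolated peak.
    """
    if len(energy_series_by_temperature) < 3:
        raise AnalysisError("need energy series at >= 3 temperatures")
    temps = np.array(sorted(energy_series_by_temperature), dtype=float)
    cv = np.empty_like(temps)
    for idx, t in enumerate(temps):
        e = np.asarray(energy_series_by_temperature[float(t)], dtype=float)
        if e.size < 2:
            raise AnalysisError(f"energy series at T={t} has fewer than 2 frames")
        if t <= 0:
            raise AnalysisError("temperatures must be positive")
        cv[idx] = float(np.var(e)) / (t * t)
    if equal_area:
        area = float(np.trapezoid(cv, temps))
        if area > 0:
            cv = cv / area
    return CvCurve(temperatures=temps, cv=cv, t_f=_quadratic_peak(temps, cv))


def estimate_tf_from_profiles(
    q_series_by_temperature: dict[float, Union[QSeries, np.ndarray]],
    *,
    n_bins: int = DEFAULT_N_BINS,
    split_q: Optional[float] = None,
) -> float:
    """T_F from folded/unfolded population balance across temperatures.

    The basin split point is the F(Q) barrier top between the two deepest
    minima of the most bimodal temperature (ties toward lower Q), or
    ``split_q`` when given.  The folded population p_fold(T) is interpolated
    to p_fold = 1/2.  Raises when no temperature shows both basins.
    """
    temps = np.array(sorted(q_series_by_temperature), dtype=float)
    series = {
        float(t): (s.values if isinstance(s, QSeries) else np.asarray(s))
        for t, s in q_series_by_temperature.items()
    }
    if split_q is None:
        best = None
        for t in temps:
            try:
                prof = free_energy_profile(series[float(t)], n_bins)
                i, j = prof.deepest_separated_minima()
                # prefer the temperature where the shallower of the two
                # basins is deepest, i.e. the most evenly bimodal profile
                score = -max(prof.values[i], prof.values[j])
                if best is None or score > best[0]:
                    best = (score, prof)
            except AnalysisError:
                continue
        if best is None:
            raise AnalysisError(
                "no temperature shows a bimodal F(Q); cannot split basins"
            )
        split_q = best[1].barrier_top_between_deepest_minima()
    p_fold = np.array([np.mean(series[float(t)] > split_q) for t in temps])
    # p_fold decreases with T; find the 1/2 crossing by linear interpolation
    above = p_fold >= 0.5
    if above.all() or (~above).all():
        raise AnalysisError(
            f"temperatures {temps.tolist()} do not bracket the transition "
            f"(p_fold: {np.round(p_fold, 3).tolist()})"
        )
    k = int(np.where(above)[0][-1])
    # interpolate between the last folded-majority and next temperature
    t1, t2 = temps[k], temps[min(k + 1, len(temps) - 1)]
    p1, p2 = p_fold[k], p_fold[min(k + 1, len(temps) - 1)]
    if p1 == p2:
        return float(0.5 * (t1 + t2))
    return float(t1 + (0.5 - p1) * (t2 - t1) / (p2 - p1))


# ---------------------------------------------------------------------------
# Contact-formation maps
# ---------------------------------------------------------------------------


def contact_formation_map(
    trajectory: Union[Trajectory, np.ndarray],
    contacts: ContactList,
    q_series: Union[QSeries, np.ndarray],
    q_window: tuple[float, float],
    *,
    ratio: float = DEFAULT_Q_RATIO,
) -> np.ndarray:
    """Per-contact formation probability over frames with Q in a window.

    Returns an array aligned with ``contacts.entries``.  The formation
    criterion is the same distance-ratio test used for Q.  Difference maps
    between two ensembles are plain array subtraction on a shared contact
    list.
    """
    lo, hi = q_window
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else np.asarray(trajectory)
    q = q_series.values if isinstance(q_series, QSeries) else np.asarray(q_series)
    if len(q) != len(frames):
        raise AnalysisError("Q series and trajectory lengths differ")
    sel = (q >= lo) & (q <= hi)
    if not np.any(sel):
        raise AnalysisError(f"no frames with Q in [{lo}, {hi}]")
    formed = _formed_matrix(frames[sel], contacts, ratio)
    return formed.mean(axis=0)


def formation_map_tsv(contacts: ContactList, probs: np.ndarray) -> str:
    """Sparse three-column text: i j probability (1-based indices)."""
    lines = ["# i j probability"]
    for (i, j, _), p in zip(contacts.entries, probs):
        lines.append(f"{i + 1} {j + 1} {p:.6f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Domain center-of-mass PCA
# ---------------------------------------------------------------------------


def compute_com_pca(
    trajectory: Union[Trajectory, np.ndarray],
    domain_assignments: Sequence[int],
    masses: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the per-frame domain centers of mass.

    ``domain_assignments`` maps each atom to a domain id (0..D-1, every
    domain nonempty).  Per frame, the mass-weighted COM of each domain is
    computed; the pooled 3D-per-domain coordinates are mean-centered and the
    covariance eigendecomposition returned as (eigenvalues nm^2 descending,
    eigenvectors as columns).
    """
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else np.asarray(trajectory)
    if frames.shape[0] < 2:
        raise AnalysisError("COM PCA needs at least 2 frames")
    assign = np.asarray(domain_assignments, dtype=int)
    if assign.shape[0] != frames.shape[1]:
        raise AnalysisError("domain assignment length does not match atom count")
    n_dom = int(assign.max()) + 1
    if masses is None:
        masses = np.ones(frames.shape[1])
    coms = np.empty((frames.shape[0], n_dom, 3))
    for d in range(n_dom):
        sel = assign == d
        if not np.any(sel):
            raise AnalysisError(f"domain {d} is empty")
        w = masses[sel]
        coms[:, d, :] = np.einsum("fij,i->fj", frames[:, sel, :], w) / w.sum()
    flat = coms.reshape(frames.shape[0], n_dom * 3)
    flat = flat - flat.mean(axis=0, keepdims=True)
    cov = flat.T @ flat / (flat.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]
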