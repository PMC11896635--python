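"""Spin-diabatic characterization of surface hops and angle histograms.

A hop between two spin-adiabatic states is assigned fractional
spin-diabatic character by the product of squared expansion-coefficient
magnitudes: weight(i, j) = |U_i,from|^2 * |U_j,to|^2 for every pair of
spin-diabatic states (i from the initial, j from the final spin-adiabatic
state), after which the three components of each triplet are summed into
their parent triplet.  By unitarity each hop's weight matrix sums to 1,
so an ensemble's aggregated matrix sums to the number of (accepted) hops.

This hop-based bookkeeping misses diabatic-character transfer that occurs
continuously within a single active spin-adiabatic state, and diagonal
entries (from = to character) are an artifact of partial mixing; both are
inherent to the method, not bugs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .spin_mixing import sum_triplet_components

__all__ = [
    "HopCharacterMatrix",
    "AngleHistogram",
    "hop_character_weights",
    "aggregate_hop_characters",
    "singlet_outflux_fraction",
    "dihedral_angle",
    "occurrence_histogram",
]


@dataclass
class HopCharacterMatrix:
    """Non-negative (n_S + n_T) x (n_S + n_T) weights of one (or many) hops."""

    weights: np.ndarray
    n_singlets: int
    n_triplets: int

    def labels(self):
        return [f"S{i}" for i in range(self.n_singlets)] + [
            f"T{j + 1}" for j in range(self.n_triplets)
        ]


def hop_character_weights(
    u: np.ndarray,
    from_state: int,
    to_state: int,
    n_singlets: int,
    n_triplets: int,
    diagnostic: bool = False,
) -> HopCharacterMatrix:
    """Spin-diabatic character weights of one surface hop.

    ``u`` is the unitary eigenvector matrix at the hop geometry.  A
    from_state == to_state call is only permitted with ``diagnostic=True``
    (self-"hops" are a bookkeeping artifact of partial mixing).
    """
    if from_state == to_state and not diagnostic:
        raise ValueError("from == to requires diagnostic mode")
    p_from = np.abs(u[:, from_state]) ** 2
    p_to = np.abs(u[:, to_state]) ** 2
    w = np.outer(p_from, p_to)
    merged = sum_triplet_components(
        sum_triplet_components(w, n_singlets, n_triplets).T, n_singlets, n_triplets
    ).T
    return HopCharacterMatrix(weights=merged, n_singlets=n_singlets, n_triplets=n_triplets)


def aggregate_hop_characters(
    trajectories: Sequence,
    n_singlets: int,
    n_triplets: int,
    include_frustrated: bool = False,
) -> HopCharacterMatrix:
    """Sum hop-character matrices over an ensemble (accepted hops by default)."""
    n = n_singlets + n_triplets
    total = np.zeros((n, n))
    for traj in trajectories:
        for hop in traj.hops:
            if not hop.accepted and not include_frustrated:
                continue
            m = hop_character_weights(
                hop.u_at_hop, hop.from_state, hop.to_state, n_singlets, n_triplets
            )
            total += m.weights
    return HopCharacterMatrix(weights=total, n_singlets=n_singlets, n_triplets=n_triplets)


def singlet_outflux_fraction(
    trajectories: Sequence, n_singlets: int, n_triplets: int, source: str = "S1"
) -> float:
    """Fraction of a singlet's hop out-flux that ends in singlet states.

    Sums, over all accepted hops of an ensemble, the hop-character weight
    rows belonging to the source state and splits the total between
    singlet and triplet destination columns.  Used to partition a fitted
    S1 depletion rate into an internal-conversion part
    (k_IC = rate x fraction) and an ISC part; this hop-weight convention
    shares the limitations of hop-based counting noted above.
    Raises if the ensemble contains no accepted hops out of the source.
    """
    src = int(source[1:]) if source.upper().startswith("S") else int(source)
    to_singlet = 0.0
    total = 0.0
    for traj in trajectories:
        for hop in traj.hops:
            if not hop.accepted:
                continue
            m = hop_character_weights(
                hop.u_at_hop, hop.from_state, hop.to_state, n_singlets, n_triplets
            )
            row = m.weights[src]
            to_singlet += row[:n_singlets].sum() - row[src]
            total += row.sum() - row[src]
    if total <= 0:
        raise ValueError(f"no accepted hop out-flux from {source}")
    return to_singlet / total


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Dihedral angle of four points (Angstrom) in degrees, in [0, 360).

    Standard two-plane-normal construction with the convention that the
    trans-planar arrangement maps to 180 deg and cis-planar to 0 deg
    (matching dihedral-occurrence plots quoting a 170-186 deg range for
    near-planar frames).  Raises on collinear degeneracies.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("collinear points: dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    signed = np.degrees(np.arctan2(y, x))   # (-180, 180], 0 = cis, 180 = trans
    return float(signed % 360.0)


@dataclass
class AngleHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    label: str = ""


def occurrence_histogram(
    values_deg: Sequence[float],
    bin_width_deg: float = 1.0,
    weights: Optional[Sequence[float]] = None,
    label: str = "",
) -> AngleHistogram:
    """Frequency-of-occurrence histogram of angles with fixed bin width.

    The total of the counts (or of the summed weights) is preserved
    exactly.  Default bin width 1 degree.
    """
    if bin_width_deg <= 0:
        raise ValueError("bin width must be > 0")
    vals = np.asarray(values_deg, dtype=float)
    if vals.size == 0:
        raise ValueError("empty input")
    lo = np.floor(vals.min() / bin_width_deg) * bin_width_deg
    hi = np.ceil(vals.max() / bin_width_deg) * bin_width_deg
    if hi <= lo:
        hi = lo + bin_width_deg
    edges = np.arange(lo, hi + 0.5 * bin_width_deg, bin_width_deg)
    counts, _ = np.histogram(vals, bins=edges, weights=weights)
    return AngleHistogram(bin_edges=edges, counts=counts, label=label)
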