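"""Four-state weight-status transition structure and intensity-matrix algebra.

The model has four ordered states -- underweight (1), healthy weight (2),
overweight (3), obesity (4) -- and permits instantaneous movement only
between adjacent states, giving six allowed transitions.  Transition
probabilities over a finite interval follow from the matrix exponential of
the generator, so non-adjacent movements (e.g. healthy weight to obesity)
have positive probability over any positive interval even though the
corresponding instantaneous rate is structurally zero.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .errors import StructureError

N_STATES = 4

#: Ordinal state codes used in panel data (1-based, as in the CSV schema).
STATE_CODES = (1, 2, 3, 4)

STATE_NAMES = ("underweight", "healthy weight", "overweight", "obesity")

#: The six allowed instantaneous transitions, 0-based (row, col) pairs.
ADJACENT_TRANSITIONS = ((0, 1), (1, 0), (1, 2), (2, 1), (2, 3), (3, 2))


class TransitionStructure:
    """Adjacency of allowed instantaneous transitions among the four states.

    Attributes
    ----------
    allowed : (4, 4) bool ndarray
        ``allowed[r, s]`` is True iff the instantaneous rate r -> s may be
        nonzero.  The diagonal is always False.
    transitions : tuple of (int, int)
        The allowed off-diagonal index pairs, in fixed order.
    """

    def __init__(self, transitions=ADJACENT_TRANSITIONS):
        allowed = np.zeros((N_STATES, N_STATES), dtype=bool)
        for r, s in transitions:
            if r == s:
                raise StructureError("diagonal entries cannot be 'allowed'")
            allowed[r, s] = True
        self.allowed = allowed
        self.transitions = tuple(transitions)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def labels(self):
        """Human-readable 'from -> to' labels in transition order."""
        return [
            f"{STATE_NAMES[r]} -> {STATE_NAMES[s]}" for r, s in self.transitions
        ]

    def __eq__(self, other):
        return isinstance(other, TransitionStructure) and self.transitions == other.transitions

    def __repr__(self):
        return f"TransitionStructure({self.n_transitions} transitions)"


def build_structure() -> TransitionStructure:
    """Return the adjacent-only structure with its six allowed transitions."""
    return TransitionStructure(ADJACENT_TRANSITIONS)


def intensity_matrix(rates, structure: TransitionStructure | None = None) -> np.ndarray:
    """Assemble a generator matrix from per-transition rates.

    Parameters
    ----------
    rates : array-like, shape (n_transitions,)
        Non-negative per-year rates aligned with ``structure.transitions``.
    """
    structure = structure or build_structure()
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (structure.n_transitions,):
        raise StructureError(
            f"expected {structure.n_transitions} rates, got shape {rates.shape}"
        )
    if np.any(rates < 0) or not np.all(np.isfinite(rates)):
        raise StructureError("rates must be finite and non-negative")
    q = np.zeros((N_STATES, N_STATES))
    for (r, s), v in zip(structure.transitions, rates):
        q[r, s] = v
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def validate_intensity_matrix(q, structure: TransitionStructure | None = None) -> np.ndarray:
    """Check generator invariants; return q as a float ndarray.

    Off-diagonal entries must be non-negative, zero outside the allowed
    structure, and every row must sum to zero.
    """
    structure = structure or build_structure()
    q = np.asarray(q, dtype=float)
    if q.shape != (N_STATES, N_STATES):
        raise StructureError(f"intensity matrix must be 4x4, got {q.shape}")
    if not np.all(np.isfinite(q)):
        raise StructureError("intensity matrix has non-finite entries")
    off = ~np.eye(N_STATES, dtype=bool)
    if np.any(q[off] < 0):
        raise StructureError("off-diagonal intensities must be non-negative")
    if np.any(q[off & ~structure.allowed] != 0):
        raise StructureError("nonzero intensity on a disallowed transition")
    if np.any(np.abs(q.sum(axis=1)) > 1e-10):
        raise StructureError("rows of an intensity matrix must sum to zero")
    return q


def transition_probability_matrix(q, t: float,
                                  structure: TransitionStructure | None = None) -> np.ndarray:
    """P(t) = expm(Q t): state-occupancy probabilities after t years.

    Rows sum to one (up to 1e-10) and all entries lie in [0, 1]; P(0) is
    the identity.
    """
    if t < 0:
        raise ValueError("elapsed time must be non-negative")
    q = validate_intensity_matrix(q, structure)
    p = expm(q * float(t))
    # expm of a valid generator is stochastic up to roundoff; clip the dust
    p = np.clip(p, 0.0, 1.0)
    return p


def rates_from_matrix(q, structure: TransitionStructure | None = None) -> np.ndarray:
    """Extract the per-transition rate vector from a generator matrix."""
    structure = structure or build_structure()
    q = validate_intensity_matrix(q, structure)
    return np.array([q[r, s] for r, s in structure.transitions])
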