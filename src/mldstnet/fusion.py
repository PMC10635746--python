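"""Dempster-Shafer evidential fusion of two diagnostic probability sources.

Evidence about a mass is expressed as a *mass function* (basic probability
assignment) over three focal elements — {benign}, {malignant} and an
*ignorance* element — and two sources are pooled with Dempster's rule of
combination:

    m(A) = K * sum_{Ai ∩ Bj = A} m1(Ai) * m2(Bj),     K = 1 / (1 - k),

where the conflict coefficient ``k`` is the total mass product assigned to
pairs of focal elements with empty intersection.  The rule is undefined at
total conflict (k = 1).

Two readings of the ignorance element are supported:

``disjoint_singleton``
    Ignorance is a third mutually-exclusive class (a "normal / cannot tell"
    diagnosis).  Every cross-class product, including those involving
    ignorance, contributes to ``k``; the combination is the normalized
    elementwise product.  This is the package default.

``classical_ds``
    Ignorance is the whole frame Θ = {benign, malignant}, the classical
    Dempster-Shafer vacuous element.  Only benign x malignant products
    conflict, and a vacuous source (all mass on Θ) is the identity of the
    rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, TotalConflictError
from .phantom import CLASSES

__all__ = [
    "Frame",
    "DISJOINT_SINGLETON",
    "CLASSICAL_DS",
    "MassFunction",
    "FusionResult",
    "probs_to_mass",
    "conflict",
    "combine",
    "combine_many",
    "fuse_sources",
]

_MASS_TOL = 1e-9
#: Class order of mass vectors; "ignorant" labels map to the ignorance element.
_ELEMENTS = ("benign", "malignant", "ignorance")


@dataclass(frozen=True)
class Frame:
    """Frame of discernment: the hypotheses and the reading of ignorance.

    ``variant`` is ``"disjoint_singleton"`` (three pairwise-disjoint
    hypotheses) or ``"classical_ds"`` (ignorance = Θ = {benign, malignant}).
    """

    variant: str = "disjoint_singleton"

    def __post_init__(self) -> None:
        if self.variant not in ("disjoint_singleton", "classical_ds"):
            raise ContractError(f"unknown frame variant {self.variant!r}")

    @property
    def hypotheses(self) -> tuple[str, ...]:
        return _ELEMENTS


DISJOINT_SINGLETON = Frame("disjoint_singleton")
CLASSICAL_DS = Frame("classical_ds")


@dataclass(frozen=True)
class MassFunction:
    """Masses over the focal elements {benign}, {malignant}, ignorance.

    Nonnegative, summing to 1 (validated to 1e-9).
    """

    benign: float
    malignant: float
    ignorance: float

    def __post_init__(self) -> None:
        v = self.as_array()
        if np.any(v < -_MASS_TOL):
            raise ContractError(f"masses must be nonnegative, got {tuple(v)}")
        if abs(v.sum() - 1.0) > _MASS_TOL:
            raise ContractError(f"masses must sum to 1, got sum {v.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.benign, self.malignant, self.ignorance], dtype=float)

    @staticmethod
    def from_array(v) -> "MassFunction":
        v = np.asarray(v, dtype=float)
        return MassFunction(float(v[0]), float(v[1]), float(v[2]))

    def argmax_label(self) -> str:
        return _ELEMENTS[int(np.argmax(self.as_array()))]


@dataclass(frozen=True)
class FusionResult:
    """Outcome of one Dempster combination."""

    mass: MassFunction
    k: float          # conflict coefficient, in [0, 1)
    decided: str      # argmax focal element (ties: benign < malignant < ignorance)
    tie: bool = False
    conflict_flag: bool = False  # set when total conflict forced a fallback decision

    @property
    def K(self) -> float:
        """Normalization factor K = 1/(1-k)."""
        return 1.0 / (1.0 - self.k)


def probs_to_mass(probs) -> MassFunction:
    """Map a classifier probability triple to a mass function (identity).

    The triple order is (p_benign, p_malignant, p_ignorant); it is
    renormalized if its sum drifts from 1.
    """
    v = np.asarray(probs, dtype=float)
    if v.shape != (3,):
        raise ContractError(f"expected a probability triple, got shape {v.shape}")
    if np.any(v < 0):
        raise ContractError(f"probabilities must be nonnegative, got {tuple(v)}")
    s = v.sum()
    if s <= 0:
        raise ContractError("probability triple sums to 0")
    return MassFunction.from_array(v / s)


def _pairwise_products(m1: MassFunction, m2: MassFunction) -> np.ndarray:
    return np.outer(m1.as_array(), m2.as_array())


def conflict(m1: MassFunction, m2: MassFunction, frame: Frame = DISJOINT_SINGLETON) -> float:
    """Conflict coefficient ``k``: mass product on empty-intersection pairs."""
    prod = _pairwise_products(m1, m2)
    if frame.variant == "disjoint_singleton":
        # every cross-element pair is empty
        k = prod.sum() - np.trace(prod)
    else:
        # ignorance = Θ intersects everything; only {B} x {M} pairs are empty
        k = prod[0, 1] + prod[1, 0]
    return float(min(max(k, 0.0), 1.0))


def _decide(mass_vec: np.ndarray) -> tuple[str, bool]:
    idx = int(np.argmax(mass_vec))  # argmax takes the first maximum: fixed order
    tie = bool(np.sum(mass_vec == mass_vec[idx]) > 1)
    return _ELEMENTS[idx], tie


def combine(
    m1: MassFunction, m2: MassFunction, frame: Frame = DISJOINT_SINGLETON
) -> FusionResult:
    """Dempster's rule: ``m = m1 (+) m2`` with conflict renormalization.

    Raises
    ------
    TotalConflictError
        At total conflict (k = 1), naming both sources' argmax elements.
    """
    prod = _pairwise_products(m1, m2)
    k = conflict(m1, m2, frame)
    if 1.0 - k <= _MASS_TOL:
        raise TotalConflictError(m1.argmax_label(), m2.argmax_label())
    if frame.variant == "disjoint_singleton":
        num = np.diag(prod)
    else:
        b = prod[0, 0] + prod[0, 2] + prod[2, 0]
        m = prod[1, 1] + prod[1, 2] + prod[2, 1]
        theta = prod[2, 2]
        num = np.array([b, m, theta])
    combined = num / num.sum()  # exact renormalization (num.sum() == 1-k)
    decided, tie = _decide(combined)
    return FusionResult(
        mass=MassFunction.from_array(combined), k=k, decided=decided, tie=tie
    )


def combine_many(masses: list[MassFunction], frame: Frame = DISJOINT_SINGLETON) -> FusionResult:
    """Left fold of :func:`combine` over one or more mass functions.

    In the ``classical_ds`` frame the rule is associative and the fold order
    is immaterial; in ``disjoint_singleton`` it is also associative (the
    unnormalized combination is an elementwise product).
    """
    if not masses:
        raise ContractError("combine_many needs at least one mass function")
    if len(masses) == 1:
        decided, tie = _decide(masses[0].as_array())
        return FusionResult(mass=masses[0], k=0.0, decided=decided, tie=tie)
    result = combine(masses[0], masses[1], frame)
    for m in masses[2:]:
        result = combine(result.mass, m, frame)
    return result


def fuse_sources(
    probs1, probs2, frame: Frame = DISJOINT_SINGLETON
) -> tuple[np.ndarray, list[FusionResult]]:
    """Per-sample fusion of two aligned probability-source outputs.

    Parameters
    ----------
    probs1, probs2 : array-like, shape (n, 3)
        Probability triples from the two sources, aligned by sample.
    frame : Frame

    Returns
    -------
    (decided_labels, results)
        ``decided_labels`` uses the class vocabulary (``ignorant`` for the
        ignorance element).  A sample in total conflict is decided by the
        single source with the higher committed mass and its result carries
        ``conflict_flag=True``.
    """
    p1 = np.asarray(probs1, dtype=float)
    p2 = np.asarray(probs2, dtype=float)
    if p1.shape != p2.shape:
        raise ContractError(f"source shapes differ: {p1.shape} vs {p2.shape}")
    if p1.ndim != 2 or p1.shape[1] != 3:
        raise ContractError(f"expected (n, 3) probability arrays, got {p1.shape}")
    results: list[FusionResult] = []
    labels: list[str] = []
    for row1, row2 in zip(p1, p2):
        m1 = probs_to_mass(row1)
        m2 = probs_to_mass(row2)
        try:
            res = combine(m1, m2, frame)
        except TotalConflictError:
            # fall back to the more committed single source, flagged
            winner = m1 if m1.as_array().max() >= m2.as_array().max() else m2
            decided, tie = _decide(winner.as_array())
            res = FusionResult(
                mass=winner, k=1.0 - _MASS_TOL, decided=decided, tie=tie,
                conflict_flag=True,
            )
        results.append(res)
        labels.append(CLASSES[_ELEMENTS.index(res.decided)])
    return np.array(labels), results
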