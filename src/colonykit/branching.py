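"""Analytic branching-process model of abortive colony formation.

A single plated cell starts a synchronized binary branching process: at each
generation ``g`` a cell either undergoes reproductive cell death (RCD) with
probability ``P1(g)`` or divides into two generation ``g+1`` daughters with
probability ``P2(g) = 1 - P1(g)``.  A colony whose every lineage has died by
the generation horizon ``g_max`` is *abortive*; its final size ``n`` equals
the number of RCD cells, i.e. the number of leaves of the binary lineage
tree.  A lineage tree with ``n`` leaves has exactly ``n - 1`` internal nodes
(divisions), so for a generation-independent death probability ``p`` the
probability of an abortive colony of size ``n`` is

    f_n = C(n-1) * p**n * (1-p)**(n-1)

with ``C(m)`` the Catalan numbers counting full binary tree shapes.  For a
generation-dependent schedule the pmf follows the recursion

    q_g(n) = P1(g)           if n == 1
    q_g(n) = (1 - P1(g)) * sum_{k=1}^{n-1} q_{g+1}(k) * q_{g+1}(n-k)

truncated at ``g_max``: colonies still holding a proliferative cell at the
horizon are excluded (no renormalization), matching fixed-time colony
scoring in the clonogenic assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import DomainError, NoRootError

__all__ = [
    "P1Schedule",
    "ColonySizeDistribution",
    "F1Estimate",
    "pmf_constant",
    "pmf_schedule",
    "survivor_mass",
    "estimate_f1_from_f2",
]

#: maximum of (1-p) * p**2 over p in [0, 1], attained at p = 2/3
F2_MAX = 4.0 / 27.0


@dataclass(frozen=True)
class P1Schedule:
    """Death probability per generation, ``probs[g] = P1(g)`` for g=0..g_max.

    Parameters
    ----------
    probs
        Sequence of RCD probabilities, one per generation, each in [0, 1].
    c
        Optional tail-slope parameter in [0, 1].  When set, the schedule is
        expected to satisfy ``probs[g_max] == (1 - c) * probs[5]`` with the
        generations 6..g_max on the straight line between ``probs[5]`` and
        ``probs[g_max]`` (see :func:`colonykit.estimation.build_schedule`).
    """

    probs: np.ndarray
    c: float | None = None

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1 or probs.size == 0:
            raise DomainError("schedule must be a non-empty 1-D sequence")
        if np.any(probs < 0) or np.any(probs > 1) or not np.all(np.isfinite(probs)):
            raise DomainError("every P1(g) must lie in [0, 1]")
        object.__setattr__(self, "probs", probs)
        if self.c is not None:
            c = float(self.c)
            if not 0.0 <= c <= 1.0:
                raise DomainError(f"tail slope c={c} outside [0, 1]")
            if probs.size < 7:
                raise DomainError("a tail slope requires g_max >= 6")
            g_max = probs.size - 1
            g = np.arange(6, g_max + 1)
            expected = probs[5] * (1.0 - c * (g - 5) / (g_max - 5))
            if not np.allclose(probs[6:], expected, atol=1e-9):
                raise DomainError("probs[6..g_max] do not lie on the c-tail line")

    @property
    def g_max(self) -> int:
        return self.probs.size - 1

    @classmethod
    def constant(cls, p: float, g_max: int = 16) -> "P1Schedule":
        """Generation-independent schedule with ``P1(g) = p`` for all g."""
        if not 0.0 <= p <= 1.0:
            raise DomainError(f"p={p} outside [0, 1]")
        return cls(np.full(g_max + 1, float(p)))

    def __len__(self) -> int:
        return self.probs.size


@dataclass
class ColonySizeDistribution:
    """Per-dose frequencies (percent of scored colonies) of colonies with n cells.

    ``entries`` maps colony size ``n`` (cells, >= 1) to frequency in percent.
    ``f1_estimated`` marks the n=1 entry as inferred from the 2-cell class
    rather than observed (single cells are not scored in the assay).
    ``counts`` optionally carries the raw colony counts; when present together
    with ``total``, frequencies must equal ``100 * count / total``.
    """

    dose: str
    entries: dict[int, float]
    f1_estimated: bool = False
    counts: dict[int, int] | None = None
    total: int | None = None

    def __post_init__(self):
        self.dose = str(self.dose)
        entries = {}
        for n, f in self.entries.items():
            n = int(n)
            if n < 1:
                raise DomainError(f"colony size n={n} must be a positive integer")
            if n in entries:
                raise DomainError(f"duplicate colony size n={n}")
            f = float(f)
            if f < 0 or not np.isfinite(f):
                raise DomainError(f"frequency for n={n} must be finite and >= 0")
            entries[n] = f
        self.entries = dict(sorted(entries.items()))
        if self.counts is not None:
            for n, k in self.counts.items():
                if int(k) < 0:
                    raise DomainError(f"count for n={n} must be >= 0")
            if self.total is not None:
                for n, k in self.counts.items():
                    if n in self.entries and not np.isclose(
                        self.entries[n], 100.0 * k / self.total, atol=1e-3
                    ):
                        raise DomainError(
                            f"frequency for n={n} inconsistent with count under "
                            f"declared denominator {self.total}"
                        )

    @property
    def sizes(self) -> np.ndarray:
        return np.array(sorted(self.entries), dtype=int)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([self.entries[n] for n in sorted(self.entries)], dtype=float)


def pmf_constant(p: float, n_max: int) -> np.ndarray:
    """Abortive-colony size pmf for a generation-independent death probability.

    Returns ``f[n-1] = C(n-1) p^n (1-p)^(n-1)`` for n = 1..n_max, the
    probability that one plated cell yields a fully extinct colony of exactly
    ``n`` cells (no generation horizon).  The total over all n (n -> inf)
    equals the extinction probability ``min(1, p / (1 - p))``.
    """
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p={p} outside [0, 1]")
    if n_max < 1:
        raise DomainError("n_max must be >= 1")
    n = np.arange(1, n_max + 1)
    if p == 0.0:
        return np.zeros(n_max)
    if p == 1.0:
        out = np.zeros(n_max)
        out[0] = 1.0
        return out
    m = n - 1
    log_catalan = gammaln(2 * m + 1) - gammaln(m + 2) - gammaln(m + 1)
    return np.exp(log_catalan + n * np.log(p) + m * np.log1p(-p))


def pmf_schedule(schedule: P1Schedule, n_max: int) -> np.ndarray:
    """Abortive-colony size pmf under a generation-dependent schedule.

    Evaluates the lineage-tree recursion truncated at ``schedule.g_max``;
    mass not returned corresponds to colonies with at least one proliferative
    lineage at the horizon, or to sizes above ``n_max``.
    """
    if n_max < 1:
        raise DomainError("n_max must be >= 1")
    probs = schedule.probs
    # deepest generation: a cell at g_max may still die but can no longer divide
    q = np.zeros(n_max)
    q[0] = probs[-1]
    for g in range(schedule.g_max - 1, -1, -1):
        conv = np.convolve(q, q)[: n_max - 1] if n_max > 1 else np.empty(0)
        nxt = np.empty(n_max)
        nxt[0] = probs[g]
        nxt[1:] = (1.0 - probs[g]) * conv
        q = nxt
    return q


def survivor_mass(schedule: P1Schedule) -> float:
    """Probability that a plated cell still has a proliferative lineage at g_max.

    Complement of extinction within the horizon, computed by the exact
    backward recursion ``e_g = P1(g) + (1 - P1(g)) * e_{g+1}**2`` with
    ``e_{g_max} = P1(g_max)``; survivor mass is ``1 - e_0``.
    """
    e = schedule.probs[-1]
    for g in range(schedule.g_max - 1, -1, -1):
        p = schedule.probs[g]
        e = p + (1.0 - p) * e * e
    return float(min(1.0, max(0.0, 1.0 - e)))


@dataclass(frozen=True)
class F1Estimate:
    """Result of inferring the 1-cell frequency from the 2-cell frequency."""

    f1: float
    p: float
    roots: tuple[float, float]  # both roots of (1-p) p^2 = f2 in [0, 1]
    f2: float


def estimate_f1_from_f2(f2: float, hint: str = "smaller") -> F1Estimate:
    """Infer the unobserved 1-cell colony frequency from the 2-cell frequency.

    Single cells are not scored in the assay, so the 1-cell class is inferred
    by assuming the same death probability ``p`` for the first two
    generations: a 2-cell abortive colony requires one division and two
    deaths, ``f2 = (1 - p) * p**2``, while ``f1 = p``.  The cubic has two
    roots in [0, 1] whenever ``0 < f2 < 4/27``; both are reported and the one
    selected follows ``hint`` ("smaller", the default consistent with
    observed sub-50% 1-cell frequencies, or "larger").

    ``f2`` must be on the probability scale (0.125, not 12.5%).
    """
    from scipy.optimize import brentq

    if hint not in ("smaller", "larger"):
        raise DomainError(f"unknown root hint {hint!r}")
    if f2 < 0:
        raise DomainError(f"f2={f2} must be >= 0")
    if f2 > F2_MAX + 1e-12:
        raise NoRootError(
            f"f2={f2} exceeds the maximum (1-p)p^2 = 4/27 ~ {F2_MAX:.6f}; no root"
        )
    f2 = min(f2, F2_MAX)

    def g(p):
        return (1.0 - p) * p * p - f2

    if f2 == 0.0:
        roots = (0.0, 1.0)
    elif g(2.0 / 3.0) <= 0.0:  # f2 at (or numerically at) the maximum
        roots = (2.0 / 3.0, 2.0 / 3.0)
    else:
        roots = (brentq(g, 0.0, 2.0 / 3.0), brentq(g, 2.0 / 3.0, 1.0))
    p = roots[0] if hint == "smaller" else roots[1]
    return F1Estimate(f1=p, p=p, roots=roots, f2=f2)
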