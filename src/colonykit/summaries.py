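"""Colony classification, binned frequencies, SQD, surviving fraction, tests.

Assay conventions: a 1-cell "colony" is not scored; colonies with 2-49
cells are *abortive*; colonies with >= 50 cells are *clonogenic* (survivors).
Binned comparisons between simulated and observed distributions use the
fixed size classes 2-7, 8-15, 16-49 and >= 50 cells, as percentages of
colonies with >= 2 cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError
from .lattice import SimulationResult

__all__ = [
    "BIN_EDGES",
    "BinnedFrequencies",
    "SurvivingFraction",
    "ChiSquareResult",
    "classify_colony",
    "bin_frequencies",
    "sqd",
    "surviving_fraction",
    "chi_square_bonferroni",
]

#: inclusive (lo, hi) cell-count edges of the comparison bins
BIN_EDGES = ((2, 7), (8, 15), (16, 49), (50, np.inf))
BIN_LABELS = ("2-7", "8-15", "16-49", ">=50")

CLONOGENIC_MIN = 50


@dataclass(frozen=True)
class BinnedFrequencies:
    """Percent of >= 2-cell colonies per fixed size bin (sums to 100)."""

    values: np.ndarray
    n_colonies: int  # denominator: colonies with >= 2 cells

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(BIN_EDGES),):
            raise DomainError(f"expected {len(BIN_EDGES)} bin values")
        if np.any(values < 0):
            raise DomainError("bin percentages must be >= 0")
        if abs(values.sum() - 100.0) > 1e-6:
            raise DomainError("bin percentages must sum to 100")
        object.__setattr__(self, "values", values)


def classify_colony(n: int) -> str:
    """Classify a colony by final cell count: single, abortive or clonogenic."""
    n = int(n)
    if n < 1:
        raise DomainError(f"colony size n={n} must be >= 1")
    if n == 1:
        return "single"
    if n < CLONOGENIC_MIN:
        return "abortive"
    return "clonogenic"


def bin_frequencies(final_sizes) -> BinnedFrequencies:
    """Bin colony sizes into the fixed classes, as percent of >= 2-cell colonies."""
    sizes = np.asarray(final_sizes, dtype=int)
    if sizes.size and sizes.min() < 1:
        raise DomainError("colony sizes must be >= 1")
    scored = sizes[sizes >= 2]
    if scored.size == 0:
        raise DomainError("no colonies with >= 2 cells: empty denominator")
    counts = np.array([
        np.count_nonzero((scored >= lo) & (scored <= hi))
        for lo, hi in BIN_EDGES
    ], dtype=float)
    return BinnedFrequencies(values=100.0 * counts / scored.size,
                             n_colonies=int(scored.size))


def sqd(sim, obs, skip_zero_obs: bool = False, bins=None) -> float:
    """Square of the difference between simulated and observed bin frequencies.

    SQD = sum over bins of ((f_sim - f_obs) / f_obs * 100)**2, in arbitrary
    units.  Not symmetric: the observed frequencies set the denominator.
    Accepts :class:`BinnedFrequencies` or plain percentage arrays of equal
    length.  A zero observed bin makes a term undefined; opt in to
    ``skip_zero_obs`` to drop such bins, otherwise they raise.  ``bins``
    optionally restricts the sum to a subset of bin indices.
    """
    f_sim = np.asarray(getattr(sim, "values", sim), dtype=float)
    f_obs = np.asarray(getattr(obs, "values", obs), dtype=float)
    if f_sim.shape != f_obs.shape:
        raise DomainError("simulated and observed bins do not match")
    idx = np.arange(f_sim.size) if bins is None else np.asarray(bins, int)
    f_sim, f_obs = f_sim[idx], f_obs[idx]
    zero = f_obs == 0
    if np.any(zero):
        if not skip_zero_obs:
            raise DomainError(
                f"observed frequency is zero in bin index(es) {idx[zero].tolist()};"
                " term undefined"
            )
        f_sim, f_obs = f_sim[~zero], f_obs[~zero]
    return float(np.sum(((f_sim - f_obs) / f_obs * 100.0) ** 2))


@dataclass(frozen=True)
class SurvivingFraction:
    value: float
    per_set: np.ndarray  # paired per-set ratios (NaN where a control set is 0)
    dose_clonogenic: int
    control_clonogenic: int

    @property
    def sd(self) -> float:
        ok = np.isfinite(self.per_set)
        return float(np.std(self.per_set[ok], ddof=1)) if ok.sum() > 1 else np.nan


def surviving_fraction(batch_dose: SimulationResult,
                       batch_control: SimulationResult) -> SurvivingFraction:
    """Clonogenic colonies from irradiated cells relative to unirradiated ones.

    Ratio of total >= 50-cell colony counts; per-set ratios (paired by set
    index) are retained for dispersion estimates.
    """
    dose_counts = batch_dose.clonogenic_counts()
    ctrl_counts = batch_control.clonogenic_counts()
    if ctrl_counts.sum() == 0:
        raise DomainError("control batch has no clonogenic colonies")
    n = min(dose_counts.size, ctrl_counts.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_set = np.where(ctrl_counts[:n] > 0,
                           dose_counts[:n] / ctrl_counts[:n], np.nan)
    return SurvivingFraction(
        value=float(dose_counts.sum() / ctrl_counts.sum()),
        per_set=per_set,
        dose_clonogenic=int(dose_counts.sum()),
        control_clonogenic=int(ctrl_counts.sum()),
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    p_corrected: float
    dof: int


def chi_square_bonferroni(obs_counts, sim_proportions,
                          n_tests: int = 1) -> ChiSquareResult:
    """Pearson chi-square of observed bin counts against simulated proportions.

    Expected counts are the simulated proportions scaled to the observed
    total; the simulated proportions are treated as fixed (their sampling
    error is ignored), giving bins - 1 degrees of freedom.  The Bonferroni
    correction multiplies the raw p-value by ``n_tests`` (capped at 1).
    """
    obs = np.asarray(obs_counts, dtype=float)
    props = np.asarray(sim_proportions, dtype=float)
    if obs.shape != props.shape:
        raise DomainError("observed counts and simulated proportions differ in shape")
    if n_tests < 1:
        raise DomainError("n_tests must be >= 1")
    if np.any(props <= 0):
        raise DomainError("zero expected count in a bin: chi-square degenerate")
    expected = props / props.sum() * obs.sum()
    statistic, p = stats.chisquare(obs, expected)
    return ChiSquareResult(statistic=float(statistic), p_value=float(p),
                           p_corrected=float(min(1.0, p * n_tests)),
                           dof=obs.size - 1)
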