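"""Log-linear and log-log regression of colony-size frequency data.

Two line families are fitted by ordinary least squares on decadic-log
transformed frequencies:

* ``log_linear``:  log10 y = a * n + b        (exponential size decay)
* ``log_log``:     log10 y = a * log10 n + b  (power-law size decay)

and compared with a least-squares Akaike Information Criterion,
``AIC = N * ln(RSS / N) + 2 K`` with K = 3 (slope, intercept, residual
variance).  The inferred 1-cell point may enter the fit but never the AIC,
since it is model-derived rather than observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .branching import ColonySizeDistribution
from .errors import DomainError, IncomparableFitsError, InsufficientDataError

__all__ = [
    "RegressionFit",
    "ModelSelection",
    "fit_size_distribution",
    "confidence_band",
    "aic_compare",
]

FAMILIES = ("log_linear", "log_log")
_K_PARAMS = 3  # slope, intercept, residual variance


def _transform_x(family: str, n: np.ndarray) -> np.ndarray:
    if family == "log_linear":
        return np.asarray(n, dtype=float)
    if family == "log_log":
        return np.log10(np.asarray(n, dtype=float))
    raise DomainError(f"unknown family {family!r}; expected one of {FAMILIES}")


@dataclass(eq=False)
class RegressionFit:
    """One fitted line family on the transformed axes.

    ``a`` and ``b`` are the slope and intercept of ``log10 y`` against the
    family's abscissa; ``r2`` and ``aic`` are computed on that scale.
    ``aic_sizes`` records which colony sizes entered the AIC (the estimated
    1-cell class is always excluded), so selections are only made between
    fits sharing the same observation set.
    """

    family: str
    a: float
    b: float
    r2: float
    aic: float
    n_points: int
    aic_sizes: tuple[int, ...] = ()
    sizes: tuple[int, ...] = ()
    _ols: object | None = field(default=None, repr=False)

    @classmethod
    def from_params(cls, family: str, a: float, b: float) -> "RegressionFit":
        """Build a fit object from known line parameters (no data attached).

        Useful for evaluating a published regression line; prediction works
        but the confidence band is undefined (``n_points = 0``).
        """
        if family not in FAMILIES:
            raise DomainError(f"unknown family {family!r}")
        return cls(family=family, a=float(a), b=float(b), r2=np.nan,
                   aic=np.nan, n_points=0)

    def predict(self, n) -> np.ndarray:
        """Mean frequency at colony size(s) ``n``, on the original scale."""
        x = _transform_x(self.family, np.atleast_1d(n))
        return np.power(10.0, self.a * x + self.b)


@dataclass(frozen=True)
class ModelSelection:
    selected: RegressionFit
    tie: bool
    aics: dict


def fit_size_distribution(
    dist: ColonySizeDistribution,
    family: str = "log_log",
    include_f1: bool = True,
) -> RegressionFit:
    """OLS fit of one line family to a colony-size frequency distribution.

    The n=1 entry is dropped from the fit when ``include_f1`` is false; an
    *estimated* n=1 entry is additionally always excluded from the AIC.
    Frequencies must be strictly positive (log transform).
    """
    sizes = dist.sizes
    freqs = dist.frequencies
    if np.any(freqs <= 0):
        raise DomainError("all frequencies must be strictly positive for a log fit")
    keep = np.ones(sizes.size, dtype=bool)
    if not include_f1:
        keep &= sizes != 1
    sizes, freqs = sizes[keep], freqs[keep]
    if sizes.size < 3:
        raise InsufficientDataError(
            f"need >= 3 positive points, got {sizes.size}"
        )
    x = _transform_x(family, sizes)
    y = np.log10(freqs)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    b, a = res.params
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss < 1e-300 else float(res.rsquared)

    aic_mask = np.ones(sizes.size, dtype=bool)
    if dist.f1_estimated:
        aic_mask &= sizes != 1
    resid = y[aic_mask] - (a * x[aic_mask] + b)
    n_aic = int(aic_mask.sum())
    rss = max(float(np.sum(resid**2)), 1e-300)
    aic = n_aic * np.log(rss / n_aic) + 2 * _K_PARAMS

    return RegressionFit(
        family=family, a=float(a), b=float(b), r2=r2, aic=float(aic),
        n_points=int(sizes.size), aic_sizes=tuple(int(s) for s in sizes[aic_mask]),
        sizes=tuple(int(s) for s in sizes), _ols=res,
    )


def confidence_band(fit: RegressionFit, n, level: float = 0.95):
    """95% (by default) confidence limits of the mean frequency at size(s) n.

    Student-t band for the mean response on the transformed scale,
    back-transformed to frequencies; width is minimal at the centroid of the
    design points.  Undefined for fits carrying fewer than 3 points.
    """
    if fit.n_points < 3 or fit._ols is None:
        raise InsufficientDataError("confidence band requires a fit with >= 3 points")
    if not 0.0 < level < 1.0:
        raise DomainError("level must lie in (0, 1)")
    n_arr = np.atleast_1d(np.asarray(n, dtype=float))
    if np.any(n_arr < 1):
        raise DomainError("colony size must be >= 1")
    x = _transform_x(fit.family, n_arr)
    pred = fit._ols.get_prediction(sm.add_constant(x, has_constant="add"))
    lo, hi = pred.conf_int(alpha=1.0 - level).T
    return np.power(10.0, lo), np.power(10.0, hi)


def aic_compare(fits, order=None) -> ModelSelection:
    """Select the fit with the minimal AIC among comparable fits.

    All fits must share the same AIC observation set (same colony sizes).
    Ties select the first family in ``order`` (default: the order in which
    the fits are given) and are flagged.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise DomainError("need at least two fits to compare")
    ref = fits[0].aic_sizes
    if any(f.aic_sizes != ref for f in fits[1:]):
        raise IncomparableFitsError("fits cover different observation sets")
    if order is not None:
        rank = {fam: i for i, fam in enumerate(order)}
        fits = sorted(fits, key=lambda f: rank.get(f.family, len(rank)))
    best = min(fits, key=lambda f: f.aic)
    tie = sum(f.aic == best.aic for f in fits) > 1
    if tie:  # deterministic: first in declared order wins
        best = next(f for f in fits if f.aic == best.aic)
    return ModelSelection(selected=best, tie=tie,
                          aics={f.family: f.aic for f in fits})
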