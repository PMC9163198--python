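"""Year-to-year community synchrony index eta.

eta is the mean, over the n units of a community, of the Pearson correlation
between each unit's yearly series and the summed series of all the other
units:

    eta = (1/n) * sum_i Corr(X_i, sum_{j != i} X_j)

It ranges from -1 (perfect compensation: the community total is constant)
through 0 (independent fluctuations on average) to +1 (complete synchrony),
and unlike variance-ratio style statistics it does not drift with community
richness n.  With exactly two units it reduces to the plain correlation of
the two series.

Significance is assessed against surrogate communities in which
cross-correlations are destroyed while each unit's own temporal structure is
kept (see :mod:`commsync.surrogates`): circular (toroidal) shifts for
many-unit communities, IAAFT for two-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_data import SeasonalSeries
from . import surrogates as _surr

__all__ = ["EtaResult", "eta", "eta_between", "eta_test"]


@dataclass(frozen=True)
class EtaResult:
    """Outcome of one eta computation."""

    eta: float
    n_units: int
    n_years: int
    season: str | None = None
    period: str | None = None
    dropped_units: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.eta <= 1.0 + 1e-12:
            raise ValueError(f"eta out of [-1, 1]: {self.eta}")


def _as_matrix(series) -> tuple[np.ndarray, list[str], str | None, str | None]:
    if isinstance(series, SeasonalSeries):
        return series.values, series.units, series.season, series.period
    if isinstance(series, pd.DataFrame):
        return series.to_numpy(dtype=float), [str(c) for c in series.columns], None, None
    X = np.asarray(series, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a (n_years, n_units) array")
    return X, [f"u{i+1}" for i in range(X.shape[1])], None, None


def eta_stat(X: np.ndarray) -> float:
    """eta on a (n_years, n_units) array whose columns all vary.

    Low-level kernel without zero-variance screening; most callers want
    :func:`eta`.
    """
    return float(eta_stat_batch(X[None, :, :])[0])


def eta_stat_batch(X: np.ndarray) -> np.ndarray:
    """Vectorized eta over a batch of communities, shape (B, n_years, n_units).

    Used for surrogate ensembles and Monte-Carlo calibration where thousands
    of small communities are scored.
    """
    X = np.asarray(X, dtype=float)
    others = X.sum(axis=2, keepdims=True) - X
    Xc = X - X.mean(axis=1, keepdims=True)
    Oc = others - others.mean(axis=1, keepdims=True)
    num = (Xc * Oc).sum(axis=1)
    den = np.sqrt((Xc**2).sum(axis=1) * (Oc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / den
    # a unit whose complement is exactly constant has an undefined
    # correlation; exclude it from the average rather than poison it
    return np.nanmean(corr, axis=1)


def eta(series, *, min_years: int = 3) -> EtaResult:
    """Community synchrony index eta.

    Units with zero temporal variance (e.g. species never seen in this
    season) have no defined correlation; they are removed from the community
    before the index is computed and reported in ``dropped_units``.

    Parameters
    ----------
    series
        A :class:`~commsync.community_data.SeasonalSeries`, DataFrame or
        (n_years, n_units) array of yearly values.

    Raises
    ------
    ValueError
        If fewer than two units vary, or fewer than ``min_years`` years.
    """
    X, units, season, period = _as_matrix(series)
    if X.shape[0] < min_years:
        raise ValueError(f"need at least {min_years} years, got {X.shape[0]}")
    variable = X.std(axis=0) > 0
    dropped = tuple(u for u, v in zip(units, variable) if not v)
    X = X[:, variable]
    if X.shape[1] < 2:
        raise ValueError(
            f"need at least 2 units with temporal variance, got {X.shape[1]} "
            f"(dropped: {list(dropped)})"
        )
    value = eta_stat(X)
    return EtaResult(
        eta=float(np.clip(value, -1.0, 1.0)),
        n_units=X.shape[1],
        n_years=X.shape[0],
        season=season,
        period=period,
        dropped_units=dropped,
    )


def eta_between(group_a, group_b, *, season: str | None = None, period: str | None = None) -> EtaResult:
    """eta between two summed groups: the Pearson correlation of the pair.

    With n = 2 both cross-terms of the index are Corr(A, B), so eta reduces
    to a simple correlation between the two group-level series.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("the two group series must share their years")
    if a.size < 3:
        raise ValueError("need at least 3 years")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant group series: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return EtaResult(
        eta=float(np.clip(r, -1.0, 1.0)),
        n_units=2,
        n_years=a.size,
        season=season,
        period=period,
    )


def eta_test(
    series,
    method: str = "toroidal_shift",
    n_surrogates: int = 1000,
    seed: int | np.random.Generator | None = None,
    alternative: str = "two_sided",
) -> tuple[EtaResult, "_surr.TestResult"]:
    """eta plus a surrogate-based significance test.

    The null hypothesis is zero cross-correlation between units with each
    unit's own temporal structure intact.  ``method`` selects how surrogates
    are built: ``"toroidal_shift"`` (circular shifts, for many-unit
    communities) or ``"iaaft"`` (spectrum-preserving, for two-group
    comparisons).  The p-value uses the (r + 1)/(n + 1) surrogate count rule.
    """
    result = eta(series)
    X, units, _, _ = _as_matrix(series)
    X = X[:, X.std(axis=0) > 0]
    rng = _surr.as_generator(seed)
    if method == "toroidal_shift":
        # all surrogate communities scored in one vectorized pass
        T, n = X.shape
        lags = rng.integers(0, T, size=(n_surrogates, n))
        idx = (np.arange(T)[None, :, None] - lags[:, None, :]) % T
        batch = np.take_along_axis(
            np.broadcast_to(X, (n_surrogates, T, n)), idx, axis=1
        )
        stats = eta_stat_batch(batch)
        ens = _surr.SurrogateEnsemble("toroidal_shift", n_surrogates, stats=stats)
    elif method == "iaaft":
        ens = _surr.null_distribution(
            lambda M: eta_stat(M), X, method="iaaft", n_surrogates=n_surrogates, rng=rng
        )
    else:
        raise ValueError(f"unknown surrogate method {method!r}")
    test = _surr.p_value(result.eta, ens, alternative=alternative)
    return result, test
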