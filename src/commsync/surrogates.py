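"""Surrogate null models and significance machinery.

Two ways to erase cross-correlations between community time series while
keeping each series' own temporal structure:

* **toroidal shift** -- each unit's series is rotated circularly by an
  independent uniform random lag.  The value multiset and the circular
  autocorrelation are preserved exactly; phases relative to other units are
  scrambled.  Appropriate when many units are compared.
* **IAAFT** (Iterative Amplitude-Adjusted Fourier Transform) -- the
  surrogate keeps the series' exact amplitude distribution (sorted values)
  and approximates its power spectrum, while phases are randomized.
  Appropriate for two-group comparisons, where the handful of distinct
  circular shifts could leave spurious cross-correlation.

The observed statistic is compared to the surrogate ensemble with the
count-based p-value (r + 1)/(n + 1), where r counts surrogates at least as
extreme; families of tests are corrected with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurrogateEnsemble",
    "TestResult",
    "IAAFTInfo",
    "toroidal_shift",
    "iaaft",
    "iaaft_matrix",
    "null_distribution",
    "p_value",
    "bh_adjust",
    "as_generator",
]


def as_generator(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce a seed or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SurrogateEnsemble:
    """Statistic values under a surrogate null."""

    method: str
    n_surrogates: int
    stats: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stats", np.asarray(self.stats, dtype=float))
        if self.stats.shape[0] != self.n_surrogates:
            raise ValueError("stats length must equal n_surrogates")


@dataclass
class TestResult:
    """Surrogate test outcome, with both one-sided p-values retained."""

    observed: float
    p_value: float
    alternative: str
    p_greater: float
    p_less: float
    bh_reject: bool | None = None


@dataclass(frozen=True)
class IAAFTInfo:
    converged: bool
    n_iter: int
    rel_spectrum_error: float


# ---------------------------------------------------------------------------
# surrogate constructors
# ---------------------------------------------------------------------------

def toroidal_shift(
    values: np.ndarray, rng: int | np.random.Generator | None = None
) -> np.ndarray:
    """Circularly shift each column by an independent uniform random lag.

    Works on a 1-D series or a (T, n_units) matrix.  A value at position t
    moves to (t + lag) mod T, so values pushed past the end wrap around to
    the beginning.
    """
    rng = as_generator(rng)
    x = np.asarray(values, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    if x.ndim == 1:
        return np.roll(x, int(rng.integers(0, x.shape[0])))
    if x.ndim != 2:
        raise ValueError("expected 1-D or 2-D input")
    out = np.empty_like(x)
    lags = rng.integers(0, x.shape[0], size=x.shape[1])
    for j, lag in enumerate(lags):
        out[:, j] = np.roll(x[:, j], int(lag))
    return out


def iaaft(
    series: np.ndarray,
    rng: int | np.random.Generator | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    return_info: bool = False,
):
    """IAAFT surrogate of a single series.

    Starting from a random permutation, the iteration alternates (a)
    replacing the Fourier amplitudes with the original's while keeping the
    current phases, and (b) rank-remapping the values onto the original's
    sorted values.  It stops when the rank ordering no longer changes between
    iterations (a fixed point) or when the relative change in spectral
    mismatch falls below ``tol``, else after ``max_iter`` rounds (the best
    iterate is returned with ``converged=False``).

    The surrogate always ends on the rank-remap step, so its sorted values
    equal the original's exactly; the periodogram is matched approximately.
    """
    rng = as_generator(rng)
    x = np.asarray(series, dtype=float).ravel()
    N = x.size
    if N < 8:
        raise ValueError("IAAFT needs at least 8 points")
    if np.ptp(x) == 0:
        raise ValueError("IAAFT undefined for a constant series")
    zero_frac = np.mean(x == 0)
    if zero_frac > 0.5:
        warnings.warn(
            f"IAAFT input is {zero_frac:.0%} exact zeros; surrogate spectra "
            "may converge slowly",
            stacklevel=2,
        )

    sorted_x = np.sort(x)
    target_f = np.fft.rfft(x)
    target_amp = np.abs(target_f)
    amp_norm = float(np.sum(target_amp[1:] ** 2)) or 1.0

    s = rng.permutation(x)
    prev_order = None
    prev_err = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # (a) impose the original Fourier amplitudes, keep current phases
        f = np.fft.rfft(s)
        phases = np.angle(f)
        g = target_amp * np.exp(1j * phases)
        g[0] = target_f[0]  # DC kept from the original
        if N % 2 == 0:
            # Nyquist bin must stay real for a real-valued inverse
            g[-1] = target_amp[-1] * np.sign(f[-1].real or 1.0)
        s = np.fft.irfft(g, n=N)
        # (b) rank-remap onto the original's sorted values (stable in ties)
        order = np.argsort(s, kind="stable")
        s = np.empty(N)
        s[order] = sorted_x

        err = _rel_spectrum_error(s, target_amp, amp_norm)
        if prev_order is not None and np.array_equal(order, prev_order):
            converged = True
            break
        if abs(prev_err - err) < tol:
            converged = True
            break
        prev_order, prev_err = order, err

    info = IAAFTInfo(converged, it, _rel_spectrum_error(s, target_amp, amp_norm))
    if not converged:
        warnings.warn(
            f"IAAFT did not converge in {max_iter} iterations "
            f"(relative spectrum error {info.rel_spectrum_error:.2e})",
            stacklevel=2,
        )
    return (s, info) if return_info else s


def _rel_spectrum_error(s: np.ndarray, target_amp: np.ndarray, amp_norm: float) -> float:
    amp = np.abs(np.fft.rfft(s))
    return float(np.sqrt(np.sum((amp[1:] - target_amp[1:]) ** 2) / amp_norm))


def iaaft_matrix(
    values: np.ndarray,
    rng: int | np.random.Generator | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """IAAFT applied independently to every column of a (T, n) matrix.

    Constant columns are returned unchanged (their spectrum and amplitude
    distribution are trivially preserved, and there is no phase to
    randomize).
    """
    rng = as_generator(rng)
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.ptp(col) == 0:
            out[:, j] = col
        else:
            out[:, j] = iaaft(col, rng, max_iter=max_iter, tol=tol)
    return out


# ---------------------------------------------------------------------------
# null distributions and p-values
# ---------------------------------------------------------------------------

def null_distribution(
    stat_fn: Callable[[np.ndarray], float],
    data: np.ndarray,
    method: str = "toroidal_shift",
    n_surrogates: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SurrogateEnsemble:
    """Distribution of ``stat_fn`` over surrogate replicates of ``data``.

    Each replicate randomizes every unit (column) independently under the
    chosen method, then applies ``stat_fn``.
    """
    if rng is None:
        rng = as_generator(seed)
    data = np.asarray(data, dtype=float)
    make = {"toroidal_shift": toroidal_shift, "iaaft": iaaft_matrix}.get(method)
    if make is None:
        raise ValueError(f"unknown surrogate method {method!r}")
    stats = np.empty(n_surrogates)
    for k in range(n_surrogates):
        try:
            stats[k] = stat_fn(make(data, rng))
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stat_fn failed on surrogate {k}: {exc}") from exc
    return SurrogateEnsemble(method, n_surrogates, stats=stats, seed=seed)


def p_value(
    observed: float,
    ensemble: SurrogateEnsemble | np.ndarray,
    alternative: str = "two_sided",
) -> TestResult:
    """Count-based surrogate p-value (r + 1)/(n + 1).

    ``r`` counts surrogate statistics >= observed (alternative "greater") or
    <= observed ("less"); ties count as extreme.  The two-sided p-value is
    2 * min(one-sided) capped at 1 -- conservative, and never below the
    attainable floor 1/(n + 1).
    """
    stats = ensemble.stats if isinstance(ensemble, SurrogateEnsemble) else np.asarray(ensemble)
    n = stats.size
    if n == 0:
        raise ValueError("empty surrogate ensemble")
    p_greater = (np.sum(stats >= observed) + 1.0) / (n + 1.0)
    p_less = (np.sum(stats <= observed) + 1.0) / (n + 1.0)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    elif alternative == "two_sided":
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(
        observed=float(observed),
        p_value=float(p),
        alternative=alternative,
        p_greater=float(p_greater),
        p_less=float(p_less),
    )


def bh_adjust(
    p_values: Sequence[float], q: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a family of p-values.

    Returns (reject flags, adjusted p-values) at false-discovery rate ``q``
    (the analysis-wide default is q = 0.10 over the 2 seasons x 3 periods
    family).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=bool), np.empty(0)
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
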