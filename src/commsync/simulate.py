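"""Synthetic community generators.

These generators produce monthly multispecies abundance matrices with the
statistical features a reserve-scale bird survey exhibits -- strong
seasonality, guild structure with opposed environmental responses, skewed
abundance distributions, and exact zeros for rare species-months -- so the
whole analysis pipeline can be exercised and calibrated without field data.

The main generator is a Ricker-type discrete Lotka-Volterra community forced
by a shared seasonal environmental driver:

    N_i(t+1) = N_i(t) * exp( r_i (1 - sum_j a_ij N_j(t) / K_i)
                             + beta_i E(t) + sigma eps_it )
    E(t) = sin(2 pi t / period) + driver noise

Two guilds carry opposite signs of beta, so a strong shared driver
synchronizes species within a guild while pushing the two guild totals in
opposite directions -- the compensatory regime the synchrony statistics are
meant to detect.  Simpler constructors (antiphase pairs, independent AR(1)
units, noisy copies of one seasonal latent) support null calibration and
limit-case checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community_data import AbundanceMatrix

__all__ = [
    "SimulationConfig",
    "simulate_forced_community",
    "guild_labels",
    "make_antiphase_pair",
    "make_independent",
    "make_synchronous",
    "apply_zero_inflation",
    "apply_abundance_skew",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the forced Lotka-Volterra community.

    Defaults give stable forced fluctuations around the competitive
    equilibrium: modest intrinsic growth (r = 0.5), shared carrying capacity
    scale (K = 100), weak interspecific competition relative to
    intraspecific (0.2 vs 1.0), guild-level environmental responses of
    opposite sign (beta = +/-0.5), a 12-month seasonal driver with
    year-to-year irregularity (sd 0.5), and small demographic noise
    (sigma = 0.1).  Counts are rounded to integers by default, creating
    exact zeros when an abundance falls below 0.5.
    """

    n_species_per_guild: int = 10
    n_guilds: int = 2
    n_months: int = 420
    r: float = 0.5
    K: float = 100.0
    alpha_intra: float = 1.0
    alpha_inter: float = 0.2
    beta: float = 0.5
    driver_period: float = 12.0
    driver_noise_sd: float = 0.5
    demographic_sd: float = 0.1
    round_counts: bool = True
    start: str = "1981-01"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_guilds not in (1, 2):
            raise ValueError("n_guilds must be 1 or 2")
        if self.n_months < 64:
            raise ValueError("n_months must be at least 64")
        if self.K <= 0:
            raise ValueError("carrying capacity must be positive")
        if abs(self.beta) > 5:
            raise ValueError("|beta| too large: log-abundances would diverge")


class SimulationDivergedError(RuntimeError):
    pass


def simulate_forced_community(config: SimulationConfig) -> AbundanceMatrix:
    """Simulate the forced Lotka-Volterra community of ``config``.

    Species start at the symmetric competitive equilibrium
    K / (a_intra + a_inter (S - 1)).  Guild 1 responds to the driver with
    +beta, guild 2 with -beta.  Raises
    :class:`SimulationDivergedError` (reporting the parameter set) if any
    abundance becomes non-finite or explodes.
    """
    rng = np.random.default_rng(config.seed)
    S = config.n_species_per_guild * config.n_guilds
    T = config.n_months

    betas = np.full(S, config.beta)
    if config.n_guilds == 2:
        betas[config.n_species_per_guild:] *= -1.0

    A = np.full((S, S), config.alpha_inter)
    np.fill_diagonal(A, config.alpha_intra)

    N_eq = config.K / (config.alpha_intra + config.alpha_inter * (S - 1))
    N = np.full(S, N_eq)
    driver = np.sin(2 * np.pi * np.arange(T) / config.driver_period)
    driver = driver + rng.normal(0.0, config.driver_noise_sd, size=T)

    out = np.empty((T, S))
    out[0] = N
    for t in range(1, T):
        growth = config.r * (1.0 - (A @ N) / config.K)
        eps = rng.normal(0.0, config.demographic_sd, size=S)
        N = N * np.exp(growth + betas * driver[t - 1] + eps)
        if not np.isfinite(N).all() or N.max() > 1e12:
            raise SimulationDivergedError(
                f"community diverged at month {t} with config {config}"
            )
        out[t] = N

    if config.round_counts:
        out = np.rint(out)
    units = [
        f"g{g + 1}_s{i + 1:02d}"
        for g in range(config.n_guilds)
        for i in range(config.n_species_per_guild)
    ]
    return AbundanceMatrix.from_values(out, units, start=config.start)


def guild_labels(config: SimulationConfig) -> dict[str, str]:
    """Species -> guild mapping matching :func:`simulate_forced_community`."""
    return {
        f"g{g + 1}_s{i + 1:02d}": f"guild{g + 1}"
        for g in range(config.n_guilds)
        for i in range(config.n_species_per_guild)
    }


def make_antiphase_pair(
    n_months: int,
    period: float = 12.0,
    amplitudes: tuple[float, float] = (50.0, 50.0),
    offset: float | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    start: str = "1981-01",
) -> AbundanceMatrix:
    """Two units oscillating in exact antiphase around a common offset.

    unit1 = offset + a1 sin(2 pi t / period), unit2 = offset - a2 sin(...),
    plus independent Gaussian noise.  With equal amplitudes and no noise the
    community total is exactly constant -- the textbook compensation case.
    Noise excursions below zero are floored at zero.
    """
    if period < 4:
        raise ValueError("period must be at least 4 months")
    a1, a2 = amplitudes
    if offset is None:
        offset = max(a1, a2) + 4.0 * noise_sd
    if offset < max(a1, a2):
        raise ValueError("offset too small to keep abundances nonnegative")
    rng = np.random.default_rng(seed)
    t = np.arange(n_months)
    wave = np.sin(2 * np.pi * t / period)
    x1 = offset + a1 * wave
    x2 = offset - a2 * wave
    if noise_sd > 0:
        x1 = np.maximum(x1 + rng.normal(0, noise_sd, n_months), 0.0)
        x2 = np.maximum(x2 + rng.normal(0, noise_sd, n_months), 0.0)
    return AbundanceMatrix.from_values(np.column_stack([x1, x2]), ["u1", "u2"], start)


def make_independent(
    n_steps: int,
    n_units: int,
    ar_coefficient: float = 0.0,
    seed: int | None = None,
    baseline: float = 100.0,
    sd: float = 10.0,
    start: str = "1981-01",
) -> AbundanceMatrix:
    """Mutually independent AR(1) units shifted positive.

    Each unit is a stationary AR(1) with the given lag-1 coefficient and
    marginal standard deviation ``sd``, offset by ``baseline``.  Used for
    null-model calibration (no cross-correlation by construction).
    """
    if n_units < 2:
        raise ValueError("need at least 2 units")
    if not abs(ar_coefficient) < 1:
        raise ValueError("|ar_coefficient| must be < 1 for stationarity")
    rng = np.random.default_rng(seed)
    innov_sd = np.sqrt(1 - ar_coefficient**2)
    z = np.empty((n_steps, n_units))
    z[0] = rng.normal(0, 1, n_units)
    for t in range(1, n_steps):
        z[t] = ar_coefficient * z[t - 1] + rng.normal(0, innov_sd, n_units)
    vals = np.maximum(baseline + sd * z, 0.0)
    units = [f"u{i+1}" for i in range(n_units)]
    return AbundanceMatrix.from_values(vals, units, start)


def make_synchronous(
    n_steps: int,
    n_units: int,
    noise_sd: float = 0.0,
    period: float = 12.0,
    amplitude: float = 50.0,
    baseline: float = 100.0,
    latent_sd: float = 10.0,
    seed: int | None = None,
    start: str = "1981-01",
) -> AbundanceMatrix:
    """Noisy copies of one latent seasonal series (a synchronized community).

    The latent series is a seasonal sinusoid plus a shared AR(1) component
    (sd ``latent_sd``, lag-1 coefficient 0.3) that gives it year-to-year
    variability; each unit adds independent observation noise.  With
    ``noise_sd = 0`` all units are identical.
    """
    if n_units < 2:
        raise ValueError("need at least 2 units")
    rng = np.random.default_rng(seed)
    t = np.arange(n_steps)
    latent = baseline + amplitude * np.sin(2 * np.pi * t / period)
    if latent_sd > 0:
        z = np.empty(n_steps)
        z[0] = rng.normal(0, 1)
        for k in range(1, n_steps):
            z[k] = 0.3 * z[k - 1] + rng.normal(0, np.sqrt(1 - 0.3**2))
        latent = latent + latent_sd * z
    vals = latent[:, None] + rng.normal(0, noise_sd, (n_steps, n_units))
    vals = np.maximum(vals, 0.0)
    units = [f"u{i+1}" for i in range(n_units)]
    return AbundanceMatrix.from_values(vals, units, start)


def apply_zero_inflation(
    matrix: AbundanceMatrix, p_zero: float, seed: int | None = None
) -> AbundanceMatrix:
    """Set each cell to exactly zero independently with probability p_zero.

    Emulates the exact zeros that monthly snapshot counts of rare species
    produce.
    """
    if not 0 <= p_zero < 1:
        raise ValueError("p_zero must lie in [0, 1)")
    if p_zero == 0:
        return matrix
    rng = np.random.default_rng(seed)
    vals = matrix.values.copy()
    vals[rng.random(vals.shape) < p_zero] = 0.0
    return AbundanceMatrix.from_values(vals, matrix.units, str(matrix.times[0]))


def apply_abundance_skew(
    matrix: AbundanceMatrix,
    lognormal_sd: float,
    mode: str = "mean",
    seed: int | None = None,
) -> AbundanceMatrix:
    """Skew the species-abundance distribution with lognormal factors.

    ``mode="mean"`` rescales each unit's mean level (the deviations from the
    mean are kept); ``mode="amplitude"`` rescales each unit's deviations
    around its mean (the mean is kept).  ``lognormal_sd = 0`` is the
    identity.  Values pushed below zero are floored at zero.
    """
    if mode not in ("mean", "amplitude"):
        raise ValueError("mode must be 'mean' or 'amplitude'")
    if lognormal_sd < 0:
        raise ValueError("lognormal_sd must be nonnegative")
    if lognormal_sd == 0:
        return matrix
    rng = np.random.default_rng(seed)
    vals = matrix.values.copy()
    factors = rng.lognormal(0.0, lognormal_sd, size=vals.shape[1])
    means = vals.mean(axis=0)
    if mode == "mean":
        vals = vals + means * (factors - 1.0)
    else:
        vals = means + (vals - means) * factors
    vals = np.maximum(vals, 0.0)
    return AbundanceMatrix.from_values(vals, matrix.units, str(matrix.times[0]))
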