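# Methods

This note documents the statistical machinery implemented in `commsync`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Data model

The pipeline's central object is the **monthly abundance matrix**: a
gap-free time × unit grid at monthly resolution. Raw survey records
(year, month, species, count) are reduced by taking the **maximum** count
within each (month, species) cell — a "monthly snapshot" of how many birds
were present at once, never a sum over repeated visits — and months with no
record for a species become **exact zeros**. This treats absence of counts
as true absence, appropriate for an intensively watched site; no attempt is
made to impute counts from regional populations, since doing so would
destroy the local covariation structure the analysis targets.

Seasons are fixed month blocks: **warm = May–August** of one year,
**cold = November–February**, labeled by the November year (the common
ornithological convention for a wintering season that straddles the year
boundary). Seasonal series average the (exactly four) months of each
season; seasons truncated at the edges of the record are dropped rather
than averaged over fewer months, so every seasonal mean is comparable.
Period splits around a management-change year use a half-open cut: the cut
year belongs to the *post* period.

Guild analyses sum member species **on the monthly matrix, before**
seasonal averaging. Because both operations are linear this equals
averaging first and summing later (asserted by a test), but summing first
keeps the guild series interpretable as a monthly total. "Most frequent
species" filters rank by number of nonzero months, with ties broken by
total abundance and then label — deterministic under any input ordering.
Whether the frequency filter is applied before or after trimming to a
study window is left to the caller (both orders are expressible), since
either reading is defensible. Biomass variants multiply each species by a
mean body mass (grams); all statistics run on untransformed abundances
(log1p is available for display only).

## The synchrony index η

η is the mean over units of the Pearson correlation between each unit's
yearly values and the summed values of all other units. Pearson (not rank)
correlation is used, on seasonal means without detrending. Units with zero
temporal variance in a season (species never recorded then) have no defined
correlation; they are **dropped from the community and reported**, rather
than imputed as zero correlation, keeping η a mean of defined correlations.
(A constant unit would in any case not change the other units' correlations,
since adding a constant to the "rest of community" sum leaves Pearson
correlation invariant; a zero-imputation flag was considered and rejected
as it changes the meaning of *n*.) At least two varying units and three
years are required. With exactly two units η reduces to the plain
correlation of the pair, which is how between-guild comparisons are run.

## Surrogate null models

The null hypothesis is zero cross-correlation with each unit's own
temporal structure intact.

**Toroidal shift** (within-guild, many units): each unit's series is
rotated by an independent uniform lag in {0, …, T−1}; values pushed past
the end wrap to the beginning. The value multiset and the circular
autocorrelation are preserved exactly. With only two units the handful of
distinct rotations can leave spurious cross-correlation, so:

**IAAFT** (two-group comparisons, and all wavelet nulls): starting from a
random permutation, alternate (a) imposing the original Fourier amplitudes
onto the current phases and (b) rank-remapping values onto the original's
sorted values, until the rank ordering is unchanged between iterations or
the relative change in spectral mismatch falls below 1e-8 (max 100
iterations; non-convergence returns the best iterate with a warning and a
flag). The surrogate ends on the remap step, so its sorted values equal
the original's **exactly**; the periodogram is matched approximately — to
machine precision on band-limited series (where a rotation is an exact
fixed point), to a few percent relative error on broadband noisy series,
which is the known behavior of amplitude-exact IAAFT. Ties in the remap
use stable first-occurrence order; the DC bin is kept from the original
and the Nyquist bin is held real for even lengths. Series with more than
50% exact zeros run as-is but log a warning (the wavelet statistics were
verified robust to zero inflation; see below).

**p-values** use the count rule p = (r+1)/(n+1), where r counts surrogate
statistics at least as extreme as the observed (ties count as extreme),
giving the attainable floor 1/(n+1). The two-sided p-value is 2·min of the
one-sided values, capped at 1 — conservative and standard for surrogate
tests; both one-sided values are always reported alongside, since the
alternative convention (α/2 per side) is also in use. Families of tests
(2 seasons × 3 periods per grouping level, which share data) are corrected
with Benjamini–Hochberg at a 10% false-discovery rate via statsmodels;
families are never pooled across grouping levels by default.

Empirically (and asserted in the acceptance suite) the two-sided test at
the 10% level rejects ~8–10% of null communities of 10 independent AR(1)
units over 35 years — at or slightly below nominal, the expected behavior
of a conservative discrete two-sided rule.

## Morlet CWT and the wavelet modulus ratio

The continuous wavelet transform uses the analytic Morlet wavelet with
central frequency ω₀ = 6 (the standard admissible choice), implemented in
the frequency domain with the usual Torrence–Compo normalization
√(2πs/dt)·π^(−1/4)·exp(−(sω−ω₀)²/2) on positive frequencies. Each series
is mean-centered and zero-padded to the next power of two; the cone of
influence is the e-folding time √2·s of the wavelet envelope, and no value
or significance flag is ever reported inside it. The equivalent Fourier
period of scale s is 4πs/(ω₀+√(2+ω₀²)) ≈ 1.03 s. The default scale grid is
dyadic with 12 voices per octave from 2 months up to T/4 — on a
multi-decade monthly series this resolves everything from sub-seasonal
(2–4 month) scales through the annual cycle to multi-year scales. Scales
are expressed in months throughout.

The wavelet modulus ratio at time t and scale s divides the
Gaussian-smoothed **modulus of the coefficient sum** (the fluctuation of
the community total at that scale) by the smoothed **sum of coefficient
moduli** (the summed fluctuation amplitudes of the units). The Gaussian
kernel has standard deviation s (scale-adapted localization), truncated at
±4 sd (mass loss < 1e-4) and effectively renormalized at the series edges
because the same truncated window appears in numerator and denominator.
Cells where the denominator underflows are masked as undefined rather than
divided. The triangle inequality guarantees 0 ≤ ρ ≤ 1. ρ is invariant
under rescaling *all* units by a common factor, but **not** under rescaling
one unit: a unit that dominates the community's temporal variation drives
ρ toward 1 at the scales it occupies, since no combination of the others
can offset it — for an antiphase pair with amplitude ratio a the mid-series
minimum follows (a−1)/(a+1). Community-level synchrony in this sense is
therefore the reciprocal of compensation, not phase synchrony.

Significance of high and low ρ is **pointwise per cell**: every unit's
monthly series is IAAFT-surrogatized independently, ρ recomputed per
replicate, and a cell is flagged when the count-based surrogate p-value on
its side is ≤ α/2 (default α = 10%). The count rule (rather than a raw
empirical quantile) keeps the 1/(n+1) floor, so e.g. a single surrogate can
never flag anything. No areawise/cluster correction is applied — flagged
regions inherit the strong spatial correlation of the (t, s) plane, and
the expected fraction of flagged cells under the null is α only on
average. This is a documented limitation; contour regions should be read
qualitatively.

## The synthetic community generator

The generator stands in for a multi-decade monthly survey and defines the
conditions under which the pipeline is validated. It is a Ricker-type
discrete Lotka–Volterra community with an additive environmental term on
the log scale:

    N_i(t+1) = N_i(t) · exp( r (1 − Σ_j a_ij N_j / K) + β_i E(t) + σ ε_it ),
    E(t) = sin(2πt/12) + driver noise

Defaults: 2 guilds × 10 species, 420 months (35 years), r = 0.5, K = 100,
intraspecific competition 1.0, interspecific 0.2, β = ±0.5 with the sign
opposed between guilds, driver noise sd 0.5, demographic noise σ = 0.1,
counts rounded to integers (creating exact zeros below 0.5). The driver
noise sd of 0.5 — half the seasonal amplitude — gives the environment
year-to-year irregularity comparable to its seasonal cycle, so that
seasonal means genuinely vary between years; without it, seasonal averages
of a purely periodic driver would be identical every year and the
year-to-year index would see only demographic noise. Species start at the
symmetric competitive equilibrium K/(a_intra + a_inter(S−1)); divergence
(non-finite or > 1e12) raises an error naming the parameter set.

Simpler constructors cover limit cases: exact antiphase sinusoid pairs
(with configurable amplitude ratio, for compensation and dominance),
independent AR(1) units (for null calibration), and noisy copies of one
latent seasonal-plus-AR(1) series (for synchrony; the shared AR component,
sd 10, coefficient 0.3, provides the interannual variability that makes
year-to-year synchrony well defined). Perturbations add zero inflation
(each cell zeroed independently with probability p) and lognormal
species-abundance skew, applied either to mean levels (mean shifts,
fluctuations kept) or to fluctuation amplitudes (means kept).

What the generator does **not** emulate: migration phenology, spatial
sector structure, observation error beyond rounding, long-term trends or
regime shifts, and the heavy-tailed species-abundance distributions of
real communities beyond the lognormal skew device. Passing tests therefore
demonstrate correctness and calibration of the *statistics* under the
stated dynamics, not that any particular field system behaves this way.

## Validation experiments and problem sizes

The test and acceptance suites run, at sizes chosen to keep the full suite
in minutes on one CPU:

* analytic limits of η (identical copies → 1, constant-sum pair → −1) and
  of ρ (identical → 1 to 1e-10 outside the cone; equal-amplitude antiphase
  → < 0.05 at the oscillation scale on a 240-month pair);
* η centering: |mean η| < 0.02 over 1000 independent 10-species,
  35-year communities;
* exact surrogate invariants (circular ACF, value multisets, periodogram
  on 512-point band-limited series, the p floor);
* test size: 500 null communities, 200 surrogates each, two-sided 10%
  level, rejection within 10% ± 3%;
* oracle equivalence: the convolution-based ρ against an explicit-loop
  discretization (3 units × 128 months, 1e-10) and η against hand-computed
  correlations on a printed 3 × 6 table (1e-12);
* regime recovery: between-guild η < 0 and within-guild η > 0 in ≥ 95 of
  100 simulator seeds, unchanged under 20% zero inflation; and monotone
  increase of minimum ρ with the dominance ratio of an antiphase pair.

All generators and analysis tracks are bit-for-bit reproducible given a
seed; surrogate streams are derived from one root seed per analysis and
echoed in the run metadata.
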