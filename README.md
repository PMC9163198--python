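# commsync

Multi-scale synchrony and compensation analysis for community abundance
time series.

## The problem

When a multispecies community is surveyed over decades -- say, monthly bird
counts in a wetland reserve -- a basic ecological question is whether the
species fluctuate **in step** (synchrony: good years and bad years are
shared) or **compensate** (species replace one another while the community
total stays roughly flat). Compensation underpins the stabilizing effect of
biodiversity, yet it is notoriously hard to detect: a shared driver such as
seasonal climate synchronizes everything at some scales, and compensation,
if present, may live only at particular temporal scales (months, or many
years), in particular seasons, or between broad functional groups rather
than between similar species.

`commsync` implements two complementary statistics with their null models,
for ecologists analyzing long community survey data:

**Year-to-year synchrony index η.** For a community of *n* units (species
or guild totals) with yearly abundances *X<sub>i</sub>*,

        η = (1/n) Σᵢ Corr(Xᵢ, Σ_{j≠i} Xⱼ)

η ∈ [−1, 1]: +1 for complete synchrony, −1 for perfect compensation (total
constant), ≈0 for independence; unlike variance-ratio statistics it does
not drift with richness *n*. With two units it reduces to their plain
correlation. Significance comes from surrogate communities that keep each
series' own temporal structure while erasing cross-correlations —
circular (toroidal) shifts within many-unit communities, IAAFT
(spectrum- and amplitude-preserving) surrogates for two-group comparisons —
with the count-based p-value (r+1)/(n+1) and Benjamini–Hochberg correction
at a 10% false-discovery rate over each 2-seasons × 3-periods family.

**Wavelet modulus ratio ρ(t, s).** With w<sub>i</sub>(t, s) the continuous
Morlet wavelet transform of unit *i*,

        ρ(t, s) = G_s ∗ |Σᵢ wᵢ(·, s)| / G_s ∗ Σᵢ |wᵢ(·, s)|

where G_s is a Gaussian kernel in time of width s. By the triangle
inequality 0 ≤ ρ ≤ 1: ρ → 0 where units cancel (compensation at that time
and scale), ρ → 1 where they move together. Pointwise two-sided
significance is assessed against IAAFT surrogates of each unit's monthly
series.

The package also provides the data plumbing (monthly snapshot matrices from
long-format counts, zero-filling, seasonal averaging, guild summation,
period splits, biomass conversion) and a seasonally forced two-guild
Lotka–Volterra simulator used to calibrate and validate the whole pipeline
without field data.

## A worked example

```python
from commsync import (GroupScheme, SimulationConfig, eta, eta_between,
                      group_sum, seasonal_mean)
from commsync.simulate import guild_labels, simulate_forced_community

cfg = SimulationConfig(seed=7)            # 35 years, 2 guilds x 10 species
matrix = simulate_forced_community(cfg)   # opposed responses to one driver
guilds = group_sum(matrix, GroupScheme("guilds", guild_labels(cfg)))

s_species = seasonal_mean(matrix, "warm")
s_guilds = seasonal_mean(guilds, "warm")
print(eta(s_species.data.iloc[:, :10]).eta)                      # 0.849
print(eta_between(s_guilds.values[:, 0], s_guilds.values[:, 1]).eta)  # -0.854
```

Species within a guild synchronize (η = +0.85) because they share the
driver response, while the two guild totals compensate (η = −0.85) because
their responses are opposed — the exact signature these statistics are
built to separate. At the whole-community species level the same run gives
η ≈ 0: with two opposed guilds of equal size, within-guild synchrony and
between-guild compensation cancel, which is why analyses at several
functional scales are needed at all.

The `examples/` directory walks through each capability (simulation, η by
season, surrogate testing, wavelet maps, the full pipeline); each script
prints the numbers it computes and states what they mean. A thin CLI covers
shell use:

```bash
commsync simulate --config sim.yaml --out counts.csv
commsync eta --config examples/analysis_config.yaml
commsync wavelet --config examples/analysis_config.yaml
```

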