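"""Year-to-year synchrony index eta, by season and guild level.

Seasonal means (warm = May-August, cold = November-February) are computed
per year, then eta -- the mean correlation between each species and the
summed rest of its community.  eta near +1 means the species rise and fall
together; near -1 means the total is nearly constant while composition
shifts; near 0 means independent fluctuations.
"""

from commsync import GroupScheme, SimulationConfig, eta, eta_between, group_sum, seasonal_mean
from commsync.simulate import guild_labels, simulate_forced_community

cfg = SimulationConfig(seed=7)
matrix = simulate_forced_community(cfg)
scheme = GroupScheme("guilds", guild_labels(cfg))
guilds = group_sum(matrix, scheme)

for season in ("warm", "cold"):
    s_species = seasonal_mean(matrix, season)
    s_guilds = seasonal_mean(guilds, season)
    within1 = eta(s_species.data.iloc[:, :10])
    between = eta_between(s_guilds.values[:, 0], s_guilds.values[:, 1])
    print(f"{season:4s} season: eta within guild 1 = {within1.eta:+.3f} "
          f"(n={within1.n_units} species, {within1.n_years} years); "
          f"eta between guilds = {between.eta:+.3f}")
print("expected: within-guild synchrony (>0), between-guild compensation (<0)")
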