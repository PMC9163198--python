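"""End-to-end analysis tracks.

Track A (:func:`run_eta_track`): year-to-year synchrony eta per grouping
level x season x period, with surrogate p-values (toroidal shifts within
many-unit communities, IAAFT between two summed groups) and
Benjamini-Hochberg flags over each grouping's 2-seasons x 3-periods family.

Track B (:func:`run_wavelet_track`): monthly wavelet modulus ratio maps with
pointwise IAAFT significance masks, per configured community subset.

Both tracks are plain functions over :class:`AbundanceMatrix`; the config
objects and writers exist so a whole analysis can be described in one YAML
file and rerun reproducibly from the command line.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import surrogates as surr
from .community_data import (
    AbundanceMatrix,
    GroupScheme,
    SeasonalSeries,
    group_sum,
    read_counts,
    read_group_scheme,
    build_monthly_matrix,
    seasonal_mean,
    select_frequent,
    split_period,
)
from .eta import eta, eta_between, eta_test
from .simulate import SimulationConfig, guild_labels, simulate_forced_community
from .wavelets import default_scales, wmr_significance

__all__ = ["AnalysisConfig", "run_eta_track", "run_wavelet_track", "load_config"]


@dataclass
class AnalysisConfig:
    """One reproducible analysis run, loadable from YAML."""

    input_path: str | None = None
    simulation: dict[str, Any] | None = None
    groups_path: str | None = None
    seasons: Sequence[str] = ("warm", "cold")
    cut_year: int = 2006
    n_frequent: int | None = None
    n_surrogates: int = 1000
    alpha: float = 0.10
    seed: int = 0
    output_dir: str = "results"
    wavelet_subsets: dict[str, list[str]] | None = None
    surrogate_method_within: str = "toroidal_shift"
    surrogate_method_between: str = "iaaft"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path / simulation must be given")


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)


def _load_matrix(config: AnalysisConfig) -> tuple[AbundanceMatrix, GroupScheme | None]:
    if config.input_path is not None:
        records = read_counts(config.input_path)
        matrix = build_monthly_matrix(records)
    else:
        sim = SimulationConfig(**{**config.simulation, "seed": config.simulation.get("seed", config.seed)})
        matrix = simulate_forced_community(sim)
    scheme: GroupScheme | None = None
    if config.groups_path is not None:
        scheme = read_group_scheme(config.groups_path)
    elif config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation, "seed": config.simulation.get("seed", config.seed)})
        if sim.n_guilds == 2:
            scheme = GroupScheme("guilds", guild_labels(sim))
    if config.n_frequent is not None:
        matrix = select_frequent(matrix, config.n_frequent)
    return matrix, scheme


def _periods(series: SeasonalSeries, cut_year: int) -> list[SeasonalSeries]:
    out = [series]
    if series.years.min() < cut_year <= series.years.max():
        pre, post = split_period(series, cut_year)
        out += [pre, post]
    return out


def run_eta_track(
    config: AnalysisConfig,
    matrix: AbundanceMatrix | None = None,
    scheme: GroupScheme | None = None,
) -> pd.DataFrame:
    """Year-to-year eta with surrogate significance, one row per test.

    Levels analyzed: the whole community at species resolution
    (``community``), species within each group (``within:<group>``) and --
    when the scheme defines exactly two groups -- the correlation between
    the two group totals (``between:<a>|<b>``).  BH correction runs within
    each level's season x period family at FDR ``config.alpha``.
    """
    if matrix is None:
        matrix, auto_scheme = _load_matrix(config)
        scheme = scheme or auto_scheme

    ss = np.random.SeedSequence(config.seed)

    levels: list[tuple[str, AbundanceMatrix, str]] = [
        ("community", matrix, config.surrogate_method_within)
    ]
    if scheme is not None:
        grouped = group_sum(matrix, scheme)
        for g in grouped.units:
            members = [u for u in matrix.units if scheme.mapping.get(u) == g]
            if len(members) >= 2:
                levels.append(
                    (f"within:{g}", AbundanceMatrix(matrix.data[members]),
                     config.surrogate_method_within)
                )
        if len(grouped.units) == 2:
            a, b = grouped.units
            levels.append((f"between:{a}|{b}", grouped, config.surrogate_method_between))

    rows = []
    for level, level_matrix, method in levels:
        level_seed = np.random.default_rng(ss.spawn(1)[0])
        for season in config.seasons:
            series = seasonal_mean(level_matrix, season)
            for sub in _periods(series, config.cut_year):
                try:
                    if level.startswith("between:"):
                        res = eta_between(
                            sub.values[:, 0], sub.values[:, 1],
                            season=season, period=sub.period,
                        )
                        _, test = eta_test(
                            sub.values, method=method,
                            n_surrogates=config.n_surrogates, seed=level_seed,
                        )
                    else:
                        res, test = eta_test(
                            sub, method=method,
                            n_surrogates=config.n_surrogates, seed=level_seed,
                        )
                except ValueError as exc:
                    raise RuntimeError(
                        f"eta track failed at level={level} season={season} "
                        f"period={sub.period}: {exc}"
                    ) from exc
                rows.append(
                    dict(
                        level=level, season=season, period=sub.period,
                        eta=res.eta, n_units=res.n_units, n_years=res.n_years,
                        n_dropped=len(res.dropped_units),
                        method=method,
                        p_greater=test.p_greater, p_less=test.p_less,
                        p_value=test.p_value,
                    )
                )
    table = pd.DataFrame(rows)
    table["bh_reject"] = False
    for level, idx in table.groupby("level").groups.items():
        reject, p_adj = surr.bh_adjust(table.loc[idx, "p_value"], q=config.alpha)
        table.loc[idx, "bh_reject"] = reject
        table.loc[idx, "p_adjusted"] = p_adj
    return table


def run_wavelet_track(
    config: AnalysisConfig,
    matrix: AbundanceMatrix | None = None,
    scheme: GroupScheme | None = None,
    write: bool = False,
) -> dict[str, tuple]:
    """Wavelet modulus ratio maps with significance masks per subset.

    Subsets default to the whole community plus each group of the scheme.
    Subsets with fewer than two units are rejected.  With ``write=True``
    each map/mask pair goes to ``config.output_dir`` as TSV plus a JSON
    sidecar of parameters.
    """
    if matrix is None:
        matrix, auto_scheme = _load_matrix(config)
        scheme = scheme or auto_scheme

    subsets: dict[str, list[str]] = {"community": matrix.units}
    if scheme is not None:
        for g in scheme.groups():
            members = [u for u in matrix.units if scheme.mapping.get(u) == g]
            subsets[g] = members
    if config.wavelet_subsets:
        subsets.update(config.wavelet_subsets)

    ss = np.random.SeedSequence(config.seed)
    out: dict[str, tuple] = {}
    meta: dict[str, Any] = {
        "alpha": config.alpha, "n_surrogates": config.n_surrogates,
        "seed": config.seed, "subsets": {},
    }
    for name, units in subsets.items():
        if len(units) < 2:
            raise ValueError(f"wavelet subset {name!r} has fewer than 2 units")
        missing = [u for u in units if u not in matrix.units]
        if missing:
            raise ValueError(f"wavelet subset {name!r} names unknown units {missing}")
        sub = matrix.data[units].to_numpy()
        scales = default_scales(sub.shape[0])
        rng = np.random.default_rng(ss.spawn(1)[0])
        rho_map, mask = wmr_significance(
            sub, scales=scales, n_surrogates=config.n_surrogates,
            alpha=config.alpha, seed=rng,
        )
        out[name] = (rho_map, mask)
        meta["subsets"][name] = {
            "units": units,
            "scales_months": [float(s) for s in scales],
        }
        if write:
            outdir = Path(config.output_dir)
            outdir.mkdir(parents=True, exist_ok=True)
            times = matrix.times.strftime("%Y-%m")
            pd.DataFrame(rho_map.rho, index=scales, columns=times).to_csv(
                outdir / f"rho_{name}.tsv", sep="\t", index_label="scale_months"
            )
            flags = np.where(mask.high_mask, 1, np.where(mask.low_mask, -1, 0))
            pd.DataFrame(flags, index=scales, columns=times).to_csv(
                outdir / f"masks_{name}.tsv", sep="\t", index_label="scale_months"
            )
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "run_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)
    return out
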