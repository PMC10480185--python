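"""Scenario orchestration: the four media landscapes over the (epsilon, gamma,
p_m) grid, the media-free baseline replication, and the heterogeneous-bound
network ("case study") mode with echo-chamber analysis."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MediaLandscape, ModelConfig, OpinionState
from .graphs import InteractionGraph, NodeAttributes, scenario_media
from .metrics import EchoChamberStats, echo_chamber_stats
from .runner import EnsembleResult, RunResult, StoppingRule, run, run_ensemble

__all__ = [
    "GridSpec",
    "LandscapeResult",
    "run_landscape",
    "baseline_replication",
    "casestudy_mode",
    "casestudy_landscapes",
    "heatmap_table",
]

# Media landscapes of the network case study: faction-average opinions of the
# pro, neutral and against groups.
CASESTUDY_MEDIA = {
    "pro": (0.28,),
    "neutral": (0.49,),
    "against": (0.87,),
    "polarized": (0.28, 0.87),
    "three": (0.28, 0.49, 0.87),
}


def casestudy_landscapes() -> dict[str, MediaLandscape]:
    """The five media landscapes used in the network case study."""
    return {name: MediaLandscape(ops) for name, ops in CASESTUDY_MEDIA.items()}


@dataclass
class GridSpec:
    """The mean-field experimental grid; defaults mirror the full design
    (reducible for desk-scale reproduction)."""

    p_m_values: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    epsilon_values: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    gamma_values: tuple = (0.0, 0.5, 0.75, 1.0, 1.25, 1.5)
    n_runs: int = 100
    n_agents: int = 100

    def __post_init__(self) -> None:
        if not (self.p_m_values and self.epsilon_values and self.gamma_values):
            raise ValueError("grid axes must be non-empty")
        if self.n_runs < 1 or self.n_agents < 2:
            raise ValueError("need n_runs >= 1 and n_agents >= 2")

    def cells(self) -> list[tuple[float, float, float]]:
        return [
            (eps, gamma, p_m)
            for eps in self.epsilon_values
            for gamma in self.gamma_values
            for p_m in self.p_m_values
        ]


@dataclass
class LandscapeResult:
    scenario: str
    runs: pd.DataFrame
    aggregates: pd.DataFrame
    final_opinions: list


def run_landscape(
    scenario: str,
    grid: GridSpec,
    base_seed: int = 0,
    config_template: dict | None = None,
    stop: StoppingRule | None = None,
    progress=None,
) -> LandscapeResult:
    """Run one named media landscape over the full grid.

    Returns the per-run table plus per-cell aggregates; pivot them with
    :func:`heatmap_table` into the (gamma x p_m) panels used to read the
    results, one panel per epsilon.
    """
    media = scenario_media(scenario)
    ens = run_ensemble(
        media,
        grid.cells(),
        n_runs=grid.n_runs,
        base_seed=base_seed,
        config_template=config_template,
        n_agents=grid.n_agents,
        stop=stop,
        scenario_name=scenario,
        progress=progress,
    )
    return LandscapeResult(scenario, ens.runs, ens.aggregates, ens.final_opinions)


def baseline_replication(
    grid: GridSpec,
    base_seed: int = 0,
    config_template: dict | None = None,
    stop: StoppingRule | None = None,
    progress=None,
) -> LandscapeResult:
    """Media-free baseline over (epsilon, gamma): p_m forced to 0 so media are
    never consulted; serves as the comparison baseline for every scenario."""
    cells = [
        (eps, gamma, 0.0)
        for eps in grid.epsilon_values
        for gamma in grid.gamma_values
    ]
    ens = run_ensemble(
        MediaLandscape(()),
        cells,
        n_runs=grid.n_runs,
        base_seed=base_seed,
        config_template=config_template,
        n_agents=grid.n_agents,
        stop=stop,
        scenario_name="baseline",
        progress=progress,
    )
    return LandscapeResult("baseline", ens.runs, ens.aggregates, ens.final_opinions)


def heatmap_table(
    aggregates: pd.DataFrame, metric: str, epsilon: float
) -> pd.DataFrame:
    """One (gamma rows x p_m columns) panel of a mean-aggregated metric."""
    col = f"{metric}_mean"
    panel = aggregates[np.isclose(aggregates["epsilon"], epsilon)]
    if panel.empty:
        raise ValueError(f"no aggregate rows at epsilon={epsilon}")
    return panel.pivot(index="gamma", columns="p_m", values=col)


def casestudy_mode(
    graph: InteractionGraph,
    attributes: NodeAttributes,
    media: MediaLandscape,
    gamma: float = 0.0,
    p_m: float = 0.0,
    epsilon: float | Sequence[float] | None = None,
    mu: float = 0.5,
    seed: int | None = None,
    max_iterations: int = 100_000,
    stop: StoppingRule | None = None,
) -> tuple[RunResult, EchoChamberStats]:
    """Heterogeneous-bound network run with the case-study stopping rule.

    Initial opinions come from the node attributes; per-node confidence bounds
    come from ``attributes.epsilon`` unless a homogeneous ``epsilon`` overrides
    them. Stops when the maximum opinion change stays below 0.01 for 500
    consecutive iterations (cap 10^5 by default), then reports echo-chamber
    statistics of the final state.
    """
    if epsilon is None:
        if attributes.epsilon is None:
            raise ValueError(
                "heterogeneous mode requested but the attribute table carries no "
                "per-node epsilon; pass a homogeneous epsilon instead"
            )
        epsilon = attributes.epsilon
    cfg = ModelConfig(
        epsilon=epsilon,
        gamma=gamma,
        mu=mu,
        p_m=p_m,
        seed=seed,
        max_iterations=max_iterations,
    )
    if stop is None:
        stop = StoppingRule.max_change(threshold=0.01, window=500)
    result = run(OpinionState(attributes.opinions.copy()), graph, media, cfg, stop)
    stats = echo_chamber_stats(result.final_state.opinions, graph)
    return result, stats
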