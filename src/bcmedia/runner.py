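"""Full runs and ensembles: stopping rules, iteration caps, snapshots and
replicate aggregation.

A run repeatedly applies the single pair-event step until either the cluster
configuration has been stable for a configured number of consecutive checks
(mean-field equilibrium rule), the per-step maximum opinion change has stayed
below a threshold for a window of consecutive steps (case-study rule), or the
iteration cap is reached.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import MediaLandscape, ModelConfig, OpinionState, _step_inplace
from .graphs import InteractionGraph, uniform_initial_opinions
from .metrics import ClusterPartition, detect_clusters, summarize_opinions

__all__ = [
    "StoppingRule",
    "RunResult",
    "EnsembleResult",
    "run",
    "equilibrium_reached",
    "max_change_stop",
    "run_ensemble",
]

STOP_EQUILIBRIUM = "equilibrium"
STOP_MAX_CHANGE = "max_change"
STOP_ITERATION_CAP = "iteration_cap"


@dataclass
class StoppingRule:
    """Stopping condition for a run; exactly one ``kind`` is active.

    ``cluster_equilibrium``: every ``check_stride`` steps the gap-threshold
    partition is computed; the run stops once ``patience`` consecutive partitions
    are identical in membership. ``max_change``: the run stops once the per-step
    maximum absolute opinion change stays below ``change_threshold`` for
    ``patience`` consecutive steps.
    """

    kind: str = "cluster_equilibrium"
    check_stride: int = 1000
    patience: int = 10
    change_threshold: float = 0.01
    gap_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.kind not in ("cluster_equilibrium", "max_change"):
            raise ValueError(f"unknown stopping rule kind {self.kind!r}")
        if self.check_stride < 1 or self.patience < 1:
            raise ValueError("check_stride and patience must be >= 1")
        if self.change_threshold <= 0 or self.gap_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def cluster_equilibrium(
        cls, check_stride: int = 1000, patience: int = 10, gap_threshold: float = 0.01
    ) -> "StoppingRule":
        return cls("cluster_equilibrium", check_stride, patience, gap_threshold=gap_threshold)

    @classmethod
    def max_change(cls, threshold: float = 0.01, window: int = 500) -> "StoppingRule":
        """The case-study rule: change below ``threshold`` for ``window``
        consecutive iterations."""
        return cls("max_change", patience=window, change_threshold=threshold)


@dataclass
class RunResult:
    final_state: OpinionState
    iterations: int
    converged: bool
    stop_reason: str
    snapshots: list = field(default_factory=list)


def equilibrium_reached(partition_history: Sequence[ClusterPartition | tuple]) -> bool:
    """True iff all partitions in the window are identical in membership (and
    hence in cluster count). Accepts partitions or precomputed signatures."""
    sigs = [
        p.signature() if isinstance(p, ClusterPartition) else tuple(p)
        for p in partition_history
    ]
    if not sigs:
        return False
    return all(s == sigs[0] for s in sigs[1:])


def max_change_stop(
    recent_changes: Sequence[float], threshold: float, window: int
) -> bool:
    """True iff the last ``window`` entries are all strictly below ``threshold``."""
    if threshold <= 0 or window < 1:
        raise ValueError("threshold must be positive and window >= 1")
    tail = list(recent_changes)[-window:]
    return len(tail) == window and all(c < threshold for c in tail)


def run(
    initial: OpinionState,
    graph: InteractionGraph | None,
    media: MediaLandscape,
    config: ModelConfig,
    stop: StoppingRule | None = None,
    rng: np.random.Generator | None = None,
    snapshot_stride: int | None = None,
) -> RunResult:
    """Drive a single run to its stopping condition or the iteration cap.

    ``graph=None`` means mean-field. ``stop=None`` disables convergence checks
    entirely (the run executes exactly ``config.max_iterations`` steps). Passing
    an explicit ``rng`` continues an existing stream (used by ensembles whose
    replicates draw their initial opinions from their own stream); otherwise a
    fresh generator is seeded from ``config.seed``. Identical (config, seed)
    pairs yield bit-identical results.
    """
    if graph is not None and not graph.mean_field and graph.n_nodes != initial.n:
        raise ValueError(
            f"graph has {graph.n_nodes} nodes but the state has {initial.n} agents"
        )
    if rng is None:
        rng = config.rng()
    x = initial.opinions.copy()
    n = x.size
    het = config.heterogeneous
    eps = config.epsilon_array(n) if het else float(config.epsilon)
    media_arr = media.as_array()
    adjacency = None if graph is None else graph.accessor()
    gamma, mu, p_m, floor = config.gamma, config.mu, config.p_m, config.distance_floor

    snapshots: list = []
    history: deque = deque(maxlen=stop.patience if stop is not None else 1)
    below = 0
    stop_reason = STOP_ITERATION_CAP
    steps_done = 0

    for step in range(config.max_iterations):
        change = _step_inplace(
            x, eps, het, gamma, mu, p_m, floor, media_arr, rng, adjacency
        )
        steps_done = step + 1
        if snapshot_stride and steps_done % snapshot_stride == 0:
            snapshots.append((initial.time + steps_done, x.copy()))
        if stop is None:
            continue
        if stop.kind == "max_change":
            below = below + 1 if change < stop.change_threshold else 0
            if below >= stop.patience:
                stop_reason = STOP_MAX_CHANGE
                break
        else:
            if steps_done % stop.check_stride == 0:
                history.append(detect_clusters(x, stop.gap_threshold).signature())
                if len(history) == stop.patience and equilibrium_reached(history):
                    stop_reason = STOP_EQUILIBRIUM
                    break

    return RunResult(
        final_state=OpinionState(x, initial.time + steps_done),
        iterations=steps_done,
        converged=stop_reason != STOP_ITERATION_CAP,
        stop_reason=stop_reason,
        snapshots=snapshots,
    )


@dataclass
class EnsembleResult:
    """Per-run sweep records, per-grid-point aggregates, and final opinion
    vectors (in record order)."""

    runs: pd.DataFrame
    aggregates: pd.DataFrame
    final_opinions: list

    GROUP_KEYS = ["epsilon", "gamma", "p_m"]


def _aggregate(runs: pd.DataFrame) -> pd.DataFrame:
    numeric = runs.select_dtypes(include=[np.number]).columns.difference(["seed"])
    grouped = runs.groupby(EnsembleResult.GROUP_KEYS, sort=True)[list(numeric)]
    agg = grouped.agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def run_ensemble(
    scenario: MediaLandscape,
    grid: Sequence[tuple[float, float, float]],
    n_runs: int,
    base_seed: int,
    config_template: dict | None = None,
    n_agents: int = 100,
    graph: InteractionGraph | None = None,
    stop: StoppingRule | None = None,
    initial_factory: Callable[[int, np.random.Generator], np.ndarray] | None = None,
    scenario_name: str = "",
    progress: Callable[[str], None] | None = None,
) -> EnsembleResult:
    """Run ``n_runs`` independent replicates at every (epsilon, gamma, p_m) grid
    point.

    Replicate ``r`` uses seed ``base_seed + r`` and draws its initial opinions
    from its own stream (uniform on [0, 1] unless ``initial_factory`` overrides),
    so replicates are independent but reproducible and the p_m = 0 column of any
    scenario is trajectory-identical to a media-free baseline under matched
    seeds.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must contain at least one (epsilon, gamma, p_m) point")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if stop is None:
        stop = StoppingRule.cluster_equilibrium()
    template = dict(config_template or {})
    template.setdefault("mu", 0.5)
    template.setdefault("max_iterations", 1_000_000)
    draw_initial = initial_factory or uniform_initial_opinions

    records = []
    finals = []
    for eps, gamma, p_m in grid:
        for r in range(n_runs):
            seed = base_seed + r
            cfg = ModelConfig(
                epsilon=eps, gamma=gamma, p_m=p_m, seed=seed, **template
            )
            rng = cfg.rng()
            x0 = draw_initial(n_agents, rng)
            result = run(OpinionState(x0), graph, scenario, cfg, stop, rng=rng)
            row = {
                "scenario": scenario_name,
                "epsilon": eps,
                "gamma": gamma,
                "p_m": p_m,
                "seed": seed,
                "iterations": result.iterations,
                "converged": result.converged,
                "stop_reason": result.stop_reason,
            }
            row.update(
                summarize_opinions(
                    result.final_state.opinions, scenario, stop.gap_threshold
                )
            )
            records.append(row)
            finals.append(result.final_state.opinions)
        if progress is not None:
            progress(f"grid point eps={eps} gamma={gamma} p_m={p_m}: {n_runs} runs done")
    runs_df = pd.DataFrame.from_records(records)
    return EnsembleResult(runs=runs_df, aggregates=_aggregate(runs_df), final_opinions=finals)
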