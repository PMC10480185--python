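"""Compare media landscapes on a reduced parameter grid.

Runs the moderate (one medium at 0.5) and extremist (one at 0.0) landscapes at
epsilon=0.2, gamma in {0, 1}, p_m in {0, 0.5}, 10 replicates each, and prints
the mean cluster count per grid cell. Reading across a row shows how frequent
media interaction fragments the population; comparing landscapes shows the
extremist message fragments more than the moderate one.
"""

from bcmedia import GridSpec, heatmap_table, run_landscape

grid = GridSpec(
    p_m_values=(0.0, 0.5),
    epsilon_values=(0.2,),
    gamma_values=(0.0, 1.0),
    n_runs=10,
    n_agents=100,
)

for scenario in ("moderate", "extremist"):
    res = run_landscape(scenario, grid, base_seed=0)
    panel = heatmap_table(res.aggregates, "n_clusters", epsilon=0.2)
    print(f"\n{scenario} landscape — mean cluster count (rows gamma, cols p_m):")
    print(panel.round(2))
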