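"""One mean-field run with a moderate medium.

Simulates 100 agents with uniform initial opinions, confidence bound 0.3, no
algorithmic bias, and a single medium at 0.5 consumed 30% of the time, then
prints the final-state measures. The cluster count says how fragmented the
population ends up; the occupancy says what share of agents the medium captured
(within +/-0.01 of its opinion).
"""

import numpy as np

from bcmedia import (
    MediaLandscape,
    ModelConfig,
    OpinionState,
    StoppingRule,
    run,
    summarize_opinions,
    uniform_initial_opinions,
)

cfg = ModelConfig(epsilon=0.3, gamma=0.0, p_m=0.3, mu=0.5, seed=42, max_iterations=10**6)
media = MediaLandscape((0.5,))
rng = cfg.rng()
x0 = uniform_initial_opinions(100, rng)

result = run(OpinionState(x0), None, media, cfg, StoppingRule.cluster_equilibrium(), rng=rng)

print(f"stopped after {result.iterations} steps ({result.stop_reason})")
for key, value in summarize_opinions(result.final_state.opinions, media).items():
    print(f"  {key}: {value:.4f}" if isinstance(value, float) else f"  {key}: {value}")
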