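# Model and methods

## The dynamics

The model couples three ingredients on a population of N agents with
continuous opinions on [0, 1]:

1. **Bounded confidence** (cognitive bias). A pair (i, j) within opinion
   distance ε of each other averages towards one another with convergence
   parameter μ ∈ (0, 0.5]; at μ = 0.5 both adopt the pair mean, which makes
   every accepted pair event conserve the opinion sum exactly. Pairs further
   apart than ε ignore each other.
2. **Algorithmic bias** (recommender system). The peer j is not drawn
   uniformly but with probability proportional to d_ij^(−γ). γ = 0 recovers
   uniform (Deffuant–Weisbuch) partner choice; γ around 1–1.5 strongly favors
   like-minded peers. Distances are clamped from below at 10⁻⁴ so coincident
   opinions have a finite weight; the same floor applies to media selection.
3. **Stubborn media** (external propaganda). M media agents hold fixed
   opinions and are reachable by everyone. After the pair event, the selected
   agent i consumes one medium with probability p_m; the medium is chosen with
   the same biased kernel over media opinions, and persuades (one-sided
   averaging) only if it lies within the agent's confidence bound. Bias
   governs which medium is approached; ε governs whether it persuades.

One iteration is one pair event (plus the possible media event). All
randomness flows from a single seeded generator consumed in a fixed,
documented order (agent, peer, media coin, medium), so every run is
replayable and the γ = 0, p_m = 0 limit is stream-identical to a naive
textbook implementation of the Deffuant–Weisbuch model — a property the test
suite checks draw-for-draw over 10⁴ steps.

The heterogeneous variant replaces the shared ε by per-agent bounds ε_i and
gates each side of the update separately and *strictly* (d < ε_i moves i,
d < ε_j moves j, both evaluated on pre-update opinions). The homogeneous rule
keeps the non-strict `≤` gate. The discrepancy at exact equality is
intentional and documented rather than reconciled; it is observable only on a
measure-zero set of inputs.

## Parameters

| Parameter | Meaning | Default / range |
| --- | --- | --- |
| ε | confidence bound ("open-mindedness"), scalar or per-agent | [0, 1] |
| γ | algorithmic-bias exponent | ≥ 0, grid {0} ∪ {0.5 … 1.5 step 0.25} |
| μ | convergence parameter | 0.5 (pair averaging), (0, 0.5] |
| p_m | per-step media-interaction probability | [0, 1], grid 0 … 0.5 step 0.1 |
| d_floor | lower clamp on kernel distances | 10⁻⁴ |
| N | population size | 100 (mean-field experiments) |
| cap | iteration cap | 10⁶ mean-field, 10⁵ network mode |

Named media landscapes: moderate (0.5), extremist (0.0), polarized
(0.05, 0.95), balanced (0.05, 0.5, 0.95) — adjacent balanced media are 0.45
apart, which is why ε = 0.4 populations in that landscape can be torn between
two media at once and fail to equilibrate. The network case-study landscapes
are the faction averages 0.28 (pro), 0.49 (neutral), 0.87 (against), singly,
as the polarized pair, or all three.

## Stopping rules

*Cluster equilibrium* (mean-field default): every 1,000 steps the final
opinions are partitioned by the gap rule (sorted opinions split where a
consecutive gap strictly exceeds 0.01); the run stops once 10 consecutive
partitions are identical in membership. The stride and patience are our
operational choice for "the cluster configuration no longer changes" — the
published design leaves them unstated — and both are configurable. Spot
checks against runs forced to the full 10⁶-step cap show identical final
partitions at ε ≤ 0.5, γ = 0 (see the satellite caveat below for strong
bias).

*Maximum-change window* (network/case-study default): stop when the per-step
maximum absolute opinion change stays below 0.01 for 500 consecutive
iterations, cap 10⁵.

## Measures

- **Cluster count** from the gap rule; a gap exactly equal to the threshold
  does not split. Singletons count as clusters, so we also report a
  *major*-cluster count (size ≥ 2% of N) and, where the analysis concerns the
  main opinion poles, a *main*-cluster filter (≥ 10% of N).
- **Participation ratio** C = (Σc_i)²/Σc_i² ∈ [1, n]: the effective number of
  equally sized clusters (n iff all equal, ≈1 under one dominant cluster).
- **Media occupancy**: percentage of agents in the closed band x_m ± 0.01.
- **Peak pairwise distance**: mean |mean_a − mean_b| over cluster-mean pairs
  (an all-agent-pairs variant, `mean_pairwise_distance`, is provided since
  either reading of "average pairwise distance" is defensible).
- **Opinion entropy**: Shannon entropy (base 2) over 100 equal bins — base
  and binning are artifact conventions.
- **Echo-chamber statistics**: per non-isolated node, (own opinion, mean
  neighbor opinion); their Pearson correlation is the polarization measure,
  reported as undefined when a marginal is degenerate.

## Synthetic fixtures and what they do (not) show

The mean-field experiments need no data: uniform initial opinions on a
complete graph of 100 agents. The network mode is exercised on a two-block
generator: two equal communities, Bernoulli edges (dense within, sparse
between), truncated-normal opinions around community means 0.28 and 0.87
(spread 0.1 by default, chosen to produce visibly separated factions). This
emulates the two-faction structure of a polarized online discussion — the
statistics that matter for the dynamics (community opinion separation,
homophily) — but not scale-free degrees, modularity beyond two blocks, or
temporal rewiring, so network-mode results here demonstrate mechanics, not
empirical claims about any particular platform. Per-agent confidence bounds
are drawn from simple distribution specs (constant / uniform / beta) standing
in for data-estimated values; estimating bounds from data is out of scope.
The leaning pipeline is tested on a seeded synthetic annotation table with
faction-leaning hashtag score profiles.

## Numerical choices and degenerate inputs

- Updates are convex combinations, so opinions cannot leave [0, 1]; with
  μ = 0.5 and no media the opinion sum drifts by < 10⁻⁹ over 10⁴ steps
  (floating-point only).
- γ = 0 selection is implemented as an exact uniform integer draw (not a
  powered-weight computation), which is both faster and exactly matches a
  naive reference stream.
- Biased selection locates one uniform draw in the cumulative weight vector;
  the focal agent's own weight is zeroed rather than removed so no index
  remapping is needed.
- M = 0 or p_m = 0 skips the media coin entirely, making such runs
  stream-identical to the media-free model under the same seed.
- Degenerate cases: a single-opinion population is a fixed point and stops at
  the equilibrium rule's patience; `max_iterations = 0` returns the initial
  state with `stop_reason="iteration_cap"`; isolated nodes raise an error
  naming the node (mean-field populations cannot have one).

## Known limitations

- **Metastable satellites under strong bias.** At γ ≈ 1.5 with media, small
  (2–9 agent) clusters between media positions collapse to near-zero width,
  after which the floored kernel makes them overwhelmingly self-selecting;
  they survive far beyond the 10⁶-pair-event horizon even though they would
  eventually be absorbed. Raw and 2%-major cluster counts therefore overstate
  long-horizon fragmentation in that regime; the main-cluster (≥ 10%) count
  is the robust fragmentation measure there.
- **Timescale race with strong media.** Frequent media interaction (high
  p_m) pulls in-range agents to the medium faster than the peer dynamics can
  recruit out-of-range agents, so a fully open population (ε = 0.5) splits
  rather than converging onto an extremist medium at p_m = 0.5, while at
  p_m ≈ 0.05 it is captured almost entirely — media that want adherence
  should broadcast sparingly.
- Desk-scale ensembles (10–200 replicates, chosen per analysis and recorded
  in the tests and acceptance script) carry replicate noise of a few percent
  on cluster counts; the replicate count is always reported next to the
  estimate.
- Single runs in network mode (as in the case-study design) have no
  dispersion estimate; `casestudy_mode` accepts any seed so callers can
  replicate.
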