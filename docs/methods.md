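# Methods

## Model

`pdod` scores a drug against a disease by asking, for every (drug target,
disease gene) pair, three questions: does the target reach the gene through
the directed network; is the net effect along the shortest paths activating
or inhibiting; and does that net effect, combined with the drug's own
effect type on the target, *oppose* the gene's altered state in patients?

The network is a directed multigraph of genes with ±1 edge signs
(activation/expression = +1, inhibition/repression = −1). Only shortest
paths are considered: longer routes are taken to be progressively less
reliable carriers of a regulatory effect, and the bell kernel (below)
already discounts distance, so path-length truncation at the shortest tier
is the model's central simplification. Within that tier all paths are
counted, classified by the parity of their inhibition edges — an even count
composes to net activation, an odd count to net inhibition.

### Conflict-adjusted distance

With n_a activation-like and n_i inhibition-like shortest paths at hop
distance d, the conflict-adjusted distance is
d_c = (n_a + n_i)/(n_a − n_i) · d. When all paths agree (one class empty)
d_c = ±d; as the classes approach a tie the magnitude inflates, encoding
"the paths contradict each other, trust this connection less"; at an exact
tie, or when the pair is unreachable, d_c is an infinity sentinel whose
kernel value is exactly 0.0 (never NaN), so such pairs contribute nothing.

### Score

score(R, G) = 1/(n_g·n_r) Σᵢ Σⱼ sgn(rᵢ, gⱼ) · 1/(1 + |d_c/α|²), with
sgn = i(r) · sign(d_c) · s(g). The 1/n_r factor penalises off-targets
(targets that reach no disease gene dilute the score), 1/n_g normalises
across diseases; together they bound the score in [−1, 1]. The score is
exactly antisymmetric under flipping all gene states or all drug effect
types — the property tests pin this down to the last bit.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| α | kernel half-width, in hops: the \|d_c\| at which a pair's weight falls to ½ | 3 | regulatory influence over curated pathways decays quickly past a few hops; the AUC on planted fixtures is insensitive to α once it exceeds the planted hop range |
| `pdd_projection` | graph for the baseline's hop distances | `undirected` | the baseline removes *both* effect type and effect direction; a directed-unsigned variant is exposed as a switch |

## Numerical and procedural choices

- **Path counting** is a layered BFS dynamic program over (node, parity)
  states, O(V+E) per source, with exact integer counts; an exhaustive
  DFS enumeration of minimal-length paths serves as the independent oracle
  in the tests. Parallel opposite-sign edges are both retained and count as
  distinct paths — they are genuine conflicting curated assertions.
- **Hop-0 pairs** (a drug target that is itself a disease gene) are defined
  as d_c = 0 with positive sign and kernel 1: the drug acts on the gene
  directly, so only its own effect type and the gene state decide the sign.
  This is a package convention for a case the distance formula leaves
  undefined.
- **n_r** counts the typed targets that remain after restriction to the
  network: a target absent from the network contributes no path and is
  treated as outside the modelled universe rather than as an off-target.
- **Caching**: distance censuses are computed once per source gene and
  shared across drugs; cached and per-pair recomputation are bit-identical
  (asserted in tests).
- **AUC** uses midrank tie handling, which matters because all unreachable
  drugs score exactly 0 and tie; drugs scoring 0 stay in the ranking.
- **Action vocabulary**: matching is case-insensitive and trimmed;
  `simulator` is kept verbatim from the upstream curation and `stimulator`
  is additionally accepted as the evident synonym. Unknown terms are
  dropped with a logged count, never guessed.

## Synthetic data

The generator emulates the three real inputs — pathway network, drug–target
catalogue, disease gene list — at desk scale: a 200-gene directed
Erdős–Rényi graph with edge probability 0.02 (mean degree ≈ 8, matching the
density regime of merged curated pathway maps) and 30 % inhibition edges; a
10-gene disease with random up/down states drawn from non-isolated nodes;
and 50 drugs in three planted classes: therapeutic (each target's effect
type chosen so its sgn with a disease gene within 1–3 hops is +1),
aggravating (same distances, sgn −1) and neutral (targets that reach no
disease gene, hence score exactly 0). Class fractions default to
0.3/0.4/0.3. Plants are *verified* with the production distance and scoring
code — random background edges can tie the parity classes and spoil a
construction — and re-drawn when spoiled; fixture generation
rejection-samples a fresh network (same stream) in the rare draws where
every gene reaches the disease set and no neutral target exists. The whole
fixture is a pure function of the seed.

What the generator does not emulate: expression values or
differential-expression statistics (states are emitted directly as ±1),
scale-free degree structure, pathway modularity, or correlated
drug–target portfolios. Passing the recovery tests therefore shows the
scoring machinery separates planted directional signal from a random
background — not that real networks carry such clean signal.

## Problem sizes

Tests and the recovery experiment run at 80–200 genes, 12–50 drugs and
single diseases; the distance oracle cross-check uses 500+ random graphs of
at most 12 nodes, where exhaustive path enumeration is affordable. These
sizes exercise every code path while keeping the full suite under a minute.

## Known limitations

- Only shortest paths carry signal; a longer path with consistent sign is
  ignored even when the shortest tier ties and contributes nothing.
- Parity composition assumes every inhibition edge inverts the signal
  perfectly; edge confidence and effect magnitude are not modelled.
- No null model: scores rank drugs but have no significance calibration.
- The AUC benchmark treats known therapeutic associations as the complete
  positive set; unlabelled true therapies count as negatives.
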