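# pdod

Network-based drug repositioning by **predicting drugs with opposite effects
on disease genes**. Given a signed directed molecular network (genes as
nodes, edges signed +1 for activation/expression and −1 for
inhibition/repression), a catalogue of drugs with *typed* target
interactions (activation-like such as agonists, inhibition-like such as
antagonists), and a disease's genes with their altered states (up- or
down-regulated in patients), `pdod` ranks the drugs by how strongly their
targets would *reverse* the disease genes' alterations through the network.

It is aimed at computational biologists who have a curated pathway network
(e.g. merged KEGG maps via the bundled KGML reader), a drug–target table and
a differential-expression-derived disease gene list, and want a ranked
candidate list plus an AUC benchmark against known therapeutic associations.

## The score

Between a drug target *r* and a disease gene *g*, all directed shortest
paths are counted by the parity of their inhibition edges: *n_a* paths with
an even count (activation-like), *n_i* with an odd count (inhibition-like).
The **conflict-adjusted distance** is

    d_c(r, g) = (n_a + n_i) / (n_a − n_i) · |d(r, g)|

where |d(r, g)| is the hop distance. Its sign says whether *r* net-activates
or net-inhibits *g*; its magnitude grows beyond the hop distance as the two
path classes approach a tie, and becomes infinite at a tie or when *g* is
unreachable. The drug–disease score averages a bell-shaped kernel over all
target/gene pairs, signed by whether the drug opposes each gene's state:

    score(R, G) = 1/(n_g·n_r) Σᵢ Σⱼ sgn(rᵢ, gⱼ) · 1 / (1 + |d_c(rᵢ, gⱼ)/α|²)
    sgn(rᵢ, gⱼ) = i(rᵢ) · sign(d_c(rᵢ, gⱼ)) · s(gⱼ)

with *i(r)* = +1/−1 for activation-/inhibition-like drug–target effect,
*s(g)* = +1 for down- and −1 for up-regulated genes, and α the kernel
half-width (default 3 hops). Scores lie in [−1, 1]; positive means
therapeutic direction. A directionless baseline (**PDD**) — same kernel on
undirected, unsigned hop distances with all sign factors +1 — is included to
quantify what the directional information buys.

## Worked example

Everything runs on self-contained synthetic fixtures with planted ground
truth (no downloads). Generate a 200-gene network with 50 drugs split into
therapeutic / aggravating / neutral classes, score, and evaluate:

```sh
pdod simulate --out demo/fixture --seed 1
pdod score    --network demo/fixture/network.tsv --dti demo/fixture/dti.tsv \
              --diseases demo/fixture/diseases.tsv --out demo/scores
pdod evaluate --network demo/fixture/network.tsv --dti demo/fixture/dti.tsv \
              --diseases demo/fixture/diseases.tsv \
              --answers demo/fixture/answers.tsv --out demo/eval
```

The ranking (`demo/scores/scores_disease01.tsv`) starts:

```
drug_id  drug_name                pdod_score  pdd_score  rank
D010     therapeutic compound 10  0.206250    0.555231   1.000000
D008     therapeutic compound 8   0.190660    0.513846   2.000000
D012     therapeutic compound 12  0.127076    0.504231   3.000000
```

and the evaluation prints:

```
disease_id method  alpha      auc  n_answers  n_drugs
 disease01   pdod    3.0 1.000000         15       50
 disease01    pdd    3.0 0.665714         15       50
```

The signed, directed score recovers every planted therapeutic drug
(AUC 1.0) while the directionless baseline cannot separate therapeutic from
aggravating drugs — their targets sit at identical distances — and stalls at
AUC ≈ 0.67. The same computation is available as a library:

```python
from pdod import generate_fixture, score_all, auc, SyntheticConfig

fx = generate_fixture(SyntheticConfig(seed=1))
matrix = score_all(fx.drugs, [fx.disease], fx.graph)
print(auc(matrix.scores_for("disease01", "pdod"), fx.answers))  # 1.0
```

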