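"""Self-contained synthetic fixtures with planted ground truth.

Real inputs to this method are curated pathway maps, drug-target catalogues
and disease gene lists.  The generator stands in for all three: a random
signed directed network (each ordered gene pair carries an edge
independently with ``edge_probability``, signed -1 with
``inhibition_fraction``), a disease gene set with random up/down states,
and a drug panel in three planted classes:

* therapeutic -- every target's effect type is chosen so that, through the
  net sign of its shortest paths, it opposes a disease gene's altered state
  within ``planted_hop_range`` hops;
* aggravating -- same distances, reinforcing direction;
* neutral -- targets from which no disease gene is reachable, so the score
  is exactly zero.

Plants are verified with the production conflict-distance and scoring code
(random background edges can create conflicting parallel shortest paths
that spoil a construction), and re-drawn if spoiled.  The answer set for
evaluation is the therapeutic class.  The whole fixture is a pure function
of the seed: one pseudo-random stream with a fixed draw order (network
adjacency, then edge signs, then disease genes, then states, then drugs in
class order).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .entities import DiseaseGeneSet, DrugRecord
from .evaluation import AnswerSet
from .network import SignedDigraph, build_graph, conflict_distance, parity_from_source
from .scoring import ScoreParams, pdod_score

__all__ = [
    "SyntheticConfig",
    "SyntheticFixture",
    "generate_network",
    "generate_disease",
    "plant_drugs",
    "generate_fixture",
    "write_fixture",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; identical seeds reproduce identical fixtures."""

    n_genes: int = 200
    edge_probability: float = 0.02
    inhibition_fraction: float = 0.3
    n_drugs: int = 50
    targets_per_drug: tuple[int, int] = (1, 2)
    n_disease_genes: int = 10
    planted_therapeutic_fraction: float = 0.3
    planted_aggravating_fraction: float = 0.4
    planted_hop_range: tuple[int, int] = (1, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_drugs < 1 or self.n_disease_genes < 1:
            raise ValueError("counts must be positive")
        if not (0 < self.edge_probability < 1):
            raise ValueError("edge_probability must lie in (0, 1)")
        if not (0 <= self.inhibition_fraction <= 1):
            raise ValueError("inhibition_fraction must lie in [0, 1]")
        lo, hi = self.targets_per_drug
        if not (1 <= lo <= hi):
            raise ValueError("targets_per_drug must be a positive range")
        lo, hi = self.planted_hop_range
        if not (0 <= lo <= hi):
            raise ValueError("planted_hop_range must be a non-negative range")
        frac = self.planted_therapeutic_fraction + self.planted_aggravating_fraction
        if not (0 <= self.planted_therapeutic_fraction <= 1 and frac <= 1):
            raise ValueError("class fractions must be in [0, 1] and sum to at most 1")


@dataclass
class SyntheticFixture:
    """A complete generated study: network, disease, drug panel, answers."""

    config: SyntheticConfig
    graph: SignedDigraph
    disease: DiseaseGeneSet
    drugs: list[DrugRecord]
    answers: AnswerSet
    classes: dict[str, str] = field(default_factory=dict)  # drug_id -> class


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_network(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> SignedDigraph:
    """Random signed directed graph: each off-diagonal ordered pair carries
    an edge with ``edge_probability``, signed -1 with ``inhibition_fraction``."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    names = _gene_names(config.n_genes)
    adj = rng.random((config.n_genes, config.n_genes)) < config.edge_probability
    np.fill_diagonal(adj, False)
    sources, targets = np.nonzero(adj)
    negative = rng.random(len(sources)) < config.inhibition_fraction
    records = [
        (names[int(u)], names[int(v)], -1 if neg else 1)
        for u, v, neg in zip(sources, targets, negative)
    ]
    graph = build_graph(records)
    for name in names:  # keep isolated genes as nodes
        graph.add_node(name)
    return graph


def generate_disease(
    graph: SignedDigraph,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    disease_id: str = "disease01",
) -> DiseaseGeneSet:
    """Disease gene set drawn from non-isolated nodes with random ±1 states."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    candidates = sorted(n for n in graph.nodes if graph.degree(n) > 0)
    if len(candidates) < config.n_disease_genes:
        raise ValueError(
            "network too sparse for the requested disease size; "
            "raise edge_probability or n_genes"
        )
    picked = rng.choice(len(candidates), size=config.n_disease_genes, replace=False)
    states = rng.choice([1, -1], size=config.n_disease_genes)
    genes = tuple(
        (candidates[int(i)], int(s)) for i, s in zip(sorted(picked), states)
    )
    return DiseaseGeneSet(disease_id=disease_id, genes=genes)


def _reaching_set(graph: SignedDigraph, disease: DiseaseGeneSet) -> set[str]:
    """Nodes with at least one directed path to some disease gene (hop 0 counts)."""
    reverse = graph.to_networkx().reverse(copy=False)
    reaches: set[str] = set()
    for gene, _ in disease.genes:
        reaches.add(gene)
        stack = [gene]
        while stack:
            u = stack.pop()
            for v in reverse.successors(u):
                if v not in reaches:
                    reaches.add(v)
                    stack.append(v)
    return reaches


def _planted_target(
    graph: SignedDigraph,
    disease: DiseaseGeneSet,
    config: SyntheticConfig,
    rng: np.random.Generator,
    orient: int,
    nodes: list[str],
) -> tuple[str, int] | None:
    """One (target gene, effect) whose sgn with some disease gene is ``orient``,
    verified against the production conflict distance."""
    lo, hi = config.planted_hop_range
    for _ in range(50):
        source = nodes[int(rng.integers(len(nodes)))]
        census = parity_from_source(graph, source)
        eligible = []
        for gene, state in disease.genes:
            parity = census.get(gene)
            if parity is None or not (lo <= parity.hop_distance <= hi):
                continue
            dc = conflict_distance(parity)
            if dc.is_finite:
                eligible.append((gene, state, dc.sign))
        if eligible:
            gene, state, dc_sign = eligible[int(rng.integers(len(eligible)))]
            return source, orient * dc_sign * state
    return None


def plant_drugs(
    graph: SignedDigraph,
    disease: DiseaseGeneSet,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    id_offset: int = 0,
) -> tuple[list[DrugRecord], AnswerSet, dict[str, str]]:
    """Drug panel in three classes with the therapeutic class as answer set.

    Each therapeutic/aggravating drug's score sign is re-checked with the
    production scorer and the drug is re-drawn if background paths spoil
    it; neutral drugs target nodes from which no disease gene is reachable
    and therefore score exactly zero.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    nodes = sorted(graph.nodes)
    n_ther = round(config.n_drugs * config.planted_therapeutic_fraction)
    n_agg = round(config.n_drugs * config.planted_aggravating_fraction)
    n_neut = config.n_drugs - n_ther - n_agg
    # non-isolated so the target survives an edge-table round trip
    neutral_pool = sorted(
        n for n in set(nodes) - _reaching_set(graph, disease) if graph.degree(n) > 0
    )
    if n_neut > 0 and not neutral_pool:
        raise ValueError(
            "no gene is unreachable from the disease set, so neutral drugs "
            "cannot be planted; lower edge_probability or n_disease_genes"
        )

    params = ScoreParams()
    lo_t, hi_t = config.targets_per_drug
    drugs: list[DrugRecord] = []
    classes: dict[str, str] = {}
    specs = [("therapeutic", n_ther, 1), ("aggravating", n_agg, -1), ("neutral", n_neut, 0)]
    counter = id_offset
    for cls, count, orient in specs:
        for _ in range(count):
            counter += 1
            drug_id = f"D{counter:03d}"
            for attempt in range(30):
                n_t = int(rng.integers(lo_t, hi_t + 1))
                if orient == 0:
                    picks = rng.integers(len(neutral_pool), size=n_t)
                    pairs = {
                        (neutral_pool[int(i)], int(rng.choice([1, -1]))) for i in picks
                    }
                else:
                    pairs = set()
                    for _ in range(n_t):
                        planted = _planted_target(
                            graph, disease, config, rng, orient, nodes
                        )
                        if planted is None:
                            break
                        pairs.add(planted)
                    if not pairs:
                        raise ValueError(
                            "graph too sparse to plant targets within "
                            f"planted_hop_range={config.planted_hop_range}; "
                            "raise edge_probability or widen the range"
                        )
                drug = DrugRecord(
                    drug_id=drug_id, name=f"{cls} compound {counter}", targets=tuple(sorted(pairs))
                )
                score = pdod_score(drug, disease, graph, params)
                ok = (
                    (orient == 0 and score == 0.0)
                    or (orient > 0 and score > 0)
                    or (orient < 0 and score < 0)
                )
                if ok:
                    break
            else:
                raise ValueError(
                    f"could not plant a {cls} drug after 30 attempts; "
                    "adjust edge_probability or planted_hop_range"
                )
            drugs.append(drug)
            classes[drug_id] = cls
    answer_ids = frozenset(d for d, c in classes.items() if c == "therapeutic")
    return drugs, AnswerSet(disease.disease_id, answer_ids), classes


def generate_fixture(config: SyntheticConfig) -> SyntheticFixture:
    """Full study from one seed: network, disease, planted drug panel.

    Rejection-samples from the generative model (bounded retries on the
    same stream, so the fixture stays a pure function of the seed) when a
    draw leaves no gene unreachable for the neutral class.
    """
    rng = np.random.default_rng(config.seed)
    needs_neutral = (
        config.n_drugs
        - round(config.n_drugs * config.planted_therapeutic_fraction)
        - round(config.n_drugs * config.planted_aggravating_fraction)
    ) > 0
    graph = disease = None
    for _ in range(50):
        graph = generate_network(config, rng)
        for _ in range(5):
            candidate = generate_disease(graph, config, rng)
            pool = [
                n
                for n in set(graph.nodes) - _reaching_set(graph, candidate)
                if graph.degree(n) > 0
            ]
            if not needs_neutral or pool:
                disease = candidate
                break
        if disease is not None:
            break
    if disease is None:
        raise ValueError(
            "every gene reaches the disease set in all attempts; "
            "lower edge_probability or n_disease_genes"
        )
    drugs, answers, classes = plant_drugs(graph, disease, config, rng)
    return SyntheticFixture(
        config=config, graph=graph, disease=disease, drugs=drugs, answers=answers,
        classes=classes,
    )


_EFFECT_ACTION = {1: "agonist", -1: "antagonist"}
_STATE_NAME = {1: "down", -1: "up"}


def write_fixture(fixture: SyntheticFixture, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture as the TSV dialects the loaders consume.

    Emits network.tsv, dti.tsv, diseases.tsv, answers.tsv and a
    manifest.json recording the config; reruns with the same seed are
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.tsv" for name in ("network", "dti", "diseases", "answers")}

    with open(paths["network"], "w") as fh:
        fh.write("source\ttarget\teffect\n")
        for u, v, s in sorted(fixture.graph.edges()):
            fh.write(f"{u}\t{v}\t{'activation' if s == 1 else 'inhibition'}\n")
    with open(paths["dti"], "w") as fh:
        fh.write("drug_id\tdrug_name\tgene\taction\n")
        for drug in fixture.drugs:
            for gene, effect in drug.targets:
                fh.write(f"{drug.drug_id}\t{drug.name}\t{gene}\t{_EFFECT_ACTION[effect]}\n")
    with open(paths["diseases"], "w") as fh:
        fh.write("disease_id\tgene\tstate\n")
        for gene, state in fixture.disease.genes:
            fh.write(f"{fixture.disease.disease_id}\t{gene}\t{_STATE_NAME[state]}\n")
    with open(paths["answers"], "w") as fh:
        fh.write("disease_id\tdrug_id\n")
        for drug_id in sorted(fixture.answers.therapeutic_drug_ids):
            fh.write(f"{fixture.answers.disease_id}\t{drug_id}\n")

    manifest = outdir / "manifest.json"
    manifest.write_text(
        json.dumps(
            {"config": dataclasses.asdict(fixture.config), "classes": fixture.classes},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    paths["manifest"] = manifest
    return paths
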