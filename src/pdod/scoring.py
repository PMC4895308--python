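"""PDOD and PDD drug-disease scores.

The PDOD score between a drug R with typed targets r_i and a disease G with
state-annotated genes g_j is

    score(R, G) = 1/(n_g * n_r) * sum_i sum_j sgn(r_i, g_j) * 1/(1 + |d_c(r_i, g_j)/alpha|^2)

with sgn(r_i, g_j) = i(r_i) * sign(d_c(r_i, g_j)) * s(g_j): the product of
the drug-target effect type (+1 activation-like, -1 inhibition-like), the
sign of the conflict-adjusted distance, and the gene's altered state (+1
down-regulated, -1 up-regulated).  sgn = +1 means the drug opposes the
gene's alteration through this target.  The bell kernel halves at
|d_c| = alpha (default 3) and vanishes exactly at the infinity sentinel, so
unreachable or conflict-tied pairs contribute nothing.  Normalising by the
target count n_r penalises off-targets; by the gene count n_g it bounds the
score within [-1, 1].

PDD is the directionless baseline: the same kernel on plain hop distances
over the unsigned, undirected projection of the network, with every sign
factor fixed at +1, so it lies in [0, 1] and cannot tell a therapeutic
drug from an aggravating one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import pandas as pd

from .entities import DiseaseGeneSet, DrugRecord
from .network import ConflictDistance, SignedDigraph, conflict_distance, parity_from_source

__all__ = [
    "ScoreParams",
    "PairTerm",
    "ScoreMatrix",
    "DistanceCache",
    "bell_kernel",
    "sgn_term",
    "pdod_score",
    "pdd_score",
    "score_all",
]


@dataclass(frozen=True)
class ScoreParams:
    """Scoring parameters.

    alpha
        Half-width of the bell kernel: the |d_c| at which a pair's
        contribution drops to one half.  Default 3 hops.
    pdd_projection
        Graph used for the PDD baseline's hop distances: ``"undirected"``
        (default; both effect type and direction removed) or ``"directed"``
        (signs removed, direction kept).
    """

    alpha: float = 3.0
    pdd_projection: Literal["undirected", "directed"] = "undirected"

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.pdd_projection not in ("undirected", "directed"):
            raise ValueError(f"bad pdd_projection {self.pdd_projection!r}")


def bell_kernel(d_c: ConflictDistance | float, params: ScoreParams) -> float:
    """Bell-shaped proximity weight 1/(1 + (|d_c|/alpha)^2) in [0, 1].

    The infinity sentinel maps to exactly 0.0 and d_c = 0 to exactly 1.0.
    """
    value = d_c.value if isinstance(d_c, ConflictDistance) else d_c
    if math.isinf(value):
        return 0.0
    if value == 0:
        return 1.0
    return 1.0 / (1.0 + (abs(value) / params.alpha) ** 2)


def sgn_term(i_effect: int, d_c_sign: int, gene_state: int) -> int:
    """Sign product i(r) * sign(d_c) * s(g); +1 means the drug opposes the
    disease gene's altered state through this target."""
    for name, v in (("i_effect", i_effect), ("d_c_sign", d_c_sign), ("gene_state", gene_state)):
        if v not in (1, -1):
            raise ValueError(f"{name} must be +1 or -1, got {v}")
    return i_effect * d_c_sign * gene_state


class DistanceCache:
    """Per-source distance censuses, shared across drugs with common targets.

    Conflict-adjusted distances come from one signed BFS parity census per
    source gene; PDD hop distances from one BFS on the unsigned projection.
    Cached and uncached runs are bit-identical because the cache stores the
    exact objects the direct computation produces.
    """

    def __init__(self, graph: SignedDigraph, params: ScoreParams) -> None:
        self._graph = graph
        self._params = params
        self._dc: dict[str, dict[str, ConflictDistance]] = {}
        self._hops: dict[str, dict[str, int]] = {}
        if params.pdd_projection == "undirected":
            self._projection = graph.undirected_unsigned()
        else:
            self._projection = nx.DiGraph(graph.to_networkx())

    def conflict_distances_from(self, source: str) -> dict[str, ConflictDistance]:
        if source not in self._dc:
            census = parity_from_source(self._graph, source)
            self._dc[source] = {g: conflict_distance(p) for g, p in census.items()}
        return self._dc[source]

    def hops_from(self, source: str) -> dict[str, int]:
        if source not in self._hops:
            self._hops[source] = nx.single_source_shortest_path_length(
                self._projection, source
            )
        return self._hops[source]


@dataclass(frozen=True)
class PairTerm:
    """One (target, disease gene) contribution to a drug-disease score."""

    drug_id: str
    target: str
    disease_gene: str
    d_c: float
    sgn: int
    kernel: float
    contribution: float


def _pdod_terms(
    drug: DrugRecord,
    disease: DiseaseGeneSet,
    cache: DistanceCache,
    params: ScoreParams,
) -> Iterable[PairTerm]:
    for target, i_effect in drug.targets:
        dc_map = cache.conflict_distances_from(target)
        for gene, state in disease.genes:
            dc = dc_map.get(gene)
            if dc is None or not dc.is_finite:
                yield PairTerm(drug.drug_id, target, gene, math.inf, 0, 0.0, 0.0)
                continue
            k = bell_kernel(dc, params)
            s = sgn_term(i_effect, dc.sign, state)
            yield PairTerm(drug.drug_id, target, gene, dc.value, s, k, s * k)


def pdod_score(
    drug: DrugRecord,
    disease: DiseaseGeneSet,
    graph: SignedDigraph,
    params: ScoreParams | None = None,
    cache: DistanceCache | None = None,
) -> float:
    """PDOD score in [-1, 1]; positive when the drug tends to reverse the
    disease genes' altered states.

    Inputs are expected to have passed through graph restriction: every
    target and disease gene must be a node of ``graph``.
    """
    params = params or ScoreParams()
    cache = cache or DistanceCache(graph, params)
    for gene, _ in list(drug.targets) + list(disease.genes):
        if gene not in graph:
            raise KeyError(f"gene {gene!r} not in graph; run restrict_to_graph first")
    total = sum(t.contribution for t in _pdod_terms(drug, disease, cache, params))
    return total / (drug.n_targets * disease.n_genes)


def pdd_score(
    drug: DrugRecord,
    disease: DiseaseGeneSet,
    graph: SignedDigraph,
    params: ScoreParams | None = None,
    cache: DistanceCache | None = None,
) -> float:
    """Directionless baseline score in [0, 1]: bell kernel on plain hop
    distances over the unsigned projection, all sign factors +1."""
    params = params or ScoreParams()
    cache = cache or DistanceCache(graph, params)
    for gene, _ in list(drug.targets) + list(disease.genes):
        if gene not in graph:
            raise KeyError(f"gene {gene!r} not in graph; run restrict_to_graph first")
    total = 0.0
    for target, _ in drug.targets:
        hops = cache.hops_from(target)
        for gene, _ in disease.genes:
            if gene in hops:
                total += bell_kernel(float(hops[gene]), params)
    return total / (drug.n_targets * disease.n_genes)


@dataclass
class ScoreMatrix:
    """Drug x disease score matrix with per-pair provenance.

    ``pdod`` and ``pdd`` map (drug_id, disease_id) to scores; ``detail``
    maps the same key to the list of :class:`PairTerm` contributions, which
    recompose the PDOD score exactly as sum(contribution)/(n_r * n_g).
    """

    pdod: dict[tuple[str, str], float] = field(default_factory=dict)
    pdd: dict[tuple[str, str], float] = field(default_factory=dict)
    detail: dict[tuple[str, str], list[PairTerm]] = field(default_factory=dict)
    drug_names: dict[str, str] = field(default_factory=dict)

    def ranking(self, disease_id: str, method: str = "pdod") -> pd.DataFrame:
        """Per-disease ranking table (rank 1 = highest score, midrank ties)."""
        scores = getattr(self, method)
        rows = [
            {"drug_id": d, "drug_name": self.drug_names.get(d, d), f"{method}_score": s}
            for (d, dis), s in scores.items()
            if dis == disease_id
        ]
        frame = pd.DataFrame(rows).sort_values(
            [f"{method}_score", "drug_id"], ascending=[False, True]
        )
        frame["rank"] = (
            frame[f"{method}_score"].rank(ascending=False, method="average").astype(float)
        )
        return frame.reset_index(drop=True)

    def scores_for(self, disease_id: str, method: str = "pdod") -> dict[str, float]:
        scores = getattr(self, method)
        return {d: s for (d, dis), s in scores.items() if dis == disease_id}

    def detail_frame(self) -> pd.DataFrame:
        rows = []
        for (drug_id, disease_id), terms in self.detail.items():
            for t in terms:
                rows.append(
                    {
                        "drug_id": drug_id,
                        "disease_id": disease_id,
                        "target": t.target,
                        "disease_gene": t.disease_gene,
                        "d_c": t.d_c,
                        "sgn": t.sgn,
                        "kernel": t.kernel,
                        "contribution": t.contribution,
                    }
                )
        return pd.DataFrame(rows)


def score_all(
    drugs: Sequence[DrugRecord],
    diseases: Sequence[DiseaseGeneSet],
    graph: SignedDigraph,
    params: ScoreParams | None = None,
    methods: tuple[str, ...] = ("pdod", "pdd"),
    keep_detail: bool = False,
) -> ScoreMatrix:
    """Score every drug against every disease.

    Distance censuses are computed once per source gene and shared across
    drugs with common targets; results are identical to independent
    per-pair calls of :func:`pdod_score` / :func:`pdd_score`.
    """
    params = params or ScoreParams()
    cache = DistanceCache(graph, params)
    matrix = ScoreMatrix(drug_names={d.drug_id: d.name for d in drugs})
    for drug in drugs:
        for disease in diseases:
            key = (drug.drug_id, disease.disease_id)
            if "pdod" in methods:
                terms = list(_pdod_terms(drug, disease, cache, params))
                matrix.pdod[key] = sum(t.contribution for t in terms) / (
                    drug.n_targets * disease.n_genes
                )
                if keep_detail:
                    matrix.detail[key] = terms
            if "pdd" in methods:
                matrix.pdd[key] = pdd_score(drug, disease, graph, params, cache)
    return matrix
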