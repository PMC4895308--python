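"""Drugs with typed target interactions and disease genes with altered states.

Drug-target interactions carry an *effect type*: activation-like (+1, e.g.
agonist) or inhibition-like (-1, e.g. antagonist), classified from free-text
action terms against a fixed vocabulary.  Disease genes carry an *altered
state*: s(g) = +1 when the gene is down-regulated in patients, -1 when
up-regulated.  Both conventions feed the sign product of the scoring module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .network import SignedDigraph

logger = logging.getLogger(__name__)

__all__ = [
    "ActionVocabulary",
    "DrugRecord",
    "DiseaseGeneSet",
    "RestrictionReport",
    "classify_action",
    "load_dti_table",
    "load_disease_table",
    "restrict_to_graph",
]

_DEFAULT_ACTIVATION_LIKE = frozenset(
    {
        "activation",
        "agonist",
        "activator",
        "simulator",  # as curated upstream; see stimulator below
        "stimulator",  # accepted as the evident synonym
        "partial agonist",
    }
)
_DEFAULT_INHIBITION_LIKE = frozenset(
    {
        "inhibition",
        "inhibitor",
        "antagonist",
        "negative modulator",
        "inverse agonist",
        "suppressor",
        "inhibitor (competitive)",
        "partial antagonist",
        "reducer",
        "blocker",
    }
)


@dataclass(frozen=True)
class ActionVocabulary:
    """Disjoint sets of action terms mapped to ±1 effect types."""

    activation_like: frozenset[str] = _DEFAULT_ACTIVATION_LIKE
    inhibition_like: frozenset[str] = _DEFAULT_INHIBITION_LIKE

    def __post_init__(self) -> None:
        overlap = self.activation_like & self.inhibition_like
        if overlap:
            raise ValueError(f"action terms in both classes: {sorted(overlap)}")


@dataclass(frozen=True)
class DrugRecord:
    """A drug with its typed target interactions.

    ``targets`` holds unique ``(gene id, effect)`` pairs, effect +1 for
    activation-like and -1 for inhibition-like interactions.  Drugs with no
    typed target are never admitted to scoring.
    """

    drug_id: str
    name: str
    targets: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"drug {self.drug_id!r} has no typed targets")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"drug {self.drug_id!r} has duplicate target pairs")
        for gene, effect in self.targets:
            if effect not in (1, -1):
                raise ValueError(
                    f"drug {self.drug_id!r} target {gene!r}: effect must be +1 or -1"
                )

    @property
    def n_targets(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class DiseaseGeneSet:
    """Disease genes with their altered states (+1 down-, -1 up-regulated)."""

    disease_id: str
    genes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"disease {self.disease_id!r} has no genes")
        names = [g for g, _ in self.genes]
        if len(set(names)) != len(names):
            raise ValueError(f"disease {self.disease_id!r} lists a gene twice")
        for gene, state in self.genes:
            if state not in (1, -1):
                raise ValueError(
                    f"disease {self.disease_id!r} gene {gene!r}: state must be +1 or -1"
                )

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def classify_action(term: str, vocab: ActionVocabulary | None = None) -> int | str:
    """Map an action term to +1 (activation-like), -1 (inhibition-like) or
    ``"unknown"``.  Matching is case-insensitive after trimming; unknown is
    a value, not an error."""
    vocab = vocab or ActionVocabulary()
    token = term.strip().lower()
    if token in vocab.activation_like:
        return 1
    if token in vocab.inhibition_like:
        return -1
    return "unknown"


_DTI_COLUMNS = ("drug_id", "drug_name", "gene", "action")


def load_dti_table(path, vocab: ActionVocabulary | None = None) -> list[DrugRecord]:
    """Read a drug-target interaction TSV into typed :class:`DrugRecord`\\ s.

    Rows whose action terms fall outside the vocabulary are dropped (their
    count is logged); drugs left without any typed target are excluded.
    """
    vocab = vocab or ActionVocabulary()
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"DTI table {path} is empty") from exc
    missing = [c for c in _DTI_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DTI table {path} missing column(s): {missing}")
    if table.empty:
        raise ValueError(f"DTI table {path} is empty")

    effects = table["action"].map(lambda t: classify_action(t, vocab))
    n_unknown = int((effects == "unknown").sum())
    if n_unknown:
        logger.info("dropped %d DTI rows with unknown action terms", n_unknown)
    typed = table[effects != "unknown"].assign(effect=effects[effects != "unknown"])

    drugs: list[DrugRecord] = []
    for drug_id, group in typed.groupby("drug_id", sort=True):
        pairs = tuple(
            dict.fromkeys((row.gene, int(row.effect)) for row in group.itertuples())
        )
        drugs.append(
            DrugRecord(drug_id=drug_id, name=group["drug_name"].iloc[0], targets=pairs)
        )
    return drugs


_STATE_VALUES = {"down": 1, "up": -1, "+1": 1, "1": 1, "-1": -1}


def load_disease_table(path) -> list[DiseaseGeneSet]:
    """Read a disease gene table TSV (disease_id, gene, state ∈ {up, down})."""
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"disease table {path} is empty") from exc
    missing = [c for c in ("disease_id", "gene", "state") if c not in table.columns]
    if missing:
        raise ValueError(f"disease table {path} missing column(s): {missing}")
    if table.empty:
        raise ValueError(f"disease table {path} is empty")
    diseases: list[DiseaseGeneSet] = []
    for disease_id, group in table.groupby("disease_id", sort=True):
        genes = []
        for row in group.itertuples():
            token = row.state.strip().lower()
            if token not in _STATE_VALUES:
                raise ValueError(
                    f"disease {disease_id!r} gene {row.gene!r}: bad state {row.state!r}"
                )
            genes.append((row.gene, _STATE_VALUES[token]))
        diseases.append(DiseaseGeneSet(disease_id=disease_id, genes=tuple(genes)))
    return diseases


@dataclass
class RestrictionReport:
    """Counts of every removal performed by :func:`restrict_to_graph`."""

    targets_outside_graph: int = 0
    drugs_without_targets: int = 0
    genes_outside_graph: int = 0
    isolated_genes: int = 0
    diseases_without_genes: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def restrict_to_graph(
    drugs: Sequence[DrugRecord],
    diseases: Sequence[DiseaseGeneSet],
    graph: SignedDigraph,
) -> tuple[list[DrugRecord], list[DiseaseGeneSet], RestrictionReport]:
    """Drop drug targets and disease genes that cannot participate in scoring.

    Drug targets absent from the network are removed (a drug losing all its
    targets is excluded); disease genes absent from the network or isolated
    (zero total degree) are removed, and diseases losing all genes are
    excluded.  The report counts every removal class.  Idempotent.
    """
    report = RestrictionReport()
    kept_drugs: list[DrugRecord] = []
    for drug in drugs:
        in_graph = tuple(t for t in drug.targets if t[0] in graph)
        report.targets_outside_graph += drug.n_targets - len(in_graph)
        if in_graph:
            kept_drugs.append(
                DrugRecord(drug_id=drug.drug_id, name=drug.name, targets=in_graph)
            )
        else:
            report.drugs_without_targets += 1

    kept_diseases: list[DiseaseGeneSet] = []
    for disease in diseases:
        kept_genes = []
        for gene, state in disease.genes:
            if gene not in graph:
                report.genes_outside_graph += 1
            elif graph.degree(gene) == 0:
                report.isolated_genes += 1
            else:
                kept_genes.append((gene, state))
        if kept_genes:
            kept_diseases.append(
                DiseaseGeneSet(disease_id=disease.disease_id, genes=tuple(kept_genes))
            )
        else:
            report.diseases_without_genes += 1

    return kept_drugs, kept_diseases, report
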