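"""Ranking evaluation: AUC of known therapeutic drugs against the rest.

For each disease the drugs are ranked by score and the area under the ROC
curve measures how well known therapeutic ("answer") drugs separate from
all others.  The AUC equals the rank-sum (Mann-Whitney) probability that a
randomly chosen answer drug outscores a randomly chosen non-answer drug,
with tied scores -- frequent, since unreachable drugs all score exactly
zero -- resolved by midrank averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from sklearn.metrics import roc_auc_score

from .entities import DiseaseGeneSet, DrugRecord
from .network import SignedDigraph
from .scoring import ScoreParams, score_all

logger = logging.getLogger(__name__)

__all__ = ["AnswerSet", "auc", "alpha_sweep", "load_answer_table"]


@dataclass(frozen=True)
class AnswerSet:
    """Known therapeutic drug ids for one disease."""

    disease_id: str
    therapeutic_drug_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.therapeutic_drug_ids:
            raise ValueError(f"answer set for {self.disease_id!r} is empty")

    def restricted_to(self, drug_universe: set[str]) -> "AnswerSet":
        """Drop answer ids absent from the scored drug universe (logged)."""
        kept = frozenset(self.therapeutic_drug_ids & drug_universe)
        dropped = len(self.therapeutic_drug_ids) - len(kept)
        if dropped:
            logger.info(
                "disease %s: dropped %d answer drugs outside the scored universe",
                self.disease_id,
                dropped,
            )
        return AnswerSet(self.disease_id, kept)


def auc(scores: Mapping[str, float], answers: AnswerSet) -> float:
    """Midrank-tie AUC of answer drugs versus the rest, in [0, 1].

    Rejects degenerate inputs (no answers among the scored drugs, or no
    non-answer drugs).
    """
    labels = [1 if d in answers.therapeutic_drug_ids else 0 for d in scores]
    if sum(labels) == 0 or sum(labels) == len(labels):
        raise ValueError(
            f"disease {answers.disease_id!r}: need both answer and non-answer drugs"
        )
    return float(roc_auc_score(labels, list(scores.values())))


def alpha_sweep(
    drugs: Sequence[DrugRecord],
    diseases: Sequence[DiseaseGeneSet],
    graph: SignedDigraph,
    answers: Mapping[str, AnswerSet],
    alphas: Sequence[float],
    methods: tuple[str, ...] = ("pdod", "pdd"),
) -> pd.DataFrame:
    """AUC grid over diseases x alpha values for each requested method.

    Returns a tidy frame with columns disease_id, method, alpha, auc,
    n_answers, n_drugs.  Diseases with degenerate answer sets are reported
    and skipped; the sweep continues for the others.
    """
    if not list(alphas):
        raise ValueError("alphas must be non-empty")
    rows = []
    for alpha in alphas:
        params = ScoreParams(alpha=float(alpha))
        matrix = score_all(drugs, diseases, graph, params, methods=methods)
        for disease in diseases:
            if disease.disease_id not in answers:
                continue
            answer = answers[disease.disease_id]
            for method in methods:
                scores = matrix.scores_for(disease.disease_id, method)
                answer_here = answer.restricted_to(set(scores))
                try:
                    value = auc(scores, answer_here)
                except ValueError as exc:
                    logger.warning("skipping AUC: %s", exc)
                    continue
                rows.append(
                    {
                        "disease_id": disease.disease_id,
                        "method": method,
                        "alpha": float(alpha),
                        "auc": value,
                        "n_answers": len(answer_here.therapeutic_drug_ids),
                        "n_drugs": len(scores),
                    }
                )
    return pd.DataFrame(
        rows, columns=["disease_id", "method", "alpha", "auc", "n_answers", "n_drugs"]
    )


def load_answer_table(path) -> dict[str, AnswerSet]:
    """Read an answer-set TSV (disease_id, drug_id) into per-disease sets."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("disease_id", "drug_id") if c not in table.columns]
    if missing:
        raise ValueError(f"answer table {path} missing column(s): {missing}")
    return {
        disease_id: AnswerSet(disease_id, frozenset(group["drug_id"]))
        for disease_id, group in table.groupby("disease_id", sort=True)
    }
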