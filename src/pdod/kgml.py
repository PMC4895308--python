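"""KGML (KEGG Markup Language) pathway ingestion.

Only the subset of KGML that carries unambiguous regulatory direction is
consumed: ``entry`` elements of type ``gene`` (and ``group`` entries, which
expand to their member genes) contribute nodes, and ``relation`` subtypes
named activation, inhibition, expression or repression contribute signed
edges.  Everything else -- compounds, maps, binding/association,
phosphorylation and other mechanism-only subtypes -- is skipped, with a
logged count, because it states no effect direction.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from typing import Iterable

from .network import EFFECT_SIGNS

logger = logging.getLogger(__name__)

__all__ = ["parse_kgml"]

_DIRECTED_SUBTYPES = frozenset(EFFECT_SIGNS)  # activation/inhibition/expression/repression


def _entry_genes(entry: ET.Element) -> list[str]:
    # KGML "name" holds space-separated ids, e.g. "hsa:1956 hsa:2099"
    return (entry.get("name") or "").split()


def parse_kgml(xml_content: str | bytes) -> list[tuple[str, str, int]]:
    """Extract signed edge records from one KGML document.

    Returns ``(source gene, target gene, sign)`` tuples with
    activation/expression mapped to +1 and inhibition/repression to -1.
    Entries naming multiple genes fan out to all source-target pairs.  A
    document with no qualifying relation yields an empty list (valid).
    Malformed XML is rejected.
    """
    try:
        root = ET.fromstring(xml_content)
    except ET.ParseError as exc:
        raise ValueError(f"malformed KGML document: {exc}") from exc

    genes_by_entry: dict[str, list[str]] = {}
    groups: dict[str, list[str]] = {}
    for entry in root.iter("entry"):
        entry_id = entry.get("id")
        entry_type = entry.get("type")
        if entry_id is None:
            continue
        if entry_type == "gene":
            genes_by_entry[entry_id] = _entry_genes(entry)
        elif entry_type == "group":
            groups[entry_id] = [
                c.get("id") for c in entry.iter("component") if c.get("id")
            ]

    def resolve(entry_id: str) -> list[str]:
        if entry_id in genes_by_entry:
            return genes_by_entry[entry_id]
        if entry_id in groups:
            genes: list[str] = []
            for member in groups[entry_id]:
                genes.extend(genes_by_entry.get(member, []))
            return genes
        return []

    edges: list[tuple[str, str, int]] = []
    n_skipped = 0
    for relation in root.iter("relation"):
        sources = resolve(relation.get("entry1", ""))
        targets = resolve(relation.get("entry2", ""))
        subtype_names = [s.get("name", "").lower() for s in relation.iter("subtype")]
        kept = [n for n in subtype_names if n in _DIRECTED_SUBTYPES]
        n_skipped += len(subtype_names) - len(kept)
        if not sources or not targets:
            continue
        for name in kept:
            sign = EFFECT_SIGNS[name]
            for src in sources:
                for dst in targets:
                    edges.append((src, dst, sign))
    if n_skipped:
        logger.info("skipped %d relation subtypes without effect direction", n_skipped)
    return edges
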