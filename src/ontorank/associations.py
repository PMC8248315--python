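"""Entity-to-class association tables and the standard input filters.

Four relation vocabularies link genes and diseases to ontology classes:
``has-phenotype`` (MP/HPO-style), ``has-function`` (GO-style),
``expressed-in`` (UBERON-style anatomy) and ``has-celltype`` (CL-style).
The filters mirror common curation practice: GO annotations inferred
electronically (IEA) or without biological data (ND) are excluded;
a gene counts as expressed in a tissue at >= 4.0 transcripts per million
(TPM); protein interactions are kept at confidence >= 700 on the
STRING 0-1000 scale; mouse annotations are carried to human genes by an
ortholog join.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RELATION_VOCABULARY = frozenset(
    {"has-phenotype", "has-function", "expressed-in", "has-celltype"}
)
EXCLUDED_EVIDENCE_CODES = frozenset({"IEA", "ND"})
DEFAULT_TPM_CUTOFF = 4.0
DEFAULT_CONFIDENCE_CUTOFF = 700


class SchemaError(ValueError):
    """Input table is missing a required column."""


@dataclass(frozen=True)
class Association:
    """One entity -> ontology-class annotation."""

    entity_id: str
    relation: str
    class_id: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.relation not in RELATION_VOCABULARY:
            raise ValueError(
                f"relation {self.relation!r} not in vocabulary {sorted(RELATION_VOCABULARY)}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.entity_id, self.relation, self.class_id)


@dataclass(frozen=True)
class InteractionEdge:
    """A scored protein/gene interaction; the pair is unordered."""

    entity_a: str
    entity_b: str
    confidence: int

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.entity_a, self.entity_b)))  # type: ignore[return-value]


def _dedup_associations(assocs: Iterable[Association]) -> list[Association]:
    seen: dict[tuple[str, str, str], Association] = {}
    for a in assocs:
        seen.setdefault(a.key, a)
    return list(seen.values())


def filter_go_annotations(
    records: pd.DataFrame | Sequence[tuple],
    relation: str = "has-function",
    source: str = "go",
) -> list[Association]:
    """Drop electronically inferred (IEA) and no-data (ND) annotations.

    ``records`` is a table with columns ``entity``, ``class``, ``evidence``
    (a DataFrame, or an iterable of 3-tuples in that order).  Surviving
    rows become deduplicated ``has-function`` associations.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records, columns=["entity", "class", "evidence"])
    missing = {"entity", "class", "evidence"} - set(records.columns)
    if missing:
        raise SchemaError(f"annotation table missing column(s): {sorted(missing)}")
    kept = records.loc[~records["evidence"].isin(EXCLUDED_EVIDENCE_CODES)]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("excluded %d annotations with evidence in %s", n_dropped, sorted(EXCLUDED_EVIDENCE_CODES))
    return _dedup_associations(
        Association(str(e), relation, str(c), source)
        for e, c in zip(kept["entity"], kept["class"])
    )


def threshold_expression(
    tpm: pd.DataFrame,
    cutoff: float = DEFAULT_TPM_CUTOFF,
    tissue_to_class: Mapping[str, str] | None = None,
    source: str = "expression",
) -> list[Association]:
    """Binarize a gene x tissue TPM matrix into expressed-in associations.

    A gene is called expressed in a tissue when TPM >= ``cutoff``
    (inclusive).  ``tissue_to_class`` maps tissue column names to anatomy
    classes; tissues without a mapping are skipped with a log message,
    and when it is None tissue names are used as class ids directly.
    """
    values = tpm.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("TPM matrix contains negative values")
    columns = list(tpm.columns)
    if tissue_to_class is not None:
        unmapped = [t for t in columns if t not in tissue_to_class]
        if unmapped:
            logger.info("skipping %d tissue(s) without an anatomy mapping: %s", len(unmapped), unmapped)
        columns = [t for t in columns if t in tissue_to_class]
    out: list[Association] = []
    for tissue in columns:
        class_id = tissue_to_class[tissue] if tissue_to_class is not None else tissue
        expressed = tpm.index[tpm[tissue].to_numpy(dtype=float) >= cutoff]
        out.extend(
            Association(str(g), "expressed-in", str(class_id), source) for g in expressed
        )
    return _dedup_associations(out)


def filter_interactions(
    edges: pd.DataFrame | Sequence[tuple],
    cutoff: int = DEFAULT_CONFIDENCE_CUTOFF,
) -> list[InteractionEdge]:
    """Keep interactions with confidence >= ``cutoff``; dedup unordered pairs.

    Self-interactions survive the filter (they become harmless self-loops
    in the graph) but are logged.
    """
    if not isinstance(edges, pd.DataFrame):
        edges = pd.DataFrame(edges, columns=["protein1", "protein2", "combined_score"])
    missing = {"protein1", "protein2", "combined_score"} - set(edges.columns)
    if missing:
        raise SchemaError(f"interaction table missing column(s): {sorted(missing)}")
    kept = edges.loc[edges["combined_score"].astype(int) >= int(cutoff)]
    seen: dict[tuple[str, str], InteractionEdge] = {}
    n_self = 0
    for a, b, score in zip(kept["protein1"], kept["protein2"], kept["combined_score"]):
        a, b = str(a), str(b)
        if a == b:
            n_self += 1
        key = tuple(sorted((a, b)))
        seen.setdefault(key, InteractionEdge(a, b, int(score)))
    if n_self:
        logger.info("kept %d self-interaction(s)", n_self)
    return list(seen.values())


def map_orthologs(
    assocs: Sequence[Association],
    ortholog_map: Mapping[str, str] | Sequence[tuple[str, str]],
) -> list[Association]:
    """Rewrite entity ids through an ortholog map; drop unmapped entities.

    A sequence of (source, target) pairs may be many-to-many; each
    association then expands to every target of its entity before dedup.
    Drops are counted and logged, never fatal.
    """
    targets: dict[str, list[str]] = {}
    if isinstance(ortholog_map, Mapping):
        for src, dst in ortholog_map.items():
            targets.setdefault(str(src), []).append(str(dst))
    else:
        for src, dst in ortholog_map:
            targets.setdefault(str(src), []).append(str(dst))
    out: list[Association] = []
    n_dropped = 0
    for assoc in assocs:
        mapped = targets.get(assoc.entity_id)
        if not mapped:
            n_dropped += 1
            continue
        out.extend(
            Association(dst, assoc.relation, assoc.class_id, assoc.source) for dst in mapped
        )
    if n_dropped:
        logger.info("dropped %d association(s) with unmapped entities", n_dropped)
    return _dedup_associations(out)


# ---------------------------------------------------------------------------
# TSV readers for the external table formats


def read_association_table(path: str | Path, source: str = "") -> list[Association]:
    """Read a 3-column TSV of (entity, relation, class) associations."""
    df = pd.read_csv(path, sep="\t", header=None, names=["entity", "relation", "class"], dtype=str)
    return _dedup_associations(
        Association(e, r, c, source) for e, r, c in zip(df["entity"], df["relation"], df["class"])
    )


def write_association_table(assocs: Sequence[Association], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in sorted(assocs, key=lambda a: a.key):
            fh.write(f"{a.entity_id}\t{a.relation}\t{a.class_id}\n")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x tissue TPM TSV with a header row of tissue ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_interaction_table(path: str | Path) -> pd.DataFrame:
    """Read a STRING-style TSV (protein1, protein2, combined_score)."""
    return pd.read_csv(path, sep="\t", dtype={"combined_score": int})
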