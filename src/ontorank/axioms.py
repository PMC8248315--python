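"""Normalized ontology-axiom model and parsers.

The graph-transformation rules consume a restricted axiom language:
subclass or equivalence axioms whose subject is a named class and whose
right-hand side is a (possibly empty) chain of quantified relations
``Q R0 . Q R1 . ... Q Rm`` applied to either a single named class or a
flat union/intersection of named classes.  Three input dialects map onto
this model:

``tsv_simple``
    One axiom per line: ``SUBJECT<TAB>SubClassOf|EquivalentTo<TAB>EXPR``
    with ``EXPR`` a space-separated sequence of quantifier tokens
    (``some:REL``, ``only:REL``, ``card:REL``) followed by a class name
    or a parenthesized ``(C1 or C2 ...)`` / ``(C1 and C2 ...)`` group.
``obo``
    OBO 1.4 via :mod:`obonet`; ``is_a``, ``relationship``,
    ``intersection_of`` and ``union_of`` tags become axioms.
``owl_functional``
    OWL 2 functional syntax, logical axioms only, restricted to the
    patterns above; anything else is counted as skipped.

Axioms outside the supported fragment (e.g. nested boolean expressions)
are never silently dropped: they increment ``AxiomSet.n_skipped`` and are
logged at DEBUG level.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

logger = logging.getLogger(__name__)

QuantifierKind = Literal["existential", "universal", "cardinality"]
BooleanKind = Literal["union", "intersection", "single"]

_QUANT_PREFIX = {"some": "existential", "only": "universal", "card": "cardinality"}
_QUANT_TOKEN = {v: k for k, v in _QUANT_PREFIX.items()}


class AxiomParseError(ValueError):
    """Malformed axiom record; message names the offending line."""


@dataclass(frozen=True)
class ClassExpr:
    """Right-hand side of an axiom: quantifier chain applied to a filler.

    ``chain`` is an ordered tuple of ``(quantifier_kind, relation_name)``
    pairs, possibly empty.  ``filler`` is a tuple of class names; with
    ``filler_kind == "single"`` it has exactly one member, otherwise it is
    a flat union or intersection of >= 2 names.
    """

    chain: tuple[tuple[QuantifierKind, str], ...]
    filler: tuple[str, ...]
    filler_kind: BooleanKind = "single"

    def __post_init__(self) -> None:
        if self.filler_kind == "single":
            if len(self.filler) != 1:
                raise ValueError("single filler must contain exactly one class")
        elif len(self.filler) < 2:
            raise ValueError(f"{self.filler_kind} filler needs >= 2 classes")
        for kind, _rel in self.chain:
            if kind not in ("existential", "universal", "cardinality"):
                raise ValueError(f"unknown quantifier kind {kind!r}")

    @property
    def relations(self) -> tuple[str, ...]:
        return tuple(rel for _kind, rel in self.chain)


@dataclass(frozen=True)
class Axiom:
    """A subclass or equivalence axiom with a named-class subject."""

    kind: Literal["subclass", "equivalence"]
    subject: str
    rhs: ClassExpr

    def __post_init__(self) -> None:
        if self.kind not in ("subclass", "equivalence"):
            raise ValueError(f"unknown axiom kind {self.kind!r}")


@dataclass
class AxiomSet:
    """A deduplicated collection of axioms plus the symbols they mention."""

    axioms: list[Axiom] = field(default_factory=list)
    class_names: set[str] = field(default_factory=set)
    relation_names: set[str] = field(default_factory=set)
    n_skipped: int = 0

    @classmethod
    def from_axioms(cls, axioms: Iterable[Axiom], n_skipped: int = 0) -> "AxiomSet":
        seen: dict[Axiom, None] = {}
        for ax in axioms:
            seen.setdefault(ax)
        out = cls(axioms=list(seen), n_skipped=n_skipped)
        for ax in out.axioms:
            out.class_names.add(ax.subject)
            out.class_names.update(ax.rhs.filler)
            out.relation_names.update(ax.rhs.relations)
        return out

    def __len__(self) -> int:
        return len(self.axioms)

    def __iter__(self):
        return iter(self.axioms)


# ---------------------------------------------------------------------------
# tsv_simple dialect


def _parse_expr(text: str, where: str) -> ClassExpr:
    tokens = text.split()
    chain: list[tuple[QuantifierKind, str]] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if ":" in tok and tok.split(":", 1)[0] in _QUANT_PREFIX:
            prefix, rel = tok.split(":", 1)
            if not rel:
                raise AxiomParseError(f"{where}: empty relation in {tok!r}")
            chain.append((_QUANT_PREFIX[prefix], rel))
            i += 1
        else:
            break
    rest = " ".join(tokens[i:])
    if not rest:
        raise AxiomParseError(f"{where}: missing filler expression")
    if rest.startswith("("):
        if not rest.endswith(")"):
            raise AxiomParseError(f"{where}: unbalanced parentheses in {rest!r}")
        inner = rest[1:-1].strip()
        if "(" in inner or ")" in inner:
            raise AxiomParseError(f"{where}: nested boolean expressions unsupported")
        for kind, sep in (("union", " or "), ("intersection", " and ")):
            if sep in f" {inner} ".replace("  ", " "):
                members = [m.strip() for m in re.split(rf"\s+{sep.strip()}\s+", inner)]
                if len(members) < 2 or any(not m or " " in m for m in members):
                    raise AxiomParseError(f"{where}: malformed boolean group {rest!r}")
                return ClassExpr(tuple(chain), tuple(members), kind)
        raise AxiomParseError(f"{where}: boolean group without or/and: {rest!r}")
    if " " in rest:
        raise AxiomParseError(f"{where}: trailing tokens after filler: {rest!r}")
    return ClassExpr(tuple(chain), (rest,), "single")


def _parse_tsv_simple(path: Path) -> AxiomSet:
    axioms: list[Axiom] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise AxiomParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            subject, keyword, expr_text = (p.strip() for p in parts)
            if keyword == "SubClassOf":
                kind = "subclass"
            elif keyword == "EquivalentTo":
                kind = "equivalence"
            else:
                raise AxiomParseError(f"{path}:{lineno}: unknown axiom keyword {keyword!r}")
            if not subject or " " in subject:
                raise AxiomParseError(f"{path}:{lineno}: subject must be a bare class name")
            try:
                rhs = _parse_expr(expr_text, f"{path}:{lineno}")
            except AxiomParseError as exc:
                if "nested" in str(exc):
                    logger.debug("skipping unsupported axiom: %s", exc)
                    n_skipped += 1
                    continue
                raise
            axioms.append(Axiom(kind, subject, rhs))
    return AxiomSet.from_axioms(axioms, n_skipped=n_skipped)


def serialize_axioms(axiom_set: AxiomSet) -> str:
    """Render an AxiomSet in the tsv_simple dialect, deterministically sorted."""
    lines = []
    for ax in axiom_set:
        keyword = "SubClassOf" if ax.kind == "subclass" else "EquivalentTo"
        chain = " ".join(f"{_QUANT_TOKEN[kind]}:{rel}" for kind, rel in ax.rhs.chain)
        if ax.rhs.filler_kind == "single":
            filler = ax.rhs.filler[0]
        else:
            sep = " or " if ax.rhs.filler_kind == "union" else " and "
            filler = "(" + sep.join(ax.rhs.filler) + ")"
        expr = f"{chain} {filler}".strip()
        lines.append(f"{ax.subject}\t{keyword}\t{expr}")
    return "\n".join(sorted(lines)) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# OBO dialect (via obonet)


def _parse_obo(path: Path) -> AxiomSet:
    import obonet

    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    axioms: list[Axiom] = []
    n_skipped = 0
    for child, parent, rel in sorted(graph.edges(keys=True)):
        if rel == "is_a":
            axioms.append(Axiom("subclass", child, ClassExpr((), (parent,), "single")))
        else:
            axioms.append(
                Axiom("subclass", child, ClassExpr((("existential", rel),), (parent,), "single"))
            )
    for node, data in sorted(graph.nodes(data=True)):
        for tag, kind in (("intersection_of", "intersection"), ("union_of", "union")):
            members = data.get(tag)
            if not members:
                continue
            names = []
            relational = False
            for entry in members:
                tokens = entry.split()
                if len(tokens) == 1:
                    names.append(tokens[0])
                else:
                    relational = True
            if relational or len(names) < 2:
                # genus + relational differentia do not fit the flat-filler fragment
                logger.debug("skipping %s %s of %s (relational differentia)", tag, members, node)
                n_skipped += 1
                continue
            axioms.append(Axiom("equivalence", node, ClassExpr((), tuple(names), kind)))
    return AxiomSet.from_axioms(axioms, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# OWL functional syntax (restricted fragment)

_TOKEN_RE = re.compile(r"[()\s]|[^()\s]+")


def _tokenize_sexpr(text: str) -> list[str]:
    return [t for t in _TOKEN_RE.findall(text) if not t.isspace()]


def _read_sexpr(tokens: list[str], pos: int):
    tok = tokens[pos]
    if tok != "(":
        return tok, pos + 1
    # preceding token was the functor; caller handles that
    raise AxiomParseError("unexpected '('")


def _parse_owl_node(tokens: list[str], pos: int):
    """Parse one node: either a bare IRI/CURIE or FUNCTOR ( args... )."""
    head = tokens[pos]
    if pos + 1 < len(tokens) and tokens[pos + 1] == "(":
        args = []
        i = pos + 2
        while tokens[i] != ")":
            node, i = _parse_owl_node(tokens, i)
            args.append(node)
        return (head, args), i + 1
    return head, pos + 1


_CARD_FUNCTORS = {"ObjectMinCardinality", "ObjectMaxCardinality", "ObjectExactCardinality"}


def _owl_expr_to_class_expr(node) -> ClassExpr:
    chain: list[tuple[QuantifierKind, str]] = []
    while isinstance(node, tuple):
        functor, args = node
        if functor == "ObjectSomeValuesFrom" and len(args) == 2:
            chain.append(("existential", _strip_iri(args[0])))
            node = args[1]
        elif functor == "ObjectAllValuesFrom" and len(args) == 2:
            chain.append(("universal", _strip_iri(args[0])))
            node = args[1]
        elif functor in _CARD_FUNCTORS and len(args) == 3:
            chain.append(("cardinality", _strip_iri(args[1])))
            node = args[2]
        elif functor in ("ObjectUnionOf", "ObjectIntersectionOf"):
            if any(isinstance(a, tuple) for a in args):
                raise AxiomParseError("nested boolean expression")
            kind = "union" if functor == "ObjectUnionOf" else "intersection"
            return ClassExpr(tuple(chain), tuple(_strip_iri(a) for a in args), kind)
        else:
            raise AxiomParseError(f"unsupported class expression {functor}")
    return ClassExpr(tuple(chain), (_strip_iri(node),), "single")


def _strip_iri(token: str) -> str:
    token = token.strip("<>")
    if token.startswith("http"):
        token = token.rstrip("/").rsplit("/", 1)[-1].rsplit("#", 1)[-1]
    return token


_LOGICAL_FUNCTORS = {
    "SubClassOf",
    "EquivalentClasses",
    "DisjointClasses",
    "DisjointUnion",
    "ObjectPropertyDomain",
    "ObjectPropertyRange",
}


def _parse_owl_functional(path: Path) -> AxiomSet:
    text = Path(path).read_text()
    # strip comments and Prefix/Ontology wrappers are handled by scanning axioms
    axioms: list[Axiom] = []
    n_skipped = 0
    for match in re.finditer(r"\b(SubClassOf|EquivalentClasses|DisjointClasses|DisjointUnion)\s*\(", text):
        functor = match.group(1)
        start = match.end() - 1
        depth = 0
        for end in range(start, len(text)):
            if text[end] == "(":
                depth += 1
            elif text[end] == ")":
                depth -= 1
                if depth == 0:
                    break
        else:
            raise AxiomParseError(f"{path}: unbalanced parentheses")
        body = text[match.start() : end + 1]
        tokens = _tokenize_sexpr(body)
        try:
            node, _ = _parse_owl_node(tokens, 0)
        except (AxiomParseError, IndexError):
            n_skipped += 1
            continue
        _functor, args = node
        try:
            if functor == "SubClassOf" and len(args) == 2 and isinstance(args[0], str):
                axioms.append(Axiom("subclass", _strip_iri(args[0]), _owl_expr_to_class_expr(args[1])))
            elif functor == "EquivalentClasses" and len(args) == 2 and isinstance(args[0], str):
                axioms.append(
                    Axiom("equivalence", _strip_iri(args[0]), _owl_expr_to_class_expr(args[1]))
                )
            else:
                raise AxiomParseError("unsupported logical axiom shape")
        except AxiomParseError as exc:
            logger.debug("skipping OWL axiom %s: %s", body[:80], exc)
            n_skipped += 1
    return AxiomSet.from_axioms(axioms, n_skipped=n_skipped)


# ---------------------------------------------------------------------------


_DIALECTS = {
    "tsv_simple": _parse_tsv_simple,
    "obo": _parse_obo,
    "owl_functional": _parse_owl_functional,
}


def parse_axioms(path: str | Path, dialect: str = "tsv_simple") -> AxiomSet:
    """Parse an ontology axiom file into a normalized :class:`AxiomSet`.

    Parameters
    ----------
    path
        Axiom file in the named dialect.
    dialect
        One of ``tsv_simple``, ``obo``, ``owl_functional``.

    Returns
    -------
    AxiomSet
        Deduplicated axioms; ``n_skipped`` counts logical records outside
        the supported fragment (these are logged, never silently lost).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _DIALECTS[dialect](path)
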