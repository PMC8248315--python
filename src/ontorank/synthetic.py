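"""Synthetic benchmark with planted, axiom-mediated gene-disease signal.

The generator emulates the structure of the real inputs without any
download: three subclass hierarchies play the roles of a phenotype
ontology (``PH:``), a function ontology (``FN:``) and an anatomy
ontology (``AN:``).  A subset of phenotype classes carries
cross-ontology defining axioms in the style of entity-quality phenotype
definitions, e.g.::

    PH:0012  SubClassOf  some:has-part (FN:0034 or AN:0101)
    PH:0047  SubClassOf  some:has-part some:part-of AN:0072

Diseases are annotated with phenotype classes and genes with
function/anatomy classes.  For each gold (gene, disease) pair, a
``signal`` fraction of the disease's phenotype annotations are drawn
from the cross-axiom subjects and the gene is annotated to the *filler*
classes of those same axioms — so at signal=1 every gold pair is linked
by an axiom path of length <= 3
(disease -> phenotype -> filler class <- gene), the mechanism by which
a phenotype defined via a biological process connects a disease to a
gene annotated with that process.  ``noise`` appends a corresponding
fraction of uniformly random annotations to every entity.  At signal=0
gene annotations are unrelated to disease phenotypes and ranking is at
chance.

Everything is driven by one seeded RNG; the same seed reproduces the
bundle byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .associations import Association, InteractionEdge, write_association_table
from .axioms import Axiom, AxiomSet, ClassExpr, serialize_axioms

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthConfig:
    """Benchmark dimensions and signal strength.

    Defaults: 200 classes per ontology with branching factor 3, 80
    cross-ontology defining axioms, 300 genes, 40 diseases with 3 causal
    genes each, 6 annotations per entity, signal 0.8, noise 0.2.
    """

    n_classes: int = 200
    branching: int = 3
    n_cross_axioms: int = 80
    n_genes: int = 300
    n_diseases: int = 40
    genes_per_disease: int = 3
    annotations_per_entity: int = 6
    signal: float = 0.8
    noise: float = 0.2
    plant_interactions: bool = False
    interaction_confidence: int = 900
    expressed_fraction: float = 0.3
    n_tissues: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.signal <= 1.0 and 0.0 <= self.noise <= 1.0):
            raise ValueError("signal and noise must lie in [0, 1]")
        for name in ("n_classes", "branching", "n_cross_axioms", "n_genes", "n_diseases",
                     "genes_per_disease", "annotations_per_entity"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        n_sig = round(self.signal * self.annotations_per_entity)
        if n_sig > self.n_cross_axioms:
            raise ValueError(
                f"signal requires {n_sig} distinct cross-axiom phenotypes per disease "
                f"but only {self.n_cross_axioms} exist"
            )
        if self.n_cross_axioms > self.n_classes - 1:
            raise ValueError("n_cross_axioms exceeds available phenotype classes")
        if self.genes_per_disease * self.n_diseases > self.n_genes:
            raise ValueError("not enough genes to assign causal genes to every disease")


@dataclass
class SynthBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    axiom_set: AxiomSet
    associations: list[Association]
    interactions: list[InteractionEdge]
    gold_pairs: list[tuple[str, str]]
    truth: dict = field(default_factory=dict)
    config: SynthConfig | None = None

    @property
    def gene_universe(self) -> list[str]:
        return sorted({a.entity_id for a in self.associations if a.entity_id.startswith("G:")})

    def write(self, directory: str | Path) -> None:
        """Write the same plain-text formats the real pipeline reads."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "axioms.tsv").write_text(serialize_axioms(self.axiom_set))
        write_association_table(self.associations, directory / "associations.tsv")
        with open(directory / "interactions.tsv", "w") as fh:
            fh.write("protein1\tprotein2\tcombined_score\n")
            for e in sorted(self.interactions, key=lambda e: e.key):
                fh.write(f"{e.entity_a}\t{e.entity_b}\t{e.confidence}\n")
        with open(directory / "gold.tsv", "w") as fh:
            for g, d in sorted(self.gold_pairs):
                fh.write(f"{g}\t{d}\n")


def _class_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}:{i:04d}" for i in range(n)]


def _hierarchy_axioms(ids: Sequence[str], branching: int) -> list[Axiom]:
    out = []
    for i in range(1, len(ids)):
        parent = ids[(i - 1) // branching]
        out.append(Axiom("subclass", ids[i], ClassExpr((), (parent,), "single")))
    return out


def generate(config: SynthConfig) -> SynthBundle:
    """Generate a planted-signal benchmark bundle (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    ph = _class_ids("PH", config.n_classes)
    fn = _class_ids("FN", config.n_classes)
    an = _class_ids("AN", config.n_classes)
    axioms: list[Axiom] = []
    for ids in (ph, fn, an):
        axioms.extend(_hierarchy_axioms(ids, config.branching))

    # cross-ontology defining axioms on a subset of phenotype classes;
    # cycle through three shapes so unions and quantifier chains are all
    # exercised by the graph transformation
    cross_subjects = [ph[i + 1] for i in rng.choice(config.n_classes - 1,
                                                    size=config.n_cross_axioms, replace=False)]
    cross_targets: dict[str, list[tuple[str, str]]] = {}
    for j, subject in enumerate(cross_subjects):
        f = fn[int(rng.integers(1, config.n_classes))]
        a = an[int(rng.integers(1, config.n_classes))]
        shape = j % 3
        if shape == 0:
            rhs = ClassExpr((("existential", "has-part"),), (f,), "single")
            targets = [(f, "has-function")]
        elif shape == 1:
            rhs = ClassExpr((("existential", "has-part"),), tuple(sorted((f, a))), "union")
            targets = [(f, "has-function"), (a, "expressed-in")]
        else:
            rhs = ClassExpr(
                (("existential", "has-part"), ("existential", "part-of")), (a,), "single"
            )
            targets = [(a, "expressed-in")]
        axioms.append(Axiom("subclass", subject, rhs))
        cross_targets[subject] = targets
    axiom_set = AxiomSet.from_axioms(axioms)

    genes = [f"G:{i:04d}" for i in range(config.n_genes)]
    diseases = [f"D:{i:04d}" for i in range(config.n_diseases)]
    n_annot = config.annotations_per_entity
    n_sig = round(config.signal * n_annot)
    n_noise = round(config.noise * n_annot)

    # every gene draws its non-noise annotations from the same pool of
    # cross-axiom filler classes (and every disease from the pool of
    # cross-axiom phenotype subjects), so causal and decoy entities have
    # matched annotation marginals: only the *pairing* between a causal
    # gene's classes and its own disease's phenotype axioms carries
    # signal, and a label-shuffled control is genuinely at chance
    target_pool = sorted({t for targets in cross_targets.values() for t in targets})

    def random_pheno() -> str:
        return ph[int(rng.integers(1, config.n_classes))]

    def pool_pheno() -> str:
        return cross_subjects[int(rng.integers(len(cross_subjects)))]

    def pool_gene_annotation() -> tuple[str, str]:
        return target_pool[int(rng.integers(len(target_pool)))]

    def noise_gene_annotation() -> tuple[str, str]:
        if rng.random() < 0.5:
            return fn[int(rng.integers(1, config.n_classes))], "has-function"
        return an[int(rng.integers(1, config.n_classes))], "expressed-in"

    associations: list[Association] = []
    disease_signal: dict[str, list[str]] = {}
    for d in diseases:
        picked = [cross_subjects[i] for i in rng.choice(len(cross_subjects), size=n_sig, replace=False)]
        disease_signal[d] = picked
        for p in picked:
            associations.append(Association(d, "has-phenotype", p, "signal"))
        for _ in range(n_annot - n_sig):
            associations.append(Association(d, "has-phenotype", pool_pheno(), "random"))
        for _ in range(n_noise):
            associations.append(Association(d, "has-phenotype", random_pheno(), "noise"))

    gold_pairs: list[tuple[str, str]] = []
    causal_of: dict[str, str] = {}
    for i, d in enumerate(diseases):
        for k in range(config.genes_per_disease):
            g = genes[i * config.genes_per_disease + k]
            gold_pairs.append((g, d))
            causal_of[g] = d

    for g in genes:
        d = causal_of.get(g)
        n_linked = n_sig if d is not None else 0
        if n_linked:
            pool = [t for p in disease_signal[d] for t in cross_targets[p]]
            for i in rng.choice(len(pool), size=n_linked, replace=True):
                cls, rel = pool[int(i)]
                associations.append(Association(g, rel, cls, "signal"))
        for _ in range(n_annot - n_linked):
            cls, rel = pool_gene_annotation()
            associations.append(Association(g, rel, cls, "random"))
        for _ in range(n_noise):
            cls, rel = noise_gene_annotation()
            associations.append(Association(g, rel, cls, "noise"))

    # dedup while keeping deterministic order
    seen: dict[tuple[str, str, str], Association] = {}
    for a in associations:
        seen.setdefault(a.key, a)
    associations = list(seen.values())

    interactions: list[InteractionEdge] = []
    if config.plant_interactions:
        for d in diseases:
            causal = [g for g, dd in gold_pairs if dd == d]
            for i in range(len(causal)):
                for j in range(i + 1, len(causal)):
                    interactions.append(
                        InteractionEdge(causal[i], causal[j], config.interaction_confidence)
                    )

    return SynthBundle(
        axiom_set=axiom_set,
        associations=associations,
        interactions=interactions,
        gold_pairs=gold_pairs,
        truth={
            "disease_signal_phenotypes": disease_signal,
            "cross_targets": cross_targets,
        },
        config=config,
    )


def generate_expression(config: SynthConfig) -> pd.DataFrame:
    """Gene x tissue TPM matrix; a ``expressed_fraction`` of cells lie at
    or above the 4.0 TPM call threshold.  Tissue columns are anatomy
    class ids so they map to the ontology directly."""
    rng = np.random.default_rng(config.seed + 1)
    genes = [f"G:{i:04d}" for i in range(config.n_genes)]
    tissues = _class_ids("AN", config.n_classes)[1 : config.n_tissues + 1]
    expressed = rng.random((len(genes), len(tissues))) < config.expressed_fraction
    high = 4.0 + rng.exponential(20.0, size=expressed.shape)
    low = rng.uniform(0.0, 4.0, size=expressed.shape)
    # keep the sub-threshold draws strictly below the cutoff
    low = np.minimum(low, np.nextafter(4.0, 0.0))
    values = np.where(expressed, high, low)
    return pd.DataFrame(values, index=genes, columns=tissues)


def shuffled_gold(bundle: SynthBundle, seed: int = 0) -> list[tuple[str, str]]:
    """Label-shuffle control: permute the disease column of the gold
    pairs, destroying the gene-disease correspondence while keeping the
    marginal counts."""
    rng = np.random.default_rng(seed)
    genes = [g for g, _ in bundle.gold_pairs]
    diseases = [d for _, d in bundle.gold_pairs]
    permuted = [diseases[i] for i in rng.permutation(len(diseases))]
    pairs = sorted(set(zip(genes, permuted)))
    return pairs
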