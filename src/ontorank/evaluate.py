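"""Ranking evaluation: macro-averaged ROC, Hits@n, model comparison.

Evaluation ranks every candidate gene for each disease.  True/false
positive rates are computed per disease at every rank, averaged across
diseases at each rank, and the area under that macro-averaged curve is
taken by the trapezoid rule.  Per-disease areas (used for significance
testing) follow the Mann-Whitney identity ``AUC = U / (n_pos * n_neg)``
with tied scores assigned average ranks.  Hits@n is the fraction of true
gene-disease associations whose gene ranks within the top n for its
disease.  Two models evaluated on the same association set are compared
with a two-sided Mann-Whitney U test on the ranks of true positives,
reported against the conventional 0.05 threshold.

Ties in score are broken by a stable ascending sort on gene id when an
explicit ordering is needed (curve points, Hits@n).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

SIGNIFICANCE_THRESHOLD = 0.05
DEFAULT_HITS_AT = (1, 10, 100)


@dataclass
class DiseaseRanking:
    """Scored candidate genes for one disease.

    ``genes``/``scores`` are aligned and ordered by descending score,
    ties broken by ascending gene id.
    """

    disease: str
    genes: list[str]
    scores: np.ndarray
    positives: frozenset[str]
    fold: int = -1

    @classmethod
    def from_scores(
        cls,
        disease: str,
        genes: Sequence[str],
        scores: Sequence[float],
        positives: Sequence[str],
        fold: int = -1,
    ) -> "DiseaseRanking":
        scores = np.asarray(scores, dtype=float)
        if len(genes) != len(scores):
            raise ValueError("genes and scores must align")
        order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
        pos = frozenset(positives)
        unknown = pos - set(genes)
        if unknown:
            raise ValueError(f"positives not among candidates: {sorted(unknown)}")
        return cls(
            disease=disease,
            genes=[genes[i] for i in order],
            scores=scores[list(order)],
            positives=pos,
            fold=fold,
        )

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.genes) - len(self.positives)

    def positive_ranks(self) -> dict[tuple[str, str], int]:
        """1-based rank of each true gene under the tie-broken ordering."""
        return {
            (g, self.disease): r
            for r, g in enumerate(self.genes, start=1)
            if g in self.positives
        }

    def auc(self) -> float:
        """Area via the Mann-Whitney identity, average ranks for ties."""
        labels = np.fromiter((g in self.positives for g in self.genes), dtype=bool)
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError(f"disease {self.disease} needs >=1 positive and negative")
        ranks = stats.rankdata(self.scores)  # ascending, ties averaged
        u = ranks[labels].sum() - self.n_pos * (self.n_pos + 1) / 2.0
        return float(u / (self.n_pos * self.n_neg))


@dataclass
class RankingResult:
    """Per-disease scored gene lists with fold provenance."""

    rankings: list[DiseaseRanking] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rankings)

    def __len__(self) -> int:
        return len(self.rankings)

    def usable(self) -> list[DiseaseRanking]:
        kept = []
        for r in self.rankings:
            if r.n_pos == 0 or r.n_neg == 0:
                logger.warning("excluding disease %s (no positives or no negatives)", r.disease)
                continue
            kept.append(r)
        return kept

    def positive_ranks(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for r in self.rankings:
            out.update(r.positive_ranks())
        return out

    def folds(self) -> list[int]:
        return sorted({r.fold for r in self.rankings})


def per_disease_auc(results: RankingResult) -> dict[str, float]:
    return {r.disease: r.auc() for r in results.usable()}


def roc_curve_macro(results: RankingResult) -> tuple[np.ndarray, np.ndarray, float]:
    """Macro-averaged ROC curve and its trapezoid area.

    TPR and FPR are computed per disease at every rank of the shared
    candidate universe, then averaged across diseases rank-by-rank.
    All diseases must rank candidate sets of the same size.
    """
    usable = results.usable()
    if not usable:
        raise ValueError("no evaluable diseases")
    sizes = {len(r.genes) for r in usable}
    if len(sizes) > 1:
        raise ValueError(f"diseases rank different universe sizes: {sorted(sizes)}")
    n = sizes.pop()
    tpr = np.zeros(n + 1)
    fpr = np.zeros(n + 1)
    for r in usable:
        labels = np.fromiter((g in r.positives for g in r.genes), dtype=float)
        cum_pos = np.concatenate([[0.0], np.cumsum(labels)])
        cum_neg = np.arange(n + 1) - cum_pos
        tpr += cum_pos / r.n_pos
        fpr += cum_neg / r.n_neg
    tpr /= len(usable)
    fpr /= len(usable)
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, area


def hits_at_n(results: RankingResult, n: int) -> float:
    """Recall at rank n over all true gene-disease associations."""
    ranks = RankingResult(results.usable()).positive_ranks()
    if not ranks:
        raise ValueError("no positive associations to evaluate")
    return float(np.mean([r <= n for r in ranks.values()]))


def compare_models(
    ranks_a: Mapping[tuple, int] | Sequence[float],
    ranks_b: Mapping[tuple, int] | Sequence[float],
) -> float:
    """Two-sided Mann-Whitney U p-value on true-positive rank distributions.

    Both models must have been evaluated on the identical association
    set; mappings are aligned by key, plain sequences by position.
    """
    if isinstance(ranks_a, Mapping) != isinstance(ranks_b, Mapping):
        raise ValueError("compare mappings with mappings or sequences with sequences")
    if isinstance(ranks_a, Mapping):
        if set(ranks_a) != set(ranks_b):
            raise ValueError("models were evaluated on different association sets")
        keys = sorted(ranks_a)
        a = np.array([ranks_a[k] for k in keys], dtype=float)
        b = np.array([ranks_b[k] for k in keys], dtype=float)
    else:
        a = np.asarray(ranks_a, dtype=float)
        b = np.asarray(ranks_b, dtype=float)
        if len(a) != len(b):
            raise ValueError("models were evaluated on different association sets")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", use_continuity=False)
    return float(min(res.pvalue, 1.0))


@dataclass
class EvalReport:
    """Aggregate evaluation with cross-validation provenance."""

    rocauc: float
    rocauc_interval: tuple[float, float]
    mean_disease_auc: float
    hits_at: dict[int, float]
    curve_fpr: np.ndarray
    curve_tpr: np.ndarray
    per_disease: dict[str, float]
    n_diseases: int

    def to_dict(self) -> dict:
        return {
            "rocauc": self.rocauc,
            "rocauc_interval": list(self.rocauc_interval),
            "mean_disease_auc": self.mean_disease_auc,
            "hits_at": {str(k): v for k, v in self.hits_at.items()},
            "per_disease_auc": self.per_disease,
            "n_diseases": self.n_diseases,
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def save_curve(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for x, y in zip(self.curve_fpr, self.curve_tpr):
                fh.write(f"{x:.6g}\t{y:.6g}\n")

    def plot_roc(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.curve_fpr, self.curve_tpr, label=f"macro ROC (AUC={self.rocauc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def evaluate(results: RankingResult, hits: Sequence[int] = DEFAULT_HITS_AT) -> EvalReport:
    """Full evaluation: macro curve/area, per-fold min-max interval,
    per-disease areas and Hits@n."""
    fpr, tpr, area = roc_curve_macro(results)
    disease_auc = per_disease_auc(results)
    fold_areas = []
    for fold in results.folds():
        subset = RankingResult([r for r in results.usable() if r.fold == fold])
        if len(subset):
            fold_areas.append(roc_curve_macro(subset)[2])
    interval = (min(fold_areas), max(fold_areas)) if fold_areas else (area, area)
    return EvalReport(
        rocauc=area,
        rocauc_interval=interval,
        mean_disease_auc=float(np.mean(list(disease_auc.values()))),
        hits_at={int(n): hits_at_n(results, int(n)) for n in hits},
        curve_fpr=fpr,
        curve_tpr=tpr,
        per_disease=disease_auc,
        n_diseases=len(disease_auc),
    )
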