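"""Multi-label evaluation of categorization against a gold standard.

Gold and predicted assignments are encoded as aligned binary matrices G and
P of shape (genes × categories).  Because categorization is multi-label,
accuracy must credit both correct assignment and correct non-assignment:

    accuracy = (1 / (N · N_C)) Σ_g Σ_c [G(g,c) = P(g,c)]

With few categories per gene this measure is dominated by true negatives, so
the Matthews correlation coefficient over the flattened cells (micro MCC) is
reported alongside; a macro variant (mean of per-category MCCs) is available.
A degree-k uniform random assigner serves as the chance baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .categorizer import Assignment

logger = logging.getLogger(__name__)


@dataclass
class LabelMatrices:
    """Aligned binary gold (G) and prediction (P) matrices."""

    genes: list[str]
    categories: list[str]
    G: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int8)
        self.P = np.asarray(self.P, dtype=np.int8)
        expected = (len(self.genes), len(self.categories))
        if self.G.shape != expected or self.P.shape != expected:
            raise ValueError(
                f"matrix shapes {self.G.shape}/{self.P.shape} != {expected}"
            )


def load_gold_standard(path: str | Path) -> dict[str, set[str]]:
    """Read a gold-standard TSV (gene<TAB>category, repeats allowed)."""
    gold: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene<TAB>category")
            gold.setdefault(fields[0], set()).add(fields[1])
    return gold


def build_matrices(
    gold: dict[str, set[str]],
    predicted: list[Assignment],
    categories: list[str],
) -> LabelMatrices:
    """Align gold and predicted labels into binary matrices.

    Rows follow the gold gene order (sorted); a gold gene absent from the
    predictions gets an all-zero prediction row (logged).  A gold category
    missing from ``categories`` is an error.
    """
    cat_index = {c: j for j, c in enumerate(categories)}
    unknown = sorted({c for cats in gold.values() for c in cats} - set(categories))
    if unknown:
        raise ValueError(f"gold-standard categories not in scheme: {unknown}")
    genes = sorted(gold)
    pred_by_gene = {a.gene: a.categories for a in predicted}
    missing = [g for g in genes if g not in pred_by_gene]
    if missing:
        logger.warning("%d gold genes missing from predictions (all-zero rows)", len(missing))
    G = np.zeros((len(genes), len(categories)), dtype=np.int8)
    P = np.zeros_like(G)
    for i, g in enumerate(genes):
        for c in gold[g]:
            G[i, cat_index[c]] = 1
        for c in pred_by_gene.get(g, set()):
            if c in cat_index:
                P[i, cat_index[c]] = 1
    return LabelMatrices(genes=genes, categories=list(categories), G=G, P=P)


def multilabel_accuracy(m: LabelMatrices) -> float:
    """Fraction of agreeing cells over all genes × categories."""
    if m.G.size == 0:
        raise ValueError("empty matrices")
    return float((m.G == m.P).mean())


def _binary_mcc(g: np.ndarray, p: np.ndarray) -> float:
    tp = int(((g == 1) & (p == 1)).sum())
    tn = int(((g == 0) & (p == 0)).sum())
    fp = int(((g == 0) & (p == 1)).sum())
    fn = int(((g == 1) & (p == 0)).sum())
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def multilabel_mcc(m: LabelMatrices, average: str = "micro") -> float:
    """Matthews correlation coefficient of P against G.

    ``micro`` flattens all cells into one binary problem; ``macro`` averages
    per-category MCCs.  Any zero factor in the denominator yields 0.
    """
    if m.G.size == 0:
        raise ValueError("empty matrices")
    if average == "micro":
        return float(_binary_mcc(m.G.ravel(), m.P.ravel()))
    if average == "macro":
        return float(
            np.mean([_binary_mcc(m.G[:, j], m.P[:, j]) for j in range(m.G.shape[1])])
        )
    raise ValueError(f"average must be 'micro' or 'macro', got {average!r}")


def confusion_by_category(m: LabelMatrices) -> dict[str, dict[str, int]]:
    """Per-category TP/FP/TN/FN counts."""
    out = {}
    for j, cat in enumerate(m.categories):
        g, p = m.G[:, j], m.P[:, j]
        out[cat] = {
            "tp": int(((g == 1) & (p == 1)).sum()),
            "fp": int(((g == 0) & (p == 1)).sum()),
            "tn": int(((g == 0) & (p == 0)).sum()),
            "fn": int(((g == 1) & (p == 0)).sum()),
        }
    return out


def random_baseline(
    genes: list[str], categories: list[str], k: int = 3, seed: int = 0
) -> list[Assignment]:
    """Chance predictor: each gene gets ``k`` distinct categories uniformly.

    The default k = 3 approximates the typical multi-assignment degree of
    real categorizations (about 2.5 categories per gene).
    """
    if k > len(categories):
        raise ValueError(f"k={k} exceeds {len(categories)} categories")
    rng = np.random.default_rng(seed)
    out = []
    for gene in genes:
        cats = rng.choice(len(categories), size=k, replace=False)
        out.append(
            Assignment(
                gene=gene,
                assigned=[(categories[j], 1.0, ".") for j in sorted(cats)],
            )
        )
    return out
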