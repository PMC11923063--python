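"""Evaluation metrics and mutant-ranking benchmarks.

Metrics on log10-scale predictions X against experiment Y:

    PCC  = Σ(X−X̄)(Y−Ȳ) / √(Σ(X−X̄)²) √(Σ(Y−Ȳ)²)
    SCC  = 1 − 6 Σ d_i² / n(n²−1)          (tie-free; with ties,
                                            Pearson on average ranks)
    RMSE = √( (1/n) Σ (Y_i − X_i)² )

Mutant-ranking benchmarks group the wild-type and its variants sharing one
UniProtID-SMILES reaction into panels (minimum variant count N, typically
20 or 30), then score per-panel SCC, pairwise ordering accuracy
M_true / M_total with M_total = N(N−1)/2, and mean-centered mutation
effects pooled across reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "MutantPanel", "pcc", "scc", "rmse", "build_mutant_panels", "panel_scc",
    "pairwise_accuracy", "mutation_effects", "concatenate_effects",
]


def _check_pair(X, Y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape != Y.shape or X.ndim != 1:
        raise ValueError(f"need two equal-length vectors, got shapes "
                         f"{X.shape} and {Y.shape}")
    if X.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {X.size}")
    return X, Y


def pcc(X: Sequence[float], Y: Sequence[float]) -> float:
    """Pearson product-moment correlation; NaN when either input has zero
    variance (undefined)."""
    X, Y = _check_pair(X, Y, 2)
    dx, dy = X - X.mean(), Y - Y.mean()
    denom = np.sqrt((dx ** 2).sum()) * np.sqrt((dy ** 2).sum())
    if denom == 0.0:
        return float("nan")
    return float((dx * dy).sum() / denom)


def scc(X: Sequence[float], Y: Sequence[float]) -> float:
    """Spearman rank correlation.

    Tie-free inputs use the explicit 1 − 6Σd²/n(n²−1) form exactly; ties
    fall back to the average-rank (Pearson-on-ranks) generalization.  NaN
    when either input is constant.
    """
    X, Y = _check_pair(X, Y, 2)
    rx, ry = rankdata(X), rankdata(Y)
    n = X.size
    tie_free = (np.unique(X).size == n) and (np.unique(Y).size == n)
    if tie_free:
        d = rx - ry
        return float(1.0 - 6.0 * (d ** 2).sum() / (n * (n ** 2 - 1)))
    return pcc(rx, ry)


def rmse(X: Sequence[float], Y: Sequence[float]) -> float:
    """Root-mean-square error between predictions X and experiment Y."""
    X, Y = _check_pair(X, Y, 1)
    return float(np.sqrt(np.mean((Y - X) ** 2)))


@dataclass
class MutantPanel:
    """Wild-type plus variants of one reaction (one UniProtID-SMILES pair).

    Variants are (sequence, experimental label, predicted label) triples;
    variant identity is the distinct amino-acid sequence.
    """

    reaction_key: tuple[str, str]  # (enzyme_id, smiles)
    variants: list[tuple[str, float, float]] = field(default_factory=list)
    wild_type: str | None = None

    @property
    def n(self) -> int:
        return len(self.variants)

    @property
    def m_total(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def experimental(self) -> np.ndarray:
        return np.array([v[1] for v in self.variants])

    @property
    def predicted(self) -> np.ndarray:
        return np.array([v[2] for v in self.variants])


def build_mutant_panels(
    entries: Iterable,
    predictions: Mapping[tuple[str, str], float],
    min_variants: int = 20,
) -> list[MutantPanel]:
    """Group curated entries into mutant panels of ≥ min_variants variants.

    ``entries`` are curated dataset entries carrying ``enzyme_id``,
    ``sequence``, ``smiles``, ``label`` and ``enzyme_type``; panels are
    keyed by (enzyme_id, smiles) and only reactions whose distinct-sequence
    variant count (wild-type included) reaches ``min_variants`` are kept.
    ``predictions`` maps (sequence, smiles) to the predicted label.
    """
    groups: dict[tuple[str, str], MutantPanel] = {}
    seen: dict[tuple[str, str], set[str]] = {}
    for e in entries:
        if not e.enzyme_id:
            continue
        rkey = (e.enzyme_id, e.smiles)
        pred = predictions.get((e.sequence, e.smiles))
        if pred is None:
            continue
        panel = groups.setdefault(rkey, MutantPanel(reaction_key=rkey))
        if e.sequence in seen.setdefault(rkey, set()):
            continue
        seen[rkey].add(e.sequence)
        panel.variants.append((e.sequence, float(e.label), float(pred)))
        if e.enzyme_type == "wild_type":
            if panel.wild_type is not None and panel.wild_type != e.sequence:
                raise ValueError(
                    f"reaction {rkey} has two distinct wild-type sequences"
                )
            panel.wild_type = e.sequence
    return [p for p in groups.values() if p.n >= min_variants]


def panel_scc(
    panels: Sequence[MutantPanel],
) -> tuple[list[float], float, int]:
    """Within-panel SCC (predicted vs experimental) per panel, plus the
    unweighted mean.

    Panels whose SCC is undefined (constant labels) are excluded; the
    returned count says how many were dropped.
    """
    values: list[float] = []
    dropped = 0
    for p in panels:
        if p.n < 2:
            dropped += 1
            continue
        val = scc(p.predicted, p.experimental)
        if np.isnan(val):
            dropped += 1
        else:
            values.append(val)
    mean = float(np.mean(values)) if values else float("nan")
    return values, mean, dropped


def pairwise_accuracy(panel: MutantPanel) -> float:
    """Fraction of variant pairs whose predicted ordering matches experiment.

    Over all unordered pairs with *distinct* experimental values
    (experimentally tied pairs leave M_total); a predicted tie counts as
    incorrect.  NaN when every pair is experimentally tied.
    """
    if panel.n < 2:
        raise ValueError("pairwise accuracy needs at least 2 variants")
    y, p = panel.experimental, panel.predicted
    m_total = 0
    m_true = 0
    for i, j in combinations(range(panel.n), 2):
        if y[i] == y[j]:
            continue
        m_total += 1
        if (y[i] - y[j]) * (p[i] - p[j]) > 0:
            m_true += 1
    if m_total == 0:
        return float("nan")
    return m_true / m_total


def mutation_effects(panel: MutantPanel) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered experimental and predicted vectors of one panel.

    Each vector is centered by its own panel mean, so a panel's effect
    vector sums to zero; the wild-type's effect is its deviation from the
    panel mean like any other variant.
    """
    if panel.n < 2:
        raise ValueError("mutation effects need at least 2 variants")
    y, p = panel.experimental, panel.predicted
    return y - y.mean(), p - p.mean()


def concatenate_effects(
    panels: Sequence[MutantPanel],
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Pool centered mutation effects across reactions.

    Returns (experimental effects, predicted effects, pooled PCC, pooled
    SCC) on the concatenated vectors.
    """
    if len(panels) == 0:
        raise ValueError("no panels to concatenate")
    exp_parts, pred_parts = [], []
    for p in panels:
        e, q = mutation_effects(p)
        exp_parts.append(e)
        pred_parts.append(q)
    exp_all = np.concatenate(exp_parts)
    pred_all = np.concatenate(pred_parts)
    return exp_all, pred_all, pcc(pred_all, exp_all), scc(pred_all, exp_all)
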