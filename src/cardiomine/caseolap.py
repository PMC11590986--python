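"""CaseOLAP popularity–distinctiveness scoring of (protein, category) pairs.

The CaseOLAP score of an entity in a category combines two components, each
in [0, 1]:

* **popularity** — how strongly the entity features inside the category:
  ``Pop(p, C) = ln(1 + tf(p, C)) / ln(1 + T_C)`` where ``tf(p, C)`` is the
  entity's mention count in category ``C`` and ``T_C`` the category's total
  mention count (the log saturates heavy hitters; ``T_C`` may be replaced by
  the maximum per-entity count via ``popularity_denominator="max"``);
* **distinctiveness** — how concentrated the entity's relative frequency is
  in the category compared to the alternatives:
  ``Dist(p, C) = rtf(p, C) / Σ_C' rtf(p, C')`` with
  ``rtf(p, C) = tf(p, C) / T_C``.

The combined score is ``S = Pop × Dist``.  Because ``rtf`` is scale-free,
distinctiveness — and hence the ranking it drives — is robust to class
imbalance in the document counts of the categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .mentions import MentionCountMatrix


def popularity(tf_pc: float, total_c: float) -> float:
    """Log-saturated within-category frequency, in [0, 1].

    Zero when the category is empty; 1 when the entity accounts for the whole
    category total.
    """
    if tf_pc < 0 or total_c < 0:
        raise ValueError("counts must be non-negative")
    if tf_pc > total_c:
        raise ValueError(f"tf ({tf_pc}) exceeds category total ({total_c})")
    if total_c == 0:
        return 0.0
    return math.log1p(tf_pc) / math.log1p(total_c)


def distinctiveness(
    tf_p_across: Mapping[str, float], category_totals: Mapping[str, float]
) -> dict[str, float]:
    """Relative-frequency share of one protein across categories.

    Returns the all-zero map for a protein never mentioned anywhere; otherwise
    the values sum to 1.
    """
    rtf = {
        c: (tf_p_across[c] / category_totals[c] if category_totals[c] > 0 else 0.0)
        for c in tf_p_across
    }
    denom = sum(rtf.values())
    if denom == 0:
        return {c: 0.0 for c in rtf}
    return {c: v / denom for c, v in rtf.items()}


@dataclass
class ScoreMatrix:
    """Popularity, distinctiveness, and combined score per (protein, category)."""

    popularity: pd.DataFrame
    distinctiveness: pd.DataFrame
    score: pd.DataFrame

    @property
    def proteins(self) -> list[str]:
        return list(self.score.index)

    @property
    def categories(self) -> list[str]:
        return list(self.score.columns)

    def scoring_proteins(self) -> list[str]:
        """Proteins with a positive score in at least one category."""
        mask = self.score.max(axis=1) > 0
        return list(self.score.index[mask])

    def n_scoring(self) -> int:
        return len(self.scoring_proteins())

    def to_csv(self, directory, prefix: str = "caseolap") -> None:
        """Write score, popularity, and distinctiveness matrices as CSV."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.score.to_csv(d / f"{prefix}_score.csv", index_label="protein_id")
        self.popularity.to_csv(d / f"{prefix}_popularity.csv", index_label="protein_id")
        self.distinctiveness.to_csv(
            d / f"{prefix}_distinctiveness.csv", index_label="protein_id"
        )


def compute_score_matrix(
    counts: MentionCountMatrix,
    *,
    popularity_denominator: Literal["total", "max"] = "total",
) -> ScoreMatrix:
    """CaseOLAP score matrix S = Pop ⊙ Dist from a mention-count matrix.

    ``popularity_denominator`` selects the popularity normalizer: the
    category's total mention count (default) or its maximum per-protein count.
    """
    tf = counts.tf.astype(float)
    if popularity_denominator == "total":
        denom = tf.sum(axis=0)
    elif popularity_denominator == "max":
        denom = tf.max(axis=0)
    else:
        raise ValueError(f"unknown popularity_denominator {popularity_denominator!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        log_denom = np.log1p(denom.to_numpy())
        pop = np.log1p(tf.to_numpy()) / np.where(log_denom > 0, log_denom, np.inf)

        totals = tf.sum(axis=0).to_numpy()
        rtf = tf.to_numpy() / np.where(totals > 0, totals, np.inf)
        row_sums = rtf.sum(axis=1, keepdims=True)
        dist = rtf / np.where(row_sums > 0, row_sums, np.inf)

    pop_df = pd.DataFrame(pop, index=tf.index, columns=tf.columns)
    dist_df = pd.DataFrame(dist, index=tf.index, columns=tf.columns)
    return ScoreMatrix(
        popularity=pop_df, distinctiveness=dist_df, score=pop_df * dist_df
    )


def rank_proteins(scores: ScoreMatrix, category: str) -> pd.Series:
    """Proteins of one category sorted by score descending, ties by protein_id."""
    s = scores.score[category]
    order = sorted(s.index, key=lambda p: (-s[p], p))
    return s.loc[order]
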