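"""Spore-Former / Former-Spore-Former classification.

Bacterial families fall into three score patterns: unimodal high, unimodal
low, or bimodal (two well-separated score clusters). Within bimodal families
genomes are assigned to the high or low cluster by an exhaustive 1-D
two-group partition minimizing within-group variance; families too small or
without a sufficient gap are called high or low from their spo0A majority
(spo0A, the sporulation master regulator, is present in essentially all
spore-formers). A genome is classified SF iff it sits in a high cluster;
spo0A does not override cluster membership — genomes in low clusters that
retain spo0A 'discordantly' are still Former-Spore-Formers and are surfaced
through the concordance report.

The public surface is a statsmodels-style pair: :class:`SporulationModel`
built from a per-genome score table, whose :meth:`~SporulationModel.fit`
returns a :class:`SporulationResults` with the per-family patterns, the
per-genome calls, the concordance diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import format_percent

__all__ = [
    "FamilyPattern",
    "SporulationModel",
    "SporulationResults",
    "detect_family_pattern",
    "classify_genomes",
    "concordance_report",
]


@dataclass(frozen=True)
class FamilyPattern:
    family: str
    pattern: str  # "high" | "low" | "bimodal"
    cluster_boundary: Optional[float]
    n_genomes: int

    def __post_init__(self) -> None:
        if self.pattern not in ("high", "low", "bimodal"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if (self.cluster_boundary is None) == (self.pattern == "bimodal"):
            raise ValueError("cluster_boundary must be set iff pattern is bimodal")


def _best_split(sorted_scores: np.ndarray) -> tuple[int, float]:
    """Best two-group partition of sorted 1-D data.

    Returns ``(k, sse)`` where the low group is ``sorted_scores[:k]``; the
    exhaustive scan over all n-1 cut points minimizes the summed within-group
    sum of squares. Ties resolve to the smallest k.
    """
    n = sorted_scores.size
    best_k, best_sse = 1, np.inf
    for k in range(1, n):
        low, high = sorted_scores[:k], sorted_scores[k:]
        sse = ((low - low.mean()) ** 2).sum() + ((high - high.mean()) ** 2).sum()
        if sse < best_sse - 1e-12:
            best_k, best_sse = k, sse
    return best_k, best_sse


def detect_family_pattern(
    family: str,
    scores: Sequence[float],
    spo0A: Sequence[bool],
    min_n: int = 5,
    min_gap: float = 20.0,
) -> FamilyPattern:
    """Classify one family's score distribution as high, low, or bimodal.

    With ``n >= min_n`` genomes, the variance-minimizing two-group split is
    computed; the family is bimodal iff the two group means differ by at least
    ``min_gap`` score points and each group has >= 2 members, with the cluster
    boundary at the midpoint between the adjacent extreme members across the
    split. Otherwise (including all families below ``min_n``) the family is
    called high or low by its spo0A majority, ties going to low.
    """
    scores = np.asarray(scores, dtype=float)
    spo0A = np.asarray(spo0A, dtype=bool)
    if scores.size == 0:
        raise ValueError(f"family {family!r} has no genomes")
    if scores.size != spo0A.size:
        raise ValueError("scores and spo0A flags must align")

    if scores.size >= min_n:
        s = np.sort(scores)
        k, _ = _best_split(s)
        low, high = s[:k], s[k:]
        gap = high.mean() - low.mean()
        if gap >= min_gap and low.size >= 2 and high.size >= 2:
            boundary = (low[-1] + high[0]) / 2.0
            return FamilyPattern(family, "bimodal", float(boundary), scores.size)

    n_with = int(spo0A.sum())
    pattern = "high" if n_with > scores.size - n_with else "low"
    return FamilyPattern(family, pattern, None, scores.size)


def classify_genomes(
    scores: pd.DataFrame, patterns: dict[str, FamilyPattern]
) -> pd.DataFrame:
    """Assign each genome a cluster and an SF/FSF class.

    ``scores`` needs columns genome_id, family, score_percent, spo0A_present.
    Bimodal families split at the boundary (scores exactly on the boundary go
    to the low cluster); unimodal families inherit the family pattern. A
    genome is SF iff its cluster is high. ``concordant`` marks the genomes
    whose spo0A status matches their cluster (high+spo0A or low-spo0A).
    """
    missing = sorted(set(scores["family"]) - set(patterns))
    if missing:
        raise ValueError(f"no family pattern for families: {missing}")
    clusters = []
    for row in scores.itertuples():
        pat = patterns[row.family]
        if pat.pattern == "bimodal":
            clusters.append("high" if row.score_percent > pat.cluster_boundary else "low")
        else:
            clusters.append(pat.pattern)
    out = scores.copy()
    out["cluster"] = clusters
    out["sporulation_class"] = np.where(out["cluster"] == "high", "SF", "FSF")
    out["concordant"] = (
        ((out["cluster"] == "high") & out["spo0A_present"])
        | ((out["cluster"] == "low") & ~out["spo0A_present"])
    )
    return out


def concordance_report(calls: pd.DataFrame) -> tuple[int, int, float]:
    """(n_concordant, n_total, percent) — percent rounded half-up, 1 decimal."""
    if len(calls) == 0:
        raise ValueError("no calls to report on")
    n_conc = int(calls["concordant"].sum())
    n_total = len(calls)
    return n_conc, n_total, float(format_percent(n_conc, n_total, 1))


class SporulationModel:
    """Family-structured sporulation classifier over signature scores.

    Parameters
    ----------
    data:
        DataFrame with columns ``genome_id``, ``family``, ``score_percent``,
        ``spo0A_present``. An ``n_present`` column is carried through if given.
    """

    REQUIRED = ("genome_id", "family", "score_percent", "spo0A_present")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"score table missing columns: {missing}")
        if data["genome_id"].duplicated().any():
            dupes = sorted(data.loc[data["genome_id"].duplicated(), "genome_id"])
            raise ValueError(f"duplicate genome ids: {dupes}")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_scores(
        cls, scores: pd.DataFrame, metadata: pd.DataFrame
    ) -> "SporulationModel":
        """Join per-genome scores (from :func:`sporesig.signature.signature_score`)
        with genome metadata carrying the family assignment."""
        merged = scores.merge(
            metadata[["genome_id", "family"]], on="genome_id", how="left"
        )
        if merged["family"].isna().any():
            lost = sorted(merged.loc[merged["family"].isna(), "genome_id"])
            raise ValueError(f"genomes missing from metadata: {lost}")
        return cls(merged)

    def fit(self, min_n: int = 5, min_gap: float = 20.0) -> "SporulationResults":
        patterns: dict[str, FamilyPattern] = {}
        for family, grp in self.data.groupby("family", sort=True):
            patterns[family] = detect_family_pattern(
                family,
                grp["score_percent"].to_numpy(),
                grp["spo0A_present"].to_numpy(),
                min_n=min_n,
                min_gap=min_gap,
            )
        calls = classify_genomes(self.data, patterns)
        return SporulationResults(self, patterns, calls)


class SporulationResults:
    """Fitted classification: family patterns, per-genome calls, diagnostics."""

    def __init__(
        self,
        model: SporulationModel,
        patterns: dict[str, FamilyPattern],
        calls: pd.DataFrame,
    ):
        self.model = model
        self.family_patterns = patterns
        self.calls = calls

    @property
    def concordance(self) -> tuple[int, int, float]:
        return concordance_report(self.calls)

    @property
    def n_sf(self) -> int:
        return int((self.calls["sporulation_class"] == "SF").sum())

    @property
    def n_fsf(self) -> int:
        return int((self.calls["sporulation_class"] == "FSF").sum())

    def patterns_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family": p.family,
                    "pattern": p.pattern,
                    "cluster_boundary": p.cluster_boundary,
                    "n_genomes": p.n_genomes,
                }
                for p in sorted(self.family_patterns.values(), key=lambda p: p.family)
            ]
        )

    def summary(self) -> str:
        n_conc, n_total, pct = self.concordance
        lines = [
            "Sporulation classification",
            "=" * 62,
            f"genomes: {n_total}   families: {len(self.family_patterns)}",
            f"Spore-Formers (SF): {self.n_sf}   Former-Spore-Formers (FSF): {self.n_fsf}",
            f"score/spo0A concordance: {n_conc}/{n_total} ({pct}%)",
            "-" * 62,
            f"{'family':<24}{'pattern':<10}{'boundary':>10}{'n':>6}",
        ]
        for p in sorted(self.family_patterns.values(), key=lambda p: p.family):
            b = f"{p.cluster_boundary:.1f}" if p.cluster_boundary is not None else "-"
            lines.append(f"{p.family:<24}{p.pattern:<10}{b:>10}{p.n_genomes:>6}")
        return "\n".join(lines)
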