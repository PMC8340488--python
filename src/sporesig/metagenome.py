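"""Metagenomic prevalence, abundance, permutation and beta-diversity analyses.

Species presence in a metagenome is called from reference-mapping coverage: a
species is present when its genome is covered across at least 60% of its
length (breadth >= 0.60) while its depth variation stays below a calibrated
cap — the empirical 99th percentile of the depth coefficient of variation
within the corresponding breadth bin. Abundance is RPKM:
``RPKM = RS / (GL * TRC / 1_000_000)`` with RS the uniquely mapped read
count, GL the genome length in kilobases and TRC the sample's total reads.

Group comparisons use the two-tailed Wilcoxon rank-sum test on species-level
prevalences and (median, over present samples) abundances; the equal-n
permutation analysis subsamples the larger group, and beta-diversity
contributions decompose squared Aitchison distances over species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.composition import clr

from .stats import PermutationEngine, ranksum
from .types import TestResult

__all__ = [
    "CoverageSummary",
    "PresenceCalibration",
    "MappingSummary",
    "summarize_coverage",
    "calibrate",
    "call_presence",
    "rpkm",
    "prevalence",
    "abundance_compare",
    "permutation_equalized",
    "aitchison_contribution",
]


@dataclass(frozen=True)
class CoverageSummary:
    genome_id: str
    sample_id: str
    breadth: float  # fraction of positions with depth >= 1
    mean_depth: float  # mean depth over covered positions (0 if none)
    depth_cv: float  # sd/mean of depth over covered positions

    def __post_init__(self) -> None:
        if not 0 <= self.breadth <= 1:
            raise ValueError("breadth must be in [0, 1]")
        if self.depth_cv < 0:
            raise ValueError("depth_cv must be >= 0")
        if self.mean_depth == 0 and self.breadth != 0:
            raise ValueError("mean_depth = 0 implies breadth = 0")


@dataclass(frozen=True)
class MappingSummary:
    genome_id: str
    sample_id: str
    rs: int  # uniquely mapped, properly paired reads
    gl_kb: float  # genome length in kilobases
    trc: int  # total read count of the sample

    def __post_init__(self) -> None:
        if self.gl_kb <= 0:
            raise ValueError("genome length must be positive")
        if self.rs > self.trc:
            raise ValueError("RS cannot exceed TRC")


@dataclass(frozen=True)
class PresenceCalibration:
    """Per-breadth-bin depth-variation caps over [breadth_min, 1].

    ``bin_edges`` has one more element than ``cv_thresholds``; bin i covers
    [bin_edges[i], bin_edges[i+1]) (the last bin is closed above).
    """

    bin_edges: np.ndarray
    cv_thresholds: np.ndarray
    breadth_min: float = 0.60

    def threshold_for(self, breadth: float) -> float:
        if breadth < self.breadth_min:
            raise ValueError(f"breadth {breadth} below calibrated range")
        idx = min(
            int((breadth - self.breadth_min) / (self.bin_edges[1] - self.bin_edges[0])),
            len(self.cv_thresholds) - 1,
        )
        return float(self.cv_thresholds[idx])


def summarize_coverage(
    depth: np.ndarray, genome_id: str = "", sample_id: str = ""
) -> CoverageSummary:
    """Breadth / depth statistics of one genome's per-position depth vector.

    ``depth_cv`` is the population (ddof=0) coefficient of variation over
    covered positions only; an uncovered genome gets breadth 0, cv 0.
    """
    depth = np.asarray(depth)
    if depth.size == 0:
        raise ValueError(f"genome {genome_id!r} has zero length")
    covered = depth[depth >= 1]
    breadth = covered.size / depth.size
    if covered.size == 0:
        return CoverageSummary(genome_id, sample_id, 0.0, 0.0, 0.0)
    mean = float(covered.mean())
    cv = float(covered.std(ddof=0) / mean)
    return CoverageSummary(genome_id, sample_id, float(breadth), mean, cv)


def calibrate(
    summaries: list[CoverageSummary],
    breadth_min: float = 0.60,
    bin_width: float = 0.01,
    percentile: float = 99.0,
) -> PresenceCalibration:
    """Fit per-breadth-bin depth-variation caps.

    Uses every summary with breadth >= ``breadth_min``; each bin's cap is the
    empirical ``percentile`` of its members' depth CV, and empty bins inherit
    the nearest populated bin's cap (ties to the lower bin). Warns below 100
    usable summaries.
    """
    usable = [s for s in summaries if s.breadth >= breadth_min]
    if not usable:
        raise ValueError(f"no coverage summaries with breadth >= {breadth_min}")
    if len(usable) < 100:
        warnings.warn(
            f"only {len(usable)} summaries with breadth >= {breadth_min}; "
            "calibration may be unstable"
        )
    n_bins = int(round((1.0 - breadth_min) / bin_width))
    edges = breadth_min + bin_width * np.arange(n_bins + 1)
    binned: list[list[float]] = [[] for _ in range(n_bins)]
    for s in usable:
        idx = min(int((s.breadth - breadth_min) / bin_width), n_bins - 1)
        binned[idx].append(s.depth_cv)
    thresholds = np.full(n_bins, np.nan)
    for i, vals in enumerate(binned):
        if vals:
            thresholds[i] = np.percentile(vals, percentile)
    populated = np.flatnonzero(~np.isnan(thresholds))
    for i in np.flatnonzero(np.isnan(thresholds)):
        nearest = populated[np.argmin(np.abs(populated - i))]
        thresholds[i] = thresholds[nearest]
    return PresenceCalibration(edges, thresholds, breadth_min)


def call_presence(summary: CoverageSummary, calibration: PresenceCalibration) -> bool:
    """Species present iff breadth >= the hard cutoff and depth CV is below
    the calibrated cap for the summary's breadth bin."""
    if summary.breadth < calibration.breadth_min:
        return False
    return summary.depth_cv <= calibration.threshold_for(summary.breadth)


def rpkm(summary: MappingSummary) -> float:
    """Reads per kilobase of genome per million sample reads."""
    if summary.trc == 0:
        raise ValueError("total read count is zero")
    return summary.rs / (summary.gl_kb * summary.trc / 1_000_000)


def prevalence(
    presence: pd.DataFrame,
    calls: pd.DataFrame,
    sample_country: pd.Series | None = None,
) -> tuple[pd.DataFrame, TestResult]:
    """Species-level prevalence plus the SF vs FSF Wilcoxon comparison.

    ``presence`` is species x samples boolean. Prevalence is the fraction of
    samples in which a species is called present. When ``sample_country``
    maps sample -> country, per-country prevalences are appended as extra
    columns. Returns the per-species frame and the two-tailed rank-sum test
    on prevalences between groups.
    """
    if presence.shape[1] == 0:
        raise ValueError("no samples")
    cls = calls.set_index("genome_id")["sporulation_class"]
    missing = set(presence.index) - set(cls.index)
    if missing:
        raise ValueError(f"species without classification: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "genome_id": presence.index,
            "sporulation_class": cls.loc[presence.index].to_numpy(),
            "n_present": presence.sum(axis=1).to_numpy(),
            "n_samples": presence.shape[1],
        }
    )
    out["prevalence"] = out["n_present"] / out["n_samples"]
    if sample_country is not None:
        for country, samples in sample_country.groupby(sample_country):
            cols = [s for s in samples.index if s in presence.columns]
            out[f"prevalence_{country}"] = (
                presence[cols].sum(axis=1) / len(cols)
            ).to_numpy()
    sf = out.loc[out["sporulation_class"] == "SF", "prevalence"]
    fsf = out.loc[out["sporulation_class"] == "FSF", "prevalence"]
    if sf.empty or fsf.empty:
        raise ValueError("both groups must contain species")
    return out, ranksum(sf, fsf, sided="two-sided")


def abundance_compare(
    rpkm_matrix: pd.DataFrame,
    presence: pd.DataFrame,
    calls: pd.DataFrame,
    min_samples: int = 10,
) -> tuple[pd.DataFrame, TestResult]:
    """Species-level abundance comparison between SF and FSF.

    Only species present in strictly more than ``min_samples`` samples are
    retained; a species' abundance is its median RPKM over the samples where
    it is present. Returns the per-species frame and the two-tailed rank-sum
    test between groups.
    """
    if not rpkm_matrix.index.equals(presence.index) or not rpkm_matrix.columns.equals(
        presence.columns
    ):
        raise ValueError("rpkm and presence matrices must be aligned")
    cls = calls.set_index("genome_id")["sporulation_class"]
    rows = []
    for species in rpkm_matrix.index:
        present_mask = presence.loc[species].to_numpy().astype(bool)
        n_present = int(present_mask.sum())
        if n_present <= min_samples:
            continue
        rows.append(
            {
                "genome_id": species,
                "sporulation_class": cls[species],
                "n_present": n_present,
                "median_rpkm": float(
                    np.median(rpkm_matrix.loc[species].to_numpy()[present_mask])
                ),
            }
        )
    if not rows:
        raise ValueError(
            f"no species present in more than {min_samples} samples"
        )
    out = pd.DataFrame(rows)
    sf = out.loc[out["sporulation_class"] == "SF", "median_rpkm"]
    fsf = out.loc[out["sporulation_class"] == "FSF", "median_rpkm"]
    if sf.empty or fsf.empty:
        raise ValueError("both groups must survive the sample filter")
    return out, ranksum(sf, fsf, sided="two-sided")


def permutation_equalized(
    prevalences: pd.Series,
    calls: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Equal-n permutation analysis of group prevalence.

    Each permutation draws ``n_FSF`` SF species without replacement and asks
    whether their median prevalence exceeds the FSF median; the returned
    fraction of 'SF greater' permutations is in [0, 1] and is reproducible
    for a fixed seed.
    """
    cls = calls.set_index("genome_id")["sporulation_class"]
    sf = prevalences[cls.loc[prevalences.index] == "SF"].to_numpy()
    fsf = prevalences[cls.loc[prevalences.index] == "FSF"].to_numpy()
    if sf.size < fsf.size:
        raise ValueError("need at least as many SF species as FSF species")
    engine = PermutationEngine(seed)
    return engine.equalized_fraction(sf, fsf, n_perm=n_perm, statistic=np.median)


def aitchison_contribution(
    rpkm_matrix: pd.DataFrame,
    calls: pd.DataFrame,
    pseudocount: str = "half-min",
) -> pd.DataFrame:
    """Per-species (and per-group) share of Aitchison beta-diversity.

    Samples are CLR-transformed after zero replacement (per-sample
    pseudocount = half the smallest nonzero value, the default policy). The
    squared Aitchison distance between two samples is the sum over species of
    squared CLR differences, so each species' contribution to a pair is its
    share of that sum; per-species contributions average the share over all
    sample pairs with nonzero distance. Shares sum to 1. Species absent from
    every sample are dropped with a warning. ``rpkm_matrix`` is species x
    samples.
    """
    if rpkm_matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    mat = rpkm_matrix.copy()
    dead = mat.index[(mat <= 0).all(axis=1)]
    if len(dead):
        warnings.warn(f"species absent everywhere dropped: {list(dead)}")
        mat = mat.drop(index=dead)

    comp = mat.to_numpy(dtype=float).T  # samples x species
    for i in range(comp.shape[0]):
        row = comp[i]
        nz = row[row > 0]
        if nz.size == 0:
            raise ValueError(f"sample {mat.columns[i]!r} has no signal")
        if pseudocount == "half-min":
            row[row <= 0] = nz.min() / 2.0
        else:
            row[row <= 0] = float(pseudocount)
    z = clr(comp)

    n = z.shape[0]
    shares = np.zeros(z.shape[1])
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            sq = (z[i] - z[j]) ** 2
            total = sq.sum()
            if total == 0:
                continue
            shares += sq / total
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("all sample pairs are identical; no beta-diversity")
    shares /= n_pairs

    cls = calls.set_index("genome_id")["sporulation_class"]
    return pd.DataFrame(
        {
            "genome_id": mat.index,
            "sporulation_class": cls.loc[mat.index].to_numpy(),
            "contribution": shares,
        }
    )
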