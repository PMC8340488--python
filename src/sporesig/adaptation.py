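"""Genome-level host-adaptation features.

Covers protein-domain enrichment between Spore-Formers and Former-Spore-
Formers (one-sided Fisher per direction with Hochberg adjustment), grouping of
enriched domains into functional classes, paralogy as the percentage of excess
domain copies, CAZyme hit filtering and per-genome profiling with Welch's t
group tests, per-substrate growth comparisons, and genome size / gene count
comparisons (Mann-Whitney, Spearman).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import fisher_exact, hochberg, ranksum, spearman, welch_t
from .types import ContingencyTable, HomologyHit, TestResult

__all__ = [
    "EnrichmentResult",
    "CazymeProfile",
    "domain_enrichment",
    "class_comparison",
    "known_function_fraction",
    "paralog_percent",
    "cazyme_family",
    "cazyme_filter",
    "cazyme_summary",
    "substrate_comparison",
    "genome_feature_compare",
]


@dataclass(frozen=True)
class EnrichmentResult:
    domain_id: str
    group: str  # direction tested: enriched in "SF" or "FSF"
    table: ContingencyTable
    p_raw: float
    p_adjusted: float
    enriched: bool


@dataclass(frozen=True)
class CazymeProfile:
    genome_id: str
    total_cazymes: int
    n_families: int

    def __post_init__(self) -> None:
        if self.n_families > self.total_cazymes:
            raise ValueError("n_families cannot exceed total_cazymes")


def _split_groups(calls: pd.DataFrame) -> tuple[list[str], list[str]]:
    sf = calls.loc[calls["sporulation_class"] == "SF", "genome_id"].tolist()
    fsf = calls.loc[calls["sporulation_class"] == "FSF", "genome_id"].tolist()
    if not sf or not fsf:
        raise ValueError("both SF and FSF groups must be non-empty")
    return sf, fsf


def domain_enrichment(
    annotations: pd.DataFrame,
    calls: pd.DataFrame,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-domain SF/FSF enrichment by one-sided Fisher's exact test.

    ``annotations`` needs columns genome_id, domain_id (copy counts are
    irrelevant here — enrichment is on presence). For each domain a 2x2 table
    of genomes with/without the domain vs group is tested one-sided in each
    direction; Hochberg adjustment runs across all domains within a direction,
    and a domain is flagged enriched in a group at ``p_adjusted < alpha``.
    Domains present in no genome are excluded with a warning.
    """
    sf, fsf = _split_groups(calls)
    sf_set, fsf_set = set(sf), set(fsf)
    domains = sorted(annotations["domain_id"].unique())
    with_domain = annotations.groupby("domain_id")["genome_id"].agg(set)

    tables: dict[str, ContingencyTable] = {}
    for dom in domains:
        carriers = with_domain[dom]
        a = len(carriers & sf_set)
        b = len(carriers & fsf_set)
        if a + b == 0:
            warnings.warn(f"domain {dom} present in zero genomes; excluded")
            continue
        tables[dom] = ContingencyTable(a=a, b=b, c=len(sf) - a, d=len(fsf) - b)

    results: list[EnrichmentResult] = []
    for direction, sided in (("SF", "greater"), ("FSF", "less")):
        doms = list(tables)
        p_raw = [fisher_exact(tables[d], sided=sided).p_value for d in doms]
        p_adj = hochberg(p_raw)
        for d, pr, pa in zip(doms, p_raw, p_adj):
            results.append(
                EnrichmentResult(
                    domain_id=d,
                    group=direction,
                    table=tables[d],
                    p_raw=pr,
                    p_adjusted=float(pa),
                    enriched=bool(pa < alpha),
                )
            )
    return results


def enrichment_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "domain_id": r.domain_id,
                "group": r.group,
                "sf_with": r.table.a,
                "fsf_with": r.table.b,
                "sf_without": r.table.c,
                "fsf_without": r.table.d,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "enriched": r.enriched,
            }
            for r in results
        ]
    )


def class_comparison(
    enriched_sf: Sequence[str],
    enriched_fsf: Sequence[str],
    class_map: Mapping[str, Optional[str]],
) -> pd.DataFrame:
    """Compare functional-class membership between the two enriched sets.

    For each functional class, a 2x2 table (class members vs non-members) x
    (SF-enriched set, FSF-enriched set) is tested with a two-sided Fisher's
    exact test. Domains absent from ``class_map`` (or mapped to None) count as
    'unknown function'; the unmapped fraction per set is reported in the
    attrs of the returned frame.
    """
    sf = list(dict.fromkeys(enriched_sf))
    fsf = list(dict.fromkeys(enriched_fsf))
    if not sf or not fsf:
        raise ValueError("both enriched sets must be non-empty")

    def cls_of(d: str) -> Optional[str]:
        return class_map.get(d)

    classes = sorted({c for d in sf + fsf if (c := cls_of(d)) is not None})
    rows = []
    for cls in classes:
        a = sum(1 for d in sf if cls_of(d) == cls)
        b = sum(1 for d in fsf if cls_of(d) == cls)
        table = ContingencyTable(a=a, b=b, c=len(sf) - a, d=len(fsf) - b)
        res = fisher_exact(table, sided="two-sided")
        rows.append(
            {
                "functional_class": cls,
                "sf_enriched": a,
                "fsf_enriched": b,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
    out.attrs["known_fraction_sf"] = known_function_fraction(sf, class_map)
    out.attrs["known_fraction_fsf"] = known_function_fraction(fsf, class_map)
    return out


def known_function_fraction(
    enriched: Sequence[str], class_map: Mapping[str, Optional[str]]
) -> float:
    """Fraction (0-1) of an enriched set assigned to a known functional class."""
    if not enriched:
        raise ValueError("empty enriched set")
    known = sum(1 for d in enriched if class_map.get(d) is not None)
    return known / len(enriched)


def paralog_percent(
    copy_counts: Mapping[str, int], mode: str = "excess"
) -> float:
    """Percentage of paralogous domain instances in one genome.

    ``copy_counts`` maps domain_id -> copy count. With ``mode="excess"``
    (default) paralog instances are the copies beyond the first of each
    domain, so ``{A: 3, B: 1}`` -> 2/4 = 50%. ``mode="multicopy_domains"``
    instead counts domains with >= 2 copies against the number of distinct
    domains.
    """
    if not copy_counts:
        raise ValueError("genome has no annotated domains")
    counts = np.asarray(list(copy_counts.values()), dtype=np.int64)
    if (counts < 1).any():
        raise ValueError("copy counts must be >= 1")
    if mode == "excess":
        return 100.0 * (counts - 1).sum() / counts.sum()
    if mode == "multicopy_domains":
        return 100.0 * (counts > 1).sum() / counts.size
    raise ValueError(f"unknown paralog mode {mode!r}")


_FAMILY_RE = re.compile(r"^([A-Za-z]+\d+)")


def cazyme_family(hmm_name: str) -> str:
    """CAZyme family label from an HMM name: 'GH13_31.hmm' -> 'GH13'."""
    base = hmm_name.rsplit(".hmm", 1)[0]
    m = _FAMILY_RE.match(base)
    return m.group(1) if m else base


def _family_excluded(family: str, exclusions: Sequence[str]) -> bool:
    for rule in exclusions:
        if rule.endswith("*"):
            if family.startswith(rule[:-1]):
                return True
        elif family == rule:
            return True
    return False


def cazyme_filter(
    hits: Iterable[HomologyHit],
    exclusions: Sequence[str] = ("AA*", "GT*", "CE10"),
    min_alignment_aa: int = 80,
    e_strict: float = 1e-5,
    e_relaxed: float = 1e-3,
    min_hmm_coverage: float = 0.30,
) -> list[HomologyHit]:
    """Filter raw CAZyme HMM hits to confident, carbohydrate-relevant ones.

    A hit is kept iff its alignment exceeds ``min_alignment_aa`` amino acids
    AND (e-value < ``e_strict`` OR e-value < ``e_relaxed`` while covering more
    than ``min_hmm_coverage`` of the HMM). Families not directly tied to
    carbohydrate utilization — all auxiliary activities (AA*), all
    glycosyltransferases (GT*), and CE10 — are then dropped. Hits missing the
    HMM coverage fail the relaxed clause (with a warning).
    """
    kept: list[HomologyHit] = []
    warned = False
    for h in hits:
        if h.alignment_length_aa <= min_alignment_aa:
            continue
        if h.e_value < e_strict:
            ok = True
        elif h.e_value < e_relaxed:
            if h.hmm_coverage is None:
                if not warned:
                    warnings.warn(
                        "hits without hmm_coverage cannot pass the relaxed "
                        "e-value clause; treating as failed"
                    )
                    warned = True
                ok = False
            else:
                ok = h.hmm_coverage > min_hmm_coverage
        else:
            ok = False
        if ok and not _family_excluded(cazyme_family(h.query_id), exclusions):
            kept.append(h)
    return kept


def cazyme_summary(
    filtered_hits: Iterable[HomologyHit], calls: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, TestResult]]:
    """Per-genome CAZyme profiles plus SF vs FSF Welch's t-tests.

    Totals are kept hits per genome; families are distinct family labels per
    genome. Genomes with no kept hits get zero counts. Returns the per-genome
    frame and Welch tests on totals and on family counts (skipped with a
    warning if a group has < 2 genomes).
    """
    per_genome: dict[str, list[str]] = {g: [] for g in calls["genome_id"]}
    for h in filtered_hits:
        if h.subject_id not in per_genome:
            raise ValueError(f"hit references genome {h.subject_id!r} not in calls")
        per_genome[h.subject_id].append(cazyme_family(h.query_id))
    profiles = pd.DataFrame(
        {
            "genome_id": list(per_genome),
            "total_cazymes": [len(v) for v in per_genome.values()],
            "n_families": [len(set(v)) for v in per_genome.values()],
        }
    ).merge(calls[["genome_id", "sporulation_class"]], on="genome_id")

    tests: dict[str, TestResult] = {}
    sf = profiles[profiles["sporulation_class"] == "SF"]
    fsf = profiles[profiles["sporulation_class"] == "FSF"]
    if len(sf) < 2 or len(fsf) < 2:
        warnings.warn("a group has < 2 genomes; Welch tests skipped")
    else:
        tests["total_cazymes"] = welch_t(sf["total_cazymes"], fsf["total_cazymes"])
        tests["n_families"] = welch_t(sf["n_families"], fsf["n_families"])
    return profiles, tests


def pool_replicates(growth: pd.DataFrame, replicate_of: Mapping[str, str]) -> pd.DataFrame:
    """Pool replicate growth columns per isolate by majority (ties -> False)."""
    pooled: dict[str, np.ndarray] = {}
    isolates = sorted(set(replicate_of.values()))
    for isolate in isolates:
        reps = [c for c, iso in replicate_of.items() if iso == isolate]
        if not reps:
            raise ValueError(f"isolate {isolate!r} has no replicate columns")
        votes = growth[reps].to_numpy().astype(int)
        pooled[isolate] = votes.sum(axis=1) * 2 > votes.shape[1]
    return pd.DataFrame(pooled, index=growth.index)


def substrate_comparison(
    growth: pd.DataFrame, isolate_class: Mapping[str, str]
) -> pd.DataFrame:
    """Per-substrate SF vs FSF growth comparison (two-sided Fisher).

    ``growth`` is substrates x isolates boolean (replicates already pooled;
    see :func:`pool_replicates`). Substrates untested (NaN) in a whole group
    are skipped with a warning.
    """
    sf_iso = [i for i in growth.columns if isolate_class.get(i) == "SF"]
    fsf_iso = [i for i in growth.columns if isolate_class.get(i) == "FSF"]
    if not sf_iso or not fsf_iso:
        raise ValueError("need >= 1 isolate per group")
    rows = []
    for substrate, row in growth.iterrows():
        sf_calls = row[sf_iso].dropna()
        fsf_calls = row[fsf_iso].dropna()
        if sf_calls.empty or fsf_calls.empty:
            warnings.warn(f"substrate {substrate!r} untested in a group; skipped")
            continue
        a = int(sf_calls.astype(bool).sum())
        b = int(fsf_calls.astype(bool).sum())
        table = ContingencyTable(
            a=a, b=b, c=len(sf_calls) - a, d=len(fsf_calls) - b
        )
        res = fisher_exact(table, sided="two-sided")
        rows.append(
            {
                "substrate": substrate,
                "sf_grew": a,
                "sf_total": len(sf_calls),
                "fsf_grew": b,
                "fsf_total": len(fsf_calls),
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def genome_feature_compare(
    metadata: pd.DataFrame, calls: pd.DataFrame
) -> dict[str, object]:
    """Group comparisons of genome size and gene content.

    Returns genome-size Mann-Whitney (two-sided), the mean size reduction
    percent ``100 * (1 - mean(FSF)/mean(SF))``, and per-group Spearman rho of
    genome size vs gene count.
    """
    df = metadata.merge(calls[["genome_id", "sporulation_class"]], on="genome_id")
    sf = df[df["sporulation_class"] == "SF"]
    fsf = df[df["sporulation_class"] == "FSF"]
    if len(sf) < 2 or len(fsf) < 2:
        raise ValueError("need >= 2 genomes per group")
    size_test = ranksum(
        sf["genome_length_bp"], fsf["genome_length_bp"], sided="two-sided"
    )
    reduction = 100.0 * (
        1.0 - fsf["genome_length_bp"].mean() / sf["genome_length_bp"].mean()
    )
    return {
        "size_test": size_test,
        "size_reduction_percent": float(reduction),
        "spearman_sf": spearman(sf["genome_length_bp"], sf["gene_count"]),
        "spearman_fsf": spearman(fsf["genome_length_bp"], fsf["gene_count"]),
        "mean_size_sf": float(sf["genome_length_bp"].mean()),
        "mean_size_fsf": float(fsf["genome_length_bp"].mean()),
    }
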