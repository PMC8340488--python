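"""Stage-wise sporulation-gene retention profiles and group tests.

For each sporulation stage (0, I-V, germination; "unknown" genes are profiled
but not tested) the retention of that stage's signature genes is summarized as
pooled gene x genome presence events per group (SF or FSF), and SF vs FSF
retention is compared per stage with a two-sided Fisher's exact test, adjusted
across the seven tested stages by Benjamini-Hochberg. The pooled-event table
construction treats gene x genome cells as exchangeable (a pseudo-replication
caveat, documented in the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .stats import benjamini_hochberg, fisher_exact
from .types import ContingencyTable, PresenceMatrix, SignatureCatalog, TESTED_STAGES

__all__ = ["StageProfile", "stage_presence", "stage_group_test"]


@dataclass(frozen=True)
class StageProfile:
    stage: str
    n_genes: int
    group: str  # "SF" | "FSF"
    n_genomes: int
    n_presences: int
    mean_presence_percent: float


def stage_presence(
    matrix: PresenceMatrix,
    catalog: SignatureCatalog,
    calls: pd.DataFrame,
    group: str,
) -> list[StageProfile]:
    """Per-stage pooled presence profile for one group.

    ``n_presences`` counts True cells over the stage's genes and the group's
    genomes; ``mean_presence_percent`` = 100 * n_presences / (n_genes * n_genomes).
    """
    if group not in ("SF", "FSF"):
        raise ValueError(f"group must be 'SF' or 'FSF', got {group!r}")
    genomes = calls.loc[calls["sporulation_class"] == group, "genome_id"]
    missing = set(matrix.genome_ids) - set(calls["genome_id"])
    if missing:
        raise ValueError(f"calls do not cover genomes: {sorted(missing)}")
    genomes = [g for g in genomes if g in set(matrix.genome_ids)]
    if not genomes:
        raise ValueError(f"no {group} genomes in presence matrix")
    sub = matrix.df.loc[genomes]
    profiles = []
    for stage in catalog.stage_sizes():
        genes = catalog.genes_in_stage(stage)
        if not genes:
            raise ValueError(f"stage {stage!r} has zero signature genes")
        n_presences = int(sub[genes].to_numpy().sum())
        denom = len(genes) * len(genomes)
        profiles.append(
            StageProfile(
                stage=stage,
                n_genes=len(genes),
                group=group,
                n_genomes=len(genomes),
                n_presences=n_presences,
                mean_presence_percent=100.0 * n_presences / denom,
            )
        )
    return profiles


def stage_group_test(
    profiles_sf: list[StageProfile], profiles_fsf: list[StageProfile]
) -> pd.DataFrame:
    """Per-stage SF vs FSF Fisher tests on pooled presence events.

    Tests the stages in :data:`~sporesig.types.TESTED_STAGES` (the "unknown"
    bin is excluded); q-values are Benjamini-Hochberg over the tested stages.
    Returns a DataFrame with stage, the 2x2 counts, odds ratio, p and q.
    """
    sf = {p.stage: p for p in profiles_sf}
    fsf = {p.stage: p for p in profiles_fsf}
    rows = []
    for stage in TESTED_STAGES:
        if stage not in sf or stage not in fsf:
            raise ValueError(f"stage {stage!r} missing from a group's profiles")
        ps, pf = sf[stage], fsf[stage]
        table = ContingencyTable(
            a=ps.n_presences,
            b=pf.n_presences,
            c=ps.n_genes * ps.n_genomes - ps.n_presences,
            d=pf.n_genes * pf.n_genomes - pf.n_presences,
        )
        res = fisher_exact(table, sided="two-sided")
        rows.append(
            {
                "stage": stage,
                "sf_presences": table.a,
                "fsf_presences": table.b,
                "sf_absences": table.c,
                "fsf_absences": table.d,
                "odds_ratio": res.statistic,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out
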