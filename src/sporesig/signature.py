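"""Signature-gene presence calling and per-genome sporulation scores.

A genome's sporulation signature score is the percentage of the 66
sporulation-predictive genes detected in it. Detection is binary: a gene is
present in a genome iff at least one homology hit passes both thresholds
(e-value <= 1e-5 and percent identity >= 30 by default).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import HomologyHit, PresenceMatrix, SignatureCatalog

__all__ = ["call_presence", "signature_score"]


def call_presence(
    hits: Iterable[HomologyHit],
    catalog: SignatureCatalog,
    genome_ids: Sequence[str],
    e_max: float = 1e-5,
    id_min: float = 30.0,
) -> PresenceMatrix:
    """Convert homology hits into a genomes x genes boolean presence matrix.

    A cell is True iff >= 1 hit for that (gene, genome) has
    ``e_value <= e_max`` and ``percent_identity >= id_min``. Multiple
    qualifying hits (and duplicated rows from concatenated search outputs)
    collapse to a single presence. Hits naming a gene or genome outside the
    catalog / ``genome_ids`` raise a ``ValueError`` listing the offenders.
    """
    gene_index = {g: j for j, g in enumerate(catalog.gene_ids)}
    genome_index = {g: i for i, g in enumerate(genome_ids)}
    if len(genome_index) != len(genome_ids):
        raise ValueError("genome_ids contain duplicates")

    unknown_genes: set[str] = set()
    unknown_genomes: set[str] = set()
    present = np.zeros((len(genome_ids), len(gene_index)), dtype=bool)
    for hit in hits:
        if hit.query_id not in gene_index:
            unknown_genes.add(hit.query_id)
            continue
        if hit.subject_id not in genome_index:
            unknown_genomes.add(hit.subject_id)
            continue
        if hit.e_value <= e_max and hit.percent_identity >= id_min:
            present[genome_index[hit.subject_id], gene_index[hit.query_id]] = True
    if unknown_genes or unknown_genomes:
        raise ValueError(
            "hits reference unknown ids — "
            f"genes: {sorted(unknown_genes)}, genomes: {sorted(unknown_genomes)}"
        )
    return PresenceMatrix.from_arrays(list(genome_ids), catalog.gene_ids, present)


def signature_score(
    matrix: PresenceMatrix, catalog: SignatureCatalog
) -> pd.DataFrame:
    """Per-genome sporulation signature scores.

    Returns a DataFrame with columns ``genome_id``, ``n_present``,
    ``score_percent`` (= 100 * n_present / 66) and ``spo0A_present``.
    """
    missing = set(catalog.gene_ids) - set(matrix.gene_ids)
    if missing:
        raise ValueError(f"presence matrix lacks catalog genes: {sorted(missing)}")
    sub = matrix.df[catalog.gene_ids]
    n_present = sub.sum(axis=1).astype(int)
    n_genes = len(catalog.gene_ids)
    return pd.DataFrame(
        {
            "genome_id": list(matrix.genome_ids),
            "n_present": n_present.to_numpy(),
            "score_percent": 100.0 * n_present.to_numpy() / n_genes,
            "spo0A_present": sub[catalog.spo0A_id].to_numpy(),
        }
    )
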