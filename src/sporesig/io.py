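"""Readers and writers for the plain-text dialects the pipeline consumes.

Supported dialects:

* BLAST tabular (``-outfmt 6``, 12 columns) for signature-gene hits;
* hmmscan tabular (target HMM, query ``genome|protein``, e-value, alignment
  coordinates, HMM coordinates, HMM length) for CAZyme hits;
* samtools-depth style 3-column depth TSV (genome_id, 1-based position, depth);
* generic TSV results tables written with a deterministic column order.

Depth files use 1-based positions on disk; everything in memory is a dense
0-based vector of length ``genome_length_bp``.
"""

from __future__ import annotations

import decimal
import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import GenomeRecord, HomologyHit, SignatureCatalog, SignatureGene

logger = logging.getLogger("sporesig")

BLAST_TAB_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

HMM_TAB_COLUMNS = (
    "target_hmm query e_value ali_from ali_to hmm_from hmm_to hmm_length"
).split()


class ParseError(ValueError):
    """Malformed input file; the message names the file, line and column."""


def _parse_blast_row(fields: list[str], path, lineno: int) -> HomologyHit:
    if len(fields) != 12:
        raise ParseError(
            f"{path}:{lineno}: expected 12 BLAST tabular columns "
            f"({', '.join(BLAST_TAB_COLUMNS)}), got {len(fields)}"
        )
    try:
        return HomologyHit(
            query_id=fields[0],
            subject_id=fields[1],
            percent_identity=float(fields[2]),
            alignment_length_aa=int(fields[3]),
            e_value=float(fields[10]),
        )
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def _parse_hmm_row(fields: list[str], path, lineno: int) -> HomologyHit:
    if len(fields) != len(HMM_TAB_COLUMNS):
        raise ParseError(
            f"{path}:{lineno}: expected {len(HMM_TAB_COLUMNS)} hmm_tab columns "
            f"({', '.join(HMM_TAB_COLUMNS)}), got {len(fields)}"
        )
    try:
        query = fields[1]
        if "|" not in query:
            raise ValueError(
                f"query field {query!r} must be formatted 'genome_id|protein_id'"
            )
        genome_id = query.split("|", 1)[0]
        ali_from, ali_to = int(fields[3]), int(fields[4])
        hmm_from, hmm_to, hmm_len = int(fields[5]), int(fields[6]), int(fields[7])
        if hmm_len <= 0:
            raise ValueError("hmm_length must be positive")
        return HomologyHit(
            query_id=fields[0],
            subject_id=genome_id,
            percent_identity=0.0,  # hmmscan reports no identity
            alignment_length_aa=ali_to - ali_from + 1,
            e_value=float(fields[2]),
            hmm_coverage=(hmm_to - hmm_from + 1) / hmm_len,
        )
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_hit_table(path, dialect: str = "blast_tab") -> list[HomologyHit]:
    """Parse a homology hit table into :class:`HomologyHit` records.

    ``dialect`` is ``"blast_tab"`` (12-column outfmt 6) or ``"hmm_tab"``.
    Lines starting with ``#`` are skipped. Malformed rows raise
    :class:`ParseError` naming the line.
    """
    if dialect not in ("blast_tab", "hmm_tab"):
        raise ValueError(f"unknown hit-table dialect {dialect!r}")
    parse = _parse_blast_row if dialect == "blast_tab" else _parse_hmm_row
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            hits.append(parse(line.split("\t"), path, lineno))
    if not hits:
        warnings.warn(f"hit table {path} is empty", stacklevel=2)
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path, dialect: str = "blast_tab") -> None:
    """Write hits in the requested dialect (inverse of :func:`read_hit_table`)."""
    with open(path, "w") as fh:
        if dialect == "blast_tab":
            for h in hits:
                fh.write(
                    "\t".join(
                        [
                            h.query_id,
                            h.subject_id,
                            f"{h.percent_identity:.2f}",
                            str(h.alignment_length_aa),
                            "0",
                            "0",
                            "1",
                            str(h.alignment_length_aa),
                            "1",
                            str(h.alignment_length_aa),
                            f"{h.e_value:.3g}",
                            "0.0",
                        ]
                    )
                    + "\n"
                )
        elif dialect == "hmm_tab":
            for h in hits:
                cov = h.hmm_coverage if h.hmm_coverage is not None else 0.0
                hmm_len = 100
                hmm_to = max(1, round(cov * hmm_len))
                fh.write(
                    "\t".join(
                        [
                            h.query_id,
                            f"{h.subject_id}|p1",
                            f"{h.e_value:.3g}",
                            "1",
                            str(h.alignment_length_aa),
                            "1",
                            str(hmm_to),
                            str(hmm_len),
                        ]
                    )
                    + "\n"
                )
        else:
            raise ValueError(f"unknown hit-table dialect {dialect!r}")


def read_depth_profile(
    path, genome_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Read a 3-column depth file into dense per-genome depth vectors.

    Rows are ``genome_id <TAB> position (1-based) <TAB> depth``; positions
    absent from the file get depth 0. Every genome in ``genome_lengths``
    receives a vector (all zeros if unmentioned). A position outside
    ``[1, genome_length]`` is an error naming the genome and position.
    """
    vectors = {
        g: np.zeros(int(length), dtype=np.int64)
        for g, length in genome_lengths.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 columns (genome_id, pos, depth), "
                    f"got {len(fields)}"
                )
            genome, pos_s, depth_s = fields
            if genome not in vectors:
                raise ParseError(f"{path}:{lineno}: unknown genome {genome!r}")
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            length = len(vectors[genome])
            if not 1 <= pos <= length:
                raise ParseError(
                    f"{path}:{lineno}: position {pos} outside genome {genome!r} "
                    f"of length {length}"
                )
            vectors[genome][pos - 1] = depth
    return vectors


def write_depth_profile(vectors: Mapping[str, np.ndarray], path) -> None:
    """Write dense depth vectors as the sparse 3-column dialect (zeros omitted)."""
    with open(path, "w") as fh:
        for genome in vectors:
            vec = np.asarray(vectors[genome])
            for idx in np.nonzero(vec)[0]:
                fh.write(f"{genome}\t{idx + 1}\t{int(vec[idx])}\n")


def write_results_table(df: pd.DataFrame, path, float_decimals: int | None = None) -> None:
    """Write a results DataFrame as TSV with a deterministic column order."""
    fmt = f"%.{float_decimals}f" if float_decimals is not None else None
    df.to_csv(path, sep="\t", index=False, float_format=fmt)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def format_percent(numerator: int, denominator: int, decimals: int = 1) -> str:
    """``100 * numerator / denominator`` rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding matches conventional reporting:
    ``format_percent(1343, 1358)`` -> ``"98.9"``.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = decimal.Decimal(100 * numerator) / decimal.Decimal(denominator)
    q = decimal.Decimal(1).scaleb(-decimals)
    return str(pct.quantize(q, rounding=decimal.ROUND_HALF_UP))


def percent_value(numerator: int, denominator: int, decimals: int = 1) -> float:
    return float(format_percent(numerator, denominator, decimals))


# ---------------------------------------------------------------------------
# signature catalog and genome metadata


def write_catalog(catalog: SignatureCatalog, fasta_path, stages_path) -> None:
    records = [
        SeqRecord(Seq(g.protein_sequence), id=g.gene_id, description="")
        for g in catalog.genes
    ]
    SeqIO.write(records, fasta_path, "fasta")
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in catalog.genes],
            "stage": [g.stage for g in catalog.genes],
            "is_spo0A": [g.gene_id == catalog.spo0A_id for g in catalog.genes],
        }
    ).to_csv(stages_path, sep="\t", index=False)


def read_catalog(fasta_path, stages_path) -> SignatureCatalog:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    stages = pd.read_csv(stages_path, sep="\t")
    missing = set(stages["gene_id"]) - set(seqs)
    if missing:
        raise ParseError(
            f"{fasta_path}: missing protein sequences for genes {sorted(missing)}"
        )
    genes = tuple(
        SignatureGene(row.gene_id, str(row.stage), seqs[row.gene_id])
        for row in stages.itertuples()
    )
    spo0A = stages.loc[stages["is_spo0A"], "gene_id"]
    if len(spo0A) != 1:
        raise ParseError(f"{stages_path}: exactly one gene must be flagged is_spo0A")
    return SignatureCatalog(genes=genes, spo0A_id=spo0A.iloc[0])


def write_genome_metadata(records: Sequence[GenomeRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "family": r.family,
                "habitat": r.habitat,
                "genome_length_bp": r.genome_length_bp,
                "gene_count": r.gene_count,
                "phylum": r.phylum,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_genome_metadata(path) -> list[GenomeRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "family", "habitat", "genome_length_bp", "gene_count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    return [
        GenomeRecord(
            genome_id=str(row.genome_id),
            family=str(row.family),
            habitat=str(row.habitat),
            genome_length_bp=int(row.genome_length_bp),
            gene_count=int(row.gene_count),
            phylum=str(getattr(row, "phylum", "Firmicutes")),
        )
        for row in df.itertuples()
    ]
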