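"""Domain types shared by every pipeline stage.

The central objects are :class:`SignatureCatalog` (the 66 sporulation-predictive
genes with their developmental-stage assignments), :class:`PresenceMatrix`
(genomes x genes boolean detection), and :class:`ContingencyTable` (the 2x2
counts behind every Fisher test in the pipeline).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

#: Developmental stages of endospore formation. Each signature gene maps to a
#: single stage (or "unknown" when the stage assignment is unresolved).
STAGES = ("0", "I", "II", "III", "IV", "V", "germination", "unknown")

#: Number of signature genes per stage when emulating the reference catalog.
STAGE_BIN_SIZES = {
    "0": 3,
    "I": 2,
    "II": 7,
    "III": 12,
    "IV": 12,
    "V": 9,
    "germination": 2,
    "unknown": 19,
}

#: Stages that enter the stage-wise retention tests ("unknown" is excluded).
TESTED_STAGES = ("0", "I", "II", "III", "IV", "V", "germination")

HABITATS = ("gut", "oral", "rumen", "environmental", "other")

N_SIGNATURE_GENES = 66


@dataclass(frozen=True)
class SignatureGene:
    gene_id: str
    stage: str
    protein_sequence: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(
                f"unknown sporulation stage {self.stage!r} for gene {self.gene_id!r}; "
                f"expected one of {STAGES}"
            )


@dataclass(frozen=True)
class SignatureCatalog:
    """The sporulation signature: 66 predictive genes, one of which is spo0A,
    the DNA-binding master regulator initiating the sporulation cascade."""

    genes: tuple[SignatureGene, ...]
    spo0A_id: str

    def __post_init__(self) -> None:
        if len(self.genes) != N_SIGNATURE_GENES:
            raise ValueError(
                f"signature catalog must contain exactly {N_SIGNATURE_GENES} genes, "
                f"got {len(self.genes)}"
            )
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids in catalog: {dupes}")
        if self.spo0A_id not in ids:
            raise ValueError(f"spo0A id {self.spo0A_id!r} is not one of the 66 genes")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def stage_of(self) -> dict[str, str]:
        return {g.gene_id: g.stage for g in self.genes}

    def genes_in_stage(self, stage: str) -> list[str]:
        return [g.gene_id for g in self.genes if g.stage == stage]

    def stage_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {s: 0 for s in STAGES}
        for g in self.genes:
            sizes[g.stage] += 1
        return sizes


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    family: str
    habitat: str
    genome_length_bp: int
    gene_count: int
    phylum: str = "Firmicutes"

    def __post_init__(self) -> None:
        if self.genome_length_bp <= 0:
            raise ValueError(f"{self.genome_id}: genome_length_bp must be positive")
        if self.gene_count <= 0:
            raise ValueError(f"{self.genome_id}: gene_count must be positive")
        if self.habitat not in HABITATS:
            raise ValueError(
                f"{self.genome_id}: habitat {self.habitat!r} not in {HABITATS}"
            )


@dataclass(frozen=True)
class HomologyHit:
    """One row of a homology search (BLAST tabular or hmmscan tabular).

    ``query_id`` is the signature protein or HMM; ``subject_id`` is the genome.
    ``hmm_coverage`` is the fraction of the HMM covered by the alignment and is
    only populated for HMM-based hits.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length_aa: int
    e_value: float
    hmm_coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(
                f"percent_identity must be in [0, 100], got {self.percent_identity}"
            )


class PresenceMatrix:
    """Boolean genomes x genes detection matrix backed by a pandas DataFrame."""

    def __init__(self, df: pd.DataFrame):
        if not df.dtypes.map(lambda d: d == bool).all():
            raise ValueError("presence matrix must be boolean-valued")
        self._df = df

    @classmethod
    def from_arrays(
        cls,
        genome_ids: Sequence[str],
        gene_ids: Sequence[str],
        present: np.ndarray,
    ) -> "PresenceMatrix":
        present = np.asarray(present)
        if present.shape != (len(genome_ids), len(gene_ids)):
            raise ValueError(
                f"presence matrix shape {present.shape} does not match "
                f"{len(genome_ids)} genomes x {len(gene_ids)} genes"
            )
        return cls(
            pd.DataFrame(
                present.astype(bool), index=list(genome_ids), columns=list(gene_ids)
            )
        )

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def genome_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PresenceMatrix) and self._df.equals(other._df)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table; rows = outcome present/absent, columns = group 1/group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")
        if self.total == 0:
            raise ValueError("contingency table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sidedness: str
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1 + 1e-12:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass
class PipelineConfig:
    """All tunable thresholds plus the single seed every random draw flows from.

    Defaults reproduce the published analysis settings: signature detection at
    e-value <= 1e-5 and identity >= 30%; CAZyme hit filtering at alignment
    > 80 aa with E < 1e-5, or E < 1e-3 covering > 30% of the HMM; species
    presence at breadth >= 60% with a depth-variation cap at the empirical
    99th percentile per breadth bin.
    """

    signature_e_max: float = 1e-5
    signature_id_min: float = 30.0
    cazyme_min_alignment_aa: int = 80
    cazyme_e_strict: float = 1e-5
    cazyme_e_relaxed: float = 1e-3
    cazyme_min_hmm_coverage: float = 0.30
    cazyme_excluded_families: tuple[str, ...] = ("AA*", "GT*", "CE10")
    enrichment_alpha: float = 0.05
    breadth_min: float = 0.60
    cv_percentile: float = 99.0
    breadth_bin_width: float = 0.01
    min_family_n: int = 5
    min_bimodal_gap: float = 20.0
    abundance_min_samples: int = 10
    paralog_mode: str = "excess"  # or "multicopy_domains"
    rng_seed: int = 0
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.enrichment_alpha < 1:
            raise ValueError("enrichment_alpha must be in (0, 1)")
        if not 0 <= self.breadth_min <= 1:
            raise ValueError("breadth_min must be in [0, 1]")
        if not 0 < self.cv_percentile <= 100:
            raise ValueError("cv_percentile must be in (0, 100]")
        if self.signature_id_min < 0 or self.signature_id_min > 100:
            raise ValueError("signature_id_min must be in [0, 100]")
        if self.paralog_mode not in ("excess", "multicopy_domains"):
            raise ValueError("paralog_mode must be 'excess' or 'multicopy_domains'")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(self).items()
                },
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cazyme_excluded_families" in raw:
            raw["cazyme_excluded_families"] = tuple(raw["cazyme_excluded_families"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
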