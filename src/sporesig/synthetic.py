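"""Seeded generators for every input the pipeline consumes.

The generators emulate the structure of a real Firmicutes genome collection
and fecal metagenome panel: per-family signature-score distributions
(unimodal high, unimodal low, bimodal), spo0A presence concordant with score
class at a configurable rate, stage-wise gene retention (germination genes
are fully lost in Former-Spore-Formers), genome-size and CAZyme-count group
differences, domain tables with planted enriched domains, and per-sample
genome coverage with class-specific prevalence and abundance. Every
generator is bit-reproducible under a fixed seed and ships its ground truth
alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import write_depth_profile
from .metagenome import CoverageSummary, summarize_coverage
from .types import (
    GenomeRecord,
    HomologyHit,
    N_SIGNATURE_GENES,
    STAGE_BIN_SIZES,
    SignatureCatalog,
    SignatureGene,
)

__all__ = [
    "DEFAULT_FAMILY_PATTERNS",
    "make_catalog",
    "make_genomes",
    "make_domain_tables",
    "make_cazyme_hits",
    "make_growth_calls",
    "make_metagenomes",
    "GenomeSet",
    "MetagenomeSet",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Family score patterns used by default: five bimodal families plus one
#: uniformly high and one uniformly low, echoing the mix seen in real
#: gut Firmicutes collections.
DEFAULT_FAMILY_PATTERNS: dict[str, str] = {
    "Clostridiaceae": "bimodal",
    "Erysipelotrichaceae": "bimodal",
    "Lachnospiraceae": "bimodal",
    "Peptostreptococcaceae": "bimodal",
    "Ruminococcaceae": "bimodal",
    "Bacillaceae": "high",
    "Streptococcaceae": "low",
}


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    for i in range(size):
        x = rng.normal(mean, sd)
        while not lo <= x <= hi:
            x = rng.normal(mean, sd)
        out[i] = x
    return out


def make_catalog(seed: int = 0) -> SignatureCatalog:
    """Synthetic 66-gene sporulation signature with the canonical stage bins
    (3, 2, 7, 12, 12, 9, 2, 19 genes for stages 0, I-V, germination, unknown);
    the spo0A master regulator is the first stage-0 gene."""
    rng = np.random.default_rng(seed)
    genes: list[SignatureGene] = []
    for stage, n in STAGE_BIN_SIZES.items():
        for k in range(n):
            if stage == "0" and k == 0:
                gene_id = "spo0A"
            else:
                tag = stage.replace("germination", "ger").replace("unknown", "unk")
                gene_id = f"sig_s{tag}_{k + 1:02d}"
            length = int(rng.integers(120, 400))
            seq = "M" + "".join(rng.choice(AMINO_ACIDS, size=length - 1))
            genes.append(SignatureGene(gene_id, stage, seq))
    assert len(genes) == N_SIGNATURE_GENES
    return SignatureCatalog(genes=tuple(genes), spo0A_id="spo0A")


@dataclass
class GenomeSet:
    metadata: list[GenomeRecord]
    hits: list[HomologyHit]
    truth: dict

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genome_id": r.genome_id,
                    "family": r.family,
                    "habitat": r.habitat,
                    "genome_length_bp": r.genome_length_bp,
                    "gene_count": r.gene_count,
                    "phylum": r.phylum,
                }
                for r in self.metadata
            ]
        )


def make_genomes(
    catalog: SignatureCatalog,
    n_per_family: int = 40,
    family_patterns: Mapping[str, str] = DEFAULT_FAMILY_PATTERNS,
    concordance_rate: float = 0.989,
    seed: int = 0,
) -> GenomeSet:
    """Genome collection with planted SF/FSF structure.

    Spore-Formers draw signature scores ~ N(80, 8^2) truncated to [50, 100]
    and Former-Spore-Formers ~ N(20, 6^2) truncated to [0, 35] (as presence
    counts out of 66). spo0A presence agrees with the true class with
    probability ``concordance_rate`` (discordant genomes get the flag
    flipped). Germination-stage genes are never retained in FSF. Genome
    sizes: SF ~ N(3.5, 0.5^2) Mbp; FSF means are 36% smaller (N(2.24,
    0.32^2) Mbp); gene counts track size tightly. Qualifying homology hits
    are emitted exactly for present genes, plus sub-threshold decoy hits.
    """
    if not 0 <= concordance_rate <= 1:
        raise ValueError("concordance_rate must be in [0, 1]")
    for fam, pat in family_patterns.items():
        if pat not in ("high", "low", "bimodal"):
            raise ValueError(f"family {fam!r} has invalid pattern {pat!r}")
    rng = np.random.default_rng(seed)
    germination_genes = set(catalog.genes_in_stage("germination"))
    other_genes = [
        g for g in catalog.gene_ids if g != catalog.spo0A_id
    ]
    fsf_pool = [g for g in other_genes if g not in germination_genes]

    metadata: list[GenomeRecord] = []
    hits: list[HomologyHit] = []
    truth_rows: dict[str, dict] = {}

    for family in sorted(family_patterns):
        pattern = family_patterns[family]
        if pattern == "bimodal":
            n_sf = n_per_family // 2
            classes = ["SF"] * n_sf + ["FSF"] * (n_per_family - n_sf)
        elif pattern == "high":
            classes = ["SF"] * n_per_family
        else:
            classes = ["FSF"] * n_per_family
        for k, true_class in enumerate(classes):
            gid = f"{family[:4].lower()}_{k + 1:03d}"
            is_sf = true_class == "SF"
            if is_sf:
                score = _truncated_normal(rng, 80, 8, 50, 100, 1)[0]
            else:
                score = _truncated_normal(rng, 20, 6, 0, 35, 1)[0]
            n_present = int(round(score * N_SIGNATURE_GENES / 100))
            concordant = rng.random() < concordance_rate
            spo0A_present = is_sf if concordant else not is_sf

            pool = other_genes if is_sf else fsf_pool
            n_others = n_present - (1 if spo0A_present else 0)
            n_others = int(np.clip(n_others, 0, len(pool)))
            chosen = list(rng.choice(pool, size=n_others, replace=False))
            if spo0A_present:
                chosen.append(catalog.spo0A_id)

            for gene in chosen:
                hits.append(
                    HomologyHit(
                        query_id=gene,
                        subject_id=gid,
                        percent_identity=float(rng.uniform(35, 95)),
                        alignment_length_aa=int(rng.integers(80, 300)),
                        e_value=float(10.0 ** -rng.uniform(6.1, 30)),
                    )
                )
            # decoy hits that must fail the thresholds
            for gene in rng.choice(
                [g for g in catalog.gene_ids if g not in chosen],
                size=min(3, N_SIGNATURE_GENES - len(chosen)),
                replace=False,
            ):
                if rng.random() < 0.5:
                    e, ident = float(10.0 ** -rng.uniform(1, 4.9)), 50.0
                else:
                    e, ident = 1e-10, float(rng.uniform(5, 29))
                hits.append(
                    HomologyHit(
                        query_id=str(gene),
                        subject_id=gid,
                        percent_identity=ident,
                        alignment_length_aa=100,
                        e_value=e,
                    )
                )

            if is_sf:
                size = max(1.0e6, rng.normal(3.5e6, 0.5e6))
            else:
                size = max(0.5e6, rng.normal(0.64 * 3.5e6, 0.32e6))
            gene_count = max(500, int(round(size / 1080 * rng.lognormal(0, 0.02))))
            metadata.append(
                GenomeRecord(
                    genome_id=gid,
                    family=family,
                    habitat="gut",
                    genome_length_bp=int(round(size)),
                    gene_count=gene_count,
                )
            )
            truth_rows[gid] = {
                "true_class": true_class,
                "spo0A_present": bool(spo0A_present),
                "concordant": bool(concordant),
                "n_present": len(chosen),
                "family": family,
            }

    truth = {
        "seed": int(seed),
        "concordance_rate": concordance_rate,
        "family_patterns": dict(family_patterns),
        "genomes": truth_rows,
    }
    return GenomeSet(metadata=metadata, hits=hits, truth=truth)


FUNCTIONAL_CLASSES = (
    "amino acid metabolism",
    "carbohydrate metabolism",
    "cell motility",
    "cofactor metabolism",
    "energy production",
    "membrane transport",
    "replication and repair",
    "signal transduction",
    "sporulation",
    "translation",
)


def make_domain_tables(
    sf_ids: Sequence[str],
    fsf_ids: Sequence[str],
    n_domains: int = 200,
    n_enriched_per_group: int = 30,
    p_high: float = 0.9,
    p_low: float = 0.1,
    p_background: float = 0.5,
    known_class_fraction: float = 0.85,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Optional[str]], dict]:
    """Domain annotation table with planted SF- and FSF-enriched domains.

    Enriched domains are present with probability ``p_high`` in their group
    and ``p_low`` in the other; background domains sit at ``p_background`` in
    both. Copy counts are 1 + Poisson(0.3), so the table doubles as paralog
    input. Returns (annotations, functional class map, ground truth).
    """
    rng = np.random.default_rng(seed)
    if 2 * n_enriched_per_group > n_domains:
        raise ValueError("more enriched domains than domains")
    domains = [f"D{i + 1:04d}" for i in range(n_domains)]
    enriched_sf = domains[:n_enriched_per_group]
    enriched_fsf = domains[n_enriched_per_group : 2 * n_enriched_per_group]

    rows = []
    for dom_idx, dom in enumerate(domains):
        if dom in enriched_sf:
            p_sf, p_fsf = p_high, p_low
        elif dom in enriched_fsf:
            p_sf, p_fsf = p_low, p_high
        else:
            p_sf = p_fsf = p_background
        for gid, p in [(g, p_sf) for g in sf_ids] + [(g, p_fsf) for g in fsf_ids]:
            if rng.random() < p:
                rows.append(
                    {
                        "genome_id": gid,
                        "domain_id": dom,
                        "copy_count": 1 + int(rng.poisson(0.3)),
                    }
                )
    annotations = pd.DataFrame(rows)
    class_map: dict[str, Optional[str]] = {}
    for dom in domains:
        if rng.random() < known_class_fraction:
            class_map[dom] = FUNCTIONAL_CLASSES[
                int(rng.integers(len(FUNCTIONAL_CLASSES)))
            ]
        else:
            class_map[dom] = None
    truth = {
        "seed": int(seed),
        "enriched_sf": enriched_sf,
        "enriched_fsf": enriched_fsf,
        "p_high": p_high,
        "p_low": p_low,
        "p_background": p_background,
    }
    return annotations, class_map, truth


CAZYME_FAMILY_POOL = tuple(
    [f"GH{i}" for i in range(1, 61)]
    + [f"PL{i}" for i in range(1, 21)]
    + [f"CE{i}" for i in range(1, 10)]
    + [f"CBM{i}" for i in range(1, 21)]
)

CAZYME_EXCLUDED_POOL = tuple(
    [f"AA{i}" for i in range(1, 8)] + [f"GT{i}" for i in range(1, 11)] + ["CE10"]
)


def make_cazyme_hits(
    classes: Mapping[str, str],
    mean_total_sf: float = 112.0,
    mean_total_fsf: float = 57.51,
    sd_total: float = 20.0,
    mean_families_sf: float = 37.0,
    mean_families_fsf: float = 24.16,
    sd_families: float = 5.0,
    seed: int = 0,
) -> tuple[list[HomologyHit], dict]:
    """CAZyme HMM hit table with planted group differences.

    Per-genome totals and distinct-family counts are drawn around
    class-specific means (defaults follow the contrast between spore-formers
    and former-spore-formers: ~112 vs ~57.5 total CAZymes, ~37 vs ~24
    families). All planted hits pass the filter; per genome a handful of
    sub-threshold and excluded-family (AA*/GT*/CE10) decoys are added.
    """
    rng = np.random.default_rng(seed)
    hits: list[HomologyHit] = []
    truth_totals: dict[str, int] = {}
    for gid in classes:
        is_sf = classes[gid] == "SF"
        total = max(1, int(round(rng.normal(
            mean_total_sf if is_sf else mean_total_fsf, sd_total
        ))))
        n_fam = int(round(rng.normal(
            mean_families_sf if is_sf else mean_families_fsf, sd_families
        )))
        n_fam = int(np.clip(n_fam, 1, min(total, len(CAZYME_FAMILY_POOL))))
        families = rng.choice(CAZYME_FAMILY_POOL, size=n_fam, replace=False)
        # each chosen family contributes >= 1 hit
        assignment = np.concatenate(
            [np.arange(n_fam), rng.integers(0, n_fam, size=total - n_fam)]
        )
        for fam_idx in assignment:
            fam = families[fam_idx]
            if rng.random() < 0.7:
                e, cov = float(10.0 ** -rng.uniform(5.1, 20)), float(rng.uniform(0.1, 1.0))
            else:
                e, cov = float(10.0 ** -rng.uniform(3.1, 5.0)), float(rng.uniform(0.31, 1.0))
            hits.append(
                HomologyHit(
                    query_id=f"{fam}.hmm",
                    subject_id=gid,
                    percent_identity=0.0,
                    alignment_length_aa=int(rng.integers(81, 400)),
                    e_value=e,
                    hmm_coverage=cov,
                )
            )
        # decoys: excluded families and sub-threshold hits
        for fam in rng.choice(CAZYME_EXCLUDED_POOL, size=3, replace=False):
            hits.append(
                HomologyHit(
                    query_id=f"{fam}.hmm",
                    subject_id=gid,
                    percent_identity=0.0,
                    alignment_length_aa=200,
                    e_value=1e-20,
                    hmm_coverage=0.9,
                )
            )
        hits.append(
            HomologyHit(
                query_id="GH1.hmm",
                subject_id=gid,
                percent_identity=0.0,
                alignment_length_aa=60,  # fails the > 80 aa rule
                e_value=1e-20,
                hmm_coverage=0.9,
            )
        )
        truth_totals[gid] = total
    truth = {"seed": int(seed), "totals": truth_totals}
    return hits, truth


def make_growth_calls(
    sf_isolates: Sequence[str] = ("sf_iso1", "sf_iso2", "sf_iso3", "sf_iso4"),
    fsf_isolates: Sequence[str] = ("fsf_iso1", "fsf_iso2", "fsf_iso3", "fsf_iso4"),
    n_substrates: int = 95,
    n_sf_only: int = 5,
    n_fsf_only: int = 1,
    p_shared: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Binary growth-call matrix over a 95-carbon-source panel.

    A few substrates are metabolized exclusively by spore-formers (and one by
    former-spore-formers, mirroring the niche-specialist signal); the rest
    are shared at probability ``p_shared`` per isolate.
    """
    rng = np.random.default_rng(seed)
    substrates = [f"substrate_{i + 1:02d}" for i in range(n_substrates)]
    isolates = list(sf_isolates) + list(fsf_isolates)
    is_sf = np.array([True] * len(sf_isolates) + [False] * len(fsf_isolates))
    mat = np.zeros((n_substrates, len(isolates)), dtype=bool)
    for i in range(n_substrates):
        if i < n_sf_only:
            mat[i] = is_sf
        elif i < n_sf_only + n_fsf_only:
            mat[i] = ~is_sf
        else:
            mat[i] = rng.random(len(isolates)) < p_shared
    growth = pd.DataFrame(mat, index=substrates, columns=isolates)
    isolate_class = {i: ("SF" if s else "FSF") for i, s in zip(isolates, is_sf)}
    truth = {
        "seed": int(seed),
        "sf_only": substrates[:n_sf_only],
        "fsf_only": substrates[n_sf_only : n_sf_only + n_fsf_only],
    }
    return growth, isolate_class, truth


@dataclass
class MetagenomeSet:
    summaries: list[CoverageSummary]
    mapping: pd.DataFrame  # genome_id, sample_id, rs, gl_kb, trc
    true_presence: pd.DataFrame  # species x samples boolean
    species: pd.DataFrame  # genome_id, sporulation_class, genome_length_bp
    truth: dict


def make_metagenomes(
    species_classes: Mapping[str, str],
    n_samples: int = 200,
    genome_length: int = 2000,
    prevalence_beta_sf: tuple[float, float] = (7.0, 3.0),
    prevalence_beta_fsf: tuple[float, float] = (3.0, 7.0),
    depth_mean_sf: float = 4.0,
    depth_mean_fsf: float = 8.0,
    depth_sigma: float = 0.3,
    read_length: int = 100,
    off_target_factor: float = 20.0,
    seed: int = 0,
    depth_dir: Optional[Path] = None,
) -> MetagenomeSet:
    """Per-sample coverage profiles and read counts with planted group effects.

    Each species gets a class-specific prevalence drawn from a Beta
    distribution (spore-formers shifted above former-spore-formers by
    default) and a mean per-base depth from a class-specific lognormal
    (former-spore-formers 2x more abundant by default). When a species is
    present in a sample its per-base depth is Poisson with that rate, so the
    expected breadth 1 - exp(-lambda) comfortably exceeds the 60% presence
    cutoff; absent species carry sparse noise with breadth < 0.3. RS is the
    summed depth divided by the read length; TRC multiplies the sample's
    mapped reads by ``off_target_factor``. With ``depth_dir`` set, per-sample
    3-column depth TSVs are written as well.
    """
    rng = np.random.default_rng(seed)
    species_ids = sorted(species_classes)
    samples = [f"sample_{j + 1:03d}" for j in range(n_samples)]

    prev = {}
    lam = {}
    for sp in species_ids:
        if species_classes[sp] == "SF":
            prev[sp] = rng.beta(*prevalence_beta_sf)
            lam[sp] = rng.lognormal(np.log(depth_mean_sf), depth_sigma)
        else:
            prev[sp] = rng.beta(*prevalence_beta_fsf)
            lam[sp] = rng.lognormal(np.log(depth_mean_fsf), depth_sigma)

    summaries: list[CoverageSummary] = []
    mapping_rows = []
    presence = np.zeros((len(species_ids), n_samples), dtype=bool)
    gl_kb = genome_length / 1000.0

    for j, sample in enumerate(samples):
        sample_rs: list[int] = []
        sample_vectors: dict[str, np.ndarray] = {}
        for i, sp in enumerate(species_ids):
            present = rng.random() < prev[sp]
            presence[i, j] = present
            if present:
                rate = lam[sp] * rng.lognormal(0, 0.2)
                vec = rng.poisson(rate, size=genome_length)
            else:
                vec = np.zeros(genome_length, dtype=np.int64)
                frac = rng.uniform(0.02, 0.2)
                n_pos = int(frac * genome_length)
                if n_pos:
                    idx = rng.choice(genome_length, size=n_pos, replace=False)
                    vec[idx] = 1
            rs = int(round(vec.sum() / read_length))
            sample_rs.append(rs)
            if depth_dir is not None:
                sample_vectors[sp] = vec
            summaries.append(summarize_coverage(vec, genome_id=sp, sample_id=sample))
        trc = max(1, int(round(sum(sample_rs) * off_target_factor)))
        for sp, rs in zip(species_ids, sample_rs):
            mapping_rows.append(
                {
                    "genome_id": sp,
                    "sample_id": sample,
                    "rs": rs,
                    "gl_kb": gl_kb,
                    "trc": trc,
                }
            )
        if depth_dir is not None:
            depth_dir = Path(depth_dir)
            depth_dir.mkdir(parents=True, exist_ok=True)
            write_depth_profile(sample_vectors, depth_dir / f"{sample}.depth.tsv")

    species = pd.DataFrame(
        {
            "genome_id": species_ids,
            "sporulation_class": [species_classes[s] for s in species_ids],
            "genome_length_bp": genome_length,
        }
    )
    truth = {
        "seed": int(seed),
        "prevalence": prev,
        "depth_rate": lam,
        "direction": {"prevalence": "SF>FSF", "abundance": "FSF>SF"},
    }
    return MetagenomeSet(
        summaries=summaries,
        mapping=pd.DataFrame(mapping_rows),
        true_presence=pd.DataFrame(presence, index=species_ids, columns=samples),
        species=species,
        truth=truth,
    )
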