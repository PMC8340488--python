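"""End-to-end orchestration: simulate a dataset directory, run every stage,
and write the figure-level result tables plus a JSON run manifest.

Stage order follows the analysis narrative: signature scoring -> SF/FSF
classification -> stage-wise retention -> host-adaptation features ->
metagenomic prevalence/abundance. All result tables are pure functions of
the inputs and the config, so re-running with an identical manifest produces
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import adaptation, io, metagenome, signature, stages, synthetic
from .classify import SporulationModel
from .types import PipelineConfig

logger = logging.getLogger("sporesig")

__all__ = ["simulate_dataset", "run_all"]


def simulate_dataset(
    outdir: Path,
    config: PipelineConfig | None = None,
    n_per_family: int = 40,
    n_samples: int = 30,
    n_species_per_class: int = 20,
    metagenome_genome_length: int = 2000,
) -> Path:
    """Write a complete synthetic dataset directory plus ground-truth JSON."""
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.rng_seed
    rng = np.random.default_rng(seed)

    catalog = synthetic.make_catalog(seed)
    io.write_catalog(catalog, outdir / "catalog.faa", outdir / "catalog_stages.tsv")

    genomes = synthetic.make_genomes(catalog, n_per_family=n_per_family, seed=seed)
    io.write_genome_metadata(genomes.metadata, outdir / "metadata.tsv")
    io.write_hit_table(genomes.hits, outdir / "signature_hits.tsv", dialect="blast_tab")

    sf_ids = [g for g, t in genomes.truth["genomes"].items() if t["true_class"] == "SF"]
    fsf_ids = [g for g, t in genomes.truth["genomes"].items() if t["true_class"] == "FSF"]

    annotations, class_map, domain_truth = synthetic.make_domain_tables(
        sf_ids, fsf_ids, seed=seed
    )
    annotations.to_csv(outdir / "domains.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "domain_id": list(class_map),
            "functional_class": [class_map[d] or "" for d in class_map],
        }
    ).to_csv(outdir / "domain_classes.tsv", sep="\t", index=False)

    classes = {g: t["true_class"] for g, t in genomes.truth["genomes"].items()}
    cazyme_hits, cazyme_truth = synthetic.make_cazyme_hits(classes, seed=seed)
    io.write_hit_table(cazyme_hits, outdir / "cazyme_hits.tsv", dialect="hmm_tab")

    growth, isolate_class, growth_truth = synthetic.make_growth_calls(seed=seed)
    growth.to_csv(outdir / "growth.tsv", sep="\t")
    pd.DataFrame(
        {"isolate": list(isolate_class), "sporulation_class": list(isolate_class.values())}
    ).to_csv(outdir / "isolate_classes.tsv", sep="\t", index=False)

    species_classes = {f"msp_{i + 1:03d}": "SF" for i in range(n_species_per_class)}
    species_classes.update(
        {f"msp_{i + 1 + n_species_per_class:03d}": "FSF" for i in range(n_species_per_class)}
    )
    meta = synthetic.make_metagenomes(
        species_classes,
        n_samples=n_samples,
        genome_length=metagenome_genome_length,
        seed=seed,
        depth_dir=outdir / "depth",
    )
    meta.species.to_csv(outdir / "meta_species.tsv", sep="\t", index=False)
    meta.mapping.to_csv(outdir / "mapping.tsv", sep="\t", index=False)

    truth = {
        "seed": seed,
        "genomes": genomes.truth,
        "domains": domain_truth,
        "cazymes": cazyme_truth,
        "growth": growth_truth,
        "metagenomes": {
            k: v for k, v in meta.truth.items() if k in ("seed", "direction")
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    cfg.to_yaml(outdir / "config.yaml")
    return outdir


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(data_dir: Path, out_dir: Path, config: PipelineConfig | None = None) -> Path:
    """Run every stage on a dataset directory; returns the output directory.

    On a stage failure the completed stage outputs are left in place together
    with a ``FAILED`` marker naming the stage, and the error propagates.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config or (
        PipelineConfig.from_yaml(data_dir / "config.yaml")
        if (data_dir / "config.yaml").exists()
        else PipelineConfig()
    )
    stage_name = "setup"
    try:
        # --- signature stage ---------------------------------------------
        stage_name = "signature"
        logger.info("stage %s", stage_name)
        catalog = io.read_catalog(data_dir / "catalog.faa", data_dir / "catalog_stages.tsv")
        records = io.read_genome_metadata(data_dir / "metadata.tsv")
        metadata = pd.DataFrame(
            [
                {
                    "genome_id": r.genome_id,
                    "family": r.family,
                    "genome_length_bp": r.genome_length_bp,
                    "gene_count": r.gene_count,
                }
                for r in records
            ]
        )
        hits = io.read_hit_table(data_dir / "signature_hits.tsv", dialect="blast_tab")
        matrix = signature.call_presence(
            hits,
            catalog,
            metadata["genome_id"].tolist(),
            e_max=cfg.signature_e_max,
            id_min=cfg.signature_id_min,
        )
        scores = signature.signature_score(matrix, catalog)
        io.write_results_table(scores, out_dir / "scores.tsv")

        # --- classification ----------------------------------------------
        stage_name = "classify"
        logger.info("stage %s", stage_name)
        model = SporulationModel.from_scores(scores, metadata)
        results = model.fit(min_n=cfg.min_family_n, min_gap=cfg.min_bimodal_gap)
        calls = results.calls
        io.write_results_table(calls, out_dir / "calls.tsv")
        io.write_results_table(results.patterns_frame(), out_dir / "family_patterns.tsv")
        (out_dir / "classification_summary.txt").write_text(results.summary() + "\n")

        # --- stage-wise retention ----------------------------------------
        stage_name = "stages"
        logger.info("stage %s", stage_name)
        prof_sf = stages.stage_presence(matrix, catalog, calls, "SF")
        prof_fsf = stages.stage_presence(matrix, catalog, calls, "FSF")
        profile_df = pd.DataFrame(
            [vars(p) for p in prof_sf + prof_fsf]
        )
        io.write_results_table(profile_df, out_dir / "stage_profiles.tsv")
        io.write_results_table(
            stages.stage_group_test(prof_sf, prof_fsf), out_dir / "stage_tests.tsv"
        )

        # --- host adaptation ---------------------------------------------
        stage_name = "adaptation"
        logger.info("stage %s", stage_name)
        annotations = pd.read_csv(data_dir / "domains.tsv", sep="\t")
        enrich = adaptation.domain_enrichment(annotations, calls, alpha=cfg.enrichment_alpha)
        enrich_df = adaptation.enrichment_frame(enrich)
        io.write_results_table(enrich_df, out_dir / "enrichment.tsv")

        classes_df = pd.read_csv(data_dir / "domain_classes.tsv", sep="\t")
        class_map = {
            row.domain_id: (row.functional_class if isinstance(row.functional_class, str) and row.functional_class else None)
            for row in classes_df.itertuples()
        }
        enr_sf = enrich_df.query("group == 'SF' and enriched")["domain_id"].tolist()
        enr_fsf = enrich_df.query("group == 'FSF' and enriched")["domain_id"].tolist()
        if enr_sf and enr_fsf:
            cc = adaptation.class_comparison(enr_sf, enr_fsf, class_map)
            io.write_results_table(cc, out_dir / "class_comparison.tsv")

        paralog = (
            annotations.groupby("genome_id")
            .apply(
                lambda g: adaptation.paralog_percent(
                    dict(zip(g["domain_id"], g["copy_count"])), mode=cfg.paralog_mode
                ),
                include_groups=False,
            )
            .rename("paralog_percent")
            .reset_index()
        )
        io.write_results_table(paralog, out_dir / "paralogs.tsv")

        cazyme_hits = io.read_hit_table(data_dir / "cazyme_hits.tsv", dialect="hmm_tab")
        kept = adaptation.cazyme_filter(
            cazyme_hits,
            exclusions=cfg.cazyme_excluded_families,
            min_alignment_aa=cfg.cazyme_min_alignment_aa,
            e_strict=cfg.cazyme_e_strict,
            e_relaxed=cfg.cazyme_e_relaxed,
            min_hmm_coverage=cfg.cazyme_min_hmm_coverage,
        )
        profiles, caz_tests = adaptation.cazyme_summary(kept, calls)
        io.write_results_table(profiles, out_dir / "cazyme_profiles.tsv")

        growth = pd.read_csv(data_dir / "growth.tsv", sep="\t", index_col=0)
        iso = pd.read_csv(data_dir / "isolate_classes.tsv", sep="\t")
        isolate_class = dict(zip(iso["isolate"], iso["sporulation_class"]))
        io.write_results_table(
            adaptation.substrate_comparison(growth.astype(bool), isolate_class),
            out_dir / "substrate_tests.tsv",
        )

        features = adaptation.genome_feature_compare(metadata, calls)
        feature_report = {
            "genome_size_mannwhitney_p": features["size_test"].p_value,
            "size_reduction_percent": features["size_reduction_percent"],
            "spearman_sf": features["spearman_sf"],
            "spearman_fsf": features["spearman_fsf"],
            "cazyme_total_welch_p": caz_tests["total_cazymes"].p_value
            if "total_cazymes" in caz_tests
            else None,
            "cazyme_families_welch_p": caz_tests["n_families"].p_value
            if "n_families" in caz_tests
            else None,
        }
        (out_dir / "genome_features.json").write_text(
            json.dumps(feature_report, indent=1, sort_keys=True)
        )

        # --- metagenome ----------------------------------------------------
        stage_name = "metagenome"
        logger.info("stage %s", stage_name)
        species = pd.read_csv(data_dir / "meta_species.tsv", sep="\t")
        mapping = pd.read_csv(data_dir / "mapping.tsv", sep="\t")
        lengths = dict(zip(species["genome_id"], species["genome_length_bp"]))
        species_calls = species.rename(columns={})[["genome_id", "sporulation_class"]]

        summaries = []
        depth_files = sorted((data_dir / "depth").glob("*.depth.tsv"))
        for path in depth_files:
            sample = path.name.removesuffix(".depth.tsv")
            vectors = io.read_depth_profile(path, lengths)
            for gid, vec in vectors.items():
                summaries.append(
                    metagenome.summarize_coverage(vec, genome_id=gid, sample_id=sample)
                )
        calib = metagenome.calibrate(
            summaries,
            breadth_min=cfg.breadth_min,
            bin_width=cfg.breadth_bin_width,
            percentile=cfg.cv_percentile,
        )
        io.write_results_table(
            pd.DataFrame(
                {
                    "breadth_bin_low": calib.bin_edges[:-1],
                    "breadth_bin_high": calib.bin_edges[1:],
                    "cv_threshold": calib.cv_thresholds,
                }
            ),
            out_dir / "calibration.tsv",
        )
        sample_ids = sorted({s.sample_id for s in summaries})
        species_ids = species["genome_id"].tolist()
        presence = pd.DataFrame(False, index=species_ids, columns=sample_ids)
        for s in summaries:
            presence.loc[s.genome_id, s.sample_id] = metagenome.call_presence(s, calib)

        prev_df, prev_test = metagenome.prevalence(presence, species_calls)
        io.write_results_table(prev_df, out_dir / "prevalence.tsv")

        mapping["rpkm"] = [
            metagenome.rpkm(
                metagenome.MappingSummary(
                    genome_id=r.genome_id,
                    sample_id=r.sample_id,
                    rs=int(r.rs),
                    gl_kb=float(r.gl_kb),
                    trc=int(r.trc),
                )
            )
            for r in mapping.itertuples()
        ]
        rpkm_matrix = mapping.pivot(
            index="genome_id", columns="sample_id", values="rpkm"
        ).loc[species_ids, sample_ids]
        abund_df, abund_test = metagenome.abundance_compare(
            rpkm_matrix, presence, species_calls, min_samples=cfg.abundance_min_samples
        )
        io.write_results_table(abund_df, out_dir / "abundance.tsv")

        perm_fraction = metagenome.permutation_equalized(
            prev_df.set_index("genome_id")["prevalence"],
            species_calls,
            n_perm=cfg.n_permutations,
            seed=cfg.rng_seed,
        )
        contrib = metagenome.aitchison_contribution(rpkm_matrix, species_calls)
        io.write_results_table(contrib, out_dir / "aitchison_contributions.tsv")
        group_contrib = contrib.groupby("sporulation_class")["contribution"].sum()

        meta_report = {
            "prevalence_wilcoxon_p": prev_test.p_value,
            "abundance_wilcoxon_p": abund_test.p_value,
            "permutation_fraction_sf_greater": perm_fraction,
            "aitchison_share_sf": float(group_contrib.get("SF", 0.0)),
            "aitchison_share_fsf": float(group_contrib.get("FSF", 0.0)),
        }
        (out_dir / "metagenome_report.json").write_text(
            json.dumps(meta_report, indent=1, sort_keys=True)
        )

        # --- manifest ------------------------------------------------------
        stage_name = "manifest"
        manifest = {
            "config_hash": _config_hash(cfg),
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(cfg).items()
            },
            "data_dir": str(data_dir),
            "seed": cfg.rng_seed,
            "stages": ["signature", "classify", "stages", "adaptation", "metagenome"],
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage: {stage_name}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {stage_name!r}: {exc}") from exc
    return out_dir
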