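"""End-to-end pipeline: simulate -> subsets/matching -> diversity and
stability -> differential abundance -> sketches and MAG distances ->
strain trees -> clade enrichment scan -> classification.

Each stage is skippable; the run manifest records the seed, configuration,
software version and SHA-256 of every output for reproducibility.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_strata
from .cladescan import clade_unique_genes, scan_table, scan_tree
from .cohort import demographic_tests, match_state_subset, select_state_subsets
from .differential import fit_associations
from .io import (write_fasta, write_gene_presence_csv, write_mag_tsv,
                 write_metadata_csv, write_metaphlan_table)
from .magqc import tier_summary
from .metrics import (age_diversity_correlation, aitchison, alpha_diversity,
                      pcoa, stability_analysis, top_taxa_summary)
from .sketch import compare_top_species, sketch
from .synthetic import (SimulationConfig, generate_abundances, generate_cohort,
                        generate_mags, generate_strain_data)
from .trees import build_tree, gene_content_distance, write_newick

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "subset", "diversity", "stability", "differential",
              "magdist", "trees", "cladescan", "classify")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(out_dir, seed: int = 0, config: SimulationConfig | None = None,
                 stages=ALL_STAGES, classifier_trees: int = 200) -> dict:
    """Run the pipeline on a synthetic cohort and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    if "simulate" not in stages:
        raise ValueError("stage dependency missing: every downstream stage "
                         "currently consumes the simulate stage outputs")
    config = config or SimulationConfig(seed=seed)
    if config.seed != seed:
        config = dataclasses.replace(config, seed=seed)
    manifest = {"seed": seed, "version": __version__,
                "config": json.loads(json.dumps(dataclasses.asdict(config),
                                                default=str)),
                "stages": {}, "outputs": {}}

    def record(name, path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}

    t0 = time.time()
    cohort = generate_cohort(config)
    counts, rel = generate_abundances(cohort, config)
    strain = generate_strain_data(cohort, config)
    mags = generate_mags(cohort, config)
    write_metadata_csv(cohort, out / "metadata.csv")
    write_metaphlan_table(rel, out / "taxa_relative.tsv")
    write_gene_presence_csv(strain.clade.gene_presence,
                            out / "gene_presence_absence.csv")
    write_fasta(strain.clade.sequences, out / "clade_genomes.fasta")
    write_fasta(strain.probiotic.sequences, out / "probiotic_genomes.fasta")
    write_mag_tsv(mags, out / "mags.tsv")
    for name in ("metadata.csv", "taxa_relative.tsv", "gene_presence_absence.csv",
                 "clade_genomes.fasta", "probiotic_genomes.fasta", "mags.tsv"):
        record(name, out / name)
    manifest["stages"]["simulate"] = round(time.time() - t0, 2)

    if "subset" in stages:
        t0 = time.time()
        demographic_tests(cohort).to_csv(out / "demographics.tsv", sep="\t",
                                         index=False)
        subsets = select_state_subsets(cohort)
        rows = []
        for name, sub in subsets.items():
            match = match_state_subset(cohort, sub) if len(sub) else None
            for case_id, control_id in (match.pairs if match else []):
                rows.append({"subset": name, "case_sample": case_id,
                             "control_sample": control_id})
        pd.DataFrame(rows).to_csv(out / "matched_subsets.tsv", sep="\t",
                                  index=False)
        record("demographics.tsv", out / "demographics.tsv")
        record("matched_subsets.tsv", out / "matched_subsets.tsv")
        manifest["stages"]["subset"] = round(time.time() - t0, 2)

    if "diversity" in stages:
        t0 = time.time()
        alpha_diversity(counts).to_csv(out / "alpha_diversity.tsv", sep="\t")
        age_diversity_correlation(counts, cohort).to_csv(
            out / "age_diversity_correlation.tsv", sep="\t", index=False)
        groups = cohort.merged.set_index("sample_id")["group"]
        ord_res = pcoa(aitchison(rel), n_axes=2, groups=groups)
        ord_res.coordinates.assign(explained_pc1=ord_res.explained[0],
                                   anova_p=ord_res.anova_p).to_csv(
            out / "pcoa.tsv", sep="\t")
        top_taxa_summary(rel, cohort).to_csv(out / "top_taxa.tsv", sep="\t")
        for name in ("alpha_diversity.tsv", "age_diversity_correlation.tsv",
                     "pcoa.tsv", "top_taxa.tsv"):
            record(name, out / name)
        manifest["stages"]["diversity"] = round(time.time() - t0, 2)

    if "stability" in stages:
        t0 = time.time()
        stability_analysis(rel, cohort).to_csv(out / "stability.tsv", sep="\t",
                                               index=False)
        record("stability.tsv", out / "stability.tsv")
        manifest["stages"]["stability"] = round(time.time() - t0, 2)

    if "differential" in stages:
        t0 = time.time()
        fit_associations(rel, cohort, age_window=(0.0, 2.0)).to_csv(
            out / "differential_0_2_months.tsv", sep="\t", index=False)
        record("differential_0_2_months.tsv", out / "differential_0_2_months.tsv")
        manifest["stages"]["differential"] = round(time.time() - t0, 2)

    if "magdist" in stages:
        t0 = time.time()
        tier_summary(mags, total_samples=len(cohort.samples)).to_csv(
            out / "mag_tiers.tsv", sep="\t")
        sketches = {}
        for sp_data in (strain.probiotic, strain.clade):
            sketches[sp_data.species] = {
                gid: sketch(seq, genome_id=gid)
                for gid, seq in sp_data.sequences.items()}
        genome_map = pd.concat([strain.probiotic.genome_map,
                                strain.clade.genome_map])
        compare_top_species(sketches, genome_map).to_csv(
            out / "mag_distance_report.tsv", sep="\t", index=False)
        record("mag_tiers.tsv", out / "mag_tiers.tsv")
        record("mag_distance_report.tsv", out / "mag_distance_report.tsv")
        manifest["stages"]["magdist"] = round(time.time() - t0, 2)

    tree = None
    if "trees" in stages or "cladescan" in stages:
        t0 = time.time()
        dm = gene_content_distance(strain.clade.gene_presence)
        tree = build_tree(dm)
        labels = strain.clade.genome_map.set_index("genome_id")
        tree.annotate(labels)
        write_newick(tree, out / "clade_tree.nwk")
        record("clade_tree.nwk", out / "clade_tree.nwk")
        manifest["stages"]["trees"] = round(time.time() - t0, 2)

    if "cladescan" in stages:
        t0 = time.time()
        results = scan_tree(tree, expected_case_fraction=0.5)
        scan_table(results).to_csv(out / "clade_scan.tsv", sep="\t", index=False)
        best = next(r for r in results if not np.isnan(r.p))
        genes = clade_unique_genes(strain.clade.gene_presence, best.leaves,
                                   node_id=best.node_id)
        Path(out / "clade_unique_genes.txt").write_text(
            "\n".join(genes.genes) + "\n")
        record("clade_scan.tsv", out / "clade_scan.tsv")
        record("clade_unique_genes.txt", out / "clade_unique_genes.txt")
        manifest["stages"]["cladescan"] = round(time.time() - t0, 2)

    if "classify" in stages:
        t0 = time.time()
        reports = classify_strata(rel, cohort, seed=seed,
                                  n_estimators=classifier_trees)
        payload = {name: {"per_class_accuracy": rep.per_class_accuracy,
                          "n_samples": rep.n_samples,
                          "confusion": rep.confusion.to_dict(),
                          "top_features": rep.attributions.head(10)
                          .to_dict(orient="records")}
                   for name, rep in reports.items()}
        (out / "classifier_report.json").write_text(json.dumps(payload, indent=2))
        record("classifier_report.json", out / "classifier_report.json")
        manifest["stages"]["classify"] = round(time.time() - t0, 2)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
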