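"""Readers and writers for the external file formats.

Taxonomic profiler merged tables (TSV, pipe-delimited clade strings,
percentages), per-sample clinical metadata CSV, pangenome gene
presence/absence CSV (Roary dialect: presence = non-empty cell), FASTA
genomes, MAG record TSV, and Newick trees. Proportions (0-1) are the
internal unit; percentage conversion happens only here.
"""
from __future__ import annotations

import csv

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cohort import CohortTable, INFANT_COLUMNS, SAMPLE_COLUMNS
from .magqc import frame_to_records, records_to_frame
from .tables import FeatureTable

RANK_PREFIX = {"kingdom": "k__", "phylum": "p__", "class": "c__",
               "order": "o__", "family": "f__", "genus": "g__",
               "species": "s__", "strain": "t__"}

# Roary's leading metadata columns (any subset may be present)
ROARY_META_COLUMNS = [
    "Gene", "Non-unique Gene name", "Annotation", "No. isolates",
    "No. sequences", "Avg sequences per isolate", "Genome Fragment",
    "Order within Fragment", "Accessory Fragment",
    "Accessory Order with Fragment", "QC", "Min group size nuc",
    "Max group size nuc", "Avg group size nuc"]


# --------------------------------------------------- profiler tables

def read_metaphlan_table(path, level: str = "species") -> FeatureTable:
    """Read a merged taxonomic-profiler table at one taxonomy level.

    Rows are pipe-delimited clade strings; values are percentages and are
    rescaled to proportions. Per-sample sums are validated to be <= 1 plus
    tolerance. Duplicate clades and non-numeric cells raise.
    """
    prefix = RANK_PREFIX[level]
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    clade_col = df.columns[0]
    df = df.set_index(clade_col)
    if "clade_taxid" in df.columns or "NCBI_tax_id" in df.columns:
        df = df.drop(columns=[c for c in ("clade_taxid", "NCBI_tax_id")
                              if c in df.columns])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate clade row: {dup}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    rows = {}
    taxonomy = {}
    for clade in values.index:
        parts = str(clade).split("|")
        last = parts[-1]
        if not any(last.startswith(p) for p in RANK_PREFIX.values()):
            raise ValueError(f"malformed clade string: {clade}")
        if last.startswith(prefix):
            name = last[len(prefix):]
            if name in rows:
                raise ValueError(f"duplicate clade at level {level}: {clade}")
            rows[name] = values.loc[clade] / 100.0
            taxonomy[name] = str(clade)
    table = pd.DataFrame(rows).T
    sums = table.sum(axis=0)
    if (sums > 1.0 + 1e-4).any():
        bad = sums[sums > 1.0 + 1e-4].index[0]
        raise ValueError(f"sample {bad} sums to {sums[bad]:.4f} > 1 at level {level}")
    table = table / sums.where(sums > 0, 1.0)  # renormalise to exact closure
    return FeatureTable(table, kind="relative", level=level, taxonomy=taxonomy)


def write_metaphlan_table(table: FeatureTable, path):
    """Write species rows plus genus roll-ups as a merged percentage TSV."""
    rel = table.to_relative()
    out = {}
    genus_rows = {}
    for feat in rel.feature_ids:
        clade = rel.taxonomy.get(
            feat, f"k__Bacteria|g__{feat.split('_')[0]}|s__{feat}")
        out[clade] = rel.data.loc[feat] * 100.0
        genus_clade = clade.rsplit("|", 1)[0]
        genus_rows.setdefault(genus_clade, 0.0)
        genus_rows[genus_clade] = genus_rows[genus_clade] + rel.data.loc[feat] * 100.0
    frame = pd.DataFrame({**genus_rows, **out}).T
    frame.index.name = "clade_name"
    frame.to_csv(path, sep="\t")


# ----------------------------------------------------------- metadata

def read_metadata_csv(path) -> CohortTable:
    """One row per sample; infant-level columns are repeated per sample."""
    df = pd.read_csv(path)
    missing = [c for c in set(INFANT_COLUMNS + SAMPLE_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    extra_infant = [c for c in ("onset_age", "resolution_age") if c in df.columns]
    infants = (df[INFANT_COLUMNS + extra_infant]
               .drop_duplicates("infant_id").reset_index(drop=True))
    samples = df[SAMPLE_COLUMNS].copy()
    return CohortTable(infants, samples)


def write_metadata_csv(cohort: CohortTable, path):
    cohort.merged.to_csv(path, index=False)


# ------------------------------------------------------ gene presence

def read_gene_presence_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roary-dialect gene_presence_absence.csv.

    Returns (binary genes x genomes matrix, gene metadata). Presence is
    any non-empty cell; quoted commas are handled by the CSV parser.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    meta_cols = [c for c in df.columns if c in ROARY_META_COLUMNS]
    genome_cols = [c for c in df.columns if c not in ROARY_META_COLUMNS]
    if "Gene" not in df.columns:
        raise ValueError("no 'Gene' column found")
    if not genome_cols:
        raise ValueError("no genome columns detected")
    df = df.set_index("Gene")
    meta = df[[c for c in meta_cols if c != "Gene"]]
    matrix = (df[genome_cols] != "").astype(int)
    return matrix, meta


def write_gene_presence_csv(matrix: pd.DataFrame, path,
                            annotations: dict | None = None):
    """Write a binary genes x genomes matrix in the Roary dialect."""
    annotations = annotations or {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
        writer.writerow(["Gene", "Annotation"] + list(matrix.columns))
        for gene in matrix.index:
            row = [gene, annotations.get(gene, "")]
            row += [gene if v else "" for v in matrix.loc[gene]]
            writer.writerow(row)


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: dict, path):
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------------ MAGs

def write_mag_tsv(records, path):
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_mag_tsv(path):
    return frame_to_records(pd.read_csv(path, sep="\t"))
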