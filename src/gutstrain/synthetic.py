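"""Synthetic longitudinal case-control cohort generator.

Emulates the data shapes a strain-level infant microbiome study produces:
a cohort of infants sampled at scheduled visits over the first year with
disease onset/resolution ages; Dirichlet-multinomial taxonomic profiles
with an age maturation gradient, per-infant random intercepts and planted
group effects; strain haplotypes and genomes for a probiotic species (a
near-clonal lineage in probiotic-exposed carriers) and for a species
carrying a planted case-enriched clade with a unique gene set; and MAG
quality records. All randomness flows from one integer seed through
spawned generators; there is no global state.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .magqc import MagRecord, assign_tier
from .tables import FeatureTable

PROBIOTIC_SPECIES = "Lacticaseibacillus_rhamnosus"
CLADE_SPECIES = "Escherichia_coli"
INFANTIS = "Bifidobacterium_longum_subsp_infantis"

#: named species given realistic identities; remaining taxa are fillers
SPECIAL_TAXA = [
    # (name, genus, base weight, age trend)
    ("Bifidobacterium_longum", "Bifidobacterium", 8.0, -0.2),
    ("Escherichia_coli", "Escherichia", 5.0, -0.4),
    ("Bifidobacterium_breve", "Bifidobacterium", 4.0, -0.3),
    ("Bacteroides_fragilis", "Bacteroides", 3.0, 0.6),
    ("Bifidobacterium_bifidum", "Bifidobacterium", 2.0, -0.4),
    ("Klebsiella_michiganensis", "Klebsiella", 2.0, -0.5),
    ("Klebsiella_pneumoniae", "Klebsiella", 1.5, -0.4),
    ("Clostridium_paraputrificum", "Clostridium", 1.0, 0.2),
    ("Faecalibacterium_prausnitzii", "Faecalibacterium", 1.0, 1.0),
    (PROBIOTIC_SPECIES, "Lacticaseibacillus", 0.08, 0.0),
    (INFANTIS, "Bifidobacterium", 2.5, 0.0),
]


@dataclass(frozen=True)
class PlantedEffect:
    """Multiplies the Dirichlet weight of ``taxon`` by exp(log_effect) in
    ``group`` samples within [age_lo, age_hi) months."""
    taxon: str
    group: str
    age_lo: float
    age_hi: float
    log_effect: float


@dataclass(frozen=True)
class PlantedClade:
    species: str = CLADE_SPECIES
    n_unique_genes: int = 223
    clade_case_fraction: float = 1.0
    clade_size: int = 12


DEFAULT_PLANTED = (
    PlantedEffect("Escherichia_coli", "case", 0.0, 2.0, np.log(2.0)),
    PlantedEffect("Bifidobacterium_bifidum", "case", 0.0, 2.0, np.log(1.8)),
    PlantedEffect("Klebsiella_michiganensis", "control", 0.0, 2.0, np.log(2.0)),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 163 infants with an 84/163 case
    split, visits scheduled at birth through 12 months, a planted
    case-enriched clade sharing 223 unique genes, and probiotic use far
    more common among cases (85.7% vs 20.3%).
    """

    n_infants: int = 163
    case_fraction: float = 84 / 163
    visit_ages_months: tuple = (0.03, 0.5, 1.0, 2.0, 4.0, 6.0, 9.0, 12.0)
    age_jitter_sd: float = 0.15
    missingness: float = 0.5
    n_taxa: int = 60
    planted_effects: tuple = DEFAULT_PLANTED
    probiotic_strain_divergence: float = 0.01
    planted_clade: PlantedClade = field(default_factory=PlantedClade)
    sequencing_depth: int = 50_000
    seed: int = 0

    # dispersion / longitudinal structure
    concentration: float = 50.0
    infant_sigma: float = 0.45
    maturation: float = 2.0

    # demographics (case, control)
    probiotic_rates: tuple = (0.857, 0.203)
    female_rates: tuple = (0.50, 0.405)
    vaginal_rates: tuple = (0.667, 0.62)
    feeding_probs_case: tuple = (0.631, 0.226, 0.143)
    feeding_probs_control: tuple = (0.62, 0.316, 0.063)

    # disease course (months)
    onset_median: float = 1.2
    onset_sigma: float = 0.6
    duration_median: float = 4.5
    duration_sigma: float = 0.4

    # subspecies emergence (prevalence-curve structure)
    infantis_onset_month: float = 2.0
    infantis_carrier_probs: tuple = (0.45, 0.30, 0.12)  # exclusive/partial/formula

    # strain data
    n_strain_sites: int = 2000
    genome_length: int = 12_000
    n_clade_genomes: int = 40
    n_core_genes: int = 600
    n_accessory_genes: int = 400
    accessory_rate: float = 0.3
    probiotic_carrier_rates: tuple = (0.85, 0.15)  # exposed, unexposed
    background_divergence: float = 0.02

    # MAGs
    mag_tier_fractions: tuple = (0.366, 0.208, 0.426)
    mags_per_sample: float = 12.0
    p_sample_no_mag: float = 0.016

    def __post_init__(self):
        if self.n_infants <= 0:
            raise ValueError("n_infants must be positive")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        ages = self.visit_ages_months
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("visit ages must be strictly increasing")
        for rate in (self.missingness, self.probiotic_strain_divergence,
                     self.accessory_rate, self.p_sample_no_mag,
                     *self.probiotic_rates, *self.female_rates,
                     *self.vaginal_rates, *self.mag_tier_fractions,
                     *self.probiotic_carrier_rates):
            if not 0 <= rate <= 1:
                raise ValueError(f"rate/probability out of [0,1]: {rate}")
        if self.planted_clade.clade_size < 2:
            raise ValueError("planted clade size must be >= 2")

    def rng(self, stream: int) -> np.random.Generator:
        """Stream-split generator: independent per pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(
            stream + 1)[stream])


# ---------------------------------------------------------------- cohort

FEEDING_LEVELS = ("exclusive", "partial", "formula")


def generate_cohort(config: SimulationConfig) -> CohortTable:
    """Infant metadata, scheduled visits with jitter, and symptom states.

    Case infants get a log-normal onset age and a later resolution age;
    each sample's symptom state is derived from its age relative to them.
    """
    rng = config.rng(0)
    n = config.n_infants
    n_case = int(round(n * config.case_fraction))
    groups = ["case"] * n_case + ["control"] * (n - n_case)
    infants = []
    for i, group in enumerate(groups):
        g = 0 if group == "case" else 1
        feeding_p = (config.feeding_probs_case if group == "case"
                     else config.feeding_probs_control)
        feeding_p = np.asarray(feeding_p) / np.sum(feeding_p)
        onset = resolution = np.nan
        if group == "case":
            onset = rng.lognormal(np.log(config.onset_median), config.onset_sigma)
            resolution = onset + rng.lognormal(np.log(config.duration_median),
                                               config.duration_sigma)
        infants.append({
            "infant_id": f"I{i:03d}", "group": group,
            "sex": "female" if rng.random() < config.female_rates[g] else "male",
            "delivery_mode": "vaginal" if rng.random() < config.vaginal_rates[g]
            else "cesarean",
            "initial_feeding": FEEDING_LEVELS[rng.choice(3, p=feeding_p)],
            "probiotic_first_year": bool(rng.random() < config.probiotic_rates[g]),
            "onset_age": onset, "resolution_age": resolution,
        })
    infants = pd.DataFrame(infants)

    samples = []
    max_age = 13.99
    for _, row in infants.iterrows():
        attended = [v for v in config.visit_ages_months
                    if rng.random() >= config.missingness]
        if not attended:  # every infant contributes at least one sample
            attended = [config.visit_ages_months[
                rng.integers(len(config.visit_ages_months))]]
        for v, visit in enumerate(config.visit_ages_months):
            if visit not in attended:
                continue
            age = visit + rng.normal(0.0, config.age_jitter_sd) \
                if config.age_jitter_sd > 0 else float(visit)
            age = float(np.clip(age, 0.0, max_age))
            if row["group"] == "control":
                state = "control"
            elif age < row["onset_age"]:
                state = "pre_symptomatic"
            elif age < row["resolution_age"]:
                state = "symptomatic"
            else:
                state = "resolved"
            samples.append({"sample_id": f"{row['infant_id']}V{v}",
                            "infant_id": row["infant_id"],
                            "age_months": age, "symptom_state": state})
    return CohortTable(infants, pd.DataFrame(samples))


# ------------------------------------------------------------ abundances

def _taxa_catalog(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    if config.n_taxa < len(SPECIAL_TAXA):
        raise ValueError(f"n_taxa must be >= {len(SPECIAL_TAXA)}")
    rows = [{"taxon": n, "genus": g, "weight": w, "trend": t, "onset": 0.0}
            for n, g, w, t in SPECIAL_TAXA]
    n_fill = config.n_taxa - len(rows)
    weights = rng.lognormal(-1.0, 1.0, size=n_fill)
    trends = rng.uniform(-1.0, 1.0, size=n_fill)
    # half the filler taxa are later colonisers: absent before a
    # taxon-specific onset age, so richness accumulates over the first year
    late = rng.random(n_fill) < 0.5
    onsets = np.where(late, rng.uniform(3.0, 10.0, size=n_fill), 0.0)
    for i in range(n_fill):
        rows.append({"taxon": f"Species_{i:03d}", "genus": f"Genus_{i // 3:02d}",
                     "weight": float(weights[i]), "trend": float(trends[i]),
                     "onset": float(onsets[i])})
    return pd.DataFrame(rows).set_index("taxon")


def generate_abundances(cohort: CohortTable, config: SimulationConfig
                        ) -> tuple[FeatureTable, FeatureTable]:
    """Dirichlet-multinomial counts and matching relative abundances.

    Dirichlet weights follow an age maturation gradient per taxon, a
    log-normal per-infant intercept, planted group effects within their
    age windows, a probiotic multiplier on the probiotic species, and an
    emergence-age/feeding rule for the planted subspecies.
    """
    rng = config.rng(1)
    catalog = _taxa_catalog(config, rng)
    taxa = list(catalog.index)
    for eff in config.planted_effects:
        if eff.taxon not in catalog.index:
            raise ValueError(f"planted taxon {eff.taxon!r} not among the "
                             f"{config.n_taxa} taxa")
    merged = cohort.merged
    infants = list(cohort.infants["infant_id"])
    intercepts = pd.DataFrame(
        rng.lognormal(0.0, config.infant_sigma, size=(len(infants), len(taxa))),
        index=infants, columns=taxa)
    infantis_carrier = {}
    for _, row in cohort.infants.iterrows():
        p = dict(zip(FEEDING_LEVELS, config.infantis_carrier_probs))[
            row["initial_feeding"]]
        infantis_carrier[row["infant_id"]] = rng.random() < p

    base_w = catalog["weight"].values
    trend = catalog["trend"].values
    onset = catalog["onset"].values
    counts = np.zeros((len(taxa), len(merged)), dtype=int)
    probiotic_idx = taxa.index(PROBIOTIC_SPECIES)
    infantis_idx = taxa.index(INFANTIS)
    for s, row in merged.iterrows():
        age = row["age_months"]
        w = base_w * np.exp(trend * config.maturation * (age - 6.0) / 12.0)
        w = w * intercepts.loc[row["infant_id"]].values
        w[onset > age] = 0.0
        for eff in config.planted_effects:
            if row["group"] == eff.group and eff.age_lo <= age < eff.age_hi:
                w[taxa.index(eff.taxon)] *= np.exp(eff.log_effect)
        if row["probiotic_first_year"]:
            w[probiotic_idx] *= 25.0
        if age < config.infantis_onset_month or not infantis_carrier[row["infant_id"]]:
            w[infantis_idx] = 0.0
        alpha = config.concentration * w / w.sum()
        keep = alpha > 0
        p = np.zeros(len(taxa))
        p[keep] = rng.dirichlet(alpha[keep])
        counts[:, s] = rng.multinomial(config.sequencing_depth, p)

    taxonomy = {t: f"k__Bacteria|g__{catalog.loc[t, 'genus']}|s__{t}"
                for t in taxa}
    count_df = pd.DataFrame(counts, index=taxa, columns=list(merged["sample_id"]))
    count_table = FeatureTable(count_df, kind="counts", level="species",
                               taxonomy=taxonomy)
    rel = count_df / config.sequencing_depth
    rel_table = FeatureTable(rel, kind="relative", level="species",
                             taxonomy=taxonomy)
    return count_table, rel_table


# ------------------------------------------------------------ strain data

_ALPHABET = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _ALPHABET[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hits = rng.random(len(seq)) < rate
    idx = np.where(hits)[0]
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size)
        codes = np.searchsorted(_ALPHABET, out[idx])
        out[idx] = _ALPHABET[(codes + shift) % 4]
    return out


@dataclass
class SpeciesStrainData:
    species: str
    haplotypes: pd.DataFrame            # genomes x aligned marker sites
    genome_map: pd.DataFrame            # genome_id, sample_id, infant_id, group, probiotic
    sequences: dict                     # genome_id -> str
    gene_presence: pd.DataFrame | None = None
    planted_clade_genomes: list | None = None
    planted_genes: list | None = None


@dataclass
class StrainData:
    probiotic: SpeciesStrainData
    clade: SpeciesStrainData


def _probiotic_strains(cohort, config, rng, with_sequences) -> SpeciesStrainData:
    merged = cohort.merged
    carriers = []
    for _, row in cohort.infants.iterrows():
        p = config.probiotic_carrier_rates[0 if row["probiotic_first_year"] else 1]
        if rng.random() < p:
            carriers.append(row)
    ancestor_h = _random_seq(rng, config.n_strain_sites)
    ancestor_g = _random_seq(rng, config.genome_length)
    # probiotic-exposed carriers are near-clonal: 5% of the divergence of
    # unexposed carriers, whose lineages drift at probiotic_strain_divergence
    clonal_rate = 0.05 * config.probiotic_strain_divergence
    haplos, seqs, rows = {}, {}, []
    for row in carriers:
        rate = clonal_rate if row["probiotic_first_year"] \
            else config.probiotic_strain_divergence
        lineage_h = _mutate(rng, ancestor_h, rate)
        lineage_g = _mutate(rng, ancestor_g, rate)
        infant_samples = merged[merged["infant_id"] == row["infant_id"]]
        chosen = infant_samples.sort_values("sample_id").head(2)
        for _, samp in chosen.iterrows():
            gid = f"{PROBIOTIC_SPECIES}|{samp['sample_id']}"
            haplos[gid] = _mutate(rng, lineage_h, rate * 0.2)
            if with_sequences:
                seqs[gid] = "".join(_mutate(rng, lineage_g, rate * 0.2))
            rows.append({"genome_id": gid, "sample_id": samp["sample_id"],
                         "infant_id": row["infant_id"], "group": row["group"],
                         "probiotic": bool(row["probiotic_first_year"])})
    hap_df = pd.DataFrame([list(v) for v in haplos.values()],
                          index=list(haplos.keys()))
    return SpeciesStrainData(PROBIOTIC_SPECIES, hap_df, pd.DataFrame(rows), seqs)


def _clade_strains(cohort, config, rng, with_sequences) -> SpeciesStrainData:
    pc = config.planted_clade
    merged = cohort.merged
    half = config.n_clade_genomes // 2
    case_ids = list(cohort.infants.loc[cohort.infants["group"] == "case",
                                       "infant_id"])
    ctrl_ids = list(cohort.infants.loc[cohort.infants["group"] == "control",
                                       "infant_id"])
    case_pick = list(rng.choice(case_ids, size=min(half, len(case_ids)),
                                replace=False))
    ctrl_pick = list(rng.choice(ctrl_ids, size=min(half, len(ctrl_ids)),
                                replace=False))
    if pc.clade_size < 2:
        raise ValueError("clade size must be >= 2")
    n_clade_case = int(round(pc.clade_size * pc.clade_case_fraction))
    n_clade_ctrl = pc.clade_size - n_clade_case
    if n_clade_case > len(case_pick) or n_clade_ctrl > len(ctrl_pick):
        raise ValueError("clade larger than available genomes per group")
    clade_infants = case_pick[:n_clade_case] + ctrl_pick[:n_clade_ctrl]

    base_h = _random_seq(rng, config.n_strain_sites)
    base_g = _random_seq(rng, config.genome_length)
    clade_anc_h = _mutate(rng, base_h, config.background_divergence)
    clade_anc_g = _mutate(rng, base_g, config.background_divergence)
    unique_block = "".join(_random_seq(rng, 2000))

    genes = ([f"core_{i:04d}" for i in range(config.n_core_genes)]
             + [f"acc_{i:04d}" for i in range(config.n_accessory_genes)]
             + [f"uniq_{i:04d}" for i in range(pc.n_unique_genes)])
    planted_genes = [g for g in genes if g.startswith("uniq_")]

    haplos, seqs, rows, presence = {}, {}, [], {}
    for infant_id in case_pick + ctrl_pick:
        in_clade = infant_id in set(clade_infants)
        infant_rows = merged[merged["infant_id"] == infant_id]
        samp = infant_rows.sort_values("sample_id").iloc[0]
        gid = f"{pc.species}|{samp['sample_id']}"
        if in_clade:
            haplos[gid] = _mutate(rng, clade_anc_h, 0.1 * config.background_divergence)
            g_seq = "".join(_mutate(rng, clade_anc_g,
                                    0.1 * config.background_divergence))
            g_seq += unique_block
        else:
            haplos[gid] = _mutate(rng, base_h, config.background_divergence)
            g_seq = "".join(_mutate(rng, base_g, config.background_divergence))
        if with_sequences:
            seqs[gid] = g_seq
        col = np.concatenate([
            np.ones(config.n_core_genes, dtype=int),
            (rng.random(config.n_accessory_genes) < config.accessory_rate
             ).astype(int),
            np.full(pc.n_unique_genes, 1 if in_clade else 0, dtype=int)])
        presence[gid] = col
        rows.append({"genome_id": gid, "sample_id": samp["sample_id"],
                     "infant_id": infant_id,
                     "group": "case" if infant_id in case_pick else "control",
                     "probiotic": bool(cohort.infants.set_index("infant_id")
                                       .loc[infant_id, "probiotic_first_year"])})
    hap_df = pd.DataFrame([list(v) for v in haplos.values()],
                          index=list(haplos.keys()))
    gpm = pd.DataFrame(presence, index=genes)
    clade_genomes = [f"{pc.species}|{merged[merged['infant_id'] == i].sort_values('sample_id').iloc[0]['sample_id']}"
                     for i in clade_infants]
    return SpeciesStrainData(pc.species, hap_df, pd.DataFrame(rows), seqs,
                             gene_presence=gpm,
                             planted_clade_genomes=clade_genomes,
                             planted_genes=planted_genes)


def generate_strain_data(cohort: CohortTable, config: SimulationConfig,
                         with_sequences: bool = True) -> StrainData:
    """Strain haplotypes, genome sequences and the pangenome matrix.

    The probiotic species carries a near-clonal lineage in probiotic-exposed
    carriers and more diverged lineages in unexposed carriers; the planted
    clade species carries a designated genome subset sharing
    ``n_unique_genes`` genes absent from all other genomes.
    """
    rng = config.rng(2)
    probiotic = _probiotic_strains(cohort, config, rng, with_sequences)
    clade = _clade_strains(cohort, config, rng, with_sequences)
    return StrainData(probiotic, clade)


# ---------------------------------------------------------------- MAGs

# per-tier (completeness, contamination) Beta parameters and ranges
_TIER_DISTS = {
    "high": ((2.0, 1.0, 85.0, 100.0), (1.0, 3.0, 0.0, 5.0)),
    "medium": ((2.0, 2.0, 50.0, 85.0), (1.0, 3.0, 0.0, 5.0)),
    "low": ((2.0, 2.0, 5.0, 50.0), (1.0, 2.0, 0.0, 10.0)),
}


def generate_mags(cohort: CohortTable, config: SimulationConfig,
                  force_completeness: float | None = None,
                  force_contamination: float | None = None) -> list[MagRecord]:
    """MAG quality records with configurable tier fractions.

    Completeness and contamination are Beta draws scaled into each tier's
    region; the tier is then re-derived from the thresholds, so records are
    consistent by construction.
    """
    rng = config.rng(3)
    catalog = _taxa_catalog(config, config.rng(1))
    species = list(catalog.index)
    sp_p = catalog["weight"].values / catalog["weight"].values.sum()
    fractions = np.asarray(config.mag_tier_fractions, dtype=float)
    fractions = fractions / fractions.sum()
    records = []
    counter = 0
    for sid in cohort.samples["sample_id"]:
        if rng.random() < config.p_sample_no_mag:
            continue
        n = max(1, rng.poisson(config.mags_per_sample))
        for _ in range(n):
            tier = ("high", "medium", "low")[rng.choice(3, p=fractions)]
            (ca, cb, clo, chi), (ta, tb, tlo, thi) = _TIER_DISTS[tier]
            completeness = clo + (chi - clo) * rng.beta(ca, cb)
            contamination = tlo + (thi - tlo) * rng.beta(ta, tb)
            completeness = min(completeness, 100.0 - 1e-9)
            if force_completeness is not None:
                completeness = force_completeness
            if force_contamination is not None:
                contamination = force_contamination
            records.append(MagRecord(
                mag_id=f"MAG{counter:05d}", sample_id=sid,
                species=str(rng.choice(species, p=sp_p)),
                completeness=float(completeness),
                contamination=float(contamination),
                tier=assign_tier(completeness, contamination)))
            counter += 1
    return records
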