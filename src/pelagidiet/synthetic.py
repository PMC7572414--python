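"""Synthetic multi-proxy diet study generator.

Emulates the downstream data tables of a two-species (anchovy, sardine)
trophic study across a north-to-south gradient of three areas: per-fish
metadata, stomach prey counts, DNA-metabarcoding OTU read tables (COI
zooplankton and rbcL diatom markers), and muscle stable-isotope values.

The generative structure mirrors what the analysis assumes:

* prey counts are Dirichlet-multinomial over 11 prey groups, with
  individual-level diet variability and a configured southward shift from
  copepod-dominated to krill-enriched diets; stomach totals are log-normal
  with a small empty-stomach probability;
* OTU tables are built from the true per-fish diet presence with Poisson
  read depths, plus injected noise that the filter cascade is designed to
  remove: globally rare OTUs (below the 0.005% whole-dataset threshold),
  per-sample mistag reads (below the 0.01% within-sample threshold), and
  predator-species OTUs in their own host's samples;
* isotope values are bivariate normal per (species, area) with lower
  delta15N in the northernmost area, a linear total-length effect, and
  C:N ratios that occasionally exceed the 3.5 lipid threshold.

The configured gradients are retained in a ground-truth record so that
recovery tests can check the downstream pipeline against what was put in.
One seed drives independent child streams per stage, so the draws of one
stage never perturb another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .metabarcoding import OTUTable

__all__ = ["StudyConfig", "SyntheticStudy", "generate_study", "write_tables"]

PREY_GROUPS = [
    "Calanoids", "Cyclopoids", "Harpacticoids", "Euphausiacea", "Decapoda",
    "Other Malacostraca", "Crustacean remains", "Mollusca", "Cladocerans",
    "Actinopterygii", "Others",
]
KRILL_GROUPS = ("Euphausiacea", "Decapoda", "Other Malacostraca")
COPEPOD_GROUPS = ("Calanoids", "Cyclopoids", "Harpacticoids")

# representative prey taxa per group: (taxon, unit wet weight mg); the
# third member of a group, where present, is rare and preferentially eaten
# by one species, which keeps inter-specific prey lists from saturating
DEFAULT_PREY_TAXA = {
    "Calanoids": [("Calanus helgolandicus", 0.08), ("Clausocalanus spp.", 0.03),
                  ("Pleuromamma gracilis", 0.06)],
    "Cyclopoids": [("Oithona spp.", 0.015), ("Corycaeus spp.", 0.02),
                   ("Oncaea spp.", 0.012)],
    "Harpacticoids": [("Microsetella spp.", 0.01), ("Euterpina acutifrons", 0.015)],
    "Euphausiacea": [("Euphausiacea ord.", 9.0), ("Nyctiphanes couchii", 7.0)],
    "Decapoda": [("Decapoda larvae", 5.0), ("Solenocera membranacea", 8.0),
                 ("Processa spp.", 6.0)],
    "Other Malacostraca": [("Amphipoda ord.", 3.0), ("Mysida ord.", 2.5)],
    "Crustacean remains": [("Crustacea remains", 0.5)],
    "Mollusca": [("Gastropoda larvae", 0.09), ("Bivalvia larvae", 0.07),
                 ("Pteropoda", 0.1)],
    "Cladocerans": [("Evadne spp.", 0.03), ("Penilia avirostris", 0.03)],
    "Actinopterygii": [("Fish eggs", 1.8), ("Fish larvae", 2.5),
                       ("Sprattus sprattus larvae", 3.0)],
    "Others": [("Appendicularia", 0.4), ("Chaetognatha", 0.8),
               ("Clytia hemisphaerica", 1.2)],
}

# group-level Dirichlet base concentrations (copepods dominate numerically)
BASE_ALPHA = {
    "Calanoids": 30.0, "Cyclopoids": 4.0, "Harpacticoids": 3.0,
    "Euphausiacea": 1.5, "Decapoda": 1.5, "Other Malacostraca": 1.0,
    "Crustacean remains": 1.0, "Mollusca": 2.0, "Cladocerans": 1.5,
    "Actinopterygii": 1.0, "Others": 1.5,
}
# southward krill enrichment of the Dirichlet concentrations
KRILL_AREA_FACTOR = {"GSA07": 0.25, "GSA06-North": 1.0, "GSA06-South": 5.0}
ADULT_KRILL_FACTOR = 1.6

# total length (cm) ranges per species, area, stage (juvenile share follows)
LENGTH_RANGES = {
    ("anchovy", "GSA07"): {"juvenile": (8.5, 10.9)},
    ("sardine", "GSA07"): {"juvenile": (9.6, 12.8)},
    ("anchovy", "GSA06-North"): {"juvenile": (8.9, 10.9), "adult": (11.0, 14.8)},
    ("sardine", "GSA06-North"): {"juvenile": (7.8, 12.9), "adult": (13.0, 16.9)},
    ("anchovy", "GSA06-South"): {"juvenile": (9.2, 10.9), "adult": (11.0, 16.2)},
    ("sardine", "GSA06-South"): {"juvenile": (8.5, 12.9), "adult": (13.0, 17.8)},
}

# per (species, area): mean (d13C, d15N); lower d15N in the north
DEFAULT_ISOTOPE_MEANS = {
    ("anchovy", "GSA07"): (-19.4, 7.2),
    ("anchovy", "GSA06-North"): (-19.0, 8.2),
    ("anchovy", "GSA06-South"): (-18.7, 8.7),
    ("sardine", "GSA07"): (-19.2, 7.5),
    ("sardine", "GSA06-North"): (-18.9, 8.4),
    ("sardine", "GSA06-South"): (-18.6, 8.9),
}
DEFAULT_ISOTOPE_COV = [[0.30, 0.05], [0.05, 0.20]]


@dataclass
class StudyConfig:
    n_fish_per_stratum: int = 35
    areas: tuple = (("GSA07", 42.5), ("GSA06-North", 40.0), ("GSA06-South", 37.8))
    species: tuple = ("anchovy", "sardine")
    n_sites_per_area: int = 3
    depth_range: tuple = (30.0, 120.0)
    prey_taxa: dict = field(default_factory=lambda: DEFAULT_PREY_TAXA)
    base_alpha: dict = field(default_factory=lambda: BASE_ALPHA)
    krill_area_factor: dict = field(default_factory=lambda: dict(KRILL_AREA_FACTOR))
    mean_count: float = 60.0        # log-normal stomach total, median scale
    count_sigma: float = 0.8
    empty_prob: float = 0.05
    # OTU noise
    read_depth: int = 50_000
    n_rare_otus: int = 8
    rare_otu_max_reads: int = 40    # dataset-wide, below the 0.005% threshold
    mistag_cells_per_sample: int = 3
    mistag_max_reads: int = 4       # per cell, below 0.01% of sample depth
    predator_read_frac: float = 0.02
    # isotopes
    isotope_means: dict = field(default_factory=lambda: dict(DEFAULT_ISOTOPE_MEANS))
    isotope_cov: list = field(default_factory=lambda: [r[:] for r in DEFAULT_ISOTOPE_COV])
    length_slope_d15n: float = 0.06  # per cm, centered within stratum
    cn_mean: float = 3.4
    cn_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_fish_per_stratum < 1:
            raise ValueError("n_fish_per_stratum must be positive")
        for g, a in self.base_alpha.items():
            if a <= 0:
                raise ValueError(f"Dirichlet concentration for {g} must be > 0")
        cov = np.asarray(self.isotope_cov, dtype=float)
        if not np.allclose(cov, cov.T):
            raise ValueError("isotope covariance must be symmetric")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() <= 0:
            raise ValueError(
                f"isotope covariance not positive-definite (eigenvalues {eig})")

    def alpha_for(self, species: str, area: str, stage: str) -> np.ndarray:
        alpha = np.array([self.base_alpha[g] for g in PREY_GROUPS])
        kf = self.krill_area_factor.get(area, 1.0)
        for g in KRILL_GROUPS:
            i = PREY_GROUPS.index(g)
            alpha[i] *= kf
            if stage == "adult":
                alpha[i] *= ADULT_KRILL_FACTOR
        return alpha

    def expected_group_props(self, species: str, area: str, stage: str) -> pd.Series:
        a = self.alpha_for(species, area, stage)
        return pd.Series(a / a.sum(), index=PREY_GROUPS)


@dataclass
class GroundTruth:
    config: StudyConfig
    group_props: dict            # (species, area, stage) -> Series over groups
    mistag_cells: list           # (otu_id, sample_id, reads)
    rare_otus: list
    isotope_means: dict


@dataclass
class SyntheticStudy:
    fish: pd.DataFrame
    gut_counts: pd.DataFrame     # fish x prey taxon
    taxon_to_group: pd.Series
    biomass_mg: pd.Series        # taxon -> unit wet weight (mg)
    otu_coi: OTUTable
    otu_rbcl: OTUTable
    isotopes: pd.DataFrame
    ground_truth: GroundTruth

    def validate(self) -> None:
        counts = self.gut_counts.to_numpy()
        if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("gut counts must be non-negative integers")
        for df in (self.gut_counts, self.isotopes.set_index("fish_id")):
            unknown = df.index.difference(self.fish["fish_id"])
            if len(unknown):
                raise ValueError(f"unresolved fish ids: {list(unknown)[:5]}")


def _juvenile_share(species: str, area: str) -> float:
    return 1.0 if area == "GSA07" else 0.5


def _taxon_split_weights(group: str, species: str, n_taxa: int,
                         group_order: list) -> np.ndarray:
    """Within-group taxon preferences; species weight the two common taxa
    differently, and the rare third taxon of alternating groups is nearly
    exclusive to one species."""
    if n_taxa == 1:
        return np.array([1.0])
    if n_taxa == 2:
        w = [0.72, 0.28] if species == "anchovy" else [0.45, 0.55]
        return np.array(w) / sum(w)
    anchovy_leaning = group_order.index(group) % 2 == 0
    rare = 0.02 if (species == "anchovy") == anchovy_leaning else 0.0005
    w = ([0.70, 0.28] if species == "anchovy" else [0.44, 0.54]) + [rare]
    return np.array(w) / sum(w)


def generate_study(config: StudyConfig | None = None) -> SyntheticStudy:
    """Draw a full synthetic study; identical config+seed gives identical
    tables."""
    config = config or StudyConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_fish, rng_gut, rng_otu, rng_diatom, rng_iso = (
        np.random.default_rng(s) for s in ss.spawn(5))

    # ---- fish metadata -------------------------------------------------
    rows = []
    for species in config.species:
        for area, lat in config.areas:
            ranges = LENGTH_RANGES.get(
                (species, area), {"juvenile": (8.0, 10.9), "adult": (11.0, 16.0)})
            juv_share = _juvenile_share(species, area) if "adult" in ranges else 1.0
            for i in range(config.n_fish_per_stratum):
                stage = ("juvenile" if rng_fish.uniform() < juv_share or
                         "adult" not in ranges else "adult")
                lo, hi = ranges[stage if stage in ranges else "juvenile"]
                site = f"{area}-S{rng_fish.integers(1, config.n_sites_per_area + 1)}"
                rows.append({
                    "fish_id": f"{species[:3]}_{area}_{i:03d}",
                    "species": species,
                    "area": area,
                    "site_id": site,
                    "latitude": lat + rng_fish.normal(0, 0.15),
                    "depth": rng_fish.uniform(*config.depth_range),
                    "total_length": rng_fish.uniform(lo, hi),
                    "stage": stage,
                })
    fish = pd.DataFrame(rows)

    # ---- gut contents --------------------------------------------------
    taxa, tax_group, tax_mass = [], {}, {}
    for group, members in config.prey_taxa.items():
        for taxon, mg in members:
            taxa.append(taxon)
            tax_group[taxon] = group
            tax_mass[taxon] = mg
    group_taxon_split = {
        (g, sp): _taxon_split_weights(g, sp, len(m), list(config.prey_taxa))
        for g, m in config.prey_taxa.items() for sp in config.species
    }

    counts = np.zeros((len(fish), len(taxa)), dtype=int)
    taxon_index = {t: j for j, t in enumerate(taxa)}
    truth_props = {}
    for i, f in fish.iterrows():
        key = (f.species, f.area, f.stage)
        if key not in truth_props:
            truth_props[key] = config.expected_group_props(*key)
        if rng_gut.uniform() < config.empty_prob:
            continue
        total = max(1, int(np.round(rng_gut.lognormal(
            np.log(config.mean_count), config.count_sigma))))
        props = rng_gut.dirichlet(config.alpha_for(*key))
        group_counts = rng_gut.multinomial(total, props)
        for g, gc in zip(PREY_GROUPS, group_counts):
            if gc == 0:
                continue
            split = rng_gut.multinomial(gc, group_taxon_split[(g, f.species)])
            for (taxon, _), c in zip(config.prey_taxa[g], split):
                counts[i, taxon_index[taxon]] += c
    gut_counts = pd.DataFrame(counts, index=fish["fish_id"].to_numpy(),
                              columns=taxa)

    # ---- COI OTU table -------------------------------------------------
    otu_ids = [f"OTU_{t.replace(' ', '_')}" for t in taxa]
    taxonomy = {o: f"Animalia;{tax_group[t]};{t}" for o, t in zip(otu_ids, taxa)}
    predator_otus = {"anchovy": "OTU_Engraulis_encrasicolus",
                     "sardine": "OTU_Sardina_pilchardus"}
    taxonomy[predator_otus["anchovy"]] = "Animalia;Actinopterygii;Engraulis encrasicolus"
    taxonomy[predator_otus["sardine"]] = "Animalia;Actinopterygii;Sardina pilchardus"
    rare_ids = [f"OTU_rare_{i:02d}" for i in range(config.n_rare_otus)]
    for i, o in enumerate(rare_ids):
        taxonomy[o] = "unassigned" if i % 2 == 0 else f"Animalia;Others;Rare taxon {i}"

    all_otus = otu_ids + list(predator_otus.values()) + rare_ids
    sample_ids = fish["fish_id"].tolist()
    reads = pd.DataFrame(0, index=all_otus, columns=sample_ids, dtype=int)

    presence = gut_counts > 0
    for sample, f in zip(sample_ids, fish.itertuples()):
        present = [t for t in taxa if presence.loc[sample, t]]
        depth = rng_otu.poisson(config.read_depth)
        if present:
            w = rng_otu.dirichlet(np.full(len(present), 0.8)) if len(present) > 1 \
                else np.array([1.0])
            alloc = rng_otu.multinomial(depth, w)
            for t, r in zip(present, alloc):
                reads.loc[f"OTU_{t.replace(' ', '_')}", sample] = r
        # predator reads survive the blocking primers at a low rate
        pred_reads = rng_otu.poisson(config.predator_read_frac * depth)
        reads.loc[predator_otus[f.species], sample] += pred_reads

    # globally rare OTUs: dataset-wide totals kept below the global threshold
    mistag_cells = []
    for o in rare_ids:
        total = int(rng_otu.integers(1, config.rare_otu_max_reads + 1))
        placed = rng_otu.multinomial(total, np.full(len(sample_ids), 1 / len(sample_ids)))
        reads.loc[o] += placed

    # mistag reads: tiny counts of OTUs absent from the sample's true diet
    for sample in sample_ids:
        sample_total = reads[sample].sum()
        # keep injected cells strictly below the 0.01% per-sample threshold;
        # shallow samples (mostly empty stomachs) receive none
        cap = min(config.mistag_max_reads,
                  int(np.floor(sample_total * 0.0001)) - 1)
        absent = [o for o in otu_ids if reads.loc[o, sample] == 0]
        if not absent or cap < 1:
            continue
        pick = rng_otu.choice(len(absent),
                              size=min(config.mistag_cells_per_sample, len(absent)),
                              replace=False)
        for j in pick:
            r = int(rng_otu.integers(1, cap + 1))
            reads.loc[absent[j], sample] = r
            mistag_cells.append((absent[j], sample, r))

    host = fish.set_index("fish_id")["species"]
    otu_coi = OTUTable(reads, pd.Series(taxonomy).reindex(all_otus),
                       "COI", host)

    # ---- rbcL diatom table --------------------------------------------
    diatom_taxa = [
        ("Chaetoceros socialis", "Chaetocerotaceae"),
        ("Chaetoceros spp.", "Chaetocerotaceae"),
        ("Thalassiosira spp.", "Thalassiosiraceae"),
        ("Pseudo-nitzschia spp.", "Bacillariaceae"),
        ("Minidiscus trioculatus", "Thalassiosiraceae"),
        ("Cerataulina pelagica", "Hemiaulaceae"),
        ("Leptocylindrus danicus", "Leptocylindraceae"),
        ("Skeletonema spp.", "Skeletonemataceae"),
    ]
    d_ids = [f"dOTU_{i:02d}" for i in range(len(diatom_taxa) + 2)]
    d_tax = {}
    for o, (sp, fam) in zip(d_ids, diatom_taxa):
        d_tax[o] = f"Bacillariophyta;{fam};{sp}"
    d_tax[d_ids[-2]] = "Bacillariophyta;;"          # no species-level info
    d_tax[d_ids[-1]] = "Chlorophyta;;Green alga"    # non-diatom, filtered out
    d_reads = pd.DataFrame(0, index=d_ids, columns=sample_ids, dtype=int)
    base_p = np.linspace(0.55, 0.1, len(diatom_taxa))
    for sample, f in zip(sample_ids, fish.itertuples()):
        for o, p in zip(d_ids[:-2], base_p):
            if rng_diatom.uniform() < p:
                d_reads.loc[o, sample] = rng_diatom.integers(50, 2000)
        if rng_diatom.uniform() < 0.3:
            d_reads.loc[d_ids[-2], sample] = rng_diatom.integers(50, 500)
        if rng_diatom.uniform() < 0.2:
            d_reads.loc[d_ids[-1], sample] = rng_diatom.integers(50, 500)
    otu_rbcl = OTUTable(d_reads, pd.Series(d_tax).reindex(d_ids), "rbcL", host)

    # ---- isotopes ------------------------------------------------------
    cov = np.asarray(config.isotope_cov, dtype=float)
    iso_rows = []
    for (species, area), grp in fish.groupby(["species", "area"], sort=False):
        mean = np.asarray(config.isotope_means[(species, area)], dtype=float)
        draws = rng_iso.multivariate_normal(mean, cov, size=len(grp))
        lens = grp["total_length"].to_numpy()
        d15n = draws[:, 1] + config.length_slope_d15n * (lens - lens.mean())
        cn = np.maximum(rng_iso.normal(config.cn_mean, config.cn_sd, len(grp)), 2.5)
        for fid, c13, n15, r in zip(grp["fish_id"], draws[:, 0], d15n, cn):
            iso_rows.append({"fish_id": fid, "d13C": c13, "d15N": n15, "CN": r})
    isotopes = pd.DataFrame(iso_rows)

    truth = GroundTruth(
        config=config,
        group_props=truth_props,
        mistag_cells=mistag_cells,
        rare_otus=rare_ids,
        isotope_means=dict(config.isotope_means),
    )
    study = SyntheticStudy(
        fish=fish, gut_counts=gut_counts,
        taxon_to_group=pd.Series(tax_group),
        biomass_mg=pd.Series(tax_mass),
        otu_coi=otu_coi, otu_rbcl=otu_rbcl,
        isotopes=isotopes, ground_truth=truth,
    )
    study.validate()
    return study


def write_tables(study: SyntheticStudy, outdir, config_yaml: bool = True) -> list:
    """Write the four study tables (TSV) plus lookups; returns paths."""
    from pathlib import Path

    from .metabarcoding import write_biom_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    def _save(df: pd.DataFrame, name: str, **kw):
        p = out / name
        df.to_csv(p, sep="\t", **kw)
        paths.append(p)

    _save(study.fish, "fish.tsv", index=False)
    _save(study.gut_counts.rename_axis("fish_id"), "gut_counts.tsv")
    _save(study.taxon_to_group.rename("group").rename_axis("taxon").to_frame(),
          "prey_groups.tsv")
    _save(study.biomass_mg.rename("biomass_mg").rename_axis("taxon").to_frame(),
          "prey_biomass.tsv")
    _save(study.isotopes, "isotopes.tsv", index=False)
    for tbl, name in ((study.otu_coi, "otu_coi.tsv"),
                      (study.otu_rbcl, "otu_rbcl.tsv")):
        p = out / name
        write_biom_tsv(tbl, p)
        paths.append(p)
    if config_yaml:
        p = out / "config.yaml"
        cfg = {k: v for k, v in vars(study.ground_truth.config).items()
               if not isinstance(v, (dict, tuple)) or k in
               {"areas", "species", "depth_range"}}
        cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
        with open(p, "w") as fh:
            yaml.safe_dump(cfg, fh)
        paths.append(p)
    return paths
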