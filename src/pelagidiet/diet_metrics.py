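"""Gut-content metrics for individually examined stomachs.

Per fish: ontogenetic stage from total length (juvenile below 11 cm for
anchovy, 13 cm for sardine; the boundary length is adult) and the stomach
filling degree

    SFD = total prey wet weight (mg) / fish total length (mm),

a size-corrected proxy of feeding intensity.  Per stratum (species x area,
optionally x stage): prey-group composition as %N (numeric), %B (biomass
after count-to-weight conversion with a taxonomic fallback chain) and %FO
(fraction of fish containing the group), computed per sampling site first
and averaged without weights across sites within the area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FishRecord",
    "BiomassLookup",
    "SFDRecord",
    "classify_stage",
    "compute_sfd",
    "counts_to_biomass",
    "composition_summary",
]

JUVENILE_MAX_CM = {"anchovy": 11.0, "sardine": 13.0}
FALLBACK_RANKS = ("species", "genus", "family", "group")


@dataclass(frozen=True)
class FishRecord:
    fish_id: str
    species: str
    area: str
    site_id: str
    latitude: float
    depth: float
    total_length: float  # cm
    stage: str = ""

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ValueError(f"{self.fish_id}: total length must be > 0")
        if self.depth <= 0:
            raise ValueError(f"{self.fish_id}: depth must be > 0")
        derived = classify_stage(self.species, self.total_length)
        if self.stage and self.stage != derived:
            raise ValueError(
                f"{self.fish_id}: stage {self.stage!r} inconsistent with "
                f"length {self.total_length} cm ({derived})")
        object.__setattr__(self, "stage", derived)


@dataclass(frozen=True)
class SFDRecord:
    fish_id: str
    sfd: float  # mg per mm


def classify_stage(species: str, total_length_cm: float) -> str:
    """Juvenile strictly below the species threshold; boundary is adult."""
    if total_length_cm <= 0:
        raise ValueError("total length must be > 0")
    try:
        threshold = JUVENILE_MAX_CM[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}") from None
    return "juvenile" if total_length_cm < threshold else "adult"


class BiomassLookup:
    """Mean individual wet weight (mg) per prey taxon with rank fallback.

    ``values`` maps (rank, name) -> mg; ``taxon_ranks`` maps a taxon label
    to its names at each rank, e.g. ``{"Calanus helgolandicus":
    {"species": "Calanus helgolandicus", "genus": "Calanus",
    "family": "Calanidae", "group": "Calanoids"}}``.  Lookup tries
    species -> genus -> family -> group and records which rank resolved.
    """

    def __init__(self, values: dict, taxon_ranks: dict):
        for key, v in values.items():
            if v <= 0:
                raise ValueError(f"biomass for {key} must be > 0")
        self.values = dict(values)
        self.taxon_ranks = taxon_ranks
        self.provenance: dict[str, str] = {}

    @classmethod
    def flat(cls, taxon_to_mg: dict, taxon_to_group: dict | None = None):
        """Lookup resolved directly at species level (one weight per taxon)."""
        values = {("species", t): v for t, v in taxon_to_mg.items()}
        ranks = {t: {"species": t} for t in taxon_to_mg}
        if taxon_to_group:
            for t, g in taxon_to_group.items():
                ranks.setdefault(t, {})["group"] = g
        return cls(values, ranks)

    def unit_weight(self, taxon: str) -> float:
        ranks = self.taxon_ranks.get(taxon, {"species": taxon})
        for rank in FALLBACK_RANKS:
            name = ranks.get(rank)
            if name is not None and (rank, name) in self.values:
                self.provenance[taxon] = rank
                return self.values[(rank, name)]
        raise KeyError(f"no biomass value resolves for taxon {taxon!r} "
                       f"at any of {FALLBACK_RANKS}")


def compute_sfd(gut_row: pd.Series, fish: FishRecord,
                biomass_lookup: BiomassLookup) -> SFDRecord:
    """Stomach filling degree in mg prey per mm fish length."""
    counts = gut_row[gut_row > 0]
    total_mg = sum(float(c) * biomass_lookup.unit_weight(t)
                   for t, c in counts.items())
    return SFDRecord(fish_id=fish.fish_id,
                     sfd=total_mg / (fish.total_length * 10.0))


def counts_to_biomass(gut_table: pd.DataFrame,
                      biomass_lookup: BiomassLookup) -> pd.DataFrame:
    """Elementwise count x unit weight (mg); fallback ranks recorded in
    ``biomass_lookup.provenance``."""
    units = np.array([biomass_lookup.unit_weight(t) for t in gut_table.columns])
    return gut_table.mul(units, axis=1).astype(float)


def _reject_parasites(taxon_to_group: pd.Series) -> None:
    bad = taxon_to_group[taxon_to_group.astype(str).str.lower() == "parasite"]
    if len(bad):
        raise ValueError(
            f"parasite taxa must be excluded upstream: {list(bad.index)}")


def composition_summary(
    gut_table: pd.DataFrame,
    fish_table: pd.DataFrame,
    taxon_to_group,
    level: str = "N",
    stratify_by=("species", "area"),
    biomass_lookup: BiomassLookup | None = None,
    site_averaged: bool = True,
) -> pd.DataFrame:
    """Prey-group composition (%N, %B or %FO) per stratum.

    ``gut_table``: fish x taxon integer counts, indexed by fish id.
    ``fish_table``: per-fish metadata with the stratify columns and
    ``site_id``.  Percentages are formed per site and averaged without
    weights across sites (each site one vote); ``site_averaged=False``
    pools fish instead.  For %B the per-group biomass is divided by the
    number of fish in the stratum before forming percentages, removing the
    sample-size effect; %FO is the percentage of fish containing at least
    one individual of the group.  Strata with no non-empty stomach are
    omitted with a warning.
    """
    if level not in {"N", "B", "FO"}:
        raise ValueError(f"level must be one of N, B, FO, got {level!r}")
    groups = pd.Series(taxon_to_group).reindex(gut_table.columns)
    if groups.isna().any():
        missing = list(groups[groups.isna()].index)
        raise ValueError(f"taxa without group assignment: {missing[:5]}")
    _reject_parasites(groups)

    if level == "B":
        if biomass_lookup is None:
            raise ValueError("%B requires a biomass lookup")
        values = counts_to_biomass(gut_table, biomass_lookup)
    else:
        values = gut_table.astype(float)
    # fish x group matrix
    by_group = values.T.groupby(groups.values).sum().T

    meta = fish_table.set_index("fish_id") if "fish_id" in fish_table else fish_table
    meta = meta.reindex(by_group.index)
    rows = []
    for stratum, sdf in meta.groupby(list(stratify_by), observed=True):
        block = by_group.loc[sdf.index]
        if (block.sum(axis=1) <= 0).all():
            import warnings
            warnings.warn(f"stratum {stratum}: no non-empty stomach, omitted")
            continue
        n_fish = len(sdf)
        units = sdf.groupby("site_id", observed=True) if site_averaged else [(None, sdf)]
        pct_units = []
        for _, udf in units:
            ub = block.loc[udf.index]
            if level == "FO":
                pct = 100.0 * (ub > 0).mean(axis=0)
            else:
                totals = ub.sum(axis=0)
                if level == "B":
                    totals = totals / n_fish  # sample-size weighting
                s = totals.sum()
                if s <= 0:
                    continue
                pct = 100.0 * totals / s
            pct_units.append(pct)
        mean_pct = pd.concat(pct_units, axis=1).mean(axis=1)
        key = stratum if isinstance(stratum, tuple) else (stratum,)
        for group, v in mean_pct.items():
            rows.append(dict(zip(stratify_by, key)) | {
                "group": group, f"pct_{level}": float(v),
                "n_fish": n_fish, "n_sites": sdf["site_id"].nunique()})
    return pd.DataFrame(rows)
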