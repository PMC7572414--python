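"""Post-clustering OTU-table hygiene and occurrence summaries.

The filter cascade mirrors standard diet-metabarcoding practice for
multiplexed libraries:

1. drop OTUs whose whole-dataset read fraction is strictly below 0.005%
   (global rare-OTU noise);
2. zero cells whose within-sample fraction is strictly below 0.01%
   (mistagging correction — reads mis-assigned between libraries);
3. drop taxonomically uninformative OTUs (unassigned for the zooplankton
   COI marker; non-diatom for the rbcL marker);
4. zero predator-genus OTUs (Engraulis / Sardina) in samples of the
   matching host species;
5. drop COI samples left with fewer than 20 reads.

Threshold comparisons are strict ("below X"): ties are retained.  The
order is fixed and every step is logged.

Downstream, diet is treated as presence/absence: a taxon's %FO in a
stratum is the percentage of samples containing it, averaged across
sampling sites within areas.  Low-occurrence diatom taxa can be merged
into an "Other diatom groups" row by union of presences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "FilterLog",
    "filter_otu_table",
    "occurrence_summary",
    "read_biom_tsv",
    "write_biom_tsv",
]

PREDATOR_GENUS = {"anchovy": "Engraulis", "sardine": "Sardina"}


@dataclass
class OTUTable:
    """OTU x sample read counts with taxonomy, marker and host metadata.

    counts: DataFrame, index = OTU ids, columns = sample ids, integer reads.
    taxonomy: Series indexed by OTU id (ranked, ';'-separated or free text;
    "unassigned" marks no assignment).  host_species: Series indexed by
    sample id with values "anchovy"/"sardine".  marker: "COI" or "rbcL".
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    marker: str
    host_species: pd.Series

    def __post_init__(self) -> None:
        if self.marker not in {"COI", "rbcL"}:
            raise ValueError(f"unknown marker {self.marker!r}")
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        missing = c.index.difference(self.taxonomy.index)
        if len(missing):
            raise ValueError(f"taxonomy missing for OTUs: {list(missing)[:5]}")
        missing = c.columns.difference(self.host_species.index)
        if len(missing):
            raise ValueError(f"host species missing for samples: {list(missing)[:5]}")

    def copy(self) -> "OTUTable":
        return OTUTable(self.counts.copy(), self.taxonomy.copy(),
                        self.marker, self.host_species.copy())

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class FilterLog:
    steps: list = field(default_factory=list)

    def record(self, name: str, otus_removed: int, samples_removed: int,
               reads_removed: int) -> None:
        self.steps.append({
            "filter": name,
            "otus_removed": int(otus_removed),
            "samples_removed": int(samples_removed),
            "reads_removed": int(reads_removed),
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["filter", "otus_removed",
                                     "samples_removed", "reads_removed"])


def _is_diatom(tax: str) -> bool:
    return "Bacillariophyta" in str(tax)


def _is_unassigned(tax: str) -> bool:
    return str(tax).strip().lower() in {"", "unassigned", "na", "none"}


def filter_otu_table(
    table: OTUTable,
    global_min_frac: float = 0.00005,
    sample_min_frac: float = 0.0001,
    min_sample_reads: int = 20,
) -> tuple[OTUTable, FilterLog]:
    """Apply the five-step hygiene cascade; returns the table and a ledger.

    Fractions are proportions (0.00005 == 0.005%).  An empty result is
    returned as an empty table with its log, never raised.
    """
    if global_min_frac < 0 or sample_min_frac < 0 or min_sample_reads < 0:
        raise ValueError("thresholds must be non-negative")
    log = FilterLog()
    counts = table.counts.astype(int).copy()

    # 1. global rare-OTU removal (strictly below global fraction)
    total = counts.to_numpy().sum()
    if total > 0:
        frac = counts.sum(axis=1) / total
        drop = frac < global_min_frac
    else:
        drop = pd.Series(False, index=counts.index)
    reads_dropped = int(counts.loc[drop].to_numpy().sum())
    counts = counts.loc[~drop]
    log.record("global_rare_otus", drop.sum(), 0, reads_dropped)

    # 2. per-sample mistag zeroing (strictly below within-sample fraction)
    samp_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts.div(samp_tot.where(samp_tot > 0, 1), axis=1)
    mistag = (counts > 0) & (frac < sample_min_frac)
    reads_dropped = int(counts.where(mistag, 0).to_numpy().sum())
    counts = counts.where(~mistag, 0)
    empty_otus = counts.sum(axis=1) == 0
    counts = counts.loc[~empty_otus]
    log.record("per_sample_mistag", empty_otus.sum(), 0, reads_dropped)

    # 3. taxonomy filter: COI drops unassigned, rbcL keeps only diatoms
    tax = table.taxonomy.reindex(counts.index)
    if table.marker == "COI":
        drop = tax.map(_is_unassigned)
    else:
        drop = ~tax.map(_is_diatom)
    reads_dropped = int(counts.loc[drop].to_numpy().sum())
    counts = counts.loc[~drop]
    log.record("taxonomy_filter", drop.sum(), 0, reads_dropped)

    # 4. predator-genus OTUs zeroed in samples of that host species
    tax = table.taxonomy.reindex(counts.index)
    reads_dropped = 0
    for host, genus in PREDATOR_GENUS.items():
        otu_mask = tax.astype(str).str.contains(genus, na=False)
        samp_mask = table.host_species.reindex(counts.columns) == host
        if otu_mask.any() and samp_mask.any():
            block = counts.loc[otu_mask.to_numpy(), samp_mask.to_numpy()]
            reads_dropped += int(block.to_numpy().sum())
            counts.loc[otu_mask.to_numpy(), samp_mask.to_numpy()] = 0
    empty_otus = counts.sum(axis=1) == 0
    counts = counts.loc[~empty_otus]
    log.record("predator_otus", empty_otus.sum(), 0, reads_dropped)

    # 5. low-read sample removal (zooplankton marker only)
    if table.marker == "COI":
        samp_tot = counts.sum(axis=0)
        drop_s = samp_tot < min_sample_reads
        reads_dropped = int(counts.loc[:, drop_s].to_numpy().sum())
        counts = counts.loc[:, ~drop_s]
        log.record("low_read_samples", 0, drop_s.sum(), reads_dropped)
    else:
        log.record("low_read_samples", 0, 0, 0)

    out = OTUTable(counts, table.taxonomy.reindex(counts.index),
                   table.marker, table.host_species.reindex(counts.columns))
    return out, log


# ---------------------------------------------------------------------------
# occurrence summaries


def _has_species_level(tax: str) -> bool:
    # ranked strings like "...;Genus;Genus species" — species = last rank
    # non-empty and not a placeholder
    last = str(tax).split(";")[-1].strip()
    return bool(last) and not last.lower().startswith(("unclassified", "unknown", "sp."))


def _display_label(tax: str) -> str:
    parts = [p.strip() for p in str(tax).split(";") if p.strip()]
    return parts[-1] if parts else str(tax)


def occurrence_summary(
    table: OTUTable,
    sample_meta: pd.DataFrame,
    groupby=("species", "area"),
    site_col: str = "site_id",
    diatom_percentile: float = 70.0,
    merge_rule: str = "percentile",
) -> pd.DataFrame:
    """Per-taxon %FO per stratum from a filtered OTU table.

    Presence = read count > 0.  Within each stratum (groupby columns of
    ``sample_meta``, indexed by sample id) the per-site %FO is computed
    first and then averaged without weights across sites.

    For the diatom (rbcL) marker, taxa whose *overall* occurrence frequency
    falls strictly below the given percentile of the non-zero occurrence
    vector are merged as "Other diatom groups" (presence-union before %FO);
    ``merge_rule="total_share"`` instead merges taxa holding < ``diatom_percentile``
    percent of total occurrences.  OTUs without species-level taxonomy are
    reported as "Diatom remains".
    """
    counts = table.counts
    if counts.shape[1] == 0:
        raise ValueError("no samples in table")
    presence = (counts > 0).astype(int)

    # collapse OTUs to display taxon labels (deepest assigned rank)
    labels = table.taxonomy.reindex(presence.index).astype(str)
    if table.marker == "rbcL":
        labels = labels.where(labels.map(_has_species_level), "Diatom remains")
    labels = labels.map(_display_label)
    pres_tax = presence.groupby(labels.values).max()

    if table.marker == "rbcL":
        overall = 100.0 * pres_tax.mean(axis=1)
        nonzero = overall[overall > 0]
        merge_mask = pd.Series(False, index=pres_tax.index)
        mergeable = ~pres_tax.index.isin(["Diatom remains"])
        if merge_rule == "percentile" and len(nonzero):
            thr = np.percentile(nonzero.to_numpy(), diatom_percentile)
            merge_mask = (overall < thr) & mergeable
        elif merge_rule == "total_share":
            share = 100.0 * pres_tax.sum(axis=1) / max(pres_tax.to_numpy().sum(), 1)
            merge_mask = (share < diatom_percentile) & mergeable
        if merge_mask.any():
            merged = pres_tax.loc[merge_mask].max(axis=0)
            pres_tax = pres_tax.loc[~merge_mask]
            pres_tax.loc["Other diatom groups"] = merged

    meta = sample_meta.reindex(pres_tax.columns)
    rows = []
    for stratum, sdf in meta.groupby(list(groupby), observed=True):
        site_fo = []
        for _, site_df in sdf.groupby(site_col, observed=True):
            cols = site_df.index
            site_fo.append(100.0 * pres_tax[cols].mean(axis=1))
        fo = pd.concat(site_fo, axis=1).mean(axis=1)
        for taxon, v in fo.items():
            key = stratum if isinstance(stratum, tuple) else (stratum,)
            rows.append(dict(zip(groupby, key)) | {"taxon": taxon, "FO": float(v),
                        "n_samples": len(sdf), "n_sites": sdf[site_col].nunique()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BIOM-TSV I/O (OTU rows, sample columns, trailing taxonomy column)


def write_biom_tsv(table: OTUTable, path) -> None:
    df = table.counts.copy()
    df["taxonomy"] = table.taxonomy.reindex(df.index)
    df.index.name = "#OTU ID"
    with open(path, "w") as fh:
        fh.write("# Constructed from biom file\n")
        df.to_csv(fh, sep="\t")


def read_biom_tsv(path, marker: str, host_species: pd.Series) -> OTUTable:
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=lambda i: i == 0,
                     index_col=0)
    df.index.name = None
    tax = df.pop("taxonomy")
    return OTUTable(df.astype(int), tax, marker, host_species)
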