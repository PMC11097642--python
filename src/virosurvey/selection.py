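"""Run-metadata eligibility filtering and balanced sample selection.

A comparative survey built on public sequencing archives needs three things
before any statistics: harmonised binomial species names, eligibility
filters on the run metadata (transcriptomic strategy, read length, depth),
and a sampling scheme that keeps one run per species, caps the number of
species per phylum, and prefers smaller data sets so rare phyla are fully
represented while deep archives do not dominate.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

__all__ = [
    "HABITAT_CATEGORIES",
    "harmonize_species_name",
    "filter_eligible",
    "sample_selection",
    "assign_habitat",
]

logger = logging.getLogger(__name__)

HABITAT_CATEGORIES = frozenset(
    {"brackish", "freshwater", "intertidal zone", "marine", "terrestrial"}
)

REQUIRED_FIELDS = (
    "run_accession", "species_name", "phylum",
    "library_strategy", "avg_read_length", "total_bases",
)

MIN_READ_LENGTH = 75.0
MIN_TOTAL_BASES = 3e9
SIZE_PRIORITY_THRESHOLD = 30e9

_RANK_ABBREV = {"sp.", "spp.", "cf.", "aff."}


def harmonize_species_name(raw_name: str) -> str:
    """Reduce a raw archive organism name to a binomial.

    Keeps the first two rank-bearing words (genus + lowercase epithet),
    dropping strain/isolate qualifiers. A name whose species-level epithet is
    absent or uncertain (single token, or an abbreviation like 'sp.')
    becomes ``Genus sp.``. Idempotent.
    """
    if not isinstance(raw_name, str) or not raw_name.strip():
        raise ValueError("species name must be a non-empty string")
    tokens = raw_name.strip().split()
    genus = tokens[0]
    if len(tokens) == 1:
        return f"{genus} sp."
    epithet = tokens[1]
    if epithet in _RANK_ABBREV:
        return f"{genus} sp."
    # A valid epithet is a lowercase latinate word; anything else (strain
    # codes, 'strain', numbers, uppercase) means species-level uncertainty
    # stops at the genus.
    if re.fullmatch(r"[a-z][a-z-]+", epithet):
        return f"{genus} {epithet}"
    return f"{genus} sp."


def filter_eligible(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the three eligibility criteria to a run-metadata table.

    Retains records with library strategy RNA-Seq, average read length >= 75
    bases, and total sequenced bases strictly greater than 3 Gbases (the
    length bound is inclusive, the base-count bound strict). Records with
    missing required fields are excluded and reported via logging. Row order
    is preserved; the operation is idempotent.
    """
    missing_cols = [c for c in REQUIRED_FIELDS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"run table lacks required columns: {missing_cols}")
    ok_fields = records[list(REQUIRED_FIELDS)].notna().all(axis=1)
    for acc in records.loc[~ok_fields, "run_accession"].fillna("<no accession>"):
        logger.warning("record %s excluded: missing required field(s)", acc)
    rec = records[ok_fields]
    mask = (
        (rec["library_strategy"] == "RNA-Seq")
        & (rec["avg_read_length"].astype(float) >= MIN_READ_LENGTH)
        & (rec["total_bases"].astype(float) > MIN_TOTAL_BASES)
    )
    return rec[mask]


def sample_selection(
    records: pd.DataFrame,
    max_per_phylum: int = 20,
    size_priority_threshold: float = SIZE_PRIORITY_THRESHOLD,
    overrides: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Select at most one run per species and cap species counts per phylum.

    Within each species, runs below ``size_priority_threshold`` bases are
    exhausted before any larger run can be chosen; within each phylum,
    species whose chosen run is below the threshold fill the cap before any
    species whose only eligible runs are larger. Choices are uniform at
    random under those constraints and deterministic under ``seed``.
    ``overrides`` raises or lowers the cap for named phyla
    (e.g. ``{"Mollusca": 39}``). Empty input yields empty output.
    """
    overrides = overrides or {}
    if records.empty:
        return records.copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rec = records.copy()
    rec["_species"] = rec["species_name"].map(harmonize_species_name)

    chosen_rows: list[pd.DataFrame] = []
    for phylum in sorted(rec["phylum"].dropna().unique()):
        sub = rec[rec["phylum"] == phylum]
        cap = overrides.get(phylum, max_per_phylum)
        # one run per species: small runs first, uniformly within the tier
        per_species: dict[str, pd.Series] = {}
        small_species: list[str] = []
        large_species: list[str] = []
        for species in sorted(sub["_species"].unique()):
            runs = sub[sub["_species"] == species]
            small = runs[runs["total_bases"].astype(float) < size_priority_threshold]
            pool = small if not small.empty else runs
            pick = pool.iloc[int(rng.integers(len(pool)))]
            per_species[species] = pick
            (small_species if not small.empty else large_species).append(species)
        selected: list[str] = []
        for tier in (small_species, large_species):
            space = cap - len(selected)
            if space <= 0:
                break
            if len(tier) <= space:
                selected.extend(tier)
            else:
                idx = rng.choice(len(tier), size=space, replace=False)
                selected.extend(tier[i] for i in sorted(idx))
        chosen_rows.extend(per_species[s].to_frame().T for s in selected)
    if not chosen_rows:
        return rec.iloc[0:0].drop(columns="_species")
    out = pd.concat(chosen_rows).drop(columns="_species")
    return out.astype(records.dtypes.to_dict())


def assign_habitat(
    record: pd.Series,
    ecology_table: dict[str, str],
) -> str:
    """Look up a record's habitat in a user-supplied species -> habitat table.

    Returns one of the five closed habitat categories, or ``"missing"`` (with
    a logged warning) when the species is absent from the table. A table
    entry outside the category set is a validation error.
    """
    species = harmonize_species_name(record["species_name"])
    if species not in ecology_table:
        logger.warning("no habitat information for species %s; labelled missing", species)
        return "missing"
    label = ecology_table[species]
    if label not in HABITAT_CATEGORIES:
        raise ValueError(
            f"habitat {label!r} for {species} is outside the five-category set "
            f"{sorted(HABITAT_CATEGORIES)}"
        )
    return label
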