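"""Aggregation of per-read classifier calls into family count matrices.

The upstream protein-level classifier emits one line per read: a status
(C = classified, U = unclassified), the read id, and the matched taxon id.
This module tallies classified reads into viral-family counts via a
taxon-id -> family map, routes reads without a family-rank taxon into a
reserved "uncertain family" bucket, partitions families by host domain
(eukaryote / prokaryote+archaea / uncertain), and round-trips count
matrices as TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "UNCERTAIN_FAMILY",
    "HOST_DOMAINS",
    "aggregate_hits",
    "read_classifier_lines",
    "partition_by_host_domain",
    "read_count_matrix",
    "write_count_matrix",
    "read_annotation",
]

logger = logging.getLogger(__name__)

UNCERTAIN_FAMILY = "UNCERTAIN_FAMILY"
HOST_DOMAINS = ("eukaryote", "prokaryote_archaea", "uncertain")

MALFORMED_TOLERANCE = 0.01


def read_classifier_lines(path: str | Path) -> Iterable[tuple[str, ...]]:
    """Yield raw field tuples from a 3-column classifier output TSV."""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                yield tuple(line.split("\t"))


def aggregate_hits(
    lines: Iterable[tuple[str, ...]],
    taxmap: dict[int, str],
) -> pd.Series:
    """Tally classified reads into per-family counts.

    ``taxmap`` maps taxon ids to family names; ids mapped to the reserved
    uncertain bucket (or absent from the map entirely, with a warning) count
    toward ``UNCERTAIN_FAMILY``. U-status lines contribute nothing.
    Malformed lines are skipped with a counted warning; if more than 1% of
    lines are malformed the aggregation is aborted.
    """
    counts: dict[str, int] = {UNCERTAIN_FAMILY: 0}
    for fam in taxmap.values():
        counts.setdefault(fam, 0)
    n_lines = 0
    n_malformed = 0
    unknown_ids: set[int] = set()
    for fields in lines:
        n_lines += 1
        if not fields or fields[0] not in ("C", "U"):
            n_malformed += 1
            continue
        if fields[0] == "U":
            continue
        if len(fields) < 3:
            n_malformed += 1
            continue
        try:
            taxon = int(fields[2])
        except ValueError:
            n_malformed += 1
            continue
        family = taxmap.get(taxon)
        if family is None:
            unknown_ids.add(taxon)
            family = UNCERTAIN_FAMILY
        counts[family] = counts.get(family, 0) + 1
    if unknown_ids:
        logger.warning(
            "%d taxon ids absent from the taxon map routed to %s",
            len(unknown_ids), UNCERTAIN_FAMILY,
        )
    if n_malformed:
        logger.warning("%d of %d classifier lines malformed and skipped",
                       n_malformed, n_lines)
        if n_lines and n_malformed / n_lines > MALFORMED_TOLERANCE:
            raise ValueError(
                f"{n_malformed}/{n_lines} classifier lines malformed "
                f"(> {MALFORMED_TOLERANCE:.0%} tolerance)"
            )
    return pd.Series(counts, dtype=np.int64).sort_index()


def partition_by_host_domain(
    counts: pd.DataFrame,
    annotation: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a count matrix by viral host domain.

    ``annotation`` maps each family to 'eukaryote', 'prokaryote_archaea' or
    'uncertain' (the reserved uncertain-family bucket is always 'uncertain').
    Returns the eukaryotic submatrix (non-eukaryote families and the
    uncertain bucket dropped) and a per-sample fraction table with columns
    eukaryote / prokaryote_archaea / uncertain summing to 1. Samples with
    zero viral reads get NaN fractions and are flagged via logging.
    """
    annotation = annotation.copy()
    annotation[UNCERTAIN_FAMILY] = "uncertain"
    missing = [f for f in counts.columns if f not in annotation.index]
    if missing:
        raise ValueError(f"families lacking host-domain annotation: {missing}")
    bad = annotation[~annotation.isin(HOST_DOMAINS)]
    if not bad.empty:
        raise ValueError(f"invalid host domains: {bad.to_dict()}")

    domains = annotation.reindex(counts.columns)
    totals = counts.sum(axis=1).astype(float)
    fractions = pd.DataFrame(index=counts.index, columns=list(HOST_DOMAINS), dtype=float)
    for domain in HOST_DOMAINS:
        fractions[domain] = counts.loc[:, (domains == domain).to_numpy()].sum(axis=1) / totals
    empty = totals.index[totals == 0].tolist()
    if empty:
        logger.warning("samples with zero viral reads (fractions undefined): %s", empty)

    euk = counts.loc[:, (domains == "eukaryote").to_numpy()]
    return euk, fractions


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x families integer count matrix as TSV."""
    counts.to_csv(path, sep="\t", index_label="sample_id")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples x families count matrix TSV written by this module.

    Validates integrality and non-negativity cell by cell (errors name the
    offending sample and family) and rejects duplicate sample or family ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate family ids: {dups}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        if bad.any().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric count at sample {df.index[r]!r}, family {df.columns[c]!r}"
            )
        df, arr = coerced, coerced.to_numpy()
    neg = arr < 0
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise ValueError(
            f"negative count at sample {df.index[r]!r}, family {df.columns[c]!r}"
        )
    frac = arr != np.floor(arr)
    if frac.any():
        r, c = np.argwhere(frac)[0]
        raise ValueError(
            f"non-integer count at sample {df.index[r]!r}, family {df.columns[c]!r}"
        )
    return df.astype(np.int64)


def read_annotation(path: str | Path) -> pd.Series:
    """Read a 2-column family -> host-domain annotation TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["family", "host_domain"],
                     comment="#")
    ann = df.set_index("family")["host_domain"]
    bad = ann[~ann.isin(HOST_DOMAINS)]
    if not bad.empty:
        raise ValueError(f"invalid host domains in {path}: {bad.to_dict()}")
    return ann
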