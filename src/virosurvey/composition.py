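"""Compositional treatment of virome count matrices.

A sample's virome is treated as a composition: only the relative abundances
of the viral families carry information, not the sequencing depth. The
canonical pipeline implemented here is

    counts -> relative abundances -> rare-family filter -> count-zero
    multiplicative (CZM) zero replacement -> centred log-ratio (clr)
    -> Euclidean (Aitchison) distances

in that order. The clr transform maps the strictly positive simplex to a
zero-sum real space where ordinary Euclidean geometry is meaningful for
compositions; all downstream multivariate testing operates on these
coordinates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "to_relative_abundance",
    "filter_families",
    "czm_replace_zeros",
    "clr_transform",
    "aitchison_distances",
    "centroid_distances",
    "aggregate_by_group",
    "clr_pipeline",
    "linkage_to_newick",
]


def to_relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise a count matrix (samples x families) to the unit simplex.

    Raises ``ValueError`` listing offending samples if any row sums to zero.
    """
    counts = _as_numeric_frame(counts)
    totals = counts.sum(axis=1)
    zero_rows = totals.index[totals <= 0].tolist()
    if zero_rows:
        raise ValueError(f"samples with zero total counts: {zero_rows}")
    return counts.div(totals, axis=0)


def filter_families(relabund: pd.DataFrame, min_mean: float = 1e-4) -> pd.DataFrame:
    """Drop families whose mean relative abundance is below ``min_mean``.

    The default 1e-4 is the 0.01% mean-abundance threshold; the boundary is
    inclusive (a family at exactly ``min_mean`` is retained). Rows are
    renormalised afterwards so the output is again a composition.
    """
    means = relabund.mean(axis=0)
    keep = means.index[means >= min_mean]
    if len(keep) == 0:
        raise ValueError("family filter removed every family")
    filtered = relabund[keep]
    return filtered.div(filtered.sum(axis=1), axis=0)


def czm_replace_zeros(
    relabund: pd.DataFrame,
    depths: pd.Series | np.ndarray,
    label: float = 0.65,
) -> pd.DataFrame:
    """Count-zero multiplicative replacement of zeros in compositions.

    Each zero in sample *i* is imputed with a fraction of that sample's
    count-based detection limit, delta_i = label / (depth_i + 1); the nonzero
    parts are shrunk multiplicatively by (1 - z_i * delta_i), where z_i is the
    number of zeros in the row, so their ratios are preserved exactly and the
    row still sums to one.

    Parameters
    ----------
    relabund : DataFrame
        Samples x families relative abundances (rows on the simplex).
    depths : Series or array
        Per-sample total read counts used to set the detection limit; must be
        positive and aligned with ``relabund`` rows.
    label : float
        Fraction of the detection limit used for imputation, in (0, 1).
    """
    if not 0 < label < 1:
        raise ValueError(f"label must be in (0, 1), got {label}")
    depths = np.asarray(pd.Series(depths).reindex(relabund.index).to_numpy()
                        if isinstance(depths, pd.Series) else depths, dtype=float)
    if depths.shape != (relabund.shape[0],):
        raise ValueError("depths must align with the rows of the matrix")
    if np.any(depths <= 0) or np.any(~np.isfinite(depths)):
        raise ValueError("depths must be positive and finite")

    x = relabund.to_numpy(dtype=float).copy()
    delta = label / (depths + 1.0)
    zeros = x == 0.0
    n_zero = zeros.sum(axis=1)
    with np.errstate(invalid="ignore"):
        smallest_nonzero = np.where(
            (~zeros).any(axis=1), np.where(zeros, np.inf, x).min(axis=1), np.inf
        )
    bad = delta >= smallest_nonzero
    if np.any(bad & (n_zero > 0)):
        offenders = relabund.index[bad & (n_zero > 0)].tolist()
        warnings.warn(
            f"imputed value exceeds the smallest observed part for samples {offenders}",
            stacklevel=2,
        )
    shrink = 1.0 - n_zero * delta
    if np.any(shrink <= 0):
        raise ValueError("imputation mass exceeds 1; depths too small for zero count")
    x = x * shrink[:, None]
    x[zeros] = np.broadcast_to(delta[:, None], x.shape)[zeros]
    return pd.DataFrame(x, index=relabund.index, columns=relabund.columns)


def clr_transform(relabund: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio transform: log of each part over the row geometric mean.

    Requires strictly positive entries (run zero replacement first). Output
    rows sum to zero.
    """
    x = relabund.to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ValueError("clr requires strictly positive compositions; impute zeros first")
    logs = np.log(x)
    out = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=relabund.index, columns=relabund.columns)


def aitchison_distances(clr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between clr rows (the Aitchison metric)."""
    d = squareform(pdist(clr.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=clr.index, columns=clr.index)


def clr_pipeline(
    counts: pd.DataFrame,
    min_mean: float = 1e-4,
    label: float = 0.65,
) -> pd.DataFrame:
    """Full counts -> clr pipeline: relative abundance, family filter, CZM, clr.

    The detection limit for zero replacement uses the per-sample total counts
    of the input matrix (before filtering), as those are the depths at which
    the zeros were observed.
    """
    depths = counts.sum(axis=1).astype(float)
    rel = to_relative_abundance(counts)
    rel = filter_families(rel, min_mean=min_mean)
    rel = czm_replace_zeros(rel, depths.to_numpy(), label=label)
    return clr_transform(rel)


def centroid_distances(
    clr: pd.DataFrame,
    groups: pd.Series,
    min_group_size: int = 1,
) -> pd.DataFrame:
    """Distance of each sample to its own group centroid in clr space.

    The centroid is the arithmetic mean of the group's clr rows. Groups with
    fewer than ``min_group_size`` samples are dropped (the survey default for
    phylum-level analysis is 15).
    """
    groups = groups.reindex(clr.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    sizes = groups.value_counts()
    keep = sizes.index[sizes >= min_group_size]
    rows = []
    for g in keep:
        sub = clr.loc[groups == g]
        centroid = sub.mean(axis=0).to_numpy()
        dist = np.linalg.norm(sub.to_numpy() - centroid, axis=1)
        rows.append(pd.DataFrame({"sample_id": sub.index, "group": g, "distance": dist}))
    if not rows:
        raise ValueError("no group meets the minimum size")
    return pd.concat(rows, ignore_index=True)


def aggregate_by_group(
    relabund: pd.DataFrame,
    groups: pd.Series,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Equal-sample-weight group profiles in clr space plus Ward2 dendrograms.

    Each group's profile is the arithmetic mean of its samples' (strictly
    positive) relative-abundance vectors, renormalised and clr-transformed;
    every sample contributes the same weight regardless of depth. Returns the
    group x family clr matrix and two scipy linkage matrices from Ward.D2
    agglomeration on Euclidean distances: one over groups, one over families.
    Singleton groups are allowed.
    """
    if (relabund.to_numpy() <= 0).any():
        raise ValueError("aggregate_by_group expects strictly positive compositions")
    groups = groups.reindex(relabund.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    profiles = relabund.groupby(groups, sort=True).mean()
    profiles = profiles.div(profiles.sum(axis=1), axis=0)
    clr = clr_transform(profiles)
    link_groups = _ward2(clr.to_numpy())
    link_families = _ward2(clr.to_numpy().T)
    return clr, link_groups, link_families


def _ward2(x: np.ndarray) -> np.ndarray:
    # scipy's "ward" on raw observations is the Ward.D2 criterion on
    # Euclidean distances; single-row inputs get an empty linkage.
    if x.shape[0] < 2:
        return np.empty((0, 4))
    return hierarchy.linkage(x, method="ward")


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix to a Newick string with branch lengths."""
    if len(labels) == 1:
        return f"{labels[0]}:0;"
    tree = hierarchy.to_tree(link)

    def recurse(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return recurse(tree, tree.dist) + ";"


def _as_numeric_frame(df: pd.DataFrame) -> pd.DataFrame:
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("count matrix must be numeric")
    if (arr < 0).any():
        raise ValueError("count matrix must be non-negative")
    return df.astype(float)
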