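"""Quantitative bipartite virus-host network structure.

The interaction matrix has host taxa as rows, viral families as columns and
interaction intensities (relative abundances or presence fractions) as
weights. Implemented indices:

* quantitative linkage density — marginal-weighted mean effective number of
  partners per node, with effective partner counts from the exponential of
  the Shannon entropy of each node's interaction weights;
* H2' — network-level specialization: the two-dimensional interaction
  entropy standardised between its maximum (the independence table given
  the marginals) and a greedy-packing minimum, 0 = fully generalised,
  1 = fully specialised;
* NODF — nestedness by overlap and decreasing fill on the binarised matrix,
  0-100;
* Barber Q — bipartite modularity against the marginal-product null,
  maximised by seeded label propagation with restarts;
* d' — node-level specialization: Kullback-Leibler divergence of a node's
  interaction profile from partner availability, standardised to [0, 1].

Null expectations come from the Patefield algorithm (uniform integer tables
with fixed marginals, the "r2d" model); observed indices are compared to
the null ensemble with z-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "build_bipartite",
    "presence_filter",
    "linkage_density",
    "h2_prime",
    "nodf",
    "q_modularity",
    "d_prime",
    "patefield_null",
    "null_ztest",
    "dprime_anova",
    "BipartiteAnalysis",
    "BipartiteResults",
]


# --------------------------------------------------------------------------
# matrix construction
# --------------------------------------------------------------------------

def build_bipartite(
    relabund: pd.DataFrame,
    mode: str = "abundance",
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Build the host x viral-family interaction matrix.

    ``mode='abundance'`` uses relative abundances (per sample, or the
    equal-weight per-group mean when ``groups`` is given);
    ``mode='presence_fraction'`` needs ``groups`` and uses the fraction of
    the group's samples where the family has a positive weight. All-zero
    rows and columns are dropped.
    """
    if relabund.empty:
        raise ValueError("empty abundance matrix")
    if mode == "abundance":
        m = (relabund.groupby(groups.reindex(relabund.index)).mean()
             if groups is not None else relabund.copy())
    elif mode == "presence_fraction":
        if groups is None:
            raise ValueError("presence_fraction mode requires group labels")
        m = (relabund > 0).groupby(groups.reindex(relabund.index)).mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    m = m.loc[m.sum(axis=1) > 0, m.sum(axis=0) > 0]
    if m.empty:
        raise ValueError("interaction matrix is empty after dropping zero margins")
    return m


def presence_filter(
    relabund: pd.DataFrame,
    groups: pd.Series,
    min_fraction: float = 0.2,
) -> pd.DataFrame:
    """Keep families present in at least ``min_fraction`` of the samples of
    at least one group."""
    frac = (relabund > 0).groupby(groups.reindex(relabund.index)).mean()
    keep = frac.columns[(frac >= min_fraction).any(axis=0)]
    return relabund[keep]


# --------------------------------------------------------------------------
# indices
# --------------------------------------------------------------------------

def _validated(m) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("interaction matrix must be a non-empty 2-D array")
    if (a < 0).any() or not np.isfinite(a).all():
        raise ValueError("interaction weights must be finite and non-negative")
    if a.sum() == 0:
        raise ValueError("interaction matrix has zero total weight")
    return a


def _effective_partners(weights: np.ndarray) -> float:
    w = weights[weights > 0]
    p = w / w.sum()
    return float(np.exp(-(p * np.log(p)).sum()))


def linkage_density(m) -> float:
    """Quantitative linkage density.

    Half the sum, over both margins, of the marginal-weighted effective
    partner counts: LD = 1/2 * sum_i (r_i/F) n_i + 1/2 * sum_j (c_j/F) n_j,
    where n is the exponential Shannon entropy of the node's interaction
    weights. A single full diagonal gives 1; a uniform complete 2x2 gives 2.
    """
    a = _validated(m)
    total = a.sum()
    rows = sum(a[i].sum() / total * _effective_partners(a[i])
               for i in range(a.shape[0]) if a[i].sum() > 0)
    cols = sum(a[:, j].sum() / total * _effective_partners(a[:, j])
               for j in range(a.shape[1]) if a[:, j].sum() > 0)
    return 0.5 * (rows + cols)


def _greedy_min_entropy(r: np.ndarray, c: np.ndarray) -> float:
    """Greedy marginal-packing heuristic for the minimum-entropy table.

    Repeatedly allocates min(remaining row, remaining column) to the cell of
    the currently largest remaining margins. Ties break on the lowest index.
    """
    r = r.astype(float).copy()
    c = c.astype(float).copy()
    cells = []
    while r.max() > 1e-15 and c.max() > 1e-15:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        amount = min(r[i], c[j])
        cells.append(amount)
        r[i] -= amount
        c[j] -= amount
    p = np.asarray(cells)
    p = p[p > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def h2_prime(m) -> float:
    """Network-level specialization H2' in [0, 1].

    H2 is the Shannon entropy of the normalised interaction matrix; it is
    standardised between H2_max (the independence table, i.e. the entropy of
    the row marginal plus that of the column marginal) and H2_min (a greedy
    marginal-packing table): H2' = (H2_max - H2)/(H2_max - H2_min). A
    degenerate matrix with no specialization freedom returns 0 with a
    warning.
    """
    a = _validated(m)
    p = a / a.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    flat = p[p > 0]
    h2 = float(-(flat * np.log(flat)).sum())
    h2_max = float(-(r[r > 0] * np.log(r[r > 0])).sum()
                   - (c[c > 0] * np.log(c[c > 0])).sum())
    h2_min = _greedy_min_entropy(r, c)
    if h2_max - h2_min < 1e-12:
        warnings.warn("degenerate matrix: no specialization freedom; H2' set to 0",
                      stacklevel=2)
        return 0.0
    return float(np.clip((h2_max - h2) / (h2_max - h2_min), 0.0, 1.0))


def nodf(m, variant: str = "NODF2") -> float:
    """Nestedness by overlap and decreasing fill, 0-100.

    The matrix is binarised (weight > 0) and, in the NODF2 variant, rows and
    columns are sorted by decreasing fill first. For every pair of rows (and
    of columns) the paired overlap is the fraction of the poorer node's
    links shared with the richer node, times 100 — but only when the richer
    node's fill strictly exceeds the poorer's; equal fills contribute 0.
    NODF is the mean over all n(n-1)/2 + m(m-1)/2 pairs.
    """
    if variant != "NODF2":
        raise ValueError(f"unknown NODF variant {variant!r}")
    a = _validated(m) > 0
    if not a.any():
        raise ValueError("matrix empty after binarisation")
    a = a[np.argsort(-a.sum(axis=1), kind="stable")]
    a = a[:, np.argsort(-a.sum(axis=0), kind="stable")]

    def axis_pairs(b: np.ndarray) -> tuple[float, int]:
        fills = b.sum(axis=1)
        total = 0.0
        count = 0
        for i in range(b.shape[0]):
            for j in range(i + 1, b.shape[0]):
                count += 1
                hi, lo = (i, j) if fills[i] >= fills[j] else (j, i)
                if fills[hi] > fills[lo] and fills[lo] > 0:
                    shared = np.logical_and(b[hi], b[lo]).sum()
                    total += 100.0 * shared / fills[lo]
        return total, count

    row_sum, row_pairs = axis_pairs(a)
    col_sum, col_pairs = axis_pairs(a.T)
    n_pairs = row_pairs + col_pairs
    if n_pairs == 0:
        raise ValueError("NODF undefined for a single-row single-column matrix")
    return (row_sum + col_sum) / n_pairs


def q_modularity(
    m,
    n_restarts: int = 10,
    seed: int | None = None,
) -> tuple[float, dict]:
    """Barber bipartite modularity and the best module assignment.

    Q = (1/F) sum_ij (A_ij - r_i c_j / F) delta(g_i, g_j) with F the total
    weight. Optimised by label propagation over both node sets with random
    restarts and greedy local moves; the one-module partition (Q = 0) is the
    admissible floor, so the returned Q is never negative. Deterministic
    under ``seed``.

    Returns (Q, assignment) where assignment maps ``("row", i)`` and
    ``("col", j)`` node keys to module ids.
    """
    a = _validated(m)
    total = a.sum()
    r = a.sum(axis=1)
    c = a.sum(axis=0)
    b = (a - np.outer(r, c) / total) / total  # contribution matrix, sums to 0
    n_rows, n_cols = a.shape
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def q_of(row_lab: np.ndarray, col_lab: np.ndarray) -> float:
        return float(b[row_lab[:, None] == col_lab[None, :]].sum())

    def sweep(b_side: np.ndarray, own_lab: np.ndarray, other_lab: np.ndarray,
              n_modules: int) -> tuple[np.ndarray, bool]:
        # gains of every own-side node in every module: one matrix product,
        # exact because the other side's labels are fixed during the sweep
        onehot = np.zeros((b_side.shape[1], n_modules))
        onehot[np.arange(b_side.shape[1]), other_lab] = 1.0
        gains = b_side @ onehot
        best = gains.argmax(axis=1)          # ties -> lowest module id
        best_gain = gains[np.arange(len(best)), best]
        cur_gain = gains[np.arange(len(best)), own_lab]
        # the spare all-empty module (gain 0) lets a node leave a module that
        # has become unfavourable; no explicit "move alone" case is needed
        new = own_lab.copy()
        move = best_gain > cur_gain + 1e-15
        new[move] = best[move]
        return new, bool(move.any())

    def optimize(row_lab: np.ndarray, col_lab: np.ndarray):
        for _ in range(200):
            labs = np.concatenate([row_lab, col_lab])
            _, packed = np.unique(labs, return_inverse=True)
            n_modules = int(packed.max()) + 1 + 1  # one spare empty module
            row_lab = packed[:n_rows]
            col_lab = packed[n_rows:]
            row_lab, moved_r = sweep(b, row_lab, col_lab, n_modules)
            col_lab, moved_c = sweep(b.T, col_lab, row_lab,
                                     int(max(row_lab.max(), col_lab.max())) + 2)
            if not (moved_r or moved_c):
                break
        return row_lab, col_lab

    best_q = 0.0
    best_assign = (np.zeros(n_rows, dtype=int), np.zeros(n_cols, dtype=int))
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            row_lab = np.arange(n_rows)
            col_lab = np.asarray(b.argmax(axis=0))
        else:
            k = int(rng.integers(2, max(3, min(n_rows, n_cols) + 1)))
            row_lab = rng.integers(0, k, size=n_rows)
            col_lab = rng.integers(0, k, size=n_cols)
        row_lab, col_lab = optimize(row_lab, col_lab)
        q = q_of(row_lab, col_lab)
        if q > best_q + 1e-15:
            best_q = q
            best_assign = (row_lab.copy(), col_lab.copy())
    row_lab, col_lab = best_assign
    relabel = {old: new for new, old in
               enumerate(dict.fromkeys(np.concatenate([row_lab, col_lab])))}
    assignment = {("row", i): relabel[row_lab[i]] for i in range(n_rows)}
    assignment.update({("col", j): relabel[col_lab[j]] for j in range(n_cols)})
    return best_q, assignment


def d_prime(m, margin: str = "rows") -> np.ndarray:
    """Node-level standardised specialization d' in [0, 1] for one margin.

    For a node with interaction profile p (its normalised weights) and
    partner availability q (the partner marginal distribution), d is the
    Kullback-Leibler divergence KL(p || q). It is standardised by the
    extremes attainable given the node's total and the partner marginals:
    d_min = 0 (allocation proportional to availability is always feasible)
    and d_max from packing the node's total onto the rarest partners, each
    cell capped by the partner's marginal total. Zero-weight nodes get NaN.
    """
    a = _validated(m)
    if margin == "columns":
        a = a.T
    elif margin != "rows":
        raise ValueError("margin must be 'rows' or 'columns'")
    total = a.sum()
    partner_tot = a.sum(axis=0)
    q = partner_tot / total
    out = np.full(a.shape[0], np.nan)
    for i in range(a.shape[0]):
        node_total = a[i].sum()
        if node_total == 0:
            warnings.warn(f"node {i} has zero weight; d' undefined", stacklevel=2)
            continue
        p = a[i] / node_total
        mask = p > 0
        d = float((p[mask] * np.log(p[mask] / q[mask])).sum())
        d_max = _dmax_packing(node_total, partner_tot, q)
        out[i] = 0.0 if d_max <= 1e-12 else float(np.clip(d / d_max, 0.0, 1.0))
    return out


def _dmax_packing(node_total: float, partner_tot: np.ndarray, q: np.ndarray) -> float:
    order = np.argsort(q, kind="stable")  # rarest partners first
    remaining = node_total
    alloc = np.zeros_like(q)
    for j in order:
        if remaining <= 0:
            break
        take = min(remaining, partner_tot[j])
        alloc[j] = take
        remaining -= take
    p = alloc / node_total
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / q[mask])).sum())


# --------------------------------------------------------------------------
# null models and z-tests
# --------------------------------------------------------------------------

def patefield_null(
    m,
    rng: np.random.Generator,
    scale: float = 1e4,
) -> np.ndarray:
    """One Patefield ("r2d") draw: a uniform integer table with the observed
    marginals.

    Continuous weight matrices are scaled by ``scale`` and rounded to
    integers before sampling, then rescaled, so the null preserves the
    integer-rounded marginal totals of the observed matrix exactly.
    """
    a = _validated(m)
    ints = np.rint(a * scale).astype(np.int64)
    r = ints.sum(axis=1)
    c = ints.sum(axis=0)
    if r.sum() == 0:
        raise ValueError("matrix rounds to zero; increase the scale factor")
    keep_r = r > 0
    keep_c = c > 0
    draw = np.zeros_like(ints)
    if keep_r.sum() == 1 or keep_c.sum() == 1:
        draw[np.ix_(keep_r, keep_c)] = ints[np.ix_(keep_r, keep_c)]
    else:
        table = scipy.stats.random_table(r[keep_r], c[keep_c])
        draw[np.ix_(keep_r, keep_c)] = table.rvs(method="patefield", random_state=rng)
    return draw / scale


def null_ztest(
    observed: float,
    nulls: np.ndarray,
    bounds: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """z-test of an observed index against its null ensemble.

    Returns (z, two-sided normal p). Warns when the observed value or the
    null mean lies within two null standard deviations of a closed boundary
    of the index's range — the normal approximation is then suspect.
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size < 30:
        raise ValueError("need at least 30 null draws for a z-test")
    sd = nulls.std(ddof=1)
    if sd == 0:
        raise ValueError("null ensemble has zero standard deviation")
    mean = nulls.mean()
    if bounds is not None:
        lo, hi = bounds
        for value, name in ((observed, "observed value"), (mean, "null mean")):
            if min(value - lo, hi - value) < 2 * sd:
                warnings.warn(
                    f"{name} {value:.4g} lies within 2 null SDs of the boundary "
                    f"[{lo}, {hi}]; normality of the z-test is doubtful",
                    stacklevel=2,
                )
                break
    z = (observed - mean) / sd
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(z), float(p)


def dprime_anova(dprimes: pd.Series, phyla: pd.Series, min_group_size: int = 5):
    """One-way ANOVA of host d' values grouped by phylum.

    Delegates to :class:`virosurvey.diversity.DiversityANOVA` with phylum as
    the single factor and the same minimum group size rule as the other
    grouped analyses.
    """
    from .diversity import DiversityANOVA

    data = pd.DataFrame({"dprime": dprimes, "phylum": phyla.reindex(dprimes.index)})
    model = DiversityANOVA(data, response="dprime", factors=("phylum",),
                           min_group_size=min_group_size)
    return model.fit()


# --------------------------------------------------------------------------
# model/results wrapper
# --------------------------------------------------------------------------

_INDEX_BOUNDS = {"h2_prime": (0.0, 1.0), "nodf": (0.0, 100.0),
                 "q_modularity": (0.0, 1.0)}


@dataclass
class BipartiteResults:
    """Observed network indices, null ensembles and z-tests."""

    indices: pd.Series           # observed linkage_density, h2_prime, nodf, Q
    null_table: pd.DataFrame     # per-index null mean/sd, z, p
    nulls: pd.DataFrame          # raw null draws per index
    module_assignment: dict
    dprime_rows: pd.Series
    dprime_cols: pd.Series

    def summary(self) -> str:
        lines = [f"Bipartite network analysis ({len(self.nulls)} null models)"]
        tab = self.null_table.copy()
        tab.insert(0, "observed", self.indices)
        lines.append(str(tab.round(4)))
        lines.append(f"mean d' hosts = {np.nanmean(self.dprime_rows):.4f}, "
                     f"families = {np.nanmean(self.dprime_cols):.4f}")
        return "\n".join(lines)


class BipartiteAnalysis:
    """Network-structure analysis of a quantitative bipartite matrix.

    ``fit(n_null, seed)`` computes linkage density, H2', NODF and Barber Q
    on the observed matrix, simulates the same indices over ``n_null``
    Patefield draws, and z-tests each observed value against its ensemble.
    """

    def __init__(self, matrix: pd.DataFrame, scale: float = 1e4):
        self.matrix = matrix
        self.scale = scale
        _validated(matrix)

    def _indices(self, m, seed: int | None) -> dict[str, float]:
        q, assign = q_modularity(m, seed=seed)
        return {
            "linkage_density": linkage_density(m),
            "h2_prime": h2_prime(m),
            "nodf": nodf(m),
            "q_modularity": q,
        }, assign

    def fit(self, n_null: int = 1000, seed: int | None = None) -> BipartiteResults:
        root = np.random.SeedSequence(seed)
        ss_null, ss_mod = root.spawn(2)
        obs, assign = self._indices(self.matrix.to_numpy(),
                                    seed=int(ss_mod.generate_state(1)[0] % 2 ** 31))
        rng = np.random.default_rng(ss_null)
        draws = {k: [] for k in obs}
        for _ in range(n_null):
            null = patefield_null(self.matrix.to_numpy(), rng, scale=self.scale)
            null = null[null.sum(axis=1) > 0][:, null.sum(axis=0) > 0]
            vals, _ = self._indices(null, seed=int(rng.integers(2 ** 31)))
            for k, v in vals.items():
                draws[k].append(v)
        nulls = pd.DataFrame(draws)
        rows = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k, v in obs.items():
                sd = nulls[k].std(ddof=1)
                if sd == 0:
                    # the null ensemble is degenerate (e.g. binary NODF of
                    # uniformly dense draws); a z-test is meaningless
                    z, p = np.nan, np.nan
                else:
                    z, p = null_ztest(v, nulls[k].to_numpy(),
                                      bounds=_INDEX_BOUNDS.get(k))
                rows[k] = {"null_mean": nulls[k].mean(), "null_sd": sd,
                           "z": z, "p": p}
        return BipartiteResults(
            indices=pd.Series(obs),
            null_table=pd.DataFrame(rows).T,
            nulls=nulls,
            module_assignment=assign,
            dprime_rows=pd.Series(d_prime(self.matrix, "rows"),
                                  index=self.matrix.index),
            dprime_cols=pd.Series(d_prime(self.matrix, "columns"),
                                  index=self.matrix.columns),
        )
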