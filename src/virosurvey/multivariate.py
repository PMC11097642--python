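"""Distance-matrix permutation tests: PERMANOVA, PERMDISP and FDR control.

PERMANOVA partitions the total sum of squares of a distance matrix among
crossed factors (Anderson's pseudo-F on the Gower-centred matrix, sequential
type-I terms) and assesses significance by permuting sample labels.
PERMDISP tests homogeneity of multivariate dispersions: samples are embedded
by principal coordinates (keeping negative eigenvalues on an imaginary
axis), per-sample distances to the own-group centre are compared by a
one-way F test, and significance comes from permuting those distances.

Both are exposed statsmodels-style: a model object built from the distance
matrix and design, whose ``fit()`` returns a results object with the
decomposition table, permutation p-values and a ``summary()``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = ["PERMANOVA", "PERMANOVAResults", "PERMDISP", "PERMDISPResults", "fdr_adjust"]

_EXHAUSTIVE_LIMIT = 9  # 9! = 362,880 permutations


def _check_distance_matrix(dist) -> tuple[np.ndarray, list]:
    if isinstance(dist, pd.DataFrame):
        ids = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        ids = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    if (d < -1e-12).any():
        raise ValueError("distance matrix must be non-negative")
    return d, ids


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row_mean = a.mean(axis=0, keepdims=True)
    col_mean = a.mean(axis=1, keepdims=True)
    return a - row_mean - col_mean + a.mean()


def _parse_formula(formula) -> list[str]:
    if isinstance(formula, (list, tuple)):
        return list(formula)
    formula = formula.replace(" ", "")
    if "*" in formula:
        parts = formula.split("*")
        if len(parts) != 2:
            raise ValueError("only two-factor crossed formulas are supported")
        a, b = parts
        return [a, b, f"{a}:{b}"]
    return [t for t in formula.split("+") if t]


def _dummies(design: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":")
        combo = design[a].astype(str) + "\x00" + design[b].astype(str)
        return pd.get_dummies(combo, dtype=float).to_numpy()
    return pd.get_dummies(design[term].astype(str), dtype=float).to_numpy()


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x and its rank."""
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


@dataclass
class PERMANOVAResults:
    """PERMANOVA decomposition with permutation p-values."""

    table: pd.DataFrame          # term rows + Residual + Total: df, sum_sq, F, R2, p
    n_permutations: int
    seed: int | None
    exhaustive: bool
    n_obs: int

    @property
    def aic(self) -> float:
        """Pseudo-AIC n*ln(SS_res/n) + 2k with k = model df + 1.

        A documented stand-in: PERMANOVA has no likelihood, so this number is
        only comparable across models fitted to the same distance matrix.
        """
        ss_res = float(self.table.loc["Residual", "sum_sq"])
        if ss_res <= 0:
            raise ValueError("non-positive residual SS; pseudo-AIC undefined")
        n = self.n_obs
        model_df = int(self.table.loc["Total", "df"] - self.table.loc["Residual", "df"])
        k = model_df + 1
        return float(n * np.log(ss_res / n) + 2 * k)

    def term_pvalue(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def summary(self) -> str:
        kind = "exhaustive" if self.exhaustive else f"{self.n_permutations} permutations"
        return (
            f"PERMANOVA ({kind}, seed={self.seed})\n"
            + str(self.table.round(4))
            + f"\npseudo-AIC = {self.aic:.3f}"
        )


class PERMANOVA:
    """Permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    distance_matrix : DataFrame or ndarray
        Square symmetric distances between samples.
    design : DataFrame
        Factor table aligned with the distance matrix rows.
    formula : str or list of str
        Terms in fitting order, e.g. ``"phylum"``, ``"phylum+habitat"`` or
        ``"phylum*habitat"`` (which expands to main effects plus
        interaction). Sums of squares are sequential (type I) in this order.
    """

    def __init__(self, distance_matrix, design: pd.DataFrame, formula):
        self.d, self.ids = _check_distance_matrix(distance_matrix)
        self.n = self.d.shape[0]
        if isinstance(design, pd.Series):
            design = design.to_frame()
        design = design.loc[self.ids] if set(self.ids) <= set(design.index) else design
        if design.shape[0] != self.n:
            raise ValueError("design rows must align with the distance matrix")
        self.design = design.reset_index(drop=True)
        self.terms = _parse_formula(formula)
        for t in self.terms:
            for f in t.split(":"):
                if f not in self.design.columns:
                    raise ValueError(f"factor {f!r} not in design")
                if self.design[f].nunique() < 2:
                    raise ValueError(f"factor {f!r} has fewer than two levels")
        self._g = _gower_center(self.d)

    def _projections(self) -> tuple[list[np.ndarray], list[int]]:
        """Cumulative hat matrices for intercept + term prefixes, with dfs."""
        n = self.n
        x = np.ones((n, 1))
        hats = [np.full((n, n), 1.0 / n)]
        ranks = [1]
        for term in self.terms:
            x = np.hstack([x, _dummies(self.design, term)])
            h, r = _hat(x)
            hats.append(h)
            ranks.append(r)
        return hats, ranks

    def fit(
        self,
        n_perm: int = 999,
        seed: int | None = None,
        exhaustive: bool = False,
    ) -> PERMANOVAResults:
        n = self.n
        g = self._g
        hats, ranks = self._projections()
        dfs = np.diff(ranks)
        if np.any(dfs < 1):
            raise ValueError("aliased term with zero degrees of freedom")
        df_res = n - ranks[-1]
        if df_res < 1:
            raise ValueError("no residual degrees of freedom")

        ss_total = float(np.trace(g))
        cum_ss = np.array([float(np.vdot(h, g)) for h in hats[1:]])
        ss_terms = np.diff(np.concatenate([[0.0], cum_ss]))
        ss_res = ss_total - cum_ss[-1]
        f_obs = (ss_terms / dfs) / (ss_res / df_res)

        if exhaustive:
            if n > _EXHAUSTIVE_LIMIT:
                raise ValueError(
                    f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_LIMIT}"
                )
            count = np.zeros(len(self.terms))
            total = 0
            for perm in itertools.permutations(range(n)):
                gp = g[np.ix_(perm, perm)]
                f_perm = self._perm_f(gp, hats, dfs, df_res, ss_total)
                count += f_perm >= f_obs - 1e-12
                total += 1
            pvals = count / total
            n_done = total
        else:
            rng = np.random.default_rng(np.random.SeedSequence(seed))
            exceed = np.zeros(len(self.terms))
            for _ in range(n_perm):
                perm = rng.permutation(n)
                gp = g[np.ix_(perm, perm)]
                f_perm = self._perm_f(gp, hats, dfs, df_res, ss_total)
                exceed += f_perm >= f_obs - 1e-12
            pvals = (1.0 + exceed) / (1.0 + n_perm)
            n_done = n_perm

        rows = []
        for i, term in enumerate(self.terms):
            rows.append({"df": dfs[i], "sum_sq": ss_terms[i], "F": f_obs[i],
                         "R2": ss_terms[i] / ss_total, "p": pvals[i]})
        rows.append({"df": df_res, "sum_sq": ss_res, "F": np.nan,
                     "R2": ss_res / ss_total, "p": np.nan})
        rows.append({"df": n - 1, "sum_sq": ss_total, "F": np.nan, "R2": 1.0,
                     "p": np.nan})
        table = pd.DataFrame(rows, index=[*self.terms, "Residual", "Total"])
        if abs(ss_terms.sum() + ss_res - ss_total) > 1e-8 * max(1.0, abs(ss_total)):
            raise AssertionError("sum-of-squares decomposition failed to close")
        return PERMANOVAResults(table=table, n_permutations=n_done, seed=seed,
                                exhaustive=exhaustive, n_obs=n)

    @staticmethod
    def _perm_f(gp, hats, dfs, df_res, ss_total) -> np.ndarray:
        cum = np.array([float(np.vdot(h, gp)) for h in hats[1:]])
        ss_terms = np.diff(np.concatenate([[0.0], cum]))
        ss_res = ss_total - cum[-1]
        return (ss_terms / dfs) / (ss_res / df_res)


def oneway_permanova_pvalue(
    d: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 199,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Fast vectorised one-way PERMANOVA: returns (pseudo-F, permutation p).

    Same statistic and (1+b)/(1+m) p-value convention as :class:`PERMANOVA`
    restricted to a single factor, but permutations are evaluated in a batch
    from the within-group blocks of the squared distance matrix, which makes
    the per-iteration tests of the bootstrap procedure and large type-I-error
    simulations tractable.
    """
    rng = rng or np.random.default_rng()
    d2 = np.asarray(d, dtype=float) ** 2
    labels = np.asarray(labels)
    n = d2.shape[0]
    groups = pd.unique(labels)
    a = len(groups)
    if a < 2:
        raise ValueError("need at least two groups")
    positions = [np.flatnonzero(labels == g) for g in groups]
    ss_total = d2.sum() / (2.0 * n)

    def ss_within(perm_rows: np.ndarray) -> np.ndarray:
        # perm_rows: (B, n) permutation indices
        out = np.zeros(perm_rows.shape[0])
        for pos in positions:
            idx = perm_rows[:, pos]
            block = d2[idx[:, :, None], idx[:, None, :]]
            out += block.sum(axis=(1, 2)) / (2.0 * len(pos))
        return out

    identity = np.arange(n)[None, :]
    ssw_obs = float(ss_within(identity)[0])
    ssb_obs = ss_total - ssw_obs
    f_obs = (ssb_obs / (a - 1)) / (ssw_obs / (n - a))

    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    ssw = ss_within(perms)
    ssb = ss_total - ssw
    f_perm = (ssb / (a - 1)) / (ssw / (n - a))
    p = (1.0 + float((f_perm >= f_obs - 1e-12).sum())) / (1.0 + n_perm)
    return float(f_obs), p


@dataclass
class PERMDISPResults:
    """Dispersion homogeneity test results."""

    dispersions: pd.Series       # mean distance to centre per group
    distances: pd.Series         # per-sample distance to own-group centre
    f_statistic: float
    pvalue: float
    n_permutations: int
    center: str
    seed: int | None = None

    def summary(self) -> str:
        return (
            f"PERMDISP (center={self.center}, {self.n_permutations} permutations)\n"
            f"Group dispersions:\n{self.dispersions.round(4).to_string()}\n"
            f"F = {self.f_statistic:.4f}, p = {self.pvalue:.4f}"
        )


class PERMDISP:
    """Homogeneity of multivariate dispersions on a distance matrix.

    Samples are embedded by principal coordinates; axes with negative
    eigenvalues are retained and their squared contributions subtracted
    (imaginary-axis handling), so distances to group centres reproduce the
    original metric for Euclidean-embeddable input.
    """

    def __init__(self, distance_matrix, grouping):
        self.d, self.ids = _check_distance_matrix(distance_matrix)
        self.n = self.d.shape[0]
        if isinstance(grouping, pd.Series):
            grouping = (grouping.loc[self.ids]
                        if set(self.ids) <= set(grouping.index) else grouping)
            grouping = grouping.to_numpy()
        self.grouping = np.asarray(grouping)
        if self.grouping.shape[0] != self.n:
            raise ValueError("grouping must align with the distance matrix")
        counts = pd.Series(self.grouping).value_counts()
        if len(counts) < 2:
            raise ValueError("need at least two groups")
        if (counts < 2).any():
            small = counts.index[counts < 2].tolist()
            raise ValueError(f"groups of size 1 not allowed: {small}")

    def _embed(self) -> tuple[np.ndarray, np.ndarray]:
        g = _gower_center(self.d)
        eigval, eigvec = np.linalg.eigh(g)
        keep = np.abs(eigval) > 1e-9 * max(1.0, np.abs(eigval).max())
        eigval, eigvec = eigval[keep], eigvec[:, keep]
        coords = eigvec * np.sqrt(np.abs(eigval))
        return coords, eigval

    def _distances_to_center(self, center: str) -> np.ndarray:
        coords, eigval = self._embed()
        pos = eigval > 0
        dist = np.empty(self.n)
        for grp in pd.unique(self.grouping):
            mask = self.grouping == grp
            sub = coords[mask]
            if center == "centroid":
                c = sub.mean(axis=0)
            elif center == "spatial_median":
                c = _spatial_median(sub, pos)
            else:
                raise ValueError(f"unknown center {center!r}")
            diff2 = (sub - c) ** 2
            d2 = diff2[:, pos].sum(axis=1) - diff2[:, ~pos].sum(axis=1)
            dist[mask] = np.sqrt(np.clip(d2, 0.0, None))
        return dist

    def fit(
        self,
        n_perm: int = 999,
        center: str = "centroid",
        seed: int | None = None,
    ) -> PERMDISPResults:
        dist = self._distances_to_center(center)
        groups = pd.unique(self.grouping)
        samples = [dist[self.grouping == g] for g in groups]
        f_obs = _anova_f(samples)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        exceed = 0
        for _ in range(n_perm):
            shuffled = rng.permutation(dist)
            f_perm = _anova_f([shuffled[self.grouping == g] for g in groups])
            if f_perm >= f_obs - 1e-12:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_perm)
        dispersions = pd.Series({g: float(dist[self.grouping == g].mean())
                                 for g in groups}, name="dispersion")
        return PERMDISPResults(
            dispersions=dispersions,
            distances=pd.Series(dist, index=self.ids, name="distance_to_center"),
            f_statistic=float(f_obs),
            pvalue=float(p),
            n_permutations=n_perm,
            center=center,
            seed=seed,
        )


def _anova_f(samples: list[np.ndarray]) -> float:
    n = sum(len(s) for s in samples)
    a = len(samples)
    grand = np.concatenate(samples).mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ssw == 0:
        return math.inf if ssb > 0 else 0.0
    return (ssb / (a - 1)) / (ssw / (n - a))


def _spatial_median(sub: np.ndarray, pos_mask: np.ndarray, n_iter: int = 200,
                    tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld iteration in the sign-corrected principal-coordinate metric."""
    c = sub.mean(axis=0)
    sign = np.where(pos_mask, 1.0, -1.0)
    for _ in range(n_iter):
        diff2 = (sub - c) ** 2
        d = np.sqrt(np.clip((diff2 * sign).sum(axis=1), 1e-12, None))
        w = 1.0 / d
        new = (sub * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - c) < tol:
            return new
        c = new
    return c


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
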