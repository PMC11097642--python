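"""Per-sample diversity metrics and the grouped ANOVA model stack.

Richness is the number of viral families with positive read counts in a
sample; Shannon diversity H' is the natural-log entropy of the within-sample
family proportions. Group differences in either metric are assessed with a
statsmodels-backed ANOVA workflow: candidate models over the phylum and
habitat factors are compared by AIC, homoscedasticity is checked with
Levene's test (median-centred by default), a Box-Cox family transform with
lambda = 2.5 is available when variances are heterogeneous, and Tukey's HSD
with a compact letter display identifies the groups driving a rejected null.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "richness",
    "shannon",
    "diversity_table",
    "accumulation_curve",
    "boxcox",
    "levene_test",
    "DiversityANOVA",
    "AnovaResults",
    "TukeyResults",
    "compact_letter_display",
]

logger = logging.getLogger(__name__)


def richness(counts: np.ndarray | pd.Series) -> int:
    """Number of families with strictly positive counts."""
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return int((arr > 0).sum())


def shannon(counts: np.ndarray | pd.Series) -> float:
    """Shannon diversity H' = -sum p_j ln p_j over positive-count families."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("Shannon diversity undefined for an all-zero vector")
    p = arr[arr > 0] / total
    return float(scipy.stats.entropy(p))


def diversity_table(counts: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness and Shannon H' joined with phylum/habitat labels."""
    rows = {
        sid: {"richness": richness(counts.loc[sid]),
              "shannon": shannon(counts.loc[sid]) if counts.loc[sid].sum() > 0 else np.nan}
        for sid in counts.index
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return table.join(meta[[c for c in ("phylum", "habitat") if c in meta.columns]])


def accumulation_curve(
    counts: pd.DataFrame,
    sizes: list[int] | np.ndarray,
    n_iter: int = 50,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Family accumulation curve by sample pooling within one group.

    At each subsample size, ``n_iter`` random subsets of samples are drawn
    without replacement; the pooled richness (number of families with a
    positive count in the union) is averaged over iterations. An ordinary
    least squares line of the mean values on ln(size) summarises the curve.

    Returns the (size, mean_richness) table and the (intercept, slope) of the
    log-linear fit.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(np.random.SeedSequence(seed)))
    n = counts.shape[0]
    sizes = np.asarray(sizes, dtype=int)
    if sizes.min() < 1 or sizes.max() > n:
        raise ValueError(f"subsample sizes must lie in [1, {n}]")
    present = counts.to_numpy() > 0
    means = []
    for size in sizes:
        vals = []
        for _ in range(n_iter):
            idx = rng.choice(n, size=size, replace=False)
            vals.append(int(present[idx].any(axis=0).sum()))
        means.append(float(np.mean(vals)))
    table = pd.DataFrame({"size": sizes, "mean_richness": means})
    x = np.column_stack([np.ones(len(sizes)), np.log(sizes.astype(float))])
    fit = sm.OLS(np.asarray(means), x).fit()
    params = np.asarray(fit.params)
    return table, (float(params[0]), float(params[1]) if len(params) > 1 else 0.0)


def boxcox(values, lam: float, direction: str = "forward") -> np.ndarray:
    """Box-Cox power transform and its inverse.

    forward: y -> (y^lambda - 1)/lambda (requires y > 0; natural log at
    lambda = 0); inverse: z -> (lambda*z + 1)^(1/lambda) (requires
    lambda*z + 1 > 0). Both are monotone increasing and mutual inverses.
    """
    y = np.asarray(values, dtype=float)
    if direction == "forward":
        bad = np.flatnonzero(~(y > 0))
        if bad.size:
            raise ValueError(f"forward Box-Cox requires positive values; offending indices {bad.tolist()}")
        if lam == 0:
            return np.log(y)
        return (np.power(y, lam) - 1.0) / lam
    if direction == "inverse":
        if lam == 0:
            return np.exp(y)
        arg = lam * y + 1.0
        bad = np.flatnonzero(~(arg > 0))
        if bad.size:
            raise ValueError(f"inverse Box-Cox domain violated (lambda*z + 1 <= 0) at indices {bad.tolist()}")
        return np.power(arg, 1.0 / lam)
    raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")


def levene_test(values, groups, center: str = "median") -> tuple[float, float]:
    """Levene's homoscedasticity test (Brown-Forsythe median centring by default).

    Equivalent to a one-way ANOVA on absolute deviations from the group
    centre. Requires at least two groups of at least two observations.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("Levene's test needs at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("Levene's test needs at least two observations per group")
    stat, p = scipy.stats.levene(*samples, center=center)
    return float(stat), float(p)


# --------------------------------------------------------------------------
# ANOVA model stack
# --------------------------------------------------------------------------

def _aic(fit) -> float:
    # n*ln(RSS/n) + 2k with k = mean parameters + 1 for the error variance;
    # constants shared across candidates on the same response cancel.
    n = fit.nobs
    rss = fit.ssr
    k = fit.df_model + 1 + 1
    if rss <= 0:
        # a perfectly fitting (degenerate) model: -inf sorts first naturally
        return float("-inf")
    return float(n * np.log(rss / n) + 2 * k)


@dataclass
class TukeyResults:
    """Pairwise Tukey-Kramer comparisons plus a compact letter display."""

    table: pd.DataFrame          # group_a, group_b, mean_diff, p_adj, reject
    letters: dict[str, str]      # group -> letter string

    def summary(self) -> str:
        lines = ["Tukey HSD pairwise comparisons", str(self.table.round(4))]
        lines.append("Compact letter display:")
        for g, let in self.letters.items():
            lines.append(f"  {g}: {let}")
        return "\n".join(lines)


@dataclass
class AnovaResults:
    """A selected ANOVA fit: per-term tests, AIC, R^2 and the fitted data."""

    terms: list[str]
    anova_table: pd.DataFrame    # per-term df, sum_sq, F, PR(>F)
    aic: float
    rsquared: float
    transform: str               # 'none' | 'boxcox-inverse(lambda=..)' | ...
    data: pd.DataFrame = field(repr=False)
    response: str = "value"
    candidates: dict[str, float] = field(default_factory=dict)  # formula -> AIC
    _fit: object = field(default=None, repr=False)

    @property
    def formula(self) -> str:
        return f"{self.response} ~ " + " + ".join(self.terms)

    def term_pvalue(self, term: str) -> float:
        return float(self.anova_table.loc[term, "PR(>F)"])

    def tukey(self, factor: str | None = None, alpha: float = 0.05) -> TukeyResults:
        """Tukey-Kramer post hoc comparisons for one categorical term."""
        factor = factor or self.terms[0]
        if factor not in self.terms:
            raise ValueError(f"{factor!r} is not a term of the selected model")
        groups = self.data[factor].astype(str)
        counts = groups.value_counts()
        if (counts < 2).any():
            raise ValueError("Tukey comparisons need at least two observations per group")
        res = pairwise_tukeyhsd(self.data[self.response].to_numpy(), groups.to_numpy(),
                                alpha=alpha)
        tbl = pd.DataFrame(
            res.summary().data[1:],
            columns=[str(c) for c in res.summary().data[0]],
        )
        table = pd.DataFrame({
            "group_a": tbl["group1"].astype(str),
            "group_b": tbl["group2"].astype(str),
            "mean_diff": tbl["meandiff"].astype(float),
            "p_adj": tbl["p-adj"].astype(float),
            "reject": tbl["reject"].astype(bool),
        })
        order = sorted(groups.unique(),
                       key=lambda g: self.data.loc[groups == g, self.response].mean())
        nonsig = {(r.group_a, r.group_b) for r in table.itertuples() if not r.reject}
        letters = compact_letter_display(order, nonsig)
        return TukeyResults(table=table, letters=letters)

    def summary(self) -> str:
        lines = [
            "ANOVA model selection (minimum AIC)",
            f"  selected: {self.formula}",
            f"  transform: {self.transform}",
            f"  AIC = {self.aic:.3f}   R^2 = {self.rsquared:.4f}",
            "  candidates:",
        ]
        for f, a in self.candidates.items():
            lines.append(f"    {f}: AIC = {a:.3f}")
        lines.append(str(self.anova_table.round(4)))
        return "\n".join(lines)


class DiversityANOVA:
    """AIC model selection over phylum/habitat factors for one diversity metric.

    Candidate models are every non-empty combination of the supplied factors
    (one-way models and the additive model; the interaction model can be
    added with ``include_interaction=True``). Factor levels with fewer than
    ``min_group_size`` observations are dropped before fitting. ``fit()``
    returns the minimum-AIC :class:`AnovaResults` with sequential
    (type I) per-term F tests.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        factors: tuple[str, ...] = ("phylum", "habitat"),
        min_group_size: int = 5,
        transform: str | None = None,
        boxcox_lambda: float = 2.5,
        include_interaction: bool = False,
    ):
        missing = [c for c in (response, *factors) if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks columns {missing}")
        self.response = response
        self.factors = tuple(factors)
        self.min_group_size = min_group_size
        self.transform = transform
        self.boxcox_lambda = boxcox_lambda
        self.include_interaction = include_interaction
        self.data = data[[response, *factors]].dropna().copy()

    def _prepare(self) -> pd.DataFrame:
        df = self.data.copy()
        for f in self.factors:
            sizes = df[f].value_counts()
            keep = sizes.index[sizes >= self.min_group_size]
            df = df[df[f].isin(keep)]
        y = df[self.response].to_numpy(dtype=float)
        if self.transform == "boxcox-inverse":
            df[self.response] = boxcox(y, self.boxcox_lambda, "inverse")
        elif self.transform == "boxcox-forward":
            df[self.response] = boxcox(y, self.boxcox_lambda, "forward")
        elif self.transform not in (None, "none"):
            raise ValueError(f"unknown transform {self.transform!r}")
        return df

    def _candidate_terms(self, df: pd.DataFrame) -> list[list[str]]:
        usable = [f for f in self.factors if df[f].nunique() >= 2]
        for f in self.factors:
            if f not in usable:
                warnings.warn(
                    f"factor {f!r} left with <2 levels after group-size filtering; "
                    "candidates using it are skipped", stacklevel=3,
                )
        cands = []
        for r in range(1, len(usable) + 1):
            for combo in itertools.combinations(usable, r):
                cands.append(list(combo))
        if self.include_interaction and len(usable) >= 2:
            cands.append([*usable, f"{usable[0]}:{usable[1]}"])
        if not cands:
            raise ValueError("no usable factor with at least two levels")
        return cands

    def fit(self) -> AnovaResults:
        df = self._prepare()
        best = None
        candidates: dict[str, float] = {}
        for terms in self._candidate_terms(df):
            formula = f"{self.response} ~ " + " + ".join(f"C({t})" if ":" not in t
                                                         else _interaction(t) for t in terms)
            fit = smf.ols(formula, data=df).fit()
            aic = _aic(fit)
            candidates[" + ".join(terms)] = aic
            if best is None or aic < best[0]:
                best = (aic, terms, fit)
        aic, terms, fit = best
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            table = sm.stats.anova_lm(fit, typ=1)
        table = table.rename(index=_clean_term)
        # constant responses leave only rounding noise in the decomposition;
        # by convention such terms carry no evidence: F = 0, p = 1
        scale = max(1.0, float((df[self.response].to_numpy() ** 2).sum()))
        if table["sum_sq"].sum() < 1e-12 * scale:
            term_rows = table.index != "Residual"
            table.loc[term_rows, "F"] = 0.0
            table.loc[term_rows, "PR(>F)"] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rsq = float(fit.rsquared)
        return AnovaResults(
            terms=terms,
            anova_table=table,
            aic=aic,
            rsquared=rsq if np.isfinite(rsq) else 0.0,
            transform=(f"boxcox-{self.transform.split('-')[1]}(lambda={self.boxcox_lambda})"
                       if self.transform and self.transform.startswith("boxcox")
                       else "none"),
            data=df,
            response=self.response,
            candidates=candidates,
            _fit=fit,
        )


def _interaction(term: str) -> str:
    a, b = term.split(":")
    return f"C({a}):C({b})"


def _clean_term(name: str) -> str:
    return name.replace("C(", "").replace(")", "")


def compact_letter_display(
    groups: list[str],
    nonsignificant_pairs: set[tuple[str, str]],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups`` should be ordered (e.g. by group mean); two groups share a
    letter exactly when their pairwise comparison was not rejected. Ties in
    letter assignment resolve by the given group order.
    """
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(groups)
    graph.add_edges_from(p for p in nonsignificant_pairs)
    # Every maximal clique of the non-significance graph gets one letter:
    # two groups then share a letter exactly when they lie in a common
    # maximal clique, i.e. when their comparison was not rejected.
    pos = {g: i for i, g in enumerate(groups)}
    cliques = sorted((sorted(c, key=pos.get) for c in nx.find_cliques(graph)),
                     key=lambda c: [pos[g] for g in c])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for k, clique in enumerate(cliques):
        for g in groups:
            if g in clique:
                letters[g] += alphabet[k % len(alphabet)]
    return letters
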