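"""Bootstrap-balanced pairwise PERMANOVA/PERMDISP equivalence network.

Pairwise PERMANOVA between host phyla is sensitive to unbalanced group
sizes. This module implements a bootstrap procedure that rebalances groups
at every iteration and summarises, over iterations, which phylum pairs are
*not* separable in composition:

  i.   sample ``group_size`` observations per phylum with replacement;
  ii.  impute a new phylum for one randomly chosen observation (all
       bootstrap duplicates of that observation are relabelled with it);
  iii. drop observations from the imputed phylum until it is back at
       ``group_size``, always keeping the shuffled observation(s);
  iv.  redraw observations for the shuffled observation's old phylum to
       restore balance, never redrawing the shuffled observation itself;
  v.   recompute the clr matrix on the resampled absolute-abundance matrix
       (family filter + CZM zero replacement + clr);
  vi.  run PERMANOVA and PERMDISP for every unordered phylum pair and
       adjust all p-values of the iteration jointly by Benjamini-Hochberg;
  vii. encode each pair as one of four outcomes and store it.

The deliberate label shuffling in steps ii-iv injects a known false signal
so that the adjusted tests are exercised against label noise rather than
only against clean groups. A pair counts as significantly different only
when PERMANOVA rejects while PERMDISP does not (LOC_DIFF): rejection of
both cannot distinguish location from dispersion effects. The equivalence
network connects phyla whose fraction of non-LOC_DIFF iterations (the
support) exceeds a threshold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .composition import clr_pipeline, aitchison_distances
from .multivariate import PERMDISP, fdr_adjust, oneway_permanova_pvalue

__all__ = [
    "BootstrapConfig",
    "OUTCOME_CODES",
    "bootstrap_iteration",
    "pairwise_tests",
    "encode_outcomes",
    "build_network",
    "BootstrapEquivalence",
    "BootstrapEquivalenceResults",
]

logger = logging.getLogger(__name__)

# four-level outcome coding: (PERMANOVA rejects, PERMDISP rejects)
OUTCOME_CODES = ("LOC_DIFF", "BOTH_REJECT", "DISP_ONLY", "NEITHER")


@dataclass
class BootstrapConfig:
    """Knobs of the bootstrap equivalence procedure.

    ``n_perm`` is the permutation count of each within-iteration test; its
    modest default keeps the full loop tractable (an iteration runs
    n(n-1)/2 PERMANOVAs and as many PERMDISPs) and is the main runtime
    knob.
    """

    group_size: int = 15
    n_iter: int = 1500
    alpha: float = 0.05
    support_threshold: float = 0.2
    n_perm: int = 199
    min_mean: float = 1e-4
    czm_label: float = 0.65
    fdr_family: str = "pooled"   # 'pooled' (both test families jointly) | 'per_test'
    seed: int = 0

    def validate(self) -> None:
        if self.group_size < 2:
            raise ValueError("group_size must be at least 2")
        if self.n_iter < 1:
            raise ValueError("n_iter must be positive")
        for name in ("alpha", "support_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        if self.fdr_family not in ("pooled", "per_test"):
            raise ValueError("fdr_family must be 'pooled' or 'per_test'")


def bootstrap_iteration(
    counts: pd.DataFrame,
    phyla: pd.Series,
    config: BootstrapConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series, str]:
    """One balanced resample with a single label-shuffled observation.

    Returns the resampled count matrix (rows renamed ``<sample>@<k>`` so
    bootstrap duplicates stay distinct), the per-row phylum labels, and the
    id of the shuffled original observation. Every phylum label ends with
    exactly ``group_size`` rows; the shuffled observation appears only under
    its imputed phylum.
    """
    phyla = phyla.reindex(counts.index)
    levels = sorted(phyla.dropna().unique())
    if len(levels) < 2:
        raise ValueError("bootstrap needs at least two phyla")
    pools = {g: counts.index[(phyla == g).to_numpy()].to_numpy() for g in levels}
    for g, pool in pools.items():
        if len(pool) < 2:
            raise ValueError(f"phylum {g!r} has fewer than two samples")

    # (i) balanced resample with replacement
    drawn: dict[str, list[str]] = {
        g: list(rng.choice(pools[g], size=config.group_size, replace=True))
        for g in levels
    }
    # (ii) impute a new phylum for one random observation
    old_phylum = levels[int(rng.integers(len(levels)))]
    shuffled_id = drawn[old_phylum][int(rng.integers(config.group_size))]
    new_phylum = [g for g in levels if g != old_phylum][
        int(rng.integers(len(levels) - 1))
    ]
    k_moved = drawn[old_phylum].count(shuffled_id)
    drawn[old_phylum] = [s for s in drawn[old_phylum] if s != shuffled_id]
    drawn[new_phylum].extend([shuffled_id] * k_moved)
    # (iii) trim the imputed phylum back to group_size, keeping shuffled rows
    keepers = [s for s in drawn[new_phylum] if s == shuffled_id]
    others = [s for s in drawn[new_phylum] if s != shuffled_id]
    n_drop = len(drawn[new_phylum]) - config.group_size
    if n_drop > 0:
        drop_idx = set(rng.choice(len(others), size=n_drop, replace=False).tolist())
        others = [s for i, s in enumerate(others) if i not in drop_idx]
    drawn[new_phylum] = keepers + others
    # (iv) refill the old phylum, never redrawing the shuffled observation
    refill_pool = pools[old_phylum][pools[old_phylum] != shuffled_id]
    if refill_pool.size == 0:
        raise ValueError(
            f"phylum {old_phylum!r} has no alternative samples to refill from"
        )
    n_refill = config.group_size - len(drawn[old_phylum])
    drawn[old_phylum].extend(rng.choice(refill_pool, size=n_refill, replace=True))

    row_ids, row_sources, row_labels = [], [], []
    for g in levels:
        assert len(drawn[g]) == config.group_size
        for k, s in enumerate(drawn[g]):
            row_ids.append(f"{s}@{g}@{k}")
            row_sources.append(s)
            row_labels.append(g)
    resampled = counts.loc[row_sources].copy()
    resampled.index = pd.Index(row_ids, name="sample_id")
    labels = pd.Series(row_labels, index=resampled.index, name="phylum")
    return resampled, labels, shuffled_id


def pairwise_tests(
    clr: pd.DataFrame,
    labels: pd.Series,
    config: BootstrapConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """PERMANOVA and PERMDISP raw p-values for every unordered phylum pair."""
    dist = aitchison_distances(clr)
    levels = sorted(labels.unique())
    rows = []
    for a, b in itertools.combinations(levels, 2):
        mask = labels.isin([a, b]).to_numpy()
        sub = dist.to_numpy()[np.ix_(mask, mask)]
        lab = labels.to_numpy()[mask]
        _, p_perm = oneway_permanova_pvalue(sub, lab, n_perm=config.n_perm, rng=rng)
        disp = PERMDISP(sub, lab).fit(
            n_perm=config.n_perm, seed=int(rng.integers(2 ** 31))
        )
        rows.append({"phylum_a": a, "phylum_b": b,
                     "permanova_p": p_perm, "permdisp_p": disp.pvalue})
    return pd.DataFrame(rows)


def encode_outcomes(pvals: pd.DataFrame, alpha: float = 0.05,
                    fdr_family: str = "pooled") -> pd.DataFrame:
    """FDR-adjust one iteration's p-values and encode the four-level outcome.

    With ``fdr_family='pooled'`` all 2 * n(n-1)/2 p-values of the iteration
    form one Benjamini-Hochberg family ("the total number of tests per
    iteration"); ``'per_test'`` adjusts the PERMANOVA and PERMDISP families
    separately.
    """
    out = pvals.copy()
    if fdr_family == "pooled":
        adj = fdr_adjust(np.concatenate([out["permanova_p"], out["permdisp_p"]]))
        m = len(out)
        out["permanova_fdr"], out["permdisp_fdr"] = adj[:m], adj[m:]
    else:
        out["permanova_fdr"] = fdr_adjust(out["permanova_p"])
        out["permdisp_fdr"] = fdr_adjust(out["permdisp_p"])
    loc = out["permanova_fdr"] < alpha
    disp = out["permdisp_fdr"] < alpha
    code = np.where(loc & ~disp, "LOC_DIFF",
                    np.where(loc & disp, "BOTH_REJECT",
                             np.where(~loc & disp, "DISP_ONLY", "NEITHER")))
    out["code"] = code
    return out


def build_network(outcomes: pd.DataFrame, support_threshold: float = 0.2) -> nx.Graph:
    """Equivalence network: edges where the non-LOC_DIFF fraction exceeds the threshold.

    ``outcomes`` is the long-format array (iteration, phylum_a, phylum_b,
    code). Support is the fraction of iterations whose code is anything but
    LOC_DIFF; the edge rule is a strict inequality.
    """
    graph = nx.Graph()
    graph.add_nodes_from(sorted(set(outcomes["phylum_a"]) | set(outcomes["phylum_b"])))
    grouped = outcomes.groupby(["phylum_a", "phylum_b"])["code"]
    for (a, b), codes in grouped:
        support = float((codes != "LOC_DIFF").mean())
        if support > support_threshold:
            graph.add_edge(a, b, support=support)
    return graph


@dataclass
class BootstrapEquivalenceResults:
    """Outcome array and equivalence network from the bootstrap loop."""

    outcomes: pd.DataFrame       # iteration, phylum_a, phylum_b, p-values, code
    network: nx.Graph
    config: BootstrapConfig

    def support_table(self) -> pd.DataFrame:
        """Per-pair support: fraction of iterations not coded LOC_DIFF."""
        tab = (self.outcomes.assign(not_loc=lambda d: d["code"] != "LOC_DIFF")
               .groupby(["phylum_a", "phylum_b"])["not_loc"].mean()
               .rename("support").reset_index())
        return tab

    def edge_list(self) -> pd.DataFrame:
        rows = [{"phylum_a": a, "phylum_b": b, "support": d["support"]}
                for a, b, d in self.network.edges(data=True)]
        return pd.DataFrame(rows, columns=["phylum_a", "phylum_b", "support"])

    def summary(self) -> str:
        sup = self.support_table()
        return (
            f"Bootstrap equivalence network: {self.config.n_iter} iterations, "
            f"alpha={self.config.alpha}, support > {self.config.support_threshold}\n"
            f"{len(self.network.nodes)} phyla, {len(self.network.edges)} edges\n"
            + sup.round(3).to_string(index=False)
        )


class BootstrapEquivalence:
    """The full bootstrap-balanced pairwise testing procedure as a model.

    Built from the eukaryotic count matrix and the per-sample phylum labels;
    only phyla with at least ``min_samples`` observations enter the
    analysis. ``fit()`` runs the loop and returns
    :class:`BootstrapEquivalenceResults`.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        phyla: pd.Series,
        config: BootstrapConfig | None = None,
        min_samples: int = 15,
    ):
        self.config = config or BootstrapConfig()
        self.config.validate()
        phyla = phyla.reindex(counts.index)
        sizes = phyla.value_counts()
        keep = sizes.index[sizes >= min_samples]
        if len(keep) < 2:
            raise ValueError(
                f"need at least two phyla with >= {min_samples} samples"
            )
        mask = phyla.isin(keep).to_numpy()
        self.counts = counts.loc[mask]
        self.phyla = phyla.loc[mask]

    def fit(self) -> BootstrapEquivalenceResults:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        chunks = []
        for it in range(cfg.n_iter):
            resampled, labels, _ = bootstrap_iteration(self.counts, self.phyla,
                                                       cfg, rng)
            clr = clr_pipeline(resampled, min_mean=cfg.min_mean, label=cfg.czm_label)
            pvals = pairwise_tests(clr, labels, cfg, rng)
            coded = encode_outcomes(pvals, alpha=cfg.alpha, fdr_family=cfg.fdr_family)
            coded.insert(0, "iteration", it)
            chunks.append(coded)
            if (it + 1) % 100 == 0:
                logger.info("bootstrap iteration %d/%d", it + 1, cfg.n_iter)
        outcomes = pd.concat(chunks, ignore_index=True)
        network = build_network(outcomes, cfg.support_threshold)
        return BootstrapEquivalenceResults(outcomes=outcomes, network=network,
                                           config=cfg)
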