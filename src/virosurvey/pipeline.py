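"""End-to-end survey pipeline with a single flat config and one master seed.

Stages run in a fixed order — counts, diversity, composition, multivariate,
bootstrap equivalence, bipartite network — each writing its result tables
as TSV into the run directory. Every source of randomness draws its seed
from the master seed through one SeedSequence spawning scheme, so a run is
a pure function of (inputs, config): identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import bipartite as bp
from . import composition as comp
from . import counts_io, diversity
from .bootstrap import BootstrapConfig, BootstrapEquivalence
from .multivariate import PERMANOVA, PERMDISP
from .simulate import SyntheticConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Flat, serialisable configuration of the full pipeline.

    Defaults mirror the survey's analysis constants: 0.01% family filter,
    CZM label 0.65, group-size floor 5 for univariate ANOVA, 15-sample floor
    for the clr/PERMANOVA subset, Box-Cox lambda 2.5, bootstrap group size
    15 with support threshold 0.2, and 1000 bipartite null models. The
    simulation block applies when no count matrix is supplied.
    """

    counts_path: str = ""
    meta_path: str = ""
    seed: int = 0
    # simulation block (used when counts_path is empty)
    sim_n_phyla: int = 4
    sim_samples_per_phylum: int = 20
    sim_n_families: int = 30
    sim_phylum_effect: float = 1.0
    sim_habitat_effect: float = 0.0
    # analysis constants
    min_mean: float = 1e-4
    czm_label: float = 0.65
    min_group_size: int = 5
    clr_min_samples: int = 15
    boxcox_lambda: float = 2.5
    n_perm: int = 999
    # bootstrap block
    bootstrap_iters: int = 100
    bootstrap_group_size: int = 15
    bootstrap_alpha: float = 0.05
    bootstrap_support: float = 0.2
    bootstrap_perms: int = 199
    # bipartite block
    n_null: int = 1000
    accumulation_iters: int = 50

    def to_text(self) -> str:
        return "\n".join(f"{k} = {v}" for k, v in sorted(asdict(self).items())) + "\n"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"str": str, "int": int, "float": float}
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: int) -> int:
    child = np.random.SeedSequence(master).spawn(10)[stage]
    return int(child.generate_state(1)[0] % 2 ** 31)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run all stages and return the run directory.

    Any stage failure aborts with the stage name in the exception and leaves
    a ``FAILED`` marker next to the partial outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "FAILED").unlink(missing_ok=True)
    (out / "run_info.txt").write_text(
        f"config_hash = {config.digest()}\nseed = {config.seed}\n" + config.to_text()
    )
    stage = "setup"
    try:
        # ---- counts -------------------------------------------------------
        stage = "counts"
        if config.counts_path:
            counts = counts_io.read_count_matrix(config.counts_path)
            if not config.meta_path:
                raise ValueError("meta_path required when counts_path is given")
            meta = pd.read_csv(config.meta_path, sep="\t", index_col=0)
        else:
            sim = SyntheticConfig(
                n_phyla=config.sim_n_phyla,
                samples_per_phylum=config.sim_samples_per_phylum,
                n_families=config.sim_n_families,
                phylum_effect=config.sim_phylum_effect,
                habitat_effect=config.sim_habitat_effect,
                seed=_stage_seed(config.seed, 0),
            )
            counts, meta, _ = generate_dataset(sim)
        _write(counts, out / "counts.tsv")
        _write(meta, out / "meta.tsv")

        # ---- diversity ----------------------------------------------------
        stage = "diversity"
        div = diversity.diversity_table(counts, meta)
        _write(div, out / "diversity.tsv")
        factors = tuple(f for f in ("phylum", "habitat")
                        if f in div.columns and div[f].nunique() >= 2)
        anova_lines = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for metric in ("richness", "shannon"):
                fit = diversity.DiversityANOVA(
                    div, metric, factors=factors,
                    min_group_size=config.min_group_size,
                ).fit()
                # heteroscedasticity check on the selected model's first term;
                # refit on inverse-Box-Cox H' when Levene rejects
                _, lev_p = diversity.levene_test(
                    fit.data[metric], fit.data[fit.terms[0].split(":")[0]]
                )
                if metric == "shannon" and lev_p < 0.05:
                    fit = diversity.DiversityANOVA(
                        div, metric, factors=factors,
                        min_group_size=config.min_group_size,
                        transform="boxcox-inverse",
                        boxcox_lambda=config.boxcox_lambda,
                    ).fit()
                anova_lines.append(f"== {metric} (Levene p = {lev_p:.4g}) ==")
                anova_lines.append(fit.summary())
                if fit.data[fit.terms[0]].value_counts().min() >= 2:
                    tk = fit.tukey(fit.terms[0])
                    anova_lines.append(tk.summary())
        (out / "anova.txt").write_text("\n".join(anova_lines) + "\n")

        phylum_sizes = meta["phylum"].value_counts()
        big_phyla = sorted(phylum_sizes.index[phylum_sizes >= config.clr_min_samples])
        acc_rows = []
        for k, phylum in enumerate(big_phyla):
            sub = counts.loc[(meta["phylum"] == phylum).to_numpy()]
            sizes = sorted({max(1, s) for s in
                            np.linspace(1, sub.shape[0], 6).astype(int)})
            table, (icpt, slope) = diversity.accumulation_curve(
                sub, sizes, n_iter=config.accumulation_iters,
                seed=_stage_seed(config.seed, 1) + k,
            )
            table.insert(0, "phylum", phylum)
            table["intercept"] = icpt
            table["slope"] = slope
            acc_rows.append(table)
        if acc_rows:
            _write(pd.concat(acc_rows, ignore_index=True),
                   out / "accumulation.tsv", index=False)

        # ---- composition --------------------------------------------------
        stage = "composition"
        subset = meta.index[meta["phylum"].isin(big_phyla)]
        clr = comp.clr_pipeline(counts.loc[subset], min_mean=config.min_mean,
                                label=config.czm_label)
        _write(clr, out / "clr.tsv")
        dist = comp.aitchison_distances(clr)
        _write(dist, out / "distances.tsv")
        cd = comp.centroid_distances(clr, meta.loc[subset, "phylum"],
                                     min_group_size=config.clr_min_samples)
        _write(cd, out / "centroid_distances.tsv", index=False)
        rel = comp.to_relative_abundance(counts.loc[subset])
        rel = comp.filter_families(rel, min_mean=config.min_mean)
        rel = comp.czm_replace_zeros(rel, counts.loc[subset].sum(axis=1).to_numpy(),
                                     label=config.czm_label)
        profiles, link_g, link_f = comp.aggregate_by_group(
            rel, meta.loc[subset, "phylum"]
        )
        _write(profiles, out / "phylum_profiles_clr.tsv")
        (out / "dendrogram_phyla.nwk").write_text(
            comp.linkage_to_newick(link_g, list(profiles.index)) + "\n")
        (out / "dendrogram_families.nwk").write_text(
            comp.linkage_to_newick(link_f, list(profiles.columns)) + "\n")

        # ---- multivariate --------------------------------------------------
        stage = "multivariate"
        design = meta.loc[subset, [c for c in ("phylum", "habitat")
                                   if c in meta.columns]]
        formulas = ["phylum"]
        if "habitat" in design.columns and design["habitat"].nunique() >= 2:
            formulas += ["habitat", "phylum+habitat", "phylum*habitat"]
        perma_lines = []
        for k, formula in enumerate(formulas):
            res = PERMANOVA(dist, design, formula).fit(
                n_perm=config.n_perm, seed=_stage_seed(config.seed, 2) + k
            )
            perma_lines.append(f"== {formula} ==")
            perma_lines.append(res.summary())
        disp = PERMDISP(dist, design["phylum"]).fit(
            n_perm=config.n_perm, seed=_stage_seed(config.seed, 3)
        )
        perma_lines.append("== PERMDISP (phylum) ==")
        perma_lines.append(disp.summary())
        (out / "permanova.txt").write_text("\n".join(perma_lines) + "\n")

        # ---- bootstrap equivalence -----------------------------------------
        stage = "bootstrap"
        bcfg = BootstrapConfig(
            group_size=config.bootstrap_group_size,
            n_iter=config.bootstrap_iters,
            alpha=config.bootstrap_alpha,
            support_threshold=config.bootstrap_support,
            n_perm=config.bootstrap_perms,
            min_mean=config.min_mean,
            czm_label=config.czm_label,
            seed=_stage_seed(config.seed, 4),
        )
        boot = BootstrapEquivalence(counts.loc[subset], meta.loc[subset, "phylum"],
                                    bcfg, min_samples=config.clr_min_samples).fit()
        _write(boot.outcomes, out / "bootstrap_outcomes.tsv", index=False)
        _write(boot.support_table(), out / "bootstrap_support.tsv", index=False)
        _write(boot.edge_list(), out / "equivalence_edges.tsv", index=False)

        # ---- bipartite network ---------------------------------------------
        stage = "bipartite"
        rel_all = comp.to_relative_abundance(counts.loc[subset])
        rel_all = comp.filter_families(rel_all, min_mean=config.min_mean)
        matrix = bp.build_bipartite(rel_all, mode="abundance")
        res = bp.BipartiteAnalysis(matrix).fit(
            n_null=config.n_null, seed=_stage_seed(config.seed, 5)
        )
        _write(res.nulls, out / "bipartite_nulls.tsv", index=False)
        (out / "bipartite.txt").write_text(res.summary() + "\n")
        dp = pd.DataFrame({"dprime": res.dprime_rows})
        dp["phylum"] = meta.loc[subset, "phylum"]
        _write(dp, out / "dprime_hosts.tsv")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            danova = bp.dprime_anova(res.dprime_rows, meta.loc[subset, "phylum"],
                                     min_group_size=config.min_group_size)
        (out / "dprime_anova.txt").write_text(danova.summary() + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage = {stage}\nerror = {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return out
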