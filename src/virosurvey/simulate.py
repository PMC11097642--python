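"""Synthetic virome survey generator.

Emulates the statistical structure of a grouped compositional virome survey:
each host phylum has a base composition over viral families, samples draw
reads multinomially from a sample-specific composition at a log-normal
sequencing depth, habitats add a log-ratio shift to a fixed subset of
families, and a zero-inflation probability makes families structurally
absent from individual samples. The generator returns the injected ground
truth so parameter-recovery tests can ask whether the downstream pipeline
finds exactly the effects that were put in.

The between-phylum dial is a logistic-normal perturbation: phylum base
compositions are the shared Dirichlet centre perturbed in log space by
Normal(0, phylum_effect) noise. ``phylum_effect=0`` therefore makes samples
exchangeable across phyla (the null case), and increasing it separates the
phylum centroids continuously.

All randomness descends from one integer seed through a single
``numpy.random.SeedSequence`` spawning scheme, so a full pipeline is
reproducible from its master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset", "generate_run_records"]

HABITATS = ("brackish", "freshwater", "intertidal zone", "marine", "terrestrial")

_PHYLUM_POOL = (
    "Annelida", "Arthropoda", "Bryozoa", "Chordata", "Cnidaria", "Ctenophora",
    "Echinodermata", "Kinorhyncha", "Mollusca", "Nematoda", "Nemertea",
    "Onychophora", "Platyhelminthes", "Porifera", "Rotifera", "Xenacoelomorpha",
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic survey.

    Defaults describe a desk-scale survey: 4 phyla x 15 samples over 30
    viral families, depth log-normal with natural-log mean 10 (~22k classified
    reads) and sd 0.5, moderate Dirichlet concentration 5 for the family
    centre, and 15% structural zero inflation.
    """

    n_phyla: int = 4
    samples_per_phylum: int = 15
    n_families: int = 30
    concentration: float = 5.0
    phylum_effect: float = 0.0
    habitat_effect: float = 0.0
    habitats_per_phylum: dict[str, list[str]] | None = None
    depth_log_mean: float = 10.0
    depth_log_sd: float = 0.5
    zero_inflation: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_phyla", "samples_per_phylum", "n_families"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_families < 2:
            raise ValueError("n_families must be at least 2")
        if not self.concentration > 0:
            raise ValueError(f"concentration must be positive, got {self.concentration!r}")
        for name in ("phylum_effect", "habitat_effect"):
            v = getattr(self, name)
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"{name} must be a finite non-negative real, got {v!r}")
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError(f"zero_inflation must be in [0, 1], got {self.zero_inflation!r}")
        if not self.depth_log_sd >= 0:
            raise ValueError(f"depth_log_sd must be non-negative, got {self.depth_log_sd!r}")
        if self.habitats_per_phylum is not None:
            for phylum, habs in self.habitats_per_phylum.items():
                bad = [h for h in habs if h not in HABITATS]
                if bad:
                    raise ValueError(
                        f"habitats_per_phylum[{phylum!r}] contains unknown habitats {bad}"
                    )
                if len(habs) == 0:
                    raise ValueError(f"habitats_per_phylum[{phylum!r}] is empty")


@dataclass
class GroundTruth:
    """What was injected: per-phylum base compositions and effect flags."""

    base_compositions: pd.DataFrame  # phylum x family probability vectors
    phylum_effect_present: bool
    habitat_effect_present: bool
    habitat_shift_families: list[str] = field(default_factory=list)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic survey: (count matrix, sample table, ground truth).

    The count matrix is samples x families with integer read counts whose row
    sums equal the drawn depths exactly; the sample table carries species,
    phylum and habitat per sample. Identical configs (including seed) give
    bit-identical output.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_center, ss_phyla, ss_habitat, ss_samples = root.spawn(4)

    phyla = [_PHYLUM_POOL[i % len(_PHYLUM_POOL)] + ("" if i < len(_PHYLUM_POOL) else f"_{i}")
             for i in range(config.n_phyla)]
    families = [f"Family{i + 1:03d}" for i in range(config.n_families)]

    rng_center = np.random.default_rng(ss_center)
    center = rng_center.dirichlet(np.full(config.n_families, config.concentration))
    center = np.clip(center, 1e-12, None)
    center /= center.sum()

    rng_phyla = np.random.default_rng(ss_phyla)
    base = np.empty((config.n_phyla, config.n_families))
    for p in range(config.n_phyla):
        # Logistic-normal perturbation of the shared centre; sd=0 reproduces
        # the centre exactly so phyla are exchangeable under the null.
        shift = rng_phyla.normal(0.0, 1.0, size=config.n_families)
        logp = np.log(center) + config.phylum_effect * shift
        comp = np.exp(logp - logp.max())
        base[p] = comp / comp.sum()

    rng_habitat = np.random.default_rng(ss_habitat)
    habitat_families = sorted(
        rng_habitat.choice(config.n_families, size=config.n_families // 2, replace=False)
    )
    habitat_signs = rng_habitat.choice([-1.0, 1.0], size=len(habitat_families))

    habitats_map = config.habitats_per_phylum or {}
    default_habitats = ["marine"]

    sample_rows = []
    counts = np.zeros((config.n_phyla * config.samples_per_phylum, config.n_families),
                      dtype=np.int64)
    sample_ids = []
    rng_samples = np.random.default_rng(ss_samples)
    habitat_index = {h: k for k, h in enumerate(HABITATS)}
    row = 0
    for p, phylum in enumerate(phyla):
        habs = list(habitats_map.get(phylum, default_habitats))
        for s in range(config.samples_per_phylum):
            habitat = habs[s % len(habs)]
            logp = np.log(base[p]).copy()
            if config.habitat_effect > 0:
                # additive shift in log-ratio space for a fixed family subset,
                # direction alternating by family, magnitude scaled by the
                # habitat's index so different habitats shift differently
                logp[habitat_families] += (
                    config.habitat_effect * habitat_signs * habitat_index[habitat]
                )
            comp = np.exp(logp - logp.max())
            comp /= comp.sum()
            if config.zero_inflation > 0:
                absent = rng_samples.random(config.n_families) < config.zero_inflation
                if absent.all():
                    absent[int(np.argmax(comp))] = False
                comp = np.where(absent, 0.0, comp)
                comp /= comp.sum()
            depth = int(np.ceil(rng_samples.lognormal(config.depth_log_mean,
                                                      config.depth_log_sd)))
            counts[row] = rng_samples.multinomial(depth, comp)
            sid = f"S{row + 1:04d}"
            sample_ids.append(sid)
            sample_rows.append(
                {"sample_id": sid, "species": f"{phylum} species{s + 1}",
                 "phylum": phylum, "habitat": habitat}
            )
            row += 1

    count_df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                            columns=families)
    meta = pd.DataFrame(sample_rows).set_index("sample_id")
    truth = GroundTruth(
        base_compositions=pd.DataFrame(base, index=phyla, columns=families),
        phylum_effect_present=config.phylum_effect > 0,
        habitat_effect_present=config.habitat_effect > 0,
        habitat_shift_families=[families[i] for i in habitat_families],
    )
    return count_df, meta, truth


def generate_run_records(n: int, seed: int = 0) -> pd.DataFrame:
    """Generate an SRA-style run-metadata table for exercising sample selection.

    Records span eligible and ineligible cases: when ``n >= 20`` the table is
    guaranteed to contain at least one record failing each of the three
    eligibility criteria (library strategy, read length, total bases).
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    strategies = np.where(rng.random(n) < 0.7, "RNA-Seq",
                          rng.choice(["WGS", "AMPLICON", "miRNA-Seq"], size=n))
    read_len = rng.choice([50, 75, 100, 125, 150, 250], size=n).astype(float)
    gbases = rng.lognormal(np.log(8.0), 0.9, size=n)  # mode near the survey's 8.8 Gb mean
    if n >= 20:
        strategies[0] = "WGS"
        strategies[1:3] = "RNA-Seq"
        read_len[1] = 50.0
        read_len[2] = 150.0
        gbases[2] = 1.0
    phyla = rng.choice(_PHYLUM_POOL[:8], size=n)
    species_idx = rng.integers(1, max(2, n // 2), size=n)

    def epithet(k: int) -> str:
        letters = "abcdefghijklmnopqrstuvwxyz"
        out = letters[k % 26]
        while k >= 26:
            k //= 26
            out = letters[k % 26] + out
        return out + "ensis"

    rows = []
    for i in range(n):
        rows.append({
            "run_accession": f"SRR{9000000 + i}",
            "biosample": f"SAMN{7000000 + i}",
            "taxid": int(100000 + species_idx[i]),
            "species_name": f"{phyla[i]}genus {epithet(int(species_idx[i]))}",
            "phylum": phyla[i],
            "library_strategy": strategies[i],
            "library_layout": rng.choice(["PAIRED", "SINGLE"]),
            "avg_read_length": float(read_len[i]),
            "total_bases": int(gbases[i] * 1e9),
            "isolation_source": rng.choice(["sea water", "soil", "host tissue", ""]),
            "geo_loc_name": rng.choice(["Spain", "Japan", "USA", ""]),
            "lat_lon": "",
        })
    return pd.DataFrame(rows)
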