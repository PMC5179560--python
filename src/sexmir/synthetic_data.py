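"""Synthetic paired miR/mRNA experiments with the study's statistical structure.

The generator emulates a 2 x 2 sex x stress factorial sequencing design with
pooled libraries: each library is a pool of ``pool_size`` animals, modelled
as the sum of independent animal-level negative-binomial draws.  Baseline
per-animal feature means are log-normal, spanning roughly four orders of
magnitude; per-feature NB dispersion follows the decreasing trend
``a0 + a1 / mean`` typical of bulk RNA-seq; animal sequencing depth is a
log-normal library-size factor.

Stress effects are sex-specific: each sex has disjoint sets of truly
up/down-regulated miRs and genes (drawn from expressed features) that
receive a log2 effect in stressed animals of that sex.  Regulated miRs
propagate anti-correlated effects to their true targets: each true target
of a regulated miR independently (probability ``coupling_prob``) receives
the opposite-sign effect attenuated by ``coupling_attenuation`` — the
modest per-interaction repression expected of a single miR-mRNA pair.
Two (or more) noisy prediction sources each report a subset of the true
miR-target edges (per-source sensitivity) plus false edges (per-source
false-positive rate), so the dual-source intersection step has real work
to do.  Female libraries are drawn only from animals in estrus or
proestrus, mirroring the estrous-controlled pooling of the study design.

Everything is reproducible byte-for-byte from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sexmir.io_formats import CountMatrix, SampleDesign, TargetPredictionTable

SEXES = ("male", "female")
CONDITIONS = ("control", "stress")


@dataclass
class SourceConfig:
    """One miR-target prediction source: recall of true edges and noise."""

    name: str
    sensitivity: float = 0.85
    false_positive_rate: float = 0.2  # false edges as a fraction of true edges

    def __post_init__(self) -> None:
        if not 0 <= self.sensitivity <= 1:
            raise ValueError("sensitivity must lie in [0, 1]")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be non-negative")


@dataclass
class SimulationConfig:
    """Scaled-down defaults of the study design: 12 libraries per assay
    (2 sexes x 2 conditions x 3 replicate libraries, each a pool of 5
    animals); 5000 candidate genes and 400 candidate miRs stand in for the
    full 19,827 / 781 candidate universes (full size is a config change).

    Effect sets: per sex, ``frac_effect_genes`` / ``frac_effect_mirs`` of
    features receive ``effect_log2fc`` in stressed animals, split between up
    and down per ``up_fraction``; males and females get disjoint sets, and
    the male direction split skews down / female less so, matching the
    direction asymmetry of the emulated study.
    """

    n_genes: int = 5000
    n_mirs: int = 400
    libraries_per_cell: int = 3
    pool_size: int = 5
    # per-animal NB dispersion trend: alpha(m) = a0 + a1 / m
    nb_dispersion_trend: tuple[float, float] = (0.05, 2.0)
    # baseline per-animal feature means: 10^Normal(mu, sigma)
    baseline_log10_mean: float = 1.0
    baseline_log10_sd: float = 1.0
    # animal library-size factor: log-normal with this mean and CV
    library_size_mean: float = 1.0
    library_size_cv: float = 0.25
    # stress effects
    frac_effect_genes: dict = field(default_factory=lambda: {"male": 0.05, "female": 0.05})
    frac_effect_mirs: dict = field(default_factory=lambda: {"male": 0.05, "female": 0.05})
    up_fraction_genes: dict = field(default_factory=lambda: {"male": 0.25, "female": 0.33})
    up_fraction_mirs: dict = field(default_factory=lambda: {"male": 0.6, "female": 0.64})
    effect_log2fc: float = 1.0
    # expressed-feature floor for planting effects and true targets (per-animal mean)
    min_expressed_mean: float = 5.0
    # miR-target truth and coupling
    targets_per_mir: int = 30
    coupling_prob: float = 0.5
    coupling_attenuation: float = 0.5
    # prediction sources (>= 2 for the intersection step)
    sources: list[SourceConfig] = field(
        default_factory=lambda: [
            SourceConfig("targetdb_A", 0.85, 0.20),
            SourceConfig("targetdb_B", 0.80, 0.25),
        ]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.coupling_prob <= 1:
            raise ValueError("coupling_prob must lie in [0, 1]")
        if self.coupling_attenuation < 0:
            raise ValueError("coupling_attenuation must be non-negative")
        a0, a1 = self.nb_dispersion_trend
        if a0 <= 0 or a1 < 0:
            raise ValueError("dispersion trend coefficients must be positive")
        for d in (self.frac_effect_genes, self.frac_effect_mirs,
                  self.up_fraction_genes, self.up_fraction_mirs):
            for sex, v in d.items():
                if sex not in SEXES:
                    raise ValueError(f"unknown sex {sex!r} in effect config")
                if not 0 <= v <= 1:
                    raise ValueError("effect fractions must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth for recovery tests.

    Per sex: the truly up/down miR and gene id sets (signs of the *total*
    planted log2 effect, direct plus coupled), the planted anti-correlated
    miR-target edges (mir, gene, sign of the miR x gene effect product,
    always negative), and the full per-sex log2 effect vectors; plus
    per-feature baseline means.
    """

    mirs_up: dict
    mirs_down: dict
    genes_up: dict
    genes_down: dict
    coupled_edges: dict  # sex -> list of (mir_id, gene_id)
    gene_log2fc: dict  # sex -> pd.Series over gene ids
    mir_log2fc: dict  # sex -> pd.Series over mir ids
    true_targets: dict  # mir_id -> set of gene ids (all miRs)
    gene_baseline: pd.Series
    mir_baseline: pd.Series


# ---------------------------------------------------------------------------


def _gene_ids(n: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(n)]


def _mir_ids(n: int) -> list[str]:
    return [f"miR-{i:04d}" for i in range(n)]


def _effect_vector(
    rng: np.random.Generator,
    ids: list[str],
    baseline: np.ndarray,
    frac: dict,
    up_frac: dict,
    delta: float,
    min_mean: float,
) -> dict[str, pd.Series]:
    """Per-sex log2 effect vectors with disjoint male/female effect sets,
    drawn from expressed features."""
    expressed = np.flatnonzero(baseline >= min_mean)
    n_total = {sex: int(round(frac[sex] * len(ids))) for sex in SEXES}
    need = sum(n_total.values())
    if need > len(expressed):
        raise ValueError(
            f"effect sets need {need} expressed features but only "
            f"{len(expressed)} have baseline mean >= {min_mean}"
        )
    chosen = rng.choice(expressed, size=need, replace=False)
    out = {}
    offset = 0
    for sex in SEXES:
        vec = pd.Series(0.0, index=ids)
        n = n_total[sex]
        sex_idx = chosen[offset : offset + n]
        offset += n
        n_up = int(round(up_frac[sex] * n))
        for j, i in enumerate(sex_idx):
            vec.iloc[int(i)] = delta if j < n_up else -delta
        out[sex] = vec
    return out


def _assign_targets(
    rng: np.random.Generator,
    mir_ids: list[str],
    gene_ids: list[str],
    gene_baseline: np.ndarray,
    per_mir: int,
    min_mean: float,
) -> dict[str, set[str]]:
    expressed = [gene_ids[i] for i in np.flatnonzero(gene_baseline >= min_mean)]
    k = min(per_mir, len(expressed))
    return {
        mir: set(rng.choice(expressed, size=k, replace=False)) for mir in mir_ids
    }


def _apply_coupling(
    rng: np.random.Generator,
    config: SimulationConfig,
    mir_fx: dict[str, pd.Series],
    gene_fx: dict[str, pd.Series],
    true_targets: dict[str, set[str]],
) -> dict[str, list[tuple[str, str]]]:
    """Propagate attenuated opposite-sign effects from regulated miRs to their
    targets; returns, per sex, the edges whose net miR x gene product is
    negative (the planted anti-correlated couplings)."""
    coupled: dict[str, list[tuple[str, str]]] = {sex: [] for sex in SEXES}
    candidate: dict[str, list[tuple[str, str, float]]] = {sex: [] for sex in SEXES}
    for sex in SEXES:
        fx = mir_fx[sex]
        for mir in fx.index[fx != 0.0]:
            delta = fx.loc[mir]
            for gene in sorted(true_targets.get(mir, set())):
                if rng.random() < config.coupling_prob:
                    gene_fx[sex].loc[gene] += -delta * config.coupling_attenuation
                    candidate[sex].append((mir, gene, delta))
    for sex in SEXES:
        for mir, gene, delta in candidate[sex]:
            net = gene_fx[sex].loc[gene]
            if net != 0.0 and np.sign(delta) * np.sign(net) < 0:
                coupled[sex].append((mir, gene))
    return coupled


def _simulate_counts(
    rng: np.random.Generator,
    config: SimulationConfig,
    ids: list[str],
    baseline: np.ndarray,
    effects: dict[str, pd.Series],
    design: pd.DataFrame,
    assay: str,
) -> CountMatrix:
    """Library counts as sums of pool_size animal-level NB draws."""
    a0, a1 = config.nb_dispersion_trend
    alpha = a0 + a1 / np.maximum(baseline, 1e-8)
    size = 1.0 / alpha  # NB shape parameter n
    cv = config.library_size_cv
    sigma2 = np.log1p(cv**2)
    mu_ln = np.log(config.library_size_mean) - sigma2 / 2.0

    counts = np.zeros((len(ids), len(design)), dtype=np.int64)
    for j, row in design.iterrows():
        fx = effects[row["sex"]].to_numpy() if row["condition"] == "stress" else 0.0
        mean_animal = baseline * np.power(2.0, fx)
        for _ in range(config.pool_size):
            s = rng.lognormal(mu_ln, np.sqrt(sigma2))
            mu = np.maximum(mean_animal * s, 1e-12)
            p = size / (size + mu)
            counts[:, j] += rng.negative_binomial(size, p)
    return CountMatrix(ids, list(design["sample_id"]), counts, assay)


def _build_design(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        for cond in CONDITIONS:
            for r in range(config.libraries_per_cell):
                estrous = (
                    "not_applicable"
                    if sex == "male"
                    else ("estrus" if r % 2 == 0 else "proestrus")
                )
                rows.append(
                    {
                        "sample_id": f"lib_{sex}_{cond}_{r + 1}",
                        "sex": sex,
                        "condition": cond,
                        "estrous": estrous,
                        "pool_size": config.pool_size,
                    }
                )
    return pd.DataFrame(rows)


def _build_predictions(
    rng: np.random.Generator,
    config: SimulationConfig,
    true_targets: dict[str, set[str]],
    mir_ids: list[str],
    gene_ids: list[str],
) -> TargetPredictionTable:
    true_pairs = sorted(
        (mir, gene) for mir, genes in true_targets.items() for gene in genes
    )
    records = []
    for src in config.sources:
        hit = rng.random(len(true_pairs)) < src.sensitivity
        for (mir, gene), h in zip(true_pairs, hit):
            if h:
                records.append({"mir_id": mir, "gene_id": gene, "source": src.name})
        n_false = int(round(src.false_positive_rate * len(true_pairs)))
        existing = set(true_pairs)
        added = 0
        while added < n_false:
            mir = mir_ids[int(rng.integers(len(mir_ids)))]
            gene = gene_ids[int(rng.integers(len(gene_ids)))]
            if (mir, gene) in existing:
                continue
            existing.add((mir, gene))
            records.append({"mir_id": mir, "gene_id": gene, "source": src.name})
            added += 1
    return TargetPredictionTable(pd.DataFrame(records))


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def simulate_experiment(
    config: SimulationConfig, seed: int | None = None
) -> tuple[CountMatrix, CountMatrix, SampleDesign, TargetPredictionTable, GroundTruth]:
    """One full paired experiment: miR counts, mRNA counts, design, predicted
    targets from every configured source, and the planted ground truth."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("baseline", "effects", "targets", "coupling", "counts_mir",
             "counts_mrna", "predictions"),
            root.spawn(7),
        )
    }

    gene_ids = _gene_ids(config.n_genes)
    mir_ids = _mir_ids(config.n_mirs)
    rng_b = streams["baseline"]
    gene_baseline = np.power(
        10.0, rng_b.normal(config.baseline_log10_mean, config.baseline_log10_sd, config.n_genes)
    )
    mir_baseline = np.power(
        10.0, rng_b.normal(config.baseline_log10_mean, config.baseline_log10_sd, config.n_mirs)
    )

    rng_e = streams["effects"]
    gene_fx = _effect_vector(
        rng_e, gene_ids, gene_baseline, config.frac_effect_genes,
        config.up_fraction_genes, config.effect_log2fc, config.min_expressed_mean,
    )
    mir_fx = _effect_vector(
        rng_e, mir_ids, mir_baseline, config.frac_effect_mirs,
        config.up_fraction_mirs, config.effect_log2fc, config.min_expressed_mean,
    )

    true_targets = _assign_targets(
        streams["targets"], mir_ids, gene_ids, gene_baseline,
        config.targets_per_mir, config.min_expressed_mean,
    )
    coupled = _apply_coupling(streams["coupling"], config, mir_fx, gene_fx, true_targets)

    design_df = _build_design(config)
    mir_counts = _simulate_counts(
        streams["counts_mir"], config, mir_ids, mir_baseline, mir_fx, design_df, "miR"
    )
    mrna_counts = _simulate_counts(
        streams["counts_mrna"], config, gene_ids, gene_baseline, gene_fx, design_df, "mRNA"
    )
    predictions = _build_predictions(
        streams["predictions"], config, true_targets, mir_ids, gene_ids
    )

    truth = GroundTruth(
        mirs_up={s: set(mir_fx[s].index[mir_fx[s] > 0]) for s in SEXES},
        mirs_down={s: set(mir_fx[s].index[mir_fx[s] < 0]) for s in SEXES},
        genes_up={s: set(gene_fx[s].index[gene_fx[s] > 0]) for s in SEXES},
        genes_down={s: set(gene_fx[s].index[gene_fx[s] < 0]) for s in SEXES},
        coupled_edges=coupled,
        gene_log2fc=gene_fx,
        mir_log2fc=mir_fx,
        true_targets=true_targets,
        gene_baseline=pd.Series(gene_baseline, index=gene_ids),
        mir_baseline=pd.Series(mir_baseline, index=mir_ids),
    )
    # both assays come from the same pooled libraries (size-separated RNA
    # fractions), so they share a single design table
    design = SampleDesign(design_df)
    return mir_counts, mrna_counts, design, predictions, truth


def simulate_null_experiment(
    config: SimulationConfig, seed: int | None = None
):
    """As :func:`simulate_experiment` with all effect sets forced empty."""
    from dataclasses import replace

    null_cfg = replace(
        config,
        frac_effect_genes={"male": 0.0, "female": 0.0},
        frac_effect_mirs={"male": 0.0, "female": 0.0},
        coupling_prob=0.0,
    )
    return simulate_experiment(null_cfg, seed=seed)
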