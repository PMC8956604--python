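"""Synthetic data generators for the screen and cohort analyses.

This module fabricates every input the pipeline consumes:

* a pooled CRISPR-activation guide library (a fixed number of guides per
  target plus a designated housekeeping negative-control gene list),
* negative-binomial sgRNA count matrices under acute (one round) or chronic
  (three rounds) T cell selection with planted, recoverable resistance
  effects, and
* tumor expression cohorts with a planted correlation between candidate-gene
  expression and immune cytolytic activity, optionally carrying multi-dataset
  immunotherapy response labels with a configurable nonresponder shift of the
  candidate signature.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning.  Stream order (library ->
effect-gene choice -> per-replicate baselines -> counts; or cohort latent ->
gene means -> noise) is fixed, so outputs are reproducible piecewise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LibraryDesign",
    "ScreenSimConfig",
    "ScreenResult",
    "CohortSimConfig",
    "ExpressionCohort",
    "generate_library",
    "simulate_screen",
    "selection_trajectory",
    "simulate_expression_cohort",
]


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its contract."""


# ---------------------------------------------------------------------------
# guide library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryDesign:
    """A pooled activation-screen guide library manifest.

    ``table`` has one row per guide with columns ``guide_id``, ``target_id``
    (isoform-level identifier), ``gene_symbol`` and ``is_negative_control``.
    Negative-control genes are housekeeping surrogates guaranteed effect 1 by
    :func:`simulate_screen`; they serve as the empirical null downstream.
    """

    table: pd.DataFrame
    guides_per_target: int

    @property
    def guide_ids(self) -> pd.Series:
        return self.table["guide_id"]

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene_symbol"].unique())

    @property
    def negative_control_genes(self) -> set[str]:
        mask = self.table["is_negative_control"]
        return set(self.table.loc[mask, "gene_symbol"])

    @property
    def n_guides(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LibraryDesign":
        table = pd.read_csv(path, sep="\t")
        table["is_negative_control"] = table["is_negative_control"].astype(bool)
        per = table.groupby("target_id").size()
        gpt = int(per.iloc[0]) if (per == per.iloc[0]).all() else -1
        return cls(table=table, guides_per_target=gpt)


def generate_library(
    n_targets: int,
    guides_per_target: int = 3,
    n_negative_controls: int = 0,
    seed: int = 0,
    isoforms_per_gene: int = 1,
) -> LibraryDesign:
    """Generate a guide library with ``guides_per_target`` guides per target.

    Targets are isoform-level identifiers; consecutive groups of
    ``isoforms_per_gene`` targets share one gene symbol.  A random subset of
    ``n_negative_controls`` gene symbols is flagged as the housekeeping
    negative-control set.  Deterministic for fixed ``seed``.
    """
    if n_targets <= 0 or guides_per_target <= 0 or isoforms_per_gene <= 0:
        raise InvalidConfigError("counts must be positive")
    if n_negative_controls < 0:
        raise InvalidConfigError("n_negative_controls must be non-negative")
    if n_targets % isoforms_per_gene != 0:
        raise InvalidConfigError("n_targets must be a multiple of isoforms_per_gene")
    n_genes = n_targets // isoforms_per_gene
    if n_negative_controls > n_genes:
        raise InvalidConfigError(
            f"n_negative_controls ({n_negative_controls}) exceeds number of "
            f"gene symbols ({n_genes})"
        )

    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    controls = set(rng.choice(genes, size=n_negative_controls, replace=False))

    rows = []
    for g_idx, gene in enumerate(genes):
        for iso in range(1, isoforms_per_gene + 1):
            target = f"{gene}-{iso:02d}"
            for sg in range(1, guides_per_target + 1):
                rows.append((f"{target}_sg{sg}", target, gene, gene in controls))
    table = pd.DataFrame(
        rows, columns=["guide_id", "target_id", "gene_symbol", "is_negative_control"]
    )
    return LibraryDesign(table=table, guides_per_target=guides_per_target)


# ---------------------------------------------------------------------------
# selection screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSimConfig:
    """Configuration of a simulated T cell selection screen.

    The abundance model: per replicate, baseline guide abundances are drawn
    log-normally (sigma on the natural-log scale) and normalized to sum 1.
    Each selection round multiplies the selected arm's abundance of every
    guide by its gene's fitness effect and renormalizes; the unselected
    control arm keeps the baseline abundance.  Sequencing counts are drawn
    negative-binomially with mean ``abundance * sequencing_depth * n_guides``
    and variance ``mu + nb_dispersion * mu**2``.

    ``rounds=1`` mirrors acute exposure, ``rounds=3`` chronic exposure with
    three rounds of screening selection.  Effect sizes are per-round
    multiplicative fitness advantages (>= 1); non-resistance and
    negative-control genes have effect exactly 1.
    """

    n_resistance_genes: int = 50
    effect_size: float = 2.0
    effect_sizes: dict[str, float] | None = None
    rounds: int = 3
    sequencing_depth: float = 500.0
    nb_dispersion: float = 0.2
    n_replicates: int = 2
    baseline_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise InvalidConfigError("rounds must be >= 1")
        if self.n_resistance_genes < 0:
            raise InvalidConfigError("n_resistance_genes must be non-negative")
        if self.sequencing_depth <= 0 or self.n_replicates <= 0:
            raise InvalidConfigError("depth and replicate counts must be positive")
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be > 0")
        if self.effect_size < 1:
            raise InvalidConfigError("effect_size must be >= 1")
        if self.effect_sizes is not None:
            bad = [g for g, e in self.effect_sizes.items() if e < 1]
            if bad:
                raise InvalidConfigError(f"effect sizes must be >= 1: {bad}")


@dataclass(frozen=True)
class ScreenResult:
    """Counts plus sample metadata and the planted effect map.

    ``counts`` has ``guide_id``, ``target_id``, ``gene_symbol`` columns
    followed by one integer column per sample named
    ``{arm}_rep{r}_round{t}``; ``samples`` records (sample, arm, replicate,
    round).  Per-round intermediates of the selected arm are emitted for
    rounds 0..rounds so distribution skew can be tracked round over round.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    effects: dict[str, float]
    config: ScreenSimConfig

    @property
    def resistance_genes(self) -> set[str]:
        return {g for g, e in self.effects.items() if e > 1}

    def sample_name(self, arm: str, replicate: int, round_index: int | None = None) -> str:
        t = self.config.rounds if round_index is None else round_index
        return f"{arm}_rep{replicate}_round{t}"

    def final_pairs(self) -> list[tuple[str, str]]:
        """(selected, control) sample-name pairs at the final round."""
        return [
            (self.sample_name("selected", r), self.sample_name("control", r))
            for r in range(1, self.config.n_replicates + 1)
        ]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # variance = mu + dispersion * mu^2  =>  shape n = 1/dispersion
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def selection_trajectory(
    baseline: np.ndarray, guide_effect: np.ndarray, rounds: int
) -> list[np.ndarray]:
    """Abundance vectors of the selected arm for rounds 0..rounds.

    Each round multiplies every guide's abundance by its fitness effect and
    renormalizes, so every vector sums to 1.
    """
    abundance = np.asarray(baseline, dtype=float)
    abundance = abundance / abundance.sum()
    out = [abundance]
    for _ in range(rounds):
        abundance = abundance * guide_effect
        abundance = abundance / abundance.sum()
        out.append(abundance)
    return out


def simulate_screen(library: LibraryDesign, config: ScreenSimConfig) -> ScreenResult:
    """Simulate selected/control count matrices with planted resistance genes.

    Resistance genes are drawn from the non-control gene symbols (so the
    negative-control set stays a clean empirical null) unless an explicit
    ``effect_sizes`` map is supplied.  Per-round intermediate matrices of both
    arms are included in the output.
    """
    genes = library.table["gene_symbol"].to_numpy()
    gene_set = set(library.genes)
    controls = library.negative_control_genes

    ss = np.random.SeedSequence(config.seed)
    choice_ss, *rep_ss = ss.spawn(1 + config.n_replicates)

    if config.effect_sizes is not None:
        missing = sorted(set(config.effect_sizes) - gene_set)
        if missing:
            raise InvalidConfigError(f"effect map references genes absent from library: {missing}")
        bad = sorted(g for g, e in config.effect_sizes.items() if g in controls and e != 1)
        if bad:
            raise InvalidConfigError(f"negative-control genes must keep effect 1: {bad}")
        effects = dict(config.effect_sizes)
    else:
        eligible = sorted(gene_set - controls)
        if config.n_resistance_genes > len(eligible):
            raise InvalidConfigError("more resistance genes requested than eligible genes")
        rng = np.random.default_rng(choice_ss)
        chosen = rng.choice(eligible, size=config.n_resistance_genes, replace=False)
        effects = {g: config.effect_size for g in chosen}

    guide_effect = np.array([effects.get(g, 1.0) for g in genes], dtype=float)
    n_guides = library.n_guides

    sample_cols: dict[str, np.ndarray] = {}
    sample_meta = []
    for rep_idx, rep_seq in enumerate(rep_ss, start=1):
        base_rng, count_rng = (np.random.default_rng(s) for s in rep_seq.spawn(2))
        baseline = np.exp(base_rng.normal(0.0, config.baseline_sigma, size=n_guides))
        baseline /= baseline.sum()

        trajectory = selection_trajectory(baseline, guide_effect, config.rounds)
        for t in range(config.rounds + 1):
            for arm, ab in (("selected", trajectory[t]), ("control", baseline)):
                name = f"{arm}_rep{rep_idx}_round{t}"
                mean = ab * config.sequencing_depth * n_guides
                sample_cols[name] = _nb_counts(count_rng, mean, config.nb_dispersion)
                sample_meta.append((name, arm, rep_idx, t))

    counts = library.table[["guide_id", "target_id", "gene_symbol"]].copy()
    for name, col in sample_cols.items():
        counts[name] = col
    samples = pd.DataFrame(sample_meta, columns=["sample", "arm", "replicate", "round"])
    return ScreenResult(counts=counts, samples=samples, effects=effects, config=config)


# ---------------------------------------------------------------------------
# expression cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of a simulated tumor expression cohort.

    One latent immune-activity factor per sample drives the cytolytic marker
    genes (GZMA, PRF1) almost deterministically; each signature gene is given
    Pearson correlation ``planted_correlation`` with the latent factor on the
    log2 scale.  ``signature_shift`` is the standardized mean difference added
    to signature genes in nonresponders.  ``group_offset_step`` adds a global
    per-dataset location offset (dataset d gets ``d * step``), emulating
    cross-dataset batch scale that per-dataset z-scoring must remove.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 100
    n_groups: int = 3
    group_kind: str = "dataset"  # or "tumor_type"
    planted_correlation: float = 0.0
    responder_fraction: float = 0.5
    signature_shift: float = 0.0
    gene_mean_loc: float = 4.0
    gene_mean_scale: float = 1.0
    gene_sd: float = 1.0
    marker_noise_sd: float = 0.1
    group_offset_step: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.planted_correlation <= 1.0:
            raise InvalidConfigError("planted_correlation must lie in [-1, 1]")
        if not 0.0 < self.responder_fraction < 1.0:
            raise InvalidConfigError("responder_fraction must lie in (0, 1)")
        if self.n_genes <= 2 or self.n_samples_per_group < 2 or self.n_groups < 1:
            raise InvalidConfigError("cohort sizes too small")


@dataclass
class ExpressionCohort:
    """A gene x sample expression matrix with per-sample metadata.

    ``expr`` rows are gene symbols, columns sample ids; ``scale`` flags
    whether values are ``log2`` (log2(TPM+1)) or ``linear``.  ``meta`` is
    indexed by sample id with a ``group`` column (tumor type or dataset id)
    and an optional ``response`` column ({responder, nonresponder}).
    """

    expr: pd.DataFrame
    meta: pd.DataFrame
    scale: str = "log2"
    group_kind: str = "dataset"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError("scale must be 'log2' or 'linear'")
        if self.scale == "linear" and (self.expr.to_numpy() < 0).any():
            raise ValueError("linear-scale expression must be non-negative")
        missing = set(self.expr.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)[:5]}")

    def linear(self) -> pd.DataFrame:
        """Expression on the linear (TPM-like) scale."""
        if self.scale == "linear":
            return self.expr
        return np.maximum(2.0 ** self.expr - 1.0, 0.0)

    def to_tsv(self, expr_path, meta_path) -> None:
        self.expr.to_csv(expr_path, sep="\t", index_label="gene")
        self.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


CYT_MARKERS = ("GZMA", "PRF1")


def simulate_expression_cohort(
    config: CohortSimConfig, signature_genes: set[str] | None = None
) -> ExpressionCohort:
    """Simulate a multi-group expression cohort with planted structure.

    The gene universe is ``GENE00000..`` plus GZMA and PRF1.  Signature genes
    (default: none) must be drawn from that universe; an error lists any
    missing symbols.  Log2 values are clipped at 0 so the linear scale stays
    non-negative.
    """
    gene_names = [f"GENE{i:05d}" for i in range(config.n_genes - 2)] + list(CYT_MARKERS)
    universe = set(gene_names)
    signature = set() if signature_genes is None else set(signature_genes)
    missing = sorted(signature - universe)
    if missing:
        raise InvalidConfigError(f"signature genes absent from simulated universe: {missing}")

    ss = np.random.SeedSequence(config.seed)
    mean_rng, *group_ss = ss.spawn(1 + config.n_groups)
    rng_means = np.random.default_rng(mean_rng)
    gene_mu = rng_means.normal(config.gene_mean_loc, config.gene_mean_scale, size=len(gene_names))
    mu = pd.Series(gene_mu, index=gene_names)
    mu[list(CYT_MARKERS)] = config.gene_mean_loc + 1.0  # markers kept well above zero

    r = config.planted_correlation
    resid = math.sqrt(max(0.0, 1.0 - r * r))
    sig_mask = np.array([g in signature for g in gene_names])
    marker_mask = np.array([g in CYT_MARKERS for g in gene_names])

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for g_idx, g_seq in enumerate(group_ss):
        rng = np.random.default_rng(g_seq)
        group_id = f"{config.group_kind}{g_idx + 1}"
        offset = config.group_offset_step * g_idx
        n = config.n_samples_per_group
        z = rng.normal(size=n)
        responder = rng.random(n) < config.responder_fraction
        noise = rng.normal(size=(len(gene_names), n))
        x = np.empty_like(noise)
        x[~sig_mask & ~marker_mask] = noise[~sig_mask & ~marker_mask]
        x[sig_mask] = r * z[None, :] + resid * noise[sig_mask]
        x[marker_mask] = z[None, :] + config.marker_noise_sd * noise[marker_mask]
        expr = mu.to_numpy()[:, None] + offset + config.gene_sd * x
        if config.signature_shift != 0.0:
            expr[np.ix_(sig_mask, ~responder)] += config.signature_shift * config.gene_sd
        expr = np.maximum(expr, 0.0)
        for s_idx in range(n):
            sample = f"{group_id}_s{s_idx + 1:04d}"
            cols[sample] = expr[:, s_idx]
            meta_rows.append(
                (sample, group_id, "responder" if responder[s_idx] else "nonresponder")
            )

    expr_df = pd.DataFrame(cols, index=gene_names)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "group", "response"]).set_index(
        "sample_id"
    )
    return ExpressionCohort(expr=expr_df, meta=meta, scale="log2", group_kind=config.group_kind)
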