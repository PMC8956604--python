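import numpy as np
import pytest

from tcellscreen import enrichment, simulate

SPIKE_SEED = 11


def score_replicate(result, replicate, n_permutations=10_000, seed=101, alpha=0.05):
    """Normalize, compute LFC and RRA scores for one screening replicate."""
    normed = enrichment.normalize_counts(result.counts)
    sel = result.sample_name("selected", replicate)
    ctl = result.sample_name("control", replicate)
    enr = enrichment.compute_sgrna_lfc(normed, sel, ctl)
    scores = enrichment.rra_gene_score(
        enr, alpha=alpha, n_permutations=n_permutations, seed=seed + replicate
    )
    return enrichment.rank_genes(scores)


@pytest.fixture(scope="session")
def spike_screen():
    """The standard spike-in simulation: 1,000 genes x 3 guides, 50 planted
    resistance genes at per-round effect 2.0, chronic 3 rounds, depth 500,
    dispersion 0.2, 2 replicates."""
    lib = simulate.generate_library(1000, 3, n_negative_controls=50, seed=SPIKE_SEED)
    cfg = simulate.ScreenSimConfig(
        n_resistance_genes=50,
        effect_size=2.0,
        rounds=3,
        sequencing_depth=500,
        nb_dispersion=0.2,
        n_replicates=2,
        seed=SPIKE_SEED,
    )
    return lib, simulate.simulate_screen(lib, cfg)


@pytest.fixture(scope="session")
def spike_rankings(spike_screen):
    _, result = spike_screen
    return [score_replicate(result, r) for r in (1, 2)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928 % 2**31)
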