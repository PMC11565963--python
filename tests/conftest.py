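import numpy as np
import pandas as pd
import pytest

from popfit import (
    CompetitionDesign,
    GenotypeMatrix,
    ModelConfig,
    PopulationSimConfig,
    aggregate,
    classify,
    fit_hierarchical,
    remove_outlier_barcodes,
    simulate_competition,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_design():
    return CompetitionDesign(
        n_edits=40,
        barcodes_per_edit=4,
        n_neutral_barcodes=10,
        n_replicates=3,
        conditions=("2D",),
        n_timepoints=6,
        reads_per_timepoint=200_000,
        bottleneck_cells=1_000_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_competition(small_design):
    return simulate_competition(small_design)


@pytest.fixture(scope="session")
def small_fit(small_design, small_competition):
    """Fit of the small simulated competition, classified at 95%."""
    table, truth = small_competition
    neutral = set(small_design.neutral_ids)
    agg = aggregate(remove_outlier_barcodes(table, neutral_ids=neutral))
    post, mean_fit, diags = fit_hierarchical(agg, neutral, ModelConfig(), tau=small_design.tau)
    post = classify(post)
    return post, mean_fit, diags, truth


@pytest.fixture(scope="session")
def small_population():
    cfg = PopulationSimConfig(
        seed=3,
        n_strains=60,
        n_variants=150,
        clade_spec=(
            ("dom1", "domesticated", 18),
            ("dom2", "domesticated", 12),
            ("wild1", "wild", 8),
            ("wild2", "wild", 7),
            ("other1", "other", 15),
        ),
    )
    G_df, meta, tree = simulate_population(cfg)
    return GenotypeMatrix(G_df), meta, tree


def random_genotype_frame(rng, n_variants=50, n_strains=30, p_geometric=0.3):
    """Unstructured matrix: carrier count ~ 1 + geometric, carriers uniform."""
    M = np.zeros((n_variants, n_strains), dtype=np.int8)
    for i in range(n_variants):
        k = min(1 + rng.geometric(p_geometric), n_strains)
        carriers = rng.choice(n_strains, size=k, replace=False)
        M[i, carriers] = rng.choice([1, 2], size=k)
    return pd.DataFrame(
        M,
        index=[f"v{i:03d}" for i in range(n_variants)],
        columns=[f"s{j:03d}" for j in range(n_strains)],
    )
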