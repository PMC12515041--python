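import numpy as np
import pandas as pd
import pytest

import guildcraft as gc


@pytest.fixture
def small_table():
    """12 samples x 8 features, positive counts, no zeros."""
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        rng.integers(1, 60, (12, 8)).astype(np.int64),
        index=pd.Index([f"s{i}" for i in range(12)], name="sample-id"),
        columns=[f"f{i}" for i in range(8)],
    )


@pytest.fixture
def paired_meta():
    """Metadata for 12 samples: 6 mice sampled twice (baseline / week12)."""
    rows = []
    for i in range(6):
        for j, tp in enumerate(("baseline", "week12")):
            rows.append(
                {
                    "sample-id": f"s{2 * i + j}",
                    "subject-id": f"m{i}",
                    "cage": f"c{i // 3}",
                    "diet": "HFD" if i % 2 else "NFD",
                    "regime": "TRF" if i < 3 else "ad_libitum",
                    "timepoint": tp,
                    "zt_hours": 1.0,
                }
            )
    return pd.DataFrame(rows).set_index("sample-id")


def block_sim_config(seed, n_features=60, n_blocks=4, corr=0.7, n_subjects=30,
                     depth=20_000, sparsity=0.1):
    """Planted-block community at the guild-recovery study conditions:
    60 samples (30 mice x 2 timepoints), depth 20 000."""
    return gc.SimConfig(
        n_subjects=n_subjects,
        n_features=n_features,
        n_blocks=n_blocks,
        within_block_corr=corr,
        depth=depth,
        sparsity_target=sparsity,
        base_abundance_sd=1.0,
        unclassifiable_fraction=0.2,
        block_effects={},
        rhythmic_blocks={},
        phenotypes={},
        seed=seed,
    )


def recover_cags(cfg, alpha=0.001, n_perm=1_999, seed=0):
    """Run the guild pipeline on a simulated community; return (assignment, truth)."""
    table, meta, _, truth = gc.simulate_community(cfg)
    rmat = gc.rclr(table)
    corr = gc.correlation_matrix(rmat, meta)
    dist = gc.corr_to_distance(corr)
    tree = gc.ward_tree(dist)
    assignment = gc.split_cags(tree, dist, alpha=alpha, n_perm=n_perm, seed=seed,
                               table=table)
    return assignment, truth
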