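import dataclasses

import pandas as pd
import pytest

import convergene as cg
from convergene.simulate import HIT_COLUMNS, SimulationConfig


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Compact study conditions for unit tests (12 genomes, 3 environments)."""
    return SimulationConfig(
        n_genomes=12, core_size=40, ancestral_accessory=30, pool_size=8,
        polyphyly_events=2, seed=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """(config, tree, environment assignment, genome set, hit table)."""
    cfg = small_cfg
    tree = cg.simulate_tree(cfg.n_genomes, seed=cfg.stage_seed("tree"),
                            birth_rate=cfg.birth_rate)
    env = cg.assign_environments(tree, cfg.n_environments,
                                 cfg.polyphyly_events,
                                 seed=cfg.stage_seed("environments"))
    genomes = cg.evolve_gene_content(tree, env, cfg)
    hits = cg.synthesize_hit_table(genomes, tree, cfg)
    return cfg, tree, env, genomes, hits


def make_hits(rows):
    """Build a 13-column hit table from (qseqid, sseqid, bitscore, qcovs[,
    pident[, length]]) tuples; gene IDs follow the genome|gene convention."""
    records = []
    for row in rows:
        q, s, score, cov = row[:4]
        pident = row[4] if len(row) > 4 else 90.0
        length = row[5] if len(row) > 5 else 300
        records.append(
            (q, s, pident, length, 10, 0, 1, int(length * cov), 1,
             int(length * cov), 1e-50, score, cov)
        )
    return pd.DataFrame(records, columns=HIT_COLUMNS)


@pytest.fixture()
def hits_builder():
    return make_hits
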