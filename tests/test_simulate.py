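import dataclasses
import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import convergene as cg
from convergene import trees as tr
from convergene.exceptions import ValidationError
from convergene.simulate import (
    ENVIRONMENTS,
    SimulationConfig,
    synthesize_assignments,
    write_fixture_bundle,
)


class TestSimulateTree:
    def test_two_tips_is_a_cherry(self):
        tree = cg.simulate_tree(2, seed=1)
        assert len(tree.leaf_nodes()) == 2
        assert len([n for n in tree if not n.is_leaf()]) == 1

    def test_rooted_binary_node_count(self):
        tree = cg.simulate_tree(8, seed=5)
        leaves = [n for n in tree if n.is_leaf()]
        internal = [n for n in tree if not n.is_leaf()]
        assert len(leaves) == 8
        assert len(internal) == 7
        assert all(len(n.child_nodes()) == 2 for n in internal)

    def test_deterministic_newick(self):
        a = tr.write_newick(cg.simulate_tree(10, seed=42))
        b = tr.write_newick(cg.simulate_tree(10, seed=42))
        assert a == b
        c = tr.write_newick(cg.simulate_tree(10, seed=43))
        assert a != c

    def test_too_few_tips(self):
        with pytest.raises(ValidationError):
            cg.simulate_tree(1, seed=0)


def maximal_clades(tree, tips):
    """Set of maximal clades (as frozensets) whose leaves all lie in
    ``tips``."""
    tips = set(tips)
    below = {}
    clades = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
    for node in tree.preorder_node_iter():
        if below[node] <= tips:
            parent = node.parent_node
            if parent is None or not (below[parent] <= tips):
                clades.add(below[node])
    return clades


class TestAssignEnvironments:
    def test_zero_events_gives_monophyletic_environments(self):
        tree = cg.simulate_tree(20, seed=2)
        env = cg.assign_environments(tree, 3, 0, seed=9)
        for e in set(env.labels.values()):
            tips = {t for t, l in env.labels.items() if l == e}
            assert len(maximal_clades(tree, tips)) == 1
        assert env.reassigned == {}

    def test_polyphyly_events_create_polyphyly(self):
        tree = cg.simulate_tree(20, seed=2)
        env = cg.assign_environments(tree, 3, 2, seed=9)
        spans = []
        for e in set(env.labels.values()):
            tips = {t for t, l in env.labels.items() if l == e}
            spans.append(len(maximal_clades(tree, tips)))
        assert max(spans) >= 2
        assert len(env.reassigned) > 0
        for tip, (old, new) in env.reassigned.items():
            assert env.labels[tip] == new != old

    def test_single_environment(self):
        tree = cg.simulate_tree(6, seed=2)
        env = cg.assign_environments(tree, 1, 5, seed=1)
        assert set(env.labels.values()) == {ENVIRONMENTS[0]}

    def test_vocabulary_closed_and_totals(self):
        tree = cg.simulate_tree(15, seed=4)
        env = cg.assign_environments(tree, 4, 1, seed=4)
        assert set(env.labels.values()) <= set(ENVIRONMENTS)
        assert sum(env.counts().values()) == 15

    def test_too_many_environments(self):
        tree = cg.simulate_tree(3, seed=2)
        with pytest.raises(ValidationError):
            cg.assign_environments(tree, 4, 0, seed=0)


class TestEvolveGeneContent:
    def test_static_model_keeps_ancestral_profile(self):
        cfg = SimulationConfig(n_genomes=8, gain_rate=0, loss_rate=0,
                               pool_gain_prob=0, core_size=20,
                               ancestral_accessory=10, seed=7)
        tree = cg.simulate_tree(8, seed=cfg.stage_seed("tree"))
        env = cg.assign_environments(tree, 2, 0, seed=0)
        gs = cg.evolve_gene_content(tree, env, cfg)
        ancestral = {f for f in gs.profiles[gs.genomes[0]]}
        assert len(ancestral) == 30
        assert all(gs.profiles[g] == ancestral for g in gs.genomes)

    def test_forced_pool_acquisition(self):
        cfg = SimulationConfig(n_genomes=8, pool_gain_prob=1.0, pool_size=5,
                               core_size=10, ancestral_accessory=5, seed=7)
        tree = cg.simulate_tree(8, seed=cfg.stage_seed("tree"))
        env = cg.assign_environments(tree, 2, 0, seed=0)
        gs = cg.evolve_gene_content(tree, env, cfg)
        for g in gs.genomes:
            pool = set(gs.pools[env.labels[g]])
            assert pool <= gs.profiles[g]

    def test_core_never_lost(self):
        cfg = SimulationConfig(n_genomes=10, loss_rate=2.0, core_size=15,
                               ancestral_accessory=40, seed=5)
        tree = cg.simulate_tree(10, seed=cfg.stage_seed("tree"))
        env = cg.assign_environments(tree, 2, 0, seed=0)
        gs = cg.evolve_gene_content(tree, env, cfg)
        core = set(gs.core_families)
        for g in gs.genomes:
            assert core <= gs.profiles[g]

    def test_poisson_gain_mean(self):
        """Mean gains on 2000 replicate branches of length 1.5 at rate 2
        stays within 3 standard errors of the analytic mean 3.0."""
        n = 2000
        tips = ",".join(f"T{i}:1.5" for i in range(n))
        tree = tr.read_newick(f"({tips});")
        cfg = SimulationConfig(n_genomes=n, gain_rate=2.0, loss_rate=0,
                               pool_gain_prob=0, pool_size=0, core_size=1,
                               ancestral_accessory=0, seed=11)
        labels = {f"T{i}": "Aquatic" for i in range(n)}
        gs = cg.evolve_gene_content(tree, labels, cfg)
        gains = [len(gs.profiles[g]) - 1 for g in gs.genomes]
        se = math.sqrt(3.0 / n)
        assert abs(np.mean(gains) - 3.0) <= 3 * se

    def test_pools_disjoint_from_vertical_families(self, small_dataset):
        _, _, _, gs, _ = small_dataset
        pool_fams = {f for fams in gs.pools.values() for f in fams}
        vertical = {
            f for g in gs.genomes for f in gs.profiles[g]
        } - pool_fams
        assert not pool_fams & vertical
        envs = list(gs.pools)
        for i, a in enumerate(envs):
            for b in envs[i + 1:]:
                assert not set(gs.pools[a]) & set(gs.pools[b])

    def test_jaccard_similarity_decays_with_patristic_distance(self):
        """Rank correlation between patristic distance and content distance
        is positive in each of 10 pool-free simulated datasets."""
        from convergene.profiles import profile_distance_matrix
        from convergene.simulate import _patristic_matrix

        for seed in range(10):
            cfg = SimulationConfig(n_genomes=12, pool_gain_prob=0, seed=seed,
                                   core_size=30, ancestral_accessory=40)
            tree = cg.simulate_tree(12, seed=cfg.stage_seed("tree"))
            env = cg.assign_environments(tree, 3, 0,
                                         seed=cfg.stage_seed("environments"))
            gs = cg.evolve_gene_content(tree, env, cfg)
            jd = profile_distance_matrix(gs.profiles).loc[gs.genomes, gs.genomes]
            pat = _patristic_matrix(tree, gs.genomes)
            iu = np.triu_indices(len(gs.genomes), 1)
            rho = spearmanr(pat[iu], jd.to_numpy()[iu]).statistic
            assert rho > 0


@pytest.fixture(scope="module")
def fixed_tree_hits():
    tree = tr.read_newick(
        "((A:0.3,B:0.2):0.2,(C:0.4,D:0.1):0.3);"
    )
    cfg = SimulationConfig(n_genomes=4, noise_sd=0.0, spurious_rate=0.0,
                           low_coverage_frac=0.0, core_size=10,
                           ancestral_accessory=5, pool_size=3, seed=21)
    labels = {"A": "Aquatic", "B": "Aquatic",
              "C": "Terrestrial", "D": "Terrestrial"}
    gs = cg.evolve_gene_content(tree, labels, cfg)
    hits = cg.synthesize_hit_table(gs, tree, cfg)
    return tree, gs, hits


class TestSynthesizeHitTable:

    def test_self_hit_strictly_best_without_noise(self, fixed_tree_hits):
        _, _, hits = fixed_tree_hits
        self_scores = hits[hits.qseqid == hits.sseqid].set_index("qseqid")["bitscore"]
        cross = hits[hits.qseqid != hits.sseqid]
        best_cross = cross.groupby("qseqid")["bitscore"].max()
        for gene, score in best_cross.items():
            assert score < self_scores[gene]

    def test_shared_family_mutual_best(self, fixed_tree_hits):
        _, gs, hits = fixed_tree_hits
        lookup = gs.gene_lookup()
        shared = sorted(gs.profiles["A"] & gs.profiles["B"])[0]
        ga, gb = lookup[("A", shared)], lookup[("B", shared)]
        a_hits = hits[(hits.qseqid.str.startswith("A|"))
                      & (hits.sseqid.str.startswith("B|"))]
        assert a_hits.loc[a_hits.bitscore.idxmax(), "qseqid"].startswith("A|")
        best_for_ga = a_hits[a_hits.qseqid == ga].sort_values(
            "bitscore", ascending=False
        ).iloc[0]
        assert best_for_ga.sseqid == gb

    def test_bitscore_monotone_in_patristic_distance(self, fixed_tree_hits):
        tree, gs, hits = fixed_tree_hits
        from convergene.simulate import _patristic_matrix

        genomes = gs.genomes
        pat = _patristic_matrix(tree, genomes)
        lookup = gs.gene_lookup()
        family = sorted(gs.core_families)[0]
        rows = []
        for i, a in enumerate(genomes):
            for j, b in enumerate(genomes):
                if i == j:
                    continue
                ga, gb = lookup[(a, family)], lookup[(b, family)]
                score = hits[(hits.qseqid == ga) & (hits.sseqid == gb)
                             ].bitscore.iloc[0]
                rows.append((pat[i, j], score))
        rows.sort()
        scores = [s for _, s in rows]
        assert all(x >= y - 1e-9 for x, y in zip(scores, scores[1:]))

    def test_coverage_mixture_straddles_floor(self, small_dataset):
        _, _, _, _, hits = small_dataset
        cross = hits[hits.qseqid != hits.sseqid]
        frac_below = (cross.qcovs < 0.70).mean()
        assert 0.02 < frac_below < 0.25


class TestFixtureBundle:
    def test_bundle_files_and_determinism(self, tmp_path):
        cfg = SimulationConfig(n_genomes=8, core_size=15,
                               ancestral_accessory=10, pool_size=4, seed=13)
        m1 = write_fixture_bundle(tmp_path / "a", cfg)
        m2 = write_fixture_bundle(tmp_path / "b", cfg)
        assert set(m1["files"]) == {
            "tree", "environments", "presence_matrix", "hits",
            "assignments", "manifest",
        }
        for name in m1["files"]:
            if name == "manifest":
                continue
            assert m1["files"][name]["sha256"] == m2["files"][name]["sha256"]
        manifest = json.loads((tmp_path / "a" / "manifest.json").read_text())
        planted = manifest["planted"]
        assert set(planted["pools"]) == {"Aquatic", "Terrestrial", "Facultative"}
        for fams in planted["pools"].values():
            assert len(fams) == 4

    def test_empty_pool_truth(self, tmp_path):
        cfg = SimulationConfig(n_genomes=6, pool_size=0, core_size=10,
                               ancestral_accessory=5, seed=1)
        manifest = write_fixture_bundle(tmp_path, cfg)
        assert manifest["planted"]["adaptive_families"] == []

    def test_assignment_table_schema(self, small_dataset):
        cfg, _, _, gs, _ = small_dataset
        table = synthesize_assignments(gs, cfg)
        assert list(table.columns) == [
            "protein_id", "function_id", "score", "pssm_coverage",
            "qstart", "qend",
        ]
        assert (table.qstart <= table.qend).all()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(pool_gain_prob=1.5),
            dict(gain_rate=-0.1),
            dict(n_genomes=1),
            dict(core_size=-1),
            dict(n_environments=9),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SimulationConfig(**kwargs)
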