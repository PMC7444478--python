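"""Gold-standard rules, naive-Bayes training/scoring, and network queries."""

import itertools

import numpy as np
import pandas as pd
import pytest

import microdevnet as md
from microdevnet.datatypes import ExpressionMatrix
from microdevnet.simulate import EvidenceCollection


def cpm_matrix(means, n_samples=3, prefix="s"):
    """CPM-transform-labelled matrix with per-gene constant values."""
    genes = list(means)
    vals = pd.DataFrame(
        {f"{prefix}{i}": [means[g] for g in genes] for i in range(n_samples)},
        index=genes,
    )
    return ExpressionMatrix(vals, "cpm")


def toy_gold_and_evidence():
    """10-pair gold standard and a single dataset with a hand-countable table.

    High-bin counts: 4/5 positives, 1/5 negatives. With alpha -> 0 the
    high-bin likelihood ratio approaches (4/5)/(1/5) = 4.
    """
    genes = [f"g{i}" for i in range(12)]
    pos = {(genes[i], genes[i + 1]) for i in range(0, 10, 2)}  # 5 pairs
    neg = {(genes[i], genes[i + 2]) for i in range(0, 10, 2)}  # 5 pairs
    rows = []
    for k, p in enumerate(sorted(pos)):
        rows.append((*p, 10.0 if k < 4 else 0.0))  # 4 positives high
    for k, p in enumerate(sorted(neg)):
        rows.append((*p, 10.0 if k < 1 else 0.0))  # 1 negative high
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).sort_values(
        ["gene_a", "gene_b"], ignore_index=True
    )
    gold = md.GoldStandard(positives=pos, negatives=neg, context_genes=set(genes))
    return gold, EvidenceCollection({"d1": df})


class TestContextGenes:
    def test_default_cuts_and_strict_boundary(self):
        rud = cpm_matrix({"a": 100.0, "b": 50.0, "c": 60.0, "d": 10.0})
        adu = cpm_matrix({"a": 5.0, "b": 5.0, "c": 10.0, "d": 5.0})
        got = md.context_genes(rud, adu)
        assert got == {"a"}  # b fails strict >50, c fails strict <10

    def test_comparative_sets_unioned(self):
        rud = cpm_matrix({"a": 100.0, "b": 1.0})
        adu = cpm_matrix({"a": 1.0, "b": 1.0})
        got = md.context_genes(rud, adu, comparative_sets=({"b", "z"},))
        assert got == {"a", "b", "z"}

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(100)]
        for _ in range(20):
            r = {g: float(rng.uniform(0, 120)) for g in genes}
            a = {g: float(rng.uniform(0, 30)) for g in genes}
            got = md.context_genes(cpm_matrix(r), cpm_matrix(a))
            ref = {g for g in genes if r[g] > 50 and a[g] < 10}
            assert got == ref


class TestGoldStandard:
    def test_known_pair_outside_context_becomes_negative_candidate(self, module_truth):
        within = module_truth.within_module_pairs()
        context = set(g for m in module_truth.modules.values() for g in m)
        context.discard(within[0][0])  # knock one member out of context
        gold = md.build_gold_standard(context, within, set(within),
                                      n_negatives_per_positive=0.1, seed=0)
        assert within[0] not in gold.positives
        candidates_seen = gold.negatives
        assert all(p not in gold.positives for p in candidates_seen)

    def test_saturated_universe_rejected(self):
        genes = ["a", "b", "c", "d"]
        pairs = set(itertools.combinations(genes, 2))
        with pytest.raises(ValueError, match="negative"):
            md.build_gold_standard(set(genes), pairs, pairs,
                                   n_negatives_per_positive=1.0, seed=0)

    def test_class_ratio_matches_config(self, module_truth):
        within = module_truth.within_module_pairs()
        context = set(g for m in module_truth.modules.values() for g in m)
        ev = md.generate_evidence(module_truth, 1, seed=1)
        universe = {
            md.canonical_pair(a, b)
            for df in ev.datasets.values()
            for a, b in zip(df.gene_a, df.gene_b)
        }
        gold = md.build_gold_standard(context, within[:100], universe,
                                      n_negatives_per_positive=3.0, seed=1)
        assert len(gold.negatives) == 3 * len(gold.positives)

    def test_overlapping_classes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            md.GoldStandard({("a", "b")}, {("a", "b")}, {"a", "b"})


class TestBinEvidence:
    def test_median_split(self):
        df = pd.DataFrame({
            "gene_a": [f"a{i:03d}" for i in range(100)],
            "gene_b": [f"b{i:03d}" for i in range(100)],
            "score": np.arange(1.0, 101.0),
        })
        binned = md.bin_evidence(EvidenceCollection({"d": df}), n_bins=2)
        bins = np.array([binned.bin_of("d", (f"a{i:03d}", f"b{i:03d}")) for i in range(100)])
        assert (bins == 0).sum() == 50 and (bins == 1).sum() == 50

    def test_missing_pair_maps_to_missing_bin(self):
        df = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"], "score": [1.0]})
        binned = md.bin_evidence(EvidenceCollection({"d": df}), n_bins=3)
        assert binned.bin_of("d", ("x", "y")) == binned.missing_bin == 3

    @pytest.mark.parametrize("n,k", [(100, 4), (101, 5), (137, 3)])
    def test_quantile_occupancies_balanced(self, n, k):
        rng = np.random.default_rng(n)
        df = pd.DataFrame({
            "gene_a": [f"a{i:04d}" for i in range(n)],
            "gene_b": [f"b{i:04d}" for i in range(n)],
            "score": rng.normal(size=n),  # continuous, tie-free
        })
        binned = md.bin_evidence(EvidenceCollection({"d": df}), n_bins=k)
        occ = np.bincount(
            [binned.bin_of("d", (f"a{i:04d}", f"b{i:04d}")) for i in range(n)],
            minlength=k,
        )
        assert occ.max() - occ.min() <= 1

    def test_constant_scores_warn(self):
        df = pd.DataFrame({"gene_a": list("abc"), "gene_b": list("xyz"),
                           "score": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="constant"):
            md.bin_evidence(EvidenceCollection({"d": df}), n_bins=2)


class TestTrainNB:
    def test_toy_high_bin_likelihood_ratio(self):
        gold, ev = toy_gold_and_evidence()
        binned = md.bin_evidence(ev, n_bins=2)
        model = md.train_nb(gold, binned, smoothing_alpha=1e-9)
        hi = 1  # scores {0,10} split at the median
        lr = np.exp(model.log_likelihood_ratio("d1", hi))
        assert lr == pytest.approx(4.0, rel=1e-6)
        assert model.prior_odds == pytest.approx(1.0)

    def test_large_alpha_flattens_ratios(self):
        gold, ev = toy_gold_and_evidence()
        binned = md.bin_evidence(ev, n_bins=2)
        model = md.train_nb(gold, binned, smoothing_alpha=1e8)
        for b in range(3):
            assert np.exp(model.log_likelihood_ratio("d1", b)) == pytest.approx(1.0, abs=1e-6)

    def test_retraining_bit_identical(self, tmp_path):
        gold, ev = toy_gold_and_evidence()
        binned = md.bin_evidence(ev, n_bins=2)
        m1 = md.train_nb(gold, binned)
        m2 = md.train_nb(gold, binned)
        m1.to_json(tmp_path / "m1.json")
        m2.to_json(tmp_path / "m2.json")
        assert (tmp_path / "m1.json").read_bytes() == (tmp_path / "m2.json").read_bytes()
        back = md.NaiveBayesModel.from_json(tmp_path / "m1.json")
        assert back.prior_odds == m1.prior_odds
        assert np.allclose(back.p_pos["d1"], m1.p_pos["d1"])

    def test_uncovered_dataset_dropped_with_warning(self):
        gold, ev = toy_gold_and_evidence()
        far = pd.DataFrame({"gene_a": ["q1"], "gene_b": ["q2"], "score": [1.0]})
        ev2 = EvidenceCollection({**ev.datasets, "unrelated": far})
        binned = md.bin_evidence(ev2, n_bins=2)
        with pytest.warns(UserWarning, match="unrelated"):
            model = md.train_nb(gold, binned)
        assert "unrelated" not in model.p_pos


class TestScorePairs:
    def test_toy_posterior_arithmetic(self):
        gold, ev = toy_gold_and_evidence()
        binned = md.bin_evidence(ev, n_bins=2)
        model = md.train_nb(gold, binned, smoothing_alpha=1e-9)
        model.prior_odds = 0.1
        net = md.score_pairs(model, binned)
        hi_pair = sorted(gold.positives)[0]  # scored 10 -> high bin
        row = net.edges.set_index(["gene_a", "gene_b"]).loc[hi_pair]
        assert row["fold_over_prior"] == pytest.approx(4.0, rel=1e-6)
        assert row["posterior_odds"] == pytest.approx(0.4, rel=1e-6)

    def test_no_datasets_empty_product(self):
        gold, ev = toy_gold_and_evidence()
        binned = md.bin_evidence(ev, n_bins=2)
        model = md.train_nb(gold, binned)
        model.p_pos, model.p_neg = {}, {}
        net = md.score_pairs(model, binned, pairs=sorted(gold.positives))
        assert np.allclose(net.edges["posterior_odds"], model.prior_odds)

    def test_log_odds_decomposition(self, module_truth):
        ev = md.generate_evidence(module_truth, 4, seed=6)
        known = md.generate_known_interactions(module_truth, 0.6, seed=6)
        universe = {
            md.canonical_pair(a, b)
            for df in ev.datasets.values()
            for a, b in zip(df.gene_a, df.gene_b)
        }
        ctx = set(g for m in module_truth.modules.values() for g in m)
        gold = md.build_gold_standard(ctx, known, universe, 5.0, seed=6)
        binned = md.bin_evidence(ev, 4)
        model = md.train_nb(gold, binned)
        net = md.score_pairs(model, binned)
        # network-wide Bayes consistency against independent summation
        for _, r in net.edges.sample(200, random_state=0).iterrows():
            pair = (r.gene_a, r.gene_b)
            llr = sum(
                np.log(model.p_pos[d][binned.bin_of(d, pair)])
                - np.log(model.p_neg[d][binned.bin_of(d, pair)])
                for d in model.p_pos
            )
            assert np.log(r.posterior_odds) - np.log(model.prior_odds) == pytest.approx(
                llr, abs=1e-9
            )


class TestThresholdAndQueries:
    def test_threshold_inclusive_and_monotone(self):
        edges = pd.DataFrame({
            "gene_a": ["a", "a", "b"],
            "gene_b": ["b", "c", "c"],
            "posterior_odds": [0.5, 0.4, 0.1],
            "fold_over_prior": [5.0, 4.0, 1.0],
        })
        net = md.FunctionalNetwork(edges, prior_odds=0.1)
        kept = md.threshold_network(net, 5.0)
        assert len(kept) == 1 and kept.edges.fold_over_prior.iloc[0] == 5.0
        for lo, hi in [(1.0, 2.0), (2.0, 5.0)]:
            assert len(md.threshold_network(net, hi)) <= len(md.threshold_network(net, lo))

    def test_top_neighbors_truncation_and_ties(self):
        edges = pd.DataFrame({
            "gene_a": ["a", "a", "a"],
            "gene_b": ["b", "c", "d"],
            "posterior_odds": [1.0, 2.0, 2.0],
            "fold_over_prior": [1.0, 2.0, 2.0],
        })
        net = md.FunctionalNetwork(edges, prior_odds=1.0)
        assert md.top_neighbors(net, "a", k=25) == ["c", "d", "b"]  # tie c<d
        assert md.top_neighbors(net, "a", k=2) == ["c", "d"]
        with pytest.raises(ValueError):
            md.top_neighbors(net, "zz", k=3)

    def test_module_recovery_with_clean_evidence(self, module_truth):
        recovered = []
        for seed in range(5):
            ev = md.generate_evidence(module_truth, 10, within_module_signal=0.8,
                                      noise_sd=0.5, seed=seed)
            known = md.generate_known_interactions(module_truth, 0.7, seed=seed)
            universe = {
                md.canonical_pair(a, b)
                for df in ev.datasets.values()
                for a, b in zip(df.gene_a, df.gene_b)
            }
            ctx = set(g for m in module_truth.modules.values() for g in m)
            gold = md.build_gold_standard(ctx, known, universe, 5.0, seed=seed)
            binned = md.bin_evidence(ev, 5)
            net = md.score_pairs(md.train_nb(gold, binned), binned)
            seed_gene = module_truth.modules["M03"][0]
            mates = set(module_truth.modules["M03"]) - {seed_gene}
            top = md.top_neighbors(net, seed_gene, k=len(mates))
            recovered.append(len(set(top) & mates) / len(mates))
        assert min(recovered) >= 0.8

    def test_link_tfs_matches_bfs_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i:02d}" for i in range(30)]
        rows = []
        for a, b in itertools.combinations(genes, 2):
            if rng.random() < 0.1:
                rows.append((a, b, 1.0, 6.0))
        net = md.FunctionalNetwork(
            pd.DataFrame(rows, columns=["gene_a", "gene_b", "posterior_odds",
                                        "fold_over_prior"]),
            prior_odds=0.1,
        )
        hood = genes[:10]
        tfs = genes[20:25] + ["absent_tf"]
        links = md.link_tfs(net, hood, tfs, max_steps=2)

        # independent BFS truncated at depth 2
        adj = {g: set() for g in genes}
        for a, b, _, _ in rows:
            adj[a].add(b)
            adj[b].add(a)
        for tf in tfs:
            if tf == "absent_tf":
                assert links[tf] == {"present": False, "links": {}}
                continue
            depth = {tf: 0}
            frontier = [tf]
            for d in (1, 2):
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in depth:
                            depth[v] = d
                            nxt.append(v)
                frontier = nxt
            reachable = {g for g in hood if g in depth and g != tf}
            assert set(links[tf]["links"]) == reachable
            for g, path in links[tf]["links"].items():
                assert path[0] == g and path[-1] == tf
                assert len(path) - 1 == depth[g]

    def test_direct_adjacency_is_path_length_one(self):
        edges = pd.DataFrame({"gene_a": ["a"], "gene_b": ["tf"],
                              "posterior_odds": [1.0], "fold_over_prior": [6.0]})
        net = md.FunctionalNetwork(edges, prior_odds=0.1)
        links = md.link_tfs(net, ["a"], ["tf"], max_steps=2)
        assert links["tf"]["links"]["a"] == ["a", "tf"]


class TestCrossValidate:
    def test_label_independent_evidence_gives_chance_auc(self, module_truth):
        rng = np.random.default_rng(8)
        genes = sorted(g for m in module_truth.modules.values() for g in m)
        pairs = list(itertools.combinations(genes[:70], 2))[:2000]
        n_pos = len(pairs) // 4
        gold = md.GoldStandard(set(pairs[:n_pos]), set(pairs[n_pos:]), set(genes))
        df = pd.DataFrame({
            "gene_a": [p[0] for p in pairs],
            "gene_b": [p[1] for p in pairs],
            "score": rng.normal(size=len(pairs)),
        })
        cv = md.cross_validate(gold, EvidenceCollection({"d": df}), n_folds=5, seed=8)
        assert abs(cv["auc"] - 0.5) < 0.05

    def test_noise_free_evidence_near_perfect(self, module_truth):
        ev = md.generate_evidence(module_truth, 5, within_module_signal=1.0,
                                  noise_sd=0.05, seed=9)
        known = md.generate_known_interactions(module_truth, 0.8, seed=9)
        universe = {
            md.canonical_pair(a, b)
            for df in ev.datasets.values()
            for a, b in zip(df.gene_a, df.gene_b)
        }
        ctx = set(g for m in module_truth.modules.values() for g in m)
        gold = md.build_gold_standard(ctx, known, universe, 5.0, seed=9)
        cv = md.cross_validate(gold, ev, n_folds=5, seed=9)
        assert cv["auc"] >= 0.95

    def test_fold_assignment_reproducible(self, module_truth):
        ev = md.generate_evidence(module_truth, 2, seed=10)
        known = md.generate_known_interactions(module_truth, 0.5, seed=10)
        universe = {
            md.canonical_pair(a, b)
            for df in ev.datasets.values()
            for a, b in zip(df.gene_a, df.gene_b)
        }
        ctx = set(g for m in module_truth.modules.values() for g in m)
        gold = md.build_gold_standard(ctx, known, universe, 5.0, seed=10)
        a = md.cross_validate(gold, ev, n_folds=4, seed=10)
        b = md.cross_validate(gold, ev, n_folds=4, seed=10)
        assert a == b


class TestDERecapitulation:
    def make_de(self, n_genes=100, n_de=20):
        genes = [f"g{i}" for i in range(n_genes)]
        fdr = np.ones(n_genes)
        fdr[:n_de] = 0.01
        return pd.DataFrame({"gene": genes, "log2fc": 1.0, "pvalue": fdr,
                             "fdr": fdr, "stage": "brain_rudiment"})

    def test_neighbors_equal_de_genes_minimal_p(self):
        de = self.make_de()
        res = md.de_recapitulation([f"g{i}" for i in range(20)], de)
        from scipy.special import comb

        assert res["overlap"] == 20
        assert res["pvalue"] == pytest.approx(1 / comb(100, 20), rel=1e-6)

    def test_zero_overlap_gives_one(self):
        de = self.make_de()
        res = md.de_recapitulation([f"g{i}" for i in range(50, 60)], de)
        assert res["overlap"] == 0 and res["pvalue"] == pytest.approx(1.0)

    def test_matches_direct_mass_summation(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n, k = 40, int(rng.integers(5, 15))
            de = self.make_de(n_genes=n, n_de=int(rng.integers(3, 12)))
            neigh = list(rng.choice([f"g{i}" for i in range(n)], size=k, replace=False))
            res = md.de_recapitulation(neigh, de)
            K = int((de.fdr < 0.1).sum())
            # direct hypergeometric mass summation
            from math import comb

            total = sum(
                comb(K, x) * comb(n - K, k - x)
                for x in range(res["overlap"], min(K, k) + 1)
                if k - x <= n - K
            ) / comb(n, k)
            assert res["pvalue"] == pytest.approx(total, rel=1e-9)

    def test_outside_universe_neighbors_reported(self):
        de = self.make_de()
        res = md.de_recapitulation(["g1", "nope"], de)
        assert res["dropped"] == ["nope"]
        with pytest.raises(ValueError):
            md.de_recapitulation([], de)


class TestMapOrthologs:
    def make_net(self):
        edges = pd.DataFrame({
            "gene_a": ["a", "a", "b"],
            "gene_b": ["b", "c", "d"],
            "posterior_odds": [1.0, 2.0, 3.0],
            "fold_over_prior": [1.0, 2.0, 3.0],
        })
        return md.FunctionalNetwork(edges, prior_odds=0.5)

    def test_identity_map_preserves_network(self):
        net = self.make_net()
        ident = pd.DataFrame({"source": list("abcd"), "target": list("abcd")})
        mapped, dropped = md.map_orthologs(net, ident)
        assert dropped == 0
        pd.testing.assert_frame_equal(
            mapped.edges.sort_values(["gene_a", "gene_b"], ignore_index=True),
            net.edges.sort_values(["gene_a", "gene_b"], ignore_index=True),
        )

    def test_partial_map_drops_and_counts(self):
        net = self.make_net()
        part = pd.DataFrame({"source": ["a", "b"], "target": ["A", "B"]})
        mapped, dropped = md.map_orthologs(net, part)
        assert dropped == 2 and len(mapped) == 1
        assert set(mapped.edges[["gene_a", "gene_b"]].iloc[0]) == {"A", "B"}

    def test_collision_rejected_with_rows(self):
        net = self.make_net()
        bad = pd.DataFrame({"source": ["a", "b"], "target": ["X", "X"]})
        with pytest.raises(ValueError, match="target"):
            md.map_orthologs(net, bad)

    def test_edge_count_matches_direct_filter(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i:02d}" for i in range(20)]
        rows = [(a, b, 1.0, 2.0) for a, b in itertools.combinations(genes, 2)
                if rng.random() < 0.3]
        net = md.FunctionalNetwork(
            pd.DataFrame(rows, columns=["gene_a", "gene_b", "posterior_odds",
                                        "fold_over_prior"]), 1.0)
        mapped_genes = set(rng.choice(genes, size=12, replace=False))
        m = pd.DataFrame({"source": sorted(mapped_genes),
                          "target": [f"h_{g}" for g in sorted(mapped_genes)]})
        mapped, dropped = md.map_orthologs(net, m)
        expect = sum(1 for a, b, _, _ in rows if a in mapped_genes and b in mapped_genes)
        assert len(mapped) == expect and dropped == len(rows) - expect
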