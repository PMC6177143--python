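"""DEG filtering, opposing overlap, gene-set scores, connectivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from reposignals import reference, signatures, simulate


def bioset(rows, scale="linear", label="t"):
    return signatures.Bioset(
        pd.DataFrame(rows, columns=["gene_id", "effect", "p_value"]),
        scale=scale, label=label)


class TestFilterDegs:
    def test_passing_gene_goes_up(self):
        sig = signatures.filter_degs(bioset([("g1", 2.0, 0.04)]))
        assert sig.up == {"g1"} and not sig.down

    def test_fold_change_cutoff_and_p_only_mode(self):
        b = bioset([("g1", 1.2, 0.04)])
        assert not signatures.filter_degs(b).up
        assert signatures.filter_degs(b, fc_min=None).up == {"g1"}

    def test_nonsignificant_bioset_empty(self):
        sig = signatures.filter_degs(bioset([("g1", 3.0, 0.5),
                                             ("g2", -3.0, 0.5)]))
        assert not sig.up and not sig.down

    def test_log2_scale_converts_threshold(self):
        # log2 effect 0.6 ~ linear 1.52-fold
        b = bioset([("g1", 0.6, 0.01), ("g2", 0.5, 0.01)], scale="log2")
        sig = signatures.filter_degs(b)
        assert sig.up == {"g1"}

    def test_undeclared_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            bioset([("g1", 1.0, 0.5)], scale="zscore")

    @given(st.lists(st.tuples(st.floats(-4, 4), st.floats(0, 1)),
                    min_size=1, max_size=50),
           st.sampled_from([(0.01, 2.0), (0.05, 1.5), (0.1, 1.2)]))
    def test_relaxing_thresholds_is_monotone(self, rows, strict):
        b = bioset([(f"g{i}", e, p) for i, (e, p) in enumerate(rows)])
        tight = signatures.filter_degs(b, p_max=strict[0], fc_min=strict[1])
        loose = signatures.filter_degs(b, p_max=0.2, fc_min=1.1)
        assert tight.up <= loose.up and tight.down <= loose.down


class TestOpposingOverlap:
    def _sig(self, up=(), down=()):
        return signatures.SignedGeneSignature(frozenset(up), frozenset(down))

    def test_full_containment_minimal_p(self):
        disease = self._sig(up=[f"g{i}" for i in range(5)])
        drug = self._sig(down=[f"g{i}" for i in range(8)])
        res = signatures.opposing_overlap(disease, drug, universe_size=30)
        assert res.n_up_down == 5
        # P(X >= 5) = C(5,5) C(25,3) / C(30,8)
        assert res.p_up_down == pytest.approx(2300 / 5852925, rel=1e-9)
        assert res.combined_score > 0

    def test_disjoint_sets_p_one(self):
        res = signatures.opposing_overlap(
            self._sig(up=["a", "b"]), self._sig(down=["c", "d"]),
            universe_size=100)
        assert res.n_up_down == 0 and res.p_up_down == 1.0

    def test_matches_exhaustive_tail_sum(self):
        # |U|=100, two sets of 10 with overlap 4
        disease = self._sig(up=[f"g{i}" for i in range(10)])
        drug = self._sig(down=[f"g{i}" for i in range(4)]
                         + [f"h{i}" for i in range(6)])
        res = signatures.opposing_overlap(disease, drug, universe_size=100)
        assert res.p_up_down == pytest.approx(
            reference.hypergeom_tail_by_enumeration(4, 100, 10, 10),
            rel=1e-10)

    def test_empty_sets_give_p_one(self):
        res = signatures.opposing_overlap(self._sig(), self._sig(),
                                          universe_size=10)
        assert res.p_up_down == 1.0 and res.combined_score == 0.0


class TestGenesetScore:
    def test_identical_set_ranks_first(self):
        sig = signatures.SignedGeneSignature(
            frozenset(f"g{i}" for i in range(10)), frozenset())
        sets = {"match": frozenset(f"g{i}" for i in range(10)),
                "other": frozenset(f"h{i}" for i in range(10))}
        table = signatures.geneset_score(sig, sets, universe_size=1000)
        assert table["gene_set"].iloc[0] == "match"

    def test_null_p_values_roughly_uniform(self):
        """Random sets vs a random signature give ~uniform p-values."""
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(400)]
        sig = signatures.SignedGeneSignature(
            frozenset(rng.choice(genes, 50, replace=False)), frozenset())
        sets = {f"s{i}": frozenset(rng.choice(genes, 50, replace=False))
                for i in range(300)}
        table = signatures.geneset_score(sig, sets, universe_size=400)
        from scipy import stats
        # discrete p-values are stochastically >= uniform; check the
        # two moments rather than a KS test against the continuous null
        assert table["p_value"].mean() > 0.40
        assert stats.kstest(table["p_value"], "uniform").statistic < 0.25

    def test_planted_pathway_tops_surrogate_overall_score(self):
        sim = simulate.gen_biosets_frames(simulate.SimExpressionConfig(
            n_genes=2000, seed=9))
        disease_sig = signatures.filter_degs(sim.disease_bioset)
        drug_sig = signatures.filter_degs(sim.drug_bioset)
        tables = [signatures.geneset_score(s, sim.gene_sets, 2000)
                  for s in (disease_sig, drug_sig)]
        overall = signatures.surrogate_overall_score(tables)
        assert overall["gene_set"].iloc[0] == sim.manifest["planted_gene_set"]


class TestConnectivityScore:
    def test_extreme_separation_is_maximal(self):
        universe = [f"g{i}" for i in range(100)]
        up, down = universe[:5], universe[-5:]
        raw = signatures.connectivity_score(up, down, universe)
        assert raw == pytest.approx(2 - 5 / 100 - 4 / 100)

    def test_swapping_tags_negates(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(50)]
        ranking = list(rng.permutation(universe))
        up, down = universe[:4], universe[10:14]
        raw = signatures.connectivity_score(up, down, ranking)
        assert signatures.connectivity_score(down, up, ranking) == \
            pytest.approx(-raw)

    def test_matches_brute_force_on_small_universes(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(20)]
        for _ in range(50):
            ranking = list(rng.permutation(universe))
            tags = rng.choice(universe, size=6, replace=False)
            up, down = list(tags[:3]), list(tags[3:])
            assert signatures.connectivity_score(up, down, ranking) == \
                pytest.approx(
                    reference.brute_force_connectivity(up, down, ranking),
                    abs=1e-12)

    def test_missing_tag_raises(self):
        with pytest.raises(ValueError, match="absent"):
            signatures.connectivity_score(["zz"], ["g0"],
                                          [f"g{i}" for i in range(5)])


class TestConnectivityScreen:
    def _panel_with_reversal(self, n_genes=200, seed=3):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(n_genes)]
        up = frozenset(universe[:10])
        down = frozenset(universe[10:20])
        query = signatures.SignedGeneSignature(up, down)
        reversal = [*sorted(down), *universe[20:], *sorted(up)]
        panel = {"reversal": reversal}
        for i in range(9):
            panel[f"noise{i}"] = list(rng.permutation(universe))
        return query, panel

    def test_exact_reversal_ranks_first_with_unit_score(self):
        query, panel = self._panel_with_reversal()
        results = signatures.connectivity_screen(query, panel, seed=0)
        assert results[0].reference_id == "reversal"
        assert results[0].normalized_score == pytest.approx(-1.0)
        assert results[0].shortlisted

    def test_scores_bounded_and_p_valid(self):
        query, panel = self._panel_with_reversal(seed=8)
        for r in signatures.connectivity_screen(query, panel, seed=1):
            assert -1 <= r.normalized_score <= 1
            assert 0 < r.permutation_p <= 1

    def test_pure_noise_panel_shortlists_at_alpha_rate(self):
        """~5% of pure-noise references pass the permutation threshold."""
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(150)]
        query = signatures.SignedGeneSignature(
            frozenset(universe[:8]), frozenset(universe[8:16]))
        panel = {f"n{i}": list(rng.permutation(universe)) for i in range(60)}
        results = signatures.connectivity_screen(query, panel, seed=2)
        assert sum(r.shortlisted for r in results) <= 9  # ~3 expected


class TestIo:
    def test_bioset_round_trip(self, tmp_path):
        b = bioset([("g1", 1.5, 0.01), ("g2", -2.0, 0.2)], scale="log2",
                   label="demo")
        signatures.write_bioset(b, tmp_path / "b.tsv")
        again = signatures.read_bioset(tmp_path / "b.tsv")
        assert again.scale == "log2" and again.label == "demo"
        pd.testing.assert_frame_equal(b.table, again.table)

    def test_bioset_requires_sidecar_header(self, tmp_path):
        (tmp_path / "b.tsv").write_text("gene_id\teffect\tp_value\n")
        with pytest.raises(ValueError, match="sidecar"):
            signatures.read_bioset(tmp_path / "b.tsv")

    def test_gmt_round_trip(self, tmp_path):
        sets = {"s1": frozenset({"a", "b"}), "s2": frozenset({"c"})}
        signatures.write_gmt(sets, tmp_path / "x.gmt")
        assert signatures.read_gmt(tmp_path / "x.gmt") == sets

    def test_ranked_list_rejects_duplicates(self, tmp_path):
        (tmp_path / "r.txt").write_text("g1\ng2\ng1\n")
        with pytest.raises(ValueError, match="duplicate"):
            signatures.read_ranked_list(tmp_path / "r.txt")
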