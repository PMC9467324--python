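"""GO aggregation oracle, GO-level NB test, cross-species comparison, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from meristemdiff import (
    aggregate_go_expression,
    cross_species_go_compare,
    go_enrichment_hypergeometric,
    go_glm_test,
    select_candidate_go,
)
from meristemdiff.counts import NormalizedMatrix


def make_nm(values: np.ndarray, tissues=None) -> NormalizedMatrix:
    values = np.asarray(values, dtype=float)
    cols = [f"s{i+1}" for i in range(values.shape[1])]
    tissues = tissues or ["root"] * len(cols)
    meta = pd.DataFrame(
        {"species": "x", "tissue": tissues, "replicate": range(1, len(cols) + 1)},
        index=pd.Index(cols, name="sample_id"),
    )
    vals = pd.DataFrame(values, index=[f"g{i+1}" for i in range(values.shape[0])], columns=cols)
    return NormalizedMatrix(values=vals, norm_factors=pd.Series(1.0, index=cols),
                            lib_sizes=pd.Series(0, index=cols), sample_meta=meta)


def brute_force_go_expression(nm, ann, samples):
    """Independent oracle: explicit loop over (gene, term) annotation pairs."""
    sums, counts = {}, {}
    for _, row in ann.iterrows():
        g, t = row["gene_id"], row["go_id"]
        if g not in nm.values.index:
            continue
        total = 0.0
        for s in samples:
            total += nm.values.at[g, s]
        sums[t] = sums.get(t, 0.0) + total / len(samples)
        counts[t] = counts.get(t, 0) + 1
    return {t: sums[t] / counts[t] for t in sums}


class TestAggregation:
    def test_arithmetic_mean_of_member_means(self):
        nm = make_nm([[10, 10], [20, 20], [30, 30]])
        ann = pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "go_id": "GO:1"})
        out = aggregate_go_expression(nm, ann, ["s1", "s2"])
        assert out.loc["GO:1", "expr"] == pytest.approx(20.0)
        assert out.loc["GO:1", "gene_count"] == 3

    def test_single_gene_term_identity(self):
        nm = make_nm([[7, 9]])
        ann = pd.DataFrame({"gene_id": ["g1"], "go_id": ["GO:1"]})
        out = aggregate_go_expression(nm, ann, ["s1", "s2"])
        assert out.loc["GO:1", "expr"] == pytest.approx(8.0)

    def test_absent_genes_dropped_from_count(self):
        nm = make_nm([[10, 10]])
        ann = pd.DataFrame({"gene_id": ["g1", "ghost"], "go_id": "GO:1"})
        out = aggregate_go_expression(nm, ann, ["s1", "s2"])
        assert out.loc["GO:1", "gene_count"] == 1
        assert out.loc["GO:1", "expr"] == pytest.approx(10.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n_genes, n_terms = 200, 50
        nm = make_nm(rng.gamma(2.0, 50.0, size=(n_genes, 4)))
        genes = [f"g{i+1}" for i in range(n_genes)]
        rows = [
            (g, f"GO:{t}")
            for t in range(n_terms)
            for g in rng.choice(genes, size=rng.integers(1, 30), replace=False)
        ]
        ann = pd.DataFrame(rows, columns=["gene_id", "go_id"])
        samples = ["s1", "s2", "s3"]
        out = aggregate_go_expression(nm, ann, samples)
        oracle = brute_force_go_expression(nm, ann, samples)
        assert set(out.index) == set(oracle)
        for t, v in oracle.items():
            assert out.loc[t, "expr"] == pytest.approx(v, abs=1e-9)

    def test_empty_intersection_rejected(self):
        nm = make_nm([[1.0]])
        ann = pd.DataFrame({"gene_id": ["ghost"], "go_id": ["GO:1"]})
        with pytest.raises(ValueError):
            aggregate_go_expression(nm, ann, ["s1"])


class TestGOGLM:
    def _fixture(self, rng, n_terms=40, k=20, shift_first=1.0, baseline=100.0):
        """n_terms disjoint k-gene terms, Poisson-ish CPM noise around a flat
        baseline; first term multiplied by `shift_first` in the shoot group."""
        n_genes = n_terms * k
        mu = np.full((n_genes, 6), baseline)
        mu[:k, 3:] *= shift_first
        values = rng.poisson(mu).astype(float)
        nm = make_nm(values, tissues=["root"] * 3 + ["shoot"] * 3)
        ann = pd.DataFrame(
            {"gene_id": [f"g{i+1}" for i in range(n_genes)],
             "go_id": [f"GO:{i // k}" for i in range(n_genes)]}
        )
        return nm, ann

    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        nm, ann = self._fixture(rng, n_terms=10, shift_first=1.0)
        root = [s for s, t in nm.sample_meta["tissue"].items() if t == "root"]
        shoot = [s for s, t in nm.sample_meta["tissue"].items() if t == "shoot"]
        rec = go_glm_test(nm, ann, root, shoot)
        assert (rec["p_value"] > 0.01).all()
        assert rec["log_fc"].abs().max() < 0.5

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(1)
        nm, ann = self._fixture(rng, n_terms=10, shift_first=4.0)
        root = [s for s, t in nm.sample_meta["tissue"].items() if t == "root"]
        shoot = [s for s, t in nm.sample_meta["tissue"].items() if t == "shoot"]
        r1 = go_glm_test(nm, ann, root, shoot, dispersion=0.1)
        r2 = go_glm_test(nm, ann, shoot, root, dispersion=0.1)
        assert np.allclose(r1["log_fc"], -r2["log_fc"], atol=1e-9)
        assert np.allclose(r1["p_value"], r2["p_value"], atol=1e-9)

    def test_all_zero_term_degenerate(self):
        nm = make_nm(np.zeros((3, 6)), tissues=["root"] * 3 + ["shoot"] * 3)
        ann = pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "go_id": "GO:0"})
        rec = go_glm_test(nm, ann, ["s1", "s2", "s3"], ["s4", "s5", "s6"])
        assert rec.loc["GO:0", "p_value"] == 1.0
        assert rec.loc["GO:0", "expr_a"] == 0.0 and rec.loc["GO:0", "expr_b"] == 0.0

    def test_coherent_shift_detected(self):
        """A 20-gene term shifted +4 log2 at baseline 100 reaches FDR < 0.01
        in at least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            nm, ann = self._fixture(rng, n_terms=40, k=20, shift_first=16.0)
            root = [s for s, t in nm.sample_meta["tissue"].items() if t == "root"]
            shoot = [s for s, t in nm.sample_meta["tissue"].items() if t == "shoot"]
            rec = go_glm_test(nm, ann, root, shoot)
            hits += rec.loc["GO:0", "fdr"] < 0.01
        assert hits >= 9


class TestCandidateSelection:
    @pytest.mark.parametrize(
        "fdr,lfc,count,expected",
        [
            (0.001, 4.0, 10, True),
            (0.001, 4.0, 4, False),   # below the five-genes-per-term floor
            (0.05, 4.0, 10, False),
            (0.001, -4.0, 10, True),
            (0.001, 2.0, 10, False),
        ],
    )
    def test_joint_gate(self, fdr, lfc, count, expected):
        rec = pd.DataFrame(
            {"fdr": [fdr], "log_fc": [lfc], "gene_count": [count]}, index=["GO:1"]
        )
        assert ("GO:1" in select_candidate_go(rec).index) is expected


def _de_table(genes, lfc, tested=True):
    return pd.DataFrame({"log_fc": lfc, "tested": tested}, index=genes)


class TestCrossSpecies:
    def test_identical_lfc_distributions_null(self):
        genes1 = [f"a{i}" for i in range(10)]
        genes2 = [f"b{i}" for i in range(10)]
        lfc = np.linspace(-1, 1, 10)
        ann1 = pd.DataFrame({"gene_id": genes1, "go_id": "GO:1"})
        ann2 = pd.DataFrame({"gene_id": genes2, "go_id": "GO:1"})
        out = cross_species_go_compare(_de_table(genes1, lfc), _de_table(genes2, lfc), ann1, ann2)
        assert out.loc["GO:1", "p_value"] == pytest.approx(1.0)
        assert not out.loc["GO:1", "selected"]

    def test_two_gene_term_never_selected(self):
        genes1 = ["a1", "a2"]
        genes2 = [f"b{i}" for i in range(10)]
        ann1 = pd.DataFrame({"gene_id": genes1, "go_id": "GO:1"})
        ann2 = pd.DataFrame({"gene_id": genes2, "go_id": "GO:1"})
        out = cross_species_go_compare(
            _de_table(genes1, [5.0, 5.2]), _de_table(genes2, np.zeros(10)), ann1, ann2
        )
        assert out.loc["GO:1", "p_value"] < 0.05  # clearly shifted (df ~ 1)...
        assert not out.loc["GO:1", "selected"]    # ...but gene count gate blocks it

    def test_shifted_term_selected(self):
        """A 4 log2 between-species LFC shift on a 15-gene term (LFC sd 1) is
        selected in at least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genes1 = [f"a{i}" for i in range(15)]
            genes2 = [f"b{i}" for i in range(15)]
            rows1 = [(g, "GO:1") for g in genes1] + [(f"x{i}", "GO:2") for i in range(15)]
            rows2 = [(g, "GO:1") for g in genes2] + [(f"y{i}", "GO:2") for i in range(15)]
            de1 = _de_table(
                genes1 + [f"x{i}" for i in range(15)],
                np.concatenate([rng.normal(4, 1, 15), rng.normal(0, 1, 15)]),
            )
            de2 = _de_table(
                genes2 + [f"y{i}" for i in range(15)],
                rng.normal(0, 1, 30),
            )
            out = cross_species_go_compare(
                de1, de2,
                pd.DataFrame(rows1, columns=["gene_id", "go_id"]),
                pd.DataFrame(rows2, columns=["gene_id", "go_id"]),
            )
            hits += bool(out.loc["GO:1", "selected"])
        assert hits >= 9

    def test_term_missing_in_one_species_skipped(self):
        ann1 = pd.DataFrame({"gene_id": ["a1", "a2"], "go_id": "GO:1"})
        ann2 = pd.DataFrame({"gene_id": ["b1", "b2"], "go_id": "GO:2"})
        out = cross_species_go_compare(
            _de_table(["a1", "a2"], [0, 0]), _de_table(["b1", "b2"], [0, 0]), ann1, ann2
        )
        assert len(out) == 0


class TestEnrichment:
    def test_exact_probability_by_enumeration(self):
        # all five term members drawn in a 5-gene DEG set from 10 genes:
        # p = C(5,5)*C(5,0)/C(10,5) = 1/252
        background = {f"g{i}" for i in range(10)}
        term_genes = [f"g{i}" for i in range(5)]
        ann = pd.DataFrame({"gene_id": term_genes, "go_id": "GO:1"})
        out = go_enrichment_hypergeometric(set(term_genes), background, ann)
        assert out.loc["GO:1", "p_value"] == pytest.approx(1 / special.comb(10, 5), abs=1e-12)

    def test_whole_background_term_uninformative(self):
        background = {f"g{i}" for i in range(10)}
        ann = pd.DataFrame({"gene_id": sorted(background), "go_id": "GO:1"})
        out = go_enrichment_hypergeometric({"g0", "g1"}, background, ann)
        assert out.loc["GO:1", "p_value"] == pytest.approx(1.0)

    def test_disjoint_deg_p_is_one(self):
        background = {f"g{i}" for i in range(10)}
        ann = pd.DataFrame({"gene_id": ["g0", "g1"], "go_id": "GO:1"})
        out = go_enrichment_hypergeometric({"g8", "g9"}, background, ann)
        assert out.loc["GO:1", "p_value"] == pytest.approx(1.0)

    def test_gene_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        background = [f"g{i}" for i in range(50)]
        deg = set(rng.choice(background, 10, replace=False))
        term = list(rng.choice(background, 20, replace=False))
        ann = pd.DataFrame({"gene_id": term, "go_id": "GO:1"})
        p1 = go_enrichment_hypergeometric(deg, set(background), ann).loc["GO:1", "p_value"]
        relabel = {g: f"h{i}" for i, g in enumerate(background)}
        ann2 = ann.assign(gene_id=[relabel[g] for g in term])
        p2 = go_enrichment_hypergeometric(
            {relabel[g] for g in deg}, set(relabel.values()), ann2
        ).loc["GO:1", "p_value"]
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_empty_deg_warns(self):
        with pytest.warns(UserWarning):
            out = go_enrichment_hypergeometric(set(), {"g1"}, pd.DataFrame({"gene_id": ["g1"], "go_id": ["GO:1"]}))
        assert len(out) == 0

    def test_deg_outside_background_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment_hypergeometric({"zz"}, {"g1"}, pd.DataFrame({"gene_id": ["g1"], "go_id": ["GO:1"]}))
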