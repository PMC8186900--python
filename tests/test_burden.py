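import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import panelburden as pb
from panelburden.cohort import MISSING, GenotypeMatrix
from panelburden.damaging import DamagingCall

from conftest import make_phenotypes, null_burden_config
from oracles import bh_enum, fisher_enum


def rd_call(site_id, gene="G1", rare_damaging=True):
    return DamagingCall(site_id=site_id, gene=gene, is_exonic=True, is_nonsynonymous=True,
                        is_rare=True, n_damaging_algorithms=2, is_lof=False,
                        rare_damaging=rare_damaging)


def toy_matrix(dosage, n_cases, n_controls, n_sites=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites = n_sites or dosage.shape[1]
    phen = make_phenotypes(n_cases, n_controls)
    sites = [pb.VariantSite("1", 100 * (j + 1), "A", ("G",)) for j in range(n_sites)]
    return GenotypeMatrix(samples=phen.samples, sites=sites, dosage=dosage), phen


class TestFisher:
    def test_no_carriers_anywhere_is_null(self):
        assert pb.fisher_one_tailed(0, 10, 0, 8) == pytest.approx(1.0)

    def test_small_table_closed_form(self):
        # N=6, 3 carriers, 3 cases, all carriers in cases: 1/C(6,3) = 1/20
        assert pb.fisher_one_tailed(3, 0, 0, 3) == pytest.approx(0.05)

    def test_subgroup_scale_table(self):
        assert pb.fisher_one_tailed(17, 166, 3, 114) == pytest.approx(
            float(fisher_enum(17, 166, 3, 114, "one")), rel=1e-10)
        assert pb.fisher_one_tailed(17, 166, 3, 114) == pytest.approx(0.0168, abs=5e-5)

    @given(
        st.tuples(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
        .filter(lambda t: sum(t) > 0)
    )
    def test_both_sidedness_match_enumeration(self, table):
        assert pb.fisher_one_tailed(*table) == pytest.approx(
            float(fisher_enum(*table, sidedness="one")), rel=1e-9)
        assert pb.fisher_two_sided(*table) == pytest.approx(
            float(fisher_enum(*table, sidedness="two")), rel=1e-9)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            pb.fisher_one_tailed(0, 0, 0, 0)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table,expected,corrected",
        [
            ((17, 166, 3, 114), (17 * 114) / (166 * 3), False),
            ((1, 1, 1, 1), 1.0, False),
            ((2, 8, 0, 10), (2.5 * 10.5) / (8.5 * 0.5), True),
        ],
    )
    def test_values_and_zero_cell_correction(self, table, expected, corrected):
        or_val, flag = pb.odds_ratio(*table)
        assert or_val == pytest.approx(expected)
        assert flag is corrected


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_hand_computed_examples(self, pvals, expected):
        assert pb.bh_adjust(pvals) == pytest.approx(expected)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_matches_reference_and_is_monotone(self, pvals):
        q = pb.bh_adjust(pvals)
        assert q == pytest.approx(bh_enum(pvals), rel=1e-9)
        _, q_ref, _, _ = multipletests(pvals, method="fdr_bh")
        assert q == pytest.approx(q_ref, rel=1e-9)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in p-rank
        assert np.all(q <= 1.0)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            pb.bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            pb.bh_adjust([0.5, 1.2])


class TestCountCarriers:
    def test_toy_enumeration_with_missing(self):
        # 3 samples x 2 sites of one gene: s1=[1,0], s2=[0,0], s3=[missing,1]
        G, _ = toy_matrix([[1, 0], [0, 0], [MISSING, 1], [0, 0]], 2, 2)
        calls = [rd_call("1:100:A:G"), rd_call("1:200:A:G")]
        per_gene = pb.count_carriers(G, calls)
        assert per_gene["G1"]["carriers"] == {G.samples[0], G.samples[2]}

    def test_sample_counted_once_per_gene(self):
        G, _ = toy_matrix([[1, 1], [2, 0], [0, 0], [0, 0]], 2, 2)
        calls = [rd_call("1:100:A:G"), rd_call("1:200:A:G")]
        assert len(pb.count_carriers(G, calls)["G1"]["carriers"]) == 2

    def test_non_rare_damaging_sites_ignored(self):
        G, _ = toy_matrix([[1, 0], [0, 1], [0, 0], [0, 0]], 2, 2)
        calls = [rd_call("1:100:A:G"), rd_call("1:200:A:G", rare_damaging=False)]
        assert pb.count_carriers(G, calls)["G1"]["sites"] == ["1:100:A:G"]

    def test_invariant_to_splitting_across_sites(self):
        """Carrier status is unchanged whether a sample's qualifying alleles
        sit at one site or are spread across several."""
        G1, phen = toy_matrix([[2, 0], [0, 0], [0, 0], [0, 0]], 2, 2)
        G2, _ = toy_matrix([[1, 1], [0, 0], [0, 0], [0, 0]], 2, 2)
        calls = [rd_call("1:100:A:G"), rd_call("1:200:A:G")]
        c1 = pb.count_carriers(G1, calls)["G1"]["carriers"]
        c2 = pb.count_carriers(G2, calls)["G1"]["carriers"]
        assert c1 == c2


class TestRunBurden:
    def test_single_variant_gene_excluded_from_testing(self):
        dosage = np.zeros((6, 3), dtype=np.int8)
        dosage[0, 0] = 1  # G1 single site
        dosage[1, 1] = 1
        dosage[2, 2] = 1
        G, phen = toy_matrix(dosage, 3, 3)
        calls = [rd_call("1:100:A:G", gene="G1"),
                 rd_call("1:200:A:G", gene="G2"), rd_call("1:300:A:G", gene="G2")]
        results = {r.gene: r for r in pb.run_burden(G, calls, phen)}
        assert not results["G1"].included and results["G1"].q_bh is None
        assert results["G2"].included and results["G2"].q_bh is not None

    def test_bh_family_is_included_genes_only(self):
        dosage = np.zeros((8, 4), dtype=np.int8)
        dosage[0, :2] = 1  # G1 carrier (case)
        dosage[4, 2:] = 1  # G2 carrier (control)
        G, phen = toy_matrix(dosage, 4, 4)
        calls = [rd_call("1:100:A:G", "G1"), rd_call("1:200:A:G", "G1"),
                 rd_call("1:300:A:G", "G2"), rd_call("1:400:A:G", "G2")]
        results = pb.run_burden(G, calls, phen)
        included = [r for r in results if r.included]
        qs = pb.bh_adjust([r.p_one_tailed for r in included])
        assert [r.q_bh for r in included] == pytest.approx(list(qs))

    def test_no_testable_gene_raises(self):
        G, phen = toy_matrix(np.zeros((4, 1), dtype=np.int8), 2, 2)
        with pytest.raises(ValueError, match="no gene"):
            pb.run_burden(G, [rd_call("1:100:A:G")], phen)

    def test_planted_enrichment_detected(self):
        """10x case carrier enrichment at the cohort's scale is found and
        ranked first (single representative replicate; the replicated power
        experiment lives in the acceptance suite)."""
        from panelburden.simulate import PlantedGene, simulate_cohort
        from dataclasses import replace

        cfg = replace(null_burden_config(seed=123),
                      planted=(PlantedGene("GENE001", 0.10, 0.01, n_sites=3),))
        sim = simulate_cohort(cfg)
        calls = pb.adjudicate_all(pb.annotations_from_frame(sim.annotations))
        results = pb.run_burden(sim.genotypes, calls, sim.phenotypes)
        assert results[0].gene == "GENE001"
        assert results[0].q_bh < 0.20


class TestSubgroupTest:
    def test_published_asd_worked_example(self):
        """17/183 ASD carriers vs 3/117 non-ASD -> two-sided p = 0.0306."""
        phen = make_phenotypes(300, 10, subgroup="ASD", subgroup_cases=range(183))
        cases = phen.cases
        carriers = set(cases[:17]) | set(cases[183:186])
        res = pb.subgroup_carrier_test(phen, carriers, "ASD")
        assert (res.carriers_in, res.total_in, res.carriers_out, res.total_out) == (17, 183, 3, 117)
        assert round(res.p_value, 4) == 0.0306

    def test_proportional_carriers_are_null(self):
        phen = make_phenotypes(200, 10, subgroup="ASD", subgroup_cases=range(100))
        cases = phen.cases
        carriers = set(cases[:10]) | set(cases[100:110])  # 10/100 vs 10/100
        assert pb.subgroup_carrier_test(phen, carriers, "ASD").p_value == pytest.approx(1.0)

    def test_one_sided_matches_fisher_one_tailed(self):
        phen = make_phenotypes(50, 10, subgroup="ASD", subgroup_cases=range(20))
        cases = phen.cases
        carriers = set(cases[:5]) | set(cases[20:22])
        res = pb.subgroup_carrier_test(phen, carriers, "ASD", sidedness="one")
        assert res.p_value == pytest.approx(pb.fisher_one_tailed(5, 15, 2, 28))

    def test_no_carriers_is_null(self):
        phen = make_phenotypes(50, 10, subgroup="ASD", subgroup_cases=range(20))
        assert pb.subgroup_carrier_test(phen, set(), "ASD").p_value == pytest.approx(1.0)

    def test_empty_or_full_subgroup_rejected(self):
        phen = make_phenotypes(10, 5, subgroup="ASD", subgroup_cases=range(10))
        with pytest.raises(ValueError):
            pb.subgroup_carrier_test(phen, set(), "ASD")  # subgroup == all cases
        with pytest.raises(ValueError):
            pb.subgroup_carrier_test(phen, set(), "absent")
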