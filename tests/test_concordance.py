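"""Cross-omics concordance: normalization, gene calls, tau-b association."""

import numpy as np
import pandas as pd
import pytest

from pairedspc import concordance as cc
from pairedspc import stats as st
from pairedspc.differential import fit_paired_count_model
from pairedspc.io import validate_design
from pairedspc.simulate import SimulationConfig, simulate_spc_experiment, simulate_transcriptome

rng = np.random.default_rng(555)


class TestQuantileNormalize:
    def test_permuted_columns_become_identical_multisets(self):
        a = rng.normal(size=30)
        e = pd.DataFrame({"s1": a, "s2": rng.permutation(a)})
        out = cc.quantile_normalize(e)
        np.testing.assert_allclose(np.sort(out["s1"]), np.sort(out["s2"]), atol=1e-12)

    def test_single_column_identity(self):
        e = pd.DataFrame({"s1": rng.normal(size=10)})
        pd.testing.assert_frame_equal(cc.quantile_normalize(e), e)

    def test_sorted_columns_identical_after_normalization(self):
        e = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        out = cc.quantile_normalize(e)
        s = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 4):
            np.testing.assert_allclose(s[:, 0], s[:, j], atol=1e-12)

    def test_idempotent_and_rank_preserving(self):
        e = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("xyz"))
        once = cc.quantile_normalize(e)
        twice = cc.quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)
        for c in e.columns:
            assert (e[c].rank() == once[c].rank()).all()

    def test_ties_share_mean_reference_value(self):
        e = pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 3.0, 4.0]})
        out = cc.quantile_normalize(e)
        assert out.loc[0, "s1"] == out.loc[1, "s1"]

    def test_missing_values_rejected(self):
        e = pd.DataFrame({"s1": [1.0, np.nan]})
        with pytest.raises(ValueError, match="complete"):
            cc.quantile_normalize(e)


def toy_expression():
    """3 genes x 2 probes, 6 participants, 2 timepoints; gene G1 shifts up."""
    parts = [f"P{i}" for i in range(6)]
    probes = ["G0_a", "G0_b", "G1_a", "G1_b", "G2_a", "G2_b"]
    cols, ann = {}, []
    r = np.random.default_rng(3)
    for p in parts:
        base = r.normal(8, 0.1, size=6)
        for tp in ("T1", "T2"):
            vals = base + r.normal(0, 0.05, size=6)
            if tp == "T2":
                vals[2:4] += 2.0  # G1 probes shift up
            cols[f"{p}_{tp}"] = vals
            ann.append({"id": f"{p}_{tp}", "participant": p, "timepoint": tp})
    e = pd.DataFrame(cols, index=pd.Index(probes, name="id"))
    annotation = pd.DataFrame(ann).set_index("id")
    probe_map = pd.DataFrame(
        {"source_id": probes, "target_id": [p.split("_")[0] for p in probes]}
    )
    return e, annotation, probe_map


class TestCallGeneChanges:
    def test_min_p_probe_represents_gene(self):
        e, ann, pm = toy_expression()
        calls = cc.call_gene_changes(e, ann, "T1", "T2", pm)
        g1 = calls.set_index("gene_id").loc["G1"]
        assert g1["significant"] and g1["direction"] == 1.0
        assert g1["representative_probe"] in ("G1_a", "G1_b")
        # representative probe is the smaller p among the gene's probes
        per_probe_p = {
            probe: st.wilcoxon_signed_rank(
                e.filter(like="_T2").loc[probe].to_numpy()
                - e.filter(like="_T1").loc[probe].to_numpy()
            ).p
            for probe in ("G1_a", "G1_b")
        }
        assert g1["p"] == min(per_probe_p.values())

    def test_unchanged_genes_not_significant(self):
        e, ann, pm = toy_expression()
        calls = cc.call_gene_changes(e, ann, "T1", "T2", pm).set_index("gene_id")
        assert not calls.loc["G0", "significant"]
        assert not calls.loc["G2", "significant"]

    def test_unmapped_probe_retained_under_own_id(self):
        e, ann, pm = toy_expression()
        pm = pm[pm["source_id"] != "G2_a"]
        with pytest.warns(UserWarning, match="without gene mapping"):
            calls = cc.call_gene_changes(e, ann, "T1", "T2", pm)
        assert "G2_a" in set(calls["gene_id"])

    def test_missing_timepoint_errors(self):
        e, ann, pm = toy_expression()
        with pytest.raises(ValueError, match="T9"):
            cc.call_gene_changes(e, ann, "T1", "T9", pm)


class TestMatchMolecules:
    def _calls(self, genes):
        return pd.DataFrame(
            {
                "gene_id": genes,
                "p": 0.01,
                "direction": 1.0,
                "significant": True,
            }
        )

    def _prot(self, prots):
        return pd.DataFrame(
            {"log2fc": 1.0, "fdr": 0.01, "significant": True},
            index=pd.Index(prots, name="id"),
        )

    def test_one_to_one_map(self):
        genes = [f"G{i}" for i in range(10)]
        prots = [f"P{i}" for i in range(10)]
        m = pd.DataFrame({"source_id": genes, "target_id": prots})
        out = cc.match_molecules(self._calls(genes), self._prot(prots), m)
        assert len(out) == 10

    def test_gene_with_two_isoforms_gives_two_rows(self):
        m = pd.DataFrame({"source_id": ["G1", "G1"], "target_id": ["P1a", "P1b"]})
        out = cc.match_molecules(self._calls(["G1"]), self._prot(["P1a", "P1b"]), m)
        assert len(out) == 2

    def test_join_equals_bruteforce_nested_loop(self):
        genes = [f"G{i}" for i in rng.integers(0, 15, size=12)]
        prots = [f"P{i}" for i in rng.integers(0, 15, size=12)]
        m = pd.DataFrame({"source_id": genes, "target_id": prots}).sample(
            frac=1.0, random_state=1
        )
        gcalls = self._calls([f"G{i}" for i in range(10)])
        pcalls = self._prot([f"P{i}" for i in range(10)])
        out = cc.match_molecules(gcalls, pcalls, m)
        expected = {
            (g, p)
            for g, p in zip(m["source_id"], m["target_id"])
            if g in set(gcalls["gene_id"]) and p in set(pcalls.index)
        }
        assert set(zip(out["gene_id"], out["protein_id"])) == expected

    def test_empty_intersection_warns_not_errors(self):
        m = pd.DataFrame({"source_id": ["GX"], "target_id": ["PX"]})
        with pytest.warns(UserWarning, match="no molecules"):
            out = cc.match_molecules(self._calls(["G1"]), self._prot(["P1"]), m)
        assert out.empty


class TestConcordanceTest:
    def _matched(self, sec, trans):
        sec, trans = np.asarray(sec, float), np.asarray(trans, float)
        return pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(sec.size)],
                "gene_significant": trans != 0,
                "gene_direction": trans,
                "protein_significant": sec != 0,
                "protein_log2fc": sec,
            }
        )

    def test_all_up_in_both_layers(self):
        m = self._matched([1] * 8, [1] * 8)
        res = cc.concordance_test(m, background_n=100)
        assert res.n_concordant == 8
        assert res.tau_b > 0 and res.p < 0.05

    def test_no_significance_is_degenerate(self):
        m = self._matched([0] * 5, [0] * 5)
        res = cc.concordance_test(m, background_n=50)
        assert res.n_concordant == 0
        assert res.p == 1.0 and np.isnan(res.tau_b)

    def test_n_concordant_equals_brute_force(self):
        for _ in range(10):
            sec = rng.integers(-1, 2, size=30)
            trans = rng.integers(-1, 2, size=30)
            res = cc.concordance_test(self._matched(sec, trans), background_n=200)
            brute = sum(
                1 for s, t in zip(sec, trans) if s != 0 and t != 0 and s == t
            )
            assert res.n_concordant == brute

    def test_tau_matches_stat_kernel_on_toy_background(self):
        m = self._matched([1, -1, 0], [1, -1, 0])
        res = cc.concordance_test(m, background_n=8)
        sec = np.array([1, -1, 0, 0, 0, 0, 0, 0], float)
        trn = np.array([1, -1, 0, 0, 0, 0, 0, 0], float)
        ref = st.kendall_tau_b(sec, trn)
        assert res.tau_b == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.p)

    def test_background_smaller_than_matched_errors(self):
        with pytest.raises(ValueError, match="background_n"):
            cc.concordance_test(self._matched([1, 1], [1, 1]), background_n=1)


class TestGoOverlap:
    def test_identical_disjoint_and_partial(self):
        assert cc.go_overlap_fraction({"a", "b"}, {"a", "b"}).fraction == 1.0
        assert cc.go_overlap_fraction({"a", "b"}, {"c"}).fraction == 0.0
        terms = {f"t{i}" for i in range(100)}
        other = {f"t{i}" for i in range(13)} | {f"x{i}" for i in range(50)}
        assert cc.go_overlap_fraction(terms, other).fraction == pytest.approx(0.13)

    def test_empty_secretome_set_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            cc.go_overlap_fraction(set(), {"a"})


class TestEndToEndRecovery:
    def test_full_concordance_recovers_responsive_genes(self):
        """With every responsive gene shifted and a strong effect, the
        pipeline recovers the concordant set at the protein-side power."""
        cfg = SimulationConfig(seed=1)
        study = simulate_spc_experiment(cfg)
        design = validate_design(study.spc, study.samples)
        prot = fit_paired_count_model(study.spc, design, ("adult", "MPLA"))
        expr, ann, pm, gm, truth = simulate_transcriptome(
            cfg, frac_concordant=1.0, treatment="MPLA", n_background_genes=1000
        )
        calls = cc.call_gene_changes(cc.quantile_normalize(expr), ann, "T1", "T2", pm)
        matched = cc.match_molecules(calls, prot, gm, keep_unmatched_genes=True)
        res = cc.concordance_test(matched, background_n=max(len(matched), 3000))
        n_resp = int(study.truth.query("treatment == 'MPLA'")["responsive"].sum())
        assert res.n_concordant >= 0.7 * n_resp
        assert res.p < 1e-10
        # gene layer alone recovers nearly all concordant genes with sign
        gcalls = calls.set_index("gene_id")
        conc = truth.loc[truth["concordant"], "gene"]
        ok = gcalls.loc[conc]
        assert (ok["significant"] & (ok["direction"] > 0)).mean() >= 0.95

    def test_concordant_count_monotone_in_frac_concordant(self):
        counts = []
        for frac in (0.0, 0.5, 1.0):
            per_seed = []
            for seed in (11, 12):
                cfg = SimulationConfig(seed=seed)
                study = simulate_spc_experiment(cfg)
                design = validate_design(study.spc, study.samples)
                prot = fit_paired_count_model(study.spc, design, ("adult", "MPLA"))
                expr, ann, pm, gm, _ = simulate_transcriptome(
                    cfg, frac_concordant=frac, treatment="MPLA", n_background_genes=1000
                )
                calls = cc.call_gene_changes(
                    cc.quantile_normalize(expr), ann, "T1", "T2", pm
                )
                matched = cc.match_molecules(calls, prot, gm, keep_unmatched_genes=True)
                per_seed.append(
                    cc.concordance_test(matched, background_n=3000).n_concordant
                )
            counts.append(np.mean(per_seed))
        assert counts[0] < counts[1] < counts[2]
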