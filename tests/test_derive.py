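import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modsurv import (
    GeneMetaResult,
    ModsurvError,
    ModuleSpec,
    SimulationConfig,
    SubtypeSignatureModel,
    build_candidates,
    combine_fixed_effect,
    evaluate_signature,
    make_signature,
    per_gene_meta_cox,
    select_best_module,
    simulate_cohort,
)
from modsurv.datatypes import CandidateModule, GeneSignature

from conftest import planted_signature


class TestFixedEffectCombination:
    def test_equal_studies_symmetry(self):
        b, s = combine_fixed_effect([0.8, 0.8], [0.3, 0.3])
        assert b == pytest.approx(0.8, abs=1e-12)
        assert s == pytest.approx(0.3 / np.sqrt(2), abs=1e-12)

    def test_weighted_hand_case(self):
        # weights 1/se^2 = (4, 1): combined = (4*0.5 + 1*1.0)/5 = 0.6,
        # se = 1/sqrt(5)
        b, s = combine_fixed_effect([0.5, 1.0], [0.5, 1.0])
        assert b == pytest.approx(0.6, abs=1e-9)
        assert s == pytest.approx(1 / np.sqrt(5), abs=1e-9)

    def test_single_study_is_identity(self):
        b, s = combine_fixed_effect([0.42], [0.17])
        assert (b, s) == (pytest.approx(0.42), pytest.approx(0.17))

    def test_combined_se_not_larger_than_any_study(self):
        rng = np.random.default_rng(0)
        ses = rng.uniform(0.1, 1.0, size=6)
        _, s = combine_fixed_effect(rng.normal(size=6), ses)
        assert s <= ses.min() + 1e-12


class TestPerGeneMetaCox:
    def test_null_pvalues_approximately_uniform(self):
        cfg = SimulationConfig(n_studies=2, samples_per_study=200, n_genes=600,
                               centroid_shift=0.0, seed=13)
        studies, clinical, _ = simulate_cohort(cfg)
        meta = per_gene_meta_cox(studies, clinical)
        pvals = np.array([r.p for r in meta])
        assert len(pvals) > 500
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_direction_follows_combined_hr(self):
        r = GeneMetaResult("g", {}, {}, coef=0.2, se=0.1, p=0.05)
        assert r.direction == 1
        r2 = GeneMetaResult("g", {}, {}, coef=-0.2, se=0.1, p=0.05)
        assert r2.direction == -1

    def test_fewer_than_two_contributing_studies_rejected(self, planted_cohort):
        _, studies, clinical, _ = planted_cohort
        with pytest.raises(ModsurvError, match=">= 2"):
            per_gene_meta_cox(studies[:1], clinical)

    def test_planted_genes_rank_at_top(self, planted_cohort, planted_sig):
        _, studies, clinical, _ = planted_cohort
        meta = per_gene_meta_cox(studies, clinical)
        ranked = sorted(meta, key=lambda r: r.p)
        top20 = {r.gene for r in ranked[:20]}
        overlap = len(top20 & set(planted_sig.genes))
        assert overlap >= 15


class TestBuildCandidates:
    def _meta(self, n):
        rng = np.random.default_rng(1)
        out = []
        for i in range(n):
            coef = rng.normal()
            out.append(GeneMetaResult(f"g{i:04d}", {}, {}, coef=coef, se=0.2,
                                      p=float(rng.random())))
        return out

    def test_exactly_twenty_candidates_sizes_10_to_200(self):
        cands = build_candidates(self._meta(250))
        assert len(cands) == 20
        assert [c.size for c in cands] == list(range(10, 201, 10))
        assert cands[0].size == 10 and cands[-1].size == 200

    def test_candidates_are_nested(self):
        cands = build_candidates(self._meta(250))
        for small, big in zip(cands, cands[1:]):
            assert set(small.signature.genes) <= set(big.signature.genes)

    def test_weights_follow_direction(self):
        meta = self._meta(50)
        cands = build_candidates(meta)
        by_gene = {r.gene: r for r in meta}
        for g, w in cands[0].signature.entries:
            assert w == by_gene[g].direction

    def test_truncated_sweep_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            cands = build_candidates(self._meta(137))
        assert [c.size for c in cands] == list(range(10, 131, 10))

    def test_fewer_than_ten_genes_rejected(self):
        with pytest.raises(ModsurvError, match=">= 10"):
            build_candidates(self._meta(9))

    def test_ranking_invariant_to_input_order(self):
        meta = self._meta(80)
        rng = np.random.default_rng(2)
        shuffled = list(meta)
        rng.shuffle(shuffled)
        a = build_candidates(meta)
        b = build_candidates(shuffled)
        for ca, cb in zip(a, b):
            assert ca.signature.entries == cb.signature.entries


class TestSelectBestModule:
    def test_single_candidate_is_selected(self, planted_cohort, planted_sig):
        _, studies, clinical, _ = planted_cohort
        cand = CandidateModule(index=1, size=10, signature=GeneSignature(
            "top10", planted_sig.entries[:10]))
        derived = select_best_module([cand], studies, clinical)
        assert derived.selected is cand
        assert derived.sweep["selected"].sum() == 1

    def test_tie_goes_to_smaller_module(self, planted_cohort, planted_sig):
        _, studies, clinical, _ = planted_cohort
        # same gene content declared at two sweep positions -> identical HRs
        sig = GeneSignature("top10", planted_sig.entries[:10])
        c1 = CandidateModule(index=1, size=10, signature=sig)
        c2 = CandidateModule(index=2, size=20,
                             signature=GeneSignature("top20", planted_sig.entries[:10]))
        derived = select_best_module([c1, c2], studies, clinical)
        assert derived.selected.size == 10

    def test_no_candidates_rejected(self, planted_cohort):
        _, studies, clinical, _ = planted_cohort
        with pytest.raises(ModsurvError):
            select_best_module([], studies, clinical)


class TestEndToEndDerivation:
    def test_training_evaluation_reproduces_sweep_entry(self, planted_cohort):
        _, studies, clinical, _ = planted_cohort
        res = SubtypeSignatureModel(studies, clinical, subtype="all").fit()
        ev = res.evaluate()
        assert ev.in_sample
        row = res.summary().query("selected")
        assert ev.cox_univariate.hr == pytest.approx(float(row["uni_HR"].iloc[0]), rel=1e-9)

    def test_selection_optimism_in_vs_out_of_sample(self):
        sig = planted_signature()
        in_hrs, out_hrs = [], []
        for seed in range(4):
            cfg = SimulationConfig(n_studies=2, samples_per_study=250, n_genes=120,
                                   module_specs=(ModuleSpec(sig, 0.5),), seed=seed)
            studies, clinical, _ = simulate_cohort(cfg)
            res = SubtypeSignatureModel(studies, clinical, subtype="all").fit()
            held = dataclasses.replace(cfg, seed=seed + 1000)
            studies2, clinical2, _ = simulate_cohort(held)
            in_hrs.append(res.evaluate().cox_univariate.hr)
            ev_out = evaluate_signature(res.derived, studies2, clinical2,
                                        in_sample=False)
            out_hrs.append(ev_out.cox_univariate.hr)
        assert np.mean(in_hrs) >= np.mean(out_hrs)

    def test_evaluation_without_gene_overlap_rejected(self, planted_cohort):
        _, studies, clinical, _ = planted_cohort
        sig = make_signature("alien", ["NOPE1", "NOPE2"])
        with pytest.raises(ModsurvError):
            evaluate_signature(sig, studies, clinical)
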