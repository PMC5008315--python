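import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modsurv import (
    ExpressionStudy,
    ModsurvError,
    censor_dmfs,
    collapse_duplicate_genes,
    dichotomize_receptor,
    fit_receptor_cutoff,
)

from conftest import make_clinical


def study_with(rows, genes, sid="st1"):
    n = len(rows[0])
    return ExpressionStudy(sid, pd.DataFrame(
        rows, index=pd.Index(genes, name="gene"),
        columns=[f"s{i}" for i in range(n)]))


class TestCollapse:
    def test_mean_of_two_duplicate_rows(self):
        st_ = study_with([[2.0, 4.0], [4.0, 6.0]], ["ESR1", "ESR1"])
        out = collapse_duplicate_genes(st_)
        assert out.shape == (1, 2)
        assert out.data.loc["ESR1"].tolist() == [3.0, 5.0]

    def test_three_duplicates(self):
        st_ = study_with([[0.0, 0.0], [3.0, 3.0], [6.0, 6.0]], ["A"] * 3)
        assert collapse_duplicate_genes(st_).data.loc["A"].tolist() == [3.0, 3.0]

    def test_no_duplicates_is_identity(self, toy_study):
        out = collapse_duplicate_genes(toy_study)
        pd.testing.assert_frame_equal(out.data, toy_study.data)

    def test_idempotent(self):
        st_ = study_with([[1.0, 2.0], [3.0, 4.0], [9.0, 9.0]], ["A", "A", "B"])
        once = collapse_duplicate_genes(st_)
        twice = collapse_duplicate_genes(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_unique_rows_untouched_and_order_kept(self):
        st_ = study_with([[1.0], [5.0], [2.0]], ["B", "A", "B"])
        out = collapse_duplicate_genes(st_)
        assert list(out.genes) == ["B", "A"]
        assert out.data.loc["A", "s0"] == 5.0


class TestCensor:
    def test_beyond_horizon_truncated_and_event_zeroed(self):
        clin = make_clinical([12.3], [1])
        out = censor_dmfs(clin, 10.0)
        assert out.df.loc[0, "dmfs_time"] == 10.0
        assert out.df.loc[0, "dmfs_event"] == 0

    def test_event_exactly_at_horizon_kept(self):
        out = censor_dmfs(make_clinical([10.0], [1]), 10.0)
        assert out.df.loc[0, "dmfs_time"] == 10.0
        assert out.df.loc[0, "dmfs_event"] == 1

    def test_below_horizon_unchanged(self):
        out = censor_dmfs(make_clinical([4.9], [0]), 10.0)
        assert out.df.loc[0, "dmfs_time"] == 4.9
        assert out.df.loc[0, "dmfs_event"] == 0

    def test_negative_time_rejected(self):
        clin = make_clinical([1.0], [0])
        clin.df.loc[0, "dmfs_time"] = -0.5  # bypass constructor check
        with pytest.raises(ModsurvError):
            censor_dmfs(clin, 10.0)

    @settings(max_examples=30, derandomize=True)
    @given(
        times=st.lists(st.floats(0, 30, allow_nan=False), min_size=1, max_size=20),
        horizon=st.floats(1, 15),
    )
    def test_never_increases_time_never_creates_event(self, times, horizon):
        events = [i % 2 for i in range(len(times))]
        clin = make_clinical(times, events)
        out = censor_dmfs(clin, horizon)
        assert (out.df["dmfs_time"] <= clin.df["dmfs_time"] + 1e-12).all()
        assert (out.df["dmfs_event"] <= clin.df["dmfs_event"]).all()
        assert (out.df["dmfs_time"] <= horizon).all()


class TestMixtureCutoff:
    def _mixture_study(self, means, sds, weight_hi, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        hi = rng.random(n) < weight_hi
        x = np.where(hi, rng.normal(means[1], sds[1], n), rng.normal(means[0], sds[0], n))
        return study_with([x], ["ESR1"]), hi

    def test_symmetric_mixture_cutoff_near_zero(self):
        st_, _ = self._mixture_study((-1, 1), (0.4, 0.4), 0.5)
        cut = fit_receptor_cutoff(st_, "ESR1")
        assert cut.converged
        assert abs(cut.cutoff) < 0.1
        assert cut.means[0] < cut.cutoff < cut.means[1]
        assert sum(cut.weights) == pytest.approx(1.0)

    def test_well_separated_mixture(self):
        # true equal-posterior point of N(0,1)/N(6,1) at equal weights is 3.0
        st_, hi = self._mixture_study((0, 6), (1, 1), 0.5, seed=1)
        cut = fit_receptor_cutoff(st_, "ESR1")
        assert 2.5 <= cut.cutoff <= 3.5
        assert abs(cut.means[0] - 0) < 0.2 and abs(cut.means[1] - 6) < 0.2
        # classification consistent with the generating component
        x = st_.data.loc["ESR1"].to_numpy()
        agree = ((x > cut.cutoff) == hi).mean()
        assert agree >= 0.95

    def test_constant_gene_falls_back_to_median(self):
        st_ = study_with([np.full(50, 7.0)], ["ESR1"])
        with pytest.warns(UserWarning, match="degenerate"):
            cut = fit_receptor_cutoff(st_, "ESR1")
        assert not cut.converged
        assert cut.cutoff == 7.0

    def test_too_few_samples_rejected(self):
        st_ = study_with([np.arange(10.0)], ["ESR1"])
        with pytest.raises(ModsurvError, match=">= 20"):
            fit_receptor_cutoff(st_, "ESR1")

    def test_missing_gene_rejected(self, toy_study):
        with pytest.raises(ModsurvError, match="not in study"):
            fit_receptor_cutoff(toy_study, "ESR1")


class TestDichotomize:
    def _setup(self, values):
        st_ = study_with([values], ["ESR1"])
        clin = make_clinical([1.0] * len(values), [0] * len(values),
                             study_ids=["st1"] * len(values))
        clin.df["sample_id"] = [f"s{i}" for i in range(len(values))]
        return st_, clin

    def test_strictly_above_cutoff_is_positive(self):
        st_, clin = self._setup([5.0, 5.0 + 1e-9])
        out = dichotomize_receptor(st_, clin, "ESR1", cutoff=5.0, receptor="er")
        assert out.df["er_status"].tolist() == ["negative", "positive"]

    def test_exactly_at_cutoff_is_negative(self):
        st_, clin = self._setup([5.0])
        out = dichotomize_receptor(st_, clin, "ESR1", cutoff=5.0, receptor="her2")
        assert out.df["her2_status"].tolist() == ["negative"]

    def test_all_below_cutoff_all_negative(self):
        st_, clin = self._setup([1.0, 2.0, 3.0])
        out = dichotomize_receptor(st_, clin, "ESR1", cutoff=9.0)
        assert (out.df["er_status"] == "negative").all()

    def test_absent_gene_rejected(self):
        st_, clin = self._setup([1.0])
        with pytest.raises(ModsurvError):
            dichotomize_receptor(st_, clin, "NOPE", cutoff=0.0)
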