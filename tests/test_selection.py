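"""Cross-validation harness, region scan, and coupled elimination/addition."""

import numpy as np
import pytest

from bsisurv import (
    Cohort,
    ModelSpec,
    REGIONS,
    backward_elimination,
    c_index,
    default_config,
    forward_addition,
    generate_cohort,
    repeated_cv,
    summarize_trace,
    univariate_region_scan,
)
from bsisurv.normalize import fit_normalizer
from bsisurv.selection import FoldStream, event_stratified_folds
from bsisurv.synthetic import sample_survival


class TestFolds:
    def test_event_stratification_balances_events(self, rng):
        event = np.r_[np.ones(200, dtype=int), np.zeros(100, dtype=int)]
        labels = event_stratified_folds(event, 3, rng)
        per_fold = [event[labels == f].sum() for f in range(3)]
        assert max(per_fold) - min(per_fold) <= 1

    def test_stream_is_deterministic_and_seed_sensitive(self):
        event = np.random.default_rng(0).integers(0, 2, 90)
        a = FoldStream(event, 4, 3, seed=5)
        b = FoldStream(event, 4, 3, seed=5)
        c = FoldStream(event, 4, 3, seed=6)
        assert a.partition_hash == b.partition_hash != c.partition_hash


class TestRepeatedCv:
    def test_same_seed_identical_results(self, small_cohort):
        spec = ModelSpec("cox", ("age", "total_bsi"))
        a = repeated_cv(spec, small_cohort, repeats=3, folds=3, seed=1)
        b = repeated_cv(spec, small_cohort, repeats=3, folds=3, seed=1)
        assert np.array_equal(a.entries, b.entries)
        assert a.partition_hash == b.partition_hash

    def test_null_region_model_is_chance_level(self):
        # hazard ignores every region: a single-noise-region model adds
        # nothing over age, so with age removed it sits near 0.5
        coh = generate_cohort(default_config(n=600, seed=3, true_betas={"age": 0.04}))
        res = repeated_cv(ModelSpec("cox", ("Humerus",)), coh, repeats=4, folds=3, seed=2)
        se = res.sd / np.sqrt(res.entries.size)
        assert abs(res.median - 0.5) < max(4 * se, 0.04)

    def test_median_matches_large_sample_oracle(self):
        # validation C of the refitted model should approach the C of the
        # true risk score measured on a large independent sample
        cfg = default_config(n=1000, seed=0)
        rng = np.random.default_rng(42)
        X = rng.standard_normal((1000, 1))
        t, e = sample_survival(cfg, X, rng, betas=np.array([1.0]))
        regional = np.zeros((1000, 12))
        regional[:, 0] = np.exp(X[:, 0])  # monotone wrap keeps ordering
        coh = Cohort(
            ids=np.arange(1000), age=np.full(1000, 70.0), regional=regional, time=t, event=e
        )
        res = repeated_cv(ModelSpec("cox", ("C_Spine",)), coh, repeats=5, folds=3, seed=3)

        big = np.random.default_rng(7)
        Xb = big.standard_normal((20_000, 1))
        tb, eb = sample_survival(cfg, Xb, big, betas=np.array([1.0]))
        oracle = c_index(Xb[:, 0], tb, eb).value
        assert abs(res.median - oracle) < 0.02

    def test_normalization_fitted_on_training_rows_only(self, small_cohort):
        # outliers planted in one fold's rows must not move the training
        # statistics used when that fold is held out
        from bsisurv.cox import fit_cox

        labels = FoldStream(small_cohort.event, 1, 3, seed=0).partitions[0]
        X = small_cohort.covariate_matrix(["age", "total_bsi"])
        train = labels != 0
        contaminated = X.copy()
        contaminated[labels == 0] += 1e6
        fit_clean = fit_cox(X[train], small_cohort.time[train], small_cohort.event[train])
        fit_dirty = fit_cox(
            contaminated[train], small_cohort.time[train], small_cohort.event[train]
        )
        ref = fit_normalizer(X[train])
        assert fit_clean.normalization.mean == pytest.approx(ref.mean)
        assert fit_dirty.normalization.mean == pytest.approx(ref.mean)


class TestScan:
    def test_thirteen_models_share_partitions(self, small_cohort):
        results = univariate_region_scan(small_cohort, repeats=2, folds=3, seed=4)
        assert set(results) == {*REGIONS, "total_bsi"}
        hashes = {r.partition_hash for r in results.values()}
        assert len(hashes) == 1

    def test_total_bsi_model_leads_when_hazard_is_total_burden(self, medium_cohort):
        results = univariate_region_scan(medium_cohort, repeats=3, folds=3, seed=5)
        total = results["total_bsi"]
        for region in REGIONS:
            assert results[region].median <= total.median + total.sd


def _duplicated_signal_cohort(n=400, seed=0):
    """Two identical strong region columns; the rest carry weaker
    independent signals, so only the duplicate is a free removal."""
    rng = np.random.default_rng(seed)
    x = rng.lognormal(-1.0, 0.8, n)
    regional = np.empty((n, 12))
    i_dup = [REGIONS.index("Pelvis"), REGIONS.index("Skull")]
    others = [j for j in range(12) if j not in i_dup]
    for j in others:
        regional[:, j] = rng.lognormal(-1.2, 0.6, n)
    regional[:, i_dup[0]] = x
    regional[:, i_dup[1]] = x  # exact duplicate
    cfg = default_config(n=n)
    covs = np.column_stack([x] + [regional[:, j] for j in others])
    betas = np.array([1.2] + [0.6] * len(others))
    t, e = sample_survival(cfg, covs, rng, betas=betas)
    return Cohort(
        ids=np.arange(n),
        age=rng.normal(75, 9, n),
        regional=regional,
        time=t,
        event=e,
    )


class TestElimination:
    def test_structural_invariants_and_summary_shape(self, small_cohort):
        trace = backward_elimination(small_cohort, "cox", repeats=2, folds=3, seed=0)
        trace.validate()
        trace = forward_addition(trace, small_cohort, repeats=2, folds=3, seed=0)
        df = summarize_trace(trace)
        assert len(df) == 1 + 2 * len(REGIONS)
        assert set(trace.steps[-1].forward_covariates) == {"age", *REGIONS}
        # summary is a pure function of the trace
        assert summarize_trace(trace).equals(df)

    def test_duplicated_column_removed_early_with_tiny_drop(self):
        coh = _duplicated_signal_cohort()
        trace = backward_elimination(coh, "cox", repeats=3, folds=3, seed=1)
        order = trace.removal_order
        dup_first_out = min(order.index("Pelvis"), order.index("Skull"))
        assert dup_first_out < 3  # a duplicate is among the first removals
        drop = trace.initial_result.median - trace.steps[dup_first_out].backward_result.median
        assert abs(drop) < trace.initial_result.sd

    def test_forward_curve_reaches_backward_plateau_with_overlap(self):
        coh = _duplicated_signal_cohort(seed=3)
        trace = backward_elimination(coh, "cox", repeats=3, folds=3, seed=2)
        trace = forward_addition(trace, coh, repeats=3, folds=3, seed=2)
        plateau = trace.initial_result.median
        sd = trace.initial_result.sd
        first_informative = next(
            k for k, s in enumerate(trace.steps) if {"Pelvis", "Skull"} & {s.removed}
        )
        reached = [
            s.forward_result.median for s in trace.steps[first_informative:]
        ]
        assert max(reached) > plateau - sd

    def test_ann_elimination_runs_and_validates(self, small_cohort):
        from bsisurv import AnnConfig

        trace = backward_elimination(
            small_cohort,
            "ann",
            repeats=1,
            folds=3,
            seed=0,
            ann_config=AnnConfig(members=2, iterations=20),
        )
        trace.validate()
        assert len(trace.removal_order) == 12
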