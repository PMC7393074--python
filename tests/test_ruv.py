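"""Replicate design, control scaling, and the RUV-III / RUV-III-C estimators.

The estimator is checked against an independently coded dense-projection
oracle of the same six steps (explicit projection matrices and an
eigendecomposition instead of the production SVD path).
"""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from pronorm.matrix import IntensityMatrix
from pronorm.ruv import (
    ReplicateDesign,
    build_replicate_design,
    median_normalize,
    peptide_eligibility,
    ruv3,
    ruv3c,
    scale_negative_controls,
)

from conftest import make_matrix, simple_meta


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------

def ruv3_oracle(Y, M, ctl_mask, k):
    """Dense-projection implementation of the six estimator steps.

    Residualizes with the explicit projector M (M'M)^+ M', extracts the
    top-k left singular directions from the eigendecomposition of
    Y0 Y0', and regresses the centered control sub-matrix on alpha_c.
    """
    m = Y.shape[0]
    P = M @ scipy.linalg.pinv(M.T @ M) @ M.T
    Y0 = (np.eye(m) - P) @ Y
    evals, evecs = scipy.linalg.eigh(Y0 @ Y0.T)
    order = np.argsort(evals)[::-1]
    U = evecs[:, order[:k]]
    alpha = U.T @ Y
    ac = alpha[:, ctl_mask]
    Yc = Y[:, ctl_mask]
    C = np.eye(m) - np.ones((m, m)) / m  # column-centering projector
    W = (C @ Yc) @ ac.T @ scipy.linalg.inv(ac @ ac.T)
    return Y - W @ alpha


def random_instance(rng, m=12, n=8, n_groups=4, n_ctl=3):
    Y = rng.normal(10, 2, size=(m, n))
    groups = np.repeat(np.arange(n_groups), m // n_groups)
    M = np.zeros((m, n_groups))
    M[np.arange(m), groups] = 1
    ctl = np.zeros(n, dtype=bool)
    ctl[:n_ctl] = True
    return Y, M, groups, ctl


def design_from_groups(run_ids, groups):
    return ReplicateDesign(group_of={r: f"g{g}" for r, g in zip(run_ids, groups)})


class TestRUV3:
    def test_matches_oracle_on_random_instance(self):
        rng = np.random.default_rng(42)
        Y, M, groups, ctl = random_instance(rng)
        x = make_matrix(Y)
        fit = ruv3(x, design_from_groups(x.run_ids, groups),
                   [f"p{j}" for j in np.flatnonzero(ctl)], k=2)
        expected = ruv3_oracle(Y, M, ctl, 2)
        np.testing.assert_allclose(fit.normalized_.values.to_numpy(), expected, atol=1e-8)

    def test_rank_one_contamination_removed(self):
        # B constant within each duplicate group; control column constant;
        # contamination w a' varies within groups
        B = np.array(
            [[5.0, 8.0, 3.0], [5.0, 8.0, 3.0], [7.0, 9.0, 3.0], [7.0, 9.0, 3.0]]
        )
        w = np.array([1.0, -1.0, 2.0, 0.5])
        a = np.array([0.5, 1.0, 2.0])
        Y = B + np.outer(w, a)
        x = make_matrix(Y)
        design = design_from_groups(x.run_ids, [0, 0, 1, 1])
        fit = ruv3(x, design, ["p2"], k=1)
        out = fit.normalized_.values.to_numpy()
        # rows identical within groups, control column constant
        np.testing.assert_allclose(out[0], out[1], atol=1e-9)
        np.testing.assert_allclose(out[2], out[3], atol=1e-9)
        np.testing.assert_allclose(out[:, 2], out[0, 2], atol=1e-9)
        # between-group differences of non-control columns equal those in B
        np.testing.assert_allclose(
            out[2, :2] - out[0, :2], B[2, :2] - B[0, :2], atol=1e-9
        )

    def test_degenerate_identical_rows_error(self):
        Y = np.repeat(np.array([[4.0, 5.0, 6.0]]), 4, axis=0)
        x = make_matrix(Y)
        design = design_from_groups(x.run_ids, [0, 0, 1, 1])
        with pytest.raises(ValueError, match="within-replicate"):
            ruv3(x, design, ["p0"], k=1)

    def test_k_exceeding_residual_rank_errors(self):
        rng = np.random.default_rng(0)
        Y, M, groups, ctl = random_instance(rng)
        x = make_matrix(Y)
        with pytest.raises(ValueError, match="k="):
            ruv3(x, design_from_groups(x.run_ids, groups),
                 [f"p{j}" for j in np.flatnonzero(ctl)], k=9)

    def test_missing_values_rejected(self):
        Y = np.full((4, 3), 5.0)
        Y[0, 0] = np.nan
        x = make_matrix(Y)
        with pytest.raises(ValueError, match="complete"):
            ruv3(x, design_from_groups(x.run_ids, [0, 0, 1, 1]), ["p2"], k=1)

    def test_row_permutation_equivariant(self):
        rng = np.random.default_rng(7)
        Y, M, groups, ctl = random_instance(rng)
        x = make_matrix(Y)
        ctl_ids = [f"p{j}" for j in np.flatnonzero(ctl)]
        design = design_from_groups(x.run_ids, groups)
        fit = ruv3(x, design, ctl_ids, k=2)
        perm = rng.permutation(Y.shape[0])
        xp = IntensityMatrix(x.values.iloc[perm])
        fitp = ruv3(xp, design, ctl_ids, k=2)
        np.testing.assert_allclose(
            fitp.normalized_.values.loc[x.run_ids].to_numpy(),
            fit.normalized_.values.to_numpy(),
            atol=1e-8,
        )

    def test_recovery_of_signal_with_control_supported_contamination(self):
        # B constant within groups; W_true zero-mean and varying within
        # groups; A_true supported on controls only
        rng = np.random.default_rng(11)
        m, n, n_groups, n_ctl, noise_sd = 30, 20, 6, 8, 0.1
        groups = np.repeat(np.arange(n_groups), m // n_groups)
        B = rng.normal(12, 2, size=(n_groups, n))[groups]
        W_true = rng.normal(0, 1, size=(m, 2))
        W_true -= W_true.mean(axis=0)
        A_true = np.zeros((2, n))
        A_true[:, :n_ctl] = rng.normal(0, 1, size=(2, n_ctl))
        eps = rng.normal(0, noise_sd, size=(m, n))
        x = make_matrix(B + W_true @ A_true + eps)
        fit = ruv3(x, design_from_groups(x.run_ids, groups),
                   [f"p{j}" for j in range(n_ctl)], k=2)
        resid = fit.normalized_.values.to_numpy()[:, n_ctl:] - B[:, n_ctl:]
        assert np.sqrt(np.mean(resid**2)) < 3 * noise_sd


class TestReplicateDesign:
    def test_cross_instrument_groups_have_distinct_instruments(self):
        meta = simple_meta(
            [f"r{i}" for i in range(6)],
            ["S5"] * 6,
            instruments=["A", "B", "C", "A", "B", "C"],
        )
        design = build_replicate_design(meta, group_size=3, cross_instrument=True, seed=0)
        groups = design.groups()
        assert len(groups) == 2
        instr = meta.set_index("run_id")["instrument"]
        for runs in groups.values():
            assert len({instr[r] for r in runs}) == 3

    def test_leftover_runs_unassigned(self):
        meta = simple_meta([f"r{i}" for i in range(7)], ["S1"] * 7)
        design = build_replicate_design(meta, group_size=3, cross_instrument=False, seed=1)
        assert design.m1 == 2 and len(design.group_of) == 6

    def test_deterministic_given_seed(self):
        meta = simple_meta(
            [f"r{i}" for i in range(12)],
            ["S1"] * 6 + ["S2"] * 6,
            instruments=list("ABCABC") * 2,
        )
        d1 = build_replicate_design(meta, seed=5)
        d2 = build_replicate_design(meta, seed=5)
        assert d1.group_of == d2.group_of

    def test_groups_share_sample_type(self):
        meta = simple_meta(
            [f"r{i}" for i in range(12)],
            ["S1"] * 6 + ["S2"] * 6,
            instruments=list("ABCABC") * 2,
        )
        design = build_replicate_design(meta, seed=2)
        sample = meta.set_index("run_id")["sample_type"]
        for runs in design.groups().values():
            assert len({sample[r] for r in runs}) == 1

    def test_infeasible_cross_instrument_errors(self):
        meta = simple_meta(["r0", "r1", "r2"], ["S1"] * 3, instruments=["A", "A", "B"])
        with pytest.raises(ValueError, match="S1"):
            build_replicate_design(meta, group_size=3, cross_instrument=True, seed=0)

    def test_membership_matrix_one_hot(self):
        design = ReplicateDesign(group_of={"a": "g0", "b": "g0", "c": "g1"})
        M = design.membership_matrix(["a", "b", "c"])
        assert M.shape == (3, 2)
        np.testing.assert_array_equal(M.sum(axis=1), [1, 1, 1])


class TestControlScaling:
    def test_per_sample_means_equalized(self):
        # control peptide with per-sample means 10 (S1) and 8 (S2)
        vals = np.array([[10.4, 5.0], [9.6, 5.0], [8.0, 6.0], [8.0, 6.0]])
        x = make_matrix(vals, peptide_ids=["ctl", "other"])
        meta = simple_meta(list(x.run_ids), ["S1", "S1", "S2", "S2"])
        cs = scale_negative_controls(x, ["ctl"], meta)
        scaled = cs.scaled.values["ctl"]
        assert scaled.iloc[0] == pytest.approx(9.4)
        assert scaled.iloc[:2].mean() == pytest.approx(9.0)
        assert scaled.iloc[2:].mean() == pytest.approx(9.0)
        # non-control column untouched
        pd.testing.assert_series_equal(cs.scaled.values["other"], x.values["other"])

    def test_already_equal_means_unchanged(self):
        vals = np.array([[9.0], [11.0], [10.0], [10.0]])
        x = make_matrix(vals, peptide_ids=["ctl"])
        meta = simple_meta(list(x.run_ids), ["S1", "S1", "S2", "S2"])
        cs = scale_negative_controls(x, ["ctl"], meta)
        pd.testing.assert_frame_equal(cs.scaled.values, x.values)

    def test_single_sample_type_unchanged(self):
        vals = np.array([[9.0], [11.0]])
        x = make_matrix(vals, peptide_ids=["ctl"])
        meta = simple_meta(list(x.run_ids), ["S1", "S1"])
        cs = scale_negative_controls(x, ["ctl"], meta)
        pd.testing.assert_frame_equal(cs.scaled.values, x.values)

    def test_missing_entries_untouched(self):
        vals = np.array([[10.0], [np.nan], [8.0], [8.0]])
        x = make_matrix(vals, peptide_ids=["ctl"])
        meta = simple_meta(list(x.run_ids), ["S1", "S1", "S2", "S2"])
        cs = scale_negative_controls(x, ["ctl"], meta)
        assert np.isnan(cs.scaled.values["ctl"].iloc[1])

    def test_empty_control_set_errors(self):
        x = make_matrix([[1.0]])
        meta = simple_meta(list(x.run_ids), ["S1"])
        with pytest.raises(ValueError, match="empty"):
            scale_negative_controls(x, [], meta)


class TestEligibility:
    def _matrix_with_rows(self, n_obs, n_groups_obs, m=30, n_groups=6):
        """Peptide observed in n_obs runs spanning n_groups_obs groups."""
        groups = np.repeat(np.arange(n_groups), m // n_groups)
        vals = np.full((m, 1), np.nan)
        chosen = []
        for g in range(n_groups_obs):
            chosen += list(np.flatnonzero(groups == g))
        vals[chosen[:n_obs], 0] = 10.0
        x = make_matrix(vals)
        return x, design_from_groups(x.run_ids, groups)

    def test_equality_is_eligible(self):
        # 25 observed runs across 5 groups, k = 20: 25 - 5 = 20 >= 20
        x, design = self._matrix_with_rows(25, 5)
        rep = peptide_eligibility(x, design, k=20)
        assert bool(rep["eligible"].iloc[0])

    def test_one_short_is_ineligible(self):
        x, design = self._matrix_with_rows(24, 5)
        rep = peptide_eligibility(x, design, k=20)
        assert not bool(rep["eligible"].iloc[0])

    def test_fully_observed_reduces_to_ruv3_precondition(self):
        x, design = self._matrix_with_rows(30, 6)
        assert bool(peptide_eligibility(x, design, k=24)["eligible"].iloc[0])
        assert not bool(peptide_eligibility(x, design, k=25)["eligible"].iloc[0])


class TestRUVIIIC:
    def test_complete_matrix_reduces_to_ruv3(self):
        rng = np.random.default_rng(19)
        Y, M, groups, ctl = random_instance(rng, m=24, n=12, n_groups=8, n_ctl=4)
        x = make_matrix(Y)
        ctl_ids = [f"p{j}" for j in np.flatnonzero(ctl)]
        meta = simple_meta(list(x.run_ids), ["S1"] * 24)
        design = design_from_groups(x.run_ids, groups)
        cs = scale_negative_controls(x, ctl_ids, meta)
        normalized, report = ruv3c(x, design, cs, k=2)
        whole = ruv3(cs.scaled, design, ctl_ids, k=2).normalized_
        targets = [p for p in x.peptide_ids if p not in ctl_ids]
        np.testing.assert_allclose(
            normalized.values[targets].to_numpy(),
            whole.values[targets].to_numpy(),
            atol=1e-8,
        )
        assert report["eligible"].all()

    def test_all_missing_peptide_reported_ineligible(self):
        rng = np.random.default_rng(3)
        Y, M, groups, ctl = random_instance(rng, m=12, n=8, n_groups=4, n_ctl=3)
        Y[:, 5] = np.nan
        x = make_matrix(Y)
        meta = simple_meta(list(x.run_ids), ["S1"] * 12)
        cs = scale_negative_controls(x, [f"p{j}" for j in np.flatnonzero(ctl)], meta)
        normalized, report = ruv3c(x, design_from_groups(x.run_ids, groups), cs, k=1)
        assert normalized.values["p5"].isna().all()
        row = report.set_index("peptide_id").loc["p5"]
        assert not row["eligible"] and row["reason"] == "no_rows"

    def test_missingness_preserved(self, bench):
        raw = bench["cohort"].matrix
        norm = bench["normalized"]
        raw_mask = raw.mask()[norm.peptide_ids]
        out_mask = norm.mask()
        # never missing -> observed
        assert not (out_mask & ~raw_mask).to_numpy().any()

    def test_runs_without_control_signal_all_missing(self, bench):
        # S6 and S8 contain no yeast, hence no scaled control signal
        meta = bench["cohort"].meta
        norm = bench["normalized"]
        runs = meta.loc[meta["sample_type"].isin(["S6", "S8"]), "run_id"]
        assert norm.values.loc[runs].isna().all().all()


class TestMedianNormalize:
    def test_simple_values(self):
        x = make_matrix([[1.0, 2.0, 3.0]])
        out = median_normalize(x)
        np.testing.assert_allclose(out.values.to_numpy()[0], [-1, 0, 1])

    def test_missing_ignored_and_preserved(self):
        x = make_matrix([[5.0, np.nan, 7.0]])
        out = median_normalize(x)
        np.testing.assert_allclose(out.values.to_numpy()[0, [0, 2]], [-1, 1])
        assert np.isnan(out.values.iloc[0, 1])

    def test_observed_median_exactly_zero(self):
        rng = np.random.default_rng(23)
        vals = rng.normal(10, 3, size=(20, 40))
        vals[rng.uniform(size=vals.shape) < 0.25] = np.nan
        out = median_normalize(make_matrix(vals))
        medians = out.values.median(axis=1, skipna=True)
        np.testing.assert_allclose(medians.to_numpy(), 0.0, atol=1e-12)
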