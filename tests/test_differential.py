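"""BH step-up correction and the per-protein differential screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmpanel import SimulationConfig, benjamini_hochberg, differential_test, generate_cohort
from cmpanel.cohort import AbundanceMatrix
from cmpanel.errors import AlignmentError


def bh_brute_force(p):
    """Independent step-up oracle: sort, scale by m/rank, cummin from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def _clinical(n_case, n_ctrl):
    ids = [f"S{i}" for i in range(n_case + n_ctrl)]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "status": ["case"] * n_case + ["control"] * n_ctrl,
        }
    )


def _matrix(values, prefix="P"):
    values = np.asarray(values, float)
    return AbundanceMatrix(
        sample_ids=[f"S{i}" for i in range(values.shape[0])],
        protein_ids=[f"{prefix}{j}" for j in range(values.shape[1])],
        values=values,
        trimester="T2",
    )


class TestBenjaminiHochberg:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_p_identity(self):
        assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)

    def test_boundary_ones(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0]), [1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])
        with pytest.raises(ValueError):
            benjamini_hochberg([np.nan, 0.1])

    @pytest.mark.parametrize("seed,size", [(0, 10), (1, 100), (2, 1000), (3, 10000)])
    def test_matches_brute_force(self, seed, size):
        p = np.random.default_rng(seed).random(size)
        np.testing.assert_allclose(benjamini_hochberg(p), bh_brute_force(p))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = benjamini_hochberg(pvals)
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_preserves_input_order(self):
        p = [0.9, 0.001, 0.5, 0.04]
        adj = benjamini_hochberg(p)
        assert np.argmin(adj) == 1 and np.argmax(adj) == 0


class TestDifferentialTest:
    def test_planted_four_fold_change_detected(self):
        """A true 4-fold (log2FC=2) protein at d~1 is flagged in >=95% of
        replicates among 20 null companions (35 vs 70 samples)."""
        hits = 0
        n_rep = 60
        rng = np.random.default_rng(123)
        clinical = _clinical(35, 70)
        for _ in range(n_rep):
            null = rng.normal(0, 2, size=(105, 20))
            signal = rng.normal(0, 2, size=105)
            signal[:35] += 2.0  # log2 units, sd=2 -> d=1
            res = differential_test(_matrix(np.column_stack([signal, null])), clinical)
            hits += bool(res.iloc[0]["significant"])
        assert hits / n_rep >= 0.95

    def test_null_rejection_rate_small_version(self):
        rng = np.random.default_rng(7)
        clinical = _clinical(35, 70)
        res = differential_test(_matrix(rng.normal(size=(105, 2000))), clinical)
        rate = (res["p"] < 0.05).mean()
        assert 0.03 < rate < 0.07
        assert res["significant"].sum() == 0

    def test_fold_change_threshold_is_inclusive(self):
        """|log2FC| exactly 1 with tiny adj p counts as significant."""
        # +-0.25 is exactly representable, so the group means are exact
        delta = np.tile([0.25, -0.25], 20)
        case = 1.0 + delta
        ctrl = 0.0 + delta
        values = np.concatenate([case, ctrl])[:, None]
        res = differential_test(_matrix(values), _clinical(40, 40))
        assert res.iloc[0]["log2fc"] == pytest.approx(1.0, abs=1e-12)
        assert res.iloc[0]["adj_p"] < 0.05
        assert bool(res.iloc[0]["significant"])

    def test_invariant_to_sample_order_and_constant_shift(self, rng):
        values = rng.normal(size=(30, 8))
        clinical = _clinical(10, 20)
        res1 = differential_test(_matrix(values), clinical)
        perm = rng.permutation(30)
        m2 = AbundanceMatrix(
            sample_ids=[f"S{i}" for i in perm],
            protein_ids=[f"P{j}" for j in range(8)],
            values=values[perm],
            trimester="T2",
        )
        res2 = differential_test(m2, clinical)
        pd.testing.assert_frame_equal(res1, res2)
        shifted = values.copy()
        shifted[:, 3] += 100.0  # constant shift of one protein
        res3 = differential_test(_matrix(shifted), clinical)
        assert res3.iloc[3]["log2fc"] == pytest.approx(res1.iloc[3]["log2fc"])
        assert res3.iloc[3]["p"] == pytest.approx(res1.iloc[3]["p"])

    def test_untestable_proteins_excluded_from_bh(self, rng):
        values = rng.normal(size=(12, 3))
        values[0:11, 2] = np.nan  # one case value only -> untestable
        res = differential_test(_matrix(values), _clinical(4, 8))
        assert not res.iloc[2]["testable"]
        assert np.isnan(res.iloc[2]["adj_p"])
        tested = res[res["testable"]]
        np.testing.assert_allclose(
            tested["adj_p"].to_numpy(), benjamini_hochberg(tested["p"].to_numpy())
        )

    def test_no_overlap_raises_alignment_error(self, rng):
        matrix = _matrix(rng.normal(size=(4, 2)))
        clinical = _clinical(2, 2)
        clinical["sample_id"] = ["X1", "X2", "X3", "X4"]
        with pytest.raises(AlignmentError):
            differential_test(matrix, clinical)

    def test_on_generated_cohort(self, small_planted):
        matrices, cohort, truth = small_planted
        res = differential_test(matrices["T2"], cohort)
        assert len(res) == 60
        # planted proteins should be strongly enriched among the smallest p
        top10 = set(res.nsmallest(10, "p")["protein_id"])
        assert len(top10 & set(truth.planted_protein_ids)) >= 2
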