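"""Perturbation statistics: deltas, Welch tests, BH, screening filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdxscreen.differential import (
    SignificanceConfig,
    bh_adjust,
    compute_perturbations,
    delta_percent_D,
    mean_perturbation_over_timepoints,
    significance_filter,
    to_matrix,
)


def bh_brute_force(p):
    """Independent step-up BH oracle straight from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestDelta:
    def test_hand_arithmetic_and_zero_variance(self):
        res = delta_percent_D([40, 40, 40], [55, 55, 55])
        assert res.delta == -15.0
        assert res.zero_variance and res.p_value == 0.0

    def test_identical_groups(self):
        res = delta_percent_D([50, 50], [50, 50])
        assert res.delta == 0.0 and res.p_value == 1.0 and res.zero_variance

    def test_frozen_welch_example(self):
        res = delta_percent_D([42.1, 40.3, 41.8], [45.0, 44.2, 46.1])
        assert res.delta == pytest.approx(-3.7)
        assert res.t_statistic == pytest.approx(-4.724473745711056)
        assert res.p_value == pytest.approx(0.009143953377675903)

    def test_underreplication_rejected(self):
        with pytest.raises(ValueError, match="[Ii]nsufficient"):
            delta_percent_D([50.0], [50.0, 50.0])

    def test_delta_without_p_allowed(self):
        res = delta_percent_D([50.0], [40.0, 42.0], require_p=False)
        assert res.delta == pytest.approx(9.0)

    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=6),
        st.lists(st.floats(0, 100), min_size=2, max_size=6),
    )
    @settings(max_examples=80, derandomize=True)
    def test_antisymmetry(self, a, b):
        """Swapping arms negates delta and preserves the p-value."""
        fwd = delta_percent_D(a, b)
        rev = delta_percent_D(b, a)
        assert fwd.delta == pytest.approx(-rev.delta, abs=1e-9)
        if not np.isnan(fwd.p_value):
            assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.3], [0.3]),
            ([0.03, 0.03, 0.03], [0.03, 0.03, 0.03]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(0, 1, 50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _small_obs(n_compounds=3, delta_for=None, seed=0, n_rep=4):
    """Tiny observation table: 4 peptides x 2 timepoints, optional shift."""
    rng = np.random.default_rng(seed)
    delta_for = delta_for or {}
    rows = []
    for comp in ["vehicle"] + [f"c{i}" for i in range(n_compounds)]:
        for pid in ["p1", "p2", "p3", "p4"]:
            for t in (10.0, 14400.0):
                base = 50.0 + delta_for.get((comp, pid, t), 0.0)
                for r in range(n_rep):
                    rows.append((pid, comp, t, r + 1, base + rng.normal(0, 0.5)))
    return pd.DataFrame(
        rows, columns=["peptide_id", "condition", "timepoint_s", "replicate", "percent_d"]
    )


class TestPerturbationTable:
    def test_records_cover_all_cells(self):
        rec = compute_perturbations(_small_obs())
        assert len(rec) == 3 * 4 * 2
        assert not rec["delta_percent_d"].isna().any()

    def test_planted_shift_recovered(self):
        shift = {(f"c{i}", "p2", 10.0): -20.0 for i in range(3)}
        rec = compute_perturbations(_small_obs(delta_for=shift))
        hit = rec[(rec.peptide_id == "p2") & (rec.timepoint_s == 10.0)]
        assert (hit.delta_percent_d < -15).all()
        assert hit.significant.all()

    def test_vectorised_matches_scalar_api(self):
        obs = _small_obs(seed=3)
        rec = compute_perturbations(obs)
        row = rec[(rec.compound == "c1") & (rec.peptide_id == "p3") & (rec.timepoint_s == 10.0)].iloc[0]
        treated = obs[(obs.condition == "c1") & (obs.peptide_id == "p3") & (obs.timepoint_s == 10.0)]
        veh = obs[(obs.condition == "vehicle") & (obs.peptide_id == "p3") & (obs.timepoint_s == 10.0)]
        scalar = delta_percent_D(treated.percent_d, veh.percent_d)
        assert row.delta_percent_d == pytest.approx(scalar.delta)
        assert row.p_value == pytest.approx(scalar.p_value)

    def test_paired_experiments_use_their_own_vehicle(self, tiny_study):
        rec = compute_perturbations(tiny_study.observations)
        assert rec["compound"].nunique() == 12
        assert (rec["n_vehicle"] == tiny_study.config.n_replicates).all()

    def test_adjusted_p_dominates_raw(self):
        rec = compute_perturbations(_small_obs(seed=2))
        ok = rec.dropna(subset=["adjusted_p"])
        assert (ok.adjusted_p >= ok.p_value - 1e-12).all()

    def test_missing_vehicle_rejected(self):
        obs = _small_obs()
        with pytest.raises(ValueError, match="vehicle"):
            compute_perturbations(obs[obs.condition != "vehicle"])

    def test_matrix_shape_and_missing_cells(self):
        obs = _small_obs()
        # drop one cell entirely -> must surface as NaN, not zero
        obs = obs[~((obs.condition == "c0") & (obs.peptide_id == "p1") & (obs.timepoint_s == 10.0))]
        mat = to_matrix(compute_perturbations(obs))
        assert mat.shape == (3, 8)
        assert np.isnan(mat.loc["c0", ("p1", 10.0)])


class TestSignificanceFilter:
    def _records(self, n_sig, n_compounds=38):
        rows = []
        for i in range(n_compounds):
            rows.append(
                {
                    "compound": f"c{i}",
                    "peptide_id": "p",
                    "timepoint_s": 10.0,
                    "delta_percent_d": -8.0,
                    "t_statistic": -5.0,
                    "p_value": 0.001,
                    "adjusted_p": 0.01,
                    "significant": i < n_sig,
                    "n_treated": 5,
                    "n_vehicle": 5,
                    "zero_variance": False,
                }
            )
        return pd.DataFrame(rows)

    def test_boundary_of_15_compound_rule(self):
        kept, _ = significance_filter(self._records(15))
        assert kept == [("p", 10.0)]
        kept, _ = significance_filter(self._records(14))
        assert kept == []

    def test_fractional_rule_generalises(self):
        cfg = SignificanceConfig(
            min_significant_compounds=None, min_significant_fraction=15 / 38
        )
        kept, _ = significance_filter(self._records(4, n_compounds=10), cfg)
        assert kept == [("p", 10.0)]  # ceil(10 * 15/38) = 4

    def test_exactly_one_rule_enforced(self):
        with pytest.raises(ValueError, match="exactly one"):
            SignificanceConfig(min_significant_compounds=15, min_significant_fraction=0.4)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            significance_filter(self._records(1).iloc[0:0])


class TestMeanOverTimepoints:
    def test_mean_and_count_of_present_values(self):
        rec = pd.DataFrame(
            {
                "compound": ["c"] * 3,
                "peptide_id": ["p"] * 3,
                "timepoint_s": [10.0, 30.0, 110.0],
                "delta_percent_d": [-10.0, -20.0, np.nan],
            }
        )
        out = mean_perturbation_over_timepoints(rec)
        assert out.iloc[0].mean_delta_percent_d == pytest.approx(-15.0)
        assert out.iloc[0].n_timepoints == 2
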