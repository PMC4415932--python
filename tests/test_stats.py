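import itertools
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from batmap.stats import (
    CohortMeasurements,
    PairedTestResult,
    attribute_mechanism,
    summarize_protocol,
    wilcoxon_signed_rank,
)


def _enumeration_p(abs_d: np.ndarray, signs: np.ndarray) -> float:
    """Independent oracle: exact two-sided p by explicit enumeration of
    all 2^n sign assignments (midranks for tied |d|)."""
    from scipy.stats import rankdata

    ranks = rankdata(abs_d)
    w_obs = ranks[signs > 0].sum()
    centre = ranks.sum() / 2.0
    dev = abs(w_obs - centre)
    n = len(ranks)
    count = 0
    for pattern in itertools.product([0, 1], repeat=n):
        w = sum(r for r, p in zip(ranks, pattern) if p)
        if abs(w - centre) >= dev - 1e-12:
            count += 1
    return count / 2**n


class TestWilcoxonSignedRank:
    def test_five_positive_distinct_differences(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = wilcoxon_signed_rank(x, np.zeros(5))
        assert res.p_value == pytest.approx(0.0625)
        assert not res.significant

    def test_identical_samples_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        res = wilcoxon_signed_rank(x, x)
        assert res.degenerate
        assert res.p_value == 1.0
        assert not res.significant

    def test_matches_enumeration_with_ties_and_zeros(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(4, 11))
            d = np.round(rng.normal(0, 2, n), 0)  # forces ties and zeros
            if np.all(d == 0):
                continue
            res = wilcoxon_signed_rank(d, np.zeros(n))
            nz = d[d != 0]
            oracle = _enumeration_p(np.abs(nz), np.sign(nz))
            assert res.p_value == pytest.approx(oracle, abs=1e-12)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.8, 1.0, 40)
        res = wilcoxon_signed_rank(x, np.zeros(40))
        from scipy.stats import wilcoxon as scipy_wilcoxon

        ref = scipy_wilcoxon(x, correction=False, method="approx").pvalue
        assert res.p_value == pytest.approx(ref, rel=1e-6)

    def test_detects_reported_cold_effect_majority_of_cohorts(self):
        """Cohorts drawn at the reported cold sBAT-FF change statistics
        (-1.94 +- 1.83 pp, n = 9) are significant in most replicates."""
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(200):
            d = rng.normal(-1.94, 1.83, 9)
            ps.append(wilcoxon_signed_rank(d, np.zeros(9)).p_value)
        assert np.median(ps) < 0.05

    def test_type_one_error_calibrated(self):
        """Exact-test type-I error at alpha = 0.05 under the null (n = 9)
        lies in [0.01, 0.09] (exact tests are conservative)."""
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            x = rng.normal(0, 1, 9)
            if wilcoxon_signed_rank(x, np.zeros(9)).significant:
                hits += 1
        assert 0.01 <= hits / n_rep <= 0.09

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=15))
    def test_p_value_in_unit_interval(self, xs):
        x = np.array(xs)
        res = wilcoxon_signed_rank(x, np.zeros_like(x))
        assert 0 < res.p_value <= 1
        assert res.significant == (res.p_value < 0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0], [0.0])
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [0.0])


def _result(mean, p, voi="sbat", quantity="ff", transition=""):
    return PairedTestResult(
        mean_change=mean, sd_change=1.0, statistic=0.0, p_value=p,
        significant=p < 0.05, trend=0.05 <= p < 0.10, n=9,
        voi=voi, quantity=quantity, transition=transition,
    )


class TestAttributeMechanism:
    @pytest.mark.parametrize(
        "cold, rb, rc, expected",
        [
            ((-1.9, 0.02), (-1.9, 0.01), (0.02, 0.95), "lipid"),
            ((-1.9, 0.02), (-0.1, 0.60), (1.9, 0.01), "perfusion"),
            ((-1.9, 0.02), (-1.0, 0.01), (0.9, 0.01), "mixed"),
            ((-0.1, 0.60), (-0.1, 0.60), (0.0, 0.90), "none"),
            ((-1.9, 0.02), (1.5, 0.01), (3.4, 0.01), "indeterminate"),
        ],
    )
    def test_rule_table(self, cold, rb, rc, expected):
        res = attribute_mechanism(_result(*cold), _result(*rb), _result(*rc))
        assert res.mechanism == expected

    def test_pure_function_of_flags_and_signs(self):
        base = (_result(-1.9, 0.02), _result(-1.9, 0.01), _result(0.02, 0.95))
        ref = attribute_mechanism(*base).mechanism
        # perturbing irrelevant fields never changes the outcome
        for i in range(3):
            mutated = list(base)
            mutated[i] = replace(base[i], sd_change=9.9, statistic=3.0, n=5)
            assert attribute_mechanism(*mutated).mechanism == ref

    def test_mismatched_vois_rejected(self):
        with pytest.raises(ValueError):
            attribute_mechanism(
                _result(-1.9, 0.02, voi="sbat"),
                _result(-1.9, 0.01, voi="sat"),
                _result(0.0, 0.9, voi="sbat"),
            )

    def test_perfusion_only_cohorts_attributed_in_90pct(self):
        """Reversible -3 +- 1 pp effects (n = 9) are attributed to
        perfusion in at least 90% of simulated cohorts."""
        from batmap.phantom import EffectSpec
        from batmap.pipeline import (
            _replicate_seeds,
            attribution_replicate,
            perfusion_only_spec,
        )

        hits = 0
        n_rep = 100
        for seed in _replicate_seeds(55, n_rep):
            spec = perfusion_only_spec(
                seed=seed, sbat_perfusion_ff_change=EffectSpec(-3.0, 1.0)
            )
            rng = np.random.default_rng(seed + 1)
            if attribution_replicate(spec, 0.1, rng) == "perfusion":
                hits += 1
        assert hits / n_rep >= 0.90


def _measurements(mode="cooling_reheating", n=9, seed=0, effects=None):
    rng = np.random.default_rng(seed)
    states = ("Baseline", "Cold", "Reheated") if mode == "cooling_reheating" else ("Scan1", "Scan2")
    rows = []
    for s in range(1, n + 1):
        base = {"sbat": 82.8 + rng.normal(0, 5), "sat": 85.2 + rng.normal(0, 5)}
        base_r = {"sbat": 21.0, "sat": 19.6}
        for state in states:
            for voi in ("sbat", "sat"):
                delta = (effects or {}).get((voi, state), 0.0)
                rows.append(
                    {
                        "subject": s, "state": state, "voi": voi,
                        "mean_ff_pct": base[voi] + delta + rng.normal(0, 0.05),
                        "mean_r2s": base_r[voi] + rng.normal(0, 0.1),
                    }
                )
    return CohortMeasurements(data=pd.DataFrame(rows), protocol_mode=mode)


class TestSummarizeProtocol:
    def test_identical_states_give_zero_change_p_one(self):
        m = _measurements(seed=1)
        tables = summarize_protocol(m)
        ch = tables["changes"]
        assert set(ch["transition"]) == {
            "Cold-Baseline", "Reheated-Baseline", "Reheated-Cold"
        }
        null = ch[(ch["voi"] == "sbat") & (ch["quantity"] == "ff")]
        assert np.all(np.abs(null["mean_change"]) < 0.2)
        assert np.all(~null["significant"])

    def test_procedure_mode_single_transition(self):
        m = _measurements(mode="procedure_study", n=8, seed=2)
        tables = summarize_protocol(m)
        assert set(tables["changes"]["transition"]) == {"Scan2-Scan1"}
        assert set(tables["states"]["state"]) == {"Scan1", "Scan2"}

    def test_state_summary_recovers_group_means(self):
        m = _measurements(seed=3, n=50)
        st_tab = summarize_protocol(m)["states"]
        row = st_tab[
            (st_tab["voi"] == "sbat") & (st_tab["quantity"] == "ff")
            & (st_tab["state"] == "Baseline")
        ].iloc[0]
        assert row["mean"] == pytest.approx(82.8, abs=3 * 5.0 / np.sqrt(50))
        assert row["min"] <= row["mean"] <= row["max"]

    def test_missing_state_excluded_pairwise_with_warning(self):
        m = _measurements(seed=4)
        data = m.data[~((m.data["subject"] == 3) & (m.data["state"] == "Cold"))]
        m2 = CohortMeasurements(data=data, protocol_mode="cooling_reheating")
        with pytest.warns(UserWarning, match="missing a state"):
            a, b = m2.paired("sbat", "ff", "Cold", "Baseline")
        assert len(a) == 8

    def test_baseline_contrast_rows_emitted(self):
        tables = summarize_protocol(_measurements(seed=5))
        assert set(tables["contrasts"]["quantity"]) == {"ff", "r2s"}
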