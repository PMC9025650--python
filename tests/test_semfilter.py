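import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epigx import semfilter
from epigx.dataio import MethylationMatrix, SampleTable
from epigx.semfilter import (
    HMO,
    LMO,
    detect_sems,
    filter_sem_probes,
    sem_burden,
    sem_enrichment,
)


def _meth(values: np.ndarray, probe_ids=None) -> MethylationMatrix:
    n, m = values.shape
    probe_ids = probe_ids or [f"cg{j}" for j in range(m)]
    manifest = pd.DataFrame({
        "probe_id": probe_ids,
        "chrom": [1] * m,
        "pos": range(1000, 1000 + m),
        "island_status": ["Open Sea"] * m,
        "gene": [""] * m,
        "polymorphic": [False] * m,
    })
    df = pd.DataFrame(values, index=[f"S{i}" for i in range(n)], columns=probe_ids)
    return MethylationMatrix(df, manifest)


def brute_force_calls(values: np.ndarray, multiplier=3.0):
    """Independent oracle: sort-based quartiles and direct fence arithmetic."""
    out = set()
    for j in range(values.shape[1]):
        col = values[:, j]
        col_ok = np.sort(col[~np.isnan(col)])
        if len(col_ok) < 8:
            continue
        q1 = np.quantile(col_ok, 0.25)
        q3 = np.quantile(col_ok, 0.75)
        iqr = q3 - q1
        for i, v in enumerate(col):
            if np.isnan(v):
                continue
            if v > q3 + multiplier * iqr:
                out.add((j, i, HMO))
            elif v < q1 - multiplier * iqr:
                out.add((j, i, LMO))
    return out


class TestDetectSems:
    def test_degenerate_iqr_hand_example(self):
        # 9 values at 0.10 and one 0.90: Q1 = Q3 = 0.10, IQR = 0,
        # fences collapse to 0.10 and the 0.90 value is an HMO.
        vals = np.array([[0.10]] * 9 + [[0.90]])
        calls = detect_sems(_meth(vals))
        assert len(calls) == 1
        c = calls[0]
        assert (c.sem_class, c.sample_id) == (HMO, "S9")
        assert c.upper_fence == pytest.approx(0.10)
        assert c.lower_fence == pytest.approx(0.10)

    def test_uniform_probes_yield_no_calls(self, rng):
        # For U(0.4, 0.6), Q3 + 3 IQR = 0.55 + 0.3 sits far outside the
        # support, so the 3 x IQR rule can never fire.
        vals = rng.uniform(0.4, 0.6, size=(500, 200))
        assert detect_sems(_meth(vals)) == []

    def test_planted_outliers_recovered_exactly(self, planted_cohort):
        _, _, meth, _, truth = planted_cohort
        calls = detect_sems(meth)
        got = {(c.probe_id, c.sample_id, c.sem_class) for c in calls}
        want = {
            (r.probe_id, r.sample_id, r["class"])
            for _, r in truth.sem_placements.iterrows()
        }
        assert want <= got
        # no spurious calls on the SEM-planted probes
        planted_probes = set(truth.sem_placements["probe_id"])
        extra = {g for g in got if g[0] in planted_probes} - want
        assert extra == set()

    def test_agrees_with_brute_force_oracle(self, rng):
        vals = rng.beta(2, 5, size=(60, 1000))
        # sprinkle heavy-tailed contamination to create genuine outliers
        mask = rng.random(vals.shape) < 0.002
        vals[mask] = rng.uniform(0.95, 1.0, mask.sum())
        calls = detect_sems(_meth(vals))
        got = {
            (int(c.probe_id[2:]), int(c.sample_id[1:]), c.sem_class)
            for c in calls
        }
        assert got == brute_force_calls(vals)

    def test_short_probe_skipped_with_warning(self, rng):
        vals = rng.uniform(0, 1, size=(6, 3))
        with pytest.warns(UserWarning, match="skipped"):
            assert detect_sems(_meth(vals)) == []

    def test_bad_multiplier(self, rng):
        with pytest.raises(ValueError):
            detect_sems(_meth(rng.uniform(0, 1, (20, 2))), multiplier=0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_hmo_lmo_disjoint_and_strict(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.beta(0.5, 0.5, size=(40, 10))
        calls = detect_sems(_meth(vals))
        seen = {}
        for c in calls:
            key = (c.probe_id, c.sample_id)
            assert key not in seen  # a value cannot be both HMO and LMO
            seen[key] = c
            if c.sem_class == HMO:
                assert c.value > c.upper_fence
            else:
                assert c.value < c.lower_fence

    def test_affine_equivariance_of_callset(self, rng):
        """Scaling/shifting a probe transforms fences but not the call set."""
        base = rng.normal(0.5, 0.02, 50)
        base[:3] = [0.95, 0.93, 0.05]
        scaled = 0.3 + 0.5 * base
        c1 = detect_sems(_meth(base[:, None]))
        c2 = detect_sems(_meth(scaled[:, None]))
        ids1 = {(c.sample_id, c.sem_class) for c in c1}
        ids2 = {(c.sample_id, c.sem_class) for c in c2}
        assert ids1 == ids2 and len(ids1) > 0


class TestBurden:
    def test_empty(self):
        out = sem_burden([])
        assert out["summary"]["n_calls"] == 0
        assert out["by_probe"].empty and out["by_subject"].empty

    def test_conservation_and_class_split(self, rng):
        vals = rng.normal(0.5, 0.01, size=(80, 30))
        hot = rng.choice(80 * 30, size=49, replace=False)
        for k in hot:
            i, j = divmod(k, 30)
            vals[i, j] = 0.99 if k % 2 else 0.01
        calls = detect_sems(_meth(np.clip(vals, 0, 1)))
        out = sem_burden(calls)
        assert out["by_subject"]["total"].sum() == len(calls)
        assert out["by_probe"]["total"].sum() == len(calls)
        assert (out["by_probe"][HMO] + out["by_probe"][LMO]
                == out["by_probe"]["total"]).all()


def _fisher_p_enumeration(table):
    """Brute force: enumerate all tables with the same margins."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (math.comb(r1, x) * math.comb(n - r1, c1 - x)
                / math.comb(n, c1))

    p_obs = prob(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


def _samples_with_classes(classes):
    n = len(classes)
    df = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "age": 50.0, "sex": 1, "bmi": 30.0,
        "hba1c": [8.0 if c == "diabetic" else 5.0 for c in classes],
        "self_report_dx_diabetes": False,
        "self_report_rx_diabetes": False,
    })
    return SampleTable(df)


def _calls_for(sample_ids):
    return [semfilter.SEMCall("cgX", s, HMO, 0.9, 0.1, 0.5) for s in sample_ids]


class TestEnrichment:
    def test_symmetric_table_is_null(self):
        classes = ["diabetic"] * 20 + ["control"] * 20
        carriers = [f"S{i}" for i in range(10)] + [f"S{i}" for i in range(20, 30)]
        res = sem_enrichment(_calls_for(carriers), _samples_with_classes(classes))
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0)

    def test_p_matches_hypergeometric_enumeration(self):
        # carriers: 1 of 10 diabetic, 11 of 14 non-diabetic
        classes = ["diabetic"] * 10 + ["control"] * 14
        carriers = ["S0"] + [f"S{i}" for i in range(10, 21)]
        res = sem_enrichment(_calls_for(carriers), _samples_with_classes(classes))
        np.testing.assert_array_equal(res.table, [[1, 9], [11, 3]])
        assert res.p_value == pytest.approx(
            _fisher_p_enumeration([[1, 9], [11, 3]]), abs=1e-12)

    def test_ci_brackets_conditional_mle(self):
        classes = ["diabetic"] * 30 + ["control"] * 40
        carriers = [f"S{i}" for i in range(18)] + [f"S{i}" for i in range(30, 38)]
        res = sem_enrichment(_calls_for(carriers), _samples_with_classes(classes))
        assert res.ci_low < res.odds_ratio < res.ci_high
        assert res.odds_ratio > 1  # SEMs concentrated in the diabetic group

    def test_one_group_empty_errors(self):
        with pytest.raises(ValueError):
            sem_enrichment([], _samples_with_classes(["control"] * 10))


class TestFilterProbes:
    def test_target_probe_protected(self, rng):
        vals = rng.normal(0.5, 0.01, size=(40, 3))
        vals[0, 0] = 0.99  # probe cg0 gets a call
        meth = _meth(np.clip(vals, 0, 1))
        calls = detect_sems(meth)
        out = filter_sem_probes(meth, calls, target_probe="cg1")
        assert "cg0" not in out.probe_ids and "cg1" in out.probe_ids

    def test_empty_callset_is_identity(self, rng):
        meth = _meth(rng.uniform(0.4, 0.6, (20, 4)))
        out = filter_sem_probes(meth, [])
        assert list(out.probe_ids) == list(meth.probe_ids)

    def test_all_probes_flagged_warns(self, rng):
        meth = _meth(rng.uniform(0.4, 0.6, (20, 2)))
        with pytest.warns(UserWarning, match="all probes"):
            out = filter_sem_probes(meth, [], probe_set={"cg0", "cg1"})
        assert out.values.shape[1] == 0
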