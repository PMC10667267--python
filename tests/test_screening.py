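"""QED desirability scoring, Veber's rule, and EAC selection."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.screening import (
    CompoundRecord,
    DescriptorSet,
    DesirabilityParams,
    desirability,
    load_qed_params,
    load_qed_weights,
    qed_score,
    screen_compounds,
    select_eac,
    veber_pass,
    weighted_geometric_mean,
)


def _ads_direct(x, p):
    """Independent closed-form evaluation of the asymmetric double sigmoid."""
    raw = p.a + p.b / (1 + math.exp(-(x - p.c + p.d / 2) / p.e)) * (
        1 - 1 / (1 + math.exp(-(x - p.c - p.d / 2) / p.f))
    )
    return raw / p.dmax


class TestDesirability:
    def test_published_mw_curve_matches_direct_evaluation(self):
        p = load_qed_params()["MW"]
        for x in (100.0, 300.0, 500.0, 800.0):
            assert desirability(x, p) == pytest.approx(_ads_direct(x, p), abs=1e-12)

    def test_normalization_peaks_at_one(self):
        # with dmax omitted the maximum is located numerically and the peak is 1
        p = DesirabilityParams(a=0.1, b=100.0, c=5.0, d=2.0, e=1.0, f=1.5)
        import numpy as np

        xs = np.linspace(-50, 60, 20001)
        peak = max(desirability(float(x), p) for x in xs)
        assert peak == pytest.approx(1.0, abs=1e-6)
        assert all(0 < desirability(float(x), p) <= 1 + 1e-12 for x in xs[::500])

    def test_symmetric_params_give_even_function_about_c(self):
        p = DesirabilityParams(a=0.0, b=1.0, c=3.0, d=0.0, e=0.7, f=0.7, dmax=1.0)
        for t in (0.1, 0.5, 1.0, 2.5):
            assert desirability(3.0 + t, p) == pytest.approx(desirability(3.0 - t, p), rel=1e-12)

    def test_lower_plateau_in_the_tails(self):
        p = load_qed_params()["MW"]
        mid = desirability(300.0, p)
        assert desirability(-1e4, p) < mid and desirability(1e5, p) < mid

    def test_degenerate_slope_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            DesirabilityParams(a=0, b=1, c=0, d=0, e=0.0, f=1.0)


class TestQedScore:
    def test_all_ones_gives_one_and_equal_values_pass_through(self):
        assert weighted_geometric_mean([1.0] * 8, [1.0] * 8) == pytest.approx(1.0)
        assert weighted_geometric_mean([0.7] * 8, [0.66, 0.46, 0.05, 0.61, 0.06, 0.65, 0.48, 0.95]) == pytest.approx(0.7)

    def test_unweighted_geometric_mean_closed_form(self):
        vals = [0.25] + [1.0] * 7
        assert weighted_geometric_mean(vals, [1.0] * 8) == pytest.approx(0.25 ** (1 / 8), abs=1e-12)

    def test_weight_scale_invariance(self, druglike_descriptors):
        w = load_qed_weights("mean")
        q1 = qed_score(druglike_descriptors, weights=w)
        q3 = qed_score(druglike_descriptors, weights={k: 3.0 * v for k, v in w.items()})
        assert q1 == pytest.approx(q3, rel=1e-12)

    def test_weighted_differs_from_unweighted_unless_flat(self, druglike_descriptors):
        assert qed_score(druglike_descriptors, mode="mean") != pytest.approx(
            qed_score(druglike_descriptors, mode="unweighted"), abs=1e-9
        )

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=8, max_size=8),
        st.integers(0, 7),
        st.floats(min_value=0.01, max_value=0.99),
    )
    def test_improving_one_desirability_never_decreases_score(self, vals, idx, bump):
        w = [0.66, 0.46, 0.05, 0.61, 0.06, 0.65, 0.48, 0.95]
        better = list(vals)
        better[idx] = min(1.0, better[idx] + bump)
        assert weighted_geometric_mean(better, w) >= weighted_geometric_mean(vals, w) - 1e-12

    def test_score_in_unit_interval(self, druglike_descriptors):
        for mode in ("unweighted", "mean", "max"):
            assert 0.0 < qed_score(druglike_descriptors, mode=mode) <= 1.0

    def test_invalid_weights_rejected(self, druglike_descriptors):
        with pytest.raises(ValueError, match="positive"):
            qed_score(druglike_descriptors, weights={k: 0.0 for k in load_qed_weights("mean")})
        with pytest.raises(ValueError, match="unknown QED weight mode"):
            load_qed_weights("median")


class TestVeber:
    @pytest.mark.parametrize(
        "rotb,tpsa,expected",
        [
            (10, 140.0, True),   # both boundaries inclusive
            (11, 50.0, False),   # rotatable bonds alone fail
            (3, 141.0, False),   # polar surface area alone fails
            (0, 0.0, True),
        ],
    )
    def test_boundary_semantics(self, rotb, tpsa, expected):
        d = DescriptorSet(mw=300, alogp=2, hba=3, hbd=1, tpsa=tpsa, rotb=rotb,
                          arom=1, alerts=0)
        assert veber_pass(d) is expected


class TestSelectEac:
    def _record(self, cid, qed, ob):
        d = DescriptorSet(mw=300, alogp=2, hba=3, hbd=1, tpsa=60, rotb=3, arom=1, alerts=0)
        return CompoundRecord(cid, cid, d, qed=qed, ob_pass=ob)

    def test_conjunction_and_inclusive_cutoff(self):
        recs = [
            self._record("at_cutoff", 0.30, True),
            self._record("good_qed_bad_ob", 0.95, False),
            self._record("below", 0.29, True),
        ]
        chosen = select_eac(recs)
        assert [r.compound_id for r in chosen] == ["at_cutoff"]
        assert recs[0].is_eac and not recs[1].is_eac and not recs[2].is_eac

    def test_order_preserved_and_idempotent(self):
        recs = [self._record(f"c{i}", q, True) for i, q in enumerate((0.9, 0.31, 0.5))]
        first = select_eac(recs)
        assert [r.compound_id for r in first] == ["c0", "c1", "c2"]
        assert [r.compound_id for r in select_eac(recs)] == ["c0", "c1", "c2"]

    def test_monotone_in_cutoff(self):
        recs = [self._record(f"c{i}", q, True) for i, q in enumerate((0.1, 0.3, 0.5, 0.8))]
        sizes = [len(select_eac(recs, qed_cutoff=c)) for c in (0.0, 0.3, 0.5, 0.9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_input_and_unscreened_error(self):
        assert select_eac([]) == []
        d = DescriptorSet(mw=300, alogp=2, hba=3, hbd=1, tpsa=60, rotb=3, arom=1, alerts=0)
        with pytest.raises(ValueError, match="screened"):
            select_eac([CompoundRecord("x", "x", d)])

    def test_screen_compounds_fills_verdicts(self, druglike_descriptors):
        rec = screen_compounds([CompoundRecord("c1", "c1", druglike_descriptors)])[0]
        assert rec.qed is not None and rec.ob_pass is True
        assert rec.is_eac == (rec.qed >= 0.3)
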