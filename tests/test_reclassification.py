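import numpy as np
import pytest

from catlet.datasets import mace_reclassification_table
from catlet.errors import ValidationError
from catlet.reclassification import (
    ReclassificationTable,
    RiskCutoffs,
    build_reclass_table,
    categorize,
    category_free_nri,
    category_nri,
    derive_cutoffs,
    discrimination_slope,
    idi,
)


class TestCutoffs:
    def test_exact_rule_half_one_two_times_rate(self):
        c = derive_cutoffs(0.23)
        assert c.thresholds == pytest.approx((0.115, 0.23, 0.46))

    def test_explicit_values_accepted_verbatim(self):
        c = derive_cutoffs(0.23, "explicit", (0.10, 0.20, 0.40))
        assert c.thresholds == (0.10, 0.20, 0.40)

    def test_high_event_rate_directs_to_explicit(self):
        with pytest.raises(ValidationError, match="explicit"):
            derive_cutoffs(0.6)

    def test_unordered_cutoffs_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            RiskCutoffs((0.2, 0.1))


class TestCategorize:
    cutoffs = RiskCutoffs((0.10, 0.20, 0.40))

    @pytest.mark.parametrize(
        "pred, cat",
        [(0.10, 0), (0.1000001, 1), (0.20, 1), (0.40, 2), (0.95, 3), (0.0, 0)],
    )
    def test_left_open_right_closed_intervals(self, pred, cat):
        assert categorize([pred], self.cutoffs)[0] == cat

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            categorize([1.5], self.cutoffs)


class TestReclassTable:
    cutoffs = RiskCutoffs((0.10, 0.20, 0.40))

    def test_identity_predictions_give_diagonal_matrices(self, rng):
        p = rng.random(200)
        y = (rng.random(200) < 0.3).astype(int)
        t = build_reclass_table(p, p, y, self.cutoffs)
        assert np.all(np.asarray(t.events) == np.diag(np.diag(t.events)))
        assert np.all(np.asarray(t.nonevents) == np.diag(np.diag(t.nonevents)))

    def test_grand_totals_conserved(self, rng):
        po, pn = rng.random(300), rng.random(300)
        y = (rng.random(300) < 0.25).astype(int)
        t = build_reclass_table(po, pn, y, self.cutoffs)
        assert t.n_events == y.sum()
        assert t.n_nonevents == (1 - y).sum()

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValidationError):
            build_reclass_table([0.1], [0.1, 0.2], [1, 0], self.cutoffs)


class TestCategoryNri:
    def test_published_mace_counts_reproduce_printed_nri(self):
        table = mace_reclassification_table()
        moves = table.movements()
        assert moves == {
            "events_up": 51, "events_down": 28,
            "nonevents_up": 80, "nonevents_down": 164,
        }
        rep = category_nri(table)
        assert rep.event_nri == pytest.approx(23 / 234)       # 9.8%
        assert rep.nonevent_nri == pytest.approx(84 / 784)    # 10.7%
        assert rep.nri == pytest.approx(0.2054, abs=5e-4)
        assert rep.nri == rep.event_nri + rep.nonevent_nri    # exact decomposition
        assert rep.z > 4 and rep.p_value < 0.001              # sign and magnitude only

    def test_variance_variants_agree_in_sign(self):
        table = mace_reclassification_table()
        z_full = category_nri(table, variance="pencina").z
        z_simple = category_nri(table, variance="simple").z
        assert z_full > 0 and z_simple > 0
        assert z_full == pytest.approx(z_simple, rel=0.05)

    def test_identity_table_gives_zero(self):
        t = ReclassificationTable(events=np.diag([3, 4, 5, 6]), nonevents=np.diag([7, 8, 9, 10]))
        rep = category_nri(t)
        assert rep.nri == 0.0
        assert rep.z == 0.0

    def test_no_events_rejected(self):
        t = ReclassificationTable(events=np.zeros((4, 4), int), nonevents=np.diag([1] * 4))
        with pytest.raises(ValidationError):
            category_nri(t)


def brute_force_category_free(po, pn, y):
    e_up = e_down = ne_up = ne_down = 0
    for old, new, yi in zip(po, pn, y):
        if yi:
            e_up += new > old
            e_down += new < old
        else:
            ne_up += new > old
            ne_down += new < old
    n_e, n_ne = int(np.sum(y)), int(np.sum(1 - np.asarray(y)))
    return (e_up - e_down) / n_e + (ne_down - ne_up) / n_ne


class TestCategoryFreeNri:
    def test_identity_and_maximum(self, rng):
        p = rng.random(50)
        y = np.array([1] * 20 + [0] * 30)
        assert category_free_nri(p, p, y).nri == 0.0
        # every event moves up, every non-event moves down
        pn = np.where(y, p + 0.01, p - 0.01)
        assert category_free_nri(p, pn, y).nri == pytest.approx(2.0)

    def test_matches_brute_force_sign_counting(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 101))
            y = np.zeros(n, int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            po = np.round(rng.random(n), 1)  # rounding creates ties
            pn = np.round(rng.random(n), 1)
            rep = category_free_nri(po, pn, y)
            assert rep.nri == pytest.approx(brute_force_category_free(po, pn, y), abs=1e-12)
            assert -2 <= rep.nri <= 2


class TestIdi:
    def test_identity_zero_and_hand_example(self):
        po = np.array([0.2, 0.4, 0.1, 0.3])
        y = np.array([1, 1, 0, 0])
        assert idi(po, po, y).nri == 0.0
        pn = np.array([0.3, 0.5, 0.1, 0.2])
        # slopes: old (0.3 - 0.2) = 0.1, new (0.4 - 0.15) = 0.25
        assert idi(po, pn, y).nri == pytest.approx(0.15)

    def test_two_route_computation_agrees(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 200))
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            po, pn = rng.random(n), rng.random(n)
            direct = idi(po, pn, y).nri
            via_slopes = discrimination_slope(pn, y) - discrimination_slope(po, y)
            assert direct == pytest.approx(via_slopes, abs=1e-12)

    def test_role_swap_negates_all_metrics(self, rng):
        n = 150
        y = (rng.random(n) < 0.3).astype(int)
        po, pn = rng.random(n), rng.random(n)
        cuts = RiskCutoffs((0.1, 0.2, 0.4))
        assert idi(po, pn, y).nri == pytest.approx(-idi(pn, po, y).nri)
        assert category_free_nri(po, pn, y).nri == pytest.approx(
            -category_free_nri(pn, po, y).nri
        )
        fwd = category_nri(build_reclass_table(po, pn, y, cuts)).nri
        rev = category_nri(build_reclass_table(pn, po, y, cuts)).nri
        assert fwd == pytest.approx(-rev)
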