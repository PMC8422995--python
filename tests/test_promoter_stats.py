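"""Alignment, A/T% profiles, per-position tests and bin classification."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from discrimsc import (
    SynthConfig,
    align_promoters,
    at_profile,
    classify_and_regress,
    discriminator_at,
    discriminator_variable,
    generate_promoters,
    minus10_pwm_correlation,
    position_ttest,
    significance_stars,
)

from conftest import build_promoter


def _calls(ids_by_call):
    rows = []
    for call, ids in ids_by_call.items():
        for i in ids:
            rows.append({"id": i, "call": call, "log2fc": 0.0, "padj": 0.5})
    return pd.DataFrame(rows)


class TestAlignment:
    def test_tss_anchor_places_tss_at_plus_one(self):
        proms = [build_promoter(pid=f"p{i}") for i in range(3)]
        aligned = align_promoters(proms, anchor="tss")
        for p in proms:
            # aligned position 0 (display +1) is the TSS base
            assert aligned.window_at(p, 0, 1) == p.base_at(0)

    def test_global_shift_moves_the_axis(self):
        prom = build_promoter()
        aligned = align_promoters([prom], anchor="tss", shift=-4)
        # with shift -4, aligned position -4 reads the TSS base
        assert aligned.window_at(prom, -4, 1) == prom.base_at(0)

    def test_minus10_anchor_places_hexamer_at_minus12(self):
        prom = build_promoter(up=60, minus10_offset=-15)
        seq = list(prom.seq)
        seq[-15 + 60 : -15 + 60 + 6] = "TATAAT"
        prom.seq = "".join(seq)
        aligned = align_promoters([prom], anchor="minus10")
        assert aligned.window_at(prom, -12 + 2, 5) + aligned.window_at(
            prom, -12 + 5, 1
        ) == "TATAA" + "T"

    def test_missing_minus10_rejected(self):
        good = build_promoter(pid="a")
        bad = build_promoter(pid="b")
        bad.minus10_offset = None
        with pytest.raises(ValueError, match="lack"):
            align_promoters([good, bad], anchor="minus10")


class TestProfiles:
    def test_all_a_promoters_profile_at_hundred(self):
        proms = [
            build_promoter(bubble="A" * 14, disc=None, pid=f"p{i}") for i in range(4)
        ]
        for p in proms:
            p.seq = "A" * len(p.seq)
        aligned = align_promoters(proms)
        calls = _calls({"act": ["p0", "p1"], "rep": ["p2", "p3"]})
        prof = at_profile(aligned, calls)
        assert np.all(prof.table["mean"] == 100.0)
        assert np.all(prof.table["se"] == 0.0)

    def test_hand_counted_window_mean(self):
        p1 = build_promoter(disc="ATGCA", pid="p1")  # 3/5 A or T
        p2 = build_promoter(disc="GGGCA", pid="p2")  # 1/5
        aligned = align_promoters([p1, p2])
        prof = at_profile(aligned, _calls({"act": ["p1", "p2"]}))
        row = prof.table[(prof.table.group == "act") & (prof.table.position == -2)]
        assert row["mean"].iloc[0] == pytest.approx((60.0 + 20.0) / 2)

    def test_identical_sequences_give_identical_group_profiles(self):
        proms = [build_promoter(pid=f"p{i}") for i in range(6)]
        aligned = align_promoters(proms)
        calls = _calls({"act": ["p0", "p1", "p2"], "rep": ["p3", "p4", "p5"]})
        prof = at_profile(aligned, calls)
        act = prof.table[prof.table.group == "act"].set_index("position")["mean"]
        rep = prof.table[prof.table.group == "rep"].set_index("position")["mean"]
        assert (act == rep).all()

    def test_even_window_rejected(self):
        proms = [build_promoter(pid="a")]
        with pytest.raises(ValueError):
            at_profile(align_promoters(proms), _calls({"act": ["a"]}), window=4)

    def test_input_order_invariance(self, default_promoters):
        calls = _calls(
            {
                "act": [p.id for p in default_promoters[:150]],
                "rep": [p.id for p in default_promoters[150:300]],
            }
        )
        a = at_profile(align_promoters(default_promoters), calls)
        b = at_profile(align_promoters(default_promoters[::-1]), calls)
        key = ["group", "position"]
        pd.testing.assert_frame_equal(
            a.table.sort_values(key).reset_index(drop=True),
            b.table.sort_values(key).reset_index(drop=True),
        )


class TestDiscriminatorWindows:
    @pytest.mark.parametrize(
        "disc,expected", [("GCGCG", 0.0), ("ATGCA", 60.0), ("TATAA", 100.0)]
    )
    def test_fixed_window_levels(self, disc, expected):
        assert discriminator_at(build_promoter(disc=disc)) == expected

    def test_downstream_center_mode(self):
        # center +4 reads display +2..+6, i.e. internal offsets 1..5
        prom = build_promoter()
        seq = list(prom.seq)
        seq[prom.up + 1 : prom.up + 6] = "AATTA"
        prom.seq = "".join(seq)
        assert discriminator_at(prom, center=4) == 100.0

    def test_variable_length_extractor(self):
        prom = build_promoter(disc="ATGCA")
        seq = list(prom.seq)
        seq[prom.up - 6 : prom.up - 4] = "GC"  # internal -6, -5
        prom.seq = "".join(seq)
        # -10 at -12: variable discriminator = internal -6..-1 = GC + ATGC
        assert discriminator_variable(prom) == pytest.approx(100.0 * 2 / 6)


class TestPositionTTest:
    def test_identical_groups_t_zero_p_one(self):
        proms = [build_promoter(pid=f"p{i}") for i in range(4)]
        aligned = align_promoters(proms)
        calls = _calls({"act": ["p0", "p1"], "rep": ["p2", "p3"]})
        t, p = position_ttest(aligned, calls, -2)
        assert t == 0.0 and p == 1.0

    def test_matches_hand_evaluated_welch_formula(self):
        discs = {
            "a0": "TATAA", "a1": "ATATT", "a2": "ATTAG",  # 100, 100, 80
            "r0": "GCGCA", "r1": "GTGCA", "r2": "GCGTC",  # 20, 40, 20
        }
        proms = [build_promoter(disc=d, pid=i) for i, d in discs.items()]
        aligned = align_promoters(proms)
        calls = _calls({"act": ["a0", "a1", "a2"], "rep": ["r0", "r1", "r2"]})
        t_obs, p_obs = position_ttest(aligned, calls, -2)
        # Welch's statistic written out from its definition
        x, y = np.array([100.0, 100.0, 80.0]), np.array([20.0, 40.0, 20.0])
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 3
        t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx**2 / 2 + vy**2 / 2)
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        assert t_obs == pytest.approx(t_hand, rel=1e-12)
        assert p_obs == pytest.approx(p_hand, rel=1e-9)

    def test_small_groups_rejected(self):
        proms = [build_promoter(pid=f"p{i}") for i in range(3)]
        aligned = align_promoters(proms)
        with pytest.raises(ValueError):
            position_ttest(aligned, _calls({"act": ["p0"], "rep": ["p1", "p2"]}), -2)


class TestClassifyAndRegress:
    def _two_bin_set(self, n_act_gc=20, n_rep_gc=10, n_act_at=10, n_rep_at=20):
        proms, act, rep = [], [], []
        k = 0
        for disc, n_act, n_rep in (
            ("GCGCG", n_act_gc, n_rep_gc),
            ("ATATA", n_act_at, n_rep_at),
        ):
            for _ in range(n_act):
                proms.append(build_promoter(disc=disc, pid=f"p{k}"))
                act.append(f"p{k}")
                k += 1
            for _ in range(n_rep):
                proms.append(build_promoter(disc=disc, pid=f"p{k}"))
                rep.append(f"p{k}")
                k += 1
        return proms, _calls({"act": act, "rep": rep})

    def test_chi2_matches_textbook_formula(self):
        proms, calls = self._two_bin_set()
        res = classify_and_regress(align_promoters(proms), calls)
        # 2x2 table (20,10 / 10,20): all expected counts 15, chi2 = 4*25/15
        chi2_hand = 4 * 25 / 15
        assert res.chi2 == pytest.approx(chi2_hand, rel=1e-12)
        assert res.chi2_p == pytest.approx(stats.chi2.sf(chi2_hand, 1), rel=1e-9)

    def test_wilson_intervals_contain_point_estimates(self):
        proms, calls = self._two_bin_set()
        res = classify_and_regress(align_promoters(proms), calls)
        occ = res.bins.dropna()
        assert ((occ.ci_lo <= occ.proportion_act) & (occ.proportion_act <= occ.ci_hi)).all()

    def test_all_activated_is_flagged_degenerate(self):
        proms, _ = self._two_bin_set(20, 0, 20, 0)
        calls = _calls({"act": [p.id for p in proms]})
        res = classify_and_regress(align_promoters(proms), calls)
        occ = res.bins.dropna()
        assert (occ.proportion_act == 1.0).all()
        assert np.isnan(res.slope_p)

    def test_single_bin_not_identifiable(self):
        proms = [build_promoter(disc="GCGCG", pid=f"p{i}") for i in range(12)]
        calls = _calls({"act": [p.id for p in proms[:6]],
                        "rep": [p.id for p in proms[6:]]})
        with pytest.raises(ValueError, match="identifiable"):
            classify_and_regress(align_promoters(proms), calls)

    def test_binned_regression_mode(self):
        proms, calls = self._two_bin_set()
        res = classify_and_regress(align_promoters(proms), calls, regression="binned")
        # proportions 2/3 at 0% and 1/3 at 100%: slope -1/300 per A/T point
        assert res.slope == pytest.approx(-(1 / 3) / 100, rel=1e-9)

    def test_planted_relaxation_signal_recovered(self, default_promoters, mp, tp):
        from discrimsc import call_expression, generate_response

        cfg = SynthConfig(n_promoters=400, seed=5)
        sim = generate_response(default_promoters, cfg, mp, tp)
        calls = call_expression(sim.records)
        res = classify_and_regress(align_promoters(default_promoters), calls)
        assert res.slope > 0
        # n=400 here; the genome-scale (n=2000) check lives in the
        # end-to-end suite at a stricter threshold
        assert res.slope_p < 0.05
        assert significance_stars(res.slope_p) in ("*", "**", "***")


class TestPwmCorrelation:
    def test_identical_promoters_zero_variance_error(self):
        proms = [build_promoter(pid=f"p{i}") for i in range(12)]
        with pytest.raises(ValueError, match="variance"):
            minus10_pwm_correlation(align_promoters(proms))

    def test_planted_anticorrelation_detected(self):
        cfg = SynthConfig(n_promoters=500, seed=4, anticorrelation_strength=0.9)
        aligned = align_promoters(generate_promoters(cfg))
        r, p = minus10_pwm_correlation(aligned)
        assert r < 0 and p < 0.05

    def test_shuffled_pairing_kills_the_signal(self):
        cfg = SynthConfig(n_promoters=500, seed=4, anticorrelation_strength=0.9)
        proms = generate_promoters(cfg)
        rng = np.random.default_rng(0)
        # re-pair -10 hexamers and discriminators by shuffling discriminators
        discs = [p.subseq(-4, 0) for p in proms]
        rng.shuffle(discs)
        for p, d in zip(proms, discs):
            s = list(p.seq)
            s[p.up - 4 : p.up + 1] = d
            p.seq = "".join(s)
        r, p_val = minus10_pwm_correlation(align_promoters(proms))
        r_planted, _ = minus10_pwm_correlation(
            align_promoters(generate_promoters(cfg))
        )
        assert abs(r) < abs(r_planted) / 3
        assert p_val > 0.01


class TestStars:
    @pytest.mark.parametrize(
        "p,label",
        [(1e-5, "***"), (0.005, "**"), (0.03, "*"), (0.2, "ns")],
    )
    def test_mapping(self, p, label):
        assert significance_stars(p) == label
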