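"""DNA feature derivation: CCF/clonality, TMB, signatures, HRD scars,
HLA LOH and neoantigen filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoresponse import dnafeat
from neoresponse.synth import synthetic_reference_signatures

from conftest import segments


class TestCcf:
    @pytest.mark.parametrize(
        "vaf,p,cnn,cnt,expected",
        [
            (0.5, 1.0, 2, 2, 1.0),  # pure diploid heterozygous
            (0.25, 0.5, 2, 2, 1.0),
            (0.2, 0.8, 2, 3, 0.70),
        ],
    )
    def test_point_estimate(self, vaf, p, cnn, cnt, expected):
        assert dnafeat.compute_ccf(vaf, p, cnn, cnt) == pytest.approx(expected)

    def test_invalid_purity(self):
        with pytest.raises(ValueError):
            dnafeat.compute_ccf(0.5, 0.0)
        with pytest.raises(ValueError):
            dnafeat.compute_ccf(0.5, 1.2)

    def test_values_above_one_not_clipped(self):
        assert dnafeat.compute_ccf(1.0, 1.0, 2, 2) == pytest.approx(2.0)


class TestClonality:
    def test_balanced_het_is_clonal(self):
        # Wilson 95% CI on 50/100 is ~(0.402, 0.598); x2 -> (0.80, 1.20)
        call = dnafeat.classify_clonality(50, 100, 1.0)
        assert call.clonal
        assert call.ci_low == pytest.approx(0.8077, abs=1e-3)
        assert call.ci_high == pytest.approx(1.1923, abs=1e-3)

    def test_low_vaf_is_subclonal(self):
        call = dnafeat.classify_clonality(10, 100, 1.0)
        assert not call.clonal
        assert call.ci_high < 1

    def test_ci_entirely_above_one_is_subclonal_and_flagged(self):
        # the rule as stated: CI must overlap 1; VAF=1 at p=1 gives CCF=2
        call = dnafeat.classify_clonality(100, 100, 1.0)
        assert call.ccf == pytest.approx(2.0)
        assert not call.clonal
        assert call.above_one

    def test_wilson_interval_matches_direct_formula(self):
        # independent oracle: closed-form Wilson score interval
        alt, tot = 37, 90
        z = 1.959963984540054
        phat = alt / tot
        denom = 1 + z**2 / tot
        centre = (phat + z**2 / (2 * tot)) / denom
        half = z * np.sqrt(phat * (1 - phat) / tot + z**2 / (4 * tot**2)) / denom
        call = dnafeat.classify_clonality(alt, tot, 0.5)  # multiplier = 4
        assert call.ci_low == pytest.approx((centre - half) * 4, rel=1e-9)
        assert call.ci_high == pytest.approx((centre + half) * 4, rel=1e-9)

    @given(total=st.integers(20, 200), purity=st.floats(0.2, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_alt_count(self, total, purity):
        # increasing alt at fixed total shifts the CI upward monotonically
        lows = [
            dnafeat.classify_clonality(a, total, purity).ci_low
            for a in range(0, total + 1, max(total // 10, 1))
        ]
        assert all(b >= a - 1e-12 for a, b in zip(lows, lows[1:]))

    def test_zero_depth_raises(self):
        with pytest.raises(ValueError):
            dnafeat.classify_clonality(0, 0, 1.0)


class TestPctSubclonal:
    def _table(self, alts):
        return pd.DataFrame(
            {
                "alt_reads": alts,
                "total_reads": [100] * len(alts),
                "purity": [1.0] * len(alts),
                "cn_normal": [2] * len(alts),
                "cn_tumour": [2] * len(alts),
            }
        )

    def test_all_clonal_is_zero(self):
        assert dnafeat.pct_subclonal(self._table([50, 48, 52])) == 0.0

    def test_three_of_ten(self):
        alts = [50] * 7 + [5, 8, 10]  # 3 clearly subclonal
        assert dnafeat.pct_subclonal(self._table(alts)) == pytest.approx(30.0)

    def test_no_classifiable_is_nan(self):
        tab = self._table([50])
        tab["purity"] = np.nan
        assert np.isnan(dnafeat.pct_subclonal(tab))


class TestTmb:
    @pytest.mark.parametrize(
        "n,expected", [(0, 0.0), (4554, 100.0), (105, 105 / 45.54)]
    )
    def test_per_megabase(self, n, expected):
        assert dnafeat.compute_tmb(n) == pytest.approx(expected)

    @given(a=st.integers(0, 5000), b=st.integers(0, 5000))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_disjoint_union(self, a, b):
        assert dnafeat.compute_tmb(a) + dnafeat.compute_tmb(b) == pytest.approx(
            dnafeat.compute_tmb(a + b)
        )


@pytest.fixture(scope="module")
def reference():
    return synthetic_reference_signatures(n_signatures=5)


class TestSignatures:

    def test_pure_signature_recovered(self, reference):
        cat = reference["3"].to_numpy() * 500
        exp = dnafeat.fit_signature_exposures(cat, reference, n_mutations=500)
        assert exp.weights["3"] == pytest.approx(1.0, abs=1e-6)
        assert exp.weights.drop("3").max() == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_mixture_recovered(self, reference):
        cat = 0.6 * reference["3"] + 0.4 * reference["13"]
        exp = dnafeat.fit_signature_exposures(cat.to_numpy() * 1000, reference,
                                              n_mutations=1000)
        assert exp.weights["3"] == pytest.approx(0.6, abs=0.05)
        assert exp.weights["13"] == pytest.approx(0.4, abs=0.05)

    def test_too_few_mutations_returns_none(self, reference):
        cat = reference["1"].to_numpy() * 10
        assert dnafeat.fit_signature_exposures(cat, reference,
                                               n_mutations=10) is None
        assert dnafeat.fit_signature_exposures(cat, reference,
                                               n_mutations=11) is not None

    def test_unnormalized_reference_rejected(self, reference):
        with pytest.raises(ValueError):
            dnafeat.fit_signature_exposures(
                reference["1"].to_numpy(), reference * 2.0, n_mutations=100
            )

    def test_small_weights_discarded(self, reference):
        cat = 0.97 * reference["1"] + 0.03 * reference["13"]
        exp = dnafeat.fit_signature_exposures(cat.to_numpy() * 1000, reference,
                                              n_mutations=1000)
        assert exp.weights["13"] == 0.0
        assert exp.weights.sum() == pytest.approx(1.0)


class TestNormalizeExposures:
    def _exposure(self, weights):
        return dnafeat.SignatureExposure(
            weights=pd.Series(weights), reconstruction_error=0.0, n_mutations=100
        )

    def test_equal_weights_give_zero_ratio(self):
        ratios, _ = dnafeat.normalize_exposures(
            self._exposure({"1": 0.5, "3": 0.5})
        )
        assert ratios["3"] == pytest.approx(0.0)

    def test_fourfold_ratio_is_about_two(self):
        ratios, _ = dnafeat.normalize_exposures(
            self._exposure({"1": 0.2, "3": 0.8})
        )
        assert ratios["3"] == pytest.approx(2.0, abs=0.1)

    def test_clock_only_nonclock_zero(self):
        _, nonclock = dnafeat.normalize_exposures(self._exposure({"1": 1.0}))
        assert nonclock == pytest.approx(0.0)

    def test_pseudocount_keeps_ratio_finite(self):
        ratios, _ = dnafeat.normalize_exposures(
            self._exposure({"1": 0.0, "3": 1.0})
        )
        assert np.isfinite(ratios["3"])


class TestHrd:
    def test_balanced_diploid_scores_zero(self, genome_model):
        rows = []
        for r in genome_model.itertuples():
            rows.append(("P1", str(r.chrom), 1, int(r.length), 1, 1))
        segs = pd.DataFrame(
            rows, columns=["patient", "chrom", "start", "end", "major_cn",
                           "minor_cn"]
        )
        score = dnafeat.compute_hrd(segs, genome_model)
        assert (score.tai, score.loh, score.lst) == (0, 0, 0)
        assert score.total == 0

    def test_interstitial_loh_counts_once(self, toy_genome):
        MB = 1_000_000
        segs = segments(
            [
                (1, 30 * MB, 1, 1),
                (30 * MB + 1, 50 * MB, 1, 0),  # 20 Mb LOH, interstitial
                (50 * MB + 1, 200 * MB, 1, 1),
            ]
        )
        score = dnafeat.compute_hrd(segs, toy_genome)
        assert score.loh == 1
        assert score.tai == 0

    def test_short_loh_not_counted(self, toy_genome):
        MB = 1_000_000
        segs = segments(
            [
                (1, 30 * MB, 1, 1),
                (30 * MB + 1, 40 * MB, 1, 0),  # 10 Mb < 15 Mb threshold
                (40 * MB + 1, 200 * MB, 1, 1),
            ]
        )
        assert dnafeat.compute_hrd(segs, toy_genome).loh == 0

    def test_whole_chromosome_loh_not_counted(self, toy_genome):
        segs = segments([(1, 200_000_000, 1, 0)])
        assert dnafeat.compute_hrd(segs, toy_genome).loh == 0

    def test_telomeric_imbalance_is_tai(self, toy_genome):
        MB = 1_000_000
        segs = segments(
            [
                (1, 20 * MB, 2, 1),  # touches p telomere, imbalanced
                (20 * MB + 1, 200 * MB, 1, 1),
            ]
        )
        score = dnafeat.compute_hrd(segs, toy_genome)
        assert score.tai == 1

    def test_centromere_crossing_imbalance_not_tai(self, toy_genome):
        MB = 1_000_000
        segs = segments(
            [
                (1, 150 * MB, 2, 1),  # spans the centromere (100-103 Mb)
                (150 * MB + 1, 200 * MB, 1, 1),
            ]
        )
        assert dnafeat.compute_hrd(segs, toy_genome).tai == 0

    def test_adjacent_large_segments_make_one_lst(self, toy_genome):
        MB = 1_000_000
        segs = segments(
            [
                (1, 40 * MB, 2, 1),
                (40 * MB + 1, 80 * MB, 2, 2),  # CN change, both >= 10 Mb
                (80 * MB + 1, 200 * MB, 2, 2),
            ]
        )
        score = dnafeat.compute_hrd(segs, toy_genome)
        assert score.lst == 1  # single p-arm breakpoint (merge joins q side)

    def test_small_segment_removed_before_lst(self, toy_genome):
        MB = 1_000_000
        # a 2-Mb blip between two large same-CN segments: removed, merged, no LST
        segs = segments(
            [
                (1, 40 * MB, 2, 2),
                (40 * MB + 1, 42 * MB, 3, 1),
                (42 * MB + 1, 80 * MB, 2, 2),
                (80 * MB + 1, 200 * MB, 2, 2),
            ]
        )
        assert dnafeat.compute_hrd(segs, toy_genome).lst == 0

    def test_permutation_invariant(self, toy_genome):
        MB = 1_000_000
        segs = segments(
            [
                (1, 20 * MB, 2, 1),
                (20 * MB + 1, 50 * MB, 1, 0),
                (50 * MB + 1, 120 * MB, 1, 1),
                (120 * MB + 1, 160 * MB, 3, 1),
                (160 * MB + 1, 200 * MB, 1, 1),
            ]
        )
        base = dnafeat.compute_hrd(segs, toy_genome)
        shuffled = dnafeat.compute_hrd(
            segs.sample(frac=1, random_state=7), toy_genome
        )
        assert (base.tai, base.loh, base.lst) == (
            shuffled.tai, shuffled.loh, shuffled.lst,
        )

    def test_overlapping_segments_rejected(self, toy_genome):
        segs = segments([(1, 50_000_000, 1, 1), (40_000_000, 90_000_000, 2, 1)])
        with pytest.raises(ValueError, match="overlap"):
            dnafeat.compute_hrd(segs, toy_genome)

    def test_exhaustive_rule_oracle_on_random_instances(self, toy_genome):
        """Each component re-derived by a literal reading of the scar rules on
        randomly generated non-overlapping <= 20-segment chromosomes."""
        MB = 1_000_000
        rng = np.random.default_rng(5)
        length = int(toy_genome["length"].iloc[0])
        cen_s = int(toy_genome["centromere_start"].iloc[0])
        cen_e = int(toy_genome["centromere_end"].iloc[0])
        for _ in range(25):
            k = rng.integers(1, 20)
            cuts = np.sort(rng.choice(np.arange(2, length, MB), k - 1,
                                      replace=False)) if k > 1 else []
            bounds = [1, *cuts, length]
            rows = []
            for s, e in zip(bounds[:-1], bounds[1:]):
                ma, mi = sorted(rng.integers(0, 4, 2), reverse=True)
                if ma == 0:
                    ma = 1
                rows.append((int(s) + (s != 1), int(e), int(ma), int(mi)))
            # normalise: make contiguous 1-based segments
            rows = [
                (1 if i == 0 else rows[i - 1][1] + 1, e, ma, mi)
                for i, (_, e, ma, mi) in enumerate(rows)
            ]
            segs = segments(rows)
            got = dnafeat.compute_hrd(segs, toy_genome)

            # --- independent literal re-application of the rules ---
            loh = sum(
                1 for s, e, ma, mi in rows
                if mi == 0 and ma > 0 and (e - s + 1) > 15 * MB
                and not (s <= 1 and e >= length)
            )
            tai = sum(
                1 for s, e, ma, mi in rows
                if ma != mi and (s <= 1 or e >= length)
                and not (s < cen_s and e > cen_e)
                and not (s <= 1 and e >= length)
            )

            def lst_arm(arm):
                arm = [r for r in arm if r[1] - r[0] + 1 >= 3 * MB]
                merged = []
                for r in arm:
                    if merged and merged[-1][2:] == r[2:] \
                            and r[0] - merged[-1][1] - 1 < 3 * MB:
                        merged[-1] = (merged[-1][0], r[1], *r[2:])
                    else:
                        merged.append(r)
                return sum(
                    1 for a, b in zip(merged, merged[1:])
                    if a[1] - a[0] + 1 >= 10 * MB and b[1] - b[0] + 1 >= 10 * MB
                    and b[0] - a[1] - 1 < 3 * MB
                )

            p_arm = [
                (s, min(e, cen_s - 1), ma, mi)
                for s, e, ma, mi in rows if s < cen_s
            ]
            q_arm = [
                (max(s, cen_e + 1), e, ma, mi)
                for s, e, ma, mi in rows if e > cen_e
            ]
            lst = lst_arm([r for r in p_arm if r[1] >= r[0]]) + lst_arm(
                [r for r in q_arm if r[1] >= r[0]]
            )
            assert (got.loh, got.tai, got.lst) == (loh, tai, lst)


class TestGenomeAlteredFraction:
    def test_all_at_ploidy_is_zero(self, toy_genome):
        segs = segments([(1, 200_000_000, 1, 1)])
        assert dnafeat.genome_altered_fraction(segs, ploidy=2) == 0.0

    def test_half_genome_gained(self):
        segs = segments([(1, 100, 2, 1), (101, 200, 1, 1)])
        assert dnafeat.genome_altered_fraction(segs, ploidy=2) == pytest.approx(0.5)

    def test_matches_hand_weighted_count(self):
        segs = segments(
            [(1, 10, 2, 2), (11, 40, 1, 1), (41, 100, 3, 1), (101, 102, 1, 0)]
        )
        # altered: 10 (CN4) + 60 (CN4) + 2 (CN1) = 72 of 102
        assert dnafeat.genome_altered_fraction(segs, ploidy=2) == pytest.approx(
            72 / 102
        )


class TestHlaLoh:
    def _table(self, cn, p):
        return pd.DataFrame(
            {"patient": ["P1"], "allele": ["A1"], "cn": [cn], "p_value": [p]}
        )

    @pytest.mark.parametrize(
        "cn,p,expected",
        [(0.3, 0.01, True), (0.9, 0.001, False), (0.3, 0.2, False)],
    )
    def test_rule(self, cn, p, expected):
        assert dnafeat.call_hla_loh(self._table(cn, p))["loh"].iloc[0] == expected

    def test_missing_significance_skipped(self):
        calls = dnafeat.call_hla_loh(self._table(0.1, np.nan))
        assert not calls["loh"].iloc[0]
        assert calls["skipped"].iloc[0]


class TestHlaLohImpact:
    def test_no_loh_means_all_presentable(self):
        calls = pd.DataFrame(
            {"patient": ["P1"] * 2, "allele": ["A1", "A2"], "loh": [False, False]}
        )
        epi = pd.DataFrame(
            {"patient": ["P1"] * 3, "peptide": ["x", "y", "z"],
             "allele": ["A1", "A2", "A1"]}
        )
        pct, _ = dnafeat.hla_loh_impact(calls, epi)
        assert pct == 0.0

    def test_thirty_percent_unpresentable(self):
        calls = pd.DataFrame(
            {"patient": ["P1"] * 2, "allele": ["A1", "A2"], "loh": [True, False]}
        )
        peptides = [f"p{i}" for i in range(10)]
        alleles = ["A1"] * 3 + ["A2"] * 7  # 3 presented only by the lost allele
        epi = pd.DataFrame(
            {"patient": "P1", "peptide": peptides, "allele": alleles}
        )
        pct, frac = dnafeat.hla_loh_impact(calls, epi)
        assert pct == pytest.approx(30.0)
        assert frac == 0.0  # lost allele presents 3 < retained 7

    def test_event_fractions_match_enumeration(self):
        calls = pd.DataFrame(
            {
                "patient": ["P1", "P1", "P2", "P2", "P3", "P3", "P4", "P4"],
                "allele": ["A1", "A2"] * 4,
                "loh": [True, False, True, False, True, False, True, False],
            }
        )
        rows = []
        # lost >= retained for P1 (2 vs 1) and P3 (1 vs 1); not P2, P4
        for pat, lost_n, kept_n in [("P1", 2, 1), ("P2", 0, 3), ("P3", 1, 1),
                                    ("P4", 1, 2)]:
            for i in range(lost_n):
                rows.append((pat, f"{pat}l{i}", "A1"))
            for i in range(kept_n):
                rows.append((pat, f"{pat}k{i}", "A2"))
        epi = pd.DataFrame(rows, columns=["patient", "peptide", "allele"])
        _, frac = dnafeat.hla_loh_impact(calls, epi)
        assert frac == pytest.approx(2 / 4)


class TestNeoantigenFilter:
    def _row(self, mut, wt, tpm, length=9):
        return {"length": length, "mutant_nm": mut, "wildtype_nm": wt, "tpm": tpm}

    def test_boundary_just_under_500(self):
        tab = pd.DataFrame([self._row(499.0, 600.0, 2.0)])
        assert len(dnafeat.filter_neoantigens(tab)) == 1

    def test_exactly_500_rejected(self):
        tab = pd.DataFrame([self._row(500.0, 600.0, 2.0)])
        assert len(dnafeat.filter_neoantigens(tab)) == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(9)
        tab = pd.DataFrame(
            {
                "length": rng.choice([8, 9, 10, 11], 200),
                "mutant_nm": rng.uniform(1, 2000, 200),
                "wildtype_nm": rng.uniform(1, 2000, 200),
                "tpm": rng.uniform(0, 10, 200),
            }
        )
        expected = sum(
            1
            for _, r in tab.iterrows()
            if r.mutant_nm < 500 and r.mutant_nm < r.wildtype_nm and r.tpm > 1
        )
        assert len(dnafeat.filter_neoantigens(tab)) == expected

    def test_bad_length_rejected(self):
        tab = pd.DataFrame([self._row(100.0, 600.0, 2.0, length=12)])
        with pytest.raises(ValueError):
            dnafeat.filter_neoantigens(tab)

    def test_negative_affinity_rejected(self):
        tab = pd.DataFrame([self._row(-1.0, 600.0, 2.0)])
        with pytest.raises(ValueError):
            dnafeat.filter_neoantigens(tab)


class TestDriverFlags:
    def test_hand_counted_matrix(self):
        muts = pd.DataFrame(
            {
                "patient": ["P1", "P1", "P2", "P3", "P3", "P4"],
                "gene": ["TP53", "TP53", "PIK3CA", "TP53", "PIK3CA", "OTHER"],
            }
        )
        flags = dnafeat.driver_flags(
            muts, ["TP53", "PIK3CA"], patients=["P1", "P2", "P3", "P4", "P5"]
        )
        assert flags["TP53"].tolist() == [1, 0, 1, 0, 0]
        assert flags["PIK3CA"].tolist() == [0, 1, 1, 0, 0]

    def test_counting_summary(self):
        muts = pd.DataFrame(
            {"patient": ["P1", "P1", "P2", "P3"],
             "gene": ["TP53", "PIK3CA", "TP53", "X"]}
        )
        clin = pd.DataFrame(
            {"rcb_class": ["pCR", "RCB-II", "RCB-II", "RCB-III"]},
            index=["P1", "P2", "P3", "P4"],
        )
        counts = dnafeat.cohort_counts(muts, clin)
        assert counts["n_mutations"] == 4
        assert counts["n_tp53_cases"] == 2
        assert counts["n_pik3ca_cases"] == 1
        assert counts["n_pCR"] == 1 and counts["n_RCB-II"] == 2
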