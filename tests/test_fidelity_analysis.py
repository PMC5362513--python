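"""Error-rate inference, vendor-fidelity comparison, concordance rules."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import rankdata

from arfidelity.amplification_simulator import (
    LocusPool,
    MoleculePool,
    PolymeraseProfile,
    expected_error_fraction,
    simulate_ddpcr,
)
from arfidelity.ddpcr_quant import DropletData
from arfidelity.fidelity_analysis import (
    ControlRequiredError,
    RunInvalidError,
    classify_concordance,
    compare_locus_rates,
    estimate_error_rate,
    fidelity_report,
    fold_over_reported,
)
from arfidelity.ngs_caller import VariantCall


class TestEstimateErrorRate:
    def test_zero_artifacts(self):
        est = estimate_error_rate(0, 44104, 22)
        assert est.e_hat == 0.0 and est.ci_low == 0.0 and est.ci_high > 0

    def test_study_phusion_point_estimate(self):
        # 11 mutant vs 32975 wild-type droplets after 22 cycles
        est = estimate_error_rate(11, 32975, 22)
        assert est.e_hat == pytest.approx(2 * (11 / 32975) / 22, rel=1e-12)
        assert est.e_hat == pytest.approx(3.0e-5, rel=0.02)

    def test_degenerate_limit_flagged(self):
        est = estimate_error_rate(50, 100, 1)
        assert est.e_hat == pytest.approx(1.0)
        assert "DEGENERATE" in est.flags

    def test_cycles_required(self):
        with pytest.raises(ValueError):
            estimate_error_rate(1, 100, 0)

    @given(st.integers(0, 200), st.integers(1, 100_000), st.integers(1, 30))
    def test_ci_brackets_point_estimate(self, mut, wt, cycles):
        est = estimate_error_rate(mut, wt, cycles)
        assert est.ci_low <= est.e_hat <= est.ci_high

    @pytest.mark.parametrize("e_true", [1e-6, 1e-5, 1e-4])
    def test_ci_covers_true_rate(self, e_true, rng):
        # pools at the analytic expected artifact fraction, partitioned into
        # droplets at low occupancy; exact binomial CIs are conservative
        cycles, reps = 22, 300
        frac = expected_error_fraction(e_true, cycles, efficiency=1.0)
        n_mut = round(1e9 * frac)
        pool = MoleculePool(
            loci={"X": LocusPool("T", ("C",), {"T": 10**9 - n_mut, "C": n_mut})}
        )
        hits = 0
        for _ in range(reps):
            d = simulate_ddpcr(pool, "X", 1_000_000, 20_000, rng)
            est = estimate_error_rate(d.mut_channel, d.wt_channel, cycles)
            hits += est.ci_low <= e_true <= est.ci_high
        assert hits / reps >= 0.94


class TestFoldOverReported:
    def test_identity_fold(self):
        poly = PolymeraseProfile(name="Phusion", base_error_rate=4.4e-7, reported_error_rate=4.4e-7)
        assert fold_over_reported(4.4e-7, poly).fold == pytest.approx(1.0)

    def test_study_phusion_excess(self, polymerases):
        # the observed locus-specific rate far exceeds the vendor figure
        est = estimate_error_rate(11, 32975, 22)
        cmp = fold_over_reported(est.e_hat, polymerases["Phusion"])
        assert cmp.fold == pytest.approx(est.e_hat / 4.4e-7, rel=1e-9)
        assert 60 < cmp.fold < 80
        assert not cmp.consistent_with_reported

    def test_bound_only_vendor_claim(self, polymerases):
        superfi = polymerases["SuperFi"]
        ok = fold_over_reported(0.0, superfi)
        assert ok.kind == "bound" and ok.consistent_with_reported and ok.fold is None
        bad = fold_over_reported(2e-5, superfi)
        assert not bad.consistent_with_reported and bad.fold == pytest.approx(100.0)

    @given(st.floats(1e-9, 1e-3))
    def test_scale_equivariance(self, e_hat):
        poly = PolymeraseProfile(name="P", base_error_rate=1e-5, reported_error_rate=1e-5)
        assert fold_over_reported(2 * e_hat, poly).fold == pytest.approx(
            2 * fold_over_reported(e_hat, poly).fold
        )


def exact_signed_rank_p(a, b):
    """Brute-force two-sided signed-rank p: enumerate all 2^n sign vectors."""
    diffs = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    diffs = diffs[diffs != 0]
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    w_values = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=n)
    ]
    w_values = np.array(w_values)
    p_le = (w_values <= w_obs).mean()
    p_ge = (w_values >= w_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestCompareLocusRates:
    def test_identical_vectors_no_signal(self):
        result = compare_locus_rates([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert result.no_signal and result.wilcoxon_p == 1.0

    def test_all_positive_differences_small_n(self):
        # 7 concordant pairs: two-sided exact p = 2/2^7
        a = [0.027, 0.018, 0.014, 0.010, 0.027, 0.007, 0.021]
        b = [0.009, 0.007, 0.011, 0.000, 0.004, 0.000, 0.004]
        result = compare_locus_rates(a, b)
        assert result.n_positive_differences == 7
        assert result.wilcoxon_p == pytest.approx(2 / 128)

    def test_exact_p_matches_sign_flip_enumeration(self):
        rng = np.random.default_rng(99)
        for n in (5, 8, 12):
            for _ in range(5):
                a = rng.normal(0.3, 1, size=n)
                b = rng.normal(0.0, 1, size=n)
                result = compare_locus_rates(a, b)
                assert result.wilcoxon_p == pytest.approx(
                    exact_signed_rank_p(a, b), rel=1e-12
                )

    def test_power_under_known_shift(self, rng):
        # moderate shift at n=20 is detected most of the time (simulation
        # sanity check of the exact test)
        rejections = 0
        for _ in range(100):
            a = rng.normal(1.0, 1, size=20)
            b = rng.normal(0.0, 1, size=20)
            rejections += compare_locus_rates(a, b).wilcoxon_p < 0.05
        assert rejections > 70

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            compare_locus_rates([1, 2], [0, 0])


def dd(sample, locus, poly, mut, wt, sample_type="patient", preamp=True, cycles=22):
    return DropletData(
        sample_id=sample,
        locus_id=locus,
        polymerase=poly,
        preamp_cycles=cycles if preamp else 0,
        n_mut_pos=mut,
        n_wt_pos=wt,
        sample_type=sample_type,
        preamplified=preamp,
    )


def ngs_call(sample, locus, alt="C", alt_count=20, ref_count=8000):
    return VariantCall(
        sample_id=sample,
        locus_id=locus,
        alt_allele=alt,
        alt_count=alt_count,
        ref_count=ref_count,
        alt_fwd=alt_count // 2,
        alt_rev=alt_count - alt_count // 2,
        allelic_fraction_percent=100 * alt_count / ref_count,
    )


def controls(locus, poly, wt_mut=0):
    return [
        dd("WT", locus, poly, wt_mut, 30000, sample_type="wt_control"),
        dd("NTC", locus, poly, 0, 0, sample_type="ntc"),
    ]


class TestClassifyConcordance:
    def test_validated_when_clean_polymerase_positive(self):
        data = controls("W742C", "Phusion") + controls("W742C", "SuperFi") + [
            dd("Pt 3", "W742C", "Phusion", 4, 25067),
            dd("Pt 3", "W742C", "SuperFi", 38, 33611),
        ]
        result = classify_concordance([ngs_call("Pt 3", "W742C", alt="T")], data)
        assert result.verdict("Pt 3", "W742C") == "VALIDATED"
        assert not result.artifact_prone

    def test_false_positive_when_clean_polymerase_negative(self):
        data = controls("T878A", "Phusion", wt_mut=2) + controls("T878A", "SuperFi") + [
            dd("Pt 4", "T878A", "Phusion", 3, 26983),
            dd("Pt 4", "T878A", "SuperFi", 0, 30737),
        ]
        result = classify_concordance([ngs_call("Pt 4", "T878A", alt="G")], data)
        assert result.verdict("Pt 4", "T878A") == "FALSE_POSITIVE"
        assert ("T878A", "Phusion") in result.artifact_prone

    def test_artifact_prone_polymerase_cannot_validate(self):
        # positive only under the polymerase whose WT control is positive
        data = controls("F877L", "Phusion", wt_mut=11) + [
            dd("Pt 5", "F877L", "Phusion", 11, 32975),
        ]
        result = classify_concordance([ngs_call("Pt 5", "F877L")], data)
        assert result.verdict("Pt 5", "F877L") == "NOT_ASSESSED"

    def test_not_assessed_without_any_assay(self):
        data = controls("F877L", "SuperFi")
        result = classify_concordance([ngs_call("Pt 9", "F877L")], data)
        assert result.verdict("Pt 9", "F877L") == "NOT_ASSESSED"

    def test_control_equivalence_mapping(self):
        data = controls("F877L", "SuperFi")
        result = classify_concordance(
            [ngs_call("Male Control", "F877L")],
            data,
            control_equivalents={"Male Control": "WT"},
        )
        assert result.verdict("Male Control", "F877L") == "FALSE_POSITIVE"

    def test_positive_ntc_invalidates_run(self):
        data = controls("F877L", "SuperFi") + [
            dd("NTC", "F877L", "SuperFi", 1, 0, sample_type="ntc")
        ]
        with pytest.raises(RunInvalidError):
            classify_concordance([ngs_call("Pt 1", "F877L")], data)

    def test_missing_controls_refused(self):
        data = [dd("Pt 1", "F877L", "SuperFi", 0, 30000)]
        with pytest.raises(ControlRequiredError):
            classify_concordance([ngs_call("Pt 1", "F877L")], data)

    def test_total_and_deterministic_over_input_domain(self):
        # every combination of WT-control / patient positivity under two
        # polymerases maps to exactly one verdict
        verdicts = set()
        for wt_a, wt_b, pt_a, pt_b in itertools.product([0, 3], repeat=4):
            data = (
                controls("F877L", "A", wt_mut=wt_a)
                + controls("F877L", "B", wt_mut=wt_b)
                + [
                    dd("Pt", "F877L", "A", pt_a, 30000),
                    dd("Pt", "F877L", "B", pt_b, 30000),
                ]
            )
            result = classify_concordance([ngs_call("Pt", "F877L")], data)
            v = result.verdict("Pt", "F877L")
            assert v in {"VALIDATED", "FALSE_POSITIVE", "NOT_ASSESSED"}
            again = classify_concordance([ngs_call("Pt", "F877L")], data)
            assert again.verdict("Pt", "F877L") == v
            verdicts.add(v)
        assert verdicts == {"VALIDATED", "FALSE_POSITIVE", "NOT_ASSESSED"}


class TestFidelityReport:
    def test_empty_cohort_empty_report(self, polymerases):
        report = fidelity_report([], [], polymerases, patient_samples=[])
        assert report.ngs_locus_prevalence == {}
        assert report.error_estimates == ()
        assert report.concordance is None

    def test_deterministic_rendering(self):
        from arfidelity.study import run_study_analysis

        a = run_study_analysis().report
        b = run_study_analysis().report
        assert a.to_text() == b.to_text()
        assert a.to_dict() == b.to_dict()

    def test_study_summary_content(self):
        from arfidelity.study import run_study_analysis

        report = run_study_analysis().report
        text = report.to_text()
        assert "F877L: called in 5/11 patients + 1 control(s)" in text
        d = report.to_dict()
        verdicts = {
            (v["sample_id"], v["locus_id"]): v["verdict"] for v in d["verdicts"]
        }
        assert verdicts[("JHU Pt 3", "W742C")] == "VALIDATED"
        f877l_fp = [
            k for k, v in verdicts.items() if k[1] == "F877L" and v == "FALSE_POSITIVE"
        ]
        assert len(f877l_fp) == 6
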