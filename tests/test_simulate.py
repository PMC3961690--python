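"""Tests for the seeded synthetic-data generators."""

import numpy as np
import pytest
from scipy import stats

from trxpka.activity import (
    average_relative_activity,
    relative_activity,
    summarize_replicates,
)
from trxpka.models import (
    CoupledSiteModel,
    OnePkaParams,
    shift_one_pka,
    site_deprotonation_fraction,
)
from trxpka.simulate import (
    CoupledTitrationSimSpec,
    DensitometrySimSpec,
    MotifSimSpec,
    TitrationSimSpec,
    coupled_clean_curve,
    default_ph_grid,
    gen_coupled_titration,
    gen_densitometry,
    gen_motif_sequences,
    gen_titration,
    replicate_sets_from_table,
)

TRUTH = OnePkaParams(28.0, 30.5, 10.6)


class TestGenTitration:
    def test_noise_free_points_on_curve(self):
        spec = TitrationSimSpec(truth=TRUTH, noise_sd=0.0, n_resonances=2, seed=1)
        series, truths = gen_titration(spec)
        for s, t in zip(series, truths):
            assert np.allclose(s.shift, shift_one_pka(s.ph, t))

    def test_determinism(self):
        spec = TitrationSimSpec(truth=TRUTH, n_resonances=3, seed=11, amplitude_range=(0.5, 2.5))
        a, ta = gen_titration(spec)
        b, tb = gen_titration(spec)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.shift, sb.shift)
        assert ta == tb

    def test_different_seeds_differ(self):
        a, _ = gen_titration(TitrationSimSpec(truth=TRUTH, seed=1))
        b, _ = gen_titration(TitrationSimSpec(truth=TRUTH, seed=2))
        assert not np.array_equal(a[0].shift, b[0].shift)

    def test_amplitude_range_respected(self):
        spec = TitrationSimSpec(
            truth=TRUTH, n_resonances=50, amplitude_range=(0.5, 2.5), seed=5
        )
        _, truths = gen_titration(spec)
        for t in truths:
            assert 0.5 <= t.amplitude <= 2.5
            assert t.pka == TRUTH.pka

    def test_noise_sd_matches_chi_square_bounds(self):
        """Sample SD of (generated - truth curve) stays inside the central
        chi-square band at n=19 for at least 95% of seeds."""
        grid = default_ph_grid(0.5)
        n = len(grid)
        lo = 0.05 * np.sqrt(stats.chi2.ppf(0.01, n) / n)
        hi = 0.05 * np.sqrt(stats.chi2.ppf(0.99, n) / n)
        inside = 0
        for seed in range(200):
            series, truths = gen_titration(
                TitrationSimSpec(truth=TRUTH, noise_sd=0.05, seed=seed, ph_grid=grid)
            )
            resid = series[0].shift - shift_one_pka(grid, truths[0])
            sd = resid.std(ddof=0)
            inside += lo <= sd <= hi
        assert inside >= 190
        # and the coarse bracket stated for the design
        assert 0.025 <= lo and hi <= 0.075

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            TitrationSimSpec(truth=TRUTH, ph_grid=np.array([]))


class TestGenCoupledTitration:
    SYM = CoupledSiteModel.symmetric(7.6, 10.4)

    def test_symmetric_noiseless_curve_has_equal_steps(self):
        spec = CoupledTitrationSimSpec(model=self.SYM, noise_sd=0.0, seed=1)
        series, truths = gen_coupled_titration(spec)
        base, amp = truths[0]
        curve = series[0].shift
        # intermediate plateau midway between the limits: two equal steps
        plateau = curve[np.argmin(np.abs(series[0].ph - 9.0))]
        assert plateau - base == pytest.approx(0.5 * amp, abs=0.01 * amp)

    def test_zero_weight_on_a_gives_site_b_marginal(self):
        spec = CoupledTitrationSimSpec(
            model=self.SYM, weight_a=0.0, weight_b=1.0, noise_sd=0.0, seed=2
        )
        series, truths = gen_coupled_titration(spec)
        base, amp = truths[0]
        expected = base + amp * site_deprotonation_fraction(series[0].ph, self.SYM, "B")
        assert np.allclose(series[0].shift, expected)

    def test_clean_curve_helper_matches_generated(self):
        spec = CoupledTitrationSimSpec(model=self.SYM, noise_sd=0.0, seed=3)
        series, truths = gen_coupled_titration(spec)
        base, amp = truths[0]
        assert np.allclose(series[0].shift, coupled_clean_curve(spec, base, amp))

    def test_determinism(self):
        spec = CoupledTitrationSimSpec(model=self.SYM, n_resonances=2, seed=9)
        a, _ = gen_coupled_titration(spec)
        b, _ = gen_coupled_titration(spec)
        assert np.array_equal(a[1].shift, b[1].shift)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CoupledTitrationSimSpec(model=self.SYM, weight_a=0.5, weight_b=0.8)


class TestGenDensitometry:
    def test_cv_zero_gives_exact_means(self):
        spec = DensitometrySimSpec(true_means={"WT": 20000.0, "V": 15400.0}, cv=0.0, seed=1)
        table = gen_densitometry(spec)
        assert set(table["construct"]) == {"WT", "V"}
        for construct, mean in spec.true_means.items():
            assert np.allclose(table.loc[table.construct == construct, "reading"], mean)

    def test_determinism(self):
        spec = DensitometrySimSpec(true_means={"WT": 20000.0}, n_datasets=2, seed=4)
        assert gen_densitometry(spec).equals(gen_densitometry(spec))

    def test_lognormal_moments(self):
        spec = DensitometrySimSpec(
            true_means={"WT": 20000.0}, cv=0.07, n_replicates=4000, seed=8
        )
        readings = gen_densitometry(spec)["reading"]
        assert readings.mean() == pytest.approx(20000.0, rel=0.01)
        assert readings.std() / readings.mean() == pytest.approx(0.07, rel=0.1)
        assert (readings > 0).all()

    def test_pipeline_recovery_of_true_relative_activity(self):
        """A 77% true relative activity is recovered within 3x the propagated
        uncertainty for nearly all seeds."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            spec = DensitometrySimSpec(
                true_means={"WT": 20000.0, "V": 0.77 * 20000.0},
                cv=0.1,
                n_datasets=3,
                seed=seed,
            )
            sets = {
                (s.construct_label, s.dataset_label): summarize_replicates(s)
                for s in replicate_sets_from_table(gen_densitometry(spec))
            }
            rels = [
                relative_activity(sets[("V", d)], sets[("WT", d)])
                for d in ("1", "2", "3")
            ]
            avg = average_relative_activity(rels)
            hits += abs(avg.percent - 77.0) <= 3 * avg.uncertainty
        assert hits >= int(0.95 * n_seeds)


class TestGenMotifSequences:
    def test_single_sequence_contains_planted_layout(self):
        spec = MotifSimSpec(n_sequences=1, seed=2)
        records, truth = gen_motif_sequences(spec)
        seq = records[0].residues
        m = spec.motif_position
        assert seq[m] == "C" and seq[m + 3] == "C"
        assert seq[m + 1 : m + 3] == truth[0]["xx"]
        assert seq[m - 6] == truth[0]["beta1_minus6"]
        assert seq[m + spec.partner_offset] == truth[0]["partner"]

    def test_determinism(self):
        spec = MotifSimSpec(n_sequences=5, seed=6)
        a, _ = gen_motif_sequences(spec)
        b, _ = gen_motif_sequences(spec)
        assert [r.residues for r in a] == [r.residues for r in b]

    def test_planted_frequencies_recovered_within_binomial_bounds(self):
        from trxpka.motifs import extract_extended_site, tabulate_conservation

        freqs = {"Q": 380 / 494, "R": 72 / 494, "K": 42 / 494}
        spec = MotifSimSpec(
            n_sequences=494,
            seed=10,
            slot_frequencies={
                "beta1_minus6": {"D": 1.0},
                "xx": {"VA": 1.0},
                "alpha1_acidic": {"E": 1.0},
                "partner": freqs,
            },
        )
        records, _ = gen_motif_sequences(spec)
        sites = [extract_extended_site(r, spec.motif_position) for r in records]
        table = tabulate_conservation(sites, "distal_partner")
        assert table.total == 494
        for res, p in freqs.items():
            lo, hi = stats.binom.interval(0.95, 494, p)
            assert lo <= table.counts.get(res, 0) <= hi

    def test_slot_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MotifSimSpec(slot_frequencies={"xx": {"VA": 0.6}})
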