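"""Divergence oracles and entropy-profile behaviour.

Closed-form Gaussian KL values are the independent oracle for the
discretization pipeline:
D_KL(N(m1,s1) || N(m2,s2)) = ln(s2/s1) + (s1^2 + (m1-m2)^2)/(2 s2^2) - 1/2.
"""

import numpy as np
import pytest

from ramanld import entropy_ranking as er
from ramanld import synthetic_data as sd
from ramanld.spectra_prep import RamanSpectrum, SpectrumSet

L = 100_000


def gauss_pair(mu_a, s_a, mu_b, s_b, length=L):
    lo = min(mu_a, mu_b) - 6 * max(s_a, s_b)
    hi = max(mu_a, mu_b) + 6 * max(s_a, s_b)
    return (
        er.discretize_gaussian(mu_a, s_a, (lo, hi), length),
        er.discretize_gaussian(mu_b, s_b, (lo, hi), length),
    )


class TestFitClassDistributions:
    def _set(self, blocks):
        wn = np.array([1000.0, 1001.0])
        spectra = []
        for label, rows in blocks.items():
            for row in rows:
                spectra.append(RamanSpectrum(wn, np.asarray(row, float), {"g": label}))
        return SpectrumSet.from_spectra(spectra)

    def test_identical_spectra_floored_sd(self):
        sset = self._set({"a": [[1, 2]] * 3, "b": [[0, 1], [2, 3]]})
        model = er.fit_class_distributions(sset, "g")
        i = model.classes.index("a")
        assert np.all(model.sigma[i] == model.sigma_floor)

    def test_hand_computed_moments(self):
        # two spectra {0, 2} at one wavenumber: mu = 1, sd = sqrt(2)
        sset = self._set({"a": [[0, 0], [2, 2]], "b": [[0, 0], [1, 1]]})
        model = er.fit_class_distributions(sset, "g")
        i = model.classes.index("a")
        assert model.mu[i][0] == pytest.approx(1.0)
        assert model.sigma[i][0] == pytest.approx(np.sqrt(2.0))

    def test_small_class_rejected_by_name(self):
        sset = self._set({"a": [[1, 2]] * 3, "tiny": [[0, 1]]})
        with pytest.raises(ValueError, match="tiny"):
            er.fit_class_distributions(sset, "g")


class TestDiscretizeGaussian:
    def test_symmetric_support_gives_symmetric_vector(self):
        p = er.discretize_gaussian(0.0, 1.0, (-5.0, 5.0), 10_000)
        assert np.allclose(p.p, p.p[::-1], atol=1e-12)

    def test_normalized(self):
        p = er.discretize_gaussian(2.0, 0.5, (-1.0, 5.0), 5000)
        assert p.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_first_moment_within_half_bin(self):
        p = er.discretize_gaussian(1.3, 0.7, (-4.0, 6.0), 2000)
        bin_width = 10.0 / 2000
        assert abs(np.sum(p.centers * p.p) - 1.3) < bin_width / 2

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError, match="length"):
            er.discretize_gaussian(0.0, 1.0, (-5.0, 5.0), 500)


class TestDivergences:
    def test_cross_entropy_identity_is_shannon(self):
        pa, _ = gauss_pair(0.0, 1.0, 0.0, 1.0)
        shannon = -np.sum(pa.p * np.log(pa.p))
        assert er.cross_entropy(pa, pa) == pytest.approx(shannon, abs=1e-12)

    def test_cross_entropy_decomposition(self):
        pa, pb = gauss_pair(0.0, 1.0, 1.2, 0.8)
        lhs = er.cross_entropy(pa, pb)
        rhs = er.cross_entropy(pa, pa) + er.kl_divergence(pa, pb)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_unit_mean_shift_costs_half_nat(self):
        pa, pb = gauss_pair(0.0, 1.0, 1.0, 1.0)
        assert er.cross_entropy(pa, pb) - er.cross_entropy(pa, pa) == pytest.approx(
            0.5, rel=0.01
        )

    def test_kl_of_identical_vectors_is_zero(self):
        pa, _ = gauss_pair(0.0, 1.0, 0.0, 1.0)
        assert er.kl_divergence(pa, pa) == 0.0

    @pytest.mark.parametrize(
        "args,expected",
        [
            ((0.0, 1.0, 0.0, 2.0), 0.3181),  # ln2 + 1/8 - 1/2
            ((0.0, 2.0, 0.0, 1.0), 0.8069),  # -ln2 + 2 - 1/2
        ],
    )
    def test_kl_against_closed_form(self, args, expected):
        pa, pb = gauss_pair(*args)
        assert er.kl_divergence(pa, pb) == pytest.approx(expected, rel=0.01)
        assert er.kl_divergence(pa, pb) == pytest.approx(
            er.gaussian_kl_closed_form(*args), rel=1e-4
        )

    def test_support_mismatch_rejected(self):
        pa = er.discretize_gaussian(0.0, 1.0, (-6.0, 6.0), 2000)
        pb = er.discretize_gaussian(0.0, 1.0, (-5.0, 6.0), 2000)
        with pytest.raises(ValueError, match="support"):
            er.kl_divergence(pa, pb)

    def test_symmetric_kl_is_symmetric(self):
        pa, pb = gauss_pair(0.0, 1.0, 2.0, 0.6)
        assert er.symmetric_kl(pa, pb) == er.symmetric_kl(pb, pa)

    def test_symmetric_kl_values(self):
        pa, pb = gauss_pair(0.0, 1.0, 1.0, 1.0)
        assert er.symmetric_kl(pa, pb) == pytest.approx(0.5, rel=0.01)
        pa, pb = gauss_pair(0.0, 1.0, 0.0, 2.0)
        assert er.symmetric_kl(pa, pb) == pytest.approx(
            (0.3181 + 0.8069) / 2, rel=0.01
        )

    def test_multiclass_reduces_to_symmetric_at_k2(self):
        pa, pb = gauss_pair(0.3, 1.1, -0.4, 0.9)
        assert er.multiclass_divergence([pa, pb]) == pytest.approx(
            er.symmetric_kl(pa, pb), abs=1e-15
        )

    def test_multiclass_of_identical_vectors_is_zero(self):
        pa, _ = gauss_pair(0.0, 1.0, 0.0, 1.0)
        assert er.multiclass_divergence([pa, pa, pa]) == 0.0

    def test_multiclass_k3_against_closed_form(self):
        params = [(0.0, 1.0), (1.0, 1.3), (2.5, 0.8)]
        lo = min(p[0] for p in params) - 6 * max(p[1] for p in params)
        hi = max(p[0] for p in params) + 6 * max(p[1] for p in params)
        vecs = [er.discretize_gaussian(m, s, (lo, hi), L) for m, s in params]
        hand = sum(
            er.gaussian_kl_closed_form(*params[i], *params[j])
            for i in range(3)
            for j in range(3)
            if i != j
        ) / 6.0
        assert er.multiclass_divergence(vecs) == pytest.approx(hand, rel=0.01)

    def test_multiclass_needs_two(self):
        pa, _ = gauss_pair(0.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            er.multiclass_divergence([pa])

    def test_divergence_monotone_in_mean_gap(self):
        scores = [
            er.gaussian_pair_divergence(0.0, 1.0, gap, 1.0, length=10_000)
            for gap in (0.0, 0.5, 1.0, 2.0, 3.0)
        ]
        assert np.all(np.diff(scores) > 0)


class TestEntropyProfile:
    @staticmethod
    def _cohort(seed=0, scale=1.0, permute=False, shift=2.0, n=25):
        from ramanld.experiments import _two_class_cohort

        sset = _two_class_cohort(3010.0, shift, n, 0.02, seed)
        if scale != 1.0:
            sset = SpectrumSet(
                sset.wavenumbers, sset.intensities * scale, sset.metadata
            )
        if permute:
            md = sset.metadata.copy()
            rng = np.random.default_rng(seed)
            md["methionine_x"] = rng.permutation(md["methionine_x"].to_numpy())
            sset = SpectrumSet(sset.wavenumbers, sset.intensities, md)
        return sset

    def test_profile_matches_modular_pipeline(self):
        # the chunked profile must agree with discretize_gaussian + symmetric_kl
        sset = self._cohort()
        prof = er.entropy_profile(sset, "methionine_x", length=10_000)
        model = er.fit_class_distributions(sset, "methionine_x")
        for i in (0, 150, int(np.argmax(prof.scores))):
            ref = er.gaussian_pair_divergence(
                model.mu[0, i],
                model.sigma[0, i],
                model.mu[1, i],
                model.sigma[1, i],
                length=10_000,
            )
            assert prof.scores[i] == pytest.approx(ref, rel=1e-4)

    def test_null_profile_is_uniformly_small(self):
        # identical class distributions: plug-in symmetric KL keeps an
        # O(2/n) small-sample bias, far below any genuine band shift
        n = 50
        sset = self._cohort(seed=3, shift=0.0, n=n)
        prof = er.entropy_profile(sset, "methionine_x", length=10_000)
        assert prof.scores.max() < 0.7
        assert 0.5 * (2 / n) < prof.scores.mean() < 3 * (2 / n)

    def test_scores_nonnegative_and_full_length(self):
        sset = self._cohort()
        prof = er.entropy_profile(sset, "methionine_x", length=5000)
        assert prof.scores.shape == sset.wavenumbers.shape
        assert np.all(prof.scores >= 0)

    def test_relabel_invariance(self):
        sset = self._cohort()
        prof = er.entropy_profile(sset, "methionine_x", length=5000)
        md = sset.metadata.copy()
        md["methionine_x"] = md["methionine_x"].map({1.0: "z_ctrl", 20.0: "a_excess"})
        swapped = SpectrumSet(sset.wavenumbers, sset.intensities, md)
        prof2 = er.entropy_profile(swapped, "methionine_x", length=5000)
        assert np.allclose(prof.scores, prof2.scores, rtol=1e-6)

    def test_scale_invariance_with_data_driven_support(self):
        prof = er.entropy_profile(self._cohort(), "methionine_x", length=5000)
        prof_scaled = er.entropy_profile(
            self._cohort(scale=7.5), "methionine_x", length=5000
        )
        assert np.allclose(prof.scores, prof_scaled.scores, rtol=1e-4, atol=1e-6)

    def test_shifted_band_ranks_top_for_true_factor_only(self):
        sset = self._cohort(seed=5, shift=3.0)
        prof = er.entropy_profile(sset, "methionine_x", length=5000)
        top = prof.top_bands(5)["wavenumber"].to_numpy()
        assert np.any(np.abs(top - 3010.0) <= 30.0)
        null = er.entropy_profile(
            self._cohort(seed=5, shift=3.0, permute=True), "methionine_x", length=5000
        )
        assert null.scores.max() < prof.scores.max() / 3

    def test_three_class_profile_uses_average_divergence(self):
        design = sd.CohortDesign(
            cell_lines=("X",),
            methionine_levels=(1.0,),
            insulin_levels=(0.1, 1.0, 2.0),
            multipliers={
                ("X", 1.0, 0.1): {2850.0: 0.9},
                ("X", 1.0, 2.0): {2850.0: 1.1},
            },
            cells_per_group=3,
            spectra_per_cell=5,
            grid=np.arange(2700.0, 3101.0),
            noise_sd=0.02,
            seed=2,
        )
        sset, _ = sd.generate_spectrum_cohort(design)
        prof = er.entropy_profile(sset, "insulin_x", length=5000)
        assert prof.n_classes == 3
        top = prof.top_bands(5)["wavenumber"].to_numpy()
        assert np.any(np.abs(top - 2850.0) <= 35.0)
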