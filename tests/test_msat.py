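"""Microsatellite filtering, discovery-curve fit, and the mixed model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cetadiv as cd
from cetadiv.errors import (DomainError, IdentifiabilityError,
                            ValidationError)
from cetadiv.simulate import MsatSpec, simulate_msat_dataset


def _rec(locus, species, n, alleles, asc=False, scope="regional"):
    return cd.MicrosatRecord(locus_id=locus, species_id=species,
                             study_id=f"{locus}_{species}", sample_size=n,
                             n_alleles=alleles, ascertained=asc, scope=scope)


class TestFilter:
    def test_locus_in_four_species_removed(self):
        records = [_rec("L1", f"sp{i}", 20, 5) for i in range(4)]
        # loci L2..L6 give sp0..sp4 enough coverage to survive otherwise
        for l in range(2, 7):
            records += [_rec(f"L{l}", f"sp{i}", 20, 5) for i in range(5)]
        kept = cd.filter_msat_records(records)
        assert "L1" not in {r.locus_id for r in kept}
        assert {r.locus_id for r in kept} == {f"L{l}" for l in range(2, 7)}

    def test_sample_size_threshold_is_strict(self):
        base = [_rec(f"L{l}", f"sp{i}", 20, 5)
                for l in range(1, 6) for i in range(5)]
        edge5 = _rec("L1", "sp0", 5, 5)
        edge6 = _rec("L2", "sp0", 6, 5)
        kept = cd.filter_msat_records(base + [edge5, edge6])
        assert edge5 not in kept
        assert edge6 in kept

    def test_single_allele_records_removed(self):
        base = [_rec(f"L{l}", f"sp{i}", 20, 5)
                for l in range(1, 6) for i in range(5)]
        mono = _rec("L1", "sp1", 50, 1)
        assert mono not in cd.filter_msat_records(base + [mono])

    def test_empty_input_gives_empty_output(self):
        assert cd.filter_msat_records([]) == []

    def test_species_needs_four_loci(self):
        records = [_rec(f"L{l}", f"sp{i}", 20, 5)
                   for l in range(1, 6) for i in range(5)]
        records.append(_rec("L1", "sp9", 20, 5))  # sp9 has one locus only
        kept = cd.filter_msat_records(records)
        assert "sp9" not in {r.species_id for r in kept}

    def test_mixed_scopes_rejected(self):
        with pytest.raises(ValidationError, match="scope"):
            cd.filter_msat_records([_rec("L1", "sp1", 20, 5),
                                    _rec("L1", "sp2", 20, 5,
                                         scope="rangewide")])


class TestCorrection:
    def test_hand_values(self):
        assert cd.correct_allele_count(10, 20, 0.25) == pytest.approx(12.0)
        assert cd.correct_allele_count(5, 1, 1.0) == pytest.approx(10.0)

    def test_large_samples_need_no_correction(self):
        assert cd.correct_allele_count(7, 10**9, 0.2) == pytest.approx(
            7.0, rel=1e-8)

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(DomainError):
            cd.correct_allele_count(10, 20, 0.0)

    @given(n1=st.integers(6, 500), n2=st.integers(6, 500),
           alleles=st.integers(2, 40),
           mu=st.floats(0.01, 2.0, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_sample_size_linear_in_alleles(self, n1, n2,
                                                       alleles, mu):
        lo, hi = sorted((n1, n2))
        assert cd.correct_allele_count(alleles, hi, mu) <= \
            cd.correct_allele_count(alleles, lo, mu) + 1e-12
        assert cd.correct_allele_count(2 * alleles, n1, mu) == pytest.approx(
            2 * cd.correct_allele_count(alleles, n1, mu))
        assert cd.correct_allele_count(alleles, n1, mu) >= alleles


class TestFitMu:
    def test_noise_free_recovery(self):
        species = [f"sp{i}" for i in range(12)]
        spec = MsatSpec(n_loci=8, mu_true=0.2, noise_sd=0.0,
                        ascertainment_delta=0.0, round_counts=False)
        records = simulate_msat_dataset(species, spec,
                                        {s: 0.0 for s in species}, seed=1)
        assert cd.fit_mu(records).mu == pytest.approx(0.2, abs=1e-6)

    def test_noisy_recovery_within_bootstrap_interval(self):
        """Lognormal noise sd 0.1, 30 loci x 40 species: bootstrap CI covers 0.2."""
        species = [f"sp{i}" for i in range(40)]
        spec = MsatSpec(n_loci=30, mu_true=0.2, noise_sd=0.1,
                        ascertainment_delta=0.0)
        records = simulate_msat_dataset(species, spec,
                                        {s: 0.0 for s in species}, seed=1)
        mu_hat = cd.fit_mu(records).mu
        rng = np.random.default_rng(1)
        boots = []
        for _ in range(60):
            idx = rng.integers(len(records), size=len(records))
            boots.append(cd.fit_mu([records[i] for i in idx]).mu)
        lo, hi = np.quantile(boots, [0.025, 0.975])
        half = max(mu_hat - lo, hi - mu_hat)
        assert abs(mu_hat - 0.2) <= half

    def test_single_sample_size_unidentifiable(self):
        records = [_rec(f"L{l}", f"sp{i}", 20, 5)
                   for l in range(1, 6) for i in range(5)]
        with pytest.raises(IdentifiabilityError):
            cd.fit_mu(records)

    def test_mechanistic_discovery_curve_fit(self):
        """Saturating fit tracks gene-copy-sampling discovery within 10%.

        The empirical mean discovery curve from broken-stick gene-copy
        sampling is compared with the fitted asymptotic curve over the
        sample sizes used in compilations (6..200).
        """
        rng = np.random.default_rng(4)
        from cetadiv.simulate import _broken_stick
        sizes = [6, 12, 25, 50, 100, 200]
        records = []
        curves = {}
        for l in range(12):
            k = 12
            freqs = _broken_stick(k, rng)
            means = []
            for n in sizes:
                counts = [int(np.count_nonzero(rng.multinomial(2 * n, freqs)))
                          for _ in range(40)]
                means.append(np.mean(counts))
                for c in counts[:5]:
                    records.append(_rec(f"L{l}", f"sp{n}_{len(records)}",
                                        n, max(c, 1)))
            curves[f"L{l}"] = means
        model = cd.fit_mu(records)
        rel_errs = []
        for locus, means in curves.items():
            A = model.locus_asymptotes[locus]
            for n, m in zip(sizes, means):
                fit = A * n * model.mu / (1 + n * model.mu)
                rel_errs.append(abs(fit - m) / m)
        assert np.mean(rel_errs) <= 0.10


class TestSpeciesEffects:
    def _noise_free_records(self, effects):
        species = sorted(effects)
        spec = MsatSpec(n_loci=6, mu_true=0.25, noise_sd=0.0,
                        asymptote_log_sd=0.0, ascertainment_delta=0.0,
                        round_counts=False)
        return simulate_msat_dataset(species, spec, effects, seed=2)

    def test_noise_free_identity_up_to_centering(self):
        # correcting with the generating mu makes the model exact, so the
        # fixed effects must reproduce the planted values up to centering
        effects = {f"sp{i}": v for i, v in enumerate(
            [0.4, -0.2, 0.0, 0.3, -0.5, 0.1])}
        records = self._noise_free_records(effects)
        correction = cd.CorrectionModel(
            mu=0.25, scope="regional", locus_asymptotes={}, converged=True,
            rss=0.0, n_records=len(records))
        fit = cd.fit_species_effects(records, correction)
        centred = {k: v - np.mean(list(effects.values()))
                   for k, v in effects.items()}
        for sp, v in centred.items():
            assert fit.species_effects[sp] == pytest.approx(v, abs=1e-8)
        assert fit.residual_variance == 0.0

    def test_reported_effects_sum_to_zero(self, study_bundle):
        records = cd.filter_msat_records(study_bundle["msat_regional"])
        fit = cd.fit_species_effects(records, cd.fit_mu(records))
        assert sum(fit.species_effects.values()) == pytest.approx(0, abs=1e-9)

    def test_single_species_unidentifiable(self):
        records = [_rec(f"L{l}", "solo", 20 + l, 5) for l in range(6)]
        with pytest.raises(IdentifiabilityError):
            cd.fit_species_effects(records, cd.fit_mu(records))

    def test_locus_relabeling_invariance(self):
        effects = {f"sp{i}": v for i, v in enumerate(
            [0.4, -0.2, 0.0, 0.3, -0.5, 0.1])}
        spec = MsatSpec(n_loci=8, mu_true=0.2, noise_sd=0.1)
        records = simulate_msat_dataset(sorted(effects), spec, effects, seed=3)
        correction = cd.fit_mu(records)
        fit1 = cd.fit_species_effects(records, correction)
        relabeled = [cd.MicrosatRecord(
            locus_id="X" + r.locus_id, species_id=r.species_id,
            study_id=r.study_id, sample_size=r.sample_size,
            n_alleles=r.n_alleles, ascertained=r.ascertained, scope=r.scope)
            for r in records]
        correction2 = cd.CorrectionModel(
            mu=correction.mu, scope=correction.scope,
            locus_asymptotes={"X" + k: v for k, v
                              in correction.locus_asymptotes.items()},
            converged=True, rss=correction.rss,
            n_records=correction.n_records)
        fit2 = cd.fit_species_effects(relabeled, correction2)
        for sp in effects:
            assert fit1.species_effects[sp] == pytest.approx(
                fit2.species_effects[sp], abs=1e-8)

    def test_duplicating_every_record_keeps_point_estimates(self):
        effects = {f"sp{i}": v for i, v in enumerate(
            [0.4, -0.2, 0.0, 0.3, -0.5, 0.1])}
        spec = MsatSpec(n_loci=8, mu_true=0.2, noise_sd=0.1)
        records = simulate_msat_dataset(sorted(effects), spec, effects, seed=4)
        correction = cd.fit_mu(records)
        fit1 = cd.fit_species_effects(records, correction)
        fit2 = cd.fit_species_effects(records + records, correction)
        for sp in effects:
            assert fit1.species_effects[sp] == pytest.approx(
                fit2.species_effects[sp], abs=1e-5)


class TestEndToEnd:
    def test_one_estimate_per_retained_species(self):
        cfg = cd.SimulationConfig(seed=3, n_species=30)
        bundle = cd.simulate_study(cfg)
        estimates = cd.estimate_relative_diversity(bundle["msat_regional"])
        kept = cd.filter_msat_records(bundle["msat_regional"])
        species = sorted({r.species_id for r in kept})
        assert sorted(e.species_id for e in estimates) == species
        assert {e.marker for e in estimates} == {"micR"}

    def test_below_average_species_gets_negative_estimate(self, study_bundle):
        estimates, _, mixed = cd.estimate_relative_diversity(
            study_bundle["msat_regional"], return_fits=True)
        truth = study_bundle["truth"]["species_effects"]
        lowest = min(truth, key=truth.get)
        by_sp = {e.species_id: e.value for e in estimates}
        assert by_sp[lowest] < 0
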