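"""The synthetic survey generator: Mendelian rules, detection model,
PCR error model, determinism."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from scatcap.dtypes import ConfigError
from scatcap.secr import segment_transects
from scatcap.simulate import (
    PedigreeSpec,
    SimulationConfig,
    draw_activity_centers,
    default_geometry,
    generate_population,
    simulate_dataset,
    simulate_dyad,
    simulate_pcr_replicates,
    simulate_selfed,
    simulate_survey,
)


class TestPopulation:
    def test_offspring_alleles_come_from_parents(self):
        cfg = SimulationConfig(
            pedigree=PedigreeSpec(n_founders=6, n_generations=2, offspring_per_generation=8),
            seed=3,
        )
        pop = generate_population(cfg)
        by_id = {r.individual_id: r for r in pop.records}
        for rec in pop.records:
            p1, p2 = rec.parents
            if p1 is None:
                continue
            for locus, (a, b) in rec.genotype.items():
                # the stored pair is sorted, so either split must work
                g1 = by_id[p1].genotype[locus]
                g2 = by_id[p2].genotype[locus]
                assert (a in g1 and b in g2) or (a in g2 and b in g1)

    def test_selfed_offspring_pedigree_f(self):
        cfg = SimulationConfig(
            pedigree=PedigreeSpec(
                n_founders=1, n_generations=1, offspring_per_generation=10, selfing_rate=1.0
            ),
            seed=1,
        )
        pop = generate_population(cfg)
        offspring = pop.records[1:]
        assert all(r.f_pedigree == pytest.approx(0.5) for r in offspring)

    def test_ml_f_on_many_selfed_loci_recovers_half(self):
        # one selfed individual typed at thousands of biallelic loci:
        # the ML inbreeding estimate converges to the pedigree F of 1/2
        from scatcap.relatedness import estimate_F_ml

        freqs = {f"L{i}": {1: 0.5, 2: 0.5} for i in range(3000)}
        rng = np.random.default_rng(11)
        g = simulate_selfed(freqs, 1, rng)[0]
        est = estimate_F_ml(g, freqs, n_boot=0)
        assert est.f == pytest.approx(0.5, abs=0.05)

    def test_full_sib_and_po_categories(self):
        cfg = SimulationConfig(
            pedigree=PedigreeSpec(n_founders=2, n_generations=1, offspring_per_generation=3),
            seed=2,
        )
        pop = generate_population(cfg)
        f1, f2 = pop.records[0].individual_id, pop.records[1].individual_id
        kids = [r.individual_id for r in pop.records[2:]]
        assert pop.relationship(kids[0], kids[1]) == "FS"
        assert pop.relationship(f1, kids[0]) == "PO"
        assert pop.relationship(f1, f2) == "U"

    def test_same_seed_identical_population(self):
        cfg = SimulationConfig(seed=9)
        a = generate_population(cfg)
        b = generate_population(cfg)
        assert [r.genotype for r in a.records] == [r.genotype for r in b.records]

    def test_degenerate_frequency_vector_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_loci=1, founder_allele_freqs={"L01": {}})


class TestSurveyDetection:
    def _setup(self):
        detectors = segment_transects([LineString([(0, 0), (1000, 0)])], 200.0)
        return detectors

    def test_zero_g0_no_detections(self):
        det = self._setup()
        centers = np.array([[100.0, 0.0]])
        rng = np.random.default_rng(0)
        d, truth = simulate_survey(centers, ["I1"], det, 0.0, 500.0, 5, rng)
        assert len(d) == 0 and truth == {}

    def test_detection_frequency_at_distance_zero(self):
        # one animal sitting on a detector, 10,000 occasions
        det = segment_transects([LineString([(0, 0), (200, 0)])], 200.0)
        centers = det.coords[:1].copy()
        rng = np.random.default_rng(1)
        g0 = 0.37
        d, _ = simulate_survey(centers, ["I1"], det, g0, 1e-6, 10_000, rng)
        phat = len(d) / 10_000
        se = np.sqrt(g0 * (1 - g0) / 10_000)
        assert abs(phat - g0) < 3 * se

    def test_tiny_sigma_only_nearest_detector(self):
        det = self._setup()
        centers = np.array([[310.0, 0.0]])  # nearest detector at x=300
        rng = np.random.default_rng(2)
        d, _ = simulate_survey(centers, ["I1"], det, 0.9, 20.0, 50, rng)
        assert len(d) > 0
        assert set(d["x"]) == {300.0}

    def test_negative_sigma_rejected(self):
        det = self._setup()
        with pytest.raises(ConfigError):
            simulate_survey(
                np.zeros((1, 2)), ["I1"], det, 0.5, -1.0, 1, np.random.default_rng(0)
            )

    def test_centers_fall_inside_habitat(self):
        geom = default_geometry()
        pts = draw_activity_centers(50, geom.habitat, np.random.default_rng(3))
        assert all(geom.habitat.contains(Point(*p)) for p in pts)


class TestPCRModel:
    def _truth(self, cfg, het=True):
        loci = cfg.loci
        freqs = cfg.freqs()
        g = {}
        for l in loci:
            alleles = sorted(freqs[l])
            g[l] = (alleles[0], alleles[1]) if het else (alleles[0], alleles[0])
        return {"scat1": g}

    def test_error_free_replicates_equal_truth(self):
        cfg = SimulationConfig(
            dropout_rate=0.0, false_allele_rate=0.0, pcr_failure_rate=0.0,
            degraded_fraction=0.0,
        )
        truth = self._truth(cfg)
        reps = simulate_pcr_replicates(truth, cfg, np.random.default_rng(0))
        for r in reps.records:
            assert r.call == truth["scat1"][r.locus_id]

    def test_total_dropout_shows_single_alleles(self):
        cfg = SimulationConfig(
            dropout_rate=1.0, false_allele_rate=0.0, pcr_failure_rate=0.0,
            degraded_fraction=0.0,
        )
        reps = simulate_pcr_replicates(self._truth(cfg), cfg, np.random.default_rng(0))
        successes = [r for r in reps.records if r.call is not None]
        # both alleles dropping fails the reaction, so nothing survives
        assert successes == []

    def test_empirical_dropout_rate(self):
        # heterozygote observed as a single allele when exactly one of its
        # two alleles drops: expected rate 2 d (1-d)
        d_rate = 0.2
        cfg = SimulationConfig(
            n_loci=1, alleles_per_locus=2, n_replicates=10_000,
            dropout_rate=d_rate, false_allele_rate=0.0, pcr_failure_rate=0.0,
            degraded_fraction=0.0,
        )
        reps = simulate_pcr_replicates(self._truth(cfg), cfg, np.random.default_rng(5))
        n = len(reps.records)
        single = sum(
            1 for r in reps.records if r.call is not None and r.call[0] == r.call[1]
        )
        expected = 2 * d_rate * (1 - d_rate)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(single / n - expected) < 3 * se

    def test_false_alleles_keep_records_diploid(self):
        cfg = SimulationConfig(
            dropout_rate=0.0, false_allele_rate=1.0, pcr_failure_rate=0.0,
            degraded_fraction=0.0,
        )
        reps = simulate_pcr_replicates(self._truth(cfg), cfg, np.random.default_rng(0))
        for r in reps.records:
            assert r.call is not None and len(r.call) == 2


class TestDataset:
    def test_same_seed_byte_identical(self):
        a = simulate_dataset(seed=4)
        b = simulate_dataset(seed=4)
        assert a.replicates == b.replicates
        assert a.geometry.detections.equals(b.geometry.detections)
        assert a.species.equals(b.species)
        assert a.scat_to_individual == b.scat_to_individual

    def test_every_scat_maps_to_one_individual(self):
        data = simulate_dataset(seed=6)
        ids = {r.individual_id for r in data.population.records}
        assert all(v in ids for v in data.scat_to_individual.values())

    def test_scale_mirrors_survey_conditions(self):
        # ~45 bobcat scats among ~117 collected, 9 individuals
        data = simulate_dataset(seed=1)
        n_bob = len(data.scat_to_individual)
        assert 25 <= n_bob <= 70
        assert len(data.geometry.detections) == n_bob + 46 + 26
        assert len(data.population.records) == 9


class TestDyadSimulator:
    @pytest.mark.parametrize("cat,expected_r", [("U", 0.0), ("HS", 0.25), ("FS", 0.5), ("PO", 0.5)])
    def test_realized_allele_sharing_tracks_kinship(self, cat, expected_r, fixture_freqs):
        # mean molecular similarity ~ s + r/2 (1 - s) ... loose moment check
        from scatcap.popgen import molecular_similarity

        rng = np.random.default_rng(8)
        loci = list(fixture_freqs)
        s_exp = np.mean(
            [sum(p**2 for p in fixture_freqs[l].values()) for l in loci]
        )
        sims = []
        for _ in range(400):
            g1, g2 = simulate_dyad(cat, fixture_freqs, rng)
            sims.append(np.mean([molecular_similarity(g1[l], g2[l]) for l in loci]))
        observed_kinship = (np.mean(sims) - s_exp) / (1 - s_exp)
        assert observed_kinship == pytest.approx(expected_r / 2, abs=0.03)
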