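"""Unit and property tests for the synthetic study generator."""

import numpy as np
import pytest

from hapshift import synthdata
from hapshift._seq import hamming, hamming_matrix


class TestHaplotypePool:
    def test_degenerate_pool_is_root_only(self):
        pool = synthdata.generate_haplotype_pool("Sp x", 313, n_haplotypes=1, seed=3)
        assert len(pool.haplotypes) == 1
        assert pool.haplotypes[0].sequence == pool.root_sequence
        assert pool.haplotypes[0].mutation_steps == 0

    def test_pool_distinct_and_within_step_budget(self):
        pool = synthdata.generate_haplotype_pool(
            "Sp x", 313, n_haplotypes=8, max_steps=2, seed=7
        )
        seqs = pool.sequences
        assert len(set(seqs)) == 8
        assert all(len(s) == 313 for s in seqs)
        # every haplotype derives from the root via <= 2 steps per branch of a
        # tree with at most 7 edges, so Hamming(root, h) <= 2 * 7
        dists = [hamming(pool.root_sequence, s) for s in seqs]
        assert max(dists) <= 2 * (8 - 1)
        # pairwise distances are symmetric-bounded the same way
        D = hamming_matrix(seqs)
        assert D.max() <= 2 * 2 * (8 - 1)

    def test_mutation_steps_match_parent_distance_invariant(self):
        pool = synthdata.generate_haplotype_pool("Sp x", 80, 12, 3, seed=11)
        for h in pool.haplotypes[1:]:
            assert 1 <= h.mutation_steps <= 3

    def test_determinism(self):
        a = synthdata.generate_haplotype_pool("Sp x", 120, 6, 2, seed=5)
        b = synthdata.generate_haplotype_pool("Sp x", 120, 6, 2, seed=5)
        assert a.sequences == b.sequences

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            synthdata.generate_haplotype_pool("Sp x", 10, 1)
        with pytest.raises(ValueError):
            synthdata.generate_haplotype_pool("Sp x", 313, 0)


class TestMetapopulation:
    def setup_method(self):
        self.pool = synthdata.generate_haplotype_pool("Sp x", 60, 4, 2, seed=1)
        self.sites = [("S1", 0.0), ("S2", 100.0)]

    def test_all_absent_gives_zero_vectors(self):
        freqs = synthdata.generate_metapopulation(
            self.pool, self.sites, occupancy_map={"S1": "absent", "S2": "absent"}
        )
        assert all((sf.frequencies["Sp x"] == 0).all() for sf in freqs)

    def test_frequencies_sum_to_one_when_occupied(self):
        freqs = synthdata.generate_metapopulation(
            self.pool, self.sites, occupancy_map={"S1": "common", "S2": "scarce"}
        )
        for sf in freqs:
            np.testing.assert_allclose(sf.frequencies["Sp x"].sum(), 1.0)

    def test_years_identical_without_drift(self):
        freqs = synthdata.generate_metapopulation(self.pool, self.sites, seed=9)
        by_site = {}
        for sf in freqs:
            by_site.setdefault(sf.site_id, []).append(sf.frequencies["Sp x"])
        for vecs in by_site.values():
            np.testing.assert_array_equal(vecs[0], vecs[1])

    def test_large_concentration_approaches_uniform(self):
        # mean absolute deviation from 1/k shrinks as concentration grows
        k = len(self.pool.haplotypes)
        devs = {c: [] for c in (1.0, 1000.0)}
        for c in devs:
            for seed in range(100):
                freqs = synthdata.generate_metapopulation(
                    self.pool, self.sites, concentration=c, seed=seed
                )
                devs[c].append(np.abs(freqs[0].frequencies["Sp x"] - 1 / k).mean())
        assert np.mean(devs[1000.0]) < 0.02 < np.mean(devs[1.0])

    def test_empty_site_list_rejected(self):
        with pytest.raises(ValueError):
            synthdata.generate_metapopulation(self.pool, [])


class TestTissueSampling:
    def setup_method(self):
        self.pool = synthdata.generate_haplotype_pool("Sp x", 60, 2, 1, seed=2)

    def _freqs(self, vec, category="common"):
        return synthdata.SiteFrequencies(
            "S1", 0.0, 2017, {"Sp x": np.asarray(vec, float)}, {"Sp x": category}
        )

    def test_point_mass_gives_identical_individuals(self):
        recs = synthdata.sample_tissue(self._freqs([1.0, 0.0]), self.pool, 20, seed=1)
        assert len({s for _, s in recs}) == 1

    def test_record_count_and_id_encoding(self):
        recs = synthdata.sample_tissue(self._freqs([0.5, 0.5]), self.pool, 10, seed=1)
        assert len(recs) == 10
        assert all(n.startswith("S1|Sp_x|2017|") for n, _ in recs)

    def test_multinomial_proportions_converge(self):
        recs = synthdata.sample_tissue(self._freqs([0.5, 0.5]), self.pool, 10_000, seed=4)
        p = np.mean([s == self.pool.haplotypes[0].sequence for _, s in recs])
        assert abs(p - 0.5) < 0.02  # 4 sigma of a fair binomial at n=10^4

    def test_unoccupied_site_rejected(self):
        with pytest.raises(ValueError):
            synthdata.sample_tissue(
                self._freqs([0.0, 0.0], category="absent"), self.pool, 5
            )


class TestEdnaReads:
    def setup_method(self):
        self.pool = synthdata.generate_haplotype_pool("Sp x", 313, 3, 2, seed=3)
        f = np.array([0.5, 0.3, 0.2])
        self.sf = synthdata.SiteFrequencies(
            "S1", 0.0, 2017, {"Sp x": f}, {"Sp x": "common"}
        )

    def test_error_free_reads_match_templates_and_negatives_empty(self):
        reads, samples, origins = synthdata.simulate_edna_reads(
            {"Sp x": self.pool}, [self.sf], depth=500, error_rate=0.0,
            contamination_rate=0.0, seed=5,
        )
        true = set(self.pool.sequences)
        for sid, recs in reads.items():
            if samples.loc[sid, "is_negative_control"]:
                assert recs == []
            else:
                assert all(seq in true for _, seq, _ in recs)

    def test_depth_conservation_per_replicate(self):
        reads, samples, _ = synthdata.simulate_edna_reads(
            {"Sp x": self.pool}, [self.sf], depth=777, n_replicates=3, seed=6
        )
        for sid in samples.index[~samples["is_negative_control"]]:
            assert len(reads[sid]) == 777

    def test_error_fraction_matches_binomial_closed_form(self):
        reads, _, origins = synthdata.simulate_edna_reads(
            {"Sp x": self.pool}, [self.sf], depth=10_000, n_replicates=1,
            error_rate=0.001, n_negatives=0, seed=7,
        )
        true = set(self.pool.sequences)
        frac = np.mean([seq not in true for _, seq, _ in reads["S1_COI_R1"]])
        expected = 1 - (1 - 0.001) ** 313  # ~0.269
        # reads mutated onto another true haplotype are rare; 0.02 absorbs them
        assert abs(frac - expected) < 0.02

    def test_length_jitter_produces_out_of_window_reads(self):
        reads, _, _ = synthdata.simulate_edna_reads(
            {"Sp x": self.pool}, [self.sf], depth=2000, n_replicates=1,
            error_rate=0.0, length_jitter=15, n_negatives=0, seed=8,
        )
        lengths = {len(seq) for _, seq, _ in reads["S1_COI_R1"]}
        assert any(l < 303 or l > 323 for l in lengths)

    def test_frequency_recovery_at_depth(self):
        reads, _, _ = synthdata.simulate_edna_reads(
            {"Sp x": self.pool}, [self.sf], depth=10_000, n_replicates=1,
            error_rate=0.0, n_negatives=0, seed=9,
        )
        counts = {s: 0 for s in self.pool.sequences}
        for _, seq, _ in reads["S1_COI_R1"]:
            counts[seq] += 1
        f = self.sf.frequencies["Sp x"]
        for s, target in zip(self.pool.sequences, f):
            assert abs(counts[s] / 10_000 - target) < 0.03

    def test_contamination_populates_negatives(self):
        reads, samples, _ = synthdata.simulate_edna_reads(
            {"Sp x": self.pool}, [self.sf], depth=5000, contamination_rate=0.01,
            n_negatives=2, seed=10,
        )
        negs = samples.index[samples["is_negative_control"]]
        assert sum(len(reads[s]) for s in negs) > 0

    def test_byte_identical_for_same_seed(self):
        kwargs = dict(depth=300, n_replicates=2, error_rate=0.002, seed=11)
        a, _, _ = synthdata.simulate_edna_reads({"Sp x": self.pool}, [self.sf], **kwargs)
        b, _, _ = synthdata.simulate_edna_reads({"Sp x": self.pool}, [self.sf], **kwargs)
        assert a == b


class TestReferenceDb:
    def setup_method(self):
        self.pool = synthdata.generate_haplotype_pool("Genus species", 120, 4, 2, seed=4)

    def test_no_congeners_when_disabled(self):
        refs, tax = synthdata.generate_reference_db([self.pool], include_congeners=False)
        assert set(tax["species"]) == {"Genus species"}
        assert len(refs) >= 2

    def test_congener_at_exact_divergence(self):
        refs, tax = synthdata.generate_reference_db(
            [self.pool], congener_divergence=1, include_congeners=True, seed=1
        )
        decoy_id = tax.loc[tax["species"] != "Genus species", "reference_id"].iloc[0]
        decoy_seq = dict(refs)[decoy_id]
        assert hamming(self.pool.root_sequence, decoy_seq) == 1

    def test_divergence_zero_congener_identical(self):
        refs, tax = synthdata.generate_reference_db(
            [self.pool], congener_divergence=0, include_congeners=True
        )
        decoy_id = tax.loc[tax["species"] != "Genus species", "reference_id"].iloc[0]
        assert dict(refs)[decoy_id] == self.pool.root_sequence


class TestSurveyScenario:
    def setup_method(self):
        self.sites = [(f"S{i}", float(i * 100)) for i in range(6)]
        self.baseline = {"Sp x": {"S1": "common", "S2": "dominant", "S3": "scarce"}}

    def test_stable_trajectory_identical_years(self):
        df = synthdata.generate_survey_scenario(
            self.sites, (2009, 2017), {"Sp x": ("stable",)}, self.baseline
        )
        y1 = df[df["year"] == 2009].set_index("site_id")["category"]
        y2 = df[df["year"] == 2017].set_index("site_id")["category"]
        assert (y1 == y2).all()

    def test_expand_east_moves_east_bound(self):
        df = synthdata.generate_survey_scenario(
            self.sites, (2009, 2017), {"Sp x": ("expand_east", 2)}, self.baseline
        )
        occ = df[df["category"] != "absent"]
        east = occ.groupby("year")["position_km"].max()
        assert east[2017] > east[2009]

    def test_unknown_trajectory_rejected(self):
        with pytest.raises(ValueError):
            synthdata.generate_survey_scenario(
                self.sites, (2009, 2017), {"Sp x": ("teleport", 1)}, self.baseline
            )


def test_truth_round_trips_through_json(tmp_path):
    pool = synthdata.generate_haplotype_pool("Sp x", 60, 3, 1, seed=1)
    freqs = synthdata.generate_metapopulation(pool, [("S1", 0.0), ("S2", 5.0)], seed=2)
    truth = synthdata.SyntheticTruth(
        pools={"Sp x": pool}, site_frequencies=freqs,
        contamination_rate=0.001, error_rate=0.001, seed=2,
    )
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = synthdata.SyntheticTruth.from_json(path)
    assert back.pools["Sp x"].sequences == pool.sequences
    np.testing.assert_array_equal(
        back.site_frequencies[0].frequencies["Sp x"],
        freqs[0].frequencies["Sp x"],
    )
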