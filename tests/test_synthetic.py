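"""Generator structure: precision draws, cohorts, reads, family counts."""

import numpy as np
import pandas as pd
import pytest

from gutsig import da, em, synthetic
from gutsig.composition import clr_transform


class TestPrecisionMatrix:
    def test_zero_sparsity_gives_diagonal_matrix(self):
        omega, sup, _ = synthetic.sample_precision_matrix(5, 0.0, seed=0)
        assert sup.sum() == 0
        assert np.allclose(omega, np.diag(np.diag(omega)))
        # inverse of a diagonal matrix is diagonal: zero-edge network
        inv = np.linalg.inv(omega)
        assert np.allclose(inv, np.diag(np.diag(inv)))

    def test_forced_chain_support_yields_conditional_independence(self):
        omega, sup, _ = synthetic.sample_precision_matrix(
            3, 0.5, seed=1, support={(0, 1), (1, 2)}
        )
        assert omega[0, 2] == 0.0 and omega[0, 1] != 0 and omega[1, 2] != 0
        # marginally the end nodes correlate through the middle one
        sigma = np.linalg.inv(omega)
        expected_02 = omega[0, 1] * omega[1, 2] / np.linalg.det(omega)
        assert sigma[0, 2] == pytest.approx(expected_02, rel=1e-9)

    def test_positive_definite_with_target_sparsity(self):
        omega, sup, _ = synthetic.sample_precision_matrix(30, 0.1, seed=1)
        assert np.linalg.eigvalsh(omega).min() > 0
        frac = sup[np.triu_indices(30, 1)].mean()
        assert 0.05 <= frac <= 0.15


class TestGenerateCohort:
    def _spec(self, da_spec=(), seed=0, **kw):
        return synthetic.CohortSpec(
            groups=[
                synthetic.GroupSpec("case", 20, (0.5, 0.5, 0, 0, 0)),
                synthetic.GroupSpec("ctrl", 20, (0.5, 0.5, 0, 0, 0)),
            ],
            D=20,
            sparsity=0.1,
            da_spec=list(da_spec),
            seed=seed,
            **kw,
        )

    def test_rows_closed_to_one(self):
        m, _, _ = synthetic.generate_cohort(self._spec())
        np.testing.assert_allclose(m.abundance.sum(axis=1), 1.0, atol=1e-9)

    def test_planted_effect_visible_in_group_means(self):
        folds = []
        for seed in range(5):
            m, _, _ = synthetic.generate_cohort(
                self._spec(da_spec=[("sp000", "case", 2.0)], seed=seed)
            )
            means = m.abundance["sp000"].groupby(m.groups).mean()
            folds.append(means["case"] / means["ctrl"])
        assert np.median(folds) >= 2.0

    def test_same_seed_identical_output(self):
        a, _, _ = synthetic.generate_cohort(self._spec(seed=5))
        b, _, _ = synthetic.generate_cohort(self._spec(seed=5))
        assert a.abundance.to_csv() == b.abundance.to_csv()
        assert a.metadata.to_csv() == b.metadata.to_csv()

    def test_unknown_species_in_da_spec_rejected(self):
        with pytest.raises(ValueError):
            self._spec(da_spec=[("sp999", "case", 2.0)])

    def test_replicates_within_cap(self):
        m, _, _ = synthetic.generate_cohort(self._spec())
        assert m.metadata["subject_id"].value_counts().max() <= 5

    def test_latent_covariance_matches_inverse_precision(self):
        spec = synthetic.CohortSpec(
            groups=[synthetic.GroupSpec("g", 2000)],
            D=10,
            sparsity=0.2,
            subject_sd=0.0,
            seed=3,
        )
        _, _, truth = synthetic.generate_cohort(spec)
        sample_cov = np.cov(truth.latent, rowvar=False)
        sigma = np.linalg.inv(truth.precision)
        rel_err = np.linalg.norm(sample_cov - sigma) / np.linalg.norm(sigma)
        assert rel_err < 0.2

    def test_null_cohorts_control_consensus_false_positives(self):
        """With no planted effects the consensus DA rate stays below 10%."""
        rates = []
        for seed in range(20):
            spec = synthetic.CohortSpec(
                groups=[
                    synthetic.GroupSpec("case", 15),
                    synthetic.GroupSpec("c1", 15),
                    synthetic.GroupSpec("c2", 15),
                ],
                D=15,
                sparsity=0.1,
                seed=seed,
            )
            m, _, _ = synthetic.generate_cohort(spec)
            clr = clr_transform(m)
            res = da.consensus_da(
                clr.values, m.abundance, m.groups, "case", ["c1", "c2"]
            )
            rates.append(len(res.consensus_species) / spec.D)
        assert np.mean(rates) <= 0.10


class TestTruthObject:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            synthetic.SyntheticTruth(
                precision_support=np.array([[0, 1], [0, 0]]),  # asymmetric
                edge_signs=np.zeros((2, 2)),
                da_species=[],
                group_means={},
            )
        with pytest.raises(ValueError):
            synthetic.SyntheticTruth(
                precision_support=np.zeros((2, 2)),
                edge_signs=np.zeros((2, 2)),
                da_species=[("sp000", 0.5, "elevated")],  # below twofold
                group_means={},
            )

    def test_json_roundtrip(self, tmp_path, small_cohort):
        _, truth = small_cohort
        truth.to_json(tmp_path / "t.json")
        back = synthetic.SyntheticTruth.from_json(tmp_path / "t.json")
        assert np.array_equal(back.precision_support, truth.precision_support)
        assert back.da_species == truth.da_species


class TestReadCompatibility:
    def test_unambiguous_counts_near_proportions(self):
        table, _ = synthetic.generate_read_compatibility(
            np.array([0.3, 0.7]), 10_000, ambiguity=0.0, seed=0
        )
        assert all(len(p) == 1 for p in table.patterns)
        est = em.em_estimate(table)
        assert abs(est.proportions["g0"] - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 10_000)

    def test_full_ambiguity_links_every_read_to_both(self):
        table, _ = synthetic.generate_read_compatibility(
            np.array([0.5, 0.5]), 500, ambiguity=1.0, seed=0
        )
        assert table.patterns == [("g0", "g1")]

    def test_low_depth_sample_fails_qc(self):
        table, _ = synthetic.generate_read_compatibility(
            np.array([0.5, 0.5]), 200_000, ambiguity=0.0, seed=0
        )
        est = em.em_estimate(table)
        assert not em.qc_min_mapped(est)


class TestFamilyCounts:
    def test_planted_family_tracks_carrier_abundance(self):
        counts = synthetic.generate_family_counts(
            ["spA", "spB"], n_families=5, role_map_size=2,
            planted_roles=[("spA", "FAM0000", 50)], seed=0,
        )
        carrier = counts.counts.loc["spA", "FAM0000"]
        other = counts.counts.loc["spB", "FAM0000"]
        # weighted family abundance rises with the carrier's abundance
        low = 0.1 * carrier + 0.9 * other
        high = 0.9 * carrier + 0.1 * other
        assert high > low

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_family_counts(
                ["spA"], n_families=3, role_map_size=1,
                planted_roles=[("spA", "FAM9999", 5)],
            )

    def test_deterministic_under_seed(self):
        a = synthetic.generate_family_counts(5, seed=3)
        b = synthetic.generate_family_counts(5, seed=3)
        pd.testing.assert_frame_equal(a.counts, b.counts)
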