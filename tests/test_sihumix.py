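"""Community shares, phase statistics, pathway filters, ordination
statistics and the exposure-design arithmetic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from vamrstat.sihumix import (
    DoseSpec,
    ExposureDesign,
    PathwayMap,
    bioreactor_dose,
    bray_curtis,
    community_profile,
    dunn_test,
    ordinate,
    pairwise_permanova,
    pathway_profile,
    permanova,
    phase_log2fc,
    phase_species_stats,
)


def make_table(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "bioreactor", "phase", "species", "protein_group", "intensity", "ko"],
    )


class TestCommunityProfile:
    def test_single_species_owns_the_whole_profile(self):
        table = make_table([("s1", "BR1", "exposure", "Escherichia coli", "p1", 7.0, "")])
        shares, _ = community_profile(table)
        assert shares.loc["s1", "Escherichia coli"] == 1.0

    def test_three_to_one_intensity_split(self):
        table = make_table(
            [
                ("s1", "BR1", "exposure", "A", "p1", 2.0, ""),
                ("s1", "BR1", "exposure", "A", "p2", 1.0, ""),
                ("s1", "BR1", "exposure", "B", "p3", 1.0, ""),
            ]
        )
        shares, _ = community_profile(table)
        assert shares.loc["s1", "A"] == pytest.approx(0.75)
        assert shares.loc["s1", "B"] == pytest.approx(0.25)

    def test_unassigned_mass_is_excluded_but_logged(self):
        table = make_table(
            [
                ("s1", "BR1", "exposure", "A", "p1", 3.0, ""),
                ("s1", "BR1", "exposure", "unassigned", "p2", 1.0, ""),
            ]
        )
        shares, unassigned = community_profile(table)
        assert shares.loc["s1", "A"] == 1.0
        assert unassigned["s1"] == pytest.approx(0.25)

    def test_zero_assigned_intensity_names_the_sample(self):
        table = make_table([("bad", "BR1", "exposure", "A", "p1", 0.0, "")])
        with pytest.raises(ValueError, match="bad"):
            community_profile(table)


class TestPhaseStats:
    def test_identical_phase_means_give_null_statistics(self):
        profiles = pd.DataFrame(
            {"A": [0.5] * 12, "B": [0.5] * 12},
            index=pd.Index([f"s{i}" for i in range(12)], name="sample_id"),
        )
        meta = pd.DataFrame(
            {
                "bioreactor": [f"BR{i % 4}" for i in range(12)],
                "phase": ["stabilization"] * 4 + ["exposure"] * 4 + ["recovery"] * 4,
            },
            index=profiles.index,
        )
        kw, dunn = phase_species_stats(profiles, meta)
        assert (kw["H"] == 0).all()
        assert (dunn["p_adj"] == 1.0).all()

    def test_fully_separated_ranks_reach_the_closed_form_maximum(self):
        """Three groups of four with disjoint value ranges: H for ranks
        (1-4 | 5-8 | 9-12) is 12/(N(N+1))*sum(n*Rbar^2) - 3(N+1) = 9.846."""
        profiles = pd.DataFrame(
            {"A": np.arange(1.0, 13.0)},
            index=pd.Index([f"s{i}" for i in range(12)], name="sample_id"),
        )
        meta = pd.DataFrame(
            {
                "bioreactor": [f"BR{i}" for i in range(12)],  # one mean per reactor
                "phase": ["stabilization"] * 4 + ["exposure"] * 4 + ["recovery"] * 4,
            },
            index=profiles.index,
        )
        kw, _ = phase_species_stats(profiles, meta)
        expected_h = 12 / (12 * 13) * 4 * (2.5**2 + 6.5**2 + 10.5**2) - 3 * 13
        assert kw["H"].iloc[0] == pytest.approx(expected_h)

    def test_dunn_matches_a_hand_computed_no_ties_fixture(self):
        groups = {"A": np.array([1.0, 2.0]), "B": np.array([3.0, 4.0]), "C": np.array([5.0, 6.0])}
        res = dunn_test(groups).set_index(["group_a", "group_b"])
        # mean ranks 1.5 / 3.5 / 5.5, variance N(N+1)/12 * (1/2 + 1/2) = 3.5
        assert res.loc[("A", "B"), "z"] == pytest.approx(-2 / math.sqrt(3.5))
        assert res.loc[("A", "C"), "z"] == pytest.approx(-4 / math.sqrt(3.5))
        assert res.loc[("A", "C"), "p_raw"] == pytest.approx(0.03251, abs=2e-5)

    def test_duplicating_observations_preserves_dunn_z_ordering(self, rng):
        groups = {g: rng.normal(i, 1.0, size=5) for i, g in enumerate("XYZ")}
        doubled = {g: np.repeat(v, 2) for g, v in groups.items()}
        z1 = dunn_test(groups).sort_values("z")[["group_a", "group_b"]].to_numpy()
        z2 = dunn_test(doubled).sort_values("z")[["group_a", "group_b"]].to_numpy()
        assert (z1 == z2).all()

    def test_a_phase_with_one_bioreactor_is_insufficient(self):
        profiles = pd.DataFrame(
            {"A": [0.1, 0.2, 0.3]},
            index=pd.Index(["s0", "s1", "s2"], name="sample_id"),
        )
        meta = pd.DataFrame(
            {"bioreactor": ["BR1", "BR2", "BR1"],
             "phase": ["stabilization", "stabilization", "exposure"]},
            index=profiles.index,
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            phase_species_stats(profiles, meta)


class TestPathwayProfile:
    @staticmethod
    def toy_table():
        rows = []
        # pathway pwA: 2 detected KOs carried by 6 protein groups, total 42
        for j, (ko, inten) in enumerate(
            [("K1", 10.0), ("K1", 5.0), ("K1", 6.0), ("K2", 11.0), ("K2", 4.0), ("K2", 6.0)]
        ):
            rows.append(("s1", "BR1", "exposure", "A", f"pA{j}", inten, ko))
        # pathway pwB: high coverage but only 4 proteins
        for j in range(4):
            rows.append(("s1", "BR1", "exposure", "A", f"pB{j}", 1.0, f"K1{j}"))
        # pathway pwC: 20 proteins but 10% coverage
        for j in range(20):
            rows.append(("s1", "BR1", "exposure", "A", f"pC{j}", 1.0, f"K2{j % 2}"))
        return make_table(rows)

    @staticmethod
    def toy_map():
        return PathwayMap(
            {
                "pwA": frozenset({"K1", "K2"} | {f"pad{i}" for i in range(8)}),      # 2/10 detected
                "pwB": frozenset({f"K1{j}" for j in range(4)}),                        # 100% coverage
                "pwC": frozenset({"K20", "K21"} | {f"padC{i}" for i in range(18)}),   # 2/20 detected
            }
        )

    def test_filters_and_aggregation_on_the_toy_map(self):
        profile = pathway_profile(self.toy_table(), self.toy_map())
        cov = profile.coverage.set_index("pathway")
        assert cov.loc["pwA", "coverage"] == pytest.approx(0.2)
        assert cov.loc["pwA", "retained"]
        assert profile.matrix.loc["s1", "pwA"] == pytest.approx(42.0)
        assert not cov.loc["pwB", "retained"] and cov.loc["pwB", "excluded_reason"] == "protein_count"
        assert not cov.loc["pwC", "retained"] and cov.loc["pwC", "excluded_reason"] == "coverage"

    def test_relaxing_filters_never_drops_a_retained_pathway(self):
        table, pmap = self.toy_table(), self.toy_map()
        strict = pathway_profile(table, pmap, min_coverage=0.15, min_proteins=5)
        loose = pathway_profile(table, pmap, min_coverage=0.05, min_proteins=2)
        kept_strict = set(strict.matrix.columns)
        kept_loose = set(loose.matrix.columns)
        assert kept_strict <= kept_loose

    def test_empty_pathway_membership_is_a_map_error(self):
        with pytest.raises(ValueError, match="zero KOs"):
            PathwayMap({"pwEmpty": frozenset()})

    def test_missing_ko_annotations_are_rejected(self):
        table = make_table([("s1", "BR1", "exposure", "A", "p1", 1.0, "")])
        with pytest.raises(ValueError, match="KO"):
            pathway_profile(table, self.toy_map())


class TestPhaseLog2FC:
    @staticmethod
    def profile_from(values_a, values_b, pathway="pw1"):
        samples = [f"a{i}" for i in range(len(values_a))] + [f"b{i}" for i in range(len(values_b))]
        from vamrstat.sihumix import PathwayProfile

        matrix = pd.DataFrame({pathway: list(values_a) + list(values_b)},
                              index=pd.Index(samples, name="sample_id"))
        meta = pd.DataFrame(
            {"bioreactor": "BR1",
             "phase": ["stabilization"] * len(values_a) + ["exposure"] * len(values_b)},
            index=matrix.index,
        )
        totals = pd.Series(1.0, index=matrix.index)
        return PathwayProfile(matrix=matrix, sample_totals=totals, meta=meta,
                              coverage=pd.DataFrame())

    def test_identical_phases_are_not_retained(self):
        prof = self.profile_from([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = phase_log2fc(prof).iloc[0]
        assert res.log2fc == pytest.approx(0.0)
        assert not res.retained

    def test_exact_doubling_gives_log2fc_one(self):
        prof = self.profile_from([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        res = phase_log2fc(prof).iloc[0]
        assert res.log2fc == pytest.approx(1.0)
        assert res.direction == "up"

    def test_zero_phase_mean_is_flagged_not_infinite(self):
        prof = self.profile_from([0.0, 0.0], [1.0, 2.0])
        res = phase_log2fc(prof).iloc[0]
        assert np.isnan(res.log2fc) and res.undefined_fc
        assert not res.retained


class TestOrdinationStats:
    def test_bray_curtis_examples(self):
        x = np.array([[1.0, 0.0, 3.0], [2.0, 1.0, 1.0]])
        d = bray_curtis(x)
        assert d[0, 1] == pytest.approx(0.5)  # (1+1+2)/(3+1+4)
        same = bray_curtis(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert same[0, 1] == 0.0
        disjoint = bray_curtis(np.array([[1.0, 0.0], [0.0, 2.0]]))
        assert disjoint[0, 1] == 1.0

    def test_bray_curtis_properties(self, rng):
        x = rng.gamma(2.0, 1.0, size=(6, 8))
        d = bray_curtis(x)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert ((d >= 0) & (d <= 1)).all()
        perm = rng.permutation(8)
        np.testing.assert_allclose(bray_curtis(x[:, perm]), d)
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(np.array([[1.0, 1.0], [0.0, 0.0]]))

    def test_permanova_matches_exhaustive_enumeration_on_two_plus_two(self, rng):
        x = rng.normal(size=(4, 3)) ** 2
        d = bray_curtis(x)
        labels = np.array(["a", "a", "b", "b"])
        from vamrstat.sihumix import _permanova_f

        d2 = d**2
        f_obs = _permanova_f(d2, labels)
        exhaustive = [
            _permanova_f(d2, np.array(perm)) >= f_obs
            for perm in set(itertools.permutations(labels))
        ]
        p_exact = float(np.mean(exhaustive))
        res = permanova(d, labels, n_perm=999, seed=5)
        assert abs(res["p"] - p_exact) <= 3 * np.sqrt(p_exact * (1 - p_exact) / 999) + 1e-3

    def test_separated_groups_hit_the_permutation_floor(self):
        """Groups far apart relative to their spread: no sampled label
        permutation recreates the split, so p sits at 1/(n_perm+1)."""
        x = np.vstack([np.tile([1.0, 0.0, 0.0], (6, 1)) + 1e-3 * np.arange(6)[:, None],
                       np.tile([0.0, 1.0, 0.0], (6, 1)) + 1e-3 * np.arange(6)[:, None]])
        d = bray_curtis(x)
        labels = np.array(["g1"] * 6 + ["g2"] * 6)
        res = permanova(d, labels, n_perm=99, seed=0)
        assert res["p"] == pytest.approx(1 / 100)

    def test_permanova_f_matches_scikit_bio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        x = rng.gamma(2.0, 1.0, size=(12, 5))
        d = bray_curtis(x)
        labels = np.repeat(["a", "b", "c"], 4)
        ours = permanova(d, labels, n_perm=499, seed=1)
        dm = skbio_stats.DistanceMatrix(d, ids=[str(i) for i in range(12)])
        theirs = skbio_stats.permanova(dm, grouping=list(labels), permutations=499)
        assert ours["pseudo_f"] == pytest.approx(float(theirs["test statistic"]), rel=1e-9)
        assert abs(ours["p"] - float(theirs["p-value"])) < 0.1

    def test_group_relabelling_leaves_f_unchanged(self, rng):
        x = rng.gamma(2.0, 1.0, size=(9, 4))
        d = bray_curtis(x)
        labels = np.repeat(["a", "b", "c"], 3)
        renamed = np.array([{"a": "zebra", "b": "yak", "c": "xerus"}[g] for g in labels])
        f1 = permanova(d, labels, n_perm=49, seed=2)["pseudo_f"]
        f2 = permanova(d, renamed, n_perm=49, seed=2)["pseudo_f"]
        assert f1 == pytest.approx(f2)

    def test_pairwise_permanova_is_hochberg_adjusted(self, rng):
        x = rng.gamma(2.0, 1.0, size=(12, 5))
        d = bray_curtis(x)
        labels = np.repeat(["a", "b", "c"], 4)
        res = pairwise_permanova(d, labels, n_perm=99, seed=3)
        assert len(res) == 3
        assert (res["p_adj"] >= res["p_raw"] - 1e-12).all()

    def test_singleton_group_is_rejected(self):
        d = bray_curtis(np.eye(3) + 0.1)
        with pytest.raises(ValueError, match="size 1"):
            permanova(d, np.array(["a", "a", "b"]), n_perm=9, seed=0)

    def test_collinear_data_load_entirely_on_pc1(self):
        t = np.linspace(0, 1, 5)[:, None]
        x = t @ np.array([[2.0, -1.0, 0.5]])
        res = ordinate(x)
        assert res["explained"][0] == pytest.approx(1.0)
        assert (np.diff(res["explained"]) <= 1e-12).all()

    def test_scores_match_an_eigendecomposition_oracle_up_to_sign(self, rng):
        x = rng.normal(size=(4, 3))
        res = ordinate(x)
        centered = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        order = np.argsort(evals)[::-1]
        oracle_scores = centered @ evecs[:, order]
        for k in range(3):
            assert np.allclose(np.abs(res["scores"][:, k]), np.abs(oracle_scores[:, k]), atol=1e-9)

    def test_constant_matrix_ordinated_to_zero(self):
        res = ordinate(np.full((4, 3), 2.5))
        assert (res["explained"] == 0).all() and (res["scores"] == 0).all()


class TestExposureDesign:
    def test_dose_reproduces_the_design_concentration(self):
        res = bioreactor_dose(DoseSpec())
        assert res.mg_per_ml == pytest.approx(0.0056)
        assert res.printed_micromolar == 13.8

    def test_unit_identity(self):
        res = bioreactor_dose(DoseSpec(adi=1.0, fraction_of_adi=1.0, body_weight=14.0, reactor_volume=14.0))
        assert res.mg_per_ml == pytest.approx(1.0)

    @pytest.mark.parametrize("kwargs", [{"adi": 0.0}, {"fraction_of_adi": 1.5}, {"reactor_volume": -1}])
    def test_invalid_specs_are_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DoseSpec(**kwargs)

    def test_design_enumerators(self):
        design = ExposureDesign()
        assert design.total_flasks == 60
        assert design.flasks_per_status == 30
        assert design.inoculum_cells == pytest.approx(8e9)
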