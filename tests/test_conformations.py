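import numpy as np
import pytest

from rpk.conformations import (
    LABEL_ASSIST,
    LABEL_NONPROD,
    LABEL_SINGLE,
    ClassificationCriteria,
    ConformationRecord,
    catalytic_distances,
    classify,
    cluster_microstates,
    hbond_occupancy,
    state_distance_summary,
)
from rpk.io_formats import Trajectory, ValidationError


def _record(nd_h, c_o, bridge=np.inf, **kw):
    """Record with explicit per-water candidate arrays."""
    nd_h = np.atleast_1d(np.asarray(nd_h, float))
    c_o = np.atleast_1d(np.asarray(c_o, float))
    k = nd_h.size
    oo_h = np.full((k, k), np.inf)
    if k > 1 and np.isfinite(bridge):
        # bridge between the attacking water (min c_o) and every other
        nuc = int(np.argmin(c_o))
        oo_h[nuc, :] = bridge
        oo_h[:, nuc] = bridge
        np.fill_diagonal(oo_h, np.inf)
    nuc = int(np.argmin(c_o))
    return ConformationRecord(
        kw.get("frame", 0), float(nd_h.min()), float(c_o[nuc]),
        float(oo_h[nuc].min()) if k > 1 else np.inf,
        kw.get("d_nd_c", 4.3), kw.get("d_ca_opopc", 2.3),
        kw.get("d_ca_ow", 3.6), nd_h, c_o, oo_h)


def _brute_force_label(rec, crit):
    """Exhaustive re-evaluation of the geometric criteria over all waters."""
    k = rec.cand_nd_h.size
    for w in range(k):
        if rec.cand_nd_h[w] < crit.d_his_h_max and \
                rec.cand_c_o[w] < crit.d_c_o_max:
            return LABEL_SINGLE
    for w1 in range(k):
        for w2 in range(k):
            if w1 == w2:
                continue
            if (rec.cand_c_o[w1] < crit.d_c_o_max
                    and rec.cand_nd_h[w2] < crit.d_his_h_max
                    and rec.cand_oo_h[w1, w2] < crit.d_bridge_max):
                return LABEL_ASSIST
    return LABEL_NONPROD


class TestCatalyticDistances:
    def test_generated_distances_match_construction_targets(
            self, active_site_5000):
        ens = active_site_5000
        recs = catalytic_distances(ens.trajectory, ens.atom_map)
        sub = np.arange(0, 5000, 50)
        for f in sub:
            r = recs[f]
            assert r.d_nd_c == pytest.approx(ens.drawn["nd_c"][f], abs=0.01)
            assert r.d_ca_opopc == pytest.approx(ens.drawn["ca_opopc"][f],
                                                 abs=0.01)
            assert r.d_nd_h == pytest.approx(ens.drawn["nd_h"][f], abs=0.01)
            assert r.d_c_o == pytest.approx(ens.drawn["c_o"][f], abs=0.01)
            assert r.d_ca_ow == pytest.approx(ens.drawn["ca_ow"][f], abs=0.01)

    def test_rigid_rotation_leaves_distances_unchanged(self, active_site_5000):
        from scipy.spatial.transform import Rotation

        ens = active_site_5000
        traj = ens.trajectory
        small = Trajectory(traj.atoms, traj.coords[:20].copy(), traj.box)
        recs_a = catalytic_distances(small, ens.atom_map)
        rot = Rotation.from_euler("zyx", [0.7, -0.2, 1.9]).as_matrix()
        rotated = Trajectory(traj.atoms, small.coords @ rot.T, traj.box)
        recs_b = catalytic_distances(rotated, ens.atom_map)
        for a, b in zip(recs_a, recs_b):
            assert a.d_nd_h == pytest.approx(b.d_nd_h, abs=1e-9)
            assert a.d_c_o == pytest.approx(b.d_c_o, abs=1e-9)
            assert a.d_o_h_bridge == pytest.approx(b.d_o_h_bridge, abs=1e-9)


class TestClassify:
    def test_single_water_satisfying_both_criteria(self):
        recs, summary = classify([_record(1.8, 3.0)])
        assert recs[0].label == LABEL_SINGLE

    def test_two_water_relay_is_assisting(self):
        # W1 attacks (3.5 Å) but is not His-bonded; W2 donates to His and
        # bridges to W1 at 1.9 Å
        recs, _ = classify([_record([4.0, 2.0], [3.5, 9.0], bridge=1.9)])
        assert recs[0].label == LABEL_ASSIST

    def test_thresholds_are_strict_inequalities(self):
        recs, _ = classify([_record([2.5, 2.5], [4.0, 4.0], bridge=2.5)])
        assert recs[0].label == LABEL_NONPROD

    def test_fractions_sum_to_one(self, classified_5000):
        _, summary = classified_5000
        assert summary["fraction"].sum() == pytest.approx(1.0)

    def test_planted_populations_recovered(self, classified_5000):
        _, summary = classified_5000
        assert summary.loc[LABEL_SINGLE, "fraction"] == pytest.approx(0.75,
                                                                      abs=0.02)
        assert summary.loc[LABEL_ASSIST, "fraction"] == pytest.approx(0.04,
                                                                      abs=0.02)

    def test_agrees_with_brute_force_over_water_assignments(
            self, classified_5000):
        recs, _ = classified_5000
        crit = ClassificationCriteria()
        for r in recs[::23]:
            assert r.label == _brute_force_label(r, crit)

    def test_classification_monotone_in_thresholds(self, classified_5000):
        import copy

        recs, summary = classified_5000
        productive = (summary.loc[LABEL_SINGLE, "count"]
                      + summary.loc[LABEL_ASSIST, "count"])
        wider = ClassificationCriteria(3.5, 5.0, 3.5)
        # classify labels in place: work on copies, the fixture is shared
        _, summary_w = classify([copy.copy(r) for r in recs], wider)
        productive_w = (summary_w.loc[LABEL_SINGLE, "count"]
                        + summary_w.loc[LABEL_ASSIST, "count"])
        assert productive_w >= productive


class TestHbondOccupancy:
    def test_all_or_none(self):
        bonded = [_record(1.8, 3.0)] * 4
        free = [_record(4.0, 5.0)] * 4
        assert hbond_occupancy(bonded) == 1.0
        assert hbond_occupancy(free) == 0.0

    def test_planted_occupancy_recovered(self):
        # full-trajectory emulation: His-bonded states total 42%
        from rpk.conformations import catalytic_distances, classify
        from rpk.synthetic_data import (ActiveSiteFixtureSpec,
                                        gen_active_site_trajectory)

        ens = gen_active_site_trajectory(ActiveSiteFixtureSpec(
            n_frames=5000, state_probabilities=(0.38, 0.04, 0.58), seed=17))
        recs = catalytic_distances(ens.trajectory, ens.atom_map)
        assert hbond_occupancy(recs) == pytest.approx(0.42, abs=0.02)


class TestClusterMicrostates:
    def _blob_records(self, centers, weights, n, sigma=0.25, seed=0):
        rng = np.random.default_rng(seed)
        which = rng.choice(len(centers), n, p=weights)
        xy = np.asarray(centers)[which] + rng.normal(0, sigma, (n, 2))
        return [_record(1.8, 3.0, d_nd_c=a, d_ca_opopc=b)
                for a, b in xy]

    def test_two_separated_blobs_split_evenly(self):
        recs = self._blob_records([[0, 0], [10, 10]], [0.5, 0.5], 1000,
                                  sigma=0.2)
        res = cluster_microstates(recs, kde_sigma=1.0, density_quantile=0.5)
        assert res.n_clusters == 2
        assert sorted(res.fractions.values()) == pytest.approx([0.5, 0.5],
                                                               abs=0.05)

    def test_single_blob_keeps_most_records(self):
        recs = self._blob_records([[3, 3]], [1.0], 800, sigma=0.5)
        res = cluster_microstates(recs, kde_sigma=1.0, density_quantile=0.5)
        assert res.n_clusters == 1
        assert res.fractions[0] >= 0.5

    def test_minority_cluster_fraction_recovered(self):
        recs = self._blob_records([[0, 0], [8, 0], [0, 8]],
                                  [0.06, 0.47, 0.47], 5000, sigma=0.3, seed=4)
        res = cluster_microstates(recs, kde_sigma=1.0, density_quantile=0.5)
        assert res.n_clusters == 3
        assert min(res.fractions.values()) == pytest.approx(0.06, abs=0.02)

    def test_degenerate_data_rejected(self):
        recs = [_record(1.8, 3.0, d_nd_c=4.3, d_ca_opopc=2.3)] * 100
        with pytest.raises(ValidationError):
            cluster_microstates(recs)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValidationError):
            cluster_microstates([_record(1.8, 3.0)] * 10)


class TestStateDistanceSummary:
    def test_lone_record_has_zero_spread(self):
        recs, _ = classify([_record(1.8, 3.0), _record(4.5, 5.5)])
        summ = state_distance_summary(recs)
        assert summ.loc[LABEL_SINGLE, ("d_nd_h", "mean")] == pytest.approx(1.8)
        assert summ.loc[LABEL_SINGLE, ("d_nd_h", "sd")] == 0.0

    def test_planted_calcium_water_distance_laws_recovered(
            self, classified_5000):
        summ = state_distance_summary(classified_5000[0])
        assert summ.loc[LABEL_SINGLE, ("d_ca_ow", "mean")] == pytest.approx(
            3.6, abs=0.1)
        assert summ.loc[LABEL_SINGLE, ("d_ca_ow", "sd")] == pytest.approx(
            1.5, abs=0.1)
        assert summ.loc[LABEL_ASSIST, ("d_ca_ow", "mean")] == pytest.approx(
            4.8, abs=0.1)
        assert summ.loc[LABEL_ASSIST, ("d_ca_ow", "sd")] == pytest.approx(
            0.2, abs=0.1)

    def test_unclassified_records_rejected(self):
        with pytest.raises(ValidationError):
            state_distance_summary([_record(1.8, 3.0)])
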