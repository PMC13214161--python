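import numpy as np
import pytest

from tsponet.network import edge_index_pairs
from tsponet.pipeline import edge_table
from tsponet.simulate import (BatchSpec, CohortBlock, DiseaseSpec,
                              FrameSchedule, PBR28_SCHEDULE, SimConfig,
                              kinetic_template, simulate_cohort,
                              simulate_edge_cohort, simulate_input_function,
                              simulate_tissue_tac, write_cohort)


class TestFrameSchedule:
    def test_pbr28_layout(self):
        s = FrameSchedule(PBR28_SCHEDULE)
        assert s.frame_durations.size == 26
        assert s.frame_end[-1] == pytest.approx(90.0)
        assert np.all(np.diff(s.mid_times) > 0)


class TestInputFunction:
    def test_dose_linearity(self):
        t = np.linspace(0, 60, 200)
        a = simulate_input_function(150.0, t)
        b = simulate_input_function(300.0, t)
        np.testing.assert_allclose(b, 2 * a)

    def test_zero_at_injection(self):
        t = np.linspace(0, 10, 50)
        assert simulate_input_function(200.0, t)[0] == 0.0

    def test_peak_at_alpha_tau(self):
        t = np.linspace(0, 10, 2001)
        c = simulate_input_function(200.0, t, alpha=2.0, tau=0.75)
        assert t[np.argmax(c)] == pytest.approx(1.5, abs=t[1] - t[0])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_input_function(0.0, np.linspace(0, 10, 5))
        with pytest.raises(ValueError):
            simulate_input_function(100.0, np.array([-1.0, 1.0]))


class TestTissueTac:
    def test_irreversible_limit_is_cumulated_input(self):
        mids = FrameSchedule(PBR28_SCHEDULE).mid_times
        cp = simulate_input_function(250.0, mids)
        ct = simulate_tissue_tac(mids, cp, 0.1, 0.0)
        from scipy.integrate import cumulative_trapezoid
        expected = 0.1 * cumulative_trapezoid(np.r_[0.0, cp], np.r_[0.0, mids])
        np.testing.assert_allclose(ct, expected, atol=1e-12)

    def test_zero_influx_gives_zero(self):
        mids = FrameSchedule(PBR28_SCHEDULE).mid_times
        cp = simulate_input_function(250.0, mids)
        assert np.all(simulate_tissue_tac(mids, cp, 0.0, 0.05) == 0.0)

    def test_washout_reduces_late_activity(self):
        mids = FrameSchedule(PBR28_SCHEDULE).mid_times
        cp = simulate_input_function(250.0, mids)
        slow = simulate_tissue_tac(mids, cp, 0.1, 0.02)
        fast = simulate_tissue_tac(mids, cp, 0.1, 0.10)
        assert fast[-1] < slow[-1]

    def test_full_occupancy_identical_shapes(self):
        """At occupancy 1 every region shares k2_eff, so TACs differ only
        by the K1 scale."""
        cfg = SimConfig(batches=(BatchSpec("S", noise_level=0.0),),
                        cohort=(CohortBlock("S", "SCZ", 2, "blocking"),),
                        occupancy=1.0, seed=1)
        c = simulate_cohort(cfg)
        block = [s for s in c.scans if s.scan_id.endswith("block")][0]
        a = block.activity
        ratios = a[1:] / a[:1]  # each column's profile relative to frame 0
        norm = a / a[-1:]       # normalize by last frame: identical shapes
        np.testing.assert_allclose(norm - norm[:, :1], 0.0, atol=1e-9)


class TestKineticTemplate:
    def test_homologs_share_kinetics(self, atlas20):
        cfg = SimConfig()
        k1, expr = kinetic_template(atlas20, cfg, np.random.SeedSequence(0))
        for i, j in atlas20.homolog_pairs():
            assert k1[i] == k1[j]
            assert expr[i] == expr[j]


class TestCohort:
    def test_byte_identical_reruns(self, tmp_path):
        cfg = SimConfig(cohort=(CohortBlock("SITE1", "HC", 3),
                                CohortBlock("SITE1", "MS", 3)),
                        diseases=(DiseaseSpec("MS", ("Left-Putamen",
                                                     "Right-Putamen")),),
                        seed=7)
        for d in ("a", "b"):
            write_cohort(simulate_cohort(cfg), tmp_path / d)
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                g = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == g.read_bytes(), f.name
        assert len(list((tmp_path / "a" / "tacs").glob("*.csv"))) == 6

    def test_disease_raises_late_suv_noise_free(self):
        """The expression multiplier slows washout in the target regions,
        so their late activity exceeds the matched HC value."""
        targets = ("Left-Putamen", "Right-Putamen", "Left-Thalamus-Proper")
        kw = dict(batches=(BatchSpec("S", noise_level=0.0),), seed=5,
                  subject_sd=0.0)
        hc = simulate_cohort(SimConfig(
            cohort=(CohortBlock("S", "HC", 1),), **kw))
        ms = simulate_cohort(SimConfig(
            cohort=(CohortBlock("S", "MS", 1),),
            diseases=(DiseaseSpec("MS", targets, 1.5),), **kw))
        idx = [hc.atlas.index(t) for t in targets]
        assert np.all(ms.scans[0].activity[-1, idx]
                      > hc.scans[0].activity[-1, idx])

    def test_noise_free_truth_closure(self, noiseless_hc_cohort):
        """Ground truth regenerates the stored noiseless TACs exactly."""
        c = noiseless_hc_cohort
        scan = c.scans[2]
        truth = c.truth.scans[scan.scan_id]
        for r in range(scan.n_roi):
            tac = simulate_tissue_tac(scan.frame_mid_times, scan.input_curve,
                                      truth["k1"][r], truth["k2_eff"][r])
            np.testing.assert_allclose(scan.activity[:, r], tac, atol=1e-12)

    def test_unknown_batch_reference_rejected(self):
        cfg = SimConfig(cohort=(CohortBlock("NOPE", "HC", 2),))
        with pytest.raises(ValueError, match="unknown batch"):
            simulate_cohort(cfg)

    def test_blocking_flattens_similarity_monotonically(self):
        """Median inter-regional similarity increases with occupancy."""
        medians = []
        for occ in (0.0, 0.5, 0.9):
            cfg = SimConfig(batches=(BatchSpec("S", noise_level=0.0),),
                            cohort=(CohortBlock("S", "SCZ", 4, "blocking"),),
                            occupancy=occ, seed=13)
            c = simulate_cohort(cfg)
            edges, cov = edge_table(c.scans, c.records)
            block = edges[(cov["session"] == "block").to_numpy()]
            medians.append(np.median(block))
        assert medians[0] < medians[1] < medians[2]


class TestEdgeCohort:
    def test_truth_reflects_planted_effects(self):
        edges, cov, truth = simulate_edge_cohort(
            n_per_group={"HC": 10, "MS": 10}, atlas=10,
            disease_effects={"MS": ([1, 3], 0.2)}, noise_sd=0.0, seed=0)
        pairs = edge_index_pairs(10)
        incident = truth["disease_incident_edges"]["MS"]
        hc = edges[(cov["group"] == "HC").to_numpy()]
        ms = edges[(cov["group"] == "MS").to_numpy()]
        # with zero noise the group difference on incident edges is exactly
        # the planted shift plus covariate differences; covariates off here
        assert incident.size == 2 * 9 - 1
        assert np.all(np.isin(pairs[incident], [1, 3]).any(axis=1))

    def test_deterministic(self):
        a = simulate_edge_cohort(n_per_group={"HC": 5}, atlas=10, seed=3)
        b = simulate_edge_cohort(n_per_group={"HC": 5}, atlas=10, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1].equals(b[1])
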