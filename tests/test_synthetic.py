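import numpy as np
import pandas as pd
import pytest

from intralobe.response import recist_classify
from intralobe.synthetic import (
    CohortConfig,
    PlacementError,
    ResponseProfile,
    build_phantom,
    generate_cohort,
    simulate_followup,
    simulate_labs,
    simulate_paired_tn,
)


def small_config(**kw):
    defaults = dict(
        n_patients=2, n_cycles=1, tn_true_log_sd=0.0, enhancement_log_sd=0.0,
        poisson_noise=False, lesions_per_lobe_range=(1, 1),
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestConfigValidation:
    def test_lesion_diameter_floor(self):
        with pytest.raises(ValueError, match="30 mm"):
            CohortConfig(lesion_diameter_range=(20.0, 40.0))

    def test_grid_must_contain_liver(self):
        with pytest.raises(ValueError, match="grid too small"):
            CohortConfig(grid_shape=(32, 32, 32))

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(background_counts=0.0)


class TestBuildPhantom:
    def test_noise_free_expectation_values(self):
        cfg = small_config(enhancement_log_mean=0.0)  # rho = 1
        p = build_phantom(cfg, 5, ia_lobe="right")
        mult = p.true_tn
        for lesion in p.lesions:
            vals = p.lesion_vois[lesion.lesion_id].values_in(p.cycle_volumes[0])
            assert np.allclose(vals, cfg.background_counts * mult)
        normal_vals = p.normal_voi.values_in(p.cycle_volumes[0])
        assert np.allclose(normal_vals, cfg.background_counts)

    def test_phantom_invariants(self):
        cfg = small_config(lesions_per_lobe_range=(1, 3), tn_true_log_sd=0.5)
        p = build_phantom(cfg, 11, ia_lobe="left")
        assert p.normal_voi.volume_ml >= 15.0
        liver = {tuple(i) for i in p.liver_mask.indices}
        normal = {tuple(i) for i in p.normal_voi.indices}
        for lobe in ("left", "right"):
            n = sum(1 for l in p.lesions if l.lobe == lobe)
            assert 1 <= n <= 3
        for lesion in p.lesions:
            assert lesion.diameter >= 30.0
            vox = {tuple(i) for i in p.lesion_vois[lesion.lesion_id].indices}
            assert vox <= liver
            assert not (vox & normal)
        # normal VOI sits in the control lobe
        lobe_code = 1 if p.control_lobe == "left" else 2
        i, j, k = p.normal_voi.indices.T
        assert np.all(p.lobe_labels[i, j, k] == lobe_code)

    def test_lesion_volume_matches_analytic_sphere(self):
        cfg = small_config(lesion_diameter_range=(30.0, 30.0))
        p = build_phantom(cfg, 3, ia_lobe="right")
        analytic_ml = 4 / 3 * np.pi * 15.0**3 / 1000.0  # 14.14 mL
        voxel_ml = cfg.grid.voxel_volume_mm3 / 1000.0
        # surface shell of a 30 mm sphere at 4 mm spacing
        shell_voxels = int(np.ceil(4 * np.pi * 15.0**2 * 4.0 / 64.0))
        for voi in p.lesion_vois.values():
            assert abs(voi.volume_ml - analytic_ml) <= shell_voxels * voxel_ml

    def test_determinism(self):
        cfg = small_config(poisson_noise=True, tn_true_log_sd=0.3)
        p1 = build_phantom(cfg, 99, ia_lobe="left")
        p2 = build_phantom(cfg, 99, ia_lobe="left")
        assert np.array_equal(p1.baseline_volume.values, p2.baseline_volume.values)
        assert np.array_equal(p1.cycle_volumes[0].values, p2.cycle_volumes[0].values)
        assert p1.true_tn == p2.true_tn

    def test_poisson_mean_matches_expectation(self):
        """Counts in lesion voxels average to the configured expectation
        (background x multiplier) within 3 standard errors."""
        cfg = small_config(poisson_noise=True)
        p = build_phantom(cfg, 7, ia_lobe="right")
        control = next(l for l in p.lesions if l.lobe == "left")
        vals = p.lesion_vois[control.lesion_id].values_in(p.cycle_volumes[0])
        expected = cfg.background_counts * p.true_tn
        se = np.sqrt(expected / vals.size)
        assert abs(vals.mean() - expected) <= 3 * se

    def test_impossible_placement_raises(self):
        cfg = small_config(lesion_diameter_range=(70.0, 70.0),
                           liver_semiaxes=(80.0, 60.0, 50.0))
        with pytest.raises(PlacementError):
            build_phantom(cfg, 1, ia_lobe="right")

    def test_misalignment_recorded_and_applied(self):
        cfg = small_config(misalignment_max_translation=6.0)
        p = build_phantom(cfg, 21, ia_lobe="right")
        tr = p.baseline_to_cycle_transforms[0]
        assert not tr.is_identity
        assert np.all(np.abs(tr.translation) <= 6.0)
        # the lesion moved with the patient: baseline mask transferred through
        # the true transform lands on hot voxels of the cycle volume
        lesion = p.lesions[0]
        world = p.baseline_volume.grid.world_coordinates(
            p.lesion_vois[lesion.lesion_id].indices)
        moved = tr.apply(world)
        cycle = p.cycle_volumes[0]
        idx = cycle.grid.nearest_indices(moved)
        keep = cycle.grid.in_bounds(idx)
        vals = cycle.values[tuple(idx[keep].T)]
        hot = cfg.background_counts * lesion.uptake_multiplier
        factor = p.true_enhancement if lesion.lobe == "right" else 1.0
        assert np.mean(np.isclose(vals, hot * factor)) > 0.85


class TestSimulateFollowup:
    def test_zero_change_profile_gives_sd(self, rng):
        cfg = small_config(response_profile=ResponseProfile.point_mass(0.0))
        p = build_phantom(cfg, 2, ia_lobe="left")
        diam = simulate_followup(p, cfg, rng)
        for _, row in diam.iterrows():
            cat = recist_classify(row["diameter_baseline"], row["diameter_3mo"],
                                  row["diameter_baseline"])
            assert cat == "SD"

    def test_minus_35_percent_profile_gives_pr(self, rng):
        cfg = small_config(response_profile=ResponseProfile.point_mass(-0.35))
        p = build_phantom(cfg, 2, ia_lobe="left")
        diam = simulate_followup(p, cfg, rng)
        for _, row in diam.iterrows():
            cat = recist_classify(row["diameter_baseline"], row["diameter_3mo"],
                                  row["diameter_baseline"])
            assert cat == "PR"

    def test_default_profile_category_proportions(self, rng):
        """Default trajectory mixture reproduces the designed response mix
        (25% PR at 3 months) over many lobes."""
        cfg = small_config()
        p = build_phantom(cfg, 2, ia_lobe="left")
        n_pr = 0
        n_lobe = 0
        for _ in range(300):
            diam = simulate_followup(p, cfg, rng)
            for (_, lobe), grp in diam.groupby(["patient_id", "lobe"]):
                base = grp["diameter_baseline"].sum()
                cur = grp["diameter_3mo"].sum()
                n_lobe += 1
                n_pr += recist_classify(base, cur, base) == "PR"
        frac = n_pr / n_lobe
        assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n_lobe)


class TestSimulateLabs:
    def test_all_analytes_present_with_baseline(self, rng):
        cfg = small_config()
        p = build_phantom(cfg, 2, ia_lobe="left")
        labs = simulate_labs(p, cfg, rng)
        assert labs["analyte"].nunique() == 15
        assert set(labs[labs["visit"] == 0]["analyte"]) == set(labs["analyte"])
        assert (labs.groupby("analyte")["visit"].max() == cfg.n_followup_visits).all()

    def test_unknown_analyte_rejected(self, rng):
        cfg = small_config()
        p = build_phantom(cfg, 2, ia_lobe="left")
        with pytest.raises(ValueError, match="unknown analyte"):
            simulate_labs(p, cfg, rng, analytes=("alat", "nonsense"))

    def test_quiet_config_produces_normal_values(self, rng):
        from intralobe.response import DEFAULT_GRADING_RULES
        from intralobe.response import grade_value
        cfg = small_config(baseline_abnormal_rate=0.0, lab_toxicity_rate=0.0)
        p = build_phantom(cfg, 2, ia_lobe="left")
        labs = simulate_labs(p, cfg, rng)
        base = labs[labs.visit == 0].set_index("analyte")["value"]
        grades = [grade_value(v, DEFAULT_GRADING_RULES[a]) for a, v in base.items()]
        assert all(g == 0 for g in grades)


class TestSimulatePairedTn:
    def test_log_ratio_distribution(self, rng):
        df = simulate_paired_tn(4000, 1.17, 0.39, rng)
        lr = np.log(df["tn_ia"] / df["tn_control"])
        assert lr.mean() == pytest.approx(np.log(1.17), abs=3 * 0.39 / np.sqrt(4000))
        assert lr.std() == pytest.approx(0.39, rel=0.1)

    def test_null_symmetry_of_downstream_estimate(self, rng):
        """With no enhancement the estimated log-ratio is centred on zero
        over replicate cohorts."""
        from intralobe.stats import log_ratio_test
        means = []
        for _ in range(200):
            df = simulate_paired_tn(27, 1.0, 0.39, rng)
            means.append(np.log(log_ratio_test(df).geometric_ratio))
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) <= 3 * se


class TestGenerateCohort:
    def test_manifests_reproducible_and_consistent(self, tmp_path):
        cfg = small_config(n_patients=3, n_cycles=2, poisson_noise=True, seed=7)
        out1 = generate_cohort(cfg, tmp_path / "a")
        out2 = generate_cohort(cfg, tmp_path / "b")
        for name in ("randomization.csv", "lesions.csv", "diameters.csv",
                     "labs.csv", "transforms.csv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
        rand = pd.read_csv(out1 / "randomization.csv")
        assert len(rand) == 3
        for _, row in rand.iterrows():
            pdir = out1 / row["patient_id"]
            assert (pdir / "baseline.nii.gz").exists()
            for c in range(1, int(row["completed_cycles"]) + 1):
                assert (pdir / f"cycle_{c}.nii.gz").exists()

    def test_single_patient_dataset_valid_but_paired_test_refuses(self, tmp_path):
        from intralobe.stats import paired_t_test
        cfg = small_config(n_patients=1, seed=3)
        out = generate_cohort(cfg, tmp_path / "solo")
        rand = pd.read_csv(out / "randomization.csv")
        assert len(rand) == 1
        df = pd.DataFrame({"patient_id": ["P01"], "cycle": [1],
                           "tn_ia": [10.0], "tn_control": [9.0]})
        with pytest.raises(ValueError, match="at least 2"):
            paired_t_test(df)

    def test_dropout_pattern(self, tmp_path):
        cfg = small_config(n_patients=6, n_cycles=4, dropout=True, seed=11)
        out = generate_cohort(cfg, tmp_path / "d")
        completed = pd.read_csv(out / "randomization.csv")["completed_cycles"]
        assert sorted(completed)[:3] == [1, 1, 2]
        assert (completed.iloc[3:] <= 4).all()
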