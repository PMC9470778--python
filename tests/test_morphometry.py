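"""Shrinkage correction, artifact exclusion, lobule aggregation, fits, report."""

import numpy as np
import pytest
from scipy import stats

from laminamap.laminar_thickness import ThicknessMap, thickness_3d
from laminamap.morphometry import (GMMFitResult, LobuleRecord, ShrinkageFactor,
                                   build_report, correct_shrinkage,
                                   exclude_artifact_vertices, fit_gamma_mle,
                                   fit_gaussian_mixture, histogram_summary,
                                   lobule_statistics)
from laminamap.phantom_forge import (PhantomSpec, inject_erosion, make_folia_phantom,
                                     make_lobule_volume, make_shell_phantom)
from laminamap.surface_extract import extract_canonical_surfaces, voxel_volume
from laminamap.volume_io import GRANULAR, MOLECULAR

from .conftest import SHELL_SPEC


class TestShrinkage:
    def test_factor_identities_are_exact(self):
        f = ShrinkageFactor(1.245)
        assert f.area == 1.245 ** 2
        assert f.volume == 1.245 ** 3

    def test_published_cerebral_area_arithmetic(self):
        # 1,848 cm^2 corrected by 1.245^2 is printed as 2,864 cm^2
        corrected = correct_shrinkage(1848.0, ShrinkageFactor(1.245), 2)
        assert round(corrected) == 2864

    def test_identity_at_lambda_one(self):
        assert correct_shrinkage(123.4, ShrinkageFactor(1.0), 3) == 123.4

    def test_volume_correction(self):
        assert correct_shrinkage(100.0, ShrinkageFactor(1.245), 3) == pytest.approx(193.1, abs=0.2)

    def test_invalid_dimensionality_and_factor(self):
        with pytest.raises(ValueError, match="dimensionality"):
            correct_shrinkage(1.0, ShrinkageFactor(1.2), 4)
        with pytest.raises(ValueError, match=">= 1"):
            ShrinkageFactor(0.9)


class TestArtifactExclusion:
    def _map(self, values):
        from .conftest import icosphere
        mesh = icosphere(2)
        vals = np.resize(np.asarray(values, dtype=float), mesh.n_vertices)
        return ThicknessMap(carrier=mesh, thickness=vals,
                            valid=np.ones(mesh.n_vertices, dtype=bool))

    def test_epsilon_zero_excludes_nothing(self):
        tmap = self._map([0.0, 0.1, 0.5])
        out = exclude_artifact_vertices(tmap, 0.0)
        assert out.valid.all()

    def test_exact_zero_fraction_excluded(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.2, 0.5, 1000)
        vals[:100] = 0.0
        tmap = self._map(vals)
        out = exclude_artifact_vertices(tmap, 0.05)
        excluded = tmap.valid.sum() - out.valid.sum()
        assert excluded == (tmap.thickness < 0.05).sum()
        # retained values untouched
        assert np.array_equal(out.thickness, tmap.thickness)

    def test_exclusion_grows_with_erosion_fraction(self):
        spec = PhantomSpec(geometry_kind="folia-slab", granular_thickness=0.3,
                           molecular_thickness=0.3, fold_amplitude=0.25,
                           voxel_spacing=0.05, slab_base_height=0.6,
                           domain_extent=(3.6, 0.9, 1.6))
        volume, _ = make_folia_phantom(spec)
        excluded = []
        for fraction in (0.0, 0.25, 0.5):
            vol = inject_erosion(volume, fraction, seed=4) if fraction else volume
            meshes = extract_canonical_surfaces(vol)
            mol = thickness_3d(meshes["purkinje_surface"], meshes["pial_surface"])
            out = exclude_artifact_vertices(mol, epsilon=0.05)
            excluded.append(1 - out.valid.mean())
        assert excluded[0] <= excluded[1] <= excluded[2]
        assert excluded[2] > excluded[0]


class TestGammaFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        fit = fit_gamma_mle(rng.gamma(2.0, 0.4, 50_000))
        assert fit.shape == pytest.approx(2.0, rel=0.05)
        assert fit.scale == pytest.approx(0.4, rel=0.05)

    def test_exponential_special_case(self):
        rng = np.random.default_rng(0)
        fit = fit_gamma_mle(rng.exponential(0.5, 50_000))
        assert fit.shape == pytest.approx(1.0, rel=0.05)

    def test_recovery_across_seeds(self):
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            fit = fit_gamma_mle(rng.gamma(3.0, 0.25, 30_000))
            assert fit.shape == pytest.approx(3.0, rel=0.05)
            assert fit.scale == pytest.approx(0.25, rel=0.05)

    def test_matches_scipy_mle(self):
        """Independent cross-check: scipy's constrained MLE on the same data."""
        rng = np.random.default_rng(5)
        x = rng.gamma(1.7, 0.3, 20_000)
        fit = fit_gamma_mle(x)
        k_ref, _, theta_ref = stats.gamma.fit(x, floc=0)
        assert fit.shape == pytest.approx(k_ref, rel=1e-4)
        assert fit.scale == pytest.approx(theta_ref, rel=1e-4)

    def test_rejects_nonpositive_and_tiny_samples(self):
        with pytest.raises(ValueError, match="exclude"):
            fit_gamma_mle(np.r_[np.ones(50), 0.0])
        with pytest.raises(ValueError, match="30"):
            fit_gamma_mle(np.ones(10) + np.arange(10) * 0.1)


class TestGaussianMixture:
    def test_single_gaussian_recovery(self):
        rng = np.random.default_rng(0)
        fit = fit_gaussian_mixture(rng.normal(0.32, 0.08, 50_000))
        assert fit.chosen_k == 1
        assert fit.dominant_mean == pytest.approx(0.32, abs=0.01)
        assert fit.dominant_std == pytest.approx(0.08, abs=0.005)

    def test_erosion_spike_mixture(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0.30, 0.05, 45_000),
                            rng.normal(0.02, 0.01, 5_000)])
        fit = fit_gaussian_mixture(x)
        assert fit.chosen_k == 2
        assert fit.dominant_mean == pytest.approx(0.30, abs=0.01)

    def test_forced_single_component_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.3, 0.06, 5_000)
        fit = fit_gaussian_mixture(x, force_K=1)
        assert fit.dominant_mean == pytest.approx(x.mean(), abs=1e-9)
        assert fit.dominant_std == pytest.approx(x.std(), abs=1e-9)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gaussian_mixture(np.full(100, 0.3))


class TestHistogramSummary:
    def _map_from_values(self, values, subdivisions=4):
        from .conftest import icosphere
        mesh = icosphere(subdivisions)
        vals = np.resize(np.asarray(values, dtype=float), mesh.n_vertices)
        return ThicknessMap(carrier=mesh, thickness=vals,
                            valid=np.ones(mesh.n_vertices, dtype=bool))

    def test_constant_map(self):
        mode, (lo, hi) = histogram_summary(self._map_from_values([0.42]))
        assert mode == lo == hi == 0.42

    def test_gaussian_quantiles(self):
        rng = np.random.default_rng(0)
        # a large synthetic map: one normal draw per carrier vertex (n ~ 41k)
        tmap = self._map_from_values(rng.normal(0.3, 0.05, 40_962), subdivisions=6)
        mode, (lo, hi) = histogram_summary(tmap)
        assert mode == pytest.approx(0.3, abs=0.02)
        assert lo == pytest.approx(0.3 - 1.96 * 0.05, abs=0.02)
        assert hi == pytest.approx(0.3 + 1.96 * 0.05, abs=0.02)

    def test_too_few_vertices_rejected(self):
        from .conftest import icosphere
        mesh = icosphere(2)
        tmap = ThicknessMap(carrier=mesh, thickness=np.full(mesh.n_vertices, 1.0),
                            valid=np.zeros(mesh.n_vertices, dtype=bool))
        with pytest.raises(ValueError, match="100"):
            histogram_summary(tmap)


@pytest.fixture(scope="module")
def shell_stats(shell_phantom, shell_meshes, shell_granular_map, shell_molecular_map):
    volume, truth = shell_phantom
    lob = make_lobule_volume(volume, SHELL_SPEC)
    records, totals = lobule_statistics(
        shell_granular_map, shell_molecular_map, lob,
        shell_meshes["pial_surface"], volume)
    return volume, truth, records, totals


class TestLobuleStatistics:

    def test_uniform_thickness_in_both_hemispheric_lobules(self, shell_stats):
        _, truth, records, _ = shell_stats
        for r in records:
            assert r.granular_mean == pytest.approx(truth.layer_thickness["granular"], abs=0.02)
            assert r.granular_std <= 0.05
            assert r.molecular_mean == pytest.approx(truth.layer_thickness["molecular"], abs=0.02)

    def test_gm_volume_conservation_exact(self, shell_stats):
        volume, _, records, totals = shell_stats
        assert sum(r.gm_volume_mm3 for r in records) == totals.gm_volume_mm3
        assert totals.gm_volume_mm3 == voxel_volume(volume, {GRANULAR, MOLECULAR})

    def test_area_conservation_exact(self, shell_stats):
        _, _, records, totals = shell_stats
        assert sum(r.area_mm2 for r in records) == pytest.approx(totals.area_mm2, rel=1e-12)

    def test_pooled_mean_is_count_weighted_lobule_mean(self, shell_stats):
        _, _, records, totals = shell_stats
        weighted = (sum(r.granular_mean * r.n_granular_vertices for r in records)
                    / sum(r.n_granular_vertices for r in records))
        assert totals.granular_mean == pytest.approx(weighted, abs=1e-12)


class TestReport:
    def _records(self):
        rec = LobuleRecord(lobule_id=1, name="lobule_1", area_mm2=125576.0,
                           gm_volume_mm3=51252.0, granular_mean=0.88, granular_std=0.84,
                           molecular_mean=0.32, molecular_std=0.08,
                           n_granular_vertices=10, n_molecular_vertices=10)
        tot = LobuleRecord(lobule_id=0, name="Total", area_mm2=125576.0,
                           gm_volume_mm3=51252.0, granular_mean=0.88, granular_std=0.84,
                           molecular_mean=0.32, molecular_std=0.08,
                           n_granular_vertices=10, n_molecular_vertices=10)
        return [rec], tot

    def test_lambda_one_leaves_raw_values(self):
        records, totals = self._records()
        df = build_report(records, totals, ShrinkageFactor(1.0))
        assert (df["area_corrected_mm2"] == df["area_mm2"]).all()

    def test_corrected_area_column(self):
        records, totals = self._records()
        df = build_report(records, totals, ShrinkageFactor(1.245))
        corrected = df.loc[df["lobule"] == "Total", "area_corrected_mm2"].iloc[0]
        assert corrected == pytest.approx(125576.0 * 1.245 ** 2, rel=1e-12)
        # cross-check against the published corrected total, 1,945 cm^2
        assert corrected / 100.0 == pytest.approx(1945.0, rel=0.002)

    def test_totals_row_matches_records(self, shell_phantom, shell_meshes,
                                        shell_granular_map, shell_molecular_map):
        volume, _ = shell_phantom
        lob = make_lobule_volume(volume, SHELL_SPEC)
        records, totals = lobule_statistics(shell_granular_map, shell_molecular_map,
                                            lob, shell_meshes["pial_surface"], volume)
        df = build_report(records, totals, ShrinkageFactor(1.0))
        body = df[df["lobule"] != "Total"]
        total_row = df[df["lobule"] == "Total"].iloc[0]
        assert body["area_mm2"].sum() == pytest.approx(total_row["area_mm2"], rel=1e-12)
        assert body["gm_volume_mm3"].sum() == pytest.approx(total_row["gm_volume_mm3"], rel=1e-12)
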