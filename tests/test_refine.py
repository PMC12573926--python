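import numpy as np
import pytest

from ssxdamage.core import (
    Atom,
    ToyStructure,
    UnitCell,
    ROLE_FE,
    ROLE_PLANE,
    ROLE_WAT,
    ROLE_WAT_ALT,
    ROLE_WATX,
)
from ssxdamage.merging import mc_merge
from ssxdamage.refine import (
    RefinementOptions,
    UnderdeterminedError,
    _model_and_jacobian,
    _pack_parameters,
    calc_structure_factors,
    refine,
    refine_two_state_water,
    scramble,
)
from ssxdamage.synth import (
    GenerationRecipe,
    make_toy_structure,
    simulate_image_set,
    unique_hkls,
)


def _skeleton(cell=UnitCell(10.0, 10.0, 10.0)):
    """Minimal valid structure; non-FE atoms can be muted via occupancy 0."""
    atoms = [
        Atom("FE", "FE", ROLE_FE, (0.0, 0.0, 0.0)),
        Atom("N1", "N", ROLE_PLANE, (2.0, 0.0, 0.0), occupancy=0.0),
        Atom("N2", "N", ROLE_PLANE, (0.0, 2.0, 0.0), occupancy=0.0),
        Atom("N3", "N", ROLE_PLANE, (-2.0, 0.0, 0.0), occupancy=0.0),
    ]
    return ToyStructure(atoms, cell)


class TestStructureFactors:
    def test_single_atom_at_origin_flat_amplitude(self):
        s = _skeleton()
        hkls = np.array([[1, 0, 0], [2, 3, 1], [0, 0, 5], [-3, 1, -2]])
        F = calc_structure_factors(s, hkls)
        np.testing.assert_allclose(np.abs(F), 26.0, rtol=1e-12)

    def test_systematic_absence_two_atoms(self):
        s = _skeleton()
        s.atoms[0].occupancy = 0.0
        s.atoms[1].occupancy = 1.0
        s.atoms[2].occupancy = 1.0
        s.atoms[1].xyz = np.array([0.0, 0.0, 0.0])
        s.atoms[2].xyz = np.array([5.0, 0.0, 0.0])  # x = 1/2 in a 10 Å cell
        for h in (1, 3, 5):
            F = calc_structure_factors(s, np.array([[h, 0, 0]]))
            assert abs(F[0]) == pytest.approx(0.0, abs=1e-10)
        for h in (2, 4):
            F = calc_structure_factors(s, np.array([[h, 0, 0]]))
            assert abs(F[0]) == pytest.approx(14.0, rel=1e-10)

    def test_b_attenuation_closed_form(self):
        s = _skeleton()
        s.atoms[0].b_factor = 20.0
        cell = s.cell
        h1, h2 = np.array([[1, 0, 0]]), np.array([[3, 0, 0]])
        F1 = abs(calc_structure_factors(s, h1)[0])
        F2 = abs(calc_structure_factors(s, h2)[0])
        s1 = 1.0 / cell.d_spacing(h1.astype(float))[0] ** 2
        s2 = 1.0 / cell.d_spacing(h2.astype(float))[0] ** 2
        assert F2 / F1 == pytest.approx(np.exp(-20.0 * (s2 - s1) / 4.0), rel=1e-12)

    def test_atom_outside_sanity_bounds(self):
        s = _skeleton()
        s.atoms[0].xyz = np.array([200.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="sanity"):
            calc_structure_factors(s, np.array([[1, 0, 0]]))


class TestJacobian:
    def test_analytic_matches_finite_differences(self):
        s = make_toy_structure(2.45, 2.1, 0.3, seed=3, n_bystanders=3)
        for atom in s.atoms:
            atom.b_factor = 5.0
            atom.occupancy = 0.9
        hkls = unique_hkls(s.cell, 3.0).astype(float)
        s2 = 1.0 / s.cell.d_spacing(hkls) ** 2
        opts = RefinementOptions(refine_positions=True, refine_b=True,
                                 refine_occupancies=True)
        pos, bs, occs = _pack_parameters(s, opts)
        I0, J = _model_and_jacobian(s, hkls, s2, opts, pos, bs, occs)

        eps = 1e-6
        col = 0
        for j in pos:
            for axis in range(3):
                trial = s.copy()
                coords = trial.coordinates
                coords[j, axis] += eps
                trial.coordinates = coords
                I1, _ = _model_and_jacobian(trial, hkls, s2, opts, [], [], [])
                fd = (I1 - I0) / eps
                scale = np.abs(fd).max()
                np.testing.assert_allclose(J[:, col], fd, atol=1e-5 * scale)
                col += 1
        for j in bs:
            trial = s.copy()
            trial.atoms[j].b_factor += eps
            I1, _ = _model_and_jacobian(trial, hkls, s2, opts, [], [], [])
            fd = (I1 - I0) / eps
            np.testing.assert_allclose(J[:, col], fd,
                                       atol=1e-5 * max(np.abs(fd).max(), 1.0))
            col += 1
        for j in occs:
            trial = s.copy()
            trial.atoms[j].occupancy += eps
            I1, _ = _model_and_jacobian(trial, hkls, s2, opts, [], [], [])
            fd = (I1 - I0) / eps
            np.testing.assert_allclose(J[:, col], fd,
                                       atol=1e-5 * np.abs(fd).max())
            col += 1


class TestScramble:
    def test_zero_sd_identity(self, toy_structure):
        out = scramble(toy_structure, 0.0, seed=1)
        np.testing.assert_array_equal(out.coordinates, toy_structure.coordinates)

    def test_displacement_statistics(self, toy_structure):
        # mean |displacement| of N(0, sd² I₃) follows the Maxwell mean
        # sd·sqrt(8/π); oracle by direct Monte Carlo
        sd = 0.3
        disp = []
        for seed in range(400):
            out = scramble(toy_structure, sd, seed=seed)
            disp.extend(
                np.linalg.norm(out.coordinates - toy_structure.coordinates, axis=1)
            )
        rng = np.random.default_rng(77)
        oracle = np.linalg.norm(rng.normal(0, sd, (len(disp), 3)), axis=1)
        assert np.mean(disp) == pytest.approx(sd * np.sqrt(8 / np.pi), rel=0.02)
        assert np.mean(disp) == pytest.approx(np.mean(oracle), rel=0.02)

    def test_seed_reproducible(self, toy_structure):
        a = scramble(toy_structure, 0.3, seed=5)
        b = scramble(toy_structure, 0.3, seed=5)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)


class TestRefine:
    def test_start_at_truth_noiseless(self, toy_structure, noiseless_merged):
        result = refine(toy_structure, noiseless_merged,
                        RefinementOptions(max_iter=10))
        assert result.converged
        assert result.n_iter <= 2
        np.testing.assert_allclose(result.structure.coordinates,
                                   toy_structure.coordinates, atol=1e-8)

    def test_residual_non_increasing(self, toy_structure, noisy_merged):
        result = refine(toy_structure, noisy_merged,
                        RefinementOptions(scramble_sd=0.3, seed=2, max_iter=60))
        residuals = [r for _, r, _ in result.history]
        assert all(b <= a + 1e-9 for a, b in zip(residuals, residuals[1:]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_scrambled_noiseless_recovery(self, toy_structure,
                                          noiseless_merged, seed):
        # intensities are blind to a global origin shift in P1, so recovery
        # is asserted modulo the common translation
        result = refine(
            toy_structure, noiseless_merged,
            RefinementOptions(scramble_sd=0.3, seed=seed, max_iter=200,
                              convergence_tol=1e-14),
        )
        diff = result.structure.coordinates - toy_structure.coordinates
        aligned = diff - diff.mean(axis=0)
        assert np.abs(aligned).max() < 1e-3

    def test_underdetermined_rejected(self, toy_structure, simple_cell):
        from ssxdamage.merging import MergedDataset, MergedEntry
        tiny = MergedDataset(
            {(1, 0, 0): MergedEntry(10.0, 1.0, 2, 5.0)}, simple_cell, 1
        )
        with pytest.raises(UnderdeterminedError):
            refine(toy_structure, tiny, RefinementOptions())

    def test_noise_shrinks_with_image_count(self, toy_structure):
        def fe_wat_after_refit(n_images, seed):
            recipe = GenerationRecipe(
                n_images=n_images, reflections_per_image=0.5, noise_sd=0.3,
                scale_sd=0.2, seed=seed, resolution_limit=2.2,
            )
            merged = mc_merge(simulate_image_set(toy_structure, recipe))
            result = refine(toy_structure, merged,
                            RefinementOptions(scramble_sd=0.1, seed=seed))
            from ssxdamage.geometry import heme_report
            return heme_report(result.structure).fe_wat

        small = [fe_wat_after_refit(8, s) for s in range(10)]
        large = [fe_wat_after_refit(32, 100 + s) for s in range(10)]
        ratio = np.std(small) / np.std(large)
        assert ratio > 1.2  # expect ~2 with wide sampling slack

    def test_crlb_style_noise_floor(self, toy_structure):
        # linearized-covariance oracle: sandwich (JᵀJ)⁻¹JᵀΣJ(JᵀJ)⁻¹ at truth
        recipe_kw = dict(n_images=20, reflections_per_image=0.5, noise_sd=0.15,
                         scale_sd=0.0, resolution_limit=2.2)
        errors = []
        predicted = None
        for seed in range(12):
            merged = mc_merge(simulate_image_set(
                toy_structure, GenerationRecipe(**recipe_kw, seed=seed)
            ))
            result = refine(toy_structure, merged,
                            RefinementOptions(scramble_sd=0.1, seed=seed))
            diff = result.structure.coordinates - toy_structure.coordinates
            aligned = diff - diff.mean(axis=0)
            errors.append(np.abs(aligned).max())
            if predicted is None:
                hkls = np.array(sorted(merged.entries.keys()), dtype=float)
                sem = np.array([
                    merged.entries[tuple(int(v) for v in h)].sem_I for h in hkls
                ])
                sem = np.nan_to_num(sem, nan=np.nanmedian(sem))
                s2 = 1.0 / toy_structure.cell.d_spacing(hkls) ** 2
                opts = RefinementOptions()
                pos, bs, occs = _pack_parameters(toy_structure, opts)
                _, J = _model_and_jacobian(toy_structure, hkls, s2, opts,
                                           pos, bs, occs)
                jtj_inv = np.linalg.pinv(J.T @ J)
                cov = jtj_inv @ (J.T * sem**2) @ J @ jtj_inv
                predicted = np.sqrt(np.abs(np.diag(cov))).max()
        assert np.median(errors) < 4.0 * predicted
        assert np.median(errors) > 0.05 * predicted


@pytest.fixture(scope="module")
def two_state_structure():
    return make_toy_structure(2.45, 2.1, 0.3, seed=1, two_state_water=True)


class TestTwoStateWater:
    def _merged_at(self, structure, q, seed=3, noise_sd=0.0):
        truth = structure.copy()
        truth.atom(ROLE_WAT).occupancy = q
        truth.atom(ROLE_WAT_ALT).occupancy = 1.0 - q
        truth.atom(ROLE_WATX).occupancy = q
        recipe = GenerationRecipe(n_images=20, reflections_per_image=0.6,
                                  seed=seed, noise_sd=noise_sd,
                                  resolution_limit=2.0)
        return mc_merge(simulate_image_set(truth, recipe))

    def test_full_occupancy_recovered(self, two_state_structure):
        out = refine_two_state_water(
            two_state_structure, self._merged_at(two_state_structure, 1.0)
        )
        assert out["occ_pos1"] == pytest.approx(1.0, abs=1e-4)
        assert out["occ_pos2"] == pytest.approx(0.0, abs=1e-4)
        assert out["occ_watx"] == pytest.approx(1.0, abs=1e-4)

    def test_partial_occupancy_recovered(self, two_state_structure):
        out = refine_two_state_water(
            two_state_structure, self._merged_at(two_state_structure, 0.7)
        )
        assert out["occ_pos1"] == pytest.approx(0.7, abs=0.05)

    def test_monotone_dose_schedule(self, two_state_structure):
        schedule = [1.0, 0.85, 0.7, 0.55, 0.4]
        recovered = [
            refine_two_state_water(
                two_state_structure,
                self._merged_at(two_state_structure, q, seed=10 + i,
                                noise_sd=0.02),
            )["occ_pos1"]
            for i, q in enumerate(schedule)
        ]
        assert all(a > b for a, b in zip(recovered, recovered[1:]))

    def test_missing_alternative_position(self, toy_structure,
                                          noiseless_merged):
        from ssxdamage.core import GeometryError
        with pytest.raises(GeometryError):
            refine_two_state_water(toy_structure, noiseless_merged)
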