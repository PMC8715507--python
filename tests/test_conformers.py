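import numpy as np
import pytest

from conftest import karplus_like_coefficients
from jchi.circstats import circ_distance
from jchi.conformers import (
    ResidueCouplings,
    classify_residue,
    fit_ums,
    predict_couplings,
    rmsd_j_tot,
    tmss_populations,
    tmst_fit,
    ums_minima,
    ums_profile,
)
from jchi.errors import DegenerateProfileError, InvalidInputError
from jchi.karplus import FourierCoefficients, KarplusSet
from jchi.synth import GroundTruth, generate_residue


def single_coupling_residue(coeffs, chi1, coupling_id="HA-HB", rtype="VAL"):
    kset = KarplusSet(rtype, {coupling_id: coeffs})
    j = kset.evaluate_at_chi1(chi1, [coupling_id])[coupling_id]
    with pytest.warns(UserWarning, match="under-determined"):
        res = ResidueCouplings("X1", rtype, {coupling_id: j})
    return res, kset


def simplex_grid(resolution=0.001):
    p60 = np.arange(0.0, 1.0 + resolution / 2, resolution)
    g60, g180 = np.meshgrid(p60, p60, indexing="ij")
    mask = g60 + g180 <= 1.0 + 1e-12
    p = np.vstack(
        [g60[mask], g180[mask], 1.0 - g60[mask] - g180[mask]]
    )
    return p  # 3 x N points on the simplex


SIMPLEX_GRID = simplex_grid()


def grid_oracle_objective(a, y):
    """Brute-force minimum of ||y - A p||^2 / m over a 0.001 simplex grid."""
    g = a.T @ a
    h = a.T @ y
    q = np.einsum("ik,ij,jk->k", SIMPLEX_GRID, g, SIMPLEX_GRID)
    obj = q - 2.0 * h @ SIMPLEX_GRID + y @ y
    return float(obj.min() / len(y))


class TestUMSProfile:
    def test_noise_free_attains_zero(self, val_kset):
        res = generate_residue(GroundTruth(kset=val_kset, mode="pure", chi1=-65.0))
        profile = ums_profile(res, val_kset, step=0.5)
        assert profile.rmsd.min() == pytest.approx(0.0, abs=1e-9)
        assert profile.chi1[np.argmin(profile.rmsd)] == pytest.approx(-65.0)

    def test_covers_half_open_interval(self, val_kset):
        res = generate_residue(GroundTruth(kset=val_kset, mode="pure", chi1=0.0))
        profile = ums_profile(res, val_kset, step=0.5)
        assert profile.chi1[0] == pytest.approx(-179.5)
        assert profile.chi1[-1] == pytest.approx(180.0)
        assert len(profile.chi1) == 720

    def test_symmetric_single_coupling(self):
        coeffs = FourierCoefficients(c0=5.0, c1=-1.0, c2=4.0)  # even curve
        kset = KarplusSet("VAL", {"NP-CG1": coeffs})  # delta_theta = 0
        with pytest.warns(UserWarning):
            res = ResidueCouplings("X1", "VAL", {"NP-CG1": 3.0})
        profile = ums_profile(res, kset, step=0.5)
        # rmsd(chi) == rmsd(-chi)
        for chi in (10.0, 45.0, 90.0, 135.0):
            i = np.argmin(np.abs(profile.chi1 - chi))
            j = np.argmin(np.abs(profile.chi1 + chi))
            assert profile.rmsd[i] == pytest.approx(profile.rmsd[j], abs=1e-12)

    def test_brute_force_oracle(self, rng, val_kset):
        res = generate_residue(
            GroundTruth(kset=val_kset, mode="staggered", populations=(0.1, 0.6, 0.3))
        )
        profile = ums_profile(res, val_kset, step=5.0)
        for i in rng.choice(len(profile.chi1), size=10, replace=False):
            chi = profile.chi1[i]
            sq = [
                (res.measurements[c] - val_kset.evaluate_at_chi1(chi, [c])[c]) ** 2
                for c in res.coupling_ids
            ]
            assert profile.rmsd[i] == pytest.approx(float(np.sqrt(np.mean(sq))))

    def test_missing_coefficients_named(self, val_kset):
        partial = KarplusSet(
            "VAL", {"HA-HB": FourierCoefficients(c0=1.0)}
        )
        res = generate_residue(GroundTruth(kset=val_kset, mode="pure", chi1=60.0))
        with pytest.raises(Exception, match="HA-CG1"):
            ums_profile(res, partial, step=1.0)


class TestUMSMinima:
    def test_exact_recovery_nine_couplings(self, val_kset):
        res = generate_residue(GroundTruth(kset=val_kset, mode="pure", chi1=-65.0))
        result = fit_ums(res, val_kset, step=0.1)
        assert result.chi1 == pytest.approx(-65.0, abs=0.1)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_minima_sorted_by_rmsd(self, val_kset):
        res = generate_residue(GroundTruth(kset=val_kset, mode="pure", chi1=100.0))
        result = fit_ums(res, val_kset, step=0.2, prefer_staggered=False)
        rmsds = [m[1] for m in result.minima]
        assert rmsds == sorted(rmsds)

    def test_single_coupling_antipodal_degeneracy(self, rng):
        # the Karplus degeneracy: a second local minimum lies near chi1+180
        for _ in range(50):
            coeffs = karplus_like_coefficients(rng)
            chi1 = float(rng.uniform(-180, 180))
            res, kset = single_coupling_residue(coeffs, chi1)
            result = fit_ums(res, kset, step=0.1, prefer_staggered=False)
            assert len(result.minima) >= 2
            best = result.minima[0][0]
            others = [m[0] for m in result.minima[1:]]
            assert min(circ_distance(best + 180.0, o) for o in others) <= 40.0

    def test_second_minimum_preferred_when_staggered(self, val_kset):
        # global minimum off-staggered, second minimum near a staggered angle:
        # mirrors the documented second-minimum choices
        res = generate_residue(GroundTruth(kset=val_kset, mode="pure", chi1=178.0))
        profile = ums_profile(res, val_kset, step=0.1)
        # corrupt: shift profile so the global min moves off-staggered
        perturbed = ResidueCouplings(
            "X1",
            "VAL",
            {
                cid: 0.75 * v
                + 0.25 * val_kset.evaluate_at_chi1(100.0, [cid])[cid]
                for cid, v in res.measurements.items()
            },
        )
        result = fit_ums(perturbed, val_kset, step=0.1)
        forced = fit_ums(perturbed, val_kset, step=0.1, prefer_staggered=False)
        # the staggered-preferring selection never lands farther from a
        # staggered angle than the global minimum does
        stag = lambda a: min(circ_distance(a, s) for s in (60.0, 180.0, -60.0))
        assert stag(result.chi1) <= stag(forced.chi1)

    def test_uncertainty_grows_with_window(self, val_kset):
        res = generate_residue(GroundTruth(kset=val_kset, mode="pure", chi1=60.0))
        narrow = fit_ums(res, val_kset, step=0.1, uncertainty_window=0.1)
        wide = fit_ums(res, val_kset, step=0.1, uncertainty_window=0.4)
        assert wide.uncertainty[0] >= narrow.uncertainty[0]
        assert wide.uncertainty[1] >= narrow.uncertainty[1]

    def test_flat_profile_rejected(self):
        kset = KarplusSet("VAL", {"NP-CG1": FourierCoefficients(c0=2.0)})
        with pytest.warns(UserWarning):
            res = ResidueCouplings("X1", "VAL", {"NP-CG1": 3.0})
        with pytest.raises(DegenerateProfileError):
            fit_ums(res, kset, step=0.5)

    def test_coarse_profile_rejected(self, val_kset):
        res = generate_residue(GroundTruth(kset=val_kset, mode="pure", chi1=60.0))
        profile = ums_profile(res, val_kset, step=1.0)
        with pytest.raises(InvalidInputError):
            ums_minima(profile)


class TestTMSS:
    def test_interior_mixture_recovery(self, val_kset):
        truth = (0.2, 0.5, 0.3)
        res = generate_residue(
            GroundTruth(kset=val_kset, mode="staggered", populations=truth)
        )
        result = tmss_populations(res, val_kset)
        assert (result.p60, result.p180, result.pm60) == pytest.approx(
            truth, abs=1e-8
        )
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_vertex_solution(self, val_kset):
        res = generate_residue(GroundTruth(kset=val_kset, mode="pure", chi1=180.0))
        result = tmss_populations(res, val_kset)
        assert result.p180 == pytest.approx(1.0, abs=1e-8)
        assert result.dominant_angle == 180.0

    def test_populations_on_simplex(self, rng, val_kset):
        for _ in range(25):
            res = ResidueCouplings(
                "X1",
                "VAL",
                {cid: float(rng.uniform(-5, 12)) for cid in val_kset.coupling_ids},
            )
            result = tmss_populations(res, val_kset)
            p = np.array([result.p60, result.p180, result.pm60])
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(p >= 0.0)

    def test_grid_oracle(self, rng, val_kset):
        ids = val_kset.coupling_ids
        a = np.column_stack(
            [
                [val_kset.evaluate_at_chi1(s, ids)[c] for c in ids]
                for s in (60.0, 180.0, -60.0)
            ]
        )
        for _ in range(100):
            y = np.array(
                [rng.uniform(-4, 12) for _ in ids]
            )
            res = ResidueCouplings("X1", "VAL", dict(zip(ids, y)))
            result = tmss_populations(res, val_kset)
            oracle = grid_oracle_objective(a, y)
            # exact solver is never beaten by the grid, and the grid can
            # only overshoot by its own discretization error
            assert result.rmsd**2 <= oracle + 1e-9
            assert oracle - result.rmsd**2 <= 1e-3


class TestTMST:
    def test_pure_conformer_recovery(self, val_kset):
        res = generate_residue(GroundTruth(kset=val_kset, mode="pure", chi1=-65.0))
        result = tmst_fit(res, val_kset, step=0.1)
        assert result.chi1 == pytest.approx(-65.0, abs=0.1)
        assert result.max_population == pytest.approx(1.0, abs=1e-6)

    def test_nesting_under_staggered_mixture(self, val_kset):
        res = generate_residue(
            GroundTruth(kset=val_kset, mode="staggered", populations=(0.2, 0.5, 0.3))
        )
        tmss = tmss_populations(res, val_kset)
        tmst = tmst_fit(res, val_kset, step=0.1)
        assert tmst.rmsd <= tmss.rmsd + 1e-9
        assert circ_distance(tmst.chi1, 180.0) <= 0.11


    def test_nesting_on_noisy_residues(self, rng, val_kset):
        for seed in range(5):
            res = generate_residue(
                GroundTruth(
                    kset=val_kset,
                    mode="trigonal",
                    chi1=float(rng.uniform(-60, 60)),
                    populations=(0.5, 0.3, 0.2),
                    sigma=0.5,
                    seed=seed,
                )
            )
            ums = fit_ums(res, val_kset, step=0.5, prefer_staggered=False)
            tmss = tmss_populations(res, val_kset)
            tmst = tmst_fit(res, val_kset, step=0.5)
            assert tmst.rmsd <= tmss.rmsd + 1e-9
            assert tmst.rmsd <= ums.rmsd + 1e-9

    def test_trigonal_mixture_recovery(self, val_kset):
        truth_chi = -47.0
        res = generate_residue(
            GroundTruth(
                kset=val_kset,
                mode="trigonal",
                chi1=truth_chi,
                populations=(0.6, 0.25, 0.15),
            )
        )
        result = tmst_fit(res, val_kset, step=0.1)
        assert result.chi1 == pytest.approx(truth_chi, abs=0.1)
        assert result.rmsd == pytest.approx(0.0, abs=1e-8)

    def test_reported_chi1_is_most_populated(self, val_kset):
        res = generate_residue(
            GroundTruth(kset=val_kset, mode="staggered", populations=(0.1, 0.3, 0.6))
        )
        result = tmst_fit(res, val_kset, step=0.2)
        pops = [c[1] for c in result.conformers]
        assert result.conformers[0][0] == result.chi1
        assert pops[0] == max(pops)
        assert sum(pops) == pytest.approx(1.0, abs=1e-9)

    def test_trigonal_label_permutation_symmetry(self, val_kset):
        from jchi.conformers import TMSTResult

        res = generate_residue(
            GroundTruth(kset=val_kset, mode="staggered", populations=(0.2, 0.5, 0.3))
        )
        result = tmst_fit(res, val_kset, step=0.2)
        # describing the same solution from a different anchor conformer
        # (rotate the reported chi1 by 120, permute the conformer list)
        # leaves the predicted couplings, hence the objective, unchanged
        base = predict_couplings(result, val_kset, res.coupling_ids)
        permuted = result.conformers[1:] + result.conformers[:1]
        relabeled = TMSTResult(
            chi1=permuted[0][0], conformers=permuted, rmsd=result.rmsd
        )
        rotated = predict_couplings(relabeled, val_kset, res.coupling_ids)
        for cid in res.coupling_ids:
            assert rotated[cid] == pytest.approx(base[cid], abs=1e-12)


class TestClassification:
    def test_val7_like_unimodal(self):
        cls = classify_residue(_FakeUMS(-177.6), _FakeTMST((0.0, 0.86, 0.14)))
        assert cls.label == "unimodal"
        assert cls.dominant_bin == 180.0

    def test_val88_like_population_failure(self):
        cls = classify_residue(_FakeUMS(164.6), _FakeTMST((0.13, 0.47, 0.40)))
        assert cls.label == "trimodal"
        assert cls.staggered_test and not cls.population_test

    def test_leu78_like_double_failure(self):
        cls = classify_residue(_FakeUMS(100.2), _FakeTMST((0.26, 0.31, 0.43)))
        assert cls.label == "trimodal"
        assert not cls.staggered_test and not cls.population_test

    def test_boundary_inclusive_staggered(self):
        cls = classify_residue(_FakeUMS(90.0), _FakeTMST((0.7, 0.2, 0.1)))
        assert cls.staggered_test  # exactly 30 degrees from 60: kept

    def test_population_strictly_greater(self):
        cls = classify_residue(_FakeUMS(60.0), _FakeTMST((0.60, 0.25, 0.15)))
        assert not cls.population_test

    def test_tmss_population_source(self, val_kset):
        res = generate_residue(GroundTruth(kset=val_kset, mode="pure", chi1=60.0))
        ums = fit_ums(res, val_kset, step=0.2)
        tmss = tmss_populations(res, val_kset)
        tmst = tmst_fit(res, val_kset, step=0.2)
        cls = classify_residue(ums, tmst, tmss, population_source="tmss")
        assert cls.population_value == pytest.approx(tmss.max_population)


class _FakeUMS:
    def __init__(self, chi1):
        self.chi1 = chi1
        self.rmsd = 0.5


class _FakeTMST:
    def __init__(self, pops):
        angles = (60.0, 180.0, -60.0)
        conf = sorted(zip(angles, pops), key=lambda t: -t[1])
        self.conformers = tuple((a, p, a) for a, p in conf)
        self.chi1 = conf[0][0]
        self.max_population = conf[0][1]


class TestPredictAndGlobalRmsd:
    def test_ums_self_consistency(self, val_kset):
        res = generate_residue(GroundTruth(kset=val_kset, mode="pure", chi1=-65.0))
        ums = fit_ums(res, val_kset, step=0.1)
        pred = predict_couplings(ums, val_kset, res.coupling_ids)
        for cid in res.coupling_ids:
            assert pred[cid] == pytest.approx(res.measurements[cid], abs=0.05)

    def test_tmss_vertex_equals_single_angle(self, val_kset):
        from jchi.conformers import TMSSResult

        vertex = TMSSResult(p60=1.0, p180=0.0, pm60=0.0, rmsd=0.0)
        pred = predict_couplings(vertex, val_kset, val_kset.coupling_ids)
        direct = val_kset.evaluate_at_chi1(60.0)
        for cid in val_kset.coupling_ids:
            assert pred[cid] == pytest.approx(direct[cid])

    def test_mixture_linearity(self, rng, val_kset):
        from jchi.conformers import TMSSResult
        from jchi.karplus import FourierCoefficients, evaluate_karplus

        mix = TMSSResult(p60=0.2, p180=0.5, pm60=0.3, rmsd=0.0)
        pred = predict_couplings(mix, val_kset, val_kset.coupling_ids)
        for cid in val_kset.coupling_ids:
            coeffs = val_kset.coefficients(cid)
            dtheta = val_kset.topology[cid].delta_theta
            # coefficient-mixture evaluation == population-weighted curve
            expected = sum(
                p * evaluate_karplus(coeffs, chi + dtheta)
                for chi, p in ((60.0, 0.2), (180.0, 0.5), (-60.0, 0.3))
            )
            assert pred[cid] == pytest.approx(expected, abs=1e-12)

    def test_rmsd_j_tot_noise_free(self, val_kset):
        fitted = []
        for chi in (-65.0, 60.0, 175.0):
            res = generate_residue(GroundTruth(kset=val_kset, mode="pure", chi1=chi))
            fitted.append((res, fit_ums(res, val_kset, step=0.1), val_kset))
        value, m = rmsd_j_tot(fitted)
        assert value == pytest.approx(0.0, abs=0.05)
        assert m == 27

    def test_rmsd_j_tot_hand_arithmetic(self, val_kset):
        from jchi.conformers import TMSSResult

        ids = val_kset.coupling_ids[:4]
        base = val_kset.evaluate_at_chi1(60.0, ids)
        measurements = dict(base)
        first = next(iter(ids))
        measurements[first] += 1.0
        res = ResidueCouplings("X1", "VAL", measurements)
        vertex = TMSSResult(p60=1.0, p180=0.0, pm60=0.0, rmsd=0.0)
        value, m = rmsd_j_tot([(res, vertex, val_kset)])
        assert m == 4
        assert value == pytest.approx(0.5)

    def test_empty_collection(self):
        with pytest.raises(InvalidInputError):
            rmsd_j_tot([])
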