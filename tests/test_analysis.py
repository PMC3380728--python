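"""Analysis instruments: Kabsch lRMSD, ensemble summaries, the native-
minimum probe, perturbation statistics, correlations."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from plow.analysis import (
    AnalysisError,
    ProbeBudgetError,
    ensemble_summary,
    export_energy_vs_lrmsd,
    native_minimum_probe,
    pearson_correlation,
    perturbation_stats,
)
from plow.chain import Conformation, wrap_angle
from plow.fixtures import FixtureSpec, make_polyala, make_toy_landscape
from plow.search import MinimaEnsemble, MinimumRecord, SearchConfig, plow_run, naive_run
from plow.superpose import kabsch, lrmsd


def _random_conf(rng, n=10):
    chain = make_polyala(n)
    return Conformation(
        chain, np.array([wrap_angle(a) for a in rng.uniform(-179, 180, 2 * n)])
    )


def brute_force_lrmsd(P, Q):
    """Independent oracle: minimise RMSD over rotations by a coarse grid
    followed by local refinement of the rotation vector."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = P0 @ R.T - Q0
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    best = None
    grid = np.linspace(-np.pi, np.pi, 7)
    for a in grid:
        for b in grid:
            for c in grid:
                v = np.array([a, b, c])
                r = rmsd_of(v)
                if best is None or r < best[0]:
                    best = (r, v)
    res = minimize(rmsd_of, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return min(best[0], res.fun)


class TestLRMSD:
    def test_identity_is_zero(self, rng):
        conf = _random_conf(rng)
        assert lrmsd(conf, conf) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_is_zero(self, rng):
        conf = _random_conf(rng)
        moved = conf.copy()
        R = Rotation.random(random_state=1).as_matrix()
        moved._coords = conf.coords @ R.T + np.array([1.0, 2.0, 3.0])
        assert lrmsd(conf, moved) < 1e-6

    def test_symmetry(self, rng):
        a, b = _random_conf(rng), _random_conf(rng)
        assert abs(lrmsd(a, b) - lrmsd(b, a)) < 1e-9

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            P = rng.normal(size=(12, 3)) * 3.0
            Q = rng.normal(size=(12, 3)) * 3.0
            assert abs(lrmsd(P, Q) - brute_force_lrmsd(P, Q)) < 1e-3

    def test_rotation_is_proper(self, rng):
        a, b = _random_conf(rng), _random_conf(rng)
        res = kabsch(a.coords.reshape(-1, 3), b.coords.reshape(-1, 3))
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-9)

    def test_reflected_pair_not_matched_by_improper_rotation(self, rng):
        """Mirror images must not superpose to zero: only proper rotations
        are allowed."""
        conf = _random_conf(rng)
        mirrored = conf.coords.reshape(-1, 3).copy()
        mirrored[:, 2] *= -1
        assert lrmsd(conf.coords.reshape(-1, 3), mirrored) > 0.1

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            lrmsd(_random_conf(rng, 10), _random_conf(rng, 11))


def _record(conf, energy, step, accepted=True, greedy_length=5, perturb_distance=None):
    return MinimumRecord(
        conformation=conf,
        energy=energy,
        step_index=step,
        accepted=accepted,
        greedy_length=greedy_length,
        perturb_distance=perturb_distance,
    )


class TestEnsembleSummary:
    def test_single_record(self, rng):
        native = _random_conf(rng)
        other = _random_conf(rng)
        d = lrmsd(native, other)
        ens = MinimaEnsemble([_record(other, -1.0, 0)], SearchConfig(), 10, "plow")
        s = ensemble_summary([ens], native)
        assert s.min_lowest == pytest.approx(d)
        assert s.avg_lowest == pytest.approx(d)
        assert s.best_energy == -1.0

    def test_min_and_mean_aggregation(self, rng):
        native = _random_conf(rng)
        runs = []
        per_run_lowest = []
        for _ in range(2):
            confs = [_random_conf(rng) for _ in range(3)]
            runs.append(
                MinimaEnsemble(
                    [_record(c, float(i), i) for i, c in enumerate(confs)],
                    SearchConfig(), 10, "plow",
                )
            )
            per_run_lowest.append(min(lrmsd(native, c) for c in confs))
        s = ensemble_summary(runs, native)
        assert s.min_lowest == pytest.approx(min(per_run_lowest))
        assert s.avg_lowest == pytest.approx(np.mean(per_run_lowest))
        # permutation invariance
        s2 = ensemble_summary(runs[::-1], native)
        assert s2.min_lowest == s.min_lowest and s2.avg_lowest == s.avg_lowest

    def test_empty_inputs_rejected(self, rng):
        with pytest.raises(AnalysisError):
            ensemble_summary([], _random_conf(rng))


class TestPerturbationStats:
    def test_hand_computed_values(self, rng):
        conf = _random_conf(rng)
        records = [
            _record(conf, -1.0, 0),
            _record(conf, -2.0, 1, perturb_distance=0.5),
            _record(conf, -3.0, 2, perturb_distance=1.5),
        ]
        ens = MinimaEnsemble(records, SearchConfig(), 10, "plow")
        st = perturbation_stats(ens)
        assert st.mean_perturb_distance == pytest.approx(1.0)
        assert st.frac_below_1A == pytest.approx(0.5)
        assert st.n_perturbations == 2

    def test_consecutive_distance_replay(self):
        """The mean consecutive-minima distance equals an independent replay
        over the accepted trajectory conformations."""
        model, lib, _ = make_toy_landscape(FixtureSpec(n_residues=12, n_basins=3, seed=1))
        ens = plow_run(lib.target_chain, model, lib, SearchConfig(budget=3000, seed=5))
        st = perturbation_stats(ens)
        accepted = [r.conformation for r in ens.records if r.accepted]
        expected = np.mean(
            [lrmsd(a, b) for a, b in zip(accepted[:-1], accepted[1:])]
        )
        assert st.mean_consecutive_minima_distance == pytest.approx(float(expected))

    def test_naive_ensemble_rejected(self):
        model, lib, _ = make_toy_landscape(FixtureSpec(n_residues=12, n_basins=3, seed=1))
        ens = naive_run(lib.target_chain, model, lib, SearchConfig(budget=1000, seed=5))
        with pytest.raises(AnalysisError):
            perturbation_stats(ens)

    def test_degenerate_perturbations(self, rng):
        conf = _random_conf(rng)
        records = [_record(conf, -1.0, 0)] + [
            _record(conf, -1.0, i, perturb_distance=0.0) for i in range(1, 4)
        ]
        st = perturbation_stats(MinimaEnsemble(records, SearchConfig(), 5, "plow"))
        assert st.mean_perturb_distance == 0.0
        assert st.frac_below_1A == 1.0


class TestNativeMinimumProbe:
    def test_zero_when_native_is_strict_minimum(self):
        model, lib, cat = make_toy_landscape(FixtureSpec(n_residues=12, n_basins=3, seed=1))
        deepest = min(cat, key=lambda n: cat[n])
        native = model.node_conformation(deepest)
        d = native_minimum_probe(
            native, model, lib, n_restarts=3, iterations=300,
            rng=np.random.default_rng(0),
        )
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_min_over_restarts(self):
        """The probe reports the minimum of the per-restart distances."""
        model, lib, cat = make_toy_landscape(FixtureSpec(n_residues=12, n_basins=4, seed=1))
        # start from a non-minimum: the probe maps it into some basin
        native = model.node_conformation((1, 0, 0, 0))
        rng = np.random.default_rng(3)
        d = native_minimum_probe(native, model, lib, n_restarts=5, iterations=200, rng=rng)
        singles = []
        rng = np.random.default_rng(3)
        for _ in range(5):
            singles.append(
                native_minimum_probe(native, model, lib, 1, 200, rng)
            )
        assert d == pytest.approx(min(singles))

    def test_budget_exhaustion_raises(self):
        model, lib, _ = make_toy_landscape(FixtureSpec(n_residues=12, n_basins=3, seed=1))
        model.budget = 50
        with pytest.raises(ProbeBudgetError):
            native_minimum_probe(
                model.node_conformation((0,) * 4), model, lib, 2, 1000,
                np.random.default_rng(0),
            )


class TestPearson:
    def test_perfect_correlations(self):
        xs = [1.0, 2.0, 3.0, 5.0]
        assert pearson_correlation(xs, xs) == pytest.approx(1.0)
        assert pearson_correlation(xs, [-x for x in xs]) == pytest.approx(-1.0)

    def test_textbook_five_points(self):
        xs = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        ys = np.array([2.0, 1.0, 5.0, 3.0, 9.0])
        sx, sy = xs - xs.mean(), ys - ys.mean()
        expected = float(np.sum(sx * sy) / np.sqrt(np.sum(sx**2) * np.sum(sy**2)))
        assert pearson_correlation(xs, ys) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(AnalysisError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short(self):
        with pytest.raises(AnalysisError):
            pearson_correlation([1.0, 2.0], [1.0, 2.0])


class TestExportScatter:
    def test_row_count_and_best_energy(self, tmp_path, rng):
        import pandas as pd

        native = _random_conf(rng)
        ens = []
        total = 0
        for n_rec in (3, 5):
            records = [_record(_random_conf(rng), -float(i), i) for i in range(n_rec)]
            ens.append(MinimaEnsemble(records, SearchConfig(), 10, "plow"))
            total += n_rec
        path = tmp_path / "scatter.tsv"
        df = export_energy_vs_lrmsd(ens, native, path)
        assert len(df) == total
        reread = pd.read_csv(path, sep="\t")
        assert len(reread) == total
        assert reread["energy"].min() == min(e.best_energy for e in ens)
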