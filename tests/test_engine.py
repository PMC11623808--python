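"""Monte-Carlo engine: neutral laws, closed-form checks, reproducibility,
establishment bookkeeping and the diffusible-resource mode."""

import math

import numpy as np
import pytest

from ecograph import EcoEvoParams
from ecograph.ecology import NoEquilibriumError, fitness_table
from ecograph.engine import (
    SimulationConfig,
    diffusible_fitness,
    diffusible_steady_state,
    estimate_fixation,
    moran_run,
)
from ecograph.exact import constant_selection_fixation, wellmixed_fixation
from ecograph.graphs import PopulationGraph, complete_graph, star_graph


def _within(est, se, truth, k=3):
    return abs(est - truth) <= k * se + 1e-12


class TestWellMixedMode:
    def test_neutral_law_across_graphs(self, small_graphs):
        for name, g in small_graphs.items():
            N = g.n_nodes
            p = EcoEvoParams(N=N, s=0.0, alpha=0.5)
            est = estimate_fixation(g, p, SimulationConfig(replicates=20_000, seed=1))
            assert _within(est.p_fix, est.se_fix, 1.0 / N), name

    def test_classical_moran_closed_form(self):
        p = EcoEvoParams(N=50, s=0.02, alpha=0.5)
        est = estimate_fixation(
            complete_graph(50), p, SimulationConfig(replicates=60_000, seed=2)
        )
        assert _within(est.p_fix, est.se_fix, constant_selection_fixation(50, 0.02))

    def test_master_seed_reproducibility(self):
        p = EcoEvoParams(N=30, s=-0.01, alpha=0.7)
        g = star_graph(30)
        cfg = SimulationConfig(replicates=5_000, seed=42, track_establishment=True)
        a = estimate_fixation(g, p, cfg)
        b = estimate_fixation(g, p, cfg)
        assert a == b

    def test_product_identity_on_sample(self):
        p = EcoEvoParams(N=40, s=-0.005, alpha=0.75)
        cfg = SimulationConfig(replicates=20_000, seed=3, track_establishment=True)
        est = estimate_fixation(complete_graph(40), p, cfg)
        assert est.p_fix == pytest.approx(est.p_est * est.p_cfix, abs=1e-12)
        # x* sits just below 1/2 for a weakly deleterious mutant -> ceil = N/2
        assert est.establishment_count == 20

    def test_establishment_undefined_without_ecology(self):
        p = EcoEvoParams(N=20, s=0.01, alpha=0.5)
        cfg = SimulationConfig(replicates=10, seed=1, track_establishment=True)
        with pytest.raises(NoEquilibriumError):
            estimate_fixation(complete_graph(20), p, cfg)

    def test_truncation_counted_not_silently_dropped(self):
        p = EcoEvoParams(N=30, s=0.0, alpha=0.9)  # strong pull to equilibrium
        cfg = SimulationConfig(replicates=200, seed=4, max_steps=50)
        est = estimate_fixation(complete_graph(30), p, cfg)
        assert est.truncated > 0
        assert est.replicates_used + est.truncated == 200

    def test_single_run_record(self):
        p = EcoEvoParams(N=15, s=0.0, alpha=0.7)
        cfg = SimulationConfig(replicates=1, seed=0, track_establishment=True)
        rec = moran_run(star_graph(15), p, cfg, seed=9)
        assert rec.outcome in {"fixation", "loss"}
        assert rec.steps >= 1
        if rec.established:
            assert rec.establishment_step is not None
            assert rec.establishment_step <= rec.steps

    def test_fixation_time_grows_with_niche_separation(self):
        # stronger frequency dependence deepens the interior well
        g = complete_graph(30)
        times = []
        for alpha in (0.5, 0.8):
            p = EcoEvoParams(N=30, s=0.0, alpha=alpha)
            est = estimate_fixation(g, p, SimulationConfig(replicates=8_000, seed=6))
            times.append(est.t_unconditional)
        assert times[1] > times[0]


class TestDiffusibleResources:
    def test_uniform_occupancy_flat_concentrations(self):
        g = star_graph(10)
        p = EcoEvoParams(N=10, s=0.0, alpha=0.7)
        field = diffusible_steady_state(g, np.zeros(10, dtype=int), p, D=2.5)
        assert np.allclose(field.concentrations[0], 0.5 / 0.3)
        assert np.allclose(field.concentrations[1], 0.5 / 0.7)

    def test_three_node_path_against_dense_oracle(self):
        import scipy.linalg

        g = PopulationGraph(__import__("networkx").path_graph(3))
        p = EcoEvoParams(N=3, s=0.0, alpha=0.8)
        occ = np.array([0, 1, 0])
        field = diffusible_steady_state(g, occ, p, D=1.0)
        L = np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1]], dtype=float)
        for i, (aw, am) in enumerate(zip(p.wt.alphas, p.mut.alphas)):
            alpha_vec = np.where(occ == 1, am, aw)
            expected = scipy.linalg.solve(L + np.diag(alpha_vec), np.full(3, 0.5))
            assert np.allclose(field.concentrations[i], expected, atol=1e-12)

    def test_large_diffusion_recovers_wellmixed_fitness(self):
        g = star_graph(20)
        p = EcoEvoParams(N=20, s=-0.004, alpha=0.8)
        occ = np.zeros(20, dtype=int)
        occ[[0, 3, 7]] = 1
        field = diffusible_steady_state(g, occ, p, D=1e4)
        f = diffusible_fitness(field, occ, p)
        expected_ratio = fitness_table(p)[3]
        assert f[0] / f[1] == pytest.approx(expected_ratio, rel=1e-3)
        # per-type fitness nearly flat at large D
        assert np.ptp(f[occ == 1]) / f[occ == 1].mean() < 1e-3

    def test_no_ecology_fitness_is_occupancy_only(self):
        g = star_graph(8)
        p = EcoEvoParams(N=8, s=0.02, alpha=0.5)
        occ = np.array([1, 0, 0, 1, 0, 0, 0, 0])
        field = diffusible_steady_state(g, occ, p, D=0.7)
        f = diffusible_fitness(field, occ, p)
        assert np.allclose(f[occ == 1] / f[occ == 0].mean(), 1.02, rtol=1e-9)

    def test_large_d_matches_wellmixed_process(self):
        """D >= 100 reproduces the well-mixed-resource fixation probability
        within Monte-Carlo error on an amplifier graph."""
        N = 20
        g = star_graph(N)
        p = EcoEvoParams(N=N, s=-0.005, alpha=0.7)
        d = estimate_fixation(
            g, p, SimulationConfig(replicates=4_000, seed=12, resource_mode="diffusible", D=100.0)
        )
        wm = estimate_fixation(g, p, SimulationConfig(replicates=40_000, seed=13))
        se = math.hypot(d.se_fix, wm.se_fix)
        assert abs(d.p_fix - wm.p_fix) <= 3 * se

    def test_rank_one_update_consistent_with_full_solve(self):
        """A replacement changes the consumption diagonal at one node; the
        Sherman-Morrison update of the inverse must track a from-scratch
        solve to well below the steady-state residual tolerance."""
        rng = np.random.default_rng(0)
        N = 15
        g = star_graph(N)
        p = EcoEvoParams(N=N, s=-0.005, alpha=0.8)
        D = 5.0
        L = g.laplacian().toarray().astype(float)
        occ = np.zeros(N, dtype=int)
        occ[2] = 1
        a_wt, a_mut = np.asarray(p.wt.alphas), np.asarray(p.mut.alphas)
        for i in range(2):
            alpha_vec = np.where(occ == 1, a_mut[i], a_wt[i])
            inv = np.linalg.inv(D * L + np.diag(alpha_vec))
            work = occ.copy()
            for _ in range(60):  # random walk of replacement events
                node = int(rng.integers(N))
                new_t = 1 - work[node]
                delta = (a_mut[i] - a_wt[i]) if new_t == 1 else (a_wt[i] - a_mut[i])
                work[node] = new_t
                col = inv[:, node]
                inv = inv - np.outer(col, inv[node, :]) * (
                    delta / (1.0 + delta * col[node])
                )
                alpha_vec = np.where(work == 1, a_mut[i], a_wt[i])
                fresh = np.linalg.solve(D * L + np.diag(alpha_vec), np.full(N, 0.5))
                assert np.abs(inv @ np.full(N, 0.5) - fresh).max() < 1e-8
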