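import numpy as np
import pytest
from scipy.optimize import nnls

from glioresponse.cnmf import (
    SpectrumMatrix,
    fit_convex_nmf,
    match_sources,
    project,
    select_tumor_spectra,
    stack_spectra,
)
from glioresponse.datatypes import MRSIGrid, SliceRecord


def _grid_record(mask_blocks, grid=4, block=4, L=32, subject="S000"):
    """Record with a grid x grid MRSI grid of block x block pixel blocks;
    the mask covers exactly the listed (row, col) blocks."""
    n = grid * block
    ppm = np.linspace(4.5, 0.5, L)
    block_map = np.empty((grid, grid, 4), dtype=np.int64)
    spectra = np.zeros((grid, grid, L))
    rng = np.random.default_rng(0)
    for r in range(grid):
        for c in range(grid):
            block_map[r, c] = (r * block, (r + 1) * block,
                               c * block, (c + 1) * block)
            spectra[r, c] = rng.uniform(0, 1, L)
    mask = np.zeros((n, n), dtype=bool)
    for r, c in mask_blocks:
        mask[r * block:(r + 1) * block, c * block:(c + 1) * block] = True
    g = MRSIGrid(dims=(grid, grid), spectra=spectra, ppm_axis=ppm,
                 block_map=block_map)
    return SliceRecord(subject_id=subject, slice_index=0, label="control",
                       image=np.zeros((n, n)), mask=mask, grid=g)


class TestSelectTumorSpectra:
    def test_full_mask_selects_all(self):
        rec = _grid_record([(r, c) for r in range(4) for c in range(4)])
        sm = select_tumor_spectra(rec)
        assert sm.n == 16

    def test_partial_block_not_selected(self):
        rec = _grid_record([(0, 0)])
        rec.mask[0, 0] = False  # chip one pixel off the block
        rec.mask[15, 15] = True  # keep mask nonempty elsewhere (partial block)
        with pytest.warns(UserWarning):
            sm = select_tumor_spectra(rec)
        assert sm.n == 0

    def test_central_3x3(self):
        blocks = [(r, c) for r in range(1, 4) for c in range(1, 4)]
        rec = _grid_record(blocks)
        sm = select_tumor_spectra(rec)
        assert sm.n == 9
        # row-major order over the grid
        assert [rid[2:] for rid in sm.row_ids] == sorted(blocks)

    def test_row_ids_carry_identity(self):
        rec = _grid_record([(2, 3)], subject="S042")
        sm = select_tumor_spectra(rec)
        assert sm.row_ids == [("S042", 0, 2, 3)]


class TestFitConvexNMF:
    def test_exact_factorization(self, sources3):
        X = np.repeat(sources3.profiles, 10, axis=0)
        ss = fit_convex_nmf(X, K=3, seed=0)
        assert ss.final_error < 1e-6
        _, cos = match_sources(ss.F, sources3.profiles)
        assert (cos >= 0.999).all()

    def test_error_monotone_every_iteration(self, sources3):
        rng = np.random.default_rng(1)
        H = rng.dirichlet(np.ones(3), size=60)
        X = H @ sources3.profiles + rng.normal(0, 0.05, (60, 256))
        ss = fit_convex_nmf(X, K=3, seed=0)
        diffs = np.diff(ss.error_log)
        assert (diffs <= 1e-9).all()

    def test_nonnegativity(self, sources3):
        rng = np.random.default_rng(2)
        H = rng.dirichlet(np.ones(3), size=50)
        X = H @ sources3.profiles + rng.normal(0, 0.05, (50, 256))
        ss = fit_convex_nmf(X, K=3, seed=0)
        assert (ss.W >= 0).all()
        assert (ss.G >= 0).all()

    def test_default_k_is_20(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (60, 64))
        ss = fit_convex_nmf(X, seed=0, max_iter=5, polish=False)
        assert ss.K == 20
        assert ss.F.shape[0] == 20

    def test_noisy_recovery(self, sources3):
        rng = np.random.default_rng(4)
        H = rng.dirichlet(np.ones(3), size=300)
        X = H @ sources3.profiles + rng.normal(0, 0.05, (300, 256))
        ss = fit_convex_nmf(X, K=3, seed=0)
        _, cos = match_sources(ss.F, sources3.profiles)
        assert cos.mean() >= 0.95

    def test_seeded_determinism(self, sources3):
        rng = np.random.default_rng(5)
        X = rng.dirichlet(np.ones(3), size=40) @ sources3.profiles
        a = fit_convex_nmf(X, K=3, seed=7)
        b = fit_convex_nmf(X, K=3, seed=7)
        assert np.array_equal(a.F, b.F)
        assert a.error_log == b.error_log

    def test_k_exceeds_n_fails(self):
        with pytest.raises(ValueError):
            fit_convex_nmf(np.ones((3, 64)), K=5)

    def test_nonfinite_fails(self):
        X = np.ones((5, 64))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_convex_nmf(X, K=2)

    def test_projected_training_matches_g(self, sources3):
        """Projecting the training spectra approximates the fitted G."""
        rng = np.random.default_rng(6)
        H = rng.dirichlet(np.ones(3), size=150)
        X = H @ sources3.profiles + rng.normal(0, 0.02, (150, 256))
        ss = fit_convex_nmf(X, K=3, seed=0)
        W = project(X, ss)
        cos = []
        for g, w in zip(ss.G, W):
            ng, nw = np.linalg.norm(g), np.linalg.norm(w)
            if ng > 0 and nw > 0:
                cos.append(g @ w / (ng * nw))
        assert np.mean(cos) >= 0.95


class TestProject:
    def _simple_sources(self, sources3):
        X = np.repeat(sources3.profiles, 5, axis=0)
        return fit_convex_nmf(X, K=3, seed=0)

    def test_pure_source_gets_all_mass(self, sources3):
        ss = self._simple_sources(sources3)
        w = project(ss.F[2][None, :], ss)[0]
        assert w[2] == pytest.approx(1.0, abs=1e-6)
        assert all(w[k] <= 1e-8 for k in (0, 1))

    def test_zero_spectrum(self, sources3):
        ss = self._simple_sources(sources3)
        w = project(np.zeros((1, 256)), ss)
        assert (w == 0).all()

    def test_homogeneity(self, sources3):
        ss = self._simple_sources(sources3)
        x = sources3.profiles[0][None, :]
        w1 = project(x, ss)
        w2 = project(2 * x, ss)
        np.testing.assert_allclose(w2, 2 * w1, atol=1e-8)

    def test_matches_nnls_oracle_small_k(self, sources3):
        """Active-set enumeration oracle for K<=3: try every support,
        solve unconstrained LS, keep feasible minimizer."""
        from itertools import combinations

        ss = self._simple_sources(sources3)
        rng = np.random.default_rng(7)
        x = rng.dirichlet(np.ones(3)) @ sources3.profiles
        w_impl = project(x[None, :], ss)[0]

        A = ss.F.T
        best, best_res = None, np.inf
        for k in range(0, 4):
            for sup in combinations(range(3), k):
                if not sup:
                    w = np.zeros(3)
                else:
                    sol, *_ = np.linalg.lstsq(A[:, sup], x, rcond=None)
                    if (sol < -1e-12).any():
                        continue
                    w = np.zeros(3)
                    w[list(sup)] = sol
                res = np.linalg.norm(A @ w - x)
                if res < best_res - 1e-12:
                    best, best_res = w, res
        np.testing.assert_allclose(w_impl, best, atol=1e-6)

    def test_axis_mismatch_fails(self, sources3):
        ss = self._simple_sources(sources3)
        sm = SpectrumMatrix(X=np.ones((1, 256)), row_ids=[("a", 0, 0, 0)],
                            ppm_axis=np.linspace(9.0, 1.0, 256))
        with pytest.raises(ValueError, match="ppm axis"):
            project(sm, ss)


class TestStackSpectra:
    def test_stack_preserves_rows(self):
        ppm = np.linspace(4.5, 0.5, 16)
        a = SpectrumMatrix(np.ones((2, 16)), [("a", 0, 0, 0), ("a", 0, 0, 1)], ppm)
        b = SpectrumMatrix(np.zeros((1, 16)), [("b", 0, 0, 0)], ppm)
        s = stack_spectra([a, b])
        assert s.n == 3
        assert s.row_ids[2] == ("b", 0, 0, 0)
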