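"""Correction algorithms: hand recursions, oracles, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tartes import (
    AngioVolume,
    StructuralVolume,
    GridMismatchError,
    MsaParams,
    ParameterError,
    SdefParams,
    TarTesParams,
    TransmittanceProfile,
    estimate_transmittance,
    mean_subtract_correct,
    sdef_correct,
    sdef_linearized,
    tartes_correct,
    tartes_correct_full,
)

from conftest import (
    column_angio,
    column_structural,
    make_grid,
    random_angio,
    random_structural,
)


# ---------------------------------------------------------------------------
# Independent oracles: per-voxel pure-Python recursions straight from the
# defining formulas, re-summing the prefix at every layer.
# ---------------------------------------------------------------------------

def tartes_pervoxel_oracle(a, s, w1):
    out = np.array(a, dtype=float)
    nz, ny, nx = a.shape
    for y in range(ny):
        for x in range(nx):
            for n in range(1, nz):
                acc = sum(out[i, y, x] ** 2 for i in range(n))
                val = a[n, y, x] - w1 * s[n, y, x] * math.sqrt(acc)
                out[n, y, x] = max(val, 0.0)
    return out


def msa_pervoxel_oracle(a, w2):
    out = np.empty_like(a)
    nz, ny, nx = a.shape
    for y in range(ny):
        for x in range(nx):
            baseline = (w2 / nz) * sum(a[i, y, x] for i in range(nz))
            for n in range(nz):
                out[n, y, x] = max(a[n, y, x] - baseline, 0.0)
    return out


def sdef_pervoxel_oracle(a, w3):
    out = np.array(a, dtype=float)
    nz, ny, nx = a.shape
    for y in range(ny):
        for x in range(nx):
            for n in range(1, nz):
                acc = sum(out[i, y, x] for i in range(n))
                out[n, y, x] = a[n, y, x] * math.exp(-w3 * acc)
    return out


class TestHandRecursions:
    def test_tartes_worked_column(self):
        A = column_angio([4.0, 3.0, 5.0])
        S = column_structural([1.0, 1.0, 2.0])
        out = tartes_correct(A, S, TarTesParams(w1=0.5))
        expected = [4.0, 1.0, 5.0 - math.sqrt(17.0)]
        np.testing.assert_allclose(out.values.ravel(), expected, atol=1e-12)

    def test_tartes_clipping_column(self):
        A = column_angio([2.0, 1.0])
        S = column_structural([1.0, 5.0])
        out = tartes_correct(A, S, TarTesParams(w1=1.0))
        np.testing.assert_allclose(out.values.ravel(), [2.0, 0.0], atol=1e-12)
        assert out.meta["provenance"]["clipped_voxels"] == 1

    def test_tartes_full_reduces_to_simple_at_unit_T(self):
        A = column_angio([4.0, 3.0, 5.0])
        S = column_structural([1.0, 1.0, 2.0])
        T = TransmittanceProfile(np.ones(3))
        simple = tartes_correct(A, S, TarTesParams(w1=0.5))
        full = tartes_correct_full(A, S, TarTesParams(w1=0.5), T)
        np.testing.assert_array_equal(simple.values, full.values)

    def test_tartes_full_worked_column_with_attenuation(self):
        A = column_angio([4.0, 3.0])
        S = column_structural([1.0, 1.0])
        T = TransmittanceProfile(np.array([1.0, 0.5]))
        out = tartes_correct_full(A, S, TarTesParams(w1=0.5), T)
        # layer 1: 3 - 0.5*(1/0.5)*sqrt(16/1) = -1 -> clips to 0
        np.testing.assert_allclose(out.values.ravel(), [4.0, 0.0], atol=1e-12)

    def test_lower_transmittance_strengthens_correction(self, rng):
        A = random_angio(rng, shape=(10, 3, 3), scale=5.0)
        S = random_structural(rng, shape=(10, 3, 3), scale=1.0)
        params = TarTesParams(w1=0.05)
        t_weak = TransmittanceProfile(np.ones(10))
        halved = np.ones(10)
        halved[1:] = 0.5
        t_strong = TransmittanceProfile(halved)
        weak = tartes_correct_full(A, S, params, t_weak)
        strong = tartes_correct_full(A, S, params, t_strong)
        assert np.all(strong.values[1:] <= weak.values[1:] + 1e-12)

    def test_msa_worked_column(self):
        out = mean_subtract_correct(column_angio([4.0, 0.0, 2.0]), MsaParams(w2=3.0))
        np.testing.assert_allclose(out.values.ravel(), [0.0, 0.0, 0.0], atol=1e-12)

    def test_msa_constant_column_vanishes_at_unit_weight(self):
        out = mean_subtract_correct(column_angio([7.0, 7.0, 7.0]), MsaParams(w2=1.0))
        assert np.all(out.values == 0.0)

    def test_sdef_worked_column(self):
        out = sdef_correct(column_angio([2.0, 3.0]), SdefParams(w3=0.5))
        np.testing.assert_allclose(out.values.ravel(), [2.0, 3.0 * math.exp(-1.0)],
                                   atol=1e-12)

    def test_sdef_linearized_worked_column(self):
        out = sdef_linearized(column_angio([2.0, 3.0]), SdefParams(w3=0.5))
        np.testing.assert_allclose(out.values.ravel(), [2.0, 0.0], atol=1e-12)

    def test_sdef_all_zero_column(self):
        out = sdef_correct(column_angio([0.0, 0.0, 0.0]), SdefParams(w3=0.5))
        assert np.all(out.values == 0.0)


class TestZeroWeightIdentity:
    def test_all_correctors(self, rng):
        A = random_angio(rng, shape=(12, 4, 4))
        S = random_structural(rng, shape=(12, 4, 4))
        for out in (
            tartes_correct(A, S, TarTesParams(w1=0.0)),
            mean_subtract_correct(A, MsaParams(w2=0.0)),
            sdef_correct(A, SdefParams(w3=0.0)),
            sdef_linearized(A, SdefParams(w3=0.0)),
        ):
            np.testing.assert_array_equal(out.values, A.values)


class TestOracleEquivalence:
    def test_pervoxel_python_oracles(self, rng):
        a = rng.uniform(0, 10, (8, 3, 4))
        s = rng.uniform(0, 2, (8, 3, 4))
        grid = make_grid(8, 3, 4)
        A = AngioVolume(grid=grid, values=a)
        S = StructuralVolume(grid=grid, values=s)
        got = tartes_correct(A, S, TarTesParams(w1=0.3)).values
        np.testing.assert_allclose(got, tartes_pervoxel_oracle(a, s, 0.3), rtol=1e-10)
        got = mean_subtract_correct(A, MsaParams(w2=1.7)).values
        np.testing.assert_allclose(got, msa_pervoxel_oracle(a, 1.7), rtol=1e-10)
        got = sdef_correct(A, SdefParams(w3=0.05)).values
        np.testing.assert_allclose(got, sdef_pervoxel_oracle(a, 0.05), rtol=1e-10)


nonneg_volumes = hnp.arrays(
    dtype=np.float64,
    shape=st.tuples(st.integers(2, 6), st.integers(1, 4), st.integers(1, 4)),
    elements=st.floats(0.0, 10.0, allow_nan=False),
)


class TestInvariants:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(values=nonneg_volumes, w=st.floats(0.0, 2.0))
    def test_dominance_and_nonnegativity(self, values, w):
        """Corrected <= uncorrected elementwise, never negative, grid preserved."""
        grid = make_grid(*values.shape)
        A = AngioVolume(grid=grid, values=values)
        S = StructuralVolume(grid=grid, values=np.ones_like(values))
        for out in (
            tartes_correct(A, S, TarTesParams(w1=w)),
            mean_subtract_correct(A, MsaParams(w2=w)),
            sdef_correct(A, SdefParams(w3=w)),
        ):
            assert np.all(out.values >= 0.0)
            assert np.all(out.values <= A.values + 1e-12)
            assert out.grid == grid

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(values=nonneg_volumes, w=st.floats(0.0, 2.0))
    def test_layer0_invariance(self, values, w):
        """TAR-TES and SDEF leave the shallowest layer bit-identical;
        Mean-Subtraction lowers it whenever the baseline is positive."""
        grid = make_grid(*values.shape)
        A = AngioVolume(grid=grid, values=values)
        S = StructuralVolume(grid=grid, values=np.ones_like(values))
        assert np.array_equal(tartes_correct(A, S, TarTesParams(w1=w)).values[0], values[0])
        assert np.array_equal(sdef_correct(A, SdefParams(w3=w)).values[0], values[0])
        msa = mean_subtract_correct(A, MsaParams(w2=w)).values[0]
        assert np.all(msa <= values[0] + 1e-12)

    def test_sdef_strictly_positive_where_input_positive(self, rng):
        A = random_angio(rng, shape=(20, 4, 4))
        out = sdef_correct(A, SdefParams(w3=5.0))
        assert np.all(out.values[A.values > 0] > 0.0)

    def test_inputs_not_mutated(self, rng):
        A = random_angio(rng, shape=(8, 3, 3))
        S = random_structural(rng, shape=(8, 3, 3))
        a0, s0 = A.values.copy(), S.values.copy()
        tartes_correct(A, S, TarTesParams(w1=0.5))
        mean_subtract_correct(A, MsaParams(w2=1.0))
        sdef_correct(A, SdefParams(w3=0.5))
        np.testing.assert_array_equal(A.values, a0)
        np.testing.assert_array_equal(S.values, s0)


class TestSdefLinearizedLimit:
    def test_gap_shrinks_quadratically(self, rng):
        """Relative gap between exact and linearized SDEF drops ~100x per
        10x weight decrease on a fixed bounded volume."""
        A = random_angio(rng, shape=(16, 6, 5), scale=1.0)
        gaps = []
        for w3 in (1e-2, 1e-3, 1e-4):
            exact = sdef_correct(A, SdefParams(w3)).values
            lin = sdef_linearized(A, SdefParams(w3)).values
            pos = A.values > 0
            gaps.append(np.max(np.abs(exact - lin)[pos] / exact[pos]))
        assert 80 < gaps[0] / gaps[1] < 120
        assert 80 < gaps[1] / gaps[2] < 120


class TestTransmittanceEstimate:
    def test_zero_structural_gives_unit_transmittance(self):
        S = column_structural([0.0, 0.0, 0.0, 0.0])
        T = estimate_transmittance(S, w1=0.1)
        assert np.all(T.values == 1.0)

    def test_hand_recursion(self):
        S = column_structural([2.0, 1.0, 0.5])
        T = estimate_transmittance(S, w1=0.1)
        t1 = 1.0 - 0.1 * 2.0 / 1.0          # 0.8
        t2 = t1 - 0.1 * 1.0 / t1            # 0.675
        np.testing.assert_allclose(T.values.ravel(), [1.0, t1, t2], atol=1e-12)

    def test_nonincreasing_with_depth(self, rng):
        S = random_structural(rng, shape=(12, 3, 3), scale=0.5)
        T = estimate_transmittance(S, w1=0.05)
        assert np.all(np.diff(T.values, axis=0) <= 1e-12)

    def test_floor_clamp_warns(self):
        S = column_structural([50.0, 50.0, 50.0])
        with pytest.warns(RuntimeWarning, match="clamped"):
            T = estimate_transmittance(S, w1=0.5)
        assert T.values.min() == pytest.approx(1e-3)

    def test_requires_positive_w1(self):
        with pytest.raises(ParameterError):
            estimate_transmittance(column_structural([1.0]), w1=0.0)


class TestValidation:
    def test_negative_weights_rejected(self):
        for cls in (lambda: TarTesParams(w1=-0.1),
                    lambda: MsaParams(w2=-1.0),
                    lambda: SdefParams(w3=-0.5)):
            with pytest.raises(ParameterError):
                cls()

    def test_grid_mismatch_rejected(self, rng):
        A = random_angio(rng, shape=(8, 3, 3))
        S = random_structural(rng, shape=(8, 3, 4))
        with pytest.raises(GridMismatchError):
            tartes_correct(A, S, TarTesParams(w1=0.1))

    def test_transmittance_domain(self):
        with pytest.raises(ParameterError):
            TransmittanceProfile(np.array([1.0, 0.0]))  # T must stay positive
        with pytest.raises(ParameterError):
            TransmittanceProfile(np.array([0.9, 0.8]))  # layer 0 must be 1

    def test_provenance_recorded(self, rng):
        A = random_angio(rng, shape=(6, 2, 2))
        S = random_structural(rng, shape=(6, 2, 2))
        out = tartes_correct(A, S, TarTesParams(w1=0.2))
        prov = out.meta["provenance"]
        assert prov["method"] == "tartes"
        assert prov["w1"] == 0.2
        assert prov["n_voxels"] == A.values.size
        assert 0 <= prov["clipped_voxels"] <= A.values.size
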