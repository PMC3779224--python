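"""Orientation reconstruction: tensor fit, DSI/QBI/CSA ODFs, peak extraction."""

import numpy as np
import pytest

from qconn.phantom import DWIDataset, simulate_dwi
from qconn.reconstruct import (
    ODFField,
    csa_odf,
    default_sh_order,
    dsi_odf,
    extract_peaks,
    fa_adc,
    fit_tensor,
    qbi_odf,
    tensor_peaks,
)
from qconn.schemes import QSample, QScheme, uniform_sphere_scheme
from qconn.tessellation import icosphere

from conftest import axial_error_deg

TESS_EDGE_DEG = 12.0  # one tessellation edge at subdivision 3


def isotropic_dataset(truth, scheme, diffusivity=0.7e-3, S0=100.0):
    """Same masks as the phantom, but a purely isotropic signal everywhere."""
    att = np.exp(-scheme.bvals * diffusivity)
    sig = S0 * att[None, None, None, :] * np.ones(truth.wm_mask.shape + (1,))
    return DWIDataset(sig, scheme, truth.voxel_size, truth.wm_mask, truth.roi_labels)


def wm_voxel(truth):
    idx = np.argwhere(truth.wm_mask)
    return tuple(idx[len(idx) // 2])


def crossing_voxel(truth):
    idx = np.argwhere(truth.n_dirs == 2)
    return tuple(idx[len(idx) // 2])


class TestTensor:
    def test_exact_recovery_on_noiseless_data(self, straight_truth, dti_scheme):
        """Log-linear LSQ is exact on consistent noiseless data."""
        dwi = simulate_dwi(straight_truth, dti_scheme)
        tf = fit_tensor(dwi)
        D_true = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        wm = straight_truth.wm_mask
        assert np.allclose(tf.tensors[wm], D_true, rtol=1e-9, atol=1e-15)

    def test_isotropic_signal_gives_isotropic_tensor(self, straight_truth, dti_scheme):
        dwi = isotropic_dataset(straight_truth, dti_scheme)
        tf = fit_tensor(dwi)
        fa, adc = fa_adc(tf)
        wm = straight_truth.wm_mask
        assert np.allclose(fa[wm], 0.0, atol=1e-9)
        assert np.allclose(adc[wm], 0.7e-3, rtol=1e-9)

    def test_b0_only_scheme_rejected(self, straight_truth):
        b0 = QSample((0, 0, 0), 0, (0, 0, 0), True)
        g = (1.0, 0.0, 0.0)
        few = QScheme(
            [b0, QSample(g, 1000.0, g, False)], "shell", 1000.0
        )
        with pytest.raises(ValueError, match="insufficient|rank"):
            fit_tensor(simulate_dwi(straight_truth, few))

    def test_fa_adc_values(self, straight_truth, dti_scheme):
        """Eigenvalues (1.7, 0.3, 0.3)e-3 give FA = 0.7990, ADC = 0.7667e-3."""
        tf = fit_tensor(simulate_dwi(straight_truth, dti_scheme))
        fa, adc = fa_adc(tf)
        wm = straight_truth.wm_mask
        assert np.allclose(fa[wm], 0.7990222, atol=1e-6)
        assert np.allclose(adc[wm], 0.76666667e-3, rtol=1e-9)

    def test_principal_direction(self, straight_truth, dti_scheme):
        tf = fit_tensor(simulate_dwi(straight_truth, dti_scheme))
        pk = tensor_peaks(tf)
        wm = straight_truth.wm_mask
        assert np.all(pk.counts[wm] == 1)
        for v in pk.vectors[wm][:, 0]:
            assert axial_error_deg(v, (1, 0, 0)) < 1e-6

    def test_oblique_principal_direction(self, crossing_truth, dti_scheme):
        """Voxels seen only by the second (y-axis) bundle point along y."""
        tf = fit_tensor(simulate_dwi(crossing_truth, dti_scheme))
        pk = tensor_peaks(tf)
        only_b2 = (
            (crossing_truth.n_dirs == 1)
            & (np.abs(crossing_truth.directions[..., 0, 1]) > 0.99)
        )
        assert np.any(only_b2)
        for v in pk.vectors[only_b2][:, 0]:
            assert axial_error_deg(v, (0, 1, 0)) < 1e-6

    def test_isotropic_tensor_flagged_degenerate(self, straight_truth, dti_scheme):
        tf = fit_tensor(isotropic_dataset(straight_truth, dti_scheme))
        pk = tensor_peaks(tf)
        wm = straight_truth.wm_mask
        assert np.all(pk.counts[wm] == 1)
        assert np.all(pk.degenerate[wm])


class TestDsiOdf:
    def test_single_fiber_argmax_near_truth(self, straight_dsi, straight_truth, tess):
        odf = dsi_odf(straight_dsi, tess)
        v = wm_voxel(straight_truth)
        best = tess.vertices[np.argmax(odf.values[v])]
        assert axial_error_deg(best, (1, 0, 0)) <= TESS_EDGE_DEG

    def test_isotropic_odf_nearly_flat(self, straight_truth, dsi_scheme, tess):
        odf = dsi_odf(isotropic_dataset(straight_truth, dsi_scheme), tess)
        vals = odf.values[wm_voxel(straight_truth)]
        assert vals.std() / vals.mean() < 0.02

    def test_crossing_resolved_into_two_peaks(self, crossing_dsi, crossing_truth, tess):
        odf = dsi_odf(crossing_dsi, tess)
        pk = extract_peaks(odf)
        v = crossing_voxel(crossing_truth)
        assert pk.counts[v] == 2
        errs = sorted(
            min(axial_error_deg(pk.vectors[v][i], ax) for ax in ((1, 0, 0), (0, 1, 0)))
            for i in range(2)
        )
        assert errs[1] <= TESS_EDGE_DEG

    def test_wrong_scheme_kind_rejected(self, straight_qbi, tess):
        with pytest.raises(ValueError, match="cartesian"):
            dsi_odf(straight_qbi, tess)

    def test_antipodal_symmetry(self, straight_dsi, straight_truth, tess):
        odf = dsi_odf(straight_dsi, tess)
        vals = odf.values[straight_truth.wm_mask]
        assert np.allclose(vals, vals[:, tess.antipode], atol=1e-6)


class TestQbiOdf:
    def test_single_fiber_argmax_near_truth(self, straight_qbi, straight_truth, tess):
        odf = qbi_odf(straight_qbi, tess)
        v = wm_voxel(straight_truth)
        best = tess.vertices[np.argmax(odf.values[v])]
        assert axial_error_deg(best, (1, 0, 0)) <= TESS_EDGE_DEG

    def test_isotropic_odf_constant(self, straight_truth, qbi_scheme, tess):
        """The Funk-Radon transform of a constant is constant."""
        odf = qbi_odf(isotropic_dataset(straight_truth, qbi_scheme), tess)
        vals = odf.values[wm_voxel(straight_truth)]
        assert (vals.max() - vals.min()) / vals.mean() < 0.01

    def test_60_degree_crossing_two_peaks(self, tess, qbi_scheme):
        from qconn.phantom import PhantomConfig, build_phantom

        truth = build_phantom(
            PhantomConfig(geometry="crossing", angle=60.0, grid_shape=(20, 20, 8))
        )
        odf = qbi_odf(simulate_dwi(truth, qbi_scheme), tess)
        pk = extract_peaks(odf)
        v = crossing_voxel(truth)
        assert pk.counts[v] == 2
        axes = ((1, 0, 0), (0.5, np.sqrt(3) / 2, 0))
        for i in range(2):
            assert min(axial_error_deg(pk.vectors[v][i], ax) for ax in axes) <= 15.0

    def test_insufficient_directions_error_names_feasible_order(self):
        sch = uniform_sphere_scheme(21, 3000, seed=0)
        from qconn.phantom import PhantomConfig, build_phantom

        truth = build_phantom(
            PhantomConfig(geometry="straight", grid_shape=(12, 8, 8))
        )
        with pytest.raises(ValueError, match="order"):
            qbi_odf(simulate_dwi(truth, sch), sh_order=8)
        assert default_sh_order(20) == 4
        assert default_sh_order(256) == 8


class TestCsaOdf:
    def test_single_fiber_argmax_near_truth(self, straight_qbi, straight_truth, tess):
        odf = csa_odf(straight_qbi, tess)
        v = wm_voxel(straight_truth)
        best = tess.vertices[np.argmax(odf.values[v])]
        assert axial_error_deg(best, (1, 0, 0)) <= TESS_EDGE_DEG

    def test_sharper_than_standard_qball(self, straight_qbi, straight_truth, tess):
        v = wm_voxel(straight_truth)
        q = qbi_odf(straight_qbi, tess).values[v].astype(float)
        c = csa_odf(straight_qbi, tess).values[v].astype(float)
        assert (c.max() - c.min()) / c.mean() > (q.max() - q.min()) / q.mean()

    def test_isotropic_odf_constant(self, straight_truth, qbi_scheme, tess):
        odf = csa_odf(isotropic_dataset(straight_truth, qbi_scheme), tess)
        vals = odf.values[wm_voxel(straight_truth)]
        assert (vals.max() - vals.min()) / abs(vals.mean()) < 0.01


class TestExtractPeaks:
    def _field(self, tess, values):
        shape = (1, 1, 1, tess.n_vertices)
        return ODFField(
            values.reshape(shape).astype(np.float32),
            tess,
            "dsi",
            np.ones((1, 1, 1), bool),
            np.ones(3),
        )

    def test_delta_odf_single_axial_peak(self, tess):
        vals = np.zeros(tess.n_vertices)
        vals[0] = vals[tess.antipode[0]] = 1.0
        pk = extract_peaks(self._field(tess, vals))
        assert pk.counts[0, 0, 0] == 1
        assert axial_error_deg(pk.vectors[0, 0, 0, 0], tess.vertices[0]) < 1e-9

    def test_constant_odf_zero_peaks(self, tess):
        pk = extract_peaks(self._field(tess, np.ones(tess.n_vertices)))
        assert pk.counts[0, 0, 0] == 0

    def test_max_peaks_cap(self, tess):
        # three well-separated lobes + cap at 2
        vals = np.zeros(tess.n_vertices)
        for axis in np.eye(3):
            i = int(np.argmax(tess.vertices @ axis))
            vals[i] = vals[tess.antipode[i]] = 1.0
        pk = extract_peaks(self._field(tess, vals), max_peaks=2)
        assert pk.counts[0, 0, 0] == 2
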