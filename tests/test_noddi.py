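"""Watson-NODDI forward model and fitter: closed forms, quadrature oracle,
parameter recovery, and the fraction-sum identity."""

import numpy as np
import pytest

from edematrack.exceptions import ParameterError, SchemeError
from edematrack.io_formats import GradientScheme, ImageGrid
from edematrack.noddi import (
    NoddiModel,
    NoddiParams,
    fit_noddi,
    forward_signal,
    kappa_from_odi,
    odi_from_kappa,
    watson_stick_signal,
    watson_tau1,
)
from edematrack.phantom import make_protocol


class TestOdi:
    def test_known_values(self):
        assert odi_from_kappa(1.0) == pytest.approx(0.5, abs=1e-12)
        assert odi_from_kappa(0.01) == pytest.approx(0.9936, abs=1e-4)

    def test_limit_and_monotonicity(self):
        ks = np.logspace(-2, 3, 50)
        odis = odi_from_kappa(ks)
        assert np.all(np.diff(odis) < 0)
        assert odi_from_kappa(1e8) < 1e-7

    def test_domain_error(self):
        with pytest.raises(ParameterError):
            odi_from_kappa(0.0)

    def test_inverse(self):
        for k in (0.05, 0.5, 4.0, 40.0):
            assert kappa_from_odi(odi_from_kappa(k)) == pytest.approx(k, rel=1e-12)


def _dense_sphere_oracle(bd, c, kappa, n=300):
    """Brute-force spherical quadrature of the Watson stick average
    (fine Gauss-Legendre x azimuth product grid, ~1.8e5 nodes)."""
    t, w = np.polynomial.legendre.leggauss(n)
    phi = (np.arange(2 * n) + 0.5) * np.pi / n
    s = np.sqrt(1 - c**2)
    st = np.sqrt(1 - t**2)
    gn = c * t[:, None] + s * st[:, None] * np.cos(phi)[None, :]
    wd = np.exp(kappa * (t[:, None] ** 2 - 1)) * w[:, None] / (2 * n)
    return (wd * np.exp(-bd * gn**2)).sum() / (np.exp(kappa * (t**2 - 1)) * w).sum()


class TestWatson:
    @pytest.mark.parametrize("kappa", [0.1, 1.0, 4.0, 16.0, 64.0])
    def test_matches_dense_spherical_quadrature(self, kappa):
        for c in (0.0, 0.35, 0.8, 1.0):
            for bd in (1.7, 3.4):
                ours = watson_stick_signal(bd, c, kappa)
                ref = _dense_sphere_oracle(bd, c, kappa)
                assert abs(ours - ref) / ref < 1e-6

    def test_tau1_limits(self):
        assert watson_tau1(1e-6) == pytest.approx(1.0 / 3.0, abs=1e-6)
        assert watson_tau1(500.0) > 0.99


class TestForward:
    def test_pure_free_water(self, protocol):
        p = NoddiParams(viso=1.0, vic=0.0, kappa=1.0, mu=[0, 0, 1])
        sig = forward_signal(p, protocol)
        b1000 = np.isclose(protocol.bvals, 1000)
        np.testing.assert_allclose(sig[b1000], np.exp(-3.0), rtol=1e-12)

    def test_b0_normalization(self, protocol):
        p = NoddiParams(viso=0.3, vic=0.5, kappa=2.0, mu=[1, 0, 0])
        sig = forward_signal(p, protocol)
        np.testing.assert_allclose(sig[protocol.b0_mask], 1.0)

    def test_coherent_stick_perpendicular_unattenuated(self):
        scheme = GradientScheme([0.0, 1000.0], [[0, 0, 0], [1, 0, 0]])
        p = NoddiParams(viso=0.0, vic=1.0, kappa=5e4, mu=[0, 0, 1])
        sig = forward_signal(p, scheme)
        assert sig[1] == pytest.approx(1.0, abs=1e-3)

    def test_signals_bounded(self, protocol, rng):
        for _ in range(20):
            mu = rng.standard_normal(3)
            p = NoddiParams(
                viso=rng.uniform(0, 1), vic=rng.uniform(0, 1),
                kappa=np.exp(rng.uniform(np.log(0.01), np.log(64))), mu=mu,
            )
            sig = forward_signal(p, protocol)
            assert np.all(sig > 0) and np.all(sig <= 1 + 1e-12)


def _fit_voxels(params_list, scheme, snr=None, seed=0, **kw):
    rng = np.random.default_rng(seed)
    n = len(params_list)
    data = np.empty((n, 1, 1, len(scheme)))
    for i, p in enumerate(params_list):
        sig = forward_signal(p, scheme)
        if snr is not None:
            s = 1.0 / snr
            sig = np.sqrt((sig + s * rng.standard_normal(sig.shape)) ** 2
                          + (s * rng.standard_normal(sig.shape)) ** 2)
        data[i, 0, 0] = sig
    init = np.stack([p.mu for p in params_list])[:, None, None, :]
    return fit_noddi(ImageGrid(data, np.eye(4)), scheme, init_orientations=init, **kw)


class TestFit:
    def test_noise_free_recovery(self, protocol):
        """Noise-free phantom voxels recover (viso, vic) and ODI within 0.02."""
        truths = [
            NoddiParams(viso=0.05, vic=0.6, kappa=16.0, mu=[0, 0, 1]),
            NoddiParams(viso=0.55, vic=0.6, kappa=16.0, mu=[0.2, 0.1, 0.97]),
            NoddiParams(viso=0.1, vic=0.4, kappa=0.5, mu=[1, 0, 0]),
        ]
        res = _fit_voxels(truths, protocol)
        for i, p in enumerate(truths):
            assert res.viso[i, 0, 0] == pytest.approx(p.viso, abs=0.02)
            assert res.vic_tissue[i, 0, 0] == pytest.approx(p.vic, abs=0.02)
            assert res.odi[i, 0, 0] == pytest.approx(p.odi, abs=0.02)

    def test_noise_free_pure_csf(self, protocol):
        res = _fit_voxels([NoddiParams(viso=1.0, vic=0.0, kappa=1.0, mu=[0, 0, 1])], protocol)
        assert res.viso[0, 0, 0] >= 0.99

    def test_fraction_sum_identity(self, protocol, rng):
        truths = [
            NoddiParams(viso=rng.uniform(0, 1), vic=rng.uniform(0, 1),
                        kappa=np.exp(rng.uniform(np.log(0.05), np.log(50))),
                        mu=rng.standard_normal(3))
            for _ in range(5)
        ]
        res = _fit_voxels(truths, protocol, snr=30)
        m = res.fitted
        total = res.vf_ic[m] + res.vf_ec[m] + res.vf_iso[m]
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_odi_monotone_on_kappa_ladder(self, protocol):
        """Raising ground-truth concentration lowers fitted ODI (noise-free)."""
        ladder = [0.5, 2.0, 8.0, 32.0]
        truths = [NoddiParams(viso=0.1, vic=0.5, kappa=k, mu=[0, 0, 1]) for k in ladder]
        res = _fit_voxels(truths, protocol)
        fitted = [res.odi[i, 0, 0] for i in range(len(ladder))]
        assert np.all(np.diff(fitted) < 0)

    def test_dead_voxel_flagged(self, protocol):
        data = np.zeros((1, 1, 1, len(protocol)))
        res = fit_noddi(ImageGrid(data, np.eye(4)), protocol,
                        init_orientations=np.zeros((1, 1, 1, 3)))
        assert not res.fitted[0, 0, 0]

    def test_single_shell_rejected(self):
        bvals = np.concatenate([[0.0], np.full(30, 1000.0)])
        rng = np.random.default_rng(0)
        vecs = rng.standard_normal((31, 3))
        vecs[0] = 0
        vecs[1:] /= np.linalg.norm(vecs[1:], axis=1, keepdims=True)
        scheme = GradientScheme(bvals, vecs)
        with pytest.raises(SchemeError):
            NoddiModel(ImageGrid(np.ones((1, 1, 1, 31)), np.eye(4)), scheme)


class TestPhantomRecovery:
    def test_orientation_recovered_in_bundle_including_edema(self, phantom_run):
        """Fitted Watson axis within 10 deg of truth in bundle voxels at
        SNR 30 — the property that makes dispersion-based tracking work."""
        gt, res = phantom_run.gt, phantom_run.noddi
        for region in ("bundle", "edematous_bundle"):
            from edematrack.phantom import LABELS

            m = (gt.labels == LABELS[region]) & res.fitted
            dot = np.abs(np.sum(res.mu[m] * gt.mu[m], axis=1))
            ang = np.degrees(np.arccos(np.clip(dot, 0, 1)))
            assert np.median(ang) < 10.0, region
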