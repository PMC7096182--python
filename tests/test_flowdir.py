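import numpy as np
import pytest

from ripplemap import synthio
from ripplemap.core import grid_atlas
from ripplemap.flowdir import (
    CircularSample,
    circular_mean_deg,
    direction_distribution,
    flow_angle,
    horn_schunck,
    kuiper_two_sample,
    resultant_length,
    shuffled_direction_null,
)


def circular_error(a, b):
    return abs((a - b + 180.0) % 360.0 - 180.0)


class TestHornSchunck:
    def test_static_frames_zero_flow(self):
        frames = np.tile(np.random.default_rng(0).standard_normal((8, 8)),
                         (4, 1, 1))
        flow = horn_schunck(frames, n_iter=50)
        assert np.max(np.abs(flow.u)) < 1e-9
        assert np.max(np.abs(flow.v)) < 1e-9

    def test_translated_gradient_recovered(self):
        # linear ramp translated 1 px/frame along columns: u ~= 1, v ~= 0
        cols = np.arange(32, dtype=float)
        frames = np.stack([np.tile(cols - k, (32, 1)) for k in range(5)])
        flow = horn_schunck(frames, n_iter=200)
        interior = (slice(None), slice(8, 24), slice(8, 24))
        assert flow.u[interior].mean() == pytest.approx(1.0, rel=0.1)
        assert abs(flow.v[interior].mean()) < 0.1

    def test_transpose_swaps_components(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((16, 16))
        frames = np.stack([np.roll(base, k, axis=1) for k in range(4)])
        f1 = horn_schunck(frames, n_iter=80)
        f2 = horn_schunck(frames.transpose(0, 2, 1), n_iter=80)
        assert np.allclose(f1.u, f2.v.transpose(0, 2, 1), atol=1e-8)
        assert np.allclose(f1.v, f2.u.transpose(0, 2, 1), atol=1e-8)

    def test_nonfinite_rejected(self):
        frames = np.zeros((3, 4, 4))
        frames[1, 2, 2] = np.inf
        with pytest.raises(ValueError):
            horn_schunck(frames)

    def test_angle_convention(self):
        assert flow_angle(1.0, 0.0) == 0.0  # lateral
        assert flow_angle(0.0, -1.0) == 90.0  # anterior = up the rows
        assert flow_angle(-1.0, 0.0) == 180.0  # medial
        assert flow_angle(0.0, 1.0) == 270.0  # posterior


class TestCircularSample:
    def test_angles_wrapped(self):
        cs = CircularSample(np.array([-10.0, 370.0]))
        assert np.allclose(cs.angles, [350.0, 10.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            CircularSample(np.array([]))

    def test_resultant_of_concentrated_sample(self):
        cs = CircularSample(np.full(10, 42.0))
        assert resultant_length(cs) == pytest.approx(1.0)
        assert circular_mean_deg(cs) == pytest.approx(42.0)


@pytest.fixture(scope="module")
def wave_session():
    atlas = grid_atlas((32, 32), ["RSC", "PtA", "V1"])
    cfg = synthio.SynthConfig(duration=70.0, seed=40)
    truth = synthio.sample_ripple_times(cfg, 30, min_gap=1.5)
    return atlas, cfg, truth


class TestDirectionDistribution:
    def test_plane_wave_angle_recovered(self, wave_session):
        atlas, cfg, truth = wave_session
        truth.wave_angle[:] = 45.0
        stack = synthio.generate_stack(cfg, truth, atlas, mode="plane_wave",
                                       noise_sd=0.02)
        cs = direction_distribution(stack, truth.ripple_times, atlas, "RSC",
                                    subset_size=20, n_iter=25, seed=0)
        assert circular_error(circular_mean_deg(cs), 45.0) < 10.0
        assert resultant_length(cs) > 0.9

    def test_rotation_equivariance(self, wave_session):
        atlas, cfg, truth = wave_session
        truth.wave_angle[:] = 0.0
        stack = synthio.generate_stack(cfg, truth, atlas, mode="plane_wave",
                                       noise_sd=0.0)
        cs = direction_distribution(stack, truth.ripple_times, atlas, "PtA",
                                    subset_size=15, n_iter=10, seed=1)
        # rotate spatial axes 90 deg counterclockwise: columns become rows
        import copy

        from ripplemap.core import ImageStack, RegionAtlas
        rot_frames = np.rot90(stack.frames, k=1, axes=(1, 2))
        rot_atlas = RegionAtlas(labels=np.rot90(atlas.labels, k=1),
                                names=dict(atlas.names))
        rot = direction_distribution(
            ImageStack(rot_frames.copy(), rate=stack.rate),
            truth.ripple_times, rot_atlas, "PtA",
            subset_size=15, n_iter=10, seed=1,
        )
        err = circular_error(
            circular_mean_deg(rot), (circular_mean_deg(cs) + 90.0) % 360.0
        )
        assert err < 10.0

    def test_isotropic_noise_no_preferred_direction(self, wave_session, rng):
        atlas, cfg, truth = wave_session
        from ripplemap.core import ImageStack
        stack = ImageStack(rng.standard_normal((7000, 32, 32)), rate=100.0)
        cs = direction_distribution(stack, truth.ripple_times, atlas, "RSC",
                                    subset_size=20, n_iter=40, seed=2)
        assert resultant_length(cs) < 0.5

    def test_single_iteration_matches_direct_computation(self, wave_session):
        atlas, cfg, truth = wave_session
        truth.wave_angle[:] = 0.0
        stack = synthio.generate_stack(cfg, truth, atlas, mode="plane_wave",
                                       noise_sd=0.0)
        cs = direction_distribution(stack, truth.ripple_times, atlas, "RSC",
                                    subset_size=20, n_iter=1, seed=3)
        assert cs.n == 1

    def test_too_few_events_rejected(self, wave_session):
        atlas, cfg, truth = wave_session
        from ripplemap.core import ImageStack
        stack = ImageStack(np.zeros((1000, 32, 32)), rate=100.0)
        with pytest.raises(ValueError):
            direction_distribution(stack, [5.0, 6.0], atlas, "RSC",
                                   subset_size=20, n_iter=5)

    def test_null_destroys_event_locking(self, wave_session):
        atlas, cfg, truth = wave_session
        truth.wave_angle[:] = 0.0
        stack = synthio.generate_stack(cfg, truth, atlas, mode="plane_wave",
                                       noise_sd=0.05)
        obs = direction_distribution(stack, truth.ripple_times, atlas, "RSC",
                                     subset_size=20, n_iter=50, seed=4)
        null = shuffled_direction_null(stack, truth.ripple_times, atlas,
                                       "RSC", subset_size=20, n_iter=50,
                                       seed=5)
        assert null.n == 50
        v, p = kuiper_two_sample(obs, null)
        assert p < 0.01


class TestKuiperTwoSample:
    def test_identical_samples_v_zero(self, rng):
        x = rng.uniform(0, 360, 50)
        v, p = kuiper_two_sample(x, x)
        assert v == 0.0
        assert p == 1.0

    def test_rotation_invariance(self, rng):
        a = rng.vonmises(0.0, 1.0, 80) * 180 / np.pi
        b = rng.vonmises(1.0, 1.0, 80) * 180 / np.pi
        v1, _ = kuiper_two_sample(a, b)
        v2, _ = kuiper_two_sample((a + 117.0) % 360, (b + 117.0) % 360)
        # common rotation moves the ECDF origin but V compares the same
        # cyclic structure; allow discreteness slack of 1/n
        assert abs(v1 - v2) <= 1.0 / 80 + 1e-12

    def test_separated_von_mises_detected(self, rng):
        a = np.degrees(rng.vonmises(0.0, 2.0, 100))
        b = np.degrees(rng.vonmises(np.pi / 2, 2.0, 100))
        _, p = kuiper_two_sample(a, b)
        assert p < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            kuiper_two_sample(np.array([1.0]), np.array([]))
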