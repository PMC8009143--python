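"""Translation losses, domain pairs and the oracle/trained translators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gastro3d.frames import ImageFrame
from gastro3d.vic_translation import (
    DOMAIN_PAIRS,
    GanLossConfig,
    TrainConfig,
    cycle_loss,
    extract_channel,
    gan_loss,
    identity_loss,
    oracle_translator,
    total_loss,
    train_translator,
    translate_sequence,
)


# ---------------------------------------------------------------------------
# losses: worked values


def test_gan_loss_examples():
    ones = np.ones((4, 4))
    zeros = np.zeros((4, 4))
    assert gan_loss(ones, zeros) == pytest.approx(0.0)
    assert gan_loss(0.5 * ones, 0.5 * ones) == pytest.approx(0.5)
    assert gan_loss(zeros, ones) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        gan_loss(np.ones((2, 2)), np.ones((3, 3)))


def test_cycle_loss_examples_and_symmetry():
    a = np.full((4, 4), 0.2)
    rec_a = np.full((4, 4), 0.5)
    b = np.zeros((4, 4))
    assert cycle_loss(a, rec_a, b, b) == pytest.approx(0.3)
    assert cycle_loss(a, a, b, b) == pytest.approx(0.0)
    # swapping the (a, rec_a) and (b, rec_b) argument pairs changes nothing
    rng = np.random.default_rng(0)
    x, rx, y, ry = (rng.random((4, 4)) for _ in range(4))
    assert cycle_loss(x, rx, y, ry) == pytest.approx(cycle_loss(y, ry, x, rx))


def test_identity_loss_examples():
    b = np.random.default_rng(1).random((4, 4))
    assert identity_loss(b, b, b, b) == pytest.approx(0.0)
    assert identity_loss(b + 0.1, b, b, b) == pytest.approx(0.1)


def test_total_loss_with_the_published_weights():
    cfg = GanLossConfig(lambda_cyc=10.0, lambda_idt=5.0)
    assert total_loss((0.5, 0.5, 0.3, 0.1), cfg) == pytest.approx(4.5)
    assert total_loss((0.0, 0.0, 0.0, 0.0), cfg) == pytest.approx(0.0)
    assert total_loss((0.7, 0.2, 9.0, 9.0), GanLossConfig(0.0, 0.0)) == pytest.approx(0.9)
    with pytest.raises(ValueError):
        GanLossConfig(lambda_cyc=-1.0)


def test_losses_match_an_independent_elementwise_oracle():
    """All four losses vs. a hand-coded scalar-loop computation on 4x4 images."""
    rng = np.random.default_rng(42)
    sr, sf = rng.random((4, 4)), rng.random((4, 4))
    a, ra, b, rb = (rng.random((4, 4)) for _ in range(4))

    def oracle_mean(img, fn):
        total = 0.0
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                total += fn(img[i, j])
        return total / img.size

    g_oracle = oracle_mean(sr, lambda x: (x - 1.0) ** 2) + oracle_mean(
        sf, lambda x: x**2
    )
    assert abs(gan_loss(sr, sf) - g_oracle) < 1e-6

    c_oracle = 0.0
    for img, ref in ((ra, a), (rb, b)):
        for i in range(4):
            for j in range(4):
                c_oracle += abs(img[i, j] - ref[i, j]) / 16.0
    assert abs(cycle_loss(a, ra, b, rb) - c_oracle) < 1e-6
    assert abs(identity_loss(ra, b, rb, a) - (
        oracle_mean(np.abs(ra - b), lambda x: x) + oracle_mean(np.abs(rb - a), lambda x: x)
    )) < 1e-6

    lam_c, lam_i = 10.0, 5.0
    t_oracle = g_oracle + gan_loss(sf, sr) + lam_c * c_oracle + lam_i * identity_loss(
        ra, b, rb, a
    )
    got = total_loss(
        (gan_loss(sr, sf), gan_loss(sf, sr), cycle_loss(a, ra, b, rb),
         identity_loss(ra, b, rb, a)),
        GanLossConfig(lam_c, lam_i),
    )
    assert abs(got - t_oracle) < 1e-6


@settings(deadline=None, max_examples=30, derandomize=True)
@given(lam_c=st.floats(0, 50), lam_i=st.floats(0, 50), seed=st.integers(0, 99))
def test_total_loss_is_affine_in_the_weights(lam_c, lam_i, seed):
    rng = np.random.default_rng(seed)
    comp = tuple(rng.random(4))
    base = total_loss(comp, GanLossConfig(0.0, 0.0))
    val = total_loss(comp, GanLossConfig(lam_c, lam_i))
    assert val == pytest.approx(base + lam_c * comp[2] + lam_i * comp[3], rel=1e-12)
    assert val >= 0.0


# ---------------------------------------------------------------------------
# channel handling


def test_extract_channel_round_trip():
    rng = np.random.default_rng(0)
    rgb = rng.random((8, 8, 3))
    frame = ImageFrame(rgb, "no_dye", 0)
    stacked = np.stack(
        [extract_channel(frame, c) for c in ("R", "G", "B")], axis=-1
    )
    assert np.array_equal(stacked, rgb)
    gray = np.stack([rgb[:, :, 0]] * 3, axis=-1)
    gframe = ImageFrame(gray, "no_dye", 1)
    for c in ("R", "G", "B"):
        assert np.array_equal(extract_channel(gframe, c), rgb[:, :, 0])
    with pytest.raises(ValueError):
        extract_channel(frame, "X")


# ---------------------------------------------------------------------------
# training mechanics (cheap; the loss-decrease study is in acceptance)


def _toy_sets(n=6, size=80):
    rng = np.random.default_rng(0)
    from scipy.ndimage import gaussian_filter

    A = [gaussian_filter(rng.random((size, size)), 6)[None] for _ in range(n)]
    B = [gaussian_filter(rng.random((size, size)), 1)[None] for _ in range(n)]
    return A, B


def test_training_is_deterministic_given_the_seed():
    A, B = _toy_sets()
    cfg = TrainConfig(epochs=1, crop_size=64, n_features=8)
    s1 = train_translator(A, B, "g2r", cfg, seed=5)
    s2 = train_translator(A, B, "g2r", cfg, seed=5)
    assert s1.epoch_losses[0] == s2.epoch_losses[0]


def test_g2r_translator_outputs_single_red_planes():
    A, B = _toy_sets()
    state = train_translator(A, B, "g2r", TrainConfig(epochs=1, crop_size=64, n_features=8), seed=0)
    rgb = np.random.default_rng(3).random((80, 80, 3))
    frames = [ImageFrame(rgb, "no_dye", i) for i in range(3)]
    out = translate_sequence(state, frames)
    assert len(out) == 3
    assert [o.frame_id for o in out] == [0, 1, 2]
    for o in out:
        assert o.pixels.shape == (80, 80)
        assert o.domain_tag == "virtual_dye"


def test_empty_training_set_is_rejected():
    with pytest.raises(ValueError):
        train_translator([], [np.zeros((1, 64, 64))], "r2r")


def test_channel_count_mismatch_is_rejected():
    A = [np.zeros((3, 64, 64))]
    B = [np.zeros((1, 64, 64))]
    with pytest.raises(ValueError, match="channel"):
        train_translator(A, B, "r2r")


def test_domain_pair_definitions():
    assert DOMAIN_PAIRS["g2r"].input_channels == ("G",)
    assert DOMAIN_PAIRS["g2r"].output_channels == ("R",)
    assert DOMAIN_PAIRS["r2r"].n_in == 1 and DOMAIN_PAIRS["r2r"].n_out == 1
    assert DOMAIN_PAIRS["rgb2rgb"].n_in == 3 and DOMAIN_PAIRS["rgb2rgb"].n_out == 3


# ---------------------------------------------------------------------------
# oracle translator (uses the session scene)


def test_oracle_translation_is_exact_and_pose_consistent(scene, vic_frames, nodye_frames):
    from gastro3d.endosim import render_frame

    orc = oracle_translator(scene)
    out = translate_sequence(orc, nodye_frames[:3])
    for i, o in enumerate(out):
        ref = extract_channel(render_frame(scene, i, "dye"), "R")
        assert np.array_equal(o.pixels, ref)
    with pytest.raises(KeyError):
        orc(999)


def test_oracle_output_has_more_texture_than_the_green_plane(scene, vic_frames, nodye_frames):
    def grms(p):
        gx, gy = np.gradient(p)
        return np.sqrt(np.mean(gx**2 + gy**2))

    i = 10
    assert grms(vic_frames[i]) > grms(nodye_frames[i].channel("G"))
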