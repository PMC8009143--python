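"""Virtual chromoendoscopy: unpaired channel-selective image translation.

Plain (no-dye) gastroscopy frames are nearly texture-less and starve
feature-based reconstruction; dye-sprayed frames carry high-contrast
texture.  Because paired no-dye / dye images of the same wall cannot be
captured, the mapping is learned from *unpaired* sets with a
cycle-consistent adversarial objective:

    L = L_GAN(G_A, D_B) + L_GAN(G_B, D_A) + λ_cyc L_cyc + λ_idt L_idt

with least-squares GAN losses, L1 cycle-consistency and L1 identity
terms (defaults λ_cyc = 10, λ_idt = 5).  Three channel-domain pairings
are supported: rgb2rgb, r2r (red to red) and g2r (no-dye green to dye
red); the frame fed to structure-from-motion is always a single red
plane — extracted post hoc for rgb2rgb.  The ``g2r`` pairing joins the
most-textured no-dye channel to the most-textured dye channel and is
the default.

For GPU-free pipeline testing, :func:`oracle_translator` maps a
simulator frame index straight to the dye-domain red channel rendered
at the same pose — a perfect translation with no learning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .frames import ImageFrame
from .vic_nn import Adam, Generator, PatchDiscriminator

logger = logging.getLogger(__name__)

__all__ = [
    "DomainPair",
    "DOMAIN_PAIRS",
    "GanLossConfig",
    "TrainConfig",
    "TranslatorState",
    "extract_channel",
    "gan_loss",
    "cycle_loss",
    "identity_loss",
    "total_loss",
    "train_translator",
    "oracle_translator",
    "OracleTranslator",
    "translate_sequence",
]


@dataclass(frozen=True)
class DomainPair:
    """Channel selection for the two translation domains."""

    name: str
    input_channels: tuple  # domain A (no-dye source)
    output_channels: tuple  # domain B (dye target)

    @property
    def n_in(self) -> int:
        return len(self.input_channels)

    @property
    def n_out(self) -> int:
        return len(self.output_channels)


DOMAIN_PAIRS = {
    "rgb2rgb": DomainPair("rgb2rgb", ("R", "G", "B"), ("R", "G", "B")),
    "r2r": DomainPair("r2r", ("R",), ("R",)),
    "g2r": DomainPair("g2r", ("G",), ("R",)),
}


@dataclass(frozen=True)
class GanLossConfig:
    lambda_cyc: float = 10.0
    lambda_idt: float = 5.0

    def __post_init__(self) -> None:
        if self.lambda_cyc < 0 or self.lambda_idt < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass(frozen=True)
class TrainConfig:
    """Desk-scale training defaults (optimizer settings are CycleGAN-standard)."""

    loss: GanLossConfig = field(default_factory=GanLossConfig)
    epochs: int = 2
    batch_size: int = 4
    crop_size: int = 64
    n_features: int = 16
    lr: float = 2e-4


# ---------------------------------------------------------------------------
# channel handling


def extract_channel(frame: ImageFrame, channel: str) -> np.ndarray:
    """Return one color plane of a frame, values unchanged in [0, 1]."""
    return frame.channel(channel)


def stack_channels(frame: ImageFrame, channels: tuple) -> np.ndarray:
    """(C, H, W) array of the selected channels."""
    return np.stack([frame.channel(c) for c in channels])


# ---------------------------------------------------------------------------
# the four losses


def gan_loss(scores_real: np.ndarray, scores_fake: np.ndarray) -> float:
    """Least-squares GAN objective for one translation direction.

    The discriminator of the target domain is driven toward score 1 on
    real samples and 0 on generated ones:
    mean((D(b) - 1)^2) + mean(D(G(a))^2).
    """
    scores_real = np.asarray(scores_real, float)
    scores_fake = np.asarray(scores_fake, float)
    if scores_real.shape != scores_fake.shape:
        raise ValueError("score maps must have the same shape")
    return float(np.mean((scores_real - 1.0) ** 2) + np.mean(scores_fake**2))


def cycle_loss(
    a: np.ndarray, rec_a: np.ndarray, b: np.ndarray, rec_b: np.ndarray
) -> float:
    """L1 penalty on both circular translations a->B->A and b->A->B."""
    a, rec_a, b, rec_b = (np.asarray(x, float) for x in (a, rec_a, b, rec_b))
    if a.shape != rec_a.shape or b.shape != rec_b.shape:
        raise ValueError("reconstructed images must match their originals' shape")
    return float(np.mean(np.abs(rec_a - a)) + np.mean(np.abs(rec_b - b)))


def identity_loss(
    ga_b: np.ndarray, b: np.ndarray, gb_a: np.ndarray, a: np.ndarray
) -> float:
    """L1 penalty on same-domain feed-through: G_A(b) vs b, G_B(a) vs a."""
    ga_b, b, gb_a, a = (np.asarray(x, float) for x in (ga_b, b, gb_a, a))
    if ga_b.shape != b.shape or gb_a.shape != a.shape:
        raise ValueError("identity outputs must match their inputs' shape")
    return float(np.mean(np.abs(ga_b - b)) + np.mean(np.abs(gb_a - a)))


def total_loss(
    components: tuple, config: GanLossConfig | None = None
) -> float:
    """Weighted sum L_GAN(A->B) + L_GAN(B->A) + λ_cyc L_cyc + λ_idt L_idt."""
    config = config or GanLossConfig()
    gan_ab, gan_ba, cyc, idt = components
    return float(
        gan_ab + gan_ba + config.lambda_cyc * cyc + config.lambda_idt * idt
    )


# ---------------------------------------------------------------------------
# training


@dataclass
class TranslatorState:
    """Generators, discriminators and the training log of one CycleGAN."""

    pair: DomainPair
    G_A: Generator  # A -> B
    G_B: Generator  # B -> A
    D_A: PatchDiscriminator
    D_B: PatchDiscriminator
    config: TrainConfig
    seed: int
    epoch_losses: list = field(default_factory=list)


def _to_signed(x: np.ndarray) -> np.ndarray:
    return 2.0 * x - 1.0  # [0, 1] -> [-1, 1]


def _to_unit(x: np.ndarray) -> np.ndarray:
    return (x + 1.0) / 2.0


def _as_batches(images: np.ndarray, batch: int, rng) -> list[np.ndarray]:
    order = rng.permutation(len(images))
    return [images[order[i : i + batch]] for i in range(0, len(images), batch)]


def _random_crops(stacks: list[np.ndarray], size: int, rng) -> np.ndarray:
    out = []
    for s in stacks:
        _, h, w = s.shape
        if h < size or w < size:
            raise ValueError(f"images ({h}x{w}) smaller than crop size {size}")
        r = rng.integers(h - size + 1)
        c = rng.integers(w - size + 1)
        out.append(s[:, r : r + size, c : c + size])
    return np.stack(out)


def _epoch_total_loss(state: TranslatorState, A: np.ndarray, B: np.ndarray) -> float:
    """Eq.-style total objective evaluated on the full training sets."""
    fake_b, _ = state.G_A.forward(A)
    fake_a, _ = state.G_B.forward(B)
    rec_a, _ = state.G_B.forward(fake_b)
    rec_b, _ = state.G_A.forward(fake_a)
    db_real, _ = state.D_B.forward(B)
    db_fake, _ = state.D_B.forward(fake_b)
    da_real, _ = state.D_A.forward(A)
    da_fake, _ = state.D_A.forward(fake_a)
    g_ab = gan_loss(db_real, db_fake)
    g_ba = gan_loss(da_real, da_fake)
    cyc = cycle_loss(A, rec_a, B, rec_b)
    if state.pair.n_in == state.pair.n_out:
        idt_b, _ = state.G_A.forward(B)
        idt_a, _ = state.G_B.forward(A)
        idt = identity_loss(idt_b, B, idt_a, A)
    else:
        idt = 0.0
    return total_loss((g_ab, g_ba, cyc, idt), state.config.loss)


def train_translator(
    set_A: list,
    set_B: list,
    pair: DomainPair | str = "g2r",
    config: TrainConfig | None = None,
    epochs: int | None = None,
    seed: int = 0,
) -> TranslatorState:
    """Train a tiny CycleGAN on unpaired image sets (random crops).

    ``set_A`` / ``set_B`` may be :class:`ImageFrame` objects or channel
    arrays ``(C, H, W)``; the pair's channel subsets are extracted from
    frames automatically.  The per-epoch total loss (the weighted
    four-term objective, evaluated on the full sets) is logged to
    ``epoch_losses``.  Identity terms require matching channel counts
    between the domains; otherwise they are skipped with a logged
    warning.  Deterministic given ``seed``.
    """
    if isinstance(pair, str):
        pair = DOMAIN_PAIRS[pair]
    config = config or TrainConfig()
    if epochs is None:
        epochs = config.epochs
    if not set_A or not set_B:
        raise ValueError("both training sets must be non-empty")

    def prep(items, channels, n_expected, side):
        out = []
        for it in items:
            if isinstance(it, ImageFrame):
                arr = (
                    stack_channels(it, channels)
                    if it.is_rgb
                    else it.pixels[None, :, :]
                )
            else:
                arr = np.asarray(it, float)
                if arr.ndim == 2:
                    arr = arr[None]
            if arr.shape[0] != n_expected:
                raise ValueError(
                    f"{side} images must have {n_expected} channel(s) for pair "
                    f"{pair.name!r}, got {arr.shape[0]}"
                )
            out.append(_to_signed(arr))
        return out

    A_list = prep(set_A, pair.input_channels, pair.n_in, "domain-A")
    B_list = prep(set_B, pair.output_channels, pair.n_out, "domain-B")

    rng = np.random.default_rng(seed)
    state = TranslatorState(
        pair=pair,
        G_A=Generator(pair.n_in, pair.n_out, config.n_features, seed=seed),
        G_B=Generator(pair.n_out, pair.n_in, config.n_features, seed=seed + 1),
        D_A=PatchDiscriminator(pair.n_in, config.n_features, seed=seed + 2),
        D_B=PatchDiscriminator(pair.n_out, config.n_features, seed=seed + 3),
        config=config,
        seed=seed,
    )
    use_idt = pair.n_in == pair.n_out
    if not use_idt and config.loss.lambda_idt > 0:
        logger.warning(
            "identity loss skipped: pair %s has mismatched channel counts",
            pair.name,
        )
    g_layers = state.G_A.layers() + state.G_B.layers()
    opt_G = Adam(g_layers, lr=config.lr)
    opt_DA = Adam(state.D_A.layers(), lr=config.lr)
    opt_DB = Adam(state.D_B.layers(), lr=config.lr)
    lam_c, lam_i = config.loss.lambda_cyc, config.loss.lambda_idt

    for _epoch in range(epochs):
        crops_A = _random_crops(A_list, config.crop_size, rng)
        crops_B = _random_crops(B_list, config.crop_size, rng)
        n_pairs = min(len(crops_A), len(crops_B))
        batches_A = _as_batches(crops_A[:n_pairs], config.batch_size, rng)
        batches_B = _as_batches(crops_B[:n_pairs], config.batch_size, rng)
        for a, b in zip(batches_A, batches_B):
            # ---- generator update (discriminators frozen)
            opt_G.zero_grad()
            fake_b, c_ga = state.G_A.forward(a)
            fake_a, c_gb = state.G_B.forward(b)
            rec_a, c_gba = state.G_B.forward(fake_b)
            rec_b, c_gab = state.G_A.forward(fake_a)
            s_fb, c_db = state.D_B.forward(fake_b)
            s_fa, c_da = state.D_A.forward(fake_a)
            # adversarial: generators push fake scores toward 1
            g_s_fb = 2.0 * (s_fb - 1.0) / s_fb.size
            g_s_fa = 2.0 * (s_fa - 1.0) / s_fa.size
            g_fb = state.D_B.backward(g_s_fb, c_db)
            g_fa = state.D_A.backward(g_s_fa, c_da)
            # cycle terms
            g_rec_a = lam_c * np.sign(rec_a - a) / rec_a.size
            g_rec_b = lam_c * np.sign(rec_b - b) / rec_b.size
            g_fb = g_fb + state.G_B.backward(g_rec_a, c_gba)
            g_fa = g_fa + state.G_A.backward(g_rec_b, c_gab)
            state.G_A.backward(g_fb, c_ga)
            state.G_B.backward(g_fa, c_gb)
            # identity terms
            if use_idt and lam_i > 0:
                idt_b, c_ib = state.G_A.forward(b)
                idt_a, c_ia = state.G_B.forward(a)
                state.G_A.backward(lam_i * np.sign(idt_b - b) / idt_b.size, c_ib)
                state.G_B.backward(lam_i * np.sign(idt_a - a) / idt_a.size, c_ia)
            # discriminator grads were accumulated as a side effect; the
            # generator optimizer only touches generator layers
            opt_G.step()
            # ---- discriminator updates (fakes detached)
            for D, opt, real, fake in (
                (state.D_B, opt_DB, b, fake_b),
                (state.D_A, opt_DA, a, fake_a),
            ):
                opt.zero_grad()
                s_r, c_r = D.forward(real)
                s_f, c_f = D.forward(fake)
                D.backward(2.0 * (s_r - 1.0) / s_r.size, c_r)
                D.backward(2.0 * s_f / s_f.size, c_f)
                opt.step()
        A_full = np.stack(A_list)
        B_full = np.stack(B_list)
        state.epoch_losses.append(_epoch_total_loss(state, A_full, B_full))
    return state


# ---------------------------------------------------------------------------
# oracle translation and sequence application


class OracleTranslator:
    """Perfect virtual-dye mapping backed by the simulator's ground truth.

    Frame index ``i`` maps to the red channel of the dye-domain render
    at the same pose — what an ideal translation network would produce.
    """

    pair = DOMAIN_PAIRS["g2r"]

    def __init__(self, scene):
        self.scene = scene

    def __call__(self, frame_id: int) -> np.ndarray:
        from .endosim import render_plane

        if not 0 <= frame_id < self.scene.trajectory.n_frames:
            raise KeyError(f"unknown frame index {frame_id}")
        return render_plane(self.scene, frame_id, "dye", "R")


def oracle_translator(scene) -> OracleTranslator:
    return OracleTranslator(scene)


def translate_sequence(
    translator,
    frames: list[ImageFrame],
    pair: DomainPair | str | None = None,
) -> list[ImageFrame]:
    """Apply a translator to an ordered frame sequence.

    Returns one single-red-plane ``virtual_dye`` frame per input, order
    preserved.  ``translator`` is a trained :class:`TranslatorState`
    (its A->B generator is applied; discriminators play no role at test
    time) or an :class:`OracleTranslator`.
    """
    if isinstance(translator, OracleTranslator):
        out = []
        for fr in frames:
            plane = translator(fr.frame_id)
            out.append(ImageFrame(plane, "virtual_dye", frame_id=fr.frame_id))
        return out
    if isinstance(pair, str):
        pair = DOMAIN_PAIRS[pair]
    if pair is None:
        pair = translator.pair
    if pair.name != translator.pair.name:
        raise ValueError(
            f"translator was trained for pair {translator.pair.name!r}, "
            f"not {pair.name!r}"
        )
    out = []
    for fr in frames:
        if fr.is_rgb:
            arr = stack_channels(fr, pair.input_channels)
        else:
            if pair.n_in != 1:
                raise ValueError("single-plane frame fed to a multi-channel pair")
            arr = fr.pixels[None]
        y, _ = translator.G_A.forward(_to_signed(arr)[None])
        y = _to_unit(y[0])
        if pair.n_out == 3:
            red = y[pair.output_channels.index("R")]
        else:
            red = y[0]
        out.append(
            ImageFrame(np.clip(red, 0.0, 1.0), "virtual_dye", frame_id=fr.frame_id)
        )
    return out
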