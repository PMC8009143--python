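"""The in-memory image container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DOMAIN_TAGS = ("no_dye", "dye", "virtual_dye")
CHANNELS = ("R", "G", "B")


@dataclass
class ImageFrame:
    """One time-stamped endoscopy frame.

    ``pixels`` is ``(H, W, 3)`` float in [0, 1] for RGB frames or ``(H, W)``
    for single-plane frames; ``domain_tag`` records whether the frame shows
    the plain mucosa (``no_dye``), dye-sprayed mucosa (``dye``) or a
    style-translated virtual-dye image (``virtual_dye``).
    """

    pixels: np.ndarray
    domain_tag: str
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.domain_tag not in DOMAIN_TAGS:
            raise ValueError(f"unknown domain tag {self.domain_tag!r}")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be (H, W) or (H, W, 3)")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("RGB frames must have exactly 3 planes")

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 3 if self.is_rgb else 1

    def channel(self, name: str) -> np.ndarray:
        """Return one color plane; single-plane frames only expose their plane."""
        if not self.is_rgb:
            raise ValueError(f"single-plane frame has no channel {name!r}")
        try:
            idx = CHANNELS.index(name)
        except ValueError:
            raise ValueError(f"unknown channel {name!r}") from None
        return self.pixels[:, :, idx]
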