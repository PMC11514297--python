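"""The dilated-convolution spectral network (WNN) and patch tiling.

The network is a WaveNet-inspired stack of valid (unpadded) dilated
convolutions for recognizing 2D spectral patterns: the first layer uses a
2x4 kernel without dilation, layer ``m`` (m = 2..n_layers) a 2x2 kernel with
dilation ``(2^(m-1), 2^m)``, every layer 50 filters with ReLU, followed by a
linear 1x1 channel projection (so negative spectral values stay
representable).  With the default five layers the receptive field is
``(31, 63)``: a 63x127 input patch maps to a 32x64 output patch.

Because there is no padding, full spectra are processed in tiles: the
spectrum is embedded in a zero-padded frame, cut into input patches whose
central output regions exactly cover the grid without overlap, and the
network outputs are stitched back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2D, ReLU, Sequential

__all__ = ["WNNSpec", "scaled_spec", "receptive_extent", "build_wnn",
           "TileScheme", "tile", "stitch", "central_crop"]


@dataclass(frozen=True)
class WNNSpec:
    """Architecture of one dilated-convolution network.

    ``n_layers`` counts the dilated ReLU stages; the closing 1x1 linear
    projection (filters -> 1 channel) is always present and not counted.
    """

    n_layers: int = 5
    filters: int = 50
    first_kernel: tuple[int, int] = (2, 4)
    later_kernel: tuple[int, int] = (2, 2)

    def __post_init__(self) -> None:
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")
        if self.filters < 1:
            raise ValueError("filters must be >= 1")

    def layer_plan(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """(kernel, dilation) per dilated layer."""
        plan = []
        for m in range(1, self.n_layers + 1):
            if m == 1:
                plan.append((self.first_kernel, (1, 1)))
            else:
                plan.append((self.later_kernel, (2 ** (m - 1), 2 ** m)))
        return plan

    @property
    def receptive_field(self) -> tuple[int, int]:
        """Total extent consumed per dimension: sum of (kernel-1)*dilation."""
        rf = [0, 0]
        for (kh, kw), (dh, dw) in self.layer_plan():
            rf[0] += (kh - 1) * dh
            rf[1] += (kw - 1) * dw
        return rf[0], rf[1]


def scaled_spec() -> WNNSpec:
    """Reduced architecture for desk-scale runs on 16x32 spectra.

    Four dilated layers with 12 filters give a (15, 31) receptive field, so
    one 31x63 input patch covers a whole 16x32 spectrum.
    """
    return WNNSpec(n_layers=4, filters=12)


def receptive_extent(spec: WNNSpec,
                     output_extent: tuple[int, int]) -> tuple[int, int]:
    """Input extent required to produce ``output_extent`` with no padding."""
    oh, ow = output_extent
    if oh < 1 or ow < 1:
        raise ValueError("output extent must be positive")
    rh, rw = spec.receptive_field
    return oh + rh, ow + rw


def build_wnn(spec: WNNSpec, seed: int = 0) -> Sequential:
    """Instantiate the network with seeded He-normal initialization."""
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = 1
    for kernel, dilation in spec.layer_plan():
        layers.append(Conv2D(in_ch, spec.filters, kernel, dilation, rng))
        layers.append(ReLU())
        in_ch = spec.filters
    layers.append(Conv2D(in_ch, 1, (1, 1), (1, 1), rng))  # linear projection
    return Sequential(layers)


@dataclass(frozen=True)
class TileScheme:
    """Non-overlapping tiling of a spectrum into network-sized patches.

    Output patches of ``output_extent`` tile a padded copy of the spectrum
    exactly; each input patch extends the corresponding output region by the
    receptive field, split ``floor(rf/2)`` before and the rest after, with
    zeros outside the spectrum.
    """

    spectrum_extent: tuple[int, int]
    output_extent: tuple[int, int] = (32, 64)
    receptive_field: tuple[int, int] = (31, 63)

    @property
    def n_tiles(self) -> tuple[int, int]:
        return tuple(-(-s // o) for s, o in
                     zip(self.spectrum_extent, self.output_extent))

    @property
    def input_extent(self) -> tuple[int, int]:
        return tuple(o + r for o, r in
                     zip(self.output_extent, self.receptive_field))


def tile(spectrum: np.ndarray, scheme: TileScheme) -> np.ndarray:
    """Cut a spectrum into input patches ``(n_tiles_total, in_h, in_w)``."""
    if spectrum.shape != scheme.spectrum_extent:
        raise ValueError("spectrum shape does not match the tile scheme")
    (nh, nw) = scheme.n_tiles
    (oh, ow) = scheme.output_extent
    (rh, rw) = scheme.receptive_field
    top, left = rh // 2, rw // 2
    frame = np.zeros((nh * oh + rh, nw * ow + rw))
    frame[top:top + spectrum.shape[0], left:left + spectrum.shape[1]] = spectrum
    ih, iw = scheme.input_extent
    patches = np.empty((nh * nw, ih, iw))
    for i in range(nh):
        for j in range(nw):
            patches[i * nw + j] = frame[i * oh:i * oh + ih, j * ow:j * ow + iw]
    return patches

def stitch(patches: np.ndarray, scheme: TileScheme) -> np.ndarray:
    """Reassemble output patches ``(n_tiles_total, out_h, out_w)``."""
    (nh, nw) = scheme.n_tiles
    (oh, ow) = scheme.output_extent
    if patches.shape != (nh * nw, oh, ow):
        raise ValueError("patch stack does not match the tile scheme")
    canvas = np.empty((nh * oh, nw * ow))
    for i in range(nh):
        for j in range(nw):
            canvas[i * oh:(i + 1) * oh, j * ow:(j + 1) * ow] = patches[i * nw + j]
    h, w = scheme.spectrum_extent
    return canvas[:h, :w]


def central_crop(patches: np.ndarray, scheme: TileScheme) -> np.ndarray:
    """Central output-sized region of each input patch (identity model)."""
    (rh, rw) = scheme.receptive_field
    (oh, ow) = scheme.output_extent
    top, left = rh // 2, rw // 2
    return patches[:, top:top + oh, left:left + ow]
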