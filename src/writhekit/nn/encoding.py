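"""Parity-aware sinusoidal positional encodings.

Scalars entering the score network are embedded with sinusoidal features
``phi±(x) = {sin(nπx/L), cos(nπx/L)}_{n=1..d/2}``.  Parity-even scalars
(distances) use both sines and cosines; parity-odd scalars (writhe) use
sines only — ``phi−(x) = {sin(nπx/L)}`` — because sine is an odd function,
so the embedding negates with its argument and the parity class of the
feature survives the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..chain import ParameterError


@dataclass(frozen=True)
class EncodingSpec:
    """Sinusoidal embedding specification.

    ``dim`` is the full embedding dimension d (both-mode output); the
    sine-only mode emits d/2 features.  ``length_scale`` L sets the longest
    wavelength; parity mode is ``"both"`` or ``"sine_only"``.
    """

    dim: int = 16
    length_scale: float = 1.0
    parity: str = "both"

    def __post_init__(self):
        if self.length_scale <= 0:
            raise ParameterError("length scale must be positive")
        if self.dim % 2 != 0 or self.dim < 2:
            raise ParameterError("embedding dim must be an even integer >= 2")
        if self.parity not in ("both", "sine_only"):
            raise ParameterError("parity mode must be 'both' or 'sine_only'")

    @property
    def out_dim(self) -> int:
        return self.dim // 2 if self.parity == "sine_only" else self.dim


def positional_encoding(x, spec: EncodingSpec) -> np.ndarray:
    """Embed scalars with sinusoidal features; shape (..., out_dim).

    Both-mode output interleaves sin/cos per frequency:
    ``[sin(πx/L), cos(πx/L), sin(2πx/L), cos(2πx/L), ...]``.
    """
    x = np.asarray(x, dtype=np.float64)
    n = np.arange(1, spec.dim // 2 + 1)
    arg = n * np.pi * x[..., None] / spec.length_scale
    if spec.parity == "sine_only":
        return np.sin(arg)
    out = np.empty(x.shape + (spec.dim,))
    out[..., 0::2] = np.sin(arg)
    out[..., 1::2] = np.cos(arg)
    return out
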