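"""Minimal numpy autodiff engine for volumetric CNNs (channels-last)."""


def _tune_allocator() -> None:
    """Keep large malloc arenas resident between steps (glibc only).

    Volumetric training allocates and frees hundreds of megabytes of
    activation and im2col scratch per step; by default glibc serves these
    via mmap and returns them to the kernel on free, so every step pays the
    page-fault cost again. Raising the mmap/trim thresholds roughly halves
    the wall time of a training step on one CPU. Harmless no-op elsewhere.
    """
    import ctypes
    import sys

    if not sys.platform.startswith("linux"):
        return
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except Exception:
        pass


_tune_allocator()

from . import functional
from .modules import (
    Conv3d,
    GlobalAvgPool,
    GroupNorm,
    Linear,
    MaxPool2,
    Module,
    Parameter,
    ReLU,
    Sequential,
    Upsample2,
)
from .optim import Adam
from .tensor import Tensor, no_grad

__all__ = [
    "Adam",
    "Conv3d",
    "GlobalAvgPool",
    "GroupNorm",
    "Linear",
    "MaxPool2",
    "Module",
    "Parameter",
    "ReLU",
    "Sequential",
    "Tensor",
    "Upsample2",
    "functional",
    "no_grad",
]
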