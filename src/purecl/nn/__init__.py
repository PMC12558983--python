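def _tune_allocator():
    """Keep large array buffers on the heap for reuse (glibc only).

    The training loop allocates and frees many multi-megabyte temporaries;
    without this, each round trip pays mmap/munmap page faults.
    """
    import ctypes
    import sys

    if not sys.platform.startswith("linux"):
        return
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
    except Exception:
        pass


_tune_allocator()

from .tensor import (Tensor, concat, split, conv2d, relu, add_relu, sigmoid,
                     batch_norm, l2_normalize, logsumexp)
from .layers import Module, ModuleList, Sequential, Conv2d, Linear, BatchNorm2d, ReLU
from .optim import SGD
from .serialize import save_checkpoint, load_checkpoint, read_checkpoint_meta

__all__ = [
    "Tensor", "concat", "split", "conv2d", "relu", "add_relu", "sigmoid",
    "batch_norm", "l2_normalize", "logsumexp",
    "Module", "ModuleList", "Sequential", "Conv2d", "Linear", "BatchNorm2d", "ReLU",
    "SGD", "save_checkpoint", "load_checkpoint", "read_checkpoint_meta",
]
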