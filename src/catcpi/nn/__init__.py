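def _tune_allocator():
    """Keep large numpy buffers on the heap instead of per-array mmap/munmap
    cycles; intermediate feature maps exceed glibc's default mmap threshold
    and the page-fault churn otherwise dominates training time."""
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 512 * 1024 * 1024)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 512 * 1024 * 1024)  # M_TRIM_THRESHOLD
    except Exception:
        pass


_tune_allocator()

from .autograd import Tensor, as_tensor, no_grad
from .modules import (Module, Linear, Conv2d, Conv1d, BatchNorm1d, BatchNorm2d,
                      LayerNorm, Embedding, DTYPE)
from .optim import Adam

__all__ = ["Tensor", "as_tensor", "no_grad", "Module", "Linear", "Conv2d",
           "Conv1d", "BatchNorm1d", "BatchNorm2d", "LayerNorm", "Embedding",
           "Adam", "DTYPE"]
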