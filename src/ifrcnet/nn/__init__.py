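"""A self-contained NumPy neural-network core (autodiff, layers, optimizers)."""

from . import functional  # noqa: F401
from .functional import (  # noqa: F401
    conv2d,
    conv_transpose2d_2x2,
    cross_entropy_logits,
    global_avg_pool,
    max_pool2d,
    softmax,
)
from .modules import (  # noqa: F401
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    Linear,
    Module,
    Parameter,
    ReLU,
    Sequential,
    default_rng,
)
from .optim import SGD, Adam, build_optimizer  # noqa: F401
from .tensor import Tensor, concat, grad_enabled, no_grad  # noqa: F401

import numpy as _np

CHECKPOINT_VERSION = 1


def save_checkpoint(model: Module, path, meta: dict | None = None) -> None:
    """Single-file .npz checkpoint with a version header and optional metadata."""
    import json

    payload = {f"state/{k}": v for k, v in model.state_dict().items()}
    payload["__version__"] = _np.array(CHECKPOINT_VERSION)
    payload["__meta__"] = _np.array(json.dumps(meta or {}))
    _np.savez(path, **payload)


def load_checkpoint(model: Module, path) -> dict:
    """Load a checkpoint saved by :func:`save_checkpoint`; returns the metadata."""
    import json

    with _np.load(path, allow_pickle=False) as f:
        version = int(f["__version__"])
        if version != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version}")
        state = {k[len("state/"):]: f[k] for k in f.files if k.startswith("state/")}
        meta = json.loads(str(f["__meta__"]))
    model.load_state_dict(state)
    return meta
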