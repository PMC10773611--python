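"""Layer modules built on the :mod:`tribrats.nn.core` autodiff primitives."""

from __future__ import annotations

import numpy as np

from . import core
from .core import Parameter, Tensor


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        for mod in (self, *self.modules()):
            for value in mod.__dict__.values():
                if isinstance(value, Parameter):
                    params.append(value)
        return params

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        bufs = []
        for mod in (self, *self.modules()):
            for name, value in mod.__dict__.items():
                if isinstance(value, np.ndarray) and name.startswith("running_"):
                    bufs.append(value)
        return bufs

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, bias=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        )
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return core.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class DepthwiseConv2d(Module):
    def __init__(self, channels, k, stride=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(channels, k, k))
        )
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return core.depthwise_conv2d(x, self.weight, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return core.batch_norm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


_ACTS = {"relu": core.relu, "silu": core.silu, "sigmoid": core.sigmoid, None: lambda t: t}


class ConvBNAct(Module):
    """Conv -> batch norm -> activation, the workhorse block."""

    def __init__(self, cin, cout, k=3, stride=1, act="relu", rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def __call__(self, x: Tensor) -> Tensor:
        return _ACTS[self.act](self.bn(self.conv(x)))


class SqueezeExcite(Module):
    """Channel attention: GAP -> 1x1 reduce -> act -> 1x1 expand -> sigmoid gate.

    The hidden width follows the backbone convention: ``se_ratio`` times
    the block's *input* channels (not the expanded width), minimum 1.
    """

    def __init__(self, channels, block_in, se_ratio=0.25, act="silu", rng=None):
        super().__init__()
        hidden = max(1, int(round(block_in * se_ratio)))
        self.reduce = Conv2d(channels, hidden, 1, bias=True, rng=rng)
        self.expand = Conv2d(hidden, channels, 1, bias=True, rng=rng)
        self.act = act
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        s = core.global_avg_pool(x)
        s = _ACTS[self.act](self.reduce(s))
        s = core.sigmoid(self.expand(s))
        return core.scale_channels(x, s)


class FusedMBConv(Module):
    """Fused inverted bottleneck: 3x3 (expand) conv [+ 1x1 project].

    With expansion 1 this is a single 3x3 conv-BN-act.  A residual
    shortcut applies when stride is 1 and channels are unchanged.
    """

    def __init__(self, cin, cout, expansion, k=3, stride=1, act="silu", rng=None):
        super().__init__()
        self.use_residual = stride == 1 and cin == cout
        mid = cin * expansion
        if expansion == 1:
            self.expand = ConvBNAct(cin, cout, k, stride, act, rng=rng)
            self.project = None
        else:
            self.expand = ConvBNAct(cin, mid, k, stride, act, rng=rng)
            self.project = ConvBNAct(mid, cout, 1, 1, act=None, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.expand(x)
        if self.project is not None:
            y = self.project(y)
        if self.use_residual:
            y = core.add(y, x)
        return y


class MBConv(Module):
    """Inverted bottleneck: 1x1 expand -> depthwise 3x3 -> SE -> 1x1 project."""

    def __init__(self, cin, cout, expansion, k=3, stride=1, se_ratio=0.25, act="silu", rng=None):
        super().__init__()
        self.use_residual = stride == 1 and cin == cout
        mid = cin * expansion
        self.expand = ConvBNAct(cin, mid, 1, 1, act, rng=rng)
        self.dw = DepthwiseConv2d(mid, k, stride, rng=rng)
        self.dw_bn = BatchNorm2d(mid)
        self.se = SqueezeExcite(mid, cin, se_ratio, act, rng=rng) if se_ratio else None
        self.project = ConvBNAct(mid, cout, 1, 1, act=None, rng=rng)
        self.act = act

    def __call__(self, x: Tensor) -> Tensor:
        y = self.expand(x)
        y = _ACTS[self.act](self.dw_bn(self.dw(y)))
        if self.se is not None:
            y = self.se(y)
        y = self.project(y)
        if self.use_residual:
            y = core.add(y, x)
        return y
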