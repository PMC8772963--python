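"""Global Channel Attention Module (GCAM).

At each tapped encoder stage x the feature map M^x (C_x channels) is pooled
into a 1x1x2C_x channel-attention vector by concatenating global max
pooling and global average pooling (in that order):

    M_cat^x = [GMP(M^x); GAP(M^x)]

A two-layer perceptron refines the vector while scaling it up to the next
stage's width:

    M_RCAMs^x = act_out(W1 * act_hidden(W2 * M_cat^x)),   hidden = 2C_x / r

where r is the shrink rate bounding the parameter cost of a transition to
(C/r)(C + C'), with C = 2C_x, C' = 2C_{x+1}.  The refined vector is
multiplied elementwise into the next stage's concatenated vector, the
refine/multiply pair is repeated down the chain, and the final vector
reweights the channels of the last feature map directly, without a further
refinement step.

With stage channels that double (the common backbone convention) the final
vector length 2C_{x+n-1} equals the last map's channel count C_{x+n}, so
the multiplication is well-posed with no extra parameters.  Non-doubling
chains are rejected unless ``final_projection='allow'``, in which case a
parameter-free fallback averages the GMP and GAP halves when the vector is
exactly twice the channel count.

Feature maps are channel-first: (C, H, W) arrays in the standalone API,
(N, C, H, W) tensors inside the network.

``normalize_taps`` optionally rescales each pooled vector to unit RMS
before it enters the chain.  The named large backbones batch-normalise
their stage outputs, so their pooled statistics are O(1); the desk-scale
stacks here are normalisation-free and carry the raw 8-bit intensity
scale, and standardising the pooled vectors restores comparable
conditioning.  The option is off in this standalone API (the primitives
compose exactly as written above) and on in the assembled network's
default configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, concat
from .nn.layers import Module

__all__ = ["GCAMConfig", "RefinementMLP", "GCAMChain", "pool_concat", "refine",
           "propagate", "apply_to_features", "gcam_forward", "count_params",
           "budget_chain", "make_refinement_mlps", "hidden_width"]

_ACTIVATIONS = {
    "relu": (lambda a: np.maximum(a, 0.0), lambda t: t.relu()),
    "sigmoid": (lambda a: 1.0 / (1.0 + np.exp(-a)), lambda t: t.sigmoid()),
    "identity": (lambda a: a, lambda t: t),
}


@dataclass(frozen=True)
class GCAMConfig:
    """Tap channels [C_x, ..., C_{x+n}] and MLP hyperparameters."""

    tap_channels: tuple
    r: float = 8.0
    hidden_activation: str = "relu"
    output_activation: str = "sigmoid"
    bias_policy: str = "none"          # 'none' or 'both'
    final_projection: str = "forbid"   # 'forbid' or 'allow'
    normalize_taps: bool = False       # RMS-normalise pooled vectors (see below)

    def __post_init__(self):
        object.__setattr__(self, "tap_channels", tuple(int(c) for c in self.tap_channels))
        if len(self.tap_channels) < 2:
            raise ValueError("tap_channels needs at least two levels")
        if any(c < 1 for c in self.tap_channels):
            raise ValueError("all tap channels must be >= 1")
        if self.r <= 0:
            raise ValueError(f"shrink rate r must be > 0, got {self.r}")
        for name in ("hidden_activation", "output_activation"):
            if getattr(self, name) not in _ACTIVATIONS:
                raise ValueError(f"{name} must be one of {sorted(_ACTIVATIONS)}")
        if self.bias_policy not in ("none", "both"):
            raise ValueError(f"bias_policy must be 'none' or 'both', got {self.bias_policy}")
        if self.final_projection not in ("forbid", "allow"):
            raise ValueError("final_projection must be 'forbid' or 'allow'")

    def validate_chain(self):
        """Raise unless the final multiplication is well-posed."""
        c_last, c_prev = self.tap_channels[-1], self.tap_channels[-2]
        if 2 * c_prev != c_last and self.final_projection == "forbid":
            raise ValueError(
                f"chain {list(self.tap_channels)} does not double into the final "
                f"stage (2*{c_prev} != {c_last}); set final_projection='allow' "
                "to fall back to a parameter-free split-and-average projection")


def hidden_width(in_dim: int, r: float) -> int:
    """MLP hidden width: max(1, round(in_dim / r))."""
    return max(1, round(in_dim / r))


class RefinementMLP(Module):
    """The two-layer refinement perceptron of one GCAM transition.

    ``W2`` maps the 2C_x input to the hidden layer, ``W1`` maps the hidden
    layer to the 2C_{x+1} output (the naming follows the order in which the
    weights act on the vector).  The output layer is zero-initialised so a
    fresh module emits a flat gate (sigmoid -> 0.5 per entry) instead of a
    random one, which avoids saturating the sigmoid at initialisation.
    """

    def __init__(self, in_dim: int, out_dim: int, r: float = 8.0,
                 hidden_activation: str = "relu", output_activation: str = "sigmoid",
                 bias_policy: str = "none", rng: np.random.Generator | None = None):
        if in_dim < 1 or out_dim < 1:
            raise ValueError("in_dim and out_dim must be >= 1")
        if r <= 0:
            raise ValueError(f"shrink rate r must be > 0, got {r}")
        rng = rng or np.random.default_rng(0)
        hidden = hidden_width(in_dim, r)
        self.in_dim, self.hidden_dim, self.out_dim = in_dim, hidden, out_dim
        self.r = r
        self.hidden_activation = hidden_activation
        self.output_activation = output_activation
        self.bias_policy = bias_policy
        w2 = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(hidden, in_dim))
        self.W2 = Tensor(w2.astype(np.float32), requires_grad=True)
        self.W1 = Tensor(np.zeros((out_dim, hidden), dtype=np.float32), requires_grad=True)
        if bias_policy == "both":
            self.b2 = Tensor(np.zeros(hidden, dtype=np.float32), requires_grad=True)
            self.b1 = Tensor(np.zeros(out_dim, dtype=np.float32), requires_grad=True)
        else:
            self.b2 = self.b1 = None

    # Tensor path: v is (N, in_dim)
    def forward(self, v: Tensor) -> Tensor:
        act_h = _ACTIVATIONS[self.hidden_activation][1]
        act_o = _ACTIVATIONS[self.output_activation][1]
        h = v @ self.W2.transpose((1, 0))
        if self.b2 is not None:
            h = h + self.b2
        out = act_h(h) @ self.W1.transpose((1, 0))
        if self.b1 is not None:
            out = out + self.b1
        return act_o(out)


# ------------------------------------------------------------ primitive ops
def pool_concat(feature_map: np.ndarray) -> np.ndarray:
    """[GMP; GAP] channel descriptor of a (C, H, W) map -> length 2C."""
    m = np.asarray(feature_map, dtype=np.float64)
    if m.ndim != 3:
        raise ValueError(f"expected a (C, H, W) feature map, got shape {m.shape}")
    return np.concatenate([m.max(axis=(1, 2)), m.mean(axis=(1, 2))])


def refine(v: np.ndarray, mlp) -> np.ndarray:
    """Apply a refinement MLP to a 1-D attention vector.

    Any object with ``in_dim``, ``out_dim`` and a ``refine_vector`` method
    is accepted, which lets tests substitute stub refiners.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1 or v.shape[0] != mlp.in_dim:
        raise ValueError(f"attention vector has length {v.shape}, "
                         f"MLP expects in_dim={mlp.in_dim}")
    if not isinstance(mlp, RefinementMLP):
        return np.asarray(mlp.refine_vector(v), dtype=np.float64)
    act_h = _ACTIVATIONS[mlp.hidden_activation][0]
    act_o = _ACTIVATIONS[mlp.output_activation][0]
    h = mlp.W2.data @ v
    if mlp.b2 is not None:
        h = h + mlp.b2.data
    out = mlp.W1.data @ act_h(h)
    if mlp.b1 is not None:
        out = out + mlp.b1.data
    return act_o(out)


def propagate(refined_prev: np.ndarray, concat_next: np.ndarray) -> np.ndarray:
    """Elementwise product carrying attention to the next level."""
    a, b = np.asarray(refined_prev), np.asarray(concat_next)
    if a.shape != b.shape:
        raise ValueError(f"attention vector lengths differ: {a.shape} vs {b.shape}")
    return a * b


def apply_to_features(feature_map: np.ndarray, attn: np.ndarray,
                      final_projection: str = "forbid") -> np.ndarray:
    """Reweight the channels of a (C, H, W) map by the attention vector.

    A vector of length 2C is accepted only under ``final_projection='allow'``
    and is reduced by averaging its GMP and GAP halves.
    """
    m = np.asarray(feature_map, dtype=np.float64)
    attn = np.asarray(attn, dtype=np.float64)
    c = m.shape[0]
    if attn.shape[0] != c:
        if final_projection == "allow" and attn.shape[0] == 2 * c:
            attn = 0.5 * (attn[:c] + attn[c:])
        else:
            raise ValueError(f"attention length {attn.shape[0]} does not match "
                             f"{c} channels (final_projection={final_projection})")
    return m * attn[:, None, None]


def gcam_forward(maps, cfg: GCAMConfig, mlps) -> np.ndarray:
    """Chain the primitives over maps at tap levels x..x+n (numpy API).

    ``maps`` holds n+1 feature maps; ``mlps`` exactly n-1 refinement MLPs
    (the final multiplication happens without further refinement).
    """
    maps = [np.asarray(m) for m in maps]
    n_levels = len(maps)
    if n_levels != len(cfg.tap_channels):
        raise ValueError(f"got {n_levels} maps for a chain of "
                         f"{len(cfg.tap_channels)} tap levels")
    for m, c in zip(maps, cfg.tap_channels):
        if m.shape[0] != c:
            raise ValueError(f"feature map with {m.shape[0]} channels does not "
                             f"match configured tap {c}")
    if len(mlps) != n_levels - 2:
        raise ValueError(f"need {n_levels - 2} refinement MLPs for "
                         f"{n_levels} tap levels, got {len(mlps)}")
    for mlp, c_in, c_out in zip(mlps, cfg.tap_channels, cfg.tap_channels[1:]):
        if (mlp.in_dim, mlp.out_dim) != (2 * c_in, 2 * c_out):
            raise ValueError(f"MLP dims ({mlp.in_dim}->{mlp.out_dim}) do not match "
                             f"transition 2*{c_in}->2*{c_out}")
    cfg.validate_chain()

    def pooled(m):
        v = pool_concat(m)
        if cfg.normalize_taps:
            v = v / (np.sqrt(np.mean(v * v)) + 1e-6)
        return v

    v = pooled(maps[0])
    for i in range(1, n_levels - 1):
        v = refine(v, mlps[i - 1])
        v = propagate(v, pooled(maps[i]))
    return apply_to_features(maps[-1], v, cfg.final_projection)


# ---------------------------------------------------------- parameter budget
def count_params(c: int, c_prime: int, r: float, bias_policy: str = "none") -> int:
    """Parameter count of one refinement MLP with in=C, out=C'.

    With h = max(1, round(C/r)) the weight tally is h*C + C'*h, i.e.
    (C/r)(C + C') when r divides C; biases add h + C' under policy 'both'.
    When budgeting a GCAM transition the caller passes the already doubled
    widths 2C_x and 2C_{x+1}.
    """
    if c < 1 or c_prime < 1:
        raise ValueError("channel counts must be >= 1")
    if r <= 0:
        raise ValueError(f"shrink rate r must be > 0, got {r}")
    h = hidden_width(c, r)
    total = h * c + c_prime * h
    if bias_policy == "both":
        total += h + c_prime
    return total


def budget_chain(cfg: GCAMConfig) -> int:
    """Total learnable parameters the chain adds to a backbone."""
    cfg.validate_chain()
    ch = cfg.tap_channels
    return sum(count_params(2 * ch[k], 2 * ch[k + 1], cfg.r, cfg.bias_policy)
               for k in range(len(ch) - 2))


def make_refinement_mlps(cfg: GCAMConfig, rng: np.random.Generator | None = None):
    """Construct the n-1 refinement MLPs for a chain configuration."""
    rng = rng or np.random.default_rng(0)
    ch = cfg.tap_channels
    return [RefinementMLP(2 * ch[k], 2 * ch[k + 1], r=cfg.r,
                          hidden_activation=cfg.hidden_activation,
                          output_activation=cfg.output_activation,
                          bias_policy=cfg.bias_policy, rng=rng)
            for k in range(len(ch) - 2)]


# ------------------------------------------------------------- network chain
class GCAMChain(Module):
    """Differentiable GCAM over batched (N, C, H, W) stage tensors."""

    def __init__(self, cfg: GCAMConfig, rng: np.random.Generator | None = None):
        cfg.validate_chain()
        self.cfg = cfg
        self.mlps = make_refinement_mlps(cfg, rng)

    def _pool_concat_t(self, x: Tensor) -> Tensor:
        v = concat([x.max(axis=(2, 3)), x.mean(axis=(2, 3))], axis=1)
        if self.cfg.normalize_taps:
            rms = (v * v).mean(axis=1, keepdims=True) ** 0.5
            v = v * (rms + 1e-6) ** -1.0
        return v

    def forward(self, stage_outputs, force_identity: bool = False) -> Tensor:
        """Reweight the last stage's channels; ``force_identity`` bypasses
        the attention entirely (multiplication by ones)."""
        if len(stage_outputs) != len(self.cfg.tap_channels):
            raise ValueError(f"got {len(stage_outputs)} stage tensors for a chain "
                             f"of {len(self.cfg.tap_channels)} tap levels")
        last = stage_outputs[-1]
        if force_identity:
            return last
        v = self._pool_concat_t(stage_outputs[0])
        for i in range(1, len(stage_outputs) - 1):
            v = self.mlps[i - 1](v)
            v = v * self._pool_concat_t(stage_outputs[i])
        c = last.shape[1]
        if v.shape[1] != c:
            if self.cfg.final_projection == "allow" and v.shape[1] == 2 * c:
                v = (v.reshape(v.shape[0], 2, c).sum(axis=1)) * 0.5
            else:
                raise ValueError(f"attention length {v.shape[1]} does not match "
                                 f"{c} channels of the final map")
        n = v.shape[0]
        return last * v.reshape(n, c, 1, 1)
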