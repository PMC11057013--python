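"""Shuffle Attention: grouped channel/spatial gating fused by a channel shuffle.

The block splits the C channels of a feature map into G groups. Each group is
halved: the first half passes through a *channel* branch (a sigmoid gate on
the globally average-pooled response), the second through a *spatial* branch
(a sigmoid gate on the group-normalized map). The gated halves are
re-concatenated and a channel shuffle with G groups mixes information across
groups. The transform is shape-preserving and adds only 4 affine vectors of
length C/(2G) per group — 2C parameters per insertion site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SAParams",
    "channel_shuffle",
    "channel_branch",
    "spatial_branch",
    "sa_forward",
    "sa_param_count",
]

_GN_EPS = 1e-5


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SAParams:
    """Affine gate parameters for one shuffle-attention block.

    Each array has shape (G, C/(2G)): one scale/shift pair per channel of each
    group's channel-branch half, and one pair for the spatial-branch half.
    """

    groups: int
    channel_scale: np.ndarray
    channel_shift: np.ndarray
    spatial_scale: np.ndarray
    spatial_shift: np.ndarray

    @classmethod
    def init(cls, channels: int, groups: int = 16) -> "SAParams":
        """Default initialization: scale 1, shift 0 (identity-leaning gates)."""
        if channels % (2 * groups) != 0:
            raise ValueError(
                f"channels ({channels}) must be divisible by 2*groups ({2 * groups})"
            )
        half = channels // (2 * groups)
        return cls(
            groups=groups,
            channel_scale=np.ones((groups, half)),
            channel_shift=np.zeros((groups, half)),
            spatial_scale=np.ones((groups, half)),
            spatial_shift=np.zeros((groups, half)),
        )

    @classmethod
    def zeros(cls, channels: int, groups: int = 16) -> "SAParams":
        """All-zero affine parameters; every gate saturates at sigmoid(0)=0.5."""
        p = cls.init(channels, groups)
        p.channel_scale = np.zeros_like(p.channel_scale)
        p.spatial_scale = np.zeros_like(p.spatial_scale)
        return p


def sa_param_count(channels: int, groups: int) -> int:
    """Learnable parameter count of one SA block: 4 * G * (C / (2G)) = 2C."""
    if channels % (2 * groups) != 0:
        raise ValueError(
            f"channels ({channels}) must be divisible by 2*groups ({2 * groups})"
        )
    return 4 * groups * (channels // (2 * groups))


def channel_shuffle(x: np.ndarray, groups: int) -> np.ndarray:
    """Permute channels by reshape(G, C/G) -> transpose -> flatten.

    A pure reindexing: the value multiset is preserved and the permutation is
    invertible (apply with C/groups to undo).
    """
    n, c, h, w = x.shape
    if c % groups != 0:
        raise ValueError(f"channel count {c} not divisible by groups {groups}")
    return (
        x.reshape(n, groups, c // groups, h, w)
        .transpose(0, 2, 1, 3, 4)
        .reshape(n, c, h, w)
    )


def channel_shuffle_inverse(x: np.ndarray, groups: int) -> np.ndarray:
    """Inverse of :func:`channel_shuffle` with the same ``groups``."""
    c = x.shape[1]
    return channel_shuffle(x, c // groups)


def channel_branch(x_sub: np.ndarray, scale: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Gate a half-group by sigmoid(scale * GAP(x) + shift), broadcast over space."""
    c = x_sub.shape[1]
    scale = np.asarray(scale).reshape(1, c, 1, 1)
    shift = np.asarray(shift).reshape(1, c, 1, 1)
    pooled = x_sub.mean(axis=(2, 3), keepdims=True)
    gate = _sigmoid(scale * pooled + shift)
    return gate * x_sub


def spatial_branch(x_sub: np.ndarray, scale: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Gate a half-group by sigmoid(scale * GroupNorm(x) + shift).

    Normalization statistics are taken over (channel-half, H, W) per sample,
    i.e. one group of group normalization per branch input.
    """
    c = x_sub.shape[1]
    scale = np.asarray(scale).reshape(1, c, 1, 1)
    shift = np.asarray(shift).reshape(1, c, 1, 1)
    mu = x_sub.mean(axis=(1, 2, 3), keepdims=True)
    var = x_sub.var(axis=(1, 2, 3), keepdims=True)
    xn = (x_sub - mu) / np.sqrt(var + _GN_EPS)
    gate = _sigmoid(scale * xn + shift)
    return gate * x_sub


def sa_forward(x: np.ndarray, params: SAParams) -> np.ndarray:
    """Full shuffle-attention transform; output shape equals input shape."""
    n, c, h, w = x.shape
    g = params.groups
    if c % (2 * g) != 0:
        raise ValueError(f"channel count {c} not divisible by 2*groups ({2 * g})")
    per_group = c // g
    half = per_group // 2
    out = np.empty_like(x, dtype=float)
    for gi in range(g):
        lo = gi * per_group
        xc = x[:, lo : lo + half]
        xs = x[:, lo + half : lo + per_group]
        out[:, lo : lo + half] = channel_branch(
            xc, params.channel_scale[gi], params.channel_shift[gi]
        )
        out[:, lo + half : lo + per_group] = spatial_branch(
            xs, params.spatial_scale[gi], params.spatial_shift[gi]
        )
    return channel_shuffle(out, g)
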