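"""Scalp montage: the 32-channel Biosemi 10-20 layout with 2-D head coordinates.

Coordinates are an azimuthal-equidistant (top view) projection of the
standard Biosemi-32 electrode positions onto the unit disc; +x is the
subject's right, +y anterior, the vertex (Cz) at the origin.  The montage
also carries a k-nearest-neighbour graph used for bad-channel
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BIOSEMI32_POSITIONS", "Montage", "build_montage"]

# Standard Biosemi 10-20 cap, 32 scalp electrodes, unit-disc projection.
BIOSEMI32_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.2936, +0.9035),
    "AF3": (-0.3229, +0.6925),
    "F7": (-0.7686, +0.5584),
    "F3": (-0.3899, +0.4815),
    "FC1": (-0.2337, +0.2337),
    "FC5": (-0.6941, +0.2664),
    "T7": (-0.9500, 0.0000),
    "C3": (-0.4750, 0.0000),
    "CP1": (-0.2337, -0.2337),
    "CP5": (-0.6941, -0.2664),
    "P7": (-0.7686, -0.5584),
    "P3": (-0.3899, -0.4815),
    "Pz": (0.0000, -0.4750),
    "PO3": (-0.3229, -0.6925),
    "O1": (-0.2936, -0.9035),
    "Oz": (0.0000, -0.9500),
    "O2": (+0.2936, -0.9035),
    "PO4": (+0.3229, -0.6925),
    "P4": (+0.3899, -0.4815),
    "P8": (+0.7686, -0.5584),
    "CP6": (+0.6941, -0.2664),
    "CP2": (+0.2337, -0.2337),
    "C4": (+0.4750, 0.0000),
    "T8": (+0.9500, 0.0000),
    "FC6": (+0.6941, +0.2664),
    "FC2": (+0.2337, +0.2337),
    "F4": (+0.3899, +0.4815),
    "F8": (+0.7686, +0.5584),
    "AF4": (+0.3229, +0.6925),
    "Fp2": (+0.2936, +0.9035),
    "Fz": (0.0000, +0.4750),
    "Cz": (0.0000, 0.0000),
}


@dataclass(frozen=True)
class Montage:
    """Electrode layout with nearest-neighbour sets.

    Attributes
    ----------
    channel_names : tuple of str
        Scalp electrode labels, fixed order.
    positions : ndarray, shape (n_channels, 2)
        Unit-disc coordinates (x right, y anterior).
    neighbor_k : int
        Number of nearest neighbours per channel.
    neighbors : dict
        ``label -> tuple`` of the ``neighbor_k`` closest other channels,
        ordered by increasing Euclidean distance.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray
    neighbor_k: int
    neighbors: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        r = np.hypot(self.positions[:, 0], self.positions[:, 1])
        if np.any(r > 1.0 + 1e-9):
            raise ValueError("positions must lie within the unit disc")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def position(self, name: str) -> tuple[float, float]:
        x, y = self.positions[self.index(name)]
        return float(x), float(y)


def build_montage(neighbor_k: int = 4) -> Montage:
    """Build the 32-channel Biosemi 10-20 montage with a k-NN graph.

    Parameters
    ----------
    neighbor_k : int
        Neighbours per channel, ``1 <= neighbor_k <= 31``.  Neighbour sets
        exclude the channel itself and are determined by Euclidean distance
        in the 2-D projection; exact distance ties are broken by channel
        order.
    """
    if not isinstance(neighbor_k, (int, np.integer)) or not 1 <= neighbor_k <= 31:
        raise ValueError(f"neighbor_k must be an integer in 1..31, got {neighbor_k!r}")
    names = tuple(BIOSEMI32_POSITIONS)
    pos = np.array([BIOSEMI32_POSITIONS[n] for n in names], dtype=float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    neighbors = {}
    for i, name in enumerate(names):
        order = np.argsort(d[i], kind="stable")[:neighbor_k]
        neighbors[name] = tuple(names[j] for j in order)
    return Montage(channel_names=names, positions=pos, neighbor_k=int(neighbor_k), neighbors=neighbors)
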