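"""Sensor layout: co-located channel triplets on a 2-D disc.

MEG systems such as the Elekta/MEGIN arrays place two planar gradiometers
and one magnetometer at each physical sensor site.  Spatial analyses here
(spatial PFI, per-sensor decoding, spatiotemporal blocks) operate on these
triplets rather than on single channels, and on small neighbourhoods of a
site plus its three nearest sites (4 sites, 12 channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: channel types within one site, in storage order
SITE_CHANNEL_TYPES = ("grad", "grad", "mag")


@dataclass
class SensorLayout:
    """Grouping of channels into co-located sites with 2-D positions.

    Attributes
    ----------
    positions : (n_sites, 2) float array
        Site coordinates on the unit disc (flattened helmet view).
    channel_site : (3 * n_sites,) int array
        Site index of every channel; channels of site ``s`` are
        ``3 s, 3 s + 1, 3 s + 2``.
    channel_types : list of str
        ``"grad"``/``"mag"`` tag per channel.
    neighborhoods : list of int arrays
        For every site, the site itself plus its nearest sites
        (up to 3), ordered by distance.
    """

    positions: np.ndarray
    channel_site: np.ndarray
    channel_types: list = field(repr=False)
    neighborhoods: list = field(repr=False)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def n_channels(self) -> int:
        return self.channel_site.shape[0]

    def site_channels(self, site: int) -> np.ndarray:
        """Indices of the 3 channels co-located at ``site``."""
        return np.flatnonzero(self.channel_site == site)

    def neighborhood_channels(self, site: int) -> np.ndarray:
        """Channels of ``site`` and its nearest sites (up to 12 channels)."""
        return np.concatenate(
            [self.site_channels(s) for s in self.neighborhoods[site]]
        )


def make_sensor_layout(n_sites: int, seed: int = 0) -> SensorLayout:
    """Build a layout of ``n_sites`` sensor triplets on a disc.

    Sites are placed on a sunflower (golden-angle) spiral with a small
    seeded jitter, which gives a roughly uniform helmet-like coverage.
    Each site's neighbourhood is itself plus its 3 nearest sites — 4 sites
    totalling 12 channels — or fewer when fewer sites exist.

    Parameters
    ----------
    n_sites : int
        Number of sensor sites; the layout has ``3 * n_sites`` channels.
    seed : int
        Seed for the positional jitter.
    """
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    rng = np.random.default_rng(seed)
    k = np.arange(n_sites)
    r = np.sqrt((k + 0.5) / n_sites)
    theta = k * GOLDEN_ANGLE
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    positions += rng.normal(scale=0.01 / np.sqrt(n_sites), size=positions.shape)

    channel_site = np.repeat(k, 3)
    channel_types = list(SITE_CHANNEL_TYPES) * n_sites

    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
    neighborhoods = []
    n_nb = min(3, n_sites - 1)
    for s in range(n_sites):
        order = np.argsort(d[s], kind="stable")
        # order[0] is the site itself (distance 0)
        neighborhoods.append(order[: n_nb + 1].copy())

    return SensorLayout(positions, channel_site, channel_types, neighborhoods)
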