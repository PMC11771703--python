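"""Synthetic 128-channel montage on the unit sphere.

The layout is not a digitized BioSemi cap: the 18 sensors used by the two
analysis clusters are pinned at approximate 10-05 positions (centro-parietal
ring around CPz for the slow positivity, occipital ring around Oz for the
driven oscillation) and the remaining channels are spread deterministically
over the upper sphere with a Fibonacci lattice.  Positions only matter for
nearest-neighbour interpolation of bad sensors, so angular plausibility is
all that is required.
"""

from __future__ import annotations

import numpy as np

# Nine-sensor centro-parietal cluster used for the late positive potential.
LPP_CLUSTER = [
    "CCP1h", "CP1", "Cz", "CPP1h", "CPz", "CPP2h", "CP2", "CCP2h", "Pz",
]

# Nine-sensor occipital cluster used for the video oscillation-power measure.
OCCIPITAL_CLUSTER = [
    "POz", "O9/I1", "O1", "OI1h", "Oz", "Iz", "O2", "OI2h", "O10/I2",
]

# Approximate spherical coordinates (azimuth deg from +x toward +y, elevation
# deg above the horizontal plane) for the named sensors.  +x = nose, +z = vertex.
_NAMED_POSITIONS = {
    "Cz": (0.0, 90.0),
    "CP1": (150.0, 62.0),
    "CP2": (-150.0, 62.0),
    "CPz": (180.0, 67.0),
    "CCP1h": (155.0, 72.0),
    "CCP2h": (-155.0, 72.0),
    "CPP1h": (165.0, 58.0),
    "CPP2h": (-165.0, 58.0),
    "Pz": (180.0, 45.0),
    "POz": (180.0, 22.0),
    "Oz": (180.0, 0.0),
    "O1": (162.0, 2.0),
    "O2": (-162.0, 2.0),
    "OI1h": (172.0, -8.0),
    "OI2h": (-172.0, -8.0),
    "Iz": (180.0, -15.0),
    "O9/I1": (150.0, -12.0),
    "O10/I2": (-150.0, -12.0),
}

N_CHANNELS = 128


def _sph_to_xyz(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    az = np.deg2rad(azimuth_deg)
    el = np.deg2rad(elevation_deg)
    return np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])


def default_montage(n_channels: int = N_CHANNELS):
    """Return ``(channel_names, positions)`` for the default montage.

    ``positions`` is an ``(n_channels, 3)`` array of unit vectors.  The 18
    cluster sensors are always present and always occupy the same positions;
    filler channels are named ``E1`` .. ``E110``.
    """
    named = list(_NAMED_POSITIONS)
    if n_channels < len(named):
        raise ValueError(
            f"montage needs at least {len(named)} channels for the analysis clusters"
        )
    names = list(named)
    pos = [_sph_to_xyz(*_NAMED_POSITIONS[n]) for n in named]

    n_fill = n_channels - len(named)
    # Fibonacci lattice over elevation -20..90 deg, avoiding the exact named spots.
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i in range(n_fill):
        frac = (i + 0.5) / n_fill
        el = np.rad2deg(np.arcsin(-0.34 + 1.34 * frac))  # sin(el) in [-0.34, 1)
        az = np.rad2deg((golden * i) % (2 * np.pi))
        names.append(f"E{i + 1}")
        pos.append(_sph_to_xyz(az, el))
    positions = np.asarray(pos)
    positions /= np.linalg.norm(positions, axis=1, keepdims=True)
    return names, positions


def great_circle_distances(positions: np.ndarray) -> np.ndarray:
    """Pairwise great-circle (angular) distances for unit-sphere positions."""
    cosang = np.clip(positions @ positions.T, -1.0, 1.0)
    return np.arccos(cosang)
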