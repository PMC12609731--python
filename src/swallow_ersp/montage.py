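"""Standard 10-20 montage: labels, coordinates, neighbor lookup.

Electrode coordinates come from MNE's ``standard_1020`` template and
are projected to 2-D with an azimuthal-equidistant projection (the
usual topographic-map flattening), which is what the spatial
interpolation of rejected channels operates on.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: 32-channel 10-20 layout of the recording cap (sensorimotor row in the middle).
MONTAGE_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "O2",
)

#: Minimal montage for fast cohort runs: sensorimotor row plus flankers.
MONTAGE_9: tuple[str, ...] = (
    "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4",
)

SENSORIMOTOR: tuple[str, str, str] = ("C3", "Cz", "C4")


def montage_for(n_channels: int) -> tuple[str, ...]:
    """Pick the named layout for a requested channel count."""
    if n_channels == 32:
        return MONTAGE_32
    if n_channels == 9:
        return MONTAGE_9
    raise ValueError(
        f"no built-in layout with {n_channels} channels (have 9 and 32); "
        "pass explicit channel labels instead"
    )


@lru_cache(maxsize=8)
def positions_2d(labels: tuple[str, ...]) -> np.ndarray:
    """(n, 2) azimuthal-equidistant electrode coordinates."""
    import mne

    try:
        std = mne.channels.make_standard_montage("colin27_1020")
    except ValueError:  # older MNE only ships the legacy name
        std = mne.channels.make_standard_montage("standard_1020")
    pos3 = std.get_positions()["ch_pos"]
    out = np.empty((len(labels), 2))
    for i, lab in enumerate(labels):
        if lab not in pos3:
            raise KeyError(f"channel {lab!r} not in the standard 10-20 montage")
        x, y, z = pos3[lab]
        r = np.sqrt(x * x + y * y + z * z)
        theta = np.arccos(np.clip(z / r, -1.0, 1.0))  # polar angle from vertex
        phi = np.arctan2(y, x)
        out[i] = theta * np.cos(phi), theta * np.sin(phi)
    return out


def nearest_neighbors(labels: list[str] | tuple[str, ...], k: int = 4
                      ) -> dict[str, list[tuple[str, float]]]:
    """For each electrode, its k nearest neighbors and distances (2-D)."""
    labels = tuple(labels)
    pos = positions_2d(labels)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    out: dict[str, list[tuple[str, float]]] = {}
    for i, lab in enumerate(labels):
        order = np.argsort(d[i])
        neigh = [(labels[j], float(d[i, j])) for j in order if j != i][:k]
        out[lab] = neigh
    return out
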