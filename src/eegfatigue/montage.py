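"""10-20 scalp montage used by the synthetic generator and topography tools.

A 32-channel subset of the international 10-20/10-10 system matching a wet
32-electrode research cap.  Positions are approximate 2-D projections onto
the unit disc (nose up, left ear at negative x) — adequate for spatial
oscillator profiles, electrode subsets and topographic maps, not for source
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "make_montage", "MONTAGE_32"]

# label -> (x, y) on the unit disc
MONTAGE_32: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.80, 0.59), "F3": (-0.55, 0.48), "Fz": (0.0, 0.48),
    "F4": (0.55, 0.48), "F8": (0.80, 0.59),
    "FC5": (-0.60, 0.25), "FC1": (-0.20, 0.25),
    "FC2": (0.20, 0.25), "FC6": (0.60, 0.25),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.60, -0.25), "CP1": (-0.20, -0.25),
    "CP2": (0.20, -0.25), "CP6": (0.60, -0.25),
    "P7": (-0.80, -0.59), "P3": (-0.55, -0.48), "Pz": (0.0, -0.48),
    "P4": (0.55, -0.48), "P8": (0.80, -0.59),
    "PO7": (-0.55, -0.73), "PO3": (-0.28, -0.73), "POz": (0.0, -0.73),
    "PO4": (0.28, -0.73), "PO8": (0.55, -0.73),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

# Ten sensorimotor electrodes used for mu-rhythm atom extraction.  The exact
# set is a documented convention: the symmetric fronto-central/centro-parietal
# ring around the hand-knob areas.
CENTRAL_10 = ("FC5", "FC1", "FC2", "FC6", "C3", "C4", "CP5", "CP1", "CP2", "CP6")

# Posterior electrodes carrying the resting alpha rhythm.
PARIETO_OCCIPITAL = (
    "P7", "P3", "Pz", "P4", "P8", "PO7", "PO3", "POz", "PO4", "PO8", "O1", "O2",
)

FRONTAL = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")


@dataclass(frozen=True)
class Montage:
    """Electrode labels, 2-D positions and named subsets."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2), unit disc
    subsets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(lb) for lb in labels], dtype=int)

    def subset_indices(self, name: str) -> np.ndarray:
        return self.indices(self.subsets[name])


def make_montage(n_channels: int = 32) -> Montage:
    """Return the supported scalp montage.

    Only the 32-channel 10-20 layout is supported; other sizes raise
    ``ValueError``.  The montage defines the named subsets ``"central10"``
    (sensorimotor ring for mu-atom extraction), ``"parieto-occipital"``
    (alpha generators) and ``"frontal"`` (blink-dominant sites).
    """
    if n_channels != 32:
        raise ValueError(f"only the 32-channel 10-20 montage is supported, got {n_channels}")
    labels = tuple(MONTAGE_32)
    positions = np.array([MONTAGE_32[lb] for lb in labels], dtype=float)
    subsets = {
        "central10": CENTRAL_10,
        "parieto-occipital": PARIETO_OCCIPITAL,
        "frontal": FRONTAL,
    }
    return Montage(labels=labels, positions=positions, subsets=subsets)
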