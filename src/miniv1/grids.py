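"""The 15-position stimulus grid used for receptive-field mapping.

Stimuli are flashed at 3 eccentricities (5°, 7°, 9° of visual angle from the
fixation point) crossed with 5 clock-position azimuths in the hemifield
contralateral to the recorded hemisphere: 1–5 o'clock for a left-hemisphere
recording, 11–7 o'clock for a right-hemisphere recording.  Positions are
numbered 1..15 in row-major order (eccentricity ring x azimuth step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ECCENTRICITIES = (5.0, 7.0, 9.0)
LEFT_HEMI_CLOCKS = (1, 2, 3, 4, 5)
RIGHT_HEMI_CLOCKS = (11, 10, 9, 8, 7)


@dataclass(frozen=True)
class StimulusGrid:
    """3 x 5 lattice of peripheral stimulus positions.

    Grid position ``p`` (1-based) maps to ring index ``(p-1)//5`` and azimuth
    index ``(p-1)%5``.  Adjacency is 8-connected on the lattice: two positions
    are neighbors when both their ring and azimuth indices differ by at most 1.
    """

    eccentricities: tuple = ECCENTRICITIES
    clock_positions: tuple = LEFT_HEMI_CLOCKS

    @property
    def n_positions(self) -> int:
        return len(self.eccentricities) * len(self.clock_positions)

    @property
    def positions(self) -> list:
        return list(range(1, self.n_positions + 1))

    def to_ring_azimuth(self, position: int) -> tuple:
        """1-based grid position -> (ring index, azimuth index)."""
        if not 1 <= position <= self.n_positions:
            raise ValueError(f"position {position} outside 1..{self.n_positions}")
        return (position - 1) // len(self.clock_positions), (position - 1) % len(
            self.clock_positions
        )

    def from_ring_azimuth(self, ring: int, azimuth: int) -> int:
        if not (0 <= ring < len(self.eccentricities)):
            raise ValueError("ring index out of range")
        if not (0 <= azimuth < len(self.clock_positions)):
            raise ValueError("azimuth index out of range")
        return ring * len(self.clock_positions) + azimuth + 1

    def label(self, position: int) -> str:
        ring, az = self.to_ring_azimuth(position)
        return f"{self.eccentricities[ring]:g}deg_{self.clock_positions[az]}oclock"

    def are_neighbors(self, a: int, b: int) -> bool:
        """8-connected lattice adjacency (a position is not its own neighbor)."""
        if a == b:
            return False
        ra, aa = self.to_ring_azimuth(a)
        rb, ab = self.to_ring_azimuth(b)
        return abs(ra - rb) <= 1 and abs(aa - ab) <= 1

    def grid_distance(self, a: int, b: int) -> float:
        """Euclidean distance in lattice steps (ring step, azimuth step)."""
        ra, aa = self.to_ring_azimuth(a)
        rb, ab = self.to_ring_azimuth(b)
        return float(np.hypot(ra - rb, aa - ab))


def rf_attenuation(grid: StimulusGrid, stim_position: int, rf_position: int,
                   scale: float = 1.0) -> float:
    """Gaussian falloff of evoked response with lattice distance from the RF.

    Attenuation is 1 at the cell's own receptive-field position and decays as
    ``exp(-d^2 / (2 scale^2))`` over grid distance ``d``, with ``scale`` in
    lattice steps.  Emulates a compact receptive field on the mapping grid.
    """
    d = grid.grid_distance(stim_position, rf_position)
    return float(np.exp(-(d ** 2) / (2.0 * scale ** 2)))
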