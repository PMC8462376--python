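"""Study design: grid transects with paired habitat sampling.

The sampling scheme this package targets is a set of rectangular forest
transects, each sampled at a regular grid of locations; at every location
two microbial communities are collected, one from the topsoil and one from
the leaf surfaces (phylloplane) directly above it.  The two habitats
therefore share an identical spatial frame within each transect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SOIL = "soil"
PHYLLOPLANE = "phylloplane"
HABITATS = (SOIL, PHYLLOPLANE)


@dataclass(frozen=True)
class StudyDesign:
    """Geometry of a grid-transect, paired-habitat sampling campaign.

    Parameters
    ----------
    n_transects:
        Number of independent transects.
    grid_rows, grid_cols:
        Grid dimensions within one transect; ``grid_rows * grid_cols``
        locations are sampled per transect.
    spacing_x, spacing_y:
        Grid spacing in meters along the two transect axes.
    habitats:
        Ordered habitat labels; exactly two in the paired design.
    """

    n_transects: int = 6
    grid_rows: int = 12
    grid_cols: int = 3
    spacing_x: float = 5.0
    spacing_y: float = 40.0 / 11.0
    habitats: tuple[str, ...] = field(default=HABITATS)

    def __post_init__(self) -> None:
        if self.n_transects < 1:
            raise ValueError("n_transects must be >= 1")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.spacing_x <= 0 or self.spacing_y <= 0:
            raise ValueError("grid spacings must be > 0")
        if len(self.habitats) != 2:
            raise ValueError("paired design requires exactly 2 habitats")

    @property
    def locations_per_transect(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def n_samples(self) -> int:
        """Total community samples: locations x habitats x transects."""
        return self.locations_per_transect * len(self.habitats) * self.n_transects

    def grid_coordinates(self) -> list[tuple[float, float]]:
        """Within-transect (x, y) meters for each location index.

        Location indices run row-major: index ``i`` sits at column
        ``i % grid_cols`` and row ``i // grid_cols``, with the origin at
        the transect corner.
        """
        return [
            (
                (i % self.grid_cols) * self.spacing_x,
                (i // self.grid_cols) * self.spacing_y,
            )
            for i in range(self.locations_per_transect)
        ]

    def transect_ids(self) -> list[str]:
        return [f"T{k + 1}" for k in range(self.n_transects)]


#: The default field design: 6 transects of 36 locations (3 x 12 grid
#: inside a 10 m x 40 m rectangle), two habitats -- 432 samples in total.
FIELD_DESIGN = StudyDesign()
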