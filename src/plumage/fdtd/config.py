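"""Solver configuration.

Lengths are in micrometres and time is measured in units of travel distance
(c = 1), so one optical period of 700 nm light is 0.7 µm of simulated time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: standard (non-dispersive) refractive index of feather keratin
N_KERATIN_DEFAULT = 1.56

#: Courant number dt/h must stay below 1/sqrt(2) in 2D
COURANT_LIMIT = 1.0 / np.sqrt(2.0)


@dataclass
class FDTDConfig:
    mesh_nm: float = 25.0
    wavelengths_nm: tuple = (400.0, 500.0, 600.0, 700.0)
    polarization: str = "both"          # "TM", "TE" or "both" (averaged)
    n_keratin: float = N_KERATIN_DEFAULT
    n_air: float = 1.0
    pml_cells: int = 20
    courant: float = 0.65               # dt = courant * h, capped at 1/sqrt(2)
    ramp_periods: float = 4.0           # smooth CW turn-on
    settle_crossings: float = 2.0       # domain traversals before steady-state checks
    measure_periods: int = 2            # periods used for the phasor measurement
    steady_tol: float = 1e-3            # relative per-period change in monitor flux
    max_periods: int = 4000
    check_convergence: bool = True
    #: rescale permittivities per run so the grid's numerical phase index
    #: equals the physical index at the run wavelength (axial propagation);
    #: removes the leading numerical-dispersion bias at coarse meshes
    dispersion_compensation: bool = True

    def __post_init__(self):
        if self.courant > COURANT_LIMIT:
            raise ValueError(
                f"courant {self.courant} exceeds 2D stability limit {COURANT_LIMIT:.4f}"
            )
        if self.polarization not in ("TM", "TE", "both"):
            raise ValueError("polarization must be 'TM', 'TE' or 'both'")
        self.wavelengths_nm = tuple(float(w) for w in self.wavelengths_nm)

    @property
    def h_um(self) -> float:
        return self.mesh_nm / 1000.0

    def with_(self, **kw) -> "FDTDConfig":
        return replace(self, **kw)


#: paper-scale profile: 25 nm mesh, dense wavelength set
PAPER_PROFILE = FDTDConfig(
    mesh_nm=25.0,
    wavelengths_nm=tuple(np.arange(400.0, 701.0, 50.0)),
)

#: desk-scale profile for tests and the acceptance script: coarser mesh,
#: fewer wavelengths; scene builders additionally shorten barbules
COARSE_PROFILE = FDTDConfig(
    mesh_nm=75.0,
    wavelengths_nm=(450.0, 550.0, 650.0),
)
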