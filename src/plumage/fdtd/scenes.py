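"""Feather-geometry builders.

A :class:`FeatherScene` is a rasterized relative-permittivity strip covering
the structure; the solver pads it with source, monitor and PML rows.  Two
families of scenes mirror the two simulation campaigns:

* ``dihedral_scene`` — a periodic array of strap-shaped barbules of length L
  and thickness t, tilted by an angle theta out of the feather plane, sitting
  on a keratin substrate that extends down through the lower absorbing
  boundary (no feather–air interface at the bottom: in a plumage the underside
  of a feather rests on the next feather).  The barbules tile the periodic
  cell edge to edge, so at theta = 0 they form a flat keratin surface.
* ``oblong_barb_scene`` — a single elliptical barb cross-section (height H x
  width W), optionally with a circular air vacuole, a truncated base (barb
  silhouette extended down through the lower PML, removing the bottom
  interface), or angled side barbules.

Validation scenes (``slab_scene``, ``halfspace_scene``, ``empty_scene``)
exercise the solver against Fresnel / transfer-matrix closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..errors import DomainSizeError
from .config import FDTDConfig, N_KERATIN_DEFAULT


@dataclass
class FeatherScene:
    """Rasterized material map of the structure region.

    ``eps`` has shape (nx, ny) with x along the periodic direction and y
    increasing upward; row 0 is the bottom of the strip.  ``extend_bottom``
    tells the solver to continue the bottom row of material through the lower
    padding and PML (no bottom interface).
    """

    eps: np.ndarray
    h: float                      # mesh pitch, µm
    period: float                 # physical width of the periodic cell, µm
    y_bottom: float               # y coordinate of the bottom strip row center, µm
    extend_bottom: bool
    descriptor: dict
    name: str = "scene"

    @property
    def nx(self) -> int:
        return self.eps.shape[0]

    @property
    def ny(self) -> int:
        return self.eps.shape[1]

    @property
    def y_top(self) -> float:
        return self.y_bottom + (self.ny - 1) * self.h

    def x_coords(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.h - self.period / 2.0

    def y_coords(self) -> np.ndarray:
        return self.y_bottom + np.arange(self.ny) * self.h


def _grid(width: float, height: float, h: float, y_bottom: float):
    nx = max(int(round(width / h)), 4)
    ny = max(int(round(height / h)) + 1, 4)
    x = (np.arange(nx) + 0.5) * h - (nx * h) / 2.0
    y = y_bottom + np.arange(ny) * h
    return nx, ny, x, y


def empty_scene(width: float = 2.0, height: float = 2.0, *, cfg: FDTDConfig = None) -> FeatherScene:
    """All-air domain (vacuum check: R = 0, T = 1)."""
    h = (cfg.h_um if cfg else 0.025)
    nx, ny, _, _ = _grid(width, height, h, 0.0)
    return FeatherScene(np.ones((nx, ny)), h, nx * h, 0.0, False,
                        {"type": "empty"}, "empty")


def halfspace_scene(width: float = 2.0, depth: float = 3.0, *,
                    n: float = N_KERATIN_DEFAULT, cfg: FDTDConfig = None) -> FeatherScene:
    """Keratin half-space with a flat top at y = 0, extended through the lower PML."""
    h = (cfg.h_um if cfg else 0.025)
    nx, ny, _, y = _grid(width, depth + 1.0, h, -depth)
    eps = np.ones((nx, ny))
    eps[:, y <= 0.0] = n * n
    return FeatherScene(eps, h, nx * h, -depth, True,
                        {"type": "halfspace", "n": n}, "halfspace")


def slab_scene(thickness: float = 1.0, width: float = 2.0, *,
               n: float = N_KERATIN_DEFAULT, cfg: FDTDConfig = None) -> FeatherScene:
    """Free-standing keratin slab in air (transfer-matrix oracle target)."""
    h = (cfg.h_um if cfg else 0.025)
    nx, ny, _, y = _grid(width, thickness + 2.0, h, -thickness - 1.0)
    eps = np.ones((nx, ny))
    eps[:, (y >= -thickness) & (y < 0.0)] = n * n
    return FeatherScene(eps, h, nx * h, float(y[0]), False,
                        {"type": "slab", "n": n, "thickness": thickness}, "slab")


def dihedral_scene(theta_deg: float, *,
                   barbule_length: float = 80.0,
                   barbule_thickness: float = 2.0,
                   r_barb: float = 12.5,
                   substrate_depth: float = 2.0,
                   n_keratin: float = N_KERATIN_DEFAULT,
                   cfg: FDTDConfig = None) -> FeatherScene:
    """Periodic dihedral-barbule relief over a keratin substrate.

    Each period holds one ridge formed by two mirrored barbule faces of
    length ``barbule_length`` tilted ``theta_deg`` out of the feather plane
    (period 2 L cos(theta)); ``barbule_thickness`` caps the ridge.  With the
    feather bottom extended through the lower PML the scene is solid keratin
    under a triangular surface: flat at 0° (Fresnel reflectance), deep
    light-trapping V-grooves at steep angles.  ``r_barb`` (the hemispherical
    barb radius of the full geometry) is recorded in the descriptor for
    provenance; the barb body is subsumed in the substrate.
    """
    if not (0.0 <= theta_deg <= 80.0):
        raise DomainSizeError(f"barbule angle {theta_deg} outside [0, 80] degrees")
    if barbule_length <= 0 or barbule_thickness <= 0:
        raise DomainSizeError("barbule dimensions must be positive")
    h = (cfg.h_um if cfg else 0.025)
    th = np.deg2rad(theta_deg)
    L, t = barbule_length, barbule_thickness
    # two mirrored barbule faces of length L meeting at the angle theta form
    # one dihedral ridge per period; with the feather bottom extended through
    # the lower PML, the surface is a symmetric triangular relief whose
    # grooves trap light (each wall bounce turns the ray by the apex angle
    # and loses ~96% of its power into the keratin)
    period = 2.0 * L * np.cos(th)
    top = L * np.sin(th) + t * np.cos(th)
    depth = max(substrate_depth, 1.0)
    nx, ny, x, y = _grid(period, depth + top, h, -depth)
    eps = np.ones((nx, ny))
    X, Y = np.meshgrid(x, y, indexing="ij")
    surface = np.tan(th) * (period / 2.0 - np.abs(X)) if theta_deg > 0 else np.zeros_like(X)
    inside = Y <= surface + t * np.cos(th)
    eps[inside] = n_keratin ** 2
    desc = {"type": "dihedral", "theta_deg": theta_deg, "barbule_length": L,
            "barbule_thickness": t, "r_barb": r_barb}
    return FeatherScene(eps, h, nx * h, -depth, True, desc, f"dihedral_{theta_deg:g}")


def oblong_barb_scene(height_um: float, width_um: float, *,
                      vacuole_diameter: float = 0.0,
                      truncate: bool = False,
                      barbule_angle: Optional[float] = None,
                      barbule_length: float = 10.0,
                      barbule_thickness: float = 2.0,
                      domain_width: Optional[float] = None,
                      margin_top: float = 5.0,
                      margin_bottom: float = 3.0,
                      n_keratin: float = N_KERATIN_DEFAULT,
                      cfg: FDTDConfig = None) -> FeatherScene:
    """Elliptical barb cross-section centered at (0, 0).

    ``truncate`` replaces everything below the ellipse midline with a column
    of keratin of the ellipse's full width extended through the lower PML,
    removing the feather-bottom interface.  ``vacuole_diameter`` carves a
    circular air vacuole at the center.  Optional barbules are straps attached
    at the ellipse's widest points, tilted ``barbule_angle`` degrees upward.

    By default the periodic cell is exactly one barb wide: adjacent feathers
    lie flush in a plumage, so the barbs tile edge to edge.
    """
    if height_um <= 0 or width_um <= 0:
        raise DomainSizeError("barb dimensions must be positive")
    if domain_width is None:
        domain_width = width_um
    if width_um > domain_width:
        raise DomainSizeError(
            f"barb width {width_um} µm exceeds domain width {domain_width} µm")
    h = (cfg.h_um if cfg else 0.025)
    a, b = width_um / 2.0, height_um / 2.0  # semi-axes (x, y)
    y_bot = -b - margin_bottom
    y_top = b + margin_top
    nx, ny, x, y = _grid(domain_width, y_top - y_bot, h, y_bot)
    X, Y = np.meshgrid(x, y, indexing="ij")
    inside = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
    if truncate:
        inside |= (np.abs(X) <= a) & (Y < 0.0)
    if barbule_angle is not None:
        th = np.deg2rad(barbule_angle)
        ct, st = np.cos(th), np.sin(th)
        L, t = barbule_length, barbule_thickness
        for sign in (+1, -1):
            u = sign * (X - sign * a) * ct + Y * st
            v = -sign * (X - sign * a) * st + Y * ct
            inside |= (u >= 0) & (u <= L) & (np.abs(v) <= t / 2.0)
    eps = np.ones((nx, ny))
    eps[inside] = n_keratin ** 2
    if vacuole_diameter > 0:
        vac = X ** 2 + Y ** 2 <= (vacuole_diameter / 2.0) ** 2
        eps[vac] = 1.0
    desc = {"type": "oblong_barb", "height": height_um, "width": width_um,
            "vacuole_diameter": vacuole_diameter, "truncate": truncate,
            "barbule_angle": barbule_angle}
    return FeatherScene(eps, h, nx * h, y_bot, truncate, desc,
                        f"barb_{height_um:g}x{width_um:g}")


_BUILDERS = {
    "dihedral": lambda d, cfg: dihedral_scene(
        d.get("theta_deg", 0.0),
        barbule_length=d.get("barbule_length", 80.0),
        barbule_thickness=d.get("barbule_thickness", 2.0),
        r_barb=d.get("r_barb", 12.5), cfg=cfg),
    "oblong_barb": lambda d, cfg: oblong_barb_scene(
        d["height"], d["width"],
        vacuole_diameter=d.get("vacuole_diameter", 0.0),
        truncate=d.get("truncate", False),
        barbule_angle=d.get("barbule_angle"),
        domain_width=d.get("domain_width", 44.0), cfg=cfg),
    "slab": lambda d, cfg: slab_scene(d.get("thickness", 1.0),
                                      n=d.get("n", N_KERATIN_DEFAULT), cfg=cfg),
    "halfspace": lambda d, cfg: halfspace_scene(n=d.get("n", N_KERATIN_DEFAULT), cfg=cfg),
    "empty": lambda d, cfg: empty_scene(cfg=cfg),
}


def build_scene(descriptor: dict, cfg: FDTDConfig = None) -> FeatherScene:
    """Build a scene from a plain descriptor dict (YAML/JSON friendly)."""
    kind = descriptor.get("type")
    if kind not in _BUILDERS:
        raise DomainSizeError(f"unknown scene type {kind!r}")
    return _BUILDERS[kind](descriptor, cfg)
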