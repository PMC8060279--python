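"""Yee-grid time stepping, steady-state CW measurement, and power monitors.

Conventions
-----------
Natural units: c = eps0 = mu0 = 1, lengths in µm, so time is in µm of travel.
The grid is periodic in x; split-field PML terminates both y ends.  TM means
E = Ez zhat (out of plane); TE means H = Hz zhat.  A soft line source above
the structure launches a ramped continuous wave at one wavelength; after the
monitor fluxes settle, complex field phasors are extracted by a discrete
Fourier transform over an integer number of periods.

Reflectance is the upward flux of the scattered field (total minus an
empty-domain reference) at a monitor between source and structure, divided
by the incident downward flux; transmittance is the net downward total flux
at a monitor below (or, for scenes whose material extends through the lower
PML, inside) the structure.

Region power fluxes are quoted in W/m² for a unit-amplitude (1 V/m) source
using the peak-field convention S = Re(E x H*): the magnitude of the
time-averaged Poynting vector (power flow through the area regardless of
direction) is integrated over each monitor square and expressed per
reference mesh cell of 25 x 25 nm, so a square of air carrying the incident
plane wave transmits (7.5 µm / 25 nm)^2 x |E0|^2/eta0 = 238.9 W/m².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from ..errors import ConvergenceError, RegionWarning, ResolutionWarning
from .config import FDTDConfig
from .scenes import FeatherScene

#: reference monitor cell (25 nm)^2, µm²
A_REF_UM2 = 0.025 * 0.025
#: peak-convention flux density of a unit-amplitude (1 V/m) plane wave, W/m²
S0_WM2 = 1.0 / 376.730313668

_PML_GRADE = 3
_PML_R0 = 1e-8


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _tm_chunk(ez, eza, ezb, hx, hy, cae, cbe, dthe, cah, cbh, dth,
              js, src, cosE, sinE, cosH, sinH,
              mon_rows, mE_re, mE_im, mH_re, mH_im,
              do_full, fE_re, fE_im, fH_re, fH_im, f2_re, f2_im):
    nx, ny = ez.shape
    nsteps = src.shape[0]
    nmon = mon_rows.shape[0]
    for n in range(nsteps):
        for i in range(nx):
            for j in range(ny - 1):
                hx[i, j] = cah[j] * hx[i, j] - cbh[j] * (ez[i, j + 1] - ez[i, j])
        for i in range(nx):
            ip = i + 1 if i + 1 < nx else 0
            for j in range(ny):
                hy[i, j] += dth * (ez[ip, j] - ez[i, j])
        for i in range(nx):
            im = i - 1 if i > 0 else nx - 1
            for j in range(1, ny - 1):
                eza[i, j] += dthe[i, j] * (hy[i, j] - hy[im, j])
                ezb[i, j] = cae[j] * ezb[i, j] - cbe[i, j] * (hx[i, j] - hx[i, j - 1])
                ez[i, j] = eza[i, j] + ezb[i, j]
        sv = src[n]
        for i in range(nx):
            eza[i, js] += sv
            ez[i, js] += sv
        cE = cosE[n]; sE = sinE[n]; cH = cosH[n]; sH = sinH[n]
        for k in range(nmon):
            j = mon_rows[k]
            for i in range(nx):
                e = ez[i, j]
                hc = 0.5 * (hx[i, j - 1] + hx[i, j])
                mE_re[k, i] += e * cE
                mE_im[k, i] -= e * sE
                mH_re[k, i] += hc * cH
                mH_im[k, i] -= hc * sH
        if do_full:
            for i in range(nx):
                im = i - 1 if i > 0 else nx - 1
                for j in range(1, ny - 1):
                    e = ez[i, j]
                    hc = 0.5 * (hx[i, j - 1] + hx[i, j])
                    h2 = 0.5 * (hy[im, j] + hy[i, j])
                    fE_re[i, j] += e * cE
                    fE_im[i, j] -= e * sE
                    fH_re[i, j] += hc * cH
                    fH_im[i, j] -= hc * sH
                    f2_re[i, j] += h2 * cH
                    f2_im[i, j] -= h2 * sH


@njit(cache=True)
def _te_chunk(ex, ey, hz, hza, hzb, cae, cbex, dthey, cah, cbh, dth,
              js, src, cosE, sinE, cosH, sinH,
              mon_rows, mE_re, mE_im, mH_re, mH_im,
              do_full, fE_re, fE_im, fH_re, fH_im, f2_re, f2_im):
    nx, ny = ex.shape
    nsteps = src.shape[0]
    nmon = mon_rows.shape[0]
    for n in range(nsteps):
        for i in range(nx):
            ip = i + 1 if i + 1 < nx else 0
            for j in range(ny - 1):
                hza[i, j] -= dth * (ey[ip, j] - ey[i, j])
                hzb[i, j] = cah[j] * hzb[i, j] + cbh[j] * (ex[i, j + 1] - ex[i, j])
                hz[i, j] = hza[i, j] + hzb[i, j]
        for i in range(nx):
            for j in range(1, ny - 1):
                ex[i, j] = cae[j] * ex[i, j] + cbex[i, j] * (hz[i, j] - hz[i, j - 1])
        for i in range(nx):
            im = i - 1 if i > 0 else nx - 1
            for j in range(ny - 1):
                ey[i, j] -= dthey[i, j] * (hz[i, j] - hz[im, j])
        sv = src[n]
        for i in range(nx):
            ex[i, js] += sv
        cE = cosE[n]; sE = sinE[n]; cH = cosH[n]; sH = sinH[n]
        for k in range(nmon):
            j = mon_rows[k]
            for i in range(nx):
                e = ex[i, j]
                hc = 0.5 * (hz[i, j - 1] + hz[i, j])
                mE_re[k, i] += e * cE
                mE_im[k, i] -= e * sE
                mH_re[k, i] += hc * cH
                mH_im[k, i] -= hc * sH
        if do_full:
            for i in range(nx):
                ip = i + 1 if i + 1 < nx else 0
                for j in range(1, ny - 1):
                    e = ex[i, j]
                    hc = 0.5 * (hz[i, j - 1] + hz[i, j])
                    # Ey colocated to (i+1/2, j): average the 4 surrounding edges
                    e2 = 0.25 * (ey[i, j - 1] + ey[i, j] + ey[ip, j - 1] + ey[ip, j])
                    fE_re[i, j] += e * cE
                    fE_im[i, j] -= e * sE
                    fH_re[i, j] += hc * cH
                    fH_im[i, j] -= hc * sH
                    f2_re[i, j] += e2 * cE
                    f2_im[i, j] -= e2 * sE


# ---------------------------------------------------------------------------
# domain assembly

@dataclass
class _Domain:
    eps: np.ndarray
    h: float
    y0: float                 # y of row 0 cell center
    js: int                   # source row
    j_refl: int               # reflection monitor row (between source and structure)
    j_trans: int              # transmission monitor row (below / inside base)
    pml: int

    @property
    def shape(self):
        return self.eps.shape


def _assemble(scene: FeatherScene, cfg: FDTDConfig,
              allow_collapse: bool = True) -> _Domain:
    h = scene.h
    pml = cfg.pml_cells
    lam_max = max(cfg.wavelengths_nm) / 1000.0
    gap = max(int(round(1.0 / h)), int(round(lam_max / h)) + 2, 6)
    half = max(gap // 2, 3)
    pad_bot = pml + gap
    j0 = pad_bot
    j_trans = pml + half
    j_refl = j0 + scene.ny + gap
    js = j_refl + half
    ny = js + half + pml
    scene_eps = scene.eps
    # x-invariant scenes (flat layers) are exactly representable by a few
    # periodic columns; collapsing them makes fine-mesh 1D-like runs cheap.
    # Disabled when absolute region areas matter (power monitors).
    if allow_collapse and np.all(scene_eps == scene_eps[:1, :]):
        scene_eps = scene_eps[:4, :]
    nx = scene_eps.shape[0]
    eps = np.ones((nx, ny))
    eps[:, j0:j0 + scene.ny] = scene_eps
    if scene.extend_bottom:
        eps[:, :j0] = scene_eps[:, :1]
    return _Domain(eps, h, scene.y_bottom - pad_bot * h, js, j_refl, j_trans, pml)


def _pml_rates(ny: int, pml: int, h: float):
    """Attenuation-rate profiles (sigma/eps) at integer and half rows."""
    smax = (_PML_GRADE + 1) * (-np.log(_PML_R0)) / (2.0 * pml * h)
    jj = np.arange(ny, dtype=float)
    sE = np.zeros(ny)
    bot = jj < pml
    sE[bot] = smax * ((pml - jj[bot]) / pml) ** _PML_GRADE
    top = jj >= ny - pml
    sE[top] = smax * ((jj[top] - (ny - pml - 1)) / pml) ** _PML_GRADE
    jh = jj[:-1] + 0.5
    sH = np.zeros(ny - 1)
    bot = jh < pml
    sH[bot] = smax * ((pml - jh[bot]) / pml) ** _PML_GRADE
    top = jh > ny - pml - 1
    sH[top] = smax * ((jh[top] - (ny - pml - 1)) / pml) ** _PML_GRADE
    return sE, sH


# ---------------------------------------------------------------------------
# single-wavelength solve

class _Phasors:
    """Monitor-row and full-field complex phasors from one steady-state run."""

    def __init__(self, mE, mH, fE, fH, f2, flux_refl, flux_trans, spp, dt):
        self.mE, self.mH = mE, mH          # [2, nx]: rows (refl, trans)
        self.fE, self.fH = fE, fH          # [nx, ny] or None
        self.f2 = f2                       # second transverse component (Hy / Ey)
        self.flux_refl = flux_refl
        self.flux_trans = flux_trans
        self.spp, self.dt = spp, dt


def _pol_sign(pol: str) -> float:
    # S_y = +Re(Ez Hx*) for TM, -Re(Ex Hz*) for TE
    return 1.0 if pol == "TM" else -1.0


def _row_flux(E: np.ndarray, H: np.ndarray, pol: str) -> float:
    """Net +y Poynting flux through a monitor row (per unit cell width h applied later)."""
    return _pol_sign(pol) * float(np.sum(np.real(E * np.conj(H))))


def _run_single(dom: _Domain, cfg: FDTDConfig, lam_um: float, pol: str,
                want_full: bool) -> _Phasors:
    h, nx, ny = dom.h, dom.eps.shape[0], dom.eps.shape[1]
    period = lam_um
    omega = 2.0 * np.pi / lam_um
    spp = int(np.ceil(period / (cfg.courant * h)))
    dt = period / spp

    sE, sH = _pml_rates(ny, dom.pml, h)
    cae = (1.0 - sE * dt / 2.0) / (1.0 + sE * dt / 2.0)
    cah = (1.0 - sH * dt / 2.0) / (1.0 + sH * dt / 2.0)
    cbh = (dt / h) / (1.0 + sH * dt / 2.0)
    dth = dt / h
    eps = dom.eps
    if cfg.dispersion_compensation:
        # choose grid permittivity so the discrete dispersion relation
        # sin^2(w dt/2)/dt^2 = sin^2(k h/2)/(eps h^2) yields k = n_phys * w
        # for axial propagation at this wavelength (applied to air too)
        n_phys = np.sqrt(eps)
        eps = (np.sin(n_phys * omega * h / 2.0) * dt
               / (h * np.sin(omega * dt / 2.0))) ** 2
    if pol == "TM":
        cbe = (dt / h) / eps / (1.0 + sE[None, :] * dt / 2.0)
        dthe = (dt / h) / eps
        ez = np.zeros((nx, ny)); eza = np.zeros((nx, ny)); ezb = np.zeros((nx, ny))
        hx = np.zeros((nx, ny - 1)); hy = np.zeros((nx, ny))
        fields = (ez, eza, ezb, hx, hy)
        coefs = (cae, cbe, dthe, cah, cbh, dth)
        kernel = _tm_chunk
    else:
        epsx = 0.5 * (eps + np.roll(eps, -1, axis=0))
        epsy = 0.5 * (eps[:, :-1] + eps[:, 1:])
        cbex = (dt / h) / epsx / (1.0 + sE[None, :] * dt / 2.0)
        dthey = (dt / h) / epsy
        ex = np.zeros((nx, ny)); ey = np.zeros((nx, ny - 1))
        hz = np.zeros((nx, ny - 1)); hza = np.zeros((nx, ny - 1)); hzb = np.zeros((nx, ny - 1))
        fields = (ex, ey, hz, hza, hzb)
        coefs = (cae, cbex, dthey, cah, cbh, dth)
        kernel = _te_chunk

    mon_rows = np.array([dom.j_refl, dom.j_trans], dtype=np.int64)
    n_max = float(np.sqrt(eps.max()))
    t_warm = cfg.ramp_periods * period + cfg.settle_crossings * ny * h * n_max
    warm_periods = int(np.ceil(t_warm / period))

    dummy = np.zeros((1, 1))
    step0 = 0

    def run_periods(n_periods, do_full, full_accs=None):
        nonlocal step0
        nsteps = n_periods * spp
        tE = (np.arange(step0, step0 + nsteps) + 1.0) * dt
        tH = (np.arange(step0, step0 + nsteps) + 0.5) * dt
        src = np.sin(omega * tE)
        ramp_t = cfg.ramp_periods * period
        env = np.minimum(tE / ramp_t, 1.0) if ramp_t > 0 else np.ones_like(tE)
        env = 0.5 * (1.0 - np.cos(np.pi * np.minimum(tE / ramp_t, 1.0))) if ramp_t > 0 else env
        src = src * env
        mE_re = np.zeros((2, nx)); mE_im = np.zeros((2, nx))
        mH_re = np.zeros((2, nx)); mH_im = np.zeros((2, nx))
        if do_full:
            args_full = (True,) + tuple(full_accs)
        else:
            args_full = (False, dummy, dummy, dummy, dummy, dummy, dummy)
        kernel(*fields, *coefs, dom.js, src,
               np.cos(omega * tE), np.sin(omega * tE),
               np.cos(omega * tH), np.sin(omega * tH),
               mon_rows, mE_re, mE_im, mH_re, mH_im, *args_full)
        step0 += nsteps
        norm = 2.0 / nsteps
        mE = (mE_re + 1j * mE_im) * norm
        mH = (mH_re + 1j * mH_im) * norm
        return mE, mH

    # warm up with ramped source
    run_periods(warm_periods, False)
    # steady-state detection on per-period monitor fluxes
    prev = None
    steady = not cfg.check_convergence
    periods_done = warm_periods
    while True:
        mE, mH = run_periods(1, False)
        fr = _row_flux(mE[0], mH[0], pol)
        ft = _row_flux(mE[1], mH[1], pol)
        cur = np.array([fr, ft])
        if prev is not None:
            scale = max(abs(cur).max(), 1e-30)
            if np.max(np.abs(cur - prev)) / scale < cfg.steady_tol:
                steady = True
        periods_done += 1
        if steady or not cfg.check_convergence:
            break
        if periods_done >= cfg.max_periods:
            raise ConvergenceError(
                "CW run did not settle",
                {"periods": periods_done, "flux_refl": fr, "flux_trans": ft,
                 "last_change": float(np.max(np.abs(cur - prev))) if prev is not None else None},
            )
        prev = cur

    # final measurement over an integer number of periods
    fE = fH = f2 = None
    if want_full:
        accs = [np.zeros((nx, ny)) for _ in range(6)]
        mE, mH = run_periods(cfg.measure_periods, True, accs)
        norm = 2.0 / (cfg.measure_periods * spp)
        fE = (accs[0] + 1j * accs[1]) * norm
        fH = (accs[2] + 1j * accs[3]) * norm
        f2 = (accs[4] + 1j * accs[5]) * norm
    else:
        mE, mH = run_periods(cfg.measure_periods, False)
    return _Phasors(mE, mH, fE, fH, f2,
                    _row_flux(mE[0], mH[0], pol), _row_flux(mE[1], mH[1], pol),
                    spp, dt)


# reference (empty-domain) phasors, cached per grid/wavelength/polarization
_REF_CACHE: dict = {}


def _reference(dom: _Domain, cfg: FDTDConfig, lam_um: float, pol: str) -> _Phasors:
    key = (dom.eps.shape, dom.h, dom.js, dom.j_refl, dom.j_trans, dom.pml,
           round(lam_um, 9), pol, cfg.courant, cfg.measure_periods)
    if key not in _REF_CACHE:
        ref_dom = _Domain(np.ones_like(dom.eps), dom.h, dom.y0, dom.js,
                          dom.j_refl, dom.j_trans, dom.pml)
        _REF_CACHE[key] = _run_single(ref_dom, cfg, lam_um, pol, False)
    return _REF_CACHE[key]


# ---------------------------------------------------------------------------
# public API

@dataclass
class FDTDResult:
    wavelengths_nm: np.ndarray
    reflectance: np.ndarray          # fraction of incident power
    transmittance: np.ndarray
    region_powers: dict              # label -> array over wavelengths, W/m²
    metadata: dict = field(default_factory=dict)

    @property
    def mean_reflectance(self) -> float:
        return float(np.mean(self.reflectance))


def _check_resolution(scene: FeatherScene, cfg: FDTDConfig):
    lam_min = min(cfg.wavelengths_nm) / 1000.0
    n_max = float(np.sqrt(scene.eps.max()))
    if scene.h > lam_min / (20.0 * n_max):
        warnings.warn(
            f"mesh {scene.h*1000:.0f} nm does not resolve lambda/20 in the densest "
            f"material ({lam_min*1000:.0f} nm / {n_max:.2f})", ResolutionWarning)


def _solve_rt(scene: FeatherScene, cfg: FDTDConfig, lam_nm: float, pol: str,
              want_full: bool):
    dom = _assemble(scene, cfg, allow_collapse=not want_full)
    lam_um = lam_nm / 1000.0
    ph = _run_single(dom, cfg, lam_um, pol, want_full)
    ref = _reference(dom, cfg, lam_um, pol)
    f_inc = -ref.flux_refl                     # incident flux is downward
    scat_E = ph.mE[0] - ref.mE[0]
    scat_H = ph.mH[0] - ref.mH[0]
    r = _row_flux(scat_E, scat_H, pol) / f_inc
    t = -ph.flux_trans / f_inc
    return dom, ph, ref, f_inc, max(r, 0.0), t


def run_fdtd(scene: FeatherScene, cfg: FDTDConfig) -> FDTDResult:
    """Per-wavelength reflectance and transmittance of a scene.

    With ``polarization='both'`` the TM and TE results are averaged.
    """
    _check_resolution(scene, cfg)
    pols = ("TM", "TE") if cfg.polarization == "both" else (cfg.polarization,)
    R = np.zeros(len(cfg.wavelengths_nm))
    T = np.zeros(len(cfg.wavelengths_nm))
    for k, lam in enumerate(cfg.wavelengths_nm):
        for pol in pols:
            _, _, _, _, r, t = _solve_rt(scene, cfg, lam, pol, False)
            R[k] += r / len(pols)
            T[k] += t / len(pols)
    meta = {"mesh_nm": cfg.mesh_nm, "polarization": cfg.polarization,
            "source": "per-wavelength CW, ramped, steady-state detected",
            "scene": scene.descriptor}
    return FDTDResult(np.array(cfg.wavelengths_nm), R, T, {}, meta)


def power_transmission(scene: FeatherScene, cfg: FDTDConfig,
                       regions: dict) -> FDTDResult:
    """Downward Poynting power through square monitor regions.

    ``regions`` maps label -> (center_x_um, center_y_um, side_um) in scene
    coordinates (barb center at the origin).  Powers are per-wavelength, in
    the source-normalized W/m² convention described in the module docstring.
    """
    _check_resolution(scene, cfg)
    # warn for regions outside the structure bounding box
    solid = scene.eps > 1.0 + 1e-9
    if solid.any():
        xs = scene.x_coords()[solid.any(axis=1)]
        ys = scene.y_coords()[solid.any(axis=0)]
        bbox = (xs.min(), xs.max(), ys.min(), ys.max())
        for label, (cx, cy, side) in regions.items():
            if not (bbox[0] <= cx <= bbox[1] and bbox[2] <= cy <= bbox[3]):
                warnings.warn(f"region {label!r} center ({cx}, {cy}) lies outside the "
                              f"structure bounding box {bbox}", RegionWarning)
    pols = ("TM", "TE") if cfg.polarization == "both" else (cfg.polarization,)
    nlam = len(cfg.wavelengths_nm)
    R = np.zeros(nlam); T = np.zeros(nlam)
    powers = {label: np.zeros(nlam) for label in regions}
    for k, lam in enumerate(cfg.wavelengths_nm):
        for pol in pols:
            dom, ph, ref, f_inc, r, t = _solve_rt(scene, cfg, lam, pol, True)
            R[k] += r / len(pols)
            T[k] += t / len(pols)
            nx = dom.eps.shape[0]
            s0_density = f_inc / nx          # incident flux per cell column
            if pol == "TM":
                sy = np.real(ph.fE * np.conj(ph.fH))
                sx = -np.real(ph.fE * np.conj(ph.f2))
            else:
                sy = -np.real(ph.fE * np.conj(ph.fH))
                sx = np.real(ph.f2 * np.conj(ph.fH))
            s_mag = np.hypot(sx, sy)
            x = (np.arange(nx) + 0.5) * dom.h - (nx * dom.h) / 2.0
            y = dom.y0 + np.arange(dom.eps.shape[1]) * dom.h
            period = nx * dom.h
            for label, (cx, cy, side) in regions.items():
                # x offsets live on the periodic axis (feathers tile side by side)
                dx_p = np.mod(x - cx + period / 2.0, period) - period / 2.0
                mask_x = np.abs(dx_p) <= side / 2.0
                mask_y = np.abs(y - cy) <= side / 2.0
                block = s_mag[np.ix_(mask_x, mask_y)]
                capture_cells = float(block.sum()) / s0_density
                p_wm2 = capture_cells * dom.h * dom.h / A_REF_UM2 * S0_WM2
                powers[label][k] += p_wm2 / len(pols)
    meta = {"mesh_nm": cfg.mesh_nm, "polarization": cfg.polarization,
            "power_convention": "area-integrated time-averaged Poynting magnitude, "
                                "unit-amplitude peak convention, per 25 nm reference cell",
            "scene": scene.descriptor}
    return FDTDResult(np.array(cfg.wavelengths_nm), R, T, powers, meta)
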