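"""2D scalar-acoustic wave propagation on a staggered finite-difference grid.

The solver advances coupled first-order pressure / particle-velocity
equations with a leapfrog scheme and is used in two directions:

* forward — a photoacoustic initial-pressure distribution inside a
  silicone (PDMS) slab radiates towards the detection surface, where a
  laser Doppler vibrometer observes the normal surface motion;
* reverse — recorded boundary pressure traces are re-emitted backwards in
  time so the field refocuses onto the original sources (time reversal).

Conventions: ``x`` is lateral along the scan line, ``z`` is depth into the
sample with ``z = 0`` at the detection surface.  Arrays are indexed
``[ix, iz]``.  The detection surface and the slab backside are
pressure-release ("soft") boundaries, appropriate for a solid/air
interface; the lateral edges carry an absorbing sponge that emulates a
laterally unbounded slab.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from fractions import Fraction

from scipy.integrate import cumulative_trapezoid
from scipy.signal import resample, resample_poly

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import PhantomSpec

__all__ = [
    "Medium",
    "FieldState",
    "SurfaceRecord",
    "GeometryError",
    "ResolutionError",
    "StabilityError",
    "build_medium",
    "simulate_forward",
    "simulate_time_reversal",
    "snapshot",
    "PDMS_SOUND_SPEED",
    "PDMS_DENSITY",
    "CHANNEL_SOUND_SPEED",
    "CHANNEL_DENSITY",
]

#: Speed of sound in cured PDMS (m/s).
PDMS_SOUND_SPEED = 1020.0
#: Density used for every cell (kg/m^3); with rho fixed, c alone sets the
#: impedance: 1020 m/s -> 1.02 MRayl (PDMS), 1500 m/s -> 1.5 MRayl (channel).
PDMS_DENSITY = 1000.0
#: Water-like interior of the ink-filled channel (m/s).
CHANNEL_SOUND_SPEED = 1500.0
CHANNEL_DENSITY = 1000.0


class GeometryError(ValueError):
    """Phantom geometry does not fit the simulation domain."""


class ResolutionError(ValueError):
    """Grid spacing too coarse for the requested maximum frequency."""


class StabilityError(RuntimeError):
    """CFL violation or a diverging field during a run."""


@dataclass
class Medium:
    """Heterogeneous 2D acoustic medium on a regular grid.

    Attributes
    ----------
    dx : float
        Grid spacing (m), identical in x and z.
    c_map, rho_map : ndarray, shape (nx, nz)
        Sound speed (m/s) and density (kg/m^3) per cell.
    x0 : float
        x-coordinate (m) of the cell ``ix = 0`` centre.
    n_sponge : int
        Width in cells of the lateral absorbing sponge.
    boundary_spec : dict
        Boundary condition per edge; top/bottom ``"soft"``, lateral
        ``"absorbing"``.
    """

    dx: float
    c_map: np.ndarray
    rho_map: np.ndarray
    x0: float = 0.0
    n_sponge: int = 40
    boundary_spec: dict = field(
        default_factory=lambda: {
            "top": "soft",
            "bottom": "soft",
            "left": "absorbing",
            "right": "absorbing",
        }
    )

    def __post_init__(self) -> None:
        self.c_map = np.asarray(self.c_map, dtype=float)
        self.rho_map = np.asarray(self.rho_map, dtype=float)
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.c_map.shape != self.rho_map.shape:
            raise ValueError("c_map and rho_map shapes differ")
        if not (np.all(self.c_map > 0) and np.all(self.rho_map > 0)):
            raise ValueError("c_map and rho_map must be strictly positive")

    @property
    def nx(self) -> int:
        return self.c_map.shape[0]

    @property
    def nz(self) -> int:
        return self.c_map.shape[1]

    @property
    def impedance_map(self) -> np.ndarray:
        """Acoustic impedance Z = rho * c (Rayl) per cell."""
        return self.rho_map * self.c_map

    @property
    def x(self) -> np.ndarray:
        """Cell-centre x coordinates (m)."""
        return self.x0 + np.arange(self.nx) * self.dx

    @property
    def z(self) -> np.ndarray:
        """Cell-centre depth coordinates (m), z=0 at the detection surface."""
        return np.arange(self.nz) * self.dx

    def x_to_index(self, x: float) -> int:
        ix = int(round((x - self.x0) / self.dx))
        if not 0 <= ix < self.nx:
            raise GeometryError(f"x = {x} m outside the lateral domain")
        return ix

    def content_hash(self) -> str:
        h = hashlib.sha1()
        h.update(np.float64(self.dx).tobytes())
        h.update(self.c_map.tobytes())
        h.update(self.rho_map.tobytes())
        return h.hexdigest()[:12]


@dataclass
class FieldState:
    """State of the scalar wave equation at one instant."""

    pressure: np.ndarray  # (nx, nz), Pa
    vx: np.ndarray  # (nx-1, nz), m/s, staggered on x faces
    vz: np.ndarray  # (nx, nz-1), m/s, staggered on z faces
    time: float  # s

    def check_finite(self) -> None:
        if not np.all(np.isfinite(self.pressure)):
            raise StabilityError("non-finite pressure field")


@dataclass
class SurfaceRecord:
    """Surface motion observed by the LDV along the scan line.

    ``displacement`` and ``velocity`` have shape ``(n_positions, n_times)``
    and are related by time differentiation up to discretisation error.
    """

    positions: np.ndarray  # (n_pos,), m, strictly increasing
    time: np.ndarray  # (n_t,), s, uniform
    displacement: np.ndarray  # m
    velocity: np.ndarray  # m/s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_1d(np.asarray(self.positions, float))
        if np.any(np.diff(self.positions) <= 0) and self.positions.size > 1:
            raise ValueError("sensor positions must be strictly increasing")

    @property
    def fs(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    def trace(self, i: int, kind: str = "velocity") -> np.ndarray:
        return (self.velocity if kind == "velocity" else self.displacement)[i]


def build_medium(
    phantom: "PhantomSpec",
    dx: float = 20e-6,
    margins: float | None = None,
    width: float = 14e-3,
    f_max: float = 5e6,
    min_ppw: int = 10,
) -> Medium:
    """Rasterise a slab-with-channels phantom onto a simulation grid.

    The PDMS background gets c = 1020 m/s; each channel disc gets
    water-like properties (c = 1500 m/s).  With rho = 1000 kg/m^3
    everywhere, the impedances come out at 1.02 and 1.5 MRayl.

    Parameters
    ----------
    phantom : PhantomSpec
        Slab thickness and channel geometry.
    dx : float
        Grid spacing (m).  Must provide at least ``min_ppw`` cells per
        acoustic wavelength at ``f_max`` in the slowest medium.
    margins : float, optional
        Lateral absorbing-sponge width (m); default 40 cells.
    width : float
        Physical lateral extent of interest (m), excluding sponges.
    f_max : float
        Highest frequency the grid is expected to propagate (Hz).
    """
    if margins is None:
        margins = 40 * dx
    c_min = PDMS_SOUND_SPEED
    lam_min = c_min / f_max
    if dx > lam_min / min_ppw + 1e-12:
        raise ResolutionError(
            f"dx = {dx * 1e6:.1f} um gives {lam_min / dx:.1f} cells per wavelength "
            f"at {f_max / 1e6:.1f} MHz; need >= {min_ppw}"
        )
    thickness = phantom.thickness
    nz = int(round(thickness / dx)) + 1
    nx = int(round((width + 2 * margins) / dx)) + 1
    x0 = -(nx - 1) / 2 * dx

    c = np.full((nx, nz), PDMS_SOUND_SPEED)
    rho = np.full((nx, nz), PDMS_DENSITY)
    xg = x0 + np.arange(nx)[:, None] * dx
    zg = np.arange(nz)[None, :] * dx
    for ch in phantom.channels:
        r = ch.diameter / 2.0
        if ch.depth - r <= 0 or ch.depth + r >= thickness:
            raise GeometryError(
                f"channel at depth {ch.depth * 1e3:.2f} mm (r = {r * 1e3:.2f} mm) "
                f"does not fit inside the {thickness * 1e3:.1f} mm slab"
            )
        if abs(ch.offset) + r >= width / 2:
            raise GeometryError("channel outside the lateral domain of interest")
        mask = (xg - ch.offset) ** 2 + (zg - ch.depth) ** 2 <= r**2
        c[mask] = CHANNEL_SOUND_SPEED
        rho[mask] = CHANNEL_DENSITY

    return Medium(dx=dx, c_map=c, rho_map=rho, x0=x0, n_sponge=int(round(margins / dx)))


class _Solver:
    """Leapfrog stepper shared by forward and time-reversed runs."""

    # 2D leapfrog stability bound is 1/sqrt(2); keep a safety margin.
    CFL_LIMIT = 0.7

    def __init__(self, medium: Medium, cfl: float = 0.3):
        if not 0 < cfl <= self.CFL_LIMIT:
            raise StabilityError(
                f"CFL number {cfl} outside the stable range (0, {self.CFL_LIMIT}]"
            )
        self.medium = medium
        c = medium.c_map
        rho = medium.rho_map
        dx = medium.dx
        self.dt = cfl * dx / float(c.max())
        # pressure update: p -= dt/dx * rho c^2 * div(v)
        self._cp = self.dt / dx * rho * c**2
        # velocity updates: v -= dt/(rho_face dx) * grad(p)
        self._bx = self.dt / dx * 2.0 / (rho[1:, :] + rho[:-1, :])
        self._bz = self.dt / dx * 2.0 / (rho[:, 1:] + rho[:, :-1])
        self.state = FieldState(
            pressure=np.zeros((medium.nx, medium.nz)),
            vx=np.zeros((medium.nx - 1, medium.nz)),
            vz=np.zeros((medium.nx, medium.nz - 1)),
            time=0.0,
        )
        self._div = np.zeros_like(self.state.pressure)
        self._init_sponge(cfl)
        self.it = 0

    def _init_sponge(self, cfl: float) -> None:
        ns = self.medium.n_sponge
        c_max = float(self.medium.c_map.max())
        if ns > 0:
            # cubic damping ramp; total one-way attenuation ~ exp(-3)
            ramp = ((np.arange(ns, 0, -1)) / ns) ** 3
            sigma_max = 12.0 * c_max / (ns * self.medium.dx)
            self._damp = np.exp(-sigma_max * ramp * self.dt)
        else:
            self._damp = np.ones(0)
        self._ns = ns
        # optional absorbing bottom (used by reconstruction media emulating
        # a half-space deeper than the physical slab)
        self._ns_bottom = (
            ns if self.medium.boundary_spec.get("bottom") == "absorbing" else 0
        )

    def set_pressure(self, p0: np.ndarray) -> None:
        p0 = np.asarray(p0, float)
        if p0.shape != self.state.pressure.shape:
            raise ValueError(
                f"p0 shape {p0.shape} does not match grid "
                f"({self.medium.nx}, {self.medium.nz})"
            )
        self.state.pressure[...] = p0
        self._enforce_soft()
        self._p0_max = float(np.abs(p0).max())

    def _enforce_soft(self) -> None:
        p = self.state.pressure
        if self.medium.boundary_spec.get("top") == "soft":
            p[:, 0] = 0.0
        if self.medium.boundary_spec.get("bottom") == "soft":
            p[:, -1] = 0.0

    def _apply_sponge(self) -> None:
        ns = self._ns
        if ns == 0:
            return
        d = self._damp
        st = self.state
        for arr in (st.pressure, st.vx, st.vz):
            arr[:ns] *= d[:, None]
            arr[-ns:] *= d[::-1, None]
        nb = self._ns_bottom
        if nb:
            for arr in (st.pressure, st.vx, st.vz):
                arr[:, -nb:] *= d[::-1][None, :]

    def step(self) -> None:
        st = self.state
        p = st.pressure
        st.vx -= self._bx * (p[1:, :] - p[:-1, :])
        st.vz -= self._bz * (p[:, 1:] - p[:, :-1])
        d = self._div
        d[...] = 0.0
        d[:-1, :] += st.vx
        d[1:, :] -= st.vx
        d[:, :-1] += st.vz
        d[:, 1:] -= st.vz
        p -= self._cp * d
        self._enforce_soft()
        self._apply_sponge()
        self.it += 1
        st.time = self.it * self.dt

    def check_stability(self, reference: float) -> None:
        m = float(np.abs(self.state.pressure).max())
        if not np.isfinite(m) or (reference > 0 and m > 10.0 * reference):
            raise StabilityError(
                f"pressure magnitude {m:.3g} exceeds 10x the initial maximum "
                f"at t = {self.state.time * 1e6:.2f} us"
            )


def _sensor_indices(medium: Medium, sensor_positions) -> np.ndarray:
    pos = np.atleast_1d(np.asarray(sensor_positions, float))
    return np.array([medium.x_to_index(x) for x in pos])


def simulate_forward(
    medium: Medium,
    p0: np.ndarray,
    duration: float,
    sensor_positions,
    fs_out: float = 65e6,
    cfl: float = 0.3,
) -> SurfaceRecord:
    """Propagate an initial pressure distribution and record surface motion.

    The LDV observable is the normal particle velocity one half-cell
    inside the soft detection surface (pressure on the boundary itself is
    ~0); displacement follows by cumulative time integration.  Both are
    band-limited-resampled from the solver rate to ``fs_out`` (default the
    acquisition card's 65 MS/s).

    Returns a :class:`SurfaceRecord`; raises :class:`StabilityError`
    before the run for an unstable CFL number and during the run if the
    field diverges.
    """
    solver = _Solver(medium, cfl=cfl)
    solver.set_pressure(p0)
    idx = _sensor_indices(medium, sensor_positions)
    nsteps = max(2, int(round(duration / solver.dt)))
    vz_rec = np.empty((idx.size, nsteps))
    check_every = max(1, nsteps // 20)
    for n in range(nsteps):
        solver.step()
        vz_rec[:, n] = solver.state.vz[idx, 0]
        if (n + 1) % check_every == 0:
            solver.check_stability(solver._p0_max)

    # polyphase (local, non-wrapping) band-limited resampling to ~fs_out
    ratio = Fraction(fs_out * solver.dt).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    fs_actual = up / (down * solver.dt)
    vel = resample_poly(vz_rec, up, down, axis=1)
    disp_solver = cumulative_trapezoid(vz_rec, dx=solver.dt, axis=1, initial=0.0)
    disp = resample_poly(disp_solver, up, down, axis=1)
    t_out = np.arange(vel.shape[1]) / fs_actual
    pos = np.atleast_1d(np.asarray(sensor_positions, float))
    return SurfaceRecord(
        positions=pos,
        time=t_out,
        displacement=disp,
        velocity=vel,
        meta={
            "medium_hash": medium.content_hash(),
            "dt_solver": solver.dt,
            "fs_out": fs_actual,
            "cfl": cfl,
        },
    )


def simulate_time_reversal(
    medium: Medium,
    boundary_traces: np.ndarray,
    sensor_positions,
    fs: float,
    cfl: float = 0.3,
) -> np.ndarray:
    """Back-propagate recorded surface pressure traces (time reversal).

    Each trace is time-reversed and enforced as a pressure source at the
    grid cell one half-cell inside the detection surface while the same
    solver runs forward in time; the final-time field is the estimate of
    the initial pressure distribution.

    Parameters
    ----------
    boundary_traces : ndarray, shape (n_positions, n_times)
        Surface pressure traces on a common uniform time base.
    fs : float
        Sampling rate of the traces (Hz).
    """
    traces = np.asarray(boundary_traces, float)
    if traces.ndim != 2:
        raise ValueError("boundary_traces must be 2D (n_positions, n_times)")
    pos = np.atleast_1d(np.asarray(sensor_positions, float))
    if traces.shape[0] != pos.size:
        raise ValueError(
            f"{traces.shape[0]} traces but {pos.size} sensor positions"
        )
    solver = _Solver(medium, cfl=cfl)
    idx = _sensor_indices(medium, pos)
    if not np.any(traces):
        return np.zeros((medium.nx, medium.nz))
    duration = traces.shape[1] / fs
    nsteps = max(2, int(round(duration / solver.dt)))
    src = resample(traces, nsteps, axis=1)[:, ::-1]
    ref = float(np.abs(traces).max())
    check_every = max(1, nsteps // 20)
    for n in range(nsteps):
        solver.state.pressure[idx, 1] = src[:, n]
        solver.step()
        # re-assert the source after the update so it acts as a Dirichlet cell
        solver.state.pressure[idx, 1] = src[:, n]
        if (n + 1) % check_every == 0:
            solver.state.check_finite()
    return solver.state.pressure.copy()


def snapshot(
    medium: Medium,
    p0: np.ndarray,
    t: float,
    duration: float | None = None,
    cfl: float = 0.3,
) -> np.ndarray:
    """Pressure field of the forward problem at time ``t``.

    ``duration``, when given, bounds the admissible ``t`` (range error
    beyond it).  ``t = 0`` returns ``p0`` with the soft boundaries applied.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if duration is not None and t > duration:
        raise ValueError(f"t = {t} s beyond the simulated duration {duration} s")
    solver = _Solver(medium, cfl=cfl)
    solver.set_pressure(p0)
    nsteps = int(round(t / solver.dt))
    for n in range(nsteps):
        solver.step()
        if (n + 1) % 200 == 0:
            solver.check_stability(solver._p0_max)
    return solver.state.pressure.copy()
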