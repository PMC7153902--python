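"""Coarse-grained two-arm hinge: the synthetic-data generator.

The generator evolves two internal coordinates -- the opening angle theta
(degrees) and the twist coordinate w (the W-W' distance, nm) -- under an
analytic potential

    U(theta, w) = B [((theta - theta_m)/delta)^2 - 1]^2
                  + (A/2) (theta - theta_m)/delta
                  + (k_w/2)(w - w_0)^2
                  + c (theta - theta_m)(w - w_0)

with theta_m the midpoint and delta the half-separation of the two wells.
B and A are calibrated numerically so that the barrier above the lower well
equals ``barrier`` and the difference between the two well minima equals
``asymmetry`` (both kJ/mol).  Sampling is overdamped Langevin
(Euler-Maruyama), which has the analytic Boltzmann density
exp(-U/k_B T) as its stationary distribution, so every downstream
free-energy estimate can be checked against closed-form ground truth.

Each internal state maps deterministically to Cartesian pseudo-atom
coordinates of a 30-bead dimer (two 12-bead CA arms, one tryptophan
side-chain bead per arm, four sulfur beads at the pivot) such that the
descriptors module recovers theta and w from the frame to ~1e-8.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .model_io import (
    Atom,
    CVSeries,
    HingedynError,
    Topology,
    Trajectory,
    standard_hinge_groups,
)

__all__ = [
    "KB",
    "HingeParams",
    "HingeState",
    "EmbeddingError",
    "potential",
    "potential_grid",
    "potential_gradient",
    "theta_free_energy",
    "langevin_run",
    "hinge_topology",
    "state_to_frame",
    "embed_series",
]

#: Boltzmann constant, kJ/mol/K
KB = 0.0083144621

# embedding geometry constants (nm); see state_to_frame
_ARM_RISE = 0.35       # CA-CA rung spacing along an arm
_ARM_OFFSET0 = 0.2     # first rung distance from the pivot
_STRAND_SEP = 0.25     # half-separation of the two hairpin strands
_SULFUR_D = 0.06       # sulfur tetrahedron half-edge at the pivot
_ARM_LEN_C5C8 = _ARM_OFFSET0 + 5 * _ARM_RISE   # C5/C8 midpoint radius
_TRP_ARM = 1.2         # tryptophan bead tether length from the W3 CA


@dataclass(frozen=True)
class HingeParams:
    """Parameters of the synthetic hinge and its Langevin sampler.

    Defaults mimic the landscape the hinge peptide explores: theta wells at
    60 and 110 degrees separated by a ~4 kJ/mol barrier, a harmonic twist
    coordinate centred at 1.5 nm, 300 K.
    """

    theta_wells: tuple[float, float] = (60.0, 110.0)   # degrees
    barrier: float = 4.0          # kJ/mol above the lower well
    asymmetry: float = 0.0        # kJ/mol, well b minus well a minimum
    twist_k: float = 10.0         # kJ/mol/nm^2
    twist_center: float = 1.5     # nm
    coupling: float = 0.0         # kJ/mol/(deg*nm)
    temperature: float = 300.0    # K
    friction: float = 1.0         # ps^-1, per coordinate
    dt: float = 0.01              # ps
    seed: int = 0
    n_steps: int = 200_000
    stride: int = 10

    def __post_init__(self) -> None:
        ta, tb = self.theta_wells
        if not (0.0 < ta < tb < 180.0):
            raise ValueError("theta wells must satisfy 0 < theta_a < theta_b < 180")
        if self.barrier <= 0:
            raise ValueError("barrier must be > 0")
        if self.dt <= 0 or self.friction <= 0:
            raise ValueError("dt and friction must be > 0")
        if self.twist_k < 0 or self.temperature <= 0:
            raise ValueError("twist_k must be >= 0 and temperature > 0")
        if self.n_steps < 0 or self.stride < 1:
            raise ValueError("n_steps must be >= 0 and stride >= 1")

    @property
    def theta_mid(self) -> float:
        return 0.5 * (self.theta_wells[0] + self.theta_wells[1])

    @property
    def theta_delta(self) -> float:
        return 0.5 * (self.theta_wells[1] - self.theta_wells[0])

    @property
    def kT(self) -> float:
        return KB * self.temperature


@dataclass(frozen=True)
class HingeState:
    """Internal hinge coordinates at one instant."""

    theta: float    # degrees, in (0, 180)
    w: float        # nm, > 0
    time: float = 0.0   # ps

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 180.0:
            raise ValueError("theta must lie in (0, 180) degrees")
        if self.w <= 0:
            raise ValueError("w must be > 0")


class EmbeddingError(HingedynError):
    """(theta, w) not realizable by the fixed pseudo-atom arm geometry."""


# ---------------------------------------------------------------------------
# potential and calibration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _calibrate(barrier: float, asymmetry: float) -> tuple[float, float, float, float, float]:
    """Solve for quartic scale B and tilt A (reduced coordinate u).

    Returns (B, A, u_a, u_saddle, u_b) such that for
    g(u) = B (u^2-1)^2 + (A/2) u the saddle sits ``barrier`` above the
    lower well and the two minima differ by ``asymmetry``.
    """
    from scipy.optimize import fsolve

    def g(u: np.ndarray, B: float, A: float) -> np.ndarray:
        return B * (u * u - 1.0) ** 2 + 0.5 * A * u

    def stationary(B: float, A: float) -> np.ndarray:
        roots = np.roots([4.0 * B, 0.0, -4.0 * B, 0.5 * A])
        real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
        return real

    def residual(x: np.ndarray) -> np.ndarray:
        B, A = x
        if B <= 0:
            return np.array([1e3, 1e3])
        pts = stationary(B, A)
        if len(pts) != 3:
            return np.array([1e3, 1e3])
        ua, us, ub = pts
        ga, gs, gb = g(pts, B, A)
        lower = min(ga, gb)
        return np.array([(gs - lower) - barrier, (gb - ga) - asymmetry])

    x0 = np.array([max(barrier - abs(asymmetry) / 2.0, 0.1 * barrier),
                   asymmetry])
    sol, info, ier, msg = fsolve(residual, x0, full_output=True)
    if ier != 1 or np.max(np.abs(residual(sol))) > 1e-8:
        raise ValueError(
            f"cannot calibrate double well for barrier={barrier}, "
            f"asymmetry={asymmetry}: {msg}"
        )
    B, A = float(sol[0]), float(sol[1])
    ua, us, ub = stationary(B, A)
    return B, A, float(ua), float(us), float(ub)


def _quartic_coeffs(params: HingeParams) -> tuple[float, float]:
    return _calibrate(params.barrier, params.asymmetry)[:2]


def theta_well_positions(params: HingeParams) -> tuple[float, float, float]:
    """Exact (theta_a_min, theta_saddle, theta_b_min) in degrees."""
    _, _, ua, us, ub = _calibrate(params.barrier, params.asymmetry)
    tm, dl = params.theta_mid, params.theta_delta
    return tm + ua * dl, tm + us * dl, tm + ub * dl


def potential_grid(theta, w, params: HingeParams):
    """U(theta, w) in kJ/mol; broadcasts over numpy inputs."""
    B, A = _quartic_coeffs(params)
    theta = np.asarray(theta, dtype=float)
    w = np.asarray(w, dtype=float)
    u = (theta - params.theta_mid) / params.theta_delta
    return (B * (u * u - 1.0) ** 2 + 0.5 * A * u
            + 0.5 * params.twist_k * (w - params.twist_center) ** 2
            + params.coupling * (theta - params.theta_mid)
            * (w - params.twist_center))


def potential(state: HingeState, params: HingeParams) -> float:
    return float(potential_grid(state.theta, state.w, params))


def potential_gradient(state: HingeState, params: HingeParams) -> tuple[float, float]:
    """Analytic (dU/dtheta, dU/dw) in kJ/mol per (deg, nm)."""
    B, A = _quartic_coeffs(params)
    tm, dl = params.theta_mid, params.theta_delta
    u = (state.theta - tm) / dl
    dtheta = (4.0 * B * u * (u * u - 1.0) + 0.5 * A) / dl \
        + params.coupling * (state.w - params.twist_center)
    dw = params.twist_k * (state.w - params.twist_center) \
        + params.coupling * (state.theta - tm)
    return dtheta, dw


def theta_free_energy(theta, params: HingeParams):
    """Min-shifted analytic free energy along theta (coupling-free case).

    For coupling = 0 the twist coordinate integrates out to a constant, so
    F(theta) equals the theta part of U up to an additive constant.
    """
    if params.coupling != 0.0:
        raise ValueError("analytic theta profile requires coupling = 0")
    B, A = _quartic_coeffs(params)
    theta = np.asarray(theta, dtype=float)
    u = (theta - params.theta_mid) / params.theta_delta
    f = B * (u * u - 1.0) ** 2 + 0.5 * A * u
    return f - f.min() if f.ndim else f


# ---------------------------------------------------------------------------
# Langevin sampler
# ---------------------------------------------------------------------------

#: noise is drawn from the generator in chunks of this many steps; the
#: normal stream is continuous across chunk boundaries, so chunking does
#: not affect results
NOISE_CHUNK = 1 << 20


def _integrator_consts(params: HingeParams):
    inv_g = 1.0 / params.friction
    amp = math.sqrt(2.0 * params.kT * params.dt * inv_g)
    B, A = _quartic_coeffs(params)
    return dict(
        dt_g=params.dt * inv_g, amp=amp, B=B, A=A,
        tm=params.theta_mid, dl=params.theta_delta,
        kw=params.twist_k, w0n=params.twist_center, coup=params.coupling,
    )


def _warn_reflections(reflections: int, n_steps: int) -> None:
    if n_steps > 0 and reflections > 0.01 * n_steps:
        warnings.warn(
            f"{reflections} boundary reflections in {n_steps} steps (>1%): "
            "the sampler is marginally stable for these parameters",
            stacklevel=3,
        )


def _record_steps(step0: int, n_steps: int, stride: int) -> np.ndarray:
    """Global step indices at which the kernel records (multiples of stride)."""
    first = step0 // stride + 1
    last = (step0 + n_steps) // stride
    return stride * np.arange(first, last + 1, dtype=np.int64)


def langevin_run(
    params: HingeParams,
    bias=None,
    init: HingeState | None = None,
    rng: np.random.Generator | None = None,
    step0: int = 0,
):
    """Overdamped Langevin (Euler-Maruyama) run over (theta, w).

    x <- x - (dt/gamma) dU/dx + sqrt(2 kT dt / gamma) xi, with xi drawn
    from a seeded generator; reflecting boundaries at theta = 0/180 deg and
    w = 0 nm.  Every ``params.stride`` steps the state (and, when biased,
    the instantaneous bias energy) is recorded; times are global-step *
    dt so runs can be split and resumed exactly.  Fully reproducible given
    ``params.seed`` (or an explicit ``rng``).

    ``bias`` is either a static :class:`~hingedyn.metadynamics.BiasState`
    (evaluated on the integrator's grid cache) or any object with
    ``grad(theta, w) -> (dV/dtheta_deg, dV/dw)`` and ``value(theta, w)``
    in kJ/mol (evaluated directly; slower).

    Returns a CVSeries with columns theta (deg), ww (nm) and, when biased,
    bias (kJ/mol).  Warns if more than 1% of steps hit a reflecting
    boundary.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if init is None:
        init = HingeState(theta=params.theta_wells[0], w=params.twist_center,
                          time=step0 * params.dt)

    from .metadynamics import BiasState

    if bias is None or isinstance(bias, BiasState):
        from .metadynamics import _kernel_metad_run

        series, _ = _kernel_metad_run(
            params, bias_state=bias, depositing=False, init=init, rng=rng,
            step0=step0,
        )
        return series
    return _langevin_generic(params, bias, init, rng, step0)


def _langevin_generic(params, bias, init, rng, step0):
    """Reference path for arbitrary bias objects (direct evaluation)."""
    theta = float(init.theta)
    w = float(init.w)
    n_steps = params.n_steps
    stride = params.stride
    steps_rec = _record_steps(step0, n_steps, stride)
    n_rec = len(steps_rec)
    rec_theta = np.empty(n_rec)
    rec_w = np.empty(n_rec)
    rec_bias = np.empty(n_rec)

    c = _integrator_consts(params)
    dt_g, amp = c["dt_g"], c["amp"]
    B, A, tm, dl = c["B"], c["A"], c["tm"], c["dl"]
    kw, w0, coup = c["kw"], c["w0n"], c["coup"]

    bias_grad = bias.grad
    bias_value = bias.value

    reflections = 0
    k = 0
    step = step0
    done = 0
    while done < n_steps:
        chunk = min(NOISE_CHUNK, n_steps - done)
        noise = rng.standard_normal((chunk, 2))
        for i in range(chunk):
            u = (theta - tm) / dl
            ft = (4.0 * B * u * (u * u - 1.0) + 0.5 * A) / dl \
                + coup * (w - w0)
            fw = kw * (w - w0) + coup * (theta - tm)
            bt, bw = bias_grad(theta, w)
            ft += bt
            fw += bw
            theta += -dt_g * ft + amp * noise[i, 0]
            w += -dt_g * fw + amp * noise[i, 1]
            if theta <= 0.0:
                theta = -theta
                reflections += 1
            elif theta >= 180.0:
                theta = 360.0 - theta
                reflections += 1
            if w <= 0.0:
                w = -w
                reflections += 1
            step += 1
            if step % stride == 0:
                rec_theta[k] = theta
                rec_w[k] = w
                rec_bias[k] = bias_value(theta, w)
                k += 1
        done += chunk

    _warn_reflections(reflections, n_steps)
    return CVSeries(
        names=["theta", "ww", "bias"], units=["deg", "nm", "kJ/mol"],
        times=steps_rec * params.dt,
        values=np.column_stack([rec_theta, rec_w, rec_bias]),
    )


# ---------------------------------------------------------------------------
# Cartesian embedding
# ---------------------------------------------------------------------------

_SEQ3 = ["CYS", "HIS", "TRP", "GLU", "CYS", "ARG",
         "GLY", "CYS", "ARG", "LEU", "VAL", "CYS"]


@lru_cache(maxsize=1)
def hinge_topology() -> Topology:
    """Pseudo-atom topology of the dimeric hinge (30 beads).

    Per chain: one CA bead per residue, an SG bead on C1 and C12 (the
    disulfide cluster) and a CB side-chain bead on W3.  Standard hinge
    groups are attached.
    """
    atoms: list[Atom] = []
    for chain in ("A", "B"):
        for rid, res in enumerate(_SEQ3, start=1):
            atoms.append(Atom("CA", "C", res, rid, chain))
            if rid in (1, 12):
                atoms.append(Atom("SG", "S", res, rid, chain))
            if rid == 3:
                atoms.append(Atom("CB", "C", res, rid, chain))
    top = Topology(atoms=atoms)
    top.groups.update(standard_hinge_groups(top))
    return top


def feasible_twist_range(theta: float) -> tuple[float, float]:
    """Feasible (w_min, w_max) of the embedding at opening angle theta."""
    d = _anchor_separation(theta)
    return max(0.0, d - 2.0 * _TRP_ARM), d + 2.0 * _TRP_ARM


def _arm_axes(theta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    half = math.radians(theta) / 2.0
    c, s = math.cos(half), math.sin(half)
    e_a = np.array([c, s, 0.0])
    e_b = np.array([c, -s, 0.0])
    # in-plane perpendiculars, mirror-symmetric in y
    p_a = np.array([-s, c, 0.0])
    p_b = np.array([s, c, 0.0])
    return e_a, e_b, p_a, p_b


def _anchor(theta: float, chain: int) -> np.ndarray:
    e_a, e_b, p_a, p_b = _arm_axes(theta)
    radius = _ARM_OFFSET0 + 3 * _ARM_RISE
    if chain == 0:
        return radius * e_a + _STRAND_SEP * p_a
    return radius * e_b - _STRAND_SEP * p_b


def _anchor_separation(theta: float) -> float:
    return float(np.linalg.norm(_anchor(theta, 0) - _anchor(theta, 1)))


def state_to_frame(state: HingeState, params: HingeParams | None = None) -> np.ndarray:
    """Deterministic Cartesian embedding of one internal state.

    The construction guarantees (up to float rounding, ~1e-12):

    * the opening angle measured from c5c8/sulfur-cluster virtual atoms
      equals ``state.theta`` (the sulfur tetrahedron's center is the exact
      pivot and the C5/C8 beads straddle the arm axis symmetrically);
    * the W-W' distance between the two CB beads equals ``state.w``;
    * arms are rigid bodies rotated about the pivot, so the G7-G7'
      distance is continuous and monotone in theta.

    Raises :class:`EmbeddingError` when ``state.w`` is outside the twist
    range reachable with the fixed tryptophan tether length.
    """
    theta, w = state.theta, state.w
    lo, hi = feasible_twist_range(theta)
    if not lo < w <= hi:
        raise EmbeddingError(
            f"w={w:.4f} nm not embeddable at theta={theta:.2f} deg; "
            f"feasible range is ({lo:.4f}, {hi:.4f}] nm"
        )
    e_a, e_b, p_a, p_b = _arm_axes(theta)
    d = _SULFUR_D
    sulfur = {
        ("A", 1): np.array([d, d, d]),
        ("A", 12): np.array([d, -d, -d]),
        ("B", 1): np.array([-d, d, -d]),
        ("B", 12): np.array([-d, -d, d]),
    }

    a_a = _anchor(theta, 0)
    a_b = _anchor(theta, 1)
    sep = a_a - a_b
    dist = float(np.linalg.norm(sep))
    e_sep = sep / dist
    sin_chi = (dist - w) / (2.0 * _TRP_ARM)
    cos_chi = math.sqrt(max(0.0, 1.0 - sin_chi * sin_chi))
    z = np.array([0.0, 0.0, 1.0])
    trp = {
        "A": a_a + _TRP_ARM * (-sin_chi * e_sep + cos_chi * z),
        "B": a_b + _TRP_ARM * (sin_chi * e_sep + cos_chi * z),
    }

    coords = []
    for chain, e, p in (("A", e_a, p_a), ("B", e_b, p_b)):
        for rid in range(1, 13):
            radius = _ARM_OFFSET0 + _ARM_RISE * min(rid, 13 - rid)
            offset = _STRAND_SEP if rid <= 6 else -_STRAND_SEP
            coords.append(radius * e + offset * p)
            if rid in (1, 12):
                coords.append(sulfur[(chain, rid)])
            if rid == 3:
                coords.append(trp[chain])
    return np.array(coords)


def embed_series(series: CVSeries, params: HingeParams | None = None) -> Trajectory:
    """Embed a (theta, ww) CVSeries into a pseudo-atom Trajectory."""
    thetas = series.column("theta")
    ws = series.column("ww")
    top = hinge_topology()
    frames = np.empty((series.n_rows, top.n_atoms, 3))
    for i, (th, wv, t) in enumerate(zip(thetas, ws, series.times)):
        frames[i] = state_to_frame(HingeState(theta=float(th), w=float(wv),
                                              time=float(t)), params)
    return Trajectory(topology=top, coords=frames, times=series.times.copy())
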