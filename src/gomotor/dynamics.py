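"""Langevin dynamics in reduced units.

The equation of motion  m r'' = -zeta r' - dH/dr + Gamma(t)  is integrated
with a BBK (damped velocity-Verlet) discretization; the random force
satisfies <Gamma_i . Gamma_j> = (6 zeta kB T / h) delta_ij, i.e. each
Cartesian component has variance 2 zeta kB T / h.  Temperatures are quoted
in kelvin and converted through kB; friction and time step are quoted in
the Langevin unit tau_L = sqrt(m sigma^2 / eps_h).

Low friction (default zeta = 0.05 / tau_L) is used for efficient
conformational sampling; it affects kinetics, not the sampled ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .hamiltonian import EnergyModel, ForceFieldParams, TermSet, potential_energy
from .units import force_kj_to_reduced, reduced_temperature, tau_L


@dataclass
class LangevinConfig:
    """Sampling protocol: temperature (K), friction (1/tau_L), step (tau_L),
    relax/sample step counts, snapshot stride and seed."""

    T: float = 300.0
    zeta: float = 0.05
    h: float = 0.0025
    n_relax: int = 10_000
    n_sample: int = 200_000
    save_every: int = 200
    seed: int = 0
    energy_guard: float = 1e6

    def __post_init__(self) -> None:
        if self.zeta <= 0 or self.h <= 0:
            raise ValueError("zeta and h must be positive")

    def internal(self, params: ForceFieldParams):
        """(h, zeta, kT) in internal units (nm, eps_h, m=1)."""
        tl = tau_L(params.mass, params.sigma, 1.0)
        return self.h * tl, self.zeta / tl, reduced_temperature(self.T, params.eps_h)


@dataclass
class ExternalForce:
    """Constant pulling force on a bead group.

    ``magnitude`` is the TOTAL force in kJ mol^-1 nm^-1 (the units strain is
    quoted in), shared equally over the target beads; set
    ``per_bead=True`` to apply the magnitude to every bead instead.
    ``direction`` must be a unit vector (the actin axis for strain runs).
    """

    group: np.ndarray
    direction: np.ndarray
    magnitude: float
    per_bead: bool = False

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=int)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-10:
            raise ValueError("direction must be a unit vector")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")

    def reduced_field(self, n_beads: int, eps_h: float = 1.0) -> np.ndarray:
        f = np.zeros((n_beads, 3))
        mag = force_kj_to_reduced(self.magnitude, eps_h)
        share = mag if self.per_bead else mag / len(self.group)
        f[self.group - 1] = share * self.direction
        return f


@dataclass
class Trajectory:
    """Sampled frames with times (tau_L), energies and run provenance."""

    frames: np.ndarray          # (n_frames, N, 3) nm
    times: np.ndarray           # tau_L
    potential: np.ndarray       # eps_h
    kinetic: np.ndarray         # eps_h
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


class EnergyDivergence(RuntimeError):
    """Raised when |E| exceeds the guard; carries the offending frame."""

    def __init__(self, message: str, frame: np.ndarray):
        super().__init__(message)
        self.frame = frame


def maxwell_velocities(rng: np.random.Generator, n_beads: int, kT: float,
                       mass: float, free: np.ndarray) -> np.ndarray:
    v = rng.normal(0.0, np.sqrt(kT / mass), size=(n_beads, 3))
    v[free == 0.0] = 0.0
    return v


def kinetic_energy(vels: np.ndarray, mass: float = 1.0) -> float:
    return float(0.5 * mass * (vels ** 2).sum())


def langevin_run(model: EnergyModel, init: np.ndarray, config: LangevinConfig,
                 force: ExternalForce | None = None) -> Trajectory:
    """Relax-then-sample Langevin trajectory.

    ``n_relax`` steps are discarded, then ``n_sample`` steps are run with a
    snapshot every ``save_every`` steps.  The random stream (initial
    velocities and noise) is fully determined by ``config.seed``.  Raises
    :class:`EnergyDivergence` if |E| exceeds the guard.
    """
    coords = np.array(init, dtype=float)
    if coords.shape != (model.n_beads, 3):
        raise ValueError("init coords shape mismatch")
    if force is not None:
        model.set_external_force(
            force.reduced_field(model.n_beads, model.params.eps_h))
    h, zeta, kT = config.internal(model.params)
    mass = model.params.mass
    free = model.free_mask()
    rng = np.random.default_rng(config.seed)
    vels = maxwell_velocities(rng, model.n_beads, kT, mass, free)

    packed_ints, packed_floats = model.pack()
    fext = model.external
    fbuf = np.zeros_like(coords)
    _kernels._compute_forces(coords, packed_ints, packed_floats, fext, free, fbuf)
    noise_std = np.sqrt(2.0 * zeta * kT / h)

    def run_chunk(n_steps: int) -> float:
        noise = rng.normal(0.0, noise_std, size=(n_steps, model.n_beads, 3)) \
            if noise_std > 0 else np.zeros((n_steps, model.n_beads, 3))
        return _kernels.bbk_segment(coords, vels, fbuf, n_steps, h, zeta, mass,
                                    free, fext, noise, packed_ints, packed_floats)

    # relaxation
    left = config.n_relax
    while left > 0:
        n = min(left, 20_000)
        epot = run_chunk(n)
        left -= n
        if not np.isfinite(epot) or abs(epot) > config.energy_guard:
            raise EnergyDivergence(
                f"energy diverged during relaxation (E = {epot:.3g})", coords.copy())

    n_frames = config.n_sample // config.save_every
    frames = np.empty((n_frames, model.n_beads, 3))
    times = np.empty(n_frames)
    epots = np.empty(n_frames)
    ekins = np.empty(n_frames)
    tl = tau_L(mass, model.params.sigma, 1.0)
    for fidx in range(n_frames):
        epot = run_chunk(config.save_every)
        if not np.isfinite(epot) or abs(epot) > config.energy_guard:
            raise EnergyDivergence(
                f"energy diverged at frame {fidx} (E = {epot:.3g})", coords.copy())
        frames[fidx] = coords
        times[fidx] = (fidx + 1) * config.save_every * h / tl
        epots[fidx] = epot
        ekins[fidx] = kinetic_energy(vels, mass)

    prov = {
        "seed": config.seed, "T": config.T, "zeta": config.zeta, "h": config.h,
        "n_relax": config.n_relax, "n_sample": config.n_sample,
        "save_every": config.save_every,
        "toggles": sorted(model.active), "pi_removed": model.pi_removed,
        "force": None if force is None else {
            "magnitude_kj_mol_nm": force.magnitude,
            "direction": force.direction.tolist(),
            "per_bead": force.per_bead,
            "n_targets": int(len(force.group)),
        },
    }
    return Trajectory(frames, times, epots, ekins, prov)


def actin_axis(actin_coords: np.ndarray) -> np.ndarray:
    """Principal axis of the filament bead cloud, oriented so that it points
    from earlier- to later-listed beads."""
    xyz = np.asarray(actin_coords, dtype=float)
    if xyz.ndim != 2 or xyz.shape[0] < 2:
        raise ValueError("need at least 2 actin beads")
    centred = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    # sign convention: along increasing bead order
    if np.dot(xyz[-1] - xyz[0], axis) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def strain_scan(model: EnergyModel, init: np.ndarray, config: LangevinConfig,
                magnitudes, target_group, direction) -> list[Trajectory]:
    """One trajectory per force magnitude (kJ mol^-1 nm^-1), same seed policy
    for every magnitude so runs differ only by the applied strain."""
    out = []
    for mag in magnitudes:
        force = ExternalForce(group=np.asarray(target_group, int),
                              direction=np.asarray(direction, float),
                              magnitude=float(mag))
        traj = langevin_run(model, init, config, force=force)
        traj.provenance["strain_magnitude_kj_mol_nm"] = float(mag)
        out.append(traj)
    model.set_external_force(None)
    return out


def constant_force_check(k: float, F: float, config: LangevinConfig | None = None,
                         axis=(1.0, 0.0, 0.0), params: ForceFieldParams | None = None):
    """Validation run: one bead tethered by an isotropic harmonic spring of
    stiffness ``k`` (eps_h/nm^2) under a constant force ``F`` (eps_h/nm)
    along ``axis``.

    Returns a dict with the time-averaged displacement along the axis
    (closed form F/k), the per-coordinate positional variance (closed form
    kB T / k) and the mean kinetic energy per degree of freedom.
    The tether is realised as a zero-rest-length bond to a frozen bead.
    """
    config = config or LangevinConfig(zeta=5.0, h=0.0025, n_relax=20_000,
                                      n_sample=2_000_000, save_every=10)
    params = params or ForceFieldParams()
    tether = TermSet(bonds=np.array([[1, 2]]), bond_r0=np.array([0.0]),
                     bond_k=np.array([float(k)]))
    model = EnergyModel(
        n_beads=2, chain_ids=np.array(["A", "B"]),
        term_sets={"preMH": tether}, active={"preMH"}, params=params,
        frozen=np.array([True, False]))
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    fext = np.zeros((2, 3))
    fext[1] = F * axis
    model.set_external_force(fext)
    init = np.zeros((2, 3))
    init[1] = 1e-3 * axis if F == 0 else (F / k) * axis
    traj = langevin_run(model, init, config)
    disp = traj.frames[:, 1, :]
    along = disp @ axis
    _, _, kT = config.internal(params)
    return {
        "mean_displacement": float(along.mean()),
        "expected_displacement": F / k,
        "variance": disp.var(axis=0, ddof=0),
        "expected_variance": kT / k,
        "mean_kinetic_per_dof": float(traj.kinetic.mean() / 3.0),
        "expected_kinetic_per_dof": 0.5 * kT,
        "trajectory": traj,
    }
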