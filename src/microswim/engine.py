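"""Overdamped Langevin dynamics for self-propelled colloids.

The engine integrates the positions ``r_i`` and directors ``ê_i`` of N
microscopic particles with the Euler–Maruyama scheme:

    r  <- r + γ_t⁻¹ (F_act ê + F_int + F_ext) Δt + sqrt(2 k_B T γ_t⁻¹ Δt) ξ_t
    θ  <- θ + γ_r⁻¹ (M_act + M_int) Δt + sqrt(2 k_B T γ_r⁻¹ Δt) ξ_r   (2D)

with ξ standard normal per component (zero mean, delta-correlated unit
covariance).  In 3D the director is rotated by the angular increment
ω Δt + noise with ω = γ_r⁻¹ M and renormalized.  Reduced units throughout
(k_B = 1).  Inertia is neglected: friction, deterministic forces and thermal
noise balance instantaneously, which is the correct regime for micron-sized
swimmers in water.

Control enters through per-particle :class:`~microswim.actions.Action`
objects (propulsion force along the director, steering torque, or a direct
director override).  The engine exposes the narrow two-method environment
contract: :meth:`LangevinEngine.integrate` and
:meth:`LangevinEngine.get_particle_data`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .actions import Action

__all__ = [
    "Colloid",
    "SystemParams",
    "ConcentrationField",
    "RigidRod",
    "TrajectoryRecord",
    "LangevinEngine",
    "field_value",
    "field_gradient",
    "wca_force",
    "wca_cutoff",
]


@dataclass
class Colloid:
    """State of a single particle as exchanged between engine and control code.

    Attributes
    ----------
    id : int
        Unique non-negative particle identifier, stable over a trajectory.
    type : int
        Group label; each type is controlled by at most one agent.
    pos : ndarray, shape (d,)
        Position in simulation length units.
    director : ndarray, shape (d,)
        Unit vector giving the propulsion direction.
    radius : float
        Particle radius (length units).
    """

    id: int
    type: int
    pos: np.ndarray
    director: np.ndarray
    radius: float = 1.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.director = np.asarray(self.director, dtype=float)

    def copy(self) -> "Colloid":
        return Colloid(self.id, self.type, self.pos.copy(), self.director.copy(), self.radius)


@dataclass
class SystemParams:
    """Physical and numerical parameters of a simulation.

    Frictions may be scalars (all types) or a mapping ``type -> value``.
    ``boundary`` is one of ``"periodic"``, ``"reflective"`` or ``"open"``.
    ``interaction`` is ``"none"`` or ``"wca"``.
    """

    dimension: int = 2
    box_length: float | Sequence[float] = 100.0
    temperature: float = 1.0
    gamma_t: float | Mapping[int, float] = 1.0
    gamma_r: float | Mapping[int, float] = 1.0
    dt: float = 0.01
    boundary: str = "periodic"
    interaction: str = "none"
    wca_epsilon: float = 1.0
    wca_sigma: float = 1.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        for g in (self.gamma_t, self.gamma_r):
            vals = g.values() if isinstance(g, Mapping) else [g]
            if any(v <= 0 for v in vals):
                raise ValueError("friction coefficients must be positive")
        if self.boundary not in ("periodic", "reflective", "open"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")
        if self.interaction not in ("none", "wca"):
            raise ValueError(f"unknown interaction {self.interaction!r}")
        self.box = np.broadcast_to(
            np.asarray(self.box_length, dtype=float), (self.dimension,)
        ).copy()

    def friction_t(self, types: np.ndarray) -> np.ndarray:
        return _per_type(self.gamma_t, types)

    def friction_r(self, types: np.ndarray) -> np.ndarray:
        return _per_type(self.gamma_r, types)

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "box_length": self.box.tolist(),
            "temperature": self.temperature,
            "gamma_t": dict(self.gamma_t) if isinstance(self.gamma_t, Mapping) else self.gamma_t,
            "gamma_r": dict(self.gamma_r) if isinstance(self.gamma_r, Mapping) else self.gamma_r,
            "dt": self.dt,
            "boundary": self.boundary,
            "interaction": self.interaction,
            "wca_epsilon": self.wca_epsilon,
            "wca_sigma": self.wca_sigma,
            "seed": self.seed,
        }


def _per_type(value: float | Mapping[int, float], types: np.ndarray) -> np.ndarray:
    if isinstance(value, Mapping):
        return np.array([value[int(t)] for t in types], dtype=float)
    return np.full(len(types), float(value))


# ---------------------------------------------------------------------------
# Concentration field
# ---------------------------------------------------------------------------


@dataclass
class ConcentrationField:
    """Static Gaussian chemical concentration field.

    c(x) = c0 * exp(-|x - source|^2 / (2 σ_c^2)); positive everywhere and
    maximal at the source, emulating diffusion from a point emitter.
    """

    source: np.ndarray
    c0: float = 1.0
    sigma_c: float = 1.0
    form: str = "gaussian"

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float)
        if self.c0 <= 0 or self.sigma_c <= 0:
            raise ValueError("c0 and sigma_c must be positive")
        if self.form != "gaussian":
            raise ValueError("only the gaussian form is implemented")

    def __call__(self, x: np.ndarray) -> np.ndarray | float:
        return field_value(self, x)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return field_gradient(self, x)


def field_value(fld: ConcentrationField, x: np.ndarray) -> np.ndarray | float:
    """Evaluate the field at one position (d,) or a batch (n, d)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("position must be finite")
    d2 = np.sum((x - fld.source) ** 2, axis=-1)
    return fld.c0 * np.exp(-d2 / (2.0 * fld.sigma_c**2))


def field_gradient(fld: ConcentrationField, x: np.ndarray) -> np.ndarray:
    """∇c, pointing toward the source (up-gradient)."""
    x = np.asarray(x, dtype=float)
    c = field_value(fld, x)
    return (fld.source - x) * (np.asarray(c)[..., None] / fld.sigma_c**2)


# ---------------------------------------------------------------------------
# WCA pair force
# ---------------------------------------------------------------------------

_WCA_CAP_FRACTION = 0.5


def wca_cutoff(sigma: float) -> float:
    return 2.0 ** (1.0 / 6.0) * sigma


def wca_force(r_ij: np.ndarray, epsilon: float, sigma: float) -> np.ndarray:
    """Weeks–Chandler–Andersen force on particle i from particle j.

    ``r_ij = r_i - r_j``.  Purely repulsive: the Lennard-Jones force
    24ε(2σ¹²/r¹³ − σ⁶/r⁷) r̂ truncated to zero beyond 2^(1/6) σ.  Below
    0.5σ the magnitude is capped at its 0.5σ value (with a warning) to keep
    badly overlapping initial conditions integrable.
    """
    r_ij = np.asarray(r_ij, dtype=float)
    r = float(np.linalg.norm(r_ij))
    if r == 0.0:
        raise ValueError("wca_force requires |r_ij| > 0")
    if r >= wca_cutoff(sigma):
        return np.zeros_like(r_ij)
    if r < _WCA_CAP_FRACTION * sigma:
        warnings.warn(
            "WCA overlap below 0.5 sigma; force capped", RuntimeWarning, stacklevel=2
        )
        r_eff = _WCA_CAP_FRACTION * sigma
    else:
        r_eff = r
    mag = 24.0 * epsilon * (2.0 * sigma**12 / r_eff**13 - sigma**6 / r_eff**7)
    return mag * r_ij / r


def _wca_forces_batch(
    pos: np.ndarray, epsilon: float, sigma: float, box: np.ndarray | None
) -> np.ndarray:
    """All-pairs WCA forces, minimum image when ``box`` is given. O(N^2)."""
    n = pos.shape[0]
    forces = np.zeros_like(pos)
    if n < 2:
        return forces
    rij = pos[:, None, :] - pos[None, :, :]
    if box is not None:
        rij -= box * np.round(rij / box)
    dist = np.linalg.norm(rij, axis=-1)
    np.fill_diagonal(dist, np.inf)
    cut = wca_cutoff(sigma)
    mask = dist < cut
    if not mask.any():
        return forces
    if (dist[mask] < _WCA_CAP_FRACTION * sigma).any():
        warnings.warn(
            "WCA overlap below 0.5 sigma; force capped", RuntimeWarning, stacklevel=2
        )
    r_eff = np.clip(dist, _WCA_CAP_FRACTION * sigma, None)
    mag = np.where(mask, 24.0 * epsilon * (2.0 * sigma**12 / r_eff**13 - sigma**6 / r_eff**7), 0.0)
    with np.errstate(invalid="ignore"):
        unit = rij / dist[..., None]
    unit = np.nan_to_num(unit)
    forces = np.sum(mag[..., None] * unit, axis=1)
    return forces


# ---------------------------------------------------------------------------
# Rigid rod
# ---------------------------------------------------------------------------


@dataclass
class RigidRod:
    """A rigid chain of passive beads, updated as one overdamped rigid body.

    Net force on the beads translates the center of mass with friction
    ``gamma_t``; the net z-torque about the center rotates the rod with
    friction ``gamma_r``.  2D only.  Bead positions are reconstructed from
    (center, angle) every step, so the rod never deforms.
    """

    bead_ids: Sequence[int]
    gamma_t: float = 10.0
    gamma_r: float = 100.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    angle: float = 0.0
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.bead_ids = list(self.bead_ids)

    def bead_offsets(self) -> np.ndarray:
        n = len(self.bead_ids)
        s = (np.arange(n) - (n - 1) / 2.0) * self.spacing
        axis = np.array([np.cos(self.angle), np.sin(self.angle)])
        return s[:, None] * axis[None, :]

    def bead_positions(self) -> np.ndarray:
        return self.center[None, :] + self.bead_offsets()


# ---------------------------------------------------------------------------
# Trajectory record
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryRecord:
    """Time series of system snapshots, one per control slice.

    ``positions`` are wrapped into the box (when periodic); ``unwrapped``
    carries the image-corrected positions used for displacement statistics.
    """

    positions: np.ndarray  # (n_slices+1, N, d)
    directors: np.ndarray  # (n_slices+1, N, d)
    unwrapped: np.ndarray  # (n_slices+1, N, d)
    times: np.ndarray  # (n_slices+1,)
    ids: np.ndarray  # (N,)
    types: np.ndarray  # (N,)
    config: dict = field(default_factory=dict)
    seed: int | None = None
    rewards: np.ndarray | None = None  # (n_slices, N) when recorded
    episode_boundaries: list = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return self.positions.shape[0] - 1

    def config_json(self) -> str:
        return json.dumps(self.config, sort_keys=True)


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------


class LangevinEngine:
    """Brownian-dynamics environment for a collection of colloids.

    Parameters
    ----------
    colloids
        Initial particle states (copied).
    params
        Physical and numerical parameters; ``params.seed`` seeds the
        engine-owned counter-based RNG (PCG64), recorded in output metadata.
    rod
        Optional rigid rod whose beads (matched by id) move as a rigid body.
    external_force
        Optional hook ``f(pos (N,d), types (N,)) -> (N,d)`` adding a
        deterministic body force (e.g. gravity); default none.
    """

    def __init__(
        self,
        colloids: Sequence[Colloid],
        params: SystemParams,
        rod: RigidRod | None = None,
        external_force: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    ) -> None:
        if not colloids:
            raise ValueError("engine needs at least one colloid")
        self.params = params
        self.rod = rod
        self.external_force = external_force
        self.ids = np.array([c.id for c in colloids], dtype=int)
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("colloid ids must be unique")
        self.types = np.array([c.type for c in colloids], dtype=int)
        self.radii = np.array([c.radius for c in colloids], dtype=float)
        self.pos = np.array([c.pos for c in colloids], dtype=float)
        self.directors = np.array([c.director for c in colloids], dtype=float)
        norms = np.linalg.norm(self.directors, axis=1, keepdims=True)
        self.directors = self.directors / norms
        d = params.dimension
        if self.pos.shape[1] != d:
            raise ValueError("colloid dimension does not match params.dimension")
        self.images = np.zeros_like(self.pos)  # periodic image counts * box
        self.time = 0.0
        self.rng = np.random.Generator(np.random.PCG64(params.seed))
        self._inv_gt = 1.0 / params.friction_t(self.types)
        self._inv_gr = 1.0 / params.friction_r(self.types)
        self._rod_index: np.ndarray | None = None
        if rod is not None:
            if d != 2:
                raise ValueError("rigid rod supported in 2D only")
            id_to_row = {int(i): k for k, i in enumerate(self.ids)}
            self._rod_index = np.array([id_to_row[i] for i in rod.bead_ids], dtype=int)
            self.pos[self._rod_index] = rod.bead_positions()
        self._warned_dt = False
        self._apply_boundary()

    # -- environment contract -------------------------------------------------

    def get_particle_data(self) -> list[Colloid]:
        """Current colloid states as independent snapshots (safe to mutate)."""
        return [
            Colloid(int(i), int(t), p.copy(), e.copy(), float(r))
            for i, t, p, e, r in zip(self.ids, self.types, self.pos, self.directors, self.radii)
        ]

    def integrate(
        self, force_function, n_slices: int, steps_per_slice: int = 1
    ) -> TrajectoryRecord:
        """Run ``n_slices`` control slices of ``steps_per_slice`` inner steps.

        The force function is queried once per slice for fresh actions, which
        are then held constant and applied at every inner integration step.
        One snapshot is appended per completed slice.  If the force function
        exposes a truthy ``kill_switch`` after being queried, integration
        halts at that slice (the slice is not run).
        """
        snaps_p = [self.pos.copy()]
        snaps_d = [self.directors.copy()]
        snaps_u = [self.pos + self.images]
        times = [self.time]
        stopped_at = None
        for s in range(n_slices):
            try:
                actions = force_function.calc_action(self.get_particle_data())
            except Exception as err:
                raise RuntimeError(f"force function failed at slice {s}") from err
            if getattr(force_function, "kill_switch", False):
                stopped_at = s
                break
            if len(actions) != len(self.ids):
                raise ValueError(
                    f"force function returned {len(actions)} actions for {len(self.ids)} colloids"
                )
            for _ in range(steps_per_slice):
                self.step(actions)
            snaps_p.append(self.pos.copy())
            snaps_d.append(self.directors.copy())
            snaps_u.append(self.pos + self.images)
            times.append(self.time)
        record = TrajectoryRecord(
            positions=np.array(snaps_p),
            directors=np.array(snaps_d),
            unwrapped=np.array(snaps_u),
            times=np.array(times),
            ids=self.ids.copy(),
            types=self.types.copy(),
            config=self.params.to_dict(),
            seed=self.params.seed,
        )
        if stopped_at is not None:
            record.config["stopped_at_slice"] = stopped_at
        return record

    # -- single step ----------------------------------------------------------

    def step(self, actions: Sequence[Action]) -> None:
        """One Euler–Maruyama step with the given per-particle actions."""
        if len(actions) != len(self.ids):
            raise ValueError("need exactly one action per colloid")
        p = self.params
        dt = p.dt
        n, d = self.pos.shape

        f_act = np.array([a.force for a in actions], dtype=float)
        torque = np.array([np.asarray(a.torque, dtype=float) for a in actions])
        forces = f_act[:, None] * self.directors
        if p.interaction == "wca":
            box = p.box if p.boundary == "periodic" else None
            forces = forces + _wca_forces_batch(self.pos, p.wca_epsilon, p.wca_sigma, box)
            self._check_wca_dt(forces)
        if self.external_force is not None:
            forces = forces + self.external_force(self.pos, self.types)
        if not np.all(np.isfinite(forces)):
            raise FloatingPointError("non-finite forces: unstable parameters")

        noise_t = self.rng.standard_normal((n, d))
        disp = (
            self._inv_gt[:, None] * forces * dt
            + np.sqrt(2.0 * p.temperature * self._inv_gt * dt)[:, None] * noise_t
        )

        # rotational update
        if d == 2:
            noise_r = self.rng.standard_normal(n)
            tz = torque[:, 2]
            theta = np.arctan2(self.directors[:, 1], self.directors[:, 0])
            theta = (
                theta
                + self._inv_gr * tz * dt
                + np.sqrt(2.0 * p.temperature * self._inv_gr * dt) * noise_r
            )
            new_dir = np.column_stack([np.cos(theta), np.sin(theta)])
        else:
            noise_r = self.rng.standard_normal((n, 3))
            omega = self._inv_gr[:, None] * torque
            dphi = omega * dt + np.sqrt(2.0 * p.temperature * self._inv_gr * dt)[:, None] * noise_r
            new_dir = self.directors + np.cross(dphi, self.directors)
            new_dir /= np.linalg.norm(new_dir, axis=1, keepdims=True)

        # direction override takes precedence over the torque update
        for k, a in enumerate(actions):
            if a.new_direction is not None:
                nd = np.asarray(a.new_direction, dtype=float)
                new_dir[k] = nd / np.linalg.norm(nd)

        if self._rod_index is not None:
            self._step_rod(forces, disp, dt)
            keep = np.ones(n, dtype=bool)
            keep[self._rod_index] = False
            self.pos[keep] += disp[keep]
            self.directors[keep] = new_dir[keep]
        else:
            self.pos += disp
            self.directors = new_dir
        self.time += dt
        self._apply_boundary()

    def _step_rod(self, forces: np.ndarray, disp: np.ndarray, dt: float) -> None:
        rod = self.rod
        idx = self._rod_index
        rel = self.pos[idx] - rod.center
        f = forces[idx]
        net_f = f.sum(axis=0)
        net_tz = np.sum(rel[:, 0] * f[:, 1] - rel[:, 1] * f[:, 0])
        t_noise = self.rng.standard_normal(2)
        r_noise = self.rng.standard_normal()
        p = self.params
        rod.center = (
            rod.center
            + net_f / rod.gamma_t * dt
            + np.sqrt(2.0 * p.temperature / rod.gamma_t * dt) * t_noise
        )
        rod.angle = (
            rod.angle
            + net_tz / rod.gamma_r * dt
            + np.sqrt(2.0 * p.temperature / rod.gamma_r * dt) * r_noise
        )
        self.pos[idx] = rod.bead_positions()
        axis = np.array([np.cos(rod.angle), np.sin(rod.angle)])
        self.directors[idx] = axis

    def _check_wca_dt(self, forces: np.ndarray) -> None:
        if self._warned_dt:
            return
        p = self.params
        max_disp = np.max(np.abs(forces)) * np.max(self._inv_gt) * p.dt
        if max_disp > 0.1 * p.wca_sigma:
            warnings.warn(
                f"WCA displacement per step {max_disp:.3g} exceeds 0.1 sigma; "
                "reduce dt for stable interactions",
                RuntimeWarning,
                stacklevel=3,
            )
            self._warned_dt = True

    def _apply_boundary(self) -> None:
        p = self.params
        if p.boundary == "periodic":
            shift = np.floor(self.pos / p.box) * p.box
            self.pos -= shift
            self.images += shift
        elif p.boundary == "reflective":
            # mirror reflection keeps particles strictly inside the box
            box = p.box
            pos = np.mod(self.pos, 2.0 * box)
            over = pos > box
            pos[over] = (2.0 * box * np.ones_like(pos))[over] - pos[over]
            self.pos = pos
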