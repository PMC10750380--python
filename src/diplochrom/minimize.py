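"""Staged Langevin-dynamics energy minimization.

A minimization run starts from beads placed uniformly at random in a small
cube (side 10). Bonds alone are equilibrated first; then contact and
excluded-volume potentials are switched on and ramped up in five stages —
the contact stiffness k_c geometrically, the Gaussian width σ linearly —
until the final values (k_b = k_c = 2000) are reached. While the potentials
are soft, chains freely cross, which lets the topology sort itself out;
by the last stage bonds sit near 1.0 and contacts near 1.5.

The integrator is a BAOAB-splitting Langevin scheme (γ = 1, k_BT = 1,
dt = 0.001, unit mass). The same seed always reproduces the same
trajectory bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .model import Conformation, GenomeModel, PotentialParams, default_rcut


class SimulationDiverged(RuntimeError):
    """A coordinate became non-finite during integration."""


@dataclass(frozen=True)
class ProtocolStage:
    """One step of the staged minimization protocol."""

    k_c: float
    sigma: float
    epsilon: float
    n_steps: int
    label: str = ""

    def __post_init__(self):
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.k_c < 0 or self.sigma <= 0 or self.epsilon < 0:
            raise ValueError("invalid stage parameters")


@dataclass(frozen=True)
class IntegratorConfig:
    """Langevin thermostat parameters (simulation units)."""

    gamma: float = 1.0
    kT: float = 1.0
    dt: float = 0.001

    def __post_init__(self):
        if self.gamma < 0 or self.kT < 0 or self.dt <= 0:
            raise ValueError("invalid integrator parameters")


DEFAULT_KC_RAMP = (0.2, 2.0, 20.0, 200.0, 2000.0)


def make_schedule(
    params: PotentialParams | None = None,
    steps_equil: int = 5_000,
    steps_stage: int = 8_000,
    steps_final: int = 15_000,
    kc_ramp: Sequence[float] = DEFAULT_KC_RAMP,
) -> list[ProtocolStage]:
    """Default protocol: bond-only equilibration, then a five-stage ramp.

    k_c rises geometrically over ``kc_ramp`` while σ rises linearly to its
    final value; ε is constant once the excluded volume is on. Only the
    endpoint values are physical requirements — intermediates just need to
    take the system smoothly from zero to full potentials, and the step
    counts are configuration (long enough to re-equilibrate at each stage).
    The ramp spans four decades starting from a *very* soft k_c: while
    contacts are weak and chains can still cross, the large-scale topology
    sorts itself out, which is what makes independent minimizations land
    in the same basin. A steeper ramp visibly degrades reproducibility.
    """
    params = params or PotentialParams()
    n = len(kc_ramp)
    stages = [
        ProtocolStage(0.0, params.sigma / n, 0.0, steps_equil, "bond-equil")
    ]
    for i, kc in enumerate(kc_ramp):
        frac = (i + 1) / n
        # ε ramps with σ: excluded volume must stay soft while the
        # topology is still rearranging (crossings), and reach full
        # strength only once contacts are stiff
        stages.append(
            ProtocolStage(kc, params.sigma * frac, params.epsilon * frac,
                          steps_stage, f"ramp-{i + 1}")
        )
    if steps_final > 0:
        stages.append(
            ProtocolStage(kc_ramp[-1], params.sigma, params.epsilon,
                          steps_final, "final-hold")
        )
    validate_schedule(stages)
    return stages


def quick_schedule(params: PotentialParams | None = None) -> list[ProtocolStage]:
    """Short schedule for desk-scale systems (hundreds of beads)."""
    return make_schedule(params, steps_equil=3_000, steps_stage=4_000,
                         steps_final=8_000)


def validate_schedule(stages: Sequence[ProtocolStage]) -> None:
    """The ramp must be nondecreasing in k_c and σ."""
    if not stages:
        raise ValueError("schedule is empty")
    for a, b in zip(stages, stages[1:]):
        if b.k_c < a.k_c or b.sigma < a.sigma:
            raise ValueError(
                f"schedule not a ramp: {a.label!r} -> {b.label!r} decreases k_c or sigma"
            )


def initialize_in_cube(
    model: GenomeModel, side: float = 10.0, seed=0
) -> Conformation:
    """Uniform random bead placement inside a cube of the given side (10³
    by default). ``seed`` may be an int or a ``numpy.random.Generator``."""
    if side <= 0:
        raise ValueError("cube side must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.uniform(0.0, side, size=(model.n_beads, 3))
    return Conformation(model, x, {"init": "cube", "side": side})


@dataclass
class StageTrace:
    label: str
    n_steps: int
    energies: list[float] = field(default_factory=list)

    @property
    def final_energy(self) -> float:
        return self.energies[-1] if self.energies else float("nan")


_CHUNK = 200  # noise-buffer steps between divergence checks


def run_stage(
    conf: Conformation,
    bonds: np.ndarray,
    contacts: np.ndarray,
    stage: ProtocolStage,
    integ: IntegratorConfig | None = None,
    params: PotentialParams | None = None,
    rng: np.random.Generator | int | None = None,
    velocities: np.ndarray | None = None,
) -> tuple[Conformation, StageTrace, np.ndarray]:
    """Advance one protocol stage; returns (conformation, trace, velocities).

    The stage overrides k_c, σ and ε of ``params`` (k_b and the preferred
    lengths are fixed throughout the protocol); r_cut follows σ via the
    1%-of-maximum rule. In the kT = 0, γ > 0 limit this is damped descent
    and the total (kinetic + potential) energy is non-increasing.
    """
    integ = integ or IntegratorConfig()
    base = params or PotentialParams()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x = np.ascontiguousarray(conf.coords, dtype=np.float64).copy()
    if not np.all(np.isfinite(x)):
        raise SimulationDiverged(f"non-finite input coordinates at stage {stage.label!r}")
    bonds = np.ascontiguousarray(np.asarray(bonds, dtype=np.int64).reshape(-1, 2))
    contacts = np.ascontiguousarray(np.asarray(contacts, dtype=np.int64).reshape(-1, 2))
    n = x.shape[0]
    if velocities is None:
        v = (
            rng.normal(0.0, np.sqrt(integ.kT), size=(n, 3))
            if integ.kT > 0
            else np.zeros((n, 3))
        )
    else:
        v = np.ascontiguousarray(velocities, dtype=np.float64).copy()
    a = float(np.exp(-integ.gamma * integ.dt))
    bnoise = float(np.sqrt(integ.kT * (1.0 - a * a)))
    rcut = default_rcut(stage.sigma)
    trace = StageTrace(stage.label, stage.n_steps)
    done = 0
    while done < stage.n_steps:
        m = min(_CHUNK, stage.n_steps - done)
        noise = (
            rng.standard_normal((m, n, 3)) if integ.kT > 0 else np.zeros((m, n, 3))
        )
        e = _kernels.run_baoab(
            x, v, bonds, contacts,
            base.k_b, base.r0_b, stage.k_c, base.r0_c,
            stage.epsilon, stage.sigma, rcut,
            integ.dt, a, bnoise, noise,
        )
        done += m
        if not (np.all(np.isfinite(x)) and np.isfinite(e)):
            raise SimulationDiverged(
                f"divergence in stage {stage.label!r} near step {done}/{stage.n_steps}"
            )
        trace.energies.append(float(e))
    out = Conformation(conf.model, x, dict(conf.provenance))
    return out, trace, v


@dataclass
class MinimizeResult:
    conformation: Conformation
    traces: list[StageTrace]

    def energy_table(self):
        return [(t.label, t.n_steps, t.final_energy) for t in self.traces]


def minimize(
    model: GenomeModel,
    bead_contacts: np.ndarray,
    schedule: Sequence[ProtocolStage] | None = None,
    integ: IntegratorConfig | None = None,
    params: PotentialParams | None = None,
    seed: int = 0,
    start: Conformation | None = None,
    cube_side: float = 10.0,
) -> MinimizeResult:
    """Full staged minimization: cube init → bond equilibration → ramp.

    ``bead_contacts`` is an (M, 2) array of bead index pairs (already
    deduplicated and free of same-bead/bonded pairs). Velocities persist
    across stages. Deterministic in ``seed``.
    """
    schedule = list(schedule) if schedule is not None else make_schedule(params)
    validate_schedule(schedule)
    integ = integ or IntegratorConfig()
    rng = np.random.default_rng(seed)
    conf = start.copy() if start is not None else initialize_in_cube(model, cube_side, rng)
    conf.provenance.update({"seed": seed, "resolution": model.resolution})
    bonds = model.bonds()
    traces: list[StageTrace] = []
    v = None
    for stage in schedule:
        conf, tr, v = run_stage(
            conf, bonds, bead_contacts, stage, integ, params, rng, velocities=v
        )
        traces.append(tr)
    return MinimizeResult(conf, traces)


def reset_and_resample(
    conf: Conformation,
    bead_contacts: np.ndarray,
    schedule: Sequence[ProtocolStage] | None = None,
    integ: IntegratorConfig | None = None,
    params: PotentialParams | None = None,
    new_seed: int = 1,
    collapse_steps: int = 2_000,
) -> MinimizeResult:
    """Generate an independent conformation from an existing one.

    Bond and contact potentials are reset to zero so the structure
    collapses into an unconstrained coil (free Langevin motion erases the
    previous arrangement), then the full ramp is rerun with a fresh seed.
    """
    integ = integ or IntegratorConfig()
    base = params or PotentialParams()
    rng = np.random.default_rng(new_seed)
    free = ProtocolStage(0.0, base.sigma, 0.0, collapse_steps, "collapse")
    empty = np.empty((0, 2), dtype=np.int64)
    collapsed, _, _ = run_stage(conf, empty, empty, free, integ, base.replace(k_b=0.0), rng)
    schedule = list(schedule) if schedule is not None else make_schedule(base)
    res = minimize(
        conf.model, bead_contacts, schedule, integ, base,
        seed=new_seed, start=collapsed,
    )
    res.conformation.provenance["resampled_from"] = conf.provenance.get("seed")
    return res
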