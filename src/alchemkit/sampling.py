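"""Metropolis Monte Carlo sampling of the toy Hamiltonians.

The estimators in this package consume equilibrium ensemble averages only,
so a Metropolis sampler with single-particle displacement moves provides
exact target distributions without integrator or thermostat artifacts; it
stands in for the production molecular-dynamics runs that would supply the
same per-frame observables in a real application.

Every recorded frame carries all observables needed downstream, computed on
the fly: the total energy, both coupling derivatives, the end-state
energies along the sampled perturbation axis (hence the instantaneous
energy difference dV_BA = H_B - H_A), cross-evaluations at requested
neighbor states (for the acceptance-ratio estimator), and the dense grid of
probe-lam derivative/energy records used by extended thermodynamic
integration.  Identical (seed, config, system) inputs give bit-identical
series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .model_systems import (
    CouplingState,
    DomainError,
    StructureError,
    ThermoContext,
    as_system,
)

__all__ = [
    "SamplerConfig",
    "ObservableSeries",
    "SamplingError",
    "metropolis_sample",
    "sample_eds_reference",
    "EDSParams",
]


class SamplingError(RuntimeError):
    """The Markov chain failed to move; usually a step-size problem."""


@dataclass(frozen=True)
class SamplerConfig:
    """Monte Carlo run settings.

    burn_in defaults to 10% of n_steps; during burn-in the step size is
    tuned toward an acceptance fraction of 0.3-0.5 and then frozen, so the
    production phase obeys detailed balance exactly.
    """

    n_steps: int
    step_size: float = 0.05  # nm, initial proposal half-width
    seed: int = 0
    record_stride: int = 10
    burn_in: int | None = None

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise DomainError("step_size must be > 0")
        if self.record_stride < 1:
            raise DomainError("record_stride must be >= 1")
        bi = self.resolved_burn_in
        if not (self.n_steps > bi >= 0):
            raise DomainError("need n_steps > burn_in >= 0")

    @property
    def resolved_burn_in(self) -> int:
        return self.n_steps // 10 if self.burn_in is None else self.burn_in


@dataclass
class ObservableSeries:
    """Per-frame observables sampled at one fixed coupling state."""

    state: CouplingState
    temperature: float
    seed: int | None
    system_id: str
    H: np.ndarray
    dHdlam: np.ndarray
    dHdkap: np.ndarray
    H_A: np.ndarray
    H_B: np.ndarray
    neighbors: dict[CouplingState, np.ndarray] = field(default_factory=dict)
    probe_lams: np.ndarray | None = None
    probe_dHdlam: np.ndarray | None = None  # shape (n_frames, n_probes)
    probe_H: np.ndarray | None = None
    extra: dict[str, np.ndarray] = field(default_factory=dict)
    axis: str = "lam"

    def __post_init__(self) -> None:
        n = len(self.H)
        if n < 1:
            raise StructureError("a series must contain at least one frame")
        for name in ("H", "dHdlam", "dHdkap", "H_A", "H_B"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise StructureError(f"column {name} has length {len(arr)}, expected {n}")
            if not np.all(np.isfinite(arr)):
                raise StructureError(f"column {name} contains non-finite values")

    @property
    def n_frames(self) -> int:
        return len(self.H)

    @property
    def dV_BA(self) -> np.ndarray:
        """Instantaneous end-state energy difference H_B - H_A."""
        return self.H_B - self.H_A

    @property
    def coordinate(self) -> float:
        """The series' position on its own perturbation axis."""
        return self.state.lam if self.axis == "lam" else self.state.kap

    @property
    def axis_derivative(self) -> np.ndarray:
        """dH/dc along the perturbation axis (dHdlam or dHdkap)."""
        return self.dHdlam if self.axis == "lam" else self.dHdkap

    def neighbor_energy(self, state: CouplingState) -> np.ndarray:
        if state == self.state:
            return self.H
        try:
            return self.neighbors[state]
        except KeyError:
            raise StructureError(
                f"series at {self.state} carries no cross-energies at {state}; "
                "re-run the sampler with this state among its neighbors"
            ) from None


def _tune_step(step: float, accepted: int, window: int) -> float:
    frac = accepted / window
    if frac < 0.3:
        return step * 0.8
    if frac > 0.5:
        return step * 1.25
    return step


def metropolis_sample(
    system,
    state: CouplingState,
    cfg: SamplerConfig,
    ctx: ThermoContext = ThermoContext(),
    neighbor_states: Sequence[CouplingState] = (),
    probe_lams: Sequence[float] | None = None,
    axis: str = "lam",
    initial: Sequence[float] | None = None,
) -> ObservableSeries:
    """Sample one coupling state and record all downstream observables.

    ``axis`` names the perturbation axis of this series; the end-state
    energies H_A / H_B are evaluated with that axis set to 0 / 1 while the
    other coupling component is held at the sampled state's value.
    ``probe_lams`` requests the on-the-fly records (dH/dlam and H at each
    probe) that extended TI reweights during analysis.
    """
    system = as_system(system)
    kBT = ctx.kBT
    rng = np.random.default_rng(cfg.seed)
    dim = system.dim

    if axis == "lam":
        end_a = CouplingState(0.0, state.kap)
        end_b = CouplingState(1.0, state.kap)
    elif axis == "kap":
        end_a = CouplingState(state.lam, 0.0)
        end_b = CouplingState(state.lam, 1.0)
    else:
        raise DomainError(f"axis must be 'lam' or 'kap', got {axis!r}")
    if probe_lams is None or len(probe_lams) == 0:
        probe_states = []
    elif axis == "lam":
        probe_states = [CouplingState(float(p), state.kap) for p in probe_lams]
    else:
        probe_states = [CouplingState(state.lam, float(p)) for p in probe_lams]

    if initial is not None:
        x = np.asarray(initial, dtype=float).copy()
    elif hasattr(system, "minimum"):
        x = np.atleast_1d(system.minimum(state)).astype(float)
    else:
        x = np.full(dim, 0.1)
    e_cur = system.evaluate(x, state).energy

    burn_in = cfg.resolved_burn_in
    n_rec = (cfg.n_steps - burn_in + cfg.record_stride - 1) // cfg.record_stride
    H = np.empty(n_rec)
    dHl = np.empty(n_rec)
    dHk = np.empty(n_rec)
    HA = np.empty(n_rec)
    HB = np.empty(n_rec)
    nb = {s: np.empty(n_rec) for s in neighbor_states if s != state}
    n_pr = len(probe_states)
    pr_d = np.empty((n_rec, n_pr)) if n_pr else None
    pr_h = np.empty((n_rec, n_pr)) if n_pr else None
    probe_eval = None
    if n_pr and hasattr(system, "make_probe_evaluator"):
        probe_eval = system.make_probe_evaluator(probe_states, axis=axis)

    step = cfg.step_size
    tune_window = 200
    accepted_window = 0
    accepted_burn = 0
    rec = 0
    batch = 4096
    n_total = cfg.n_steps
    pos = 0
    while pos < n_total:
        m = min(batch, n_total - pos)
        moves = rng.uniform(-1.0, 1.0, size=(m, dim))
        us = rng.random(m)
        for t in range(m):
            i = pos + t
            prop = x + step * moves[t]
            e_new = system.evaluate(prop, state).energy
            de = e_new - e_cur
            if de <= 0.0 or ((de / kBT) < 700 and us[t] < math.exp(-de / kBT)):
                x = prop
                e_cur = e_new
                accepted_window += 1
                if i < burn_in:
                    accepted_burn += 1
            if i < burn_in:
                if (i + 1) % tune_window == 0:
                    step = _tune_step(step, accepted_window, tune_window)
                    accepted_window = 0
                if i + 1 == burn_in and accepted_burn == 0:
                    raise SamplingError(
                        "no move accepted during burn-in; adjust step_size "
                        f"(currently {cfg.step_size} nm) or check the Hamiltonian"
                    )
            elif (i - burn_in) % cfg.record_stride == 0:
                e = system.evaluate(x, state)
                H[rec] = e.energy
                dHl[rec] = e.dlam
                dHk[rec] = e.dkap
                HA[rec] = system.evaluate(x, end_a).energy
                HB[rec] = system.evaluate(x, end_b).energy
                for s, arr in nb.items():
                    arr[rec] = system.evaluate(x, s).energy
                if probe_eval is not None:
                    pr_h[rec], pr_d[rec] = probe_eval(x)
                elif n_pr:
                    for p, ps in enumerate(probe_states):
                        ep = system.evaluate(x, ps)
                        pr_d[rec, p] = ep.dlam if axis == "lam" else ep.dkap
                        pr_h[rec, p] = ep.energy
                rec += 1
        pos += m

    return ObservableSeries(
        state=state,
        temperature=ctx.temperature,
        seed=cfg.seed,
        system_id=getattr(getattr(system, "spec", None), "name", type(system).__name__),
        H=H[:rec],
        dHdlam=dHl[:rec],
        dHdkap=dHk[:rec],
        H_A=HA[:rec],
        H_B=HB[:rec],
        neighbors={s: a[:rec] for s, a in nb.items()},
        probe_lams=np.asarray(probe_lams, dtype=float) if probe_states else None,
        probe_dHdlam=pr_d[:rec] if pr_d is not None else None,
        probe_H=pr_h[:rec] if pr_h is not None else None,
        axis=axis,
    )


# ---------------------------------------------------------------------------
# EDS reference-state sampling
# ---------------------------------------------------------------------------

# EDSParams lives in estimators (it parameterizes the reference energy);
# re-exported here because the sampler is its main consumer.  The envelope
# evaluated in the sampling loop is algebraically identical to
# estimators.eds_reference_energy (asserted by the test suite); it is
# inlined there to also yield the per-state weights needed for derivatives.
from .estimators import EDSParams  # noqa: E402


def sample_eds_reference(
    end_states: Sequence,
    params: EDSParams,
    cfg: SamplerConfig,
    ctx: ThermoContext = ThermoContext(),
    state: CouplingState = CouplingState(0.0, 0.0),
    params_grad: tuple[Sequence[float], float] | None = None,
    initial: Sequence[float] | None = None,
) -> ObservableSeries:
    """Propagate on the smoothed Boltzmann-envelope reference Hamiltonian.

    ``end_states`` are >= 2 plain Hamiltonians exposing ``energy_and_deriv``
    (for EDS proper these are frozen corner states with zero derivative;
    for the EDS-TI reference they are the fixed-kap end states at the
    current lam, each carrying its own dH/dlam).  Every frame records the
    reference energy H (the envelope), the end-state energies H_A / H_B,
    the per-end-state lam-derivatives, and the total lam-derivative of the
    reference including, when ``params_grad`` = (dE_i/dlam, ds/dlam) is
    given, the contribution of lam-interpolated envelope parameters.
    """
    if len(end_states) < 2:
        raise StructureError("EDS needs at least two end states")
    if params.s <= 0:
        raise DomainError("smoothness parameter s must be > 0")
    kBT = ctx.kBT
    ns = len(end_states)
    offsets = params.offset_vector(ns)
    dE_dlam = np.zeros(ns)
    ds_dlam = 0.0
    if params_grad is not None:
        dE_dlam = np.asarray(params_grad[0], dtype=float)
        ds_dlam = float(params_grad[1])

    dim = end_states[0].dim
    rng = np.random.default_rng(cfg.seed)
    s = params.s

    def envelope(conf):
        evals = [es.energy_and_deriv(conf) for es in end_states]
        h = np.array([e[0] for e in evals])
        dh = np.array([e[1] for e in evals])
        a = h - offsets
        z = -s * a / kBT
        zmax = z.max()
        w = np.exp(z - zmax)
        wsum = w.sum()
        h_ref = -(kBT / s) * (zmax + math.log(wsum))
        p = w / wsum
        # d/dlam of -(kBT/s) ln sum exp(-s (H_i - E_i)/kBT):
        #   sum_i p_i (dH_i - dE_i)  +  ds/dlam * (sum_i p_i a_i - H_ref)/s
        d_ref = float(p @ (dh - dE_dlam))
        if ds_dlam != 0.0:
            d_ref += ds_dlam * (float(p @ a) - h_ref) / s
        return h_ref, d_ref, h, dh

    if initial is not None:
        x = np.asarray(initial, dtype=float).copy()
    else:
        x = np.full(dim, 0.05)
    e_cur = envelope(x)[0]

    burn_in = cfg.resolved_burn_in
    n_rec = (cfg.n_steps - burn_in + cfg.record_stride - 1) // cfg.record_stride
    H = np.empty(n_rec)
    dHl = np.empty(n_rec)
    HA = np.empty(n_rec)
    HB = np.empty(n_rec)
    end_d = np.empty((n_rec, ns))
    end_h = np.empty((n_rec, ns))
    xs = np.empty((n_rec, dim))

    step = cfg.step_size
    tune_window = 200
    accepted_window = 0
    accepted_burn = 0
    rec = 0
    batch = 4096
    pos = 0
    while pos < cfg.n_steps:
        m = min(batch, cfg.n_steps - pos)
        moves = rng.uniform(-1.0, 1.0, size=(m, dim))
        us = rng.random(m)
        for t in range(m):
            i = pos + t
            prop = x + step * moves[t]
            e_new = envelope(prop)[0]
            de = e_new - e_cur
            if de <= 0.0 or ((de / kBT) < 700 and us[t] < math.exp(-de / kBT)):
                x = prop
                e_cur = e_new
                accepted_window += 1
                if i < burn_in:
                    accepted_burn += 1
            if i < burn_in:
                if (i + 1) % tune_window == 0:
                    step = _tune_step(step, accepted_window, tune_window)
                    accepted_window = 0
                if i + 1 == burn_in and accepted_burn == 0:
                    raise SamplingError("no move accepted during EDS burn-in; adjust step_size")
            elif (i - burn_in) % cfg.record_stride == 0:
                h_ref, d_ref, h, dh = envelope(x)
                H[rec] = h_ref
                dHl[rec] = d_ref
                HA[rec] = h[0]
                HB[rec] = h[1]
                end_h[rec] = h
                end_d[rec] = dh
                xs[rec] = x
                rec += 1
        pos += m

    extra = {"positions": xs[:rec]}
    for idx, label in zip(range(ns), "AB"):
        extra[f"dHdlam_{label}"] = end_d[:rec, idx]
    if ns > 2:
        for idx in range(2, ns):
            extra[f"H_end_{idx}"] = end_h[:rec, idx]
    return ObservableSeries(
        state=state,
        temperature=ctx.temperature,
        seed=cfg.seed,
        system_id="eds_reference",
        H=H[:rec],
        dHdlam=dHl[:rec],
        dHdkap=np.zeros(rec),
        H_A=HA[:rec],
        H_B=HB[:rec],
        extra=extra,
    )
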