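"""Automated iterative search for the EDS parameters (E, s).

The enveloping-distribution reference state samples both end states evenly
only if the energy offset E levels them and the smoothness s lowers the
barrier between them.  The two are coupled, so they are tuned in an
alternating scheme of short simulation rounds: an initial manual offset
estimate from a short unbiased run, an offset phase that balances the
sampling ratio, a smoothness phase that drives the transition count up,
and a refinement phase of small alternating adjustments.  Convergence is
assessed mainly on the s series (relative drift over a trailing window).

On end-state pairs whose dominant configurations clash sterically, the
scheme displays a characteristic failure mode: the offset chases a huge
instantaneous energy gap, transitions stay rare, and s collapses until the
reference state no longer samples the relevant phase space.  The search
reports - never hides - this outcome.

All adjustment percentages, thresholds and phase-advance rules are this
package's own, exposed on :class:`SearchSettings`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .diagnostics import sampling_ratio_and_transitions
from .estimators import EDSParams
from .model_systems import DomainError, ThermoContext
from .sampling import ObservableSeries, SamplerConfig, sample_eds_reference

__all__ = [
    "SearchSettings",
    "SearchState",
    "initial_offset_estimate",
    "update_parameters",
    "run_search",
]

PHASES = ("offset_phase", "smoothness_phase", "refine_phase")


@dataclass(frozen=True)
class SearchSettings:
    """Tunables of the alternating (E, s) update scheme."""

    offset_gain: float = 1.0  # kBT per unit of 2*(ratio_A - 1/2), offset phase
    offset_rel_step: float = 0.10  # relative step when |E| dominates the scale
    smoothness_lower: float = 0.9  # s multiplier when transitions are scarce
    smoothness_raise: float = 1.05  # s multiplier when abundant and balanced
    transition_threshold: int = 10  # per round
    refine_scale: float = 0.02  # relative size of refine-phase adjustments
    balanced_window: float = 0.15  # |ratio - 1/2| defining "balanced"
    stable_rounds: int = 10  # consecutive rounds before a phase advances
    s_floor: float = 1e-4  # below this the search flags failure
    drift_window: int = 50  # trailing rounds for the s-plateau assessment
    drift_tolerance: float = 0.05  # relative s drift counted as a plateau


@dataclass
class SearchState:
    """Full history of one parameter search."""

    round_index: int = 0
    phase: str = "offset_phase"
    params_history: list[EDSParams] = field(default_factory=list)
    ratio_history: list[float] = field(default_factory=list)
    transitions_history: list[int] = field(default_factory=list)
    phase_stable_rounds: int = 0
    no_transition_rounds: int = 0
    refine_parity: int = 0
    failure: str | None = None

    def __post_init__(self) -> None:
        if not (
            len(self.params_history) >= len(self.ratio_history) == len(self.transitions_history)
        ):
            raise DomainError("search histories are inconsistent in length")

    @property
    def current_params(self) -> EDSParams:
        return self.params_history[-1]

    def s_plateaued(self, settings: SearchSettings) -> bool:
        """Relative drift of s over the trailing window below tolerance."""
        tail = [p.s for p in self.params_history[-settings.drift_window :]]
        if len(tail) < settings.drift_window:
            return False
        lo, hi = min(tail), max(tail)
        return (hi - lo) / hi <= settings.drift_tolerance

    def converged(self, settings: SearchSettings) -> bool:
        """Plateaued s and nonzero recent transitions in both directions."""
        if self.failure is not None or not self.s_plateaued(settings):
            return False
        tail = self.transitions_history[-settings.drift_window :]
        return len(tail) > 0 and sum(tail) > 0


def initial_offset_estimate(series: ObservableSeries) -> float:
    """Manual first estimate of E from a short unbiased state-A run.

    E = <dV_BA> over the series levels the two end states approximately;
    the offset is applied to the second (higher) state, so a B state lying
    above A by some gap yields a positive E of that size.
    """
    dv = series.dV_BA
    if len(dv) == 0:
        raise DomainError("cannot estimate an offset from an empty series")
    return float(np.mean(dv))


def update_parameters(
    state: SearchState,
    last_round: dict,
    ctx: ThermoContext = ThermoContext(),
    settings: SearchSettings = SearchSettings(),
) -> EDSParams:
    """One step of the alternating update scheme.

    The offset moves toward the undersampled state (a sampling ratio of 1
    toward A strictly raises the offset applied to B); the smoothness drops
    multiplicatively while transitions are scarce and relaxes upward once
    they are abundant and the ratio is balanced.  The refine phase repeats
    both rules at a small scale, alternating between them.  Phases advance
    after their criterion holds for ``stable_rounds`` consecutive rounds.
    """
    ratio = float(last_round["ratio"])
    transitions = int(last_round["transitions"])
    if not 0.0 <= ratio <= 1.0:
        raise DomainError(f"sampling ratio must lie in [0, 1], got {ratio}")
    params = state.current_params
    kBT = ctx.kBT
    imbalance = 2.0 * (ratio - 0.5)  # >0: A oversampled, raise E on B
    E, s = params.E, params.s

    def offset_step(scale: float) -> float:
        mag = max(settings.offset_gain * kBT, settings.offset_rel_step * abs(E))
        return scale * mag * imbalance

    balanced = abs(ratio - 0.5) <= settings.balanced_window
    abundant = transitions >= settings.transition_threshold

    if state.phase == "offset_phase":
        E += offset_step(1.0)
        criterion = balanced
    elif state.phase == "smoothness_phase":
        if not abundant:
            s *= settings.smoothness_lower
        elif balanced:
            s *= settings.smoothness_raise
        E += offset_step(0.25)
        criterion = abundant
    else:  # refine_phase
        # Alternating small corrections; balanced sampling with abundant
        # transitions is an exact fixed point of this phase.
        if state.refine_parity == 0:
            E += offset_step(settings.refine_scale)
        elif not abundant:
            s *= 1.0 - settings.refine_scale
        state.refine_parity ^= 1
        criterion = balanced and abundant

    state.no_transition_rounds = 0 if abundant else state.no_transition_rounds + 1
    if criterion:
        state.phase_stable_rounds += 1
    else:
        state.phase_stable_rounds = 0
    if state.phase != "refine_phase" and state.phase_stable_rounds >= settings.stable_rounds:
        state.phase = PHASES[PHASES.index(state.phase) + 1]
        state.phase_stable_rounds = 0
    elif (
        state.phase == "offset_phase"
        and state.no_transition_rounds >= settings.stable_rounds
    ):
        # Balance is unreachable without transitions; hand over to the
        # smoothness phase so the barrier gets lowered.
        state.phase = "smoothness_phase"
        state.phase_stable_rounds = 0

    if s < settings.s_floor:
        s = settings.s_floor
        state.failure = (
            "smoothness parameter collapsed below "
            f"{settings.s_floor:g}: the reference state no longer samples "
            "the relevant phase space of both end states (steric-clash "
            "failure mode)"
        )
    return EDSParams.two_state(s, E)


def run_search(
    end_states: Sequence,
    init: EDSParams = EDSParams.two_state(0.002, 0.0),
    n_rounds: int = 200,
    steps_per_round: int = 2000,
    seed: int = 0,
    ctx: ThermoContext = ThermoContext(),
    settings: SearchSettings = SearchSettings(),
    sampler: SamplerConfig | None = None,
) -> SearchState:
    """Alternate short reference-state rounds with parameter updates.

    Each round continues the trajectory from the previous round's final
    configuration (one long, parameter-annealed trajectory, as in the
    automated scheme the search mirrors); the returned state carries the
    complete (E, s), ratio and transition histories for convergence plots.
    """
    state = SearchState(params_history=[init])
    if n_rounds == 0:
        return state
    root = np.random.SeedSequence(seed)
    round_seeds = root.generate_state(n_rounds) % (2 ** 31)
    x = None
    base = sampler or SamplerConfig(n_steps=steps_per_round, step_size=0.05, burn_in=0)
    for r in range(n_rounds):
        cfg = replace(base, seed=int(round_seeds[r]))
        series = sample_eds_reference(
            end_states, state.current_params, cfg, ctx, initial=x
        )
        x = series.extra["positions"][-1]
        stats = sampling_ratio_and_transitions(series, offset=state.current_params.E)
        state.round_index = r + 1
        state.ratio_history.append(stats["ratio_A"])
        state.transitions_history.append(stats["transitions"])
        new_params = update_parameters(
            state, {"ratio": stats["ratio_A"], "transitions": stats["transitions"]}, ctx, settings
        )
        state.params_history.append(new_params)
    return state
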