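"""Error estimation, cycle-closure metrics, EDS sampling diagnostics, and
convergence / prolongation algorithms.

Free energy is a state function, so the signed sum of estimates around any
closed cycle of states must vanish; the per-network summaries are Sigma
(the sum of absolute cycle closures) and Omega (the average absolute
closure per constituent perturbation).  The prolongation algorithms decide
which coupling-parameter windows deserve more sampling, either
retrospectively against a reference value (accuracy then precision
criteria, each budgeted as half kBT split evenly over the contributions) or
predictively by greedily extending the window with the largest effective
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Mapping, Sequence

import numpy as np

from .model_systems import DomainError, StructureError, ThermoContext

if TYPE_CHECKING:  # pragma: no cover
    from .estimators import FreeEnergyEstimate
    from .sampling import ObservableSeries

__all__ = [
    "DiagnosticsError",
    "MissingEdgeError",
    "CycleNetwork",
    "CycleClosure",
    "CycleReport",
    "ProlongationAction",
    "ProlongationPlan",
    "ContributionTrack",
    "EndStateDistributions",
    "block_average_error",
    "bootstrap_error",
    "closure_summary",
    "cycle_closure_report",
    "hysteresis",
    "sampling_ratio_and_transitions",
    "end_state_distributions",
    "prolongation_retrospective",
    "prolongation_predictive",
]


class DiagnosticsError(ValueError):
    pass


class MissingEdgeError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Error estimators
# ---------------------------------------------------------------------------


def block_average_error(series, min_frames: int = 16) -> float:
    """One-sigma error of the mean by the blocking transformation.

    Successive pairwise averaging; the reported error is the maximum
    blocked standard error over all levels that retain at least eight
    blocks, a deterministic proxy for the blocking plateau.
    """
    x = np.asarray(series, float)
    if x.ndim != 1 or len(x) < min_frames:
        raise DiagnosticsError(
            f"block averaging needs a 1-D series of >= {min_frames} frames, got {x.shape}"
        )
    best = 0.0
    while len(x) >= 8:
        n = len(x)
        se = float(np.std(x, ddof=1) / math.sqrt(n))
        best = max(best, se)
        if n % 2:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])
    return best


def bootstrap_error(
    series,
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 100,
    seed: int = 0,
) -> float:
    """One-sigma error of ``statistic`` over seeded bootstrap resamples."""
    x = np.asarray(series, float)
    if len(x) < 2:
        raise DiagnosticsError("bootstrap needs at least two frames")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        vals[b] = statistic(x[rng.integers(0, len(x), size=len(x))])
    return float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# Thermodynamic-cycle closure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleNetwork:
    """Directed free-energy estimates on a network of states, plus the
    cycles (node sequences, implicitly closed) to audit."""

    edges: Mapping[tuple[str, str], tuple[float, float]]  # (dG, 1-sigma err)
    cycles: Sequence[Sequence[str]]

    def edge(self, a: str, b: str) -> tuple[float, float]:
        if (a, b) in self.edges:
            dg, err = self.edges[(a, b)]
            return dg, err
        if (b, a) in self.edges:
            dg, err = self.edges[(b, a)]
            return -dg, err
        raise MissingEdgeError(f"no free-energy estimate for the edge {a} <-> {b}")


@dataclass(frozen=True)
class CycleClosure:
    cycle: tuple[str, ...]
    closure: float
    error: float

    @property
    def n_legs(self) -> int:
        return len(self.cycle)


@dataclass(frozen=True)
class CycleReport:
    closures: tuple[CycleClosure, ...]
    Sigma: float
    Sigma_error: float
    Omega: float
    Omega_error: float


def cycle_closure_report(net: CycleNetwork) -> CycleReport:
    """Signed closures of every cycle plus the Sigma and Omega summaries.

    A cycle is traversed in its listed node order; edges used against their
    stored direction contribute with flipped sign.  Sigma is the sum of
    absolute closures; Omega = (1/N_cycles) sum |closure| / N_legs.  Errors
    propagate in quadrature.
    """
    closures = []
    for cyc in net.cycles:
        nodes = list(cyc)
        if len(nodes) < 3:
            raise StructureError(f"cycle {nodes} has fewer than three states")
        total, var = 0.0, 0.0
        for a, b in zip(nodes, nodes[1:] + nodes[:1]):
            dg, err = net.edge(a, b)
            total += dg
            var += err ** 2
        closures.append(CycleClosure(tuple(nodes), total, math.sqrt(var)))
    n_c = len(closures)
    sigma = sum(abs(c.closure) for c in closures)
    sigma_err = math.sqrt(sum(c.error ** 2 for c in closures))
    omega = sum(abs(c.closure) / c.n_legs for c in closures) / n_c if n_c else 0.0
    omega_err = (
        math.sqrt(sum((c.error / c.n_legs) ** 2 for c in closures)) / n_c if n_c else 0.0
    )
    return CycleReport(tuple(closures), sigma, sigma_err, omega, omega_err)


def closure_summary(closures: Sequence[float], n_legs: Sequence[int]) -> tuple[float, float]:
    """Sigma and Omega from per-cycle closures and their leg counts.

    Sigma = sum |closure|; Omega = (1/N_cycles) sum |closure| / N_legs.
    """
    if len(closures) != len(n_legs) or not closures:
        raise StructureError("need one leg count per closure")
    sigma = float(np.sum(np.abs(closures)))
    omega = float(np.mean(np.abs(closures) / np.asarray(n_legs, float)))
    return sigma, omega


def hysteresis(forward: "FreeEnergyEstimate | float", backward: "FreeEnergyEstimate | float") -> float:
    """Signed closure of the minimal two-leg cycle: forward + backward.

    ``backward`` must be computed on the reversed perturbation, so an
    ideally converged pair sums to zero; the magnitude is the hysteresis.
    """
    f = getattr(forward, "value", forward)
    b = getattr(backward, "value", backward)
    return float(f) + float(b)


# ---------------------------------------------------------------------------
# EDS sampling diagnostics
# ---------------------------------------------------------------------------


def sampling_ratio_and_transitions(series, offset: float = 0.0) -> dict:
    """State occupation and transition count from the sign of dV_BA.

    A frame belongs to state A when dV_BA > 0 and to B when < 0; exact ties
    keep the previous frame's assignment (the first frame defaults to A).
    ``offset`` subtracts the current energy offset E from dV_BA before the
    sign test, so the assignment matches the envelope's own bookkeeping
    (which state dominates H_ref); with offset 0 the raw-sign rule applies.
    """
    dv = series.dV_BA if hasattr(series, "dV_BA") else np.asarray(series, float)
    if len(dv) == 0:
        raise DiagnosticsError("empty series")
    sign = np.sign(dv - offset).astype(int)
    cur = 1  # ties at the very start count as A
    n_a = 0
    transitions = 0
    prev = 0
    for s in sign:
        if s != 0:
            if prev != 0 and s != prev:
                transitions += 1
            cur, prev = s, s
        if cur > 0:
            n_a += 1
    return {"ratio_A": n_a / len(dv), "transitions": transitions}


@dataclass(frozen=True)
class EndStateDistributions:
    bin_edges: np.ndarray
    reference: np.ndarray
    end_states: dict  # label -> normalized weighted histogram
    effective_samples: dict  # label -> effective sample size


def end_state_distributions(
    series: "ObservableSeries",
    bin_width: float,
    ctx: ThermoContext = ThermoContext(),
) -> EndStateDistributions:
    """Reference-state energy histogram next to the reweighted end states.

    End-state histograms are weighted by exp(-(H_i - H_ref)/kBT) and
    normalized; their effective sample sizes quantify how much of the
    reference trajectory actually supports each end state.
    """
    kBT = ctx.kBT
    lo = min(series.H.min(), series.H_A.min(), series.H_B.min())
    hi = max(series.H.max(), series.H_A.max(), series.H_B.max())
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    ref, _ = np.histogram(series.H, bins=edges, density=True)
    hists, ess = {}, {}
    for label, h_end in (("A", series.H_A), ("B", series.H_B)):
        log_w = -(h_end - series.H) / kBT
        w = np.exp(log_w - log_w.max())
        ess[label] = float(w.sum() ** 2 / (w * w).sum())
        hist, _ = np.histogram(h_end, bins=edges, weights=w, density=True)
        hists[label] = hist
    return EndStateDistributions(edges, ref, hists, ess)


# ---------------------------------------------------------------------------
# Convergence and prolongation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContributionTrack:
    """Cumulative per-contribution estimates indexed by prolongation steps.

    ``values[t]`` / ``errors[t]`` are the contribution's estimate and
    1-sigma error after t+1 time increments (the maximum index is the full
    available trajectory).
    """

    values: np.ndarray
    errors: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.errors) or len(self.values) == 0:
            raise StructureError("track values/errors must be equal-length and nonempty")


@dataclass(frozen=True)
class ProlongationAction:
    target: tuple[float, ...]  # the lam point (or interval) prolonged
    reason: str  # accuracy | precision | largest_effective_error
    violation: float


@dataclass(frozen=True)
class ProlongationPlan:
    actions: tuple[ProlongationAction, ...]
    converged: bool
    total_frames: int


def _weights_for(lam_grid: np.ndarray, mode: str) -> np.ndarray:
    if mode == "BAR":
        return np.ones(len(lam_grid) - 1)
    w = np.empty(len(lam_grid))
    w[0] = 0.5 * (lam_grid[1] - lam_grid[0])
    w[-1] = 0.5 * (lam_grid[-1] - lam_grid[-2])
    if len(lam_grid) > 2:
        w[1:-1] = 0.5 * (lam_grid[2:] - lam_grid[:-2])
    return w


def prolongation_retrospective(
    lam_grid: Sequence[float],
    tracks: Sequence[ContributionTrack],
    reference_final: Sequence[float],
    ctx: ThermoContext = ThermoContext(),
    mode: str = "TI",
    frames_per_increment: int = 1,
) -> ProlongationPlan:
    """Minimal-length convergence loop against a reference value.

    The allowed total deviation and total error (half kBT each) are split
    evenly over the N contributions - one per lam point for TI/X-TI, one
    per interval for BAR.  Starting from the minimal length, the single
    largest accuracy violator (both flanking points for a BAR interval) is
    prolonged by one increment until none remain, then the precision
    criterion is processed the same way.  Ties resolve toward the lowest
    lam.  The plan lists every action and the total frames consumed.
    """
    if mode not in ("TI", "BAR"):
        raise DomainError("mode must be 'TI' or 'BAR'")
    lam = np.asarray(lam_grid, float)
    n_pts = len(lam)
    n_contrib = n_pts - 1 if mode == "BAR" else n_pts
    if len(tracks) != n_contrib or len(reference_final) != n_contrib:
        raise StructureError(
            f"{mode} over {n_pts} lam points needs {n_contrib} tracks and "
            f"references; got {len(tracks)} and {len(reference_final)}"
        )
    t_max = {len(tr.values) for tr in tracks}
    if len(t_max) != 1:
        raise StructureError("all tracks must share the same number of time increments")
    t_max = t_max.pop()
    w = _weights_for(lam, mode)
    allowed = 0.5 * ctx.kBT / n_contrib
    ref = np.asarray(reference_final, float)

    times = np.zeros(n_pts, dtype=int)  # per lam-POINT increments beyond the first

    def contrib_time(j: int) -> int:
        if mode == "BAR":
            return min(times[j], times[j + 1])
        return times[j]

    def target_of(j: int) -> tuple[float, ...]:
        return (lam[j], lam[j + 1]) if mode == "BAR" else (lam[j],)

    def prolong(j: int) -> bool:
        pts = (j, j + 1) if mode == "BAR" else (j,)
        grew = False
        for p in pts:
            if times[p] < t_max - 1:
                times[p] += 1
                grew = True
        return grew

    actions: list[ProlongationAction] = []
    converged = True
    for reason, measure in (
        ("accuracy", lambda j: abs(tracks[j].values[contrib_time(j)] - ref[j]) * w[j]),
        ("precision", lambda j: tracks[j].errors[contrib_time(j)] * w[j]),
    ):
        stuck: set[int] = set()
        while True:
            viols = [(measure(j) - allowed, j) for j in range(n_contrib) if j not in stuck]
            viols = [(v, j) for v, j in viols if v > 0]
            if not viols:
                break
            v, j = max(viols, key=lambda t: (t[0], -t[1]))
            if not prolong(j):
                stuck.add(j)  # at the maximum available length; cannot improve
                converged = False
                continue
            actions.append(ProlongationAction(target_of(j), reason, v))
    total = int(np.sum(times + 1)) * frames_per_increment
    return ProlongationPlan(tuple(actions), converged, total)


def prolongation_predictive(
    lam_grid: Sequence[float],
    point_errors: Sequence[float],
    total_budget: int,
    mode: str = "TI",
) -> ProlongationPlan:
    """Greedy fixed-budget allocation toward the largest effective error.

    Each contribution's effective error is sigma_j * w_j with w_j the
    half-interval weight (unity for BAR intervals); one increment at a time
    goes to the current maximum (the pair of flanking points for BAR, which
    costs two increments), with errors decaying as 1/sqrt(n) in the number
    of increments already assigned.  Ties resolve toward the lowest lam.
    """
    if mode not in ("TI", "BAR"):
        raise DomainError("mode must be 'TI' or 'BAR'")
    lam = np.asarray(lam_grid, float)
    sig = np.asarray(point_errors, float)
    w = _weights_for(lam, mode)
    if len(sig) != len(w):
        raise StructureError(
            f"{mode} over {len(lam)} lam points needs {len(w)} error entries, got {len(sig)}"
        )
    if total_budget == 0:
        return ProlongationPlan((), True, 0)
    cost = 2 if mode == "BAR" else 1
    if total_budget < cost:
        raise DomainError(
            f"budget {total_budget} is smaller than one {mode} increment (cost {cost})"
        )
    n = np.ones(len(sig))
    spent = 0
    actions: list[ProlongationAction] = []
    while spent + cost <= total_budget:
        eff = sig * w / np.sqrt(n)
        j = int(np.argmax(eff))  # argmax takes the first (lowest-lam) maximum
        tgt = (lam[j], lam[j + 1]) if mode == "BAR" else (lam[j],)
        actions.append(ProlongationAction(tgt, "largest_effective_error", float(eff[j])))
        n[j] += 1
        spent += cost
    return ProlongationPlan(tuple(actions), True, spent)
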