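"""Free-energy estimators: BAR, TI, X-TI, EDS, EDS-TI and 2D-TI.

All six estimators consume :class:`~alchemkit.sampling.ObservableSeries`
records and return :class:`FreeEnergyEstimate` values in kJ mol^-1 with
one-sigma errors.  Exponential averages are evaluated with
max-subtraction throughout, and every reweighted quantity carries an
effective sample size (sum w)^2 / sum w^2.

Sign conventions: a pairwise estimate is Delta G = G_B - G_A for the
perturbation from the series' state A (its axis at 0) to state B (axis at
1), and every pairwise estimator negates exactly under an A/B swap of its
inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .model_systems import CouplingState, DomainError, StructureError, ThermoContext

if TYPE_CHECKING:  # pragma: no cover - type-only import keeps modules acyclic
    from .sampling import ObservableSeries

__all__ = [
    "FreeEnergyEstimate",
    "BarSolution",
    "TIProfile",
    "EDSParams",
    "Landscape2D",
    "OverlapError",
    "GridSpanError",
    "fermi_weight",
    "bar_pair",
    "bar_path",
    "ti_profile_from_series",
    "ti_integrate",
    "xti_profile",
    "eds_reference_energy",
    "eds_free_energy",
    "edsti_end_state_profile",
    "edsti_cycle_sum",
    "landscape_2d",
]


class OverlapError(RuntimeError):
    """The two ensembles share no usable energy overlap."""


class GridSpanError(ValueError):
    """A TI profile does not span the full coupling interval [0, 1]."""


@dataclass(frozen=True)
class FreeEnergyEstimate:
    value: float  # kJ mol^-1
    error: float  # kJ mol^-1, 1 sigma
    method: str  # BAR | TI | XTI | EDS | EDSTI | TI2D
    n_frames_used: int
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.error < 0:
            raise DomainError("error must be >= 0")

    def __neg__(self) -> "FreeEnergyEstimate":
        return replace(self, value=-self.value)


@dataclass(frozen=True)
class BarSolution:
    delta_G: float
    C: float
    iterations: int
    residual: float
    error: float = 0.0
    n_frames_used: int = 0


@dataclass(frozen=True)
class TIProfile:
    """A lam grid with mean dH/dlam, per-point 1-sigma errors and weights."""

    lam_grid: np.ndarray
    mean_derivative: np.ndarray
    point_error: np.ndarray
    warnings: tuple[str, ...] = ()
    #: Full-covariance 1-sigma error of the trapezoidal integral, when the
    #: producer can supply it (the dense reweighted profile predicts every
    #: point from the same frames, so point errors are strongly correlated
    #: and the independent-point propagation would be far too optimistic).
    integral_error: float | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.lam_grid, float)
        if g.ndim != 1 or len(g) < 2 or np.any(np.diff(g) <= 0):
            raise StructureError("lam_grid must be strictly ascending with >= 2 points")
        for name in ("mean_derivative", "point_error"):
            if len(getattr(self, name)) != len(g):
                raise StructureError(f"{name} length does not match lam_grid")

    @property
    def interval_weights(self) -> np.ndarray:
        """Half the distance to the flanking points (half-intervals at the ends).

        These weights make the weighted sum of the profile identical to its
        trapezoidal integral; they sum to the grid span.
        """
        g = np.asarray(self.lam_grid, float)
        w = np.empty_like(g)
        w[0] = 0.5 * (g[1] - g[0])
        w[-1] = 0.5 * (g[-1] - g[-2])
        if len(g) > 2:
            w[1:-1] = 0.5 * (g[2:] - g[:-2])
        return w


@dataclass(frozen=True)
class EDSParams:
    """Envelope parameters: smoothness s and per-state energy offsets.

    For two states only a single offset matters; the conventional form
    keeps the first state's offset at zero and applies ``E`` to the second.
    """

    s: float
    offsets: tuple[float, ...] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise DomainError("smoothness parameter s must be > 0")

    @property
    def E(self) -> float:
        """The single two-state offset (applied to the second state)."""
        return self.offsets[1] - self.offsets[0]

    @staticmethod
    def two_state(s: float, E: float) -> "EDSParams":
        return EDSParams(s=s, offsets=(0.0, E))

    def offset_vector(self, n_states: int) -> np.ndarray:
        if len(self.offsets) != n_states:
            raise StructureError(
                f"{len(self.offsets)} offsets for {n_states} end states"
            )
        return np.asarray(self.offsets, float)


@dataclass(frozen=True)
class Landscape2D:
    """Free-energy surface G(lam, kap) with G(0,0) = 0."""

    lam_grid: np.ndarray
    kap_grid: np.ndarray
    G: np.ndarray  # shape (n_lam, n_kap)
    corner_differences: dict[tuple[tuple[float, float], tuple[float, float]], float]
    corner_errors: dict[tuple[tuple[float, float], tuple[float, float]], float] | None = None


# ---------------------------------------------------------------------------
# Small numerics shared by the estimators
# ---------------------------------------------------------------------------


def fermi_weight(x, ctx: ThermoContext = ThermoContext()):
    """The Fermi function 1 / (1 + exp(x / kBT)), numerically stable."""
    return expit(-np.asarray(x, float) / ctx.kBT)


def _log_mean_exp(logs: np.ndarray) -> float:
    return float(logsumexp(logs) - math.log(len(logs)))


def _ess(log_w: np.ndarray) -> float:
    """Effective sample size of normalized exp(log_w) weights."""
    lw = log_w - np.max(log_w)
    w = np.exp(lw)
    return float(w.sum() ** 2 / (w * w).sum())


def _half_interval_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty(len(grid))
    w[0] = 0.5 * (grid[1] - grid[0])
    w[-1] = 0.5 * (grid[-1] - grid[-2])
    if len(grid) > 2:
        w[1:-1] = 0.5 * (grid[2:] - grid[:-2])
    return w


def _block_estimates(n: int, n_blocks: int):
    """Contiguous block slices covering n frames."""
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


# ---------------------------------------------------------------------------
# Bennett acceptance ratio
# ---------------------------------------------------------------------------


def _bar_works(series_lo: "ObservableSeries", series_hi: "ObservableSeries"):
    w_f = series_lo.neighbor_energy(series_hi.state) - series_lo.H
    w_r = series_hi.neighbor_energy(series_lo.state) - series_hi.H
    return np.asarray(w_f, float), np.asarray(w_r, float)


def _bar_solve(w_f: np.ndarray, w_r: np.ndarray, kBT: float, tol: float = 1e-12):
    """Solve the self-consistency condition for the shift C.

    The residual ln sum f(w_r + C) - ln sum f(w_f - C) is strictly
    decreasing in C, so a sign-changing bracket plus Brent's method finds
    the unique root; Delta G = C - kBT ln(n_r / n_f).
    """

    def log_sum_fermi(x):
        # ln sum 1/(1+exp(x/kBT)) = logsumexp(-log1p(exp(x/kBT)))
        return logsumexp(-np.logaddexp(0.0, x / kBT))

    def residual(c):
        return log_sum_fermi(w_r + c) - log_sum_fermi(w_f - c)

    # Exponential-averaging bounds for the initial bracket.
    guess = 0.5 * (float(np.mean(w_f)) - float(np.mean(w_r)))
    width = kBT + 0.5 * abs(float(np.mean(w_f)) + float(np.mean(w_r)))
    lo, hi = guess - width, guess + width
    for _ in range(200):
        if residual(lo) > 0 > residual(hi):
            break
        lo, hi = guess - 2 * (guess - lo), guess + 2 * (hi - guess)
        if hi - lo > 1e9:
            raise OverlapError(
                "no self-consistent shift found: the forward and reverse "
                "energy distributions do not overlap (one Fermi average "
                "underflows); add intermediate states or sample longer"
            )
    c, info = brentq(residual, lo, hi, xtol=tol, full_output=True)
    dg = c - kBT * math.log(len(w_r) / len(w_f))
    return dg, float(c), int(info.iterations), float(residual(c))


def bar_pair(
    series_lo: "ObservableSeries",
    series_hi: "ObservableSeries",
    ctx: ThermoContext = ThermoContext(),
    n_blocks: int = 10,
) -> BarSolution:
    """Acceptance-ratio free energy between two mutually cross-evaluated states.

    The shift C is iterated until the forward and reverse Fermi-weighted
    sums coincide (|residual| < 1e-10); with equal sample sizes Delta G = C,
    and unequal sizes use the standard ln(n_hi/n_lo) correction, which
    vanishes for equal-length runs.  The 1-sigma error comes from re-solving
    on contiguous block pairs.
    """
    kBT = ctx.kBT
    w_f, w_r = _bar_works(series_lo, series_hi)
    dg, c, iters, res = _bar_solve(w_f, w_r, kBT)

    blocks_f = _block_estimates(len(w_f), n_blocks)
    blocks_r = _block_estimates(len(w_r), n_blocks)
    vals = []
    for bf, br in zip(blocks_f, blocks_r):
        try:
            vals.append(_bar_solve(w_f[bf], w_r[br], kBT)[0])
        except OverlapError:
            continue
    if len(vals) >= 2:
        err = float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
    else:
        err = 0.0
    return BarSolution(
        delta_G=dg,
        C=c,
        iterations=iters,
        residual=res,
        error=err,
        n_frames_used=len(w_f) + len(w_r),
    )


def bar_path(
    series: Sequence["ObservableSeries"],
    ctx: ThermoContext = ThermoContext(),
    n_blocks: int = 10,
) -> FreeEnergyEstimate:
    """Sum of interval acceptance-ratio estimates along an ordered lam path."""
    if len(series) < 2:
        raise StructureError("a path needs at least two states")
    total = 0.0
    var = 0.0
    frames = 0
    for lo, hi in zip(series[:-1], series[1:]):
        sol = bar_pair(lo, hi, ctx, n_blocks=n_blocks)
        total += sol.delta_G
        var += sol.error ** 2
        frames += sol.n_frames_used
    return FreeEnergyEstimate(total, math.sqrt(var), "BAR", frames)


# ---------------------------------------------------------------------------
# Thermodynamic integration
# ---------------------------------------------------------------------------


def ti_profile_from_series(
    series: Sequence["ObservableSeries"],
    error_estimator=None,
) -> TIProfile:
    """Plain TI profile: the per-state mean dH/dlam with block-average errors."""
    from .diagnostics import block_average_error

    error_estimator = error_estimator or block_average_error
    ordered = sorted(series, key=lambda s: s.coordinate)
    grid = np.array([s.coordinate for s in ordered])
    means = np.array([float(np.mean(s.axis_derivative)) for s in ordered])
    errs = np.array([error_estimator(s.axis_derivative) for s in ordered])
    return TIProfile(grid, means, errs)


def ti_integrate(profile: TIProfile, method: str = "TI") -> FreeEnergyEstimate:
    """Trapezoidal integral of a TI profile over the full interval [0, 1].

    The 1-sigma error is sqrt(sum (sigma_i * w_i)^2) with w_i the
    half-interval weights, consistent with the effective-error weighting of
    the convergence criteria.
    """
    g = np.asarray(profile.lam_grid, float)
    if abs(g[0]) > 1e-12 or abs(g[-1] - 1.0) > 1e-12:
        raise GridSpanError(
            f"profile grid spans [{g[0]:g}, {g[-1]:g}] but integration "
            "requires the full coupling interval [0, 1]; refusing to "
            "extrapolate silently"
        )
    y = np.asarray(profile.mean_derivative, float)
    value = float(np.trapezoid(y, g))
    if profile.integral_error is not None:
        err = profile.integral_error
    else:
        w = profile.interval_weights
        err = float(np.sqrt(np.sum((np.asarray(profile.point_error, float) * w) ** 2)))
    return FreeEnergyEstimate(value, err, method, 0, warnings=profile.warnings)


# ---------------------------------------------------------------------------
# Extended thermodynamic integration
# ---------------------------------------------------------------------------


def xti_profile(
    series: Sequence["ObservableSeries"],
    probe_grid: Sequence[float] | None = None,
    ctx: ThermoContext = ThermoContext(),
    n_boot: int = 100,
    seed: int = 0,
    min_ess: float = 10.0,
) -> TIProfile:
    """Dense TI profile predicted by reweighting on-the-fly probe records.

    Each simulated state lam_S predicts the mean derivative at every probe
    lam_P via exp(-(H(lam_P) - H(lam_S)) / kBT) reweighting.  A probe that
    coincides exactly with a simulated state uses that state's direct
    average alone (the reweighting weights are all one there, so the plain
    TI value is reproduced bit-for-bit); elsewhere the per-source estimates
    are combined by inverse-variance weighting of their bootstrap errors.
    Sources whose effective sample size at a probe falls below ``min_ess``
    are dropped when another source covers the probe.
    """
    kBT = ctx.kBT
    ordered = sorted(series, key=lambda s: s.coordinate)
    for s in ordered:
        if s.probe_lams is None:
            raise StructureError(
                f"series at coordinate {s.coordinate:g} carries no probe "
                "records; extended TI needs the on-the-fly derivative and "
                "energy at every probe"
            )
    if probe_grid is None:
        probe_grid = ordered[0].probe_lams
    probes = np.asarray(probe_grid, float)
    n_p = len(probes)

    rng = np.random.default_rng(seed)
    n_src = len(ordered)
    est = np.full((n_src, n_p), np.nan)
    sig = np.full((n_src, n_p), np.nan)
    ess = np.zeros((n_src, n_p))
    own = np.zeros((n_src, n_p), dtype=bool)
    boots = np.full((n_src, n_boot, n_p), np.nan)

    for k, s in enumerate(ordered):
        idx = _match_probes(probes, s.probe_lams)
        d = s.probe_dHdlam[:, idx]
        log_w = -(s.probe_H[:, idx] - s.H[:, None]) / kBT
        log_w = log_w - log_w.max(axis=0, keepdims=True)
        w = np.exp(log_w)
        wsum = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            est[k] = (w * d).sum(axis=0) / wsum
            ess[k] = wsum ** 2 / (w * w).sum(axis=0)
        own[k] = np.abs(probes - s.coordinate) == 0.0
        # Bootstrap over frames (the same resamples for all probes keep the
        # probe-to-probe correlations of the prediction).
        n = s.n_frames
        for b in range(n_boot):
            take = rng.integers(0, n, size=n)
            wb = w[take]
            with np.errstate(invalid="ignore", divide="ignore"):
                boots[k, b] = (wb * d[take]).sum(axis=0) / wb.sum(axis=0)
        sig[k] = np.std(boots[k], axis=0, ddof=1)

    coords = np.array([s.coordinate for s in ordered])
    mean = np.empty(n_p)
    err = np.empty(n_p)
    replicates = np.zeros((n_boot, n_p))
    warns: list[str] = []
    for p in range(n_p):
        if own[:, p].any():
            # A probe that coincides with a simulated state is that
            # state's plain ensemble average, bit-for-bit.
            k = int(np.argmax(own[:, p]))
            mean[p] = float(np.mean(ordered[k].axis_derivative))
            replicates[:, p] = boots[k, :, p]
            err[p] = float(np.std(replicates[:, p], ddof=1))
            continue
        # Reweighting validity decays with distance in the coupling
        # variable (distant sources can look precise while representing
        # the wrong ensemble), so each probe is predicted from the
        # bracketing simulated states only.
        below = np.where(coords < probes[p])[0]
        above = np.where(coords > probes[p])[0]
        cand = [i for i in (below[-1] if len(below) else None,
                            above[0] if len(above) else None) if i is not None]
        cand = [i for i in cand if np.isfinite(est[i, p])]
        use = [i for i in cand if ess[i, p] >= min_ess]
        if not use:
            use = [max(cand, key=lambda i: ess[i, p])]
            warns.append(
                f"probe at {probes[p]:g}: all bracketing sources below "
                f"effective sample size {min_ess:g}; using the best one"
            )
        weights = 1.0 / np.maximum(sig[use, p], 1e-30) ** 2
        weights = weights / weights.sum()
        mean[p] = float(weights @ est[use, p])
        replicates[:, p] = (weights[None, :] * boots[use, :, p].T).sum(axis=1)
        err[p] = float(np.std(replicates[:, p], ddof=1))
        if len(use) > 1:
            # Inflate when the sources disagree beyond their stated errors.
            iv = 1.0 / np.maximum(sig[use, p], 1e-30) ** 2
            chi2 = float(np.sum(iv * (est[use, p] - mean[p]) ** 2)) / (len(use) - 1)
            if chi2 > 1.0:
                err[p] *= math.sqrt(chi2)
    # Integral error from the bootstrap replicates of the whole profile,
    # preserving probe-to-probe correlation (every source predicts all
    # probes from the same frames).
    integrals = np.trapezoid(replicates, probes, axis=1)
    int_err = float(np.std(integrals, ddof=1))
    return TIProfile(probes, mean, err, warnings=tuple(warns), integral_error=int_err)


def _match_probes(probes: np.ndarray, available: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(available, probes)
    idx = np.clip(idx, 0, len(available) - 1)
    left = np.clip(idx - 1, 0, len(available) - 1)
    idx = np.where(
        np.abs(available[left] - probes) < np.abs(available[idx] - probes), left, idx
    )
    if np.any(np.abs(available[idx] - probes) > 1e-12):
        missing = probes[np.abs(available[idx] - probes) > 1e-12]
        raise StructureError(f"probes {missing} were not recorded by the sampler")
    return idx


# ---------------------------------------------------------------------------
# Enveloping distribution sampling
# ---------------------------------------------------------------------------


def eds_reference_energy(H_i, params: EDSParams, ctx: ThermoContext = ThermoContext()):
    """Smoothed Boltzmann-envelope energy -(kBT/s) ln sum_i exp(-s(H_i-E_i)/kBT).

    ``H_i`` is an array of per-state energies; a trailing frame axis is
    broadcast (shape (n_states,) or (n_states, n_frames)).
    """
    h = np.asarray(H_i, float)
    off = params.offset_vector(h.shape[0]).reshape((h.shape[0],) + (1,) * (h.ndim - 1))
    kBT = ctx.kBT
    z = -params.s * (h - off) / kBT
    out = -(kBT / params.s) * logsumexp(z, axis=0)
    return float(out) if np.ndim(out) == 0 else out


def eds_free_energy(
    series: "ObservableSeries",
    ctx: ThermoContext = ThermoContext(),
    n_blocks: int = 16,
) -> FreeEnergyEstimate:
    """End-state free-energy difference from a reference-state trajectory.

    Delta G = -kBT ln [ <exp(-(H_B - H_ref)/kBT)> / <exp(-(H_A - H_ref)/kBT)> ]
    with the error from block averaging of the log-ratio.  An overlap
    warning is attached when either exponential average is carried by fewer
    than 10 effective frames.
    """
    kBT = ctx.kBT
    la = -(series.H_A - series.H) / kBT
    lb = -(series.H_B - series.H) / kBT
    value = -kBT * (_log_mean_exp(lb) - _log_mean_exp(la))
    warnings = []
    for name, logs in (("A", la), ("B", lb)):
        ess = _ess(logs)
        if ess < 10.0:
            warnings.append(
                f"end state {name} is carried by only {ess:.1f} effective "
                "frames; the reference state overlaps it poorly"
            )
    blocks = _block_estimates(series.n_frames, n_blocks)
    vals = [
        -kBT * (_log_mean_exp(lb[b]) - _log_mean_exp(la[b])) for b in blocks
    ]
    err = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) >= 2 else 0.0
    return FreeEnergyEstimate(value, err, "EDS", series.n_frames, tuple(warnings))


def eds_reference_to_state(
    series: "ObservableSeries",
    end_state: str,
    ctx: ThermoContext = ThermoContext(),
    n_blocks: int = 16,
) -> FreeEnergyEstimate:
    """One leg of the envelope cycle: Delta G from the reference to one end.

    G_end - G_ref = -kBT ln <exp(-(H_end - H_ref)/kBT)> over the reference
    ensemble; the difference of the two legs reproduces
    :func:`eds_free_energy` exactly.
    """
    if end_state not in ("A", "B"):
        raise DomainError("end_state must be 'A' or 'B'")
    kBT = ctx.kBT
    h_end = series.H_A if end_state == "A" else series.H_B
    logs = -(h_end - series.H) / kBT
    value = -kBT * _log_mean_exp(logs)
    warnings = ()
    ess = _ess(logs)
    if ess < 10.0:
        warnings = (
            f"end state {end_state} is carried by only {ess:.1f} effective frames",
        )
    blocks = _block_estimates(series.n_frames, n_blocks)
    vals = [-kBT * _log_mean_exp(logs[b]) for b in blocks]
    err = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) >= 2 else 0.0
    return FreeEnergyEstimate(value, err, "EDS", series.n_frames, warnings)


# ---------------------------------------------------------------------------
# EDS-TI
# ---------------------------------------------------------------------------


def edsti_end_state_profile(
    series: Sequence["ObservableSeries"],
    end_state: str,
    ctx: ThermoContext = ThermoContext(),
    n_blocks: int = 16,
    min_ess: float = 10.0,
) -> TIProfile:
    """End-state TI profile reweighted from the lam-propagated EDS reference.

    At each lam the end-state mean derivative is
    <dH/dlam e^{-(H_end - H_ref)/kBT}> / <e^{-(H_end - H_ref)/kBT}> over the
    reference ensemble; per-point errors come from block-wise reweighted
    estimates.  ``end_state`` selects "A" (first envelope member) or "B".
    """
    if end_state not in ("A", "B"):
        raise DomainError("end_state must be 'A' or 'B'")
    ordered = sorted(series, key=lambda s: s.state.lam)
    grid = np.array([s.state.lam for s in ordered])
    means = np.empty(len(ordered))
    errs = np.empty(len(ordered))
    warns: list[str] = []
    kBT = ctx.kBT
    for k, s in enumerate(ordered):
        h_end = s.H_A if end_state == "A" else s.H_B
        key = f"dHdlam_{end_state}"
        if key not in s.extra:
            raise StructureError(
                f"series at lam={s.state.lam:g} has no per-end-state "
                f"derivative column {key}; sample the EDS reference with "
                "derivative recording enabled"
            )
        d = s.extra[key]
        log_w = -(h_end - s.H) / kBT
        ess = _ess(log_w)
        if ess < min_ess:
            warns.append(
                f"lam={s.state.lam:g}: end state {end_state} carried by only "
                f"{ess:.1f} effective frames"
            )
        w = np.exp(log_w - log_w.max())
        means[k] = float(np.sum(w * d) / np.sum(w))
        blocks = _block_estimates(s.n_frames, n_blocks)
        vals = []
        for b in blocks:
            wb = np.exp(log_w[b] - log_w[b].max())
            vals.append(float(np.sum(wb * d[b]) / np.sum(wb)))
        errs[k] = (
            float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) >= 2 else 0.0
        )
    return TIProfile(grid, means, errs, warnings=tuple(warns))


def edsti_cycle_sum(
    start_leg: FreeEnergyEstimate,
    ti_leg: FreeEnergyEstimate,
    end_leg: FreeEnergyEstimate,
) -> FreeEnergyEstimate:
    """Diagonal free energy -DG(R->start end state) + DG_TI(R) + DG(R->end).

    The reference-to-end-state leg at lam=0 is traversed against its stored
    direction, hence the minus sign.
    """
    for leg, name in ((start_leg, "start"), (ti_leg, "TI"), (end_leg, "end")):
        if leg is None:
            raise StructureError(f"missing {name} leg of the EDS-TI cycle")
    value = -start_leg.value + ti_leg.value + end_leg.value
    err = math.sqrt(start_leg.error ** 2 + ti_leg.error ** 2 + end_leg.error ** 2)
    frames = start_leg.n_frames_used + ti_leg.n_frames_used + end_leg.n_frames_used
    warns = start_leg.warnings + ti_leg.warnings + end_leg.warnings
    return FreeEnergyEstimate(value, err, "EDSTI", frames, warns)


# ---------------------------------------------------------------------------
# Two-dimensional thermodynamic integration
# ---------------------------------------------------------------------------


def landscape_2d(
    lam_grid: Sequence[float],
    kap_grid: Sequence[float],
    mean_dlam: np.ndarray,
    mean_dkap: np.ndarray,
    ctx: ThermoContext = ThermoContext(),
    err_dlam: np.ndarray | None = None,
    err_dkap: np.ndarray | None = None,
) -> Landscape2D:
    """Free-energy surface from dual-derivative means on a rectangular grid.

    The surface is filled row-major from G(0,0) = 0.  Each new node takes up
    to three predecessor estimates - diagonal (both derivatives), a lam step
    from the same row and a kap step from the same column, each integrated
    with a trapezoidal increment - and combines the available m estimates by
    exponential averaging, -kBT ln((1/m) sum_i exp(-G_i/kBT)).
    """
    lam = np.asarray(lam_grid, float)
    kap = np.asarray(kap_grid, float)
    dl = np.asarray(mean_dlam, float)
    dk = np.asarray(mean_dkap, float)
    if dl.shape != (len(lam), len(kap)) or dk.shape != (len(lam), len(kap)):
        raise StructureError(
            f"derivative grids must have shape {(len(lam), len(kap))}; got "
            f"{dl.shape} and {dk.shape} - the coupling-state grid is incomplete"
        )
    kBT = ctx.kBT
    G = np.zeros((len(lam), len(kap)))
    for i in range(len(lam)):
        for j in range(len(kap)):
            if i == 0 and j == 0:
                continue
            ests = []
            if i > 0 and j > 0:
                dlm = lam[i] - lam[i - 1]
                dkp = kap[j] - kap[j - 1]
                ests.append(
                    G[i - 1, j - 1]
                    + dlm * 0.5 * (dl[i - 1, j - 1] + dl[i, j])
                    + dkp * 0.5 * (dk[i - 1, j - 1] + dk[i, j])
                )
            if i > 0:
                dlm = lam[i] - lam[i - 1]
                ests.append(G[i - 1, j] + dlm * 0.5 * (dl[i - 1, j] + dl[i, j]))
            if j > 0:
                dkp = kap[j] - kap[j - 1]
                ests.append(G[i, j - 1] + dkp * 0.5 * (dk[i, j - 1] + dk[i, j]))
            arr = np.asarray(ests, float)
            G[i, j] = -kBT * (logsumexp(-arr / kBT) - math.log(len(arr)))

    corners = {
        (lam[0], kap[0]): G[0, 0],
        (lam[0], kap[-1]): G[0, -1],
        (lam[-1], kap[0]): G[-1, 0],
        (lam[-1], kap[-1]): G[-1, -1],
    }
    keys = list(corners)
    diffs = {}
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            diffs[(keys[a], keys[b])] = corners[keys[b]] - corners[keys[a]]

    errors = None
    if err_dlam is not None and err_dkap is not None:
        el = np.asarray(err_dlam, float)
        ek = np.asarray(err_dkap, float)
        wl = _half_interval_weights(lam)
        wk = _half_interval_weights(kap)

        def edge_var(which: str, fixed: int) -> float:
            # Variance of the 1D trapezoid integral along one grid edge.
            if which == "lam":
                return float(np.sum((el[:, fixed] * wl) ** 2))
            return float(np.sum((ek[fixed, :] * wk) ** 2))

        corner_var = {
            (lam[0], kap[0]): 0.0,
            (lam[-1], kap[0]): edge_var("lam", 0),
            (lam[0], kap[-1]): edge_var("kap", 0),
            (lam[-1], kap[-1]): edge_var("lam", 0) + edge_var("kap", -1),
        }
        errors = {}
        for (a, b) in diffs:
            errors[(a, b)] = math.sqrt(corner_var[a] + corner_var[b])
    return Landscape2D(lam, kap, G, diffs, errors)
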