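"""Proliferation-Invasion-Hypoxic-Necrotic-Angiogenesis (PIHNA) model.

Five coupled species on a radial grid, all normalized to the tissue
carrying capacity K = 1 (the angiogenic factor a is normalized to its own
scale):

    c  normoxic tumor cells      h  hypoxic tumor cells
    n  necrotic debris           v  vasculature
    a  diffusible angiogenic factor (vascular growth signal)

with occupancy factor F = max(0, 1 - (c+h+n+v)/K) limiting both motility
and proliferation, a vascular-sufficiency switch s = v / (v + k_v(c+h))
governing the normoxic <-> hypoxic conversion, and contact necrosis gated
by local crowding g = (min(1, (c+h+n+v)/K))^2 (necrosis expands by
occlusion in fully occupied tissue, not in the loose infiltrative margin):

    dc/dt = div(D F grad c) + rho c F - beta_ch (1-s) c + gamma_hc s h - alpha_n g (n/K) c
    dh/dt = div(D F grad h) + beta_ch (1-s) c - gamma_hc s h - beta_hn h - alpha_n g (n/K) h
    dn/dt = beta_hn h + alpha_n g (n/K) (c + h)
    dv/dt = div(D_v F grad v) + mu_v v (1 - v/v_cap) F a/(a_half + a) - alpha_n g (n/K) v
    da/dt = delta_a (c + h) - lambda_a a - omega_a a v

Only (D, rho) vary per patient; the remaining rates are population
constants.  Because the model produces a central necrotic core, a single
imaging timepoint carrying three radii (necrosis, T1Gd, T2/FLAIR) is
enough to estimate both D and rho: a library of forward simulations over a
log-spaced (D, rho) grid is searched for the (D, rho, time) triple whose
simulated radii best match the observed ones.

The degenerate case beta_ch = alpha_n = 0 with no hypoxic/necrotic/vascular
compartments reduces exactly to the occupancy-limited single-species
solver in :mod:`gliosurv.pi_model`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pi_model import (
    DensityThresholds,
    RadialField,
    StabilityError,
    extract_radius,
    finite_volume_weights,
    radial_flux_divergence,
)

logger = logging.getLogger("gliosurv")

_TINY = 1e-300


@dataclass
class PIHNARates:
    """Model rates; only (D, rho) are patient-specific.

    Units: D and D_v in mm^2/year, every other rate in 1/year, k_v
    dimensionless (vascular-sufficiency half-saturation relative to the
    cellular density), delta_a in angiogenic-factor units per cell-density
    per year.  The fixed-rate defaults are order-of-magnitude population
    constants chosen to produce necrotic cores within simulated months.
    """

    D: float = 30.0
    rho: float = 20.0
    beta_ch: float = 10.0
    gamma_hc: float = 50.0
    beta_hn: float = 1.0
    alpha_n: float = 10.0
    D_v: float = 0.5
    mu_v: float = 10.0
    k_v: float = 0.2
    delta_a: float = 1.0
    lambda_a: float = 10.0
    omega_a: float = 10.0
    v_cap: float = 0.1
    a_half: float = 0.02

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"rate {f.name} must be non-negative")

    @property
    def max_rate(self) -> float:
        return max(
            self.rho, self.beta_ch, self.gamma_hc, self.beta_hn,
            self.alpha_n, self.mu_v, self.lambda_a + self.omega_a,
        )


@dataclass
class PIHNAState:
    """Five-species state on a uniform radial grid (mm); time in years."""

    r: np.ndarray
    c: np.ndarray
    h: np.ndarray
    n: np.ndarray
    v: np.ndarray
    a: np.ndarray
    time: float = 0.0
    K: float = 1.0

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def total(self) -> np.ndarray:
        """Total occupancy c + h + n + v."""
        return self.c + self.h + self.n + self.v

    def check(self, tol: float = 1e-6) -> None:
        """Assert positivity and the occupancy bound c+h+n+v <= K."""
        for name in ("c", "h", "n", "v", "a"):
            arr = getattr(self, name)
            if arr.min() < -1e-9:
                raise StabilityError(f"negative {name} density: {arr.min():.3g}")
        if self.total.max() > self.K * (1 + tol):
            raise StabilityError(
                f"occupancy bound violated: total = {self.total.max():.8f} K"
            )

    def copy(self) -> "PIHNAState":
        return PIHNAState(
            r=self.r, c=self.c.copy(), h=self.h.copy(), n=self.n.copy(),
            v=self.v.copy(), a=self.a.copy(), time=self.time, K=self.K,
        )


@dataclass
class ImagingObservables:
    """The three spherically-equivalent radii read off one imaging timepoint."""

    t1gd_radius_mm: float
    t2flair_radius_mm: float
    necrosis_radius_mm: float

    def __post_init__(self) -> None:
        if not (
            0 <= self.necrosis_radius_mm
            <= self.t1gd_radius_mm + 1e-9
        ) or self.t2flair_radius_mm < self.t1gd_radius_mm - 1e-9:
            raise ValueError("radii must be nested: necrosis <= T1Gd <= T2/FLAIR")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.t1gd_radius_mm, self.t2flair_radius_mm, self.necrosis_radius_mm]
        )


def default_initial_state(
    r_max: float = 70.0, dr: float = 0.25, seed_amplitude: float = 0.5,
    seed_width_mm: float = 1.5, v0: float = 0.05, K: float = 1.0,
) -> PIHNAState:
    """Small normoxic seed at the origin in normally vascularized tissue."""
    r = np.arange(0.0, r_max + dr / 2, dr)
    z = np.zeros_like(r)
    return PIHNAState(
        r=r,
        c=seed_amplitude * np.exp(-((r / seed_width_mm) ** 2)),
        h=z.copy(), n=z.copy(),
        v=np.full_like(r, v0),
        a=z.copy(), K=K,
    )


def pihna_stable_dt(rates: PIHNARates, dr: float, safety: float = 0.8) -> float:
    dt_diff = 0.25 * dr**2 / max(rates.D, rates.D_v, _TINY)
    dt_react = 0.2 / max(rates.max_rate, _TINY)
    return safety * min(dt_diff, dt_react)


def _step(state: PIHNAState, rates: PIHNARates, dt: float) -> None:
    """One explicit Euler step, in place."""
    c, h, n, v, a, r, K = state.c, state.h, state.n, state.v, state.a, state.r, state.K
    T = (c + h + n + v) / K
    F = np.clip(1.0 - T, 0.0, None)
    cells = c + h
    s = v / (v + rates.k_v * cells + _TINY)
    nec = rates.alpha_n * (n / K) * np.clip(T, 0.0, 1.0) ** 2
    to_h = rates.beta_ch * (1.0 - s) * c
    to_c = rates.gamma_hc * s * h
    dc = radial_flux_divergence(c, r, rates.D, F) + rates.rho * c * F - to_h + to_c - nec * c
    dh = radial_flux_divergence(h, r, rates.D, F) + to_h - to_c - rates.beta_hn * h - nec * h
    dn = rates.beta_hn * h + nec * cells
    dv = (
        radial_flux_divergence(v, r, rates.D_v, F)
        + rates.mu_v * v * np.clip(1.0 - v / rates.v_cap, 0.0, None) * F * a / (rates.a_half + a)
        - nec * v
    )
    da = rates.delta_a * cells - rates.lambda_a * a - rates.omega_a * a * v

    def _upd(x, dx):
        y = x + dt * dx
        return np.clip(y, 0.0, None) if y.min() > -1e-9 else y

    state.c = _upd(c, dc)
    state.h = _upd(h, dh)
    state.n = n + dt * dn
    state.v = _upd(v, dv)
    state.a = _upd(a, da)
    state.time += dt


def pihna_simulate(
    rates: PIHNARates,
    init: PIHNAState | None = None,
    t_end: float = 1.0,
    dt: float | None = None,
    dr: float = 0.25,
    r_max: float = 70.0,
    record_times: np.ndarray | None = None,
    stop_radius_mm: float | None = None,
    thresholds: DensityThresholds | None = None,
    check_every: int = 50,
) -> list[PIHNAState]:
    """Evolve the five-species system, returning recorded states.

    The stability contract of the single-species solver applies to the
    largest diffusivity; the reaction rates additionally bound the step so
    the fastest conversion (contact necrosis by default) resolves.  The
    positivity and occupancy invariants are asserted every ``check_every``
    steps and at every recorded state.  With ``stop_radius_mm`` the run
    ends early once the T1Gd radius reaches that size (used by the library
    builder), always recording the final state.
    """
    state = init.copy() if init is not None else default_initial_state(r_max, dr)
    if dt is None:
        dt = pihna_stable_dt(rates, state.dr)
    if max(rates.D, rates.D_v) * dt / state.dr**2 > 0.25 * (1 + 1e-12):
        raise StabilityError("dt violates the diffusive stability bound")
    thresholds = thresholds or DensityThresholds()
    rec = sorted(set(float(t) for t in (record_times if record_times is not None else [])))
    rec = [t for t in rec if t > state.time]
    out: list[PIHNAState] = []
    k = 0
    while state.time < t_end - 1e-12:
        step_end = min(rec[0], t_end) if rec else t_end
        _step(state, rates, min(dt, step_end - state.time))
        k += 1
        if k % check_every == 0:
            state.check()
        if rec and state.time >= rec[0] - 1e-12:
            state.check()
            out.append(state.copy())
            rec.pop(0)
            if stop_radius_mm is not None:
                obs = extract_observables(out[-1], thresholds)
                if obs.t1gd_radius_mm >= stop_radius_mm:
                    return out
    state.check()
    if not out or out[-1].time < state.time - 1e-12:
        out.append(state.copy())
    return out


def total_cell_mass(state: PIHNAState) -> float:
    """4*pi*Int (c+h+n+v) r^2 dr — conserved when all sources/sinks are off."""
    w = finite_volume_weights(state.r)
    return 4.0 * math.pi * float(np.sum(w * state.total))


def extract_observables(
    state: PIHNAState, thresholds: DensityThresholds | None = None
) -> ImagingObservables:
    """Read the three imaging radii from a simulated state.

    T1Gd: outermost radius where the total cellular density c+h+n reaches
    the high threshold (0.80 K); T2/FLAIR: same for the low threshold
    (0.16 K); necrosis: outermost radius where necrotic debris makes up at
    least half the local cellular density (a composition rule — the
    necrotic core is the region that images as non-enhancing).
    """
    thresholds = thresholds or DensityThresholds()
    cellular = state.c + state.h + state.n
    fake = RadialField(r=state.r, c=cellular, K=state.K)
    t1 = extract_radius(fake, thresholds.t1gd_frac)
    t2 = extract_radius(fake, thresholds.t2_frac)
    frac = np.where(cellular > 1e-6 * state.K, state.n / np.maximum(cellular, _TINY), 0.0)
    nec_field = RadialField(r=state.r, c=frac, K=1.0)
    nec = extract_radius(nec_field, 0.5)
    nec = min(nec, t1)  # composition rule cannot place necrosis outside T1Gd
    return ImagingObservables(
        t1gd_radius_mm=t1, t2flair_radius_mm=max(t2, t1), necrosis_radius_mm=nec
    )


# ---------------------------------------------------------------------------
# simulation library: forward (D, rho) -> radii time series, and its inversion


@dataclass
class SimulationLibrary:
    """Precomputed radii time series on a (D, rho) grid.

    ``times`` and ``radii`` are NaN-padded to a common length: radii[i, j]
    has columns (T1Gd, T2/FLAIR, necrosis) in mm at times[i, j] years.
    """

    D_grid: np.ndarray
    rho_grid: np.ndarray
    times: np.ndarray  # (nD, nrho, nt)
    radii: np.ndarray  # (nD, nrho, nt, 3)
    meta: dict = field(default_factory=dict)

    def n_valid(self, i: int, j: int) -> int:
        return int(np.sum(np.isfinite(self.times[i, j])))

    def save(self, path) -> None:
        """Persist as one stacked array plus a JSON metadata sidecar."""
        path = Path(path)
        nt = self.times.shape[2]
        payload = np.concatenate(
            [self.times[:, :, :, None], self.radii], axis=3
        )  # (nD, nrho, nt, 4)
        np.save(path.with_suffix(".npy"), payload)
        meta = dict(self.meta)
        meta.update(
            {
                "format_version": 1,
                "D_grid": self.D_grid.tolist(),
                "rho_grid": self.rho_grid.tolist(),
                "n_times": nt,
            }
        )
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "SimulationLibrary":
        path = Path(path)
        payload = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        return cls(
            D_grid=np.array(meta["D_grid"]),
            rho_grid=np.array(meta["rho_grid"]),
            times=payload[:, :, :, 0],
            radii=payload[:, :, :, 1:],
            meta=meta,
        )


def _grid_for(D: float, rho: float) -> tuple[float, float]:
    """Per-simulation spatial step and domain resolving the front width."""
    width = math.sqrt(D / max(rho, _TINY))
    dr = float(np.clip(width / 6.0, 0.15, 0.6))
    return dr, 70.0


def simulate_observables(
    D: float,
    rho: float,
    fixed: PIHNARates | None = None,
    thresholds: DensityThresholds | None = None,
    stop_radius_mm: float = 36.0,
    t_max: float = 15.0,
    n_record: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulate one (D, rho) pair; return (times, radii[nt, 3]).

    The grid adapts to the front width sqrt(D/rho); the run stops once the
    T1Gd radius exceeds the largest clinically observed size or at
    ``t_max`` years for slow-growing tumors.
    """
    fixed = fixed or PIHNARates()
    rates = dataclasses.replace(fixed, D=D, rho=rho)
    thresholds = thresholds or DensityThresholds()
    dr, r_max = _grid_for(D, rho)
    speed_est = 2.0 * math.sqrt(D * rho)
    t_stop = min(t_max, (stop_radius_mm + 10.0) / max(speed_est, _TINY) + 2.0 / max(rho, 0.5))
    record = np.linspace(t_stop / n_record, t_stop, n_record)
    # seed width follows the intrinsic profile width so very diffuse tumors
    # are not washed out before proliferation takes hold
    init = default_initial_state(
        r_max, dr, seed_width_mm=max(1.5, math.sqrt(D / max(rho, _TINY)))
    )
    states = pihna_simulate(
        rates, init=init, t_end=t_stop, dr=dr, r_max=r_max,
        record_times=record, stop_radius_mm=stop_radius_mm, thresholds=thresholds,
    )
    times = np.array([s.time for s in states])
    radii = np.array([extract_observables(s, thresholds).as_array() for s in states])
    return times, radii


def observables_at_detection(
    times: np.ndarray, radii: np.ndarray, detection_radius_mm: float = 20.0
) -> ImagingObservables:
    """Snapshot a simulated radii series at clinical detection size.

    Returns the first recorded state whose T1Gd radius reaches the
    detection size (the cohort-median presentation size by default), or
    the final state for tumors that never densify that far.  Sampling at
    detection rather than at a fixed age mirrors how patients actually
    enter an imaging cohort.
    """
    idx = np.nonzero(radii[:, 0] >= detection_radius_mm)[0]
    k = int(idx[0]) if len(idx) else len(times) - 1
    return ImagingObservables(*radii[k])


def build_library(
    D_grid: np.ndarray,
    rho_grid: np.ndarray,
    fixed: PIHNARates | None = None,
    thresholds: DensityThresholds | None = None,
    **sim_kwargs,
) -> SimulationLibrary:
    """One forward simulation per (D, rho) grid pair.

    Deterministic given the configuration; a failing member simulation
    aborts the build with the offending pair identified.
    """
    D_grid = np.asarray(D_grid, dtype=float)
    rho_grid = np.asarray(rho_grid, dtype=float)
    if not (np.all(np.diff(D_grid) > 0) and np.all(np.diff(rho_grid) > 0)):
        raise ValueError("parameter grids must be strictly increasing")
    series: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for D in D_grid:
        row = []
        for rho in rho_grid:
            try:
                row.append(simulate_observables(D, rho, fixed, thresholds, **sim_kwargs))
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise RuntimeError(
                    f"library member simulation failed at D={D}, rho={rho}: {exc}"
                ) from exc
        series.append(row)
    nt = max(len(t) for row in series for t, _ in row)
    times = np.full((len(D_grid), len(rho_grid), nt), np.nan)
    radii = np.full((len(D_grid), len(rho_grid), nt, 3), np.nan)
    for i, row in enumerate(series):
        for j, (t, rr) in enumerate(row):
            times[i, j, : len(t)] = t
            radii[i, j, : len(t)] = rr
    fixed = fixed or PIHNARates()
    thresholds = thresholds or DensityThresholds()
    meta = {
        "fixed_rates": dataclasses.asdict(fixed),
        "thresholds": dataclasses.asdict(thresholds),
        "sim_kwargs": {k: v for k, v in sim_kwargs.items()},
    }
    return SimulationLibrary(D_grid, rho_grid, times, radii, meta)


def default_parameter_grids(n: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced D in [0.3, 300] mm^2/yr and rho in [1.8, 200] /yr."""
    return np.geomspace(0.3, 300.0, n), np.geomspace(1.8, 200.0, n)


@dataclass
class PIHNAEstimate:
    D: float
    rho: float
    time: float
    residual_mm: float
    on_boundary: bool


def _series_rms(times: np.ndarray, radii: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """Best RMS radius mismatch along one time series and the time achieving it."""
    ok = np.isfinite(times)
    if not ok.any():
        return math.inf, math.nan
    res = np.sqrt(np.mean((radii[ok] - target) ** 2, axis=1))
    k = int(np.argmin(res))
    return float(res[k]), float(times[ok][k])


def _interp_radii(lib: SimulationLibrary, i0: int, j0: int, wx: float, wy: float,
                  t: float) -> np.ndarray:
    """Bilinear-in-log-parameters, linear-in-time interpolated radii."""
    out = np.zeros(3)
    for di, wxi in ((0, 1 - wx), (1, wx)):
        for dj, wyj in ((0, 1 - wy), (1, wy)):
            ti = lib.times[i0 + di, j0 + dj]
            ri = lib.radii[i0 + di, j0 + dj]
            ok = np.isfinite(ti)
            for k in range(3):
                out[k] += wxi * wyj * np.interp(t, ti[ok], ri[ok, k])
    return out


_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_section_time(fun, lo: float, hi: float, tol: float = 1e-3) -> tuple[float, float]:
    a, b = lo, hi
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1, f2 = fun(x1), fun(x2)
    while b - a > tol * max(1.0, hi):
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - _GOLDEN * (b - a)
            f1 = fun(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLDEN * (b - a)
            f2 = fun(x2)
    return (x1, f1) if f1 <= f2 else (x2, f2)


def estimate_pihna(
    obs: ImagingObservables,
    library: SimulationLibrary,
    refine: int = 7,
) -> PIHNAEstimate:
    """Patient-specific (D, rho) from one imaging timepoint.

    Stage 1 scans every (D, rho, time) triple in the library for the
    smallest root-mean-square mismatch of the three radii, breaking ties
    toward smaller D then smaller rho.  Stage 2 refines within the
    surrounding grid cell: radii are interpolated bilinearly in
    (log D, log rho) and linearly in time, a ``refine`` x ``refine``
    sub-grid of parameter candidates is scored with a golden-section
    search over time, and the best candidate is returned.  Diagnostics
    report the residual and whether the optimum sits on the grid boundary.
    """
    if library.times.size == 0:
        raise ValueError("empty simulation library")
    target = obs.as_array()
    nD, nrho = len(library.D_grid), len(library.rho_grid)
    best = (math.inf, 0, 0, math.nan)
    for i in range(nD):
        for j in range(nrho):
            res, t = _series_rms(library.times[i, j], library.radii[i, j], target)
            if res < best[0] - 1e-12:
                best = (res, i, j, t)
    res0, i0, j0, t0 = best
    # refinement cell: the 2x2 block of grid nodes around the winner
    ci = min(max(i0 - 1, 0), nD - 2) if nD > 1 else 0
    cj = min(max(j0 - 1, 0), nrho - 2) if nrho > 1 else 0
    best_ref = (res0, float(library.D_grid[i0]), float(library.rho_grid[j0]), t0)
    if nD > 1 and nrho > 1:
        for ci_ in {max(i0 - 1, 0), min(i0, nD - 2)}:
            for cj_ in {max(j0 - 1, 0), min(j0, nrho - 2)}:
                t_hi = float(
                    np.nanmin(
                        [np.nanmax(library.times[ci_ + a, cj_ + b]) for a in (0, 1) for b in (0, 1)]
                    )
                )
                for wx in np.linspace(0, 1, refine):
                    for wy in np.linspace(0, 1, refine):
                        fun = lambda t: float(
                            np.sqrt(np.mean((_interp_radii(library, ci_, cj_, wx, wy, t) - target) ** 2))
                        )
                        t_best, f_best = _golden_section_time(fun, 0.0, t_hi)
                        if f_best < best_ref[0] - 1e-12:
                            lD = (1 - wx) * math.log(library.D_grid[ci_]) + wx * math.log(
                                library.D_grid[ci_ + 1]
                            )
                            lr = (1 - wy) * math.log(library.rho_grid[cj_]) + wy * math.log(
                                library.rho_grid[cj_ + 1]
                            )
                            best_ref = (f_best, math.exp(lD), math.exp(lr), t_best)
    res, D_hat, rho_hat, t_hat = best_ref
    on_boundary = (
        D_hat <= library.D_grid[0] * (1 + 1e-9)
        or D_hat >= library.D_grid[-1] * (1 - 1e-9)
        or rho_hat <= library.rho_grid[0] * (1 + 1e-9)
        or rho_hat >= library.rho_grid[-1] * (1 - 1e-9)
    )
    if on_boundary:
        logger.warning(
            "PIHNA estimate (D=%.3g, rho=%.3g) lies on the library grid boundary",
            D_hat, rho_hat,
        )
    return PIHNAEstimate(D=D_hat, rho=rho_hat, time=t_hat, residual_mm=res, on_boundary=on_boundary)
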