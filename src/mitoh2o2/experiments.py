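"""The computational experiments: Prx3 sweep, Monte Carlo uncertainty,
perturbation sweep, collapse threshold, local sensitivity analysis, and the
efflux-refined Monte Carlo.

All experiments run on the baseline network (OxPhos source 4 uM/s) unless a
parameter set says otherwise.  Monte Carlo sampling uses one root seed with a
deterministic per-sample substream, so enlarging ``n`` extends a sample set
without reshuffling earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    PRX3_RANGE_UM,
    RateParameters,
    default_initial_state,
    default_parameters,
)
from .simulate import SteadyState, find_steady_state, fractions, integrate

__all__ = [
    "TABLE_GRID_KDAAO",
    "SweepResult",
    "basal_prx3_sweep",
    "monte_carlo_basal",
    "perturbation_sweep",
    "perturbation_run",
    "collapse_threshold",
    "BracketError",
    "sensitivity_analysis",
    "efflux_monte_carlo",
    "sample_uniform",
]

#: Default DAAO perturbation grid (uM/s), the printed sweep values.
TABLE_GRID_KDAAO: tuple[float, ...] = (0.0, 8.0, 16.0, 23.0, 31.0, 39.0, 47.0, 54.0, 62.0, 70.0)

_FRACTION_COLS = (
    "prx3_dimer", "prx5_dimer", "gpx1_oxidized", "gpx4_oxidized", "prx3_hyperoxidized",
)


@dataclass
class SweepResult:
    """Per-grid-point summary table plus (optionally) the raw trajectories."""

    table: pd.DataFrame
    trajectories: dict | None = None


def _summarize(state: np.ndarray, **extra) -> dict:
    row = dict(extra)
    row["h2o2_uM"] = float(state[0])
    row["h2o2_nM"] = float(state[0]) * 1e3
    row.update(fractions(state).as_dict())
    return row


# --------------------------------------------------------------------------
# basal sweep and Monte Carlo
# --------------------------------------------------------------------------

def basal_prx3_sweep(
    grid: Sequence[float] | None = None,
    params: RateParameters | None = None,
    n_points: int = 10,
) -> SweepResult:
    """Basal steady states across the feasible Prx3 pool (default: ten
    evenly spaced points over 48-110 uM, OxPhos 4 uM/s, no perturbation)."""
    params = params or default_parameters()
    if grid is None:
        grid = np.linspace(*PRX3_RANGE_UM, n_points)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) and grid.size > 1:
        raise ValueError("Prx3 grid must be strictly increasing")
    rows = []
    for prx3 in grid:
        ss = find_steady_state(default_initial_state(prx3), params)
        rows.append(_summarize(ss.state, prx3_total_uM=float(prx3),
                               residual=ss.residual, converged=ss.converged))
    return SweepResult(table=pd.DataFrame(rows))


def sample_uniform(n: int, lo: float, hi: float, seed: int) -> np.ndarray:
    """``n`` uniform draws on [lo, hi]: u*(hi-lo)+lo with one substream per
    sample index, derived from the root seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if hi < lo:
        raise ValueError("range must be ordered")
    u = np.array([
        np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,))).random()
        for i in range(n)
    ])
    return u * (hi - lo) + lo


def monte_carlo_basal(
    n: int = 10_000,
    prx3_range: tuple[float, float] = PRX3_RANGE_UM,
    seed: int = 0,
    params: RateParameters | None = None,
    method: str = "integrate",
) -> pd.DataFrame:
    """Distribution of basal steady-state H2O2 over uniformly sampled Prx3
    pools.

    ``method='integrate'`` relaxes every sample by stiff integration (the
    reference procedure); ``method='refine'`` Newton-refines each sample's
    fixed point starting from its neighbour's solution, which is orders of
    magnitude faster and agrees with integration to solver tolerance (the
    test suite verifies the equivalence on subsamples).
    """
    params = params or default_parameters()
    draws = sample_uniform(n, *prx3_range, seed)
    h2o2 = np.empty(n)
    if method == "integrate":
        for i, prx3 in enumerate(draws):
            ss = find_steady_state(default_initial_state(prx3, allow_out_of_range=True), params)
            h2o2[i] = ss.state[0]
    elif method == "refine":
        from .simulate import refine_steady_state

        order = np.argsort(draws)
        ref = find_steady_state(
            default_initial_state(draws[order[0]], allow_out_of_range=True), params
        ).state
        prev_prx3 = draws[order[0]]
        for i in order:
            guess = ref.copy()
            guess[1] += draws[i] - prev_prx3   # move the Prx3-SH pool
            ref = refine_steady_state(guess, params)
            prev_prx3 = draws[i]
            h2o2[i] = ref[0]
    else:
        raise ValueError("method must be 'integrate' or 'refine'")
    return pd.DataFrame({
        "sample": np.arange(n),
        "prx3_total_uM": draws,
        "h2o2_uM": h2o2,
        "h2o2_nM": h2o2 * 1e3,
    })


# --------------------------------------------------------------------------
# perturbation
# --------------------------------------------------------------------------

def perturbation_run(
    kdaao: float,
    prx3_total: float = 62.0,
    t_end: float = 3600.0,
    output_times: Sequence[float] | None = None,
    params: RateParameters | None = None,
    baseline: np.ndarray | None = None,
):
    """One perturbation trajectory: relax to the basal steady state, then
    switch the DAAO source on at t=0."""
    params = params or default_parameters()
    if baseline is None:
        baseline = find_steady_state(default_initial_state(prx3_total), params).state
    if output_times is None:
        output_times = np.linspace(0.0, t_end, 241)
    return integrate(baseline, params.with_values(kdaao=kdaao), t_end,
                     output_times=output_times)


def perturbation_sweep(
    kdaao_grid: Sequence[float] = TABLE_GRID_KDAAO,
    prx3_total: float = 62.0,
    t_end: float = 3600.0,
    params: RateParameters | None = None,
    keep_trajectories: bool = True,
) -> SweepResult:
    """Fractional oxidation of the four peroxidases at 1 h across DAAO
    perturbation rates, with the H2O2/Prx3-form time courses."""
    params = params or default_parameters()
    grid = np.asarray(kdaao_grid, dtype=float)
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("kDAAO grid must be strictly increasing")
    baseline = find_steady_state(default_initial_state(prx3_total), params).state
    rows, trajs = [], {}
    for kd in grid:
        traj = perturbation_run(kd, prx3_total, t_end, params=params, baseline=baseline)
        rows.append(_summarize(traj.final, kdaao_uM_per_s=float(kd)))
        if keep_trajectories:
            trajs[float(kd)] = traj
    return SweepResult(table=pd.DataFrame(rows), trajectories=trajs or None)


class BracketError(ValueError):
    """The collapse criterion is not bracketed by the search interval."""


def collapse_threshold(
    lo: float = 0.0,
    hi: float = 100.0,
    prx3_total: float = 62.0,
    criterion: Callable[[object], bool] | None = None,
    iterations: int = 12,
    t_end: float = 3600.0,
    params: RateParameters | None = None,
) -> float:
    """DAAO rate (uM/s) at which the Prx3 system collapses, by bisection.

    The default collapse indicator is a Prx3 hyperoxidized fraction above 0.5
    at the end of the 1-h window.
    """
    params = params or default_parameters()
    if criterion is None:
        criterion = lambda fr: fr.prx3_hyperoxidized > 0.5
    baseline = find_steady_state(default_initial_state(prx3_total), params).state

    def collapsed(kd: float) -> bool:
        traj = integrate(baseline, params.with_values(kdaao=kd), t_end,
                         output_times=[t_end])
        return bool(criterion(fractions(traj.final)))

    if collapsed(lo):
        raise BracketError(f"criterion already met at the lower bound {lo}")
    if not collapsed(hi):
        raise BracketError(f"criterion never met up to the upper bound {hi}")
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if collapsed(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# sensitivity analysis
# --------------------------------------------------------------------------

def sensitivity_analysis(
    outputs: Sequence[str] = ("H2O2", "Prx3-SH", "Prx3-SS", "Prx3-SOOH"),
    delta: float = 0.10,
    t_eval: float = 5.0,
    prx3_total: float = 62.0,
    params: RateParameters | None = None,
    central: bool = False,
    truncate: float = 1.0e-5,
) -> pd.DataFrame:
    """Finite-difference sensitivities of basal predictions to k1..k30.

    Each parameter is perturbed by ``delta`` (forward difference by default;
    ``central=True`` uses a symmetric difference for verification).  Raw
    sensitivities s_i = dC_j/dk_i are normalized to s̄_i = (dC_j/C_j)/(dk_i/k_i)
    and, per output, ranked by |s̄| descending (ties broken by parameter
    index) with entries below ``truncate`` dropped.
    """
    from .model_core import species_index

    params = params or default_parameters()
    y0 = default_initial_state(prx3_total)
    out_idx = [species_index(s) for s in outputs]

    def values_at(p: RateParameters) -> np.ndarray:
        traj = integrate(y0, p, t_eval, output_times=[t_eval])
        return traj.final[out_idx]

    c0 = values_at(params)
    rows = []
    for i in range(30):
        ki = params.k[i]
        if ki == 0.0:
            continue  # zero parameters have no relative perturbation
        up = values_at(params.with_values(**{f"k{i+1}": ki * (1.0 + delta)}))
        if central:
            dn = values_at(params.with_values(**{f"k{i+1}": ki * (1.0 - delta)}))
            raw = (up - dn) / (2.0 * delta * ki)
        else:
            raw = (up - c0) / (delta * ki)
        norm = raw * ki / c0
        for j, sp in enumerate(outputs):
            rows.append({
                "parameter": f"k{i+1}",
                "parameter_index": i + 1,
                "output": sp,
                "s_raw": float(raw[j]),
                "s_normalized": float(norm[j]),
                "t_eval_s": t_eval,
            })
    df = pd.DataFrame(rows)
    df["abs_s"] = df["s_normalized"].abs()
    df = df[df["abs_s"] >= truncate]
    df = df.sort_values(["output", "abs_s", "parameter_index"],
                        ascending=[True, False, True], kind="mergesort")
    df["rank"] = df.groupby("output").cumcount() + 1
    return df.drop(columns="abs_s").reset_index(drop=True)


# --------------------------------------------------------------------------
# efflux-refined Monte Carlo
# --------------------------------------------------------------------------

def efflux_monte_carlo(
    kdaao_range: tuple[float, float] = (50.0, 100.0),
    kefflux_range: tuple[float, float] = (50.0, 100.0),
    n: int = 10_000,
    seed: int = 0,
    times: Sequence[float] | None = None,
    percentiles: Sequence[float] = (2.5, 25.0, 50.0, 75.0, 97.5),
    prx3_total: float = 62.0,
    params: RateParameters | None = None,
) -> pd.DataFrame:
    """Time-resolved percentile bands of H2O2 and the Prx3 forms under
    independently sampled (kDAAO, kefflux) pairs.

    Returns a long table: time_s, variable, percentile, value.  Variables are
    H2O2 (uM), Prx3-SH/-SS/-SOOH (uM) and the Prx3 dimer fraction.
    """
    params = params or default_parameters()
    if times is None:
        times = np.arange(0.0, 3601.0, 300.0)
    times = np.asarray(times, dtype=float)
    kd = sample_uniform(n, *kdaao_range, seed)
    # independent second coordinate: disjoint substream indices
    ke = sample_uniform(n, *kefflux_range, seed + (1 << 20))
    baseline = find_steady_state(default_initial_state(prx3_total), params).state

    variables = ("H2O2", "Prx3-SH", "Prx3-SS", "Prx3-SOOH", "dimer_fraction")
    values = np.empty((n, times.size, len(variables)))
    prx3_pool_idx = [1, 2, 3, 4]
    for i in range(n):
        pk = params.with_values(kdaao=kd[i], kefflux=ke[i])
        traj = integrate(baseline, pk, float(times[-1]),
                         output_times=times[times > 0])
        # integrate() guarantees a t=0 row; pick the rows of the requested grid
        sel = np.searchsorted(traj.t, times)
        states = traj.states[sel]
        total = states[:, prx3_pool_idx].sum(axis=1)
        values[i, :, 0] = states[:, 0]
        values[i, :, 1] = states[:, 1]
        values[i, :, 2] = states[:, 3]
        values[i, :, 3] = states[:, 4]
        values[i, :, 4] = states[:, 3] / total
    rows = []
    for v, name in enumerate(variables):
        for q in percentiles:
            band = np.percentile(values[:, :, v], q, axis=0)
            for ti, t in enumerate(times):
                rows.append({"time_s": float(t), "variable": name,
                             "percentile": float(q), "value": float(band[ti])})
    df = pd.DataFrame(rows)
    df.attrs["samples"] = {"kdaao": kd, "kefflux": ke}
    return df
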