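"""Synthetic redox-Western data generator and the replicate-level statistics.

A non-reducing redox Western separates reduced Prx (monomer band) from the
disulfide-linked dimer; hyperoxidized Prx3-SOOH cannot form the disulfide and
migrates with the monomer.  This module generates such band intensities from
model trajectories — per D-alanine dose (mapped to a DAAO rate), per time
point, per biological replicate, with multiplicative log-normal band noise and
a lane-wide loading factor — and runs the dose-trend statistics used on the
real readout (one-way ANOVA with Tukey-HSD comparisons against the 0 mM
control).

The quantitative D-alanine dose -> kDAAO mapping is not experimentally
established; the default map is an explicitly synthetic Michaelis-type
calibration whose top dose approaches, but stays below, the collapse
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import RateParameters, default_parameters
from .simulate import integrate
from .experiments import perturbation_run

__all__ = [
    "DoseMap",
    "default_dose_map",
    "NoiseModel",
    "sample_lane",
    "simulate_westerns",
    "densitometry_fractions",
    "anova_tukey",
]


@dataclass(frozen=True)
class DoseMap:
    """Ordered (D-alanine dose in mM, kDAAO in uM/s) pairs."""

    pairs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        doses = [d for d, _ in self.pairs]
        rates = [k for _, k in self.pairs]
        if len(set(doses)) != len(doses):
            raise ValueError("doses must be unique")
        if any(d < 0 for d in doses) or any(k < 0 for k in rates):
            raise ValueError("doses and rates must be non-negative")
        order = np.argsort(doses)
        if any(np.diff(np.asarray(rates)[order]) < 0):
            raise ValueError("kDAAO must be non-decreasing in dose")
        by_dose = dict(self.pairs)
        if 0.0 in by_dose and by_dose[0.0] != 0.0:
            raise ValueError("dose 0 must map to kDAAO 0")

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(sorted(d for d, _ in self.pairs))

    def __call__(self, dose: float) -> float:
        for d, k in self.pairs:
            if d == dose:
                return k
        raise KeyError(f"dose {dose} mM not in the map")


def default_dose_map(
    doses: Sequence[float] = (0.0, 2.5, 5.0, 10.0, 25.0),
    vmax: float = 60.0,
    km_mM: float = 10.0,
) -> DoseMap:
    """Synthetic Michaelis-type calibration: kDAAO = vmax*dose/(km+dose).

    With the defaults the top 25 mM dose maps to ~43 uM/s, near but below the
    ~50 uM/s collapse threshold, mirroring the monotone dose response of the
    blotting experiments.
    """
    return DoseMap(tuple((float(d), vmax * d / (km_mM + d)) for d in doses))


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal noise for band intensities.

    ``band_sigma`` is the log-scale spread of each band's densitometry;
    ``loading_sigma`` the spread of the per-lane loading factor shared by all
    bands of a lane (what the Hsp60 loading control normalizes away).
    """

    band_sigma: float = 0.15
    loading_sigma: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_sigma < 0 or self.loading_sigma < 0:
            raise ValueError("noise scales must be non-negative")


def sample_lane(
    rng: np.random.Generator,
    noise: NoiseModel,
    dimer_share: float,
    base_intensity: float = 100.0,
) -> tuple[float, float, float]:
    """Draw one lane's (monomer, dimer, loading-control) band intensities
    for a given true dimer share."""
    loading = np.exp(rng.normal(0.0, noise.loading_sigma))

    def band(mean: float) -> float:
        return mean * loading * np.exp(rng.normal(0.0, noise.band_sigma))

    return (band(base_intensity * (1.0 - dimer_share)),
            band(base_intensity * dimer_share),
            band(base_intensity))


def simulate_westerns(
    dose_map: DoseMap | None = None,
    times_min: Sequence[float] = (15.0, 30.0, 60.0),
    n_reps: int = 3,
    noise: NoiseModel | None = None,
    prx3_total: float = 62.0,
    params: RateParameters | None = None,
    base_intensity: float = 100.0,
) -> pd.DataFrame:
    """Synthetic densitometry records from model trajectories.

    For each (dose, time) the perturbation model runs at the mapped kDAAO;
    the dimer band carries the Prx3-SS share of the pool and the monomer band
    the rest (reduced, sulfenic and hyperoxidized forms all migrate as
    monomer).  Expected dimer/(monomer+dimer) therefore equals the simulated
    dimer fraction.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dose_map = dose_map or default_dose_map()
    noise = noise or NoiseModel()
    params = params or default_parameters()
    rng = np.random.default_rng(noise.seed)
    times_s = sorted(float(t) * 60.0 for t in times_min)

    records = []
    for dose in dose_map.doses:
        traj = perturbation_run(dose_map(dose), prx3_total=prx3_total,
                                t_end=times_s[-1], output_times=times_s,
                                params=params)
        sel = np.searchsorted(traj.t, times_s)
        for t_s, state in zip(times_s, traj.states[sel]):
            pool = state[1:5]  # Prx3 SH, SOH, SS, SOOH
            dimer_share = pool[2] / pool.sum()
            for rep in range(n_reps):
                monomer, dimer, loading = sample_lane(
                    rng, noise, dimer_share, base_intensity)
                records.append({
                    "dose_mM": dose,
                    "time_min": t_s / 60.0,
                    "replicate": rep + 1,
                    "monomer": monomer,
                    "dimer": dimer,
                    "loading_control": loading,
                    "true_dimer_fraction": dimer_share,
                })
    return pd.DataFrame(records)


def densitometry_fractions(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate fraction oxidized and loading-normalized total band.

    fraction = dimer / (monomer + dimer); the loading-normalized total
    (monomer+dimer)/loading_control supports the total-abundance check.
    """
    obs = observations.copy()
    total = obs["monomer"] + obs["dimer"]
    if (total <= 0).any():
        raise ZeroDivisionError("zero total band intensity; fraction undefined")
    obs["fraction_oxidized"] = obs["dimer"] / total
    obs["total_normalized"] = total / obs["loading_control"]
    return obs


def anova_tukey(
    fractions_table: pd.DataFrame,
    time_min: float,
    control_dose: float = 0.0,
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA across doses within one time point, plus Tukey-HSD
    comparisons of every dose against the control."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sub = fractions_table[fractions_table["time_min"] == time_min]
    groups = [g["fraction_oxidized"].to_numpy()
              for _, g in sub.groupby("dose_mM")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    f_stat, p_omnibus = stats.f_oneway(*groups)
    if np.isnan(p_omnibus):   # all observations identical: no detectable effect
        f_stat, p_omnibus = 0.0, 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        tukey = pairwise_tukeyhsd(
            sub["fraction_oxidized"].to_numpy(), sub["dose_mM"].to_numpy(),
            alpha=alpha,
        )
    frame = pd.DataFrame(tukey.summary().data[1:],
                         columns=tukey.summary().data[0])
    vs_control = frame[(frame["group1"] == control_dose)
                       | (frame["group2"] == control_dose)]
    pairs = [
        {
            "dose_mM": float(r["group2"] if r["group1"] == control_dose else r["group1"]),
            "p_adjusted": 1.0 if np.isnan(float(r["p-adj"])) else float(r["p-adj"]),
            "significant": bool(r["reject"]) and not np.isnan(float(r["p-adj"])),
        }
        for _, r in vs_control.iterrows()
    ]
    return {
        "time_min": float(time_min),
        "f_statistic": float(f_stat),
        "p_omnibus": float(p_omnibus),
        "pairs_vs_control": sorted(pairs, key=lambda d: d["dose_mM"]),
    }
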