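"""Experiment orchestration.

Every experiment is reproducible from (ModelConfig, master seed): the
builder realizes the network structure from ``config.seed`` (shifted per
replicate) and the simulation dynamics from the same replicate seed, so a
replicate differs from its siblings both in wiring and in noise, matching
the protocol of averaging a handful of independent simulations and
reporting across-run standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .builders import (
    ModelConfig,
    OptoPerturbation,
    build_model,
    calibrate_auxiliary,
    complete_tables,
    _assemble,
)
from .network import ConnectionSpec, Network, PoissonDrive, PopulationSpec, run_simulation
from .spectral import (
    bin_rates,
    welch_psd,
    binomial_null,
    corrected_beta_psd,
    time_resolved,
    beta_power_skewness,
)

__all__ = [
    "AblationResult",
    "SweepResult",
    "measure_populations",
    "ablation_screen",
    "sweep",
    "size_limit_analysis",
    "opto_battery",
    "burst_analysis",
    "R_BAR",
]

#: Selection threshold on the residual-power ratio R(S->T).
R_BAR = 1.0 / 3.0


# ----------------------------------------------------------------------
# shared measurement helper


def measure_populations(
    net: Network,
    duration: float = 10000.0,
    warmup: float = 500.0,
    seed: int = 0,
    pops: Optional[Sequence[str]] = None,
    null_rep: int = 10,
    with_null: bool = True,
) -> dict:
    """Run one simulation and compute per-population spectral scalars.

    Returns {population: {"rate", "mean_f", "mean_psd", "psd_dagger",
    "Q"}} over the requested populations (default: all non-auxiliary),
    measured on each population's fixed observer subsample.
    """
    raster = run_simulation(net, duration=duration, warmup=warmup, seed=seed)
    if pops is None:
        pops = [p.name for p in net.populations if not p.is_auxiliary]
    out = {}
    for nm in pops:
        series = bin_rates(raster, nm, subsample=net.observers[nm])
        spec = welch_psd(series)
        rec = {
            "rate": series.mean_rate,
            "mean_f": spec.mean_f,
            "mean_psd": spec.mean_psd,
        }
        if with_null:
            Q, _ = binomial_null(
                series.nu0, series.n_observed, duration,
                n_rep=null_rep, seed=seed,
            )
            rec["Q"] = Q
            rec["psd_dagger"] = corrected_beta_psd(spec, Q)
        out[nm] = rec
    out["_raster"] = raster
    return out


# ----------------------------------------------------------------------
# ablation screen


@dataclass
class AblationResult:
    """Residual beta power after replacing one connection by its
    rate-matched surrogate."""

    source: str
    target: str
    R: float
    selected: bool          # R < R_BAR
    borderline: bool = False  # |R - R_BAR| within 1 SD of the estimate
    R_sd: float = float("nan")


def _ablated_network(conn: ConnectionSpec, aux_I_e: float, config: ModelConfig) -> Network:
    """Complete Model with conn replaced by an externally driven copy.

    The auxiliary population S* has the size, neuron model and external
    drive of S, no recurrent inputs, and a calibrated I_e; S -> T is
    removed and S* -> T added with the same probability and weight.
    """
    t = complete_tables()
    aux_name = conn.source + "*"
    sizes = dict(t["sizes"])
    sizes[aux_name] = sizes[conn.source]
    params = dict(t["params"])
    params[aux_name] = params[conn.source].with_(I_e=aux_I_e)
    conns = [
        c for c in t["connections"]
        if not (c.source == conn.source and c.target == conn.target)
    ]
    conns.append(
        ConnectionSpec(aux_name, conn.target, conn.p, conn.delay, conn.sign, conn.weight)
    )
    src_drive = next(d for d in t["drives"] if d.population == conn.source)
    drives = t["drives"] + [
        PoissonDrive(aux_name, src_drive.rate, src_drive.weight, src_drive.dev)
    ]
    order = ["D1", "D2", "FSN", "GPTA", "GPTI", "STN", aux_name]
    net = _assemble(order, sizes, params, conns, drives, config.seed, 1,
                    dict(t["sizes"], **{aux_name: sizes[aux_name]}),
                    aux_names=(aux_name,))
    from .builders import apply_dopamine
    apply_dopamine(net, config.D_d)
    return net


def ablation_screen(
    config: ModelConfig,
    duration: float = 5000.0,
    warmup: float = 500.0,
    seeds: Sequence[int] = (0,),
    R_bar: float = R_BAR,
    connections: Optional[Sequence[tuple]] = None,
    aux_mode: str = "rate_matched",
    calibration_tol: float = 1.0,
    baseline: Optional[tuple] = None,
) -> list[AblationResult]:
    """Screen every non-self internal connection for beta-band relevance.

    For each connection S -> T, the S -> T synapses are replaced by
    synapses from a rate-matched but oscillation-free surrogate S*, and

        R(S->T) = sum_p Mean beta PSD_p (surrogate) /
                  sum_p Mean beta PSD_p (intact)

    is computed over the real populations p.  Connections with R < R_bar
    are flagged as beta generators; self-inhibition rows are excluded
    from the screen.  ``aux_mode='identity'`` short-circuits the
    replacement (numerator simulation = denominator simulation), a
    plumbing check that must give R = 1 exactly.
    """
    t = complete_tables()
    screened = [
        c for c in t["connections"]
        if c.source != c.target
        and (connections is None or (c.source, c.target) in set(connections))
    ]

    # denominator: intact model, one Welch mean-PSD sum per seed; a
    # caller that already holds an intact-model measurement under the
    # identical protocol may pass it as `baseline` (sums, mean_rates)
    if baseline is not None:
        base_sums, mean_rates = np.asarray(baseline[0]), dict(baseline[1])
    else:
        base_sums, base_rates = [], {}
        for si in seeds:
            cfg = replace(config, seed=config.seed + si)
            net = build_model(cfg)
            m = measure_populations(net, duration, warmup, seed=cfg.seed,
                                    with_null=False)
            base_sums.append(sum(m[nm]["mean_psd"] for nm in t["sizes"]))
            for nm in t["sizes"]:
                base_rates.setdefault(nm, []).append(m[nm]["rate"])
        base_sums = np.array(base_sums)
        mean_rates = {nm: float(np.mean(v)) for nm, v in base_rates.items()}

    results = []
    aux_cache: dict[str, float] = {}
    for conn in screened:
        if aux_mode == "identity":
            ratios = []
            for si, den in zip(seeds, base_sums):
                cfg = replace(config, seed=config.seed + si)
                net = build_model(cfg)
                m = measure_populations(net, duration, warmup, seed=cfg.seed,
                                        with_null=False)
                num = sum(m[nm]["mean_psd"] for nm in t["sizes"])
                ratios.append(num / den)
        else:
            if conn.source not in aux_cache:
                src_drive = next(
                    d for d in t["drives"] if d.population == conn.source
                )
                target = mean_rates[conn.source]
                if conn.source == "D2":
                    # the D2 surrogate drive also carries the dopamine factor
                    src_drive = PoissonDrive(
                        src_drive.population, src_drive.rate * config.D_d,
                        src_drive.weight, src_drive.dev,
                    )
                ie, _ = calibrate_auxiliary(
                    t["params"][conn.source], src_drive, target,
                    tolerance=calibration_tol, seed=config.seed,
                )
                aux_cache[conn.source] = ie
            ratios = []
            for si, den in zip(seeds, base_sums):
                cfg = replace(config, seed=config.seed + si)
                net = _ablated_network(conn, aux_cache[conn.source], cfg)
                m = measure_populations(
                    net, duration, warmup, seed=cfg.seed,
                    pops=list(t["sizes"]), with_null=False,
                )
                num = sum(m[nm]["mean_psd"] for nm in t["sizes"])
                ratios.append(num / den)
        ratios = np.array(ratios)
        R = float(ratios.mean())
        sd = float(ratios.std(ddof=1)) if ratios.size > 1 else float("nan")
        results.append(
            AblationResult(
                conn.source, conn.target, R,
                selected=R < R_bar,
                borderline=(abs(R - R_bar) <= sd) if np.isfinite(sd) else False,
                R_sd=sd,
            )
        )
    return results


# ----------------------------------------------------------------------
# parameter sweeps


@dataclass
class SweepResult:
    """Aggregated scalars of one knob sweep."""

    knob: str
    values: list
    table: pd.DataFrame       # one row per (value, population)

    def series(self, population: str, column: str) -> np.ndarray:
        sub = self.table[self.table["population"] == population]
        return sub.sort_values("value")[column].to_numpy()


_KNOBS = ("D_d", "epsilon", "n", "kappa")


def sweep(
    knob: str,
    values: Iterable[float],
    config: ModelConfig,
    seeds: int = 4,
    duration: float = 10000.0,
    warmup: float = 500.0,
    pops: Sequence[str] = ("STN", "D2"),
    null_rep: int = 10,
) -> SweepResult:
    """Simulate the model over a knob grid and aggregate beta scalars.

    For each knob value, ``seeds`` independent simulations (fresh wiring
    and noise) are run; reported columns are mean and SD across seeds of
    the population rate, Eq-style mean frequency and corrected beta power
    PSD†.
    """
    if knob not in _KNOBS:
        raise ValueError(f"knob must be one of {_KNOBS}")
    rows = []
    values = list(values)
    for v in values:
        per_seed = {nm: {"rate": [], "mean_f": [], "psd_dagger": []} for nm in pops}
        for si in range(seeds):
            cfg = _with_knob(config, knob, v, si)
            net = build_model(cfg)
            m = measure_populations(
                net, duration, warmup, seed=cfg.seed, pops=pops, null_rep=null_rep
            )
            for nm in pops:
                for col in per_seed[nm]:
                    per_seed[nm][col].append(m[nm][col])
        for nm in pops:
            row = {"value": v, "population": nm}
            for col, vals in per_seed[nm].items():
                arr = np.asarray(vals, dtype=float)
                row[col] = float(np.nanmean(arr))
                row[col + "_sd"] = (
                    float(np.nanstd(arr, ddof=1)) if arr.size > 1 else float("nan")
                )
            rows.append(row)
    return SweepResult(knob, values, pd.DataFrame(rows))


def _with_knob(config: ModelConfig, knob: str, value, seed_index: int) -> ModelConfig:
    cfg = replace(config, seed=config.seed + seed_index)
    if knob == "D_d":
        return replace(cfg, D_d=float(value))
    if knob == "epsilon":
        return replace(cfg, epsilon=float(value))
    if knob == "n":
        return replace(cfg, n=int(value))
    # kappa: STN drive modulation on top of the configured baseline
    return replace(cfg, opto=OptoPerturbation("stn_modulation", kappa=float(value)))


def size_limit_analysis(
    config: ModelConfig,
    n_values: Sequence[int] = (1, 2, 4, 8),
    **sweep_kwargs,
) -> SweepResult:
    """PSD† versus population-size multiplier n.

    Observers stay fixed at the n = 1 population sizes, so spectra are
    comparable across n; in unsynchronized regimes the corrected beta
    power decays toward the shot-noise level as n grows, while in
    synchronized regimes it is preserved.
    """
    return sweep("n", list(n_values), config, **sweep_kwargs)


# ----------------------------------------------------------------------
# optogenetic validation battery


def opto_battery(
    config: Optional[ModelConfig] = None,
    duration: float = 10000.0,
    warmup: float = 500.0,
    seeds: int = 1,
    kappas: Sequence[float] = (0.65, 1.0, 1.35, 1.7),
    low_Dd: float = 0.90,
    null_rep: int = 10,
) -> dict:
    """ON/OFF comparison of the three optogenetic-style perturbations.

    OFF is the pathological Complete Model (D_d = 1.03).  Reports, per
    perturbation, the STN rate change (percent) and the STN beta PSD†,
    plus a low-D_d reference PSD† band against which "suppression" is
    judged, and a PSD†-versus-rate curve for the STN drive modulation
    kappa in [0.65, 1.7].
    """
    if config is None:
        config = ModelConfig(variant="complete", D_d=1.03)

    def run_case(opto, D_d=None, extra_pops=()):
        recs = []
        for si in range(seeds):
            cfg = replace(
                config,
                D_d=config.D_d if D_d is None else D_d,
                opto=opto,
                seed=config.seed + si,
            )
            net = build_model(cfg)
            m = measure_populations(
                net, duration, warmup, seed=cfg.seed,
                pops=("STN",) + tuple(extra_pops), null_rep=null_rep,
            )
            m.pop("_raster")
            recs.append(m)
        agg = {}
        for nm in recs[0]:
            agg[nm] = {
                k: float(np.mean([r[nm][k] for r in recs]))
                for k in recs[0][nm]
            }
        return agg

    off = run_case(None, extra_pops=("GPTA", "GPTI"))
    cortex = run_case(OptoPerturbation("cortex_inhibition"))
    gpe = run_case(OptoPerturbation("gpe_inhibition"), extra_pops=("GPTA", "GPTI"))
    low = run_case(None, D_d=low_Dd)

    kappa_rows = []
    for k in kappas:
        on = run_case(OptoPerturbation("stn_modulation", kappa=k))
        kappa_rows.append(
            {"kappa": k, "stn_rate": on["STN"]["rate"],
             "psd_dagger": on["STN"]["psd_dagger"]}
        )

    def pct(on, ref):
        return 100.0 * (on - ref) / ref

    return {
        "off": off,
        "low_Dd_reference": low,
        "cortex_inhibition": {
            **cortex,
            "stn_rate_change_pct": pct(cortex["STN"]["rate"], off["STN"]["rate"]),
        },
        "gpe_inhibition": {
            **gpe,
            "stn_rate_change_pct": pct(gpe["STN"]["rate"], off["STN"]["rate"]),
        },
        "kappa_sweep": pd.DataFrame(kappa_rows),
    }


# ----------------------------------------------------------------------
# beta-burst analysis


def burst_analysis(
    config: Optional[ModelConfig] = None,
    D_d: float = 0.90,
    duration: float = 10000.0,
    warmup: float = 500.0,
    seeds: int = 1,
    window: float = 2000.0,
    step: float = 500.0,
) -> dict:
    """Time-resolved beta dynamics at one dopamine-depletion level.

    Computes the STN spectrogram, the instantaneous frequency difference
    Delta f(t) = f_STN(t) - f_D2(t) with its median, the instantaneous
    STN beta power with its median, the sample skewness of the windowed
    beta-power distribution (per seed and pooled), and the fraction of
    windows in which below-median Delta f coincides with above-median
    beta power (the synchrony/intensity anti-correlation).
    """
    if config is None:
        config = ModelConfig(variant="complete")
    per_seed_skew, pooled_power = [], []
    traces = []
    for si in range(seeds):
        cfg = replace(config, D_d=D_d, seed=config.seed + si)
        net = build_model(cfg)
        raster = run_simulation(net, duration=duration, warmup=warmup, seed=cfg.seed)
        stn = time_resolved(
            bin_rates(raster, "STN", net.observers["STN"]), window, step
        )
        d2 = time_resolved(
            bin_rates(raster, "D2", net.observers["D2"]), window, step
        )
        delta_f = stn["mean_f"] - d2["mean_f"]
        beta_p = stn["beta_psd"]
        per_seed_skew.append(beta_power_skewness(beta_p))
        pooled_power.extend(beta_p.tolist())
        traces.append(
            {"times": stn["times"], "delta_f": delta_f, "beta_psd": beta_p,
             "spectrogram": stn["spectrogram"], "freqs": stn["freqs"]}
        )

    delta_all = np.concatenate([t["delta_f"] for t in traces])
    beta_all = np.concatenate([t["beta_psd"] for t in traces])
    low_df = delta_all < np.nanmedian(delta_all)
    high_bp = beta_all > np.nanmedian(beta_all)
    match_frac = float(np.mean(low_df == high_bp))

    return {
        "D_d": D_d,
        "traces": traces,
        "median_delta_f": float(np.nanmedian(delta_all)),
        "median_beta_psd": float(np.nanmedian(beta_all)),
        "skewness_per_seed": per_seed_skew,
        "skewness_mean": float(np.nanmean(per_seed_skew)),
        "skewness_pooled": beta_power_skewness(np.asarray(pooled_power)),
        "sync_power_match_fraction": match_frac,
    }
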