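"""Experiment configuration, dispatch, seeding and artifact serialization.

A :class:`RunConfig` is a schema-validated flat mapping (YAML or JSON on
disk) naming an experiment type plus its parameters.  ``run_experiment``
dispatches to the library, writes delimited-text/JSON/MTX artifacts and a
manifest recording the seed, package version and config hash.  A single
global seed is expanded into independent per-component seeds through a
counter-based SeedSequence scheme so that runs are reproducible without
correlated streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model_core import (
    ADAPTATION,
    SYNAPTIC,
    NoiseParams,
    TransferParams,
    UnitParams,
)
from .connectivity import (
    ConnectivitySpec,
    build_connectivity,
    save_connectivity,
    spectrum_summary,
)
from .single_unit import (
    filter_timescale,
    unit_filter,
    white_noise_variance_gain,
)
from .meanfield import popavg_stability
from .stability import critical_radius
from .simulator import population_average, simulate
from .dmft import dmft_solve
from .analysis import envelope_timescale, rate_autocorrelation

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_experiment", "make_fixtures", "component_seed"]

EXPERIMENTS = (
    "connectivity",
    "filters",
    "phase-diagram-popavg",
    "phase-diagram-hetero",
    "simulate",
    "dmft",
    "timescale",
)

# permissible keys per experiment, beyond the common ones
_COMMON_KEYS = {"experiment", "seed", "out_dir"}
_KEYS: dict[str, set[str]] = {
    "connectivity": {"N", "C_E", "C_I", "J", "g", "allow_self", "spectrum"},
    "filters": {"mechanism", "tau_m", "tau_w", "g_w", "tau_s", "t_max", "dt"},
    "phase-diagram-popavg": {
        "mechanism", "tau_m", "tau_w", "tau_s", "gw_grid", "jeff_grid",
    },
    "phase-diagram-hetero": {
        "mechanism", "tau_m", "tau_s", "gw_grid", "tauw_grid", "taus_grid",
    },
    "simulate": {
        "mechanism", "tau_m", "tau_w", "g_w", "tau_s", "gamma", "phi_max",
        "N", "C_E", "C_I", "g", "radius", "J", "sigma_eta", "T", "dt",
        "record_every",
    },
    "dmft": {
        "mechanism", "tau_m", "tau_w", "g_w", "tau_s", "gamma", "phi_max",
        "J_eff", "J_cs", "sigma_eta", "alpha", "tol", "max_iter", "T", "dt",
        "trials", "max_lag",
    },
    "timescale": {"autocorr_csv", "column"},
}


@dataclass(frozen=True)
class RunConfig:
    """Validated experiment configuration."""

    experiment: str
    options: dict
    seed: int = 0
    out_dir: str = "."

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        exp = raw.pop("experiment", None)
        if exp not in EXPERIMENTS:
            raise ValueError(
                f"experiment must be one of {EXPERIMENTS}, got {exp!r}"
            )
        seed = int(raw.pop("seed", 0))
        out_dir = str(raw.pop("out_dir", "."))
        unknown = set(raw) - _KEYS[exp]
        if unknown:
            raise ValueError(
                f"unknown keys for experiment {exp!r}: {sorted(unknown)}"
            )
        return cls(experiment=exp, options=raw, seed=seed, out_dir=out_dir)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = (
                json.load(fh)
                if path.suffix == ".json"
                else yaml.safe_load(fh)
            )
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} does not hold a mapping")
        return cls.from_mapping(raw)

    def to_mapping(self) -> dict:
        out = {"experiment": self.experiment, "seed": self.seed,
               "out_dir": self.out_dir}
        out.update(self.options)
        return out

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_mapping(), fh, indent=2, sort_keys=True)
            else:
                yaml.safe_dump(self.to_mapping(), fh, sort_keys=True)


def component_seed(seed: int, component: str) -> int:
    """Stable per-component child seed derived from the global seed."""
    h = int(hashlib.sha256(component.encode()).hexdigest()[:8], 16)
    child = np.random.SeedSequence(entropy=seed, spawn_key=(h,))
    return int(child.generate_state(1)[0] % (2**31))


def _unit_params(opts: dict) -> UnitParams:
    tf = TransferParams(
        gamma=float(opts.get("gamma", -0.5)),
        phi_max=float(opts.get("phi_max", 2.0)),
    )
    mech = opts.get("mechanism", SYNAPTIC)
    kw: dict[str, Any] = {"tau_m": float(opts.get("tau_m", 1.0)),
                          "mechanism": mech, "transfer": tf}
    if mech == ADAPTATION:
        kw["tau_w"] = float(opts.get("tau_w", 5.0))
        kw["g_w"] = float(opts.get("g_w", 0.5))
    else:
        kw["tau_s"] = float(opts.get("tau_s", 5.0))
    return UnitParams(**kw)


def run_experiment(config: RunConfig) -> dict:
    """Dispatch a configured experiment and write its artifacts.

    Returns the manifest (also written to ``manifest.json`` in the output
    directory): experiment, seed, package version, config hash and the
    produced file names.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    opts = config.options
    produced: list[str] = []

    if config.experiment == "connectivity":
        spec = ConnectivitySpec(
            N=int(opts.get("N", 3000)),
            C_E=int(opts.get("C_E", 80)),
            C_I=int(opts.get("C_I", 20)),
            J=float(opts.get("J", 1.0)),
            g=float(opts.get("g", 4.1)),
            seed=component_seed(config.seed, "connectivity"),
            allow_self=bool(opts.get("allow_self", False)),
        )
        W = build_connectivity(spec)
        save_connectivity(W, out_dir / "W.mtx")
        produced += ["W.mtx", "W.json"]
        if opts.get("spectrum", False):
            summ = spectrum_summary(W)
            pd.DataFrame(
                {
                    "re": summ["eigenvalues"].real,
                    "im": summ["eigenvalues"].imag,
                }
            ).to_csv(out_dir / "spectrum.csv", index=False)
            produced.append("spectrum.csv")

    elif config.experiment == "filters":
        params = _unit_params(opts)
        h = unit_filter(params)
        t_max = float(opts.get("t_max", 20.0 * params.tau_slow))
        dt = float(opts.get("dt", 0.01 * params.tau_m))
        t = np.arange(0.0, t_max, dt)
        pd.DataFrame({"t": t, "h": h(t)}).to_csv(
            out_dir / "filter.csv", index=False
        )
        summary = {
            "tau_corr": filter_timescale(h),
            "variance_gain": white_noise_variance_gain(h),
            "area": h.area,
        }
        (out_dir / "filter_summary.json").write_text(
            json.dumps(summary, indent=2) + "\n"
        )
        produced += ["filter.csv", "filter_summary.json"]

    elif config.experiment == "phase-diagram-popavg":
        params0 = _unit_params(opts)
        jeffs = [float(v) for v in opts.get("jeff_grid", [])]
        rows = []
        if params0.mechanism == ADAPTATION:
            gws = [float(v) for v in opts.get("gw_grid", [params0.g_w])]
            for gw in gws:
                p = UnitParams(
                    tau_m=params0.tau_m, mechanism=ADAPTATION,
                    tau_w=params0.tau_w, g_w=gw, transfer=params0.transfer,
                )
                for je in jeffs:
                    rep = popavg_stability(p, je)
                    rows.append(
                        {"g_w": gw, "J_eff": je,
                         "classification": rep.classification,
                         **{f"crit_{k}": v
                            for k, v in rep.critical_couplings.items()}}
                    )
        else:
            for je in jeffs:
                rep = popavg_stability(params0, je)
                rows.append(
                    {"J_eff": je, "classification": rep.classification,
                     **{f"crit_{k}": v
                        for k, v in rep.critical_couplings.items()}}
                )
        pd.DataFrame(rows).to_csv(out_dir / "popavg_diagram.csv", index=False)
        produced.append("popavg_diagram.csv")

    elif config.experiment == "phase-diagram-hetero":
        mech = opts.get("mechanism", ADAPTATION)
        tau_m = float(opts.get("tau_m", 1.0))
        rows = []
        if mech == ADAPTATION:
            for gw in [float(v) for v in opts.get("gw_grid", [0.5])]:
                for tw in [float(v) for v in opts.get("tauw_grid", [5.0])]:
                    p = UnitParams(
                        tau_m=tau_m, mechanism=ADAPTATION, tau_w=tw, g_w=gw
                    )
                    rep = critical_radius(ADAPTATION, p)
                    rows.append(
                        {"g_w": gw, "tau_w": tw,
                         "R_star": rep.critical_radius,
                         "omega_star": rep.critical_frequency,
                         "bifurcation": rep.bifurcation}
                    )
        else:
            for ts_ in [float(v) for v in opts.get("taus_grid", [5.0])]:
                p = UnitParams(tau_m=tau_m, mechanism=SYNAPTIC, tau_s=ts_)
                rep = critical_radius(SYNAPTIC, p)
                rows.append(
                    {"tau_s": ts_, "R_star": rep.critical_radius,
                     "omega_star": rep.critical_frequency,
                     "bifurcation": rep.bifurcation}
                )
        pd.DataFrame(rows).to_csv(out_dir / "hetero_diagram.csv", index=False)
        produced.append("hetero_diagram.csv")

    elif config.experiment == "simulate":
        params = _unit_params(opts)
        from .connectivity import radius_to_J

        C_E = int(opts.get("C_E", 80))
        C_I = int(opts.get("C_I", 20))
        g = float(opts.get("g", 4.1))
        J = (
            radius_to_J(float(opts["radius"]), C_E, C_I, g)
            if "radius" in opts
            else float(opts.get("J", 0.05))
        )
        spec = ConnectivitySpec(
            N=int(opts.get("N", 400)), C_E=C_E, C_I=C_I, J=J, g=g,
            seed=component_seed(config.seed, "connectivity"),
        )
        W = build_connectivity(spec)
        noise = NoiseParams(
            sigma_eta=float(opts.get("sigma_eta", 0.0)),
            seed=component_seed(config.seed, "simulate"),
        )
        traj = simulate(
            W, params, noise,
            T=float(opts.get("T", 100.0)),
            dt=float(opts.get("dt", 0.05 * params.tau_m)),
            record_every=int(opts.get("record_every", 1)),
        )
        np.savez(
            out_dir / "trajectory.npz",
            times=traj.times, x=traj.x, hidden=traj.hidden,
        )
        pd.DataFrame(
            {"t": traj.times, "pop_rate": population_average(traj)}
        ).to_csv(out_dir / "population_rate.csv", index=False)
        produced += ["trajectory.npz", "population_rate.csv"]

    elif config.experiment == "dmft":
        params = _unit_params(opts)
        state = dmft_solve(
            params,
            J_eff=float(opts.get("J_eff", -2.0)),
            J_cs=float(opts.get("J_cs", 1.2)),
            sigma_eta=float(opts.get("sigma_eta", 0.0)),
            alpha=float(opts.get("alpha", 0.6)),
            max_iter=int(opts.get("max_iter", 40)),
            T=(float(opts["T"]) if "T" in opts else None),
            dt=float(opts.get("dt", 0.05)),
            trials=int(opts.get("trials", 100)),
            seed=component_seed(config.seed, "dmft"),
            max_lag=(float(opts["max_lag"]) if "max_lag" in opts else None),
        )
        est = state.estimate
        ts_res = envelope_timescale(est.C, float(est.lags[1] - est.lags[0]))
        env = ts_res.envelope
        pd.DataFrame(
            {"lag": est.lags, "Delta": est.Delta, "C": est.C,
             "envelope": env if env is not None else np.nan}
        ).to_csv(out_dir / "autocorr.csv", index=False)
        summary = {
            "converged": state.converged,
            "iterations": state.iterations,
            "mu": est.mu,
            "mean_rate": est.mean_rate,
            "rate_variance": state.rate_variance,
            "tau_corr": ts_res.tau_corr if ts_res.success else None,
        }
        (out_dir / "state.json").write_text(
            json.dumps(summary, indent=2) + "\n"
        )
        produced += ["autocorr.csv", "state.json"]

    elif config.experiment == "timescale":
        df = pd.read_csv(opts["autocorr_csv"])
        col = opts.get("column", "C")
        dt = float(df["lag"].iloc[1] - df["lag"].iloc[0])
        res = envelope_timescale(df[col].to_numpy(), dt)
        (out_dir / "timescale.json").write_text(
            json.dumps(
                {"tau_corr": res.tau_corr, "method": res.method,
                 "success": res.success},
                indent=2,
            )
            + "\n"
        )
        produced.append("timescale.json")

    cfg_map = config.to_mapping()
    manifest = {
        "experiment": config.experiment,
        "seed": config.seed,
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_map, sort_keys=True).encode()
        ).hexdigest(),
        "files": produced,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info("experiment %s wrote %s", config.experiment, produced)
    return manifest


def make_fixtures(out_dir: Union[str, Path], seed: int = 0) -> dict:
    """Small deterministic fixtures for tests and demos.

    Writes an N=50 connectivity matrix (MTX + JSON sidecar) and a
    500-step synaptic-network trajectory (population rate as CSV).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = ConnectivitySpec(
        N=50, C_E=8, C_I=2, J=0.1, g=4.1,
        seed=component_seed(seed, "fixture-connectivity"),
    )
    W = build_connectivity(spec)
    save_connectivity(W, out_dir / "fixture_W.mtx")
    params = UnitParams(mechanism=SYNAPTIC, tau_s=2.0)
    noise = NoiseParams(
        sigma_eta=0.1, seed=component_seed(seed, "fixture-sim")
    )
    traj = simulate(W, params, noise, T=25.0, dt=0.05)
    pd.DataFrame(
        {"t": traj.times, "pop_rate": population_average(traj)}
    ).to_csv(out_dir / "fixture_pop_rate.csv", index=False)
    return {
        "connectivity": str(out_dir / "fixture_W.mtx"),
        "trajectory": str(out_dir / "fixture_pop_rate.csv"),
    }
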