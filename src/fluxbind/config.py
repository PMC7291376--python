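"""Run configuration, file formats, and the pipeline entry points.

A run is described by a single YAML (or JSON) file with four sections --
``system``, ``basins``, ``resampler`` and ``run`` -- plus a mandatory top
level ``seed``.  All outputs are delimited text: exit points, per-cycle rate
series and basin occupancies as CSV (floats at 17 significant digits so
round-trips are exact), resampling decisions as JSON lines, and a manifest
with seeds, versions and content hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensembles import BasinSpec, ExitPoint
from .exceptions import ConfigurationError, InvalidInputError
from .freeenergy import BindingFreeEnergyModel, estimate_v_unbound
from .revo import ResamplerConfig
from .simulate import EnsembleRunResult, SplitEnsembleSimulation
from .toy_system import SystemState, ToySystemParams
from .units import UnitsContext

__all__ = [
    "RunSettings",
    "RunConfig",
    "load_and_validate_config",
    "run_pipeline",
    "corrections_report",
    "write_exit_points",
    "read_exit_points",
]

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class RunSettings:
    """Walker/cycle/replicate counts.  Defaults mirror the study protocol:
    48 walkers, 20 ps unbinding cycles, 200 ps rebinding cycles."""

    n_walkers: int = 48
    n_cycles_unbinding: int = 500
    n_cycles_rebinding: int = 100
    cycle_time_unbinding_ps: float = 20.0
    cycle_time_rebinding_ps: float = 200.0
    n_replicates_unbinding: int = 5
    n_replicates_rebinding: int = 5
    burn_in_cycles_unbinding: int = 50
    burn_in_cycles_rebinding: int = 15

    def __post_init__(self) -> None:
        problems = []
        if self.n_walkers < 2:
            problems.append("run.n_walkers must be >= 2")
        for name in ("n_cycles_unbinding", "n_cycles_rebinding",
                     "n_replicates_unbinding", "n_replicates_rebinding"):
            if getattr(self, name) < 1:
                problems.append(f"run.{name} must be >= 1")
        for name in ("cycle_time_unbinding_ps", "cycle_time_rebinding_ps"):
            if not getattr(self, name) > 0:
                problems.append(f"run.{name} must be > 0")
        for name in ("burn_in_cycles_unbinding", "burn_in_cycles_rebinding"):
            if getattr(self, name) < 0:
                problems.append(f"run.{name} must be >= 0")
        if self.burn_in_cycles_unbinding >= self.n_cycles_unbinding:
            problems.append("run.burn_in_cycles_unbinding must be < n_cycles_unbinding")
        if self.burn_in_cycles_rebinding >= self.n_cycles_rebinding:
            problems.append("run.burn_in_cycles_rebinding must be < n_cycles_rebinding")
        if problems:
            raise ConfigurationError("; ".join(problems))


@dataclass
class RunConfig:
    """Validated configuration for one experiment."""

    seed: int
    system: ToySystemParams
    basins: BasinSpec
    resampler: ResamplerConfig
    run: RunSettings
    output_dir: str = "fluxbind_out"

    @property
    def units(self) -> UnitsContext:
        return UnitsContext(temperature=self.system.temperature)


_SECTION_TYPES = {
    "system": ToySystemParams,
    "basins": BasinSpec,
    "resampler": ResamplerConfig,
    "run": RunSettings,
}


def load_and_validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON config, applying documented defaults.

    Validation is exhaustive: every failing field is reported in one
    ConfigurationError, not just the first.  The RNG seed is mandatory.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")

    errors: list[str] = []
    known = set(_SECTION_TYPES) | {"seed", "output_dir"}
    for key in raw:
        if key not in known:
            errors.append(f"unknown section or key: {key!r}")

    seed = raw.get("seed")
    if seed is None:
        errors.append("seed is required (reproducibility is mandatory)")
    elif not isinstance(seed, int) or isinstance(seed, bool) or seed < 0:
        errors.append(f"seed must be a non-negative integer, got {seed!r}")

    sections = {}
    for name, cls in _SECTION_TYPES.items():
        body = raw.get(name, {})
        if not isinstance(body, dict):
            errors.append(f"section {name!r} must be a mapping")
            continue
        valid_fields = set(cls.__dataclass_fields__)
        for key in body:
            if key not in valid_fields:
                errors.append(f"{name}.{key}: unknown field")
        body = {k: v for k, v in body.items() if k in valid_fields}
        if name == "system" and "box_lengths" in body:
            body["box_lengths"] = np.asarray(body["box_lengths"], dtype=float)
        try:
            sections[name] = cls(**body)
        except (InvalidInputError, ConfigurationError, TypeError) as exc:
            errors.append(f"{name}: {exc}")

    if "system" in sections and "basins" in sections:
        try:
            sections["basins"].validate_against(sections["system"])
        except InvalidInputError as exc:
            errors.append(f"basins: {exc}")

    if errors:
        raise ConfigurationError(
            f"invalid configuration {path}: " + "; ".join(errors)
        )
    return RunConfig(
        seed=int(seed),
        system=sections["system"],
        basins=sections["basins"],
        resampler=sections["resampler"],
        run=sections["run"],
        output_dir=str(raw.get("output_dir", "fluxbind_out")),
    )


# -- file formats ------------------------------------------------------------

def write_exit_points(path: Path, result: EnsembleRunResult) -> None:
    rows = [
        {
            "replicate": result.replicate_id,
            "ensemble": result.ensemble,
            "cycle": ep.cycle_index,
            "elapsed_time_ps": ep.elapsed_time,
            "weight": ep.weight,
            "x": ep.snapshot.position[0],
            "y": ep.snapshot.position[1],
            "z": ep.snapshot.position[2],
        }
        for ep in result.ledger.exit_points
    ]
    cols = ["replicate", "ensemble", "cycle", "elapsed_time_ps", "weight", "x", "y", "z"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_exit_points(path: Path) -> list[ExitPoint]:
    df = pd.read_csv(path)
    points = []
    for row in df.itertuples(index=False):
        points.append(
            ExitPoint(
                weight=float(row.weight),
                cycle_index=int(row.cycle),
                elapsed_time=float(row.elapsed_time_ps),
                source_ensemble=str(row.ensemble),
                snapshot=SystemState(
                    np.array([row.x, row.y, row.z], dtype=float), np.zeros(3)
                ),
            )
        )
    return points


def _write_rates(path: Path, result: EnsembleRunResult) -> None:
    col = "k_off_s" if result.ensemble == "unbinding" else "k_on_Ms"
    pd.DataFrame(
        {
            "cycle": np.arange(len(result.cycle_times_ps)),
            "time_ps": result.cycle_times_ps,
            col: result.rate_series_per_cycle,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_occupancy(path: Path, result: EnsembleRunResult) -> None:
    col = "f_b" if result.ensemble == "unbinding" else "f_u"
    pd.DataFrame(
        {
            "cycle": np.arange(len(result.cycle_times_ps)),
            "time_ps": result.cycle_times_ps,
            col: result.basin_fraction_series,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_energies(path: Path, result: EnsembleRunResult) -> None:
    pd.DataFrame(result.eint_samples, columns=["energy_kcal_mol", "weight"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def _write_resampling_log(path: Path, result: EnsembleRunResult) -> None:
    with open(path, "w") as fh:
        for cyc, dec in result.decisions:
            fh.write(json.dumps({
                "cycle": int(cyc),
                "cloned": [[int(a), int(b)] for a, b in dec.cloned],
                "merged": [[int(a), int(b)] for a, b in dec.merged],
                "variation_before": dec.variation_before,
                "variation_after": dec.variation_after,
            }) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _replicate_rng(seed: int, stream: int, replicate: int) -> np.random.Generator:
    # independent, order-insensitive streams per (purpose, replicate)
    return np.random.default_rng([seed, stream, replicate])


def run_pipeline(config: RunConfig, mode: str, output_dir: str | Path | None = None) -> Path:
    """Run all replicates of one ensemble mode and write the artifact directory.

    ``mode`` is 'unbinding' or 'rebinding'.  Rebinding requires the unbinding
    exit-point files to exist already in the output directory.  Reruns with
    the same seed are bit-identical; completed replicates listed in the
    checkpoint file are skipped on resume.
    """
    if mode not in ("unbinding", "rebinding"):
        raise InvalidInputError(f"mode must be 'unbinding' or 'rebinding', got {mode!r}")
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = config.run
    n_reps = (s.n_replicates_unbinding if mode == "unbinding"
              else s.n_replicates_rebinding)
    n_cycles = (s.n_cycles_unbinding if mode == "unbinding" else s.n_cycles_rebinding)
    cycle_ps = (s.cycle_time_unbinding_ps if mode == "unbinding"
                else s.cycle_time_rebinding_ps)
    burn_in = (s.burn_in_cycles_unbinding if mode == "unbinding"
               else s.burn_in_cycles_rebinding)
    cycle_steps = max(int(round(cycle_ps / config.system.timestep)), 1)
    stream = 0 if mode == "unbinding" else 1

    exit_pool = None
    if mode == "rebinding":
        files = sorted(out.glob("unbinding_rep*_exits.csv"))
        if not files:
            raise InvalidInputError(
                "rebinding requires unbinding exit points: run "
                "`fluxbind run-unbinding` into the same output directory first"
            )
        exit_pool = [ep for f in files for ep in read_exit_points(f)]
        if not exit_pool:
            raise InvalidInputError("unbinding exit-point files contain no events")

    ckpt_path = out / f"checkpoint_{mode}.json"
    done: list[int] = []
    if ckpt_path.exists():
        done = json.loads(ckpt_path.read_text()).get("completed", [])

    sim = SplitEnsembleSimulation(config.system, config.basins, config.resampler,
                                  n_walkers=s.n_walkers)
    files_written: list[Path] = []
    for rep in range(n_reps):
        prefix = out / f"{mode}_rep{rep}"
        outputs = [Path(f"{prefix}_exits.csv"), Path(f"{prefix}_rates.csv"),
                   Path(f"{prefix}_occupancy.csv"), Path(f"{prefix}_resampling.jsonl")]
        if mode == "rebinding":
            outputs.append(Path(f"{prefix}_energies.csv"))
        if rep in done and all(p.exists() for p in outputs):
            files_written.extend(outputs)
            continue
        rng = _replicate_rng(config.seed, stream, rep)
        if mode == "unbinding":
            result = sim.run_unbinding(n_cycles, cycle_steps, rng,
                                       burn_in_cycles=burn_in, replicate_id=rep)
        else:
            result = sim.run_rebinding(n_cycles, cycle_steps, rng,
                                       unbinding_exit_points=exit_pool,
                                       burn_in_cycles=burn_in, replicate_id=rep)
        write_exit_points(outputs[0], result)
        _write_rates(outputs[1], result)
        _write_occupancy(outputs[2], result)
        _write_resampling_log(outputs[3], result)
        if mode == "rebinding":
            _write_energies(outputs[4], result)
        files_written.extend(outputs)
        done.append(rep)
        ckpt_path.write_text(json.dumps({"completed": sorted(set(done))}))

    from . import __version__

    manifest = {
        "mode": mode,
        "seed": config.seed,
        "fluxbind_version": __version__,
        "numpy_version": np.__version__,
        "n_replicates": n_reps,
        "n_cycles": n_cycles,
        "cycle_time_ps": cycle_ps,
        "n_walkers": s.n_walkers,
        "files": {p.name: _sha256(p) for p in files_written},
    }
    (out / f"manifest_{mode}.json").write_text(json.dumps(manifest, indent=2))
    return out


def _steady_rate(exits_path: Path, total_time_ps: float, burn_in_ps: float,
                 concentration: float | None) -> float:
    """Burn-in-excluded flux rate recomputed from an exit-point table."""
    from .units import PS_TO_S_RATE

    df = pd.read_csv(exits_path)
    late = df.loc[df["elapsed_time_ps"] > burn_in_ps, "weight"].sum()
    denom = concentration if concentration else 1.0
    return float(late / (total_time_ps - burn_in_ps) / denom * PS_TO_S_RATE)


def _mean_occupancy(path: Path, burn_in: int) -> float:
    df = pd.read_csv(path)
    col = "f_b" if "f_b" in df.columns else "f_u"
    return float(df[col].iloc[burn_in:].mean())


def corrections_report(
    config: RunConfig,
    output_dir: str | Path | None = None,
    n_volume_trials: int = 10000,
    n_volume_batches: int = 5,
) -> dict:
    """Assemble the corrected free energy from a completed pipeline directory.

    Reads the per-replicate rate, occupancy and energy files, estimates
    V_unbound/V_box by Monte Carlo, fits the free-energy model and writes
    ``report.json`` plus a human-readable ``report.txt`` table.
    """
    out = Path(output_dir or config.output_dir)
    unb_rates = sorted(out.glob("unbinding_rep*_rates.csv"))
    reb_rates = sorted(out.glob("rebinding_rep*_rates.csv"))
    if not unb_rates or not reb_rates:
        raise InvalidInputError(
            f"{out}: need completed unbinding and rebinding runs before corrections"
        )
    from .units import concentration_from_volume

    s = config.run
    conc = concentration_from_volume(config.system.volume)
    t_unb = s.n_cycles_unbinding * s.cycle_time_unbinding_ps
    t_reb = s.n_cycles_rebinding * s.cycle_time_rebinding_ps
    koff = np.array([
        _steady_rate(p, t_unb,
                     s.burn_in_cycles_unbinding * s.cycle_time_unbinding_ps, None)
        for p in sorted(out.glob("unbinding_rep*_exits.csv"))
    ])
    kon = np.array([
        _steady_rate(p, t_reb,
                     s.burn_in_cycles_rebinding * s.cycle_time_rebinding_ps, conc)
        for p in sorted(out.glob("rebinding_rep*_exits.csv"))
    ])
    fb = np.array([
        _mean_occupancy(p, s.burn_in_cycles_unbinding)
        for p in sorted(out.glob("unbinding_rep*_occupancy.csv"))
    ])
    fu = np.array([
        _mean_occupancy(p, s.burn_in_cycles_rebinding)
        for p in sorted(out.glob("rebinding_rep*_occupancy.csv"))
    ])
    energies = [pd.read_csv(p).to_numpy()
                for p in sorted(out.glob("rebinding_rep*_energies.csv"))]
    eint = np.vstack([e for e in energies if e.size]) if energies else np.empty((0, 2))

    v_rng = _replicate_rng(config.seed, 2, 0)
    v_ratio, v_sem = estimate_v_unbound(config.system, config.basins, v_rng,
                                        n_trials=n_volume_trials,
                                        n_batches=n_volume_batches)

    def sem(a: np.ndarray) -> float:
        return float(np.std(a, ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0

    model = BindingFreeEnergyModel.from_tables(
        k_on=float(np.mean(kon)), k_off=float(np.mean(koff)),
        f_b=float(np.mean(fb)), f_u=float(np.mean(fu)),
        energies=eint, v_ratio=v_ratio, v_ratio_sem=v_sem,
        f_b_sem=sem(fb), f_u_sem=sem(fu),
        k_on_sem=sem(kon), k_off_sem=sem(koff),
        units=config.units,
    )
    results = model.fit()
    payload = results.to_dict()
    payload["k_on_Ms"] = float(np.mean(kon))
    payload["k_off_s"] = float(np.mean(koff))
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    (out / "report.txt").write_text(results.summary() + "\n")
    return payload
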