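"""Config files, report rendering, run manifests and the command line.

The config schema mirrors :class:`~scdsim.cohort_engine.SimulationConfig`
flattened to scalars (YAML or JSON); omitted keys take the published
defaults and unknown keys are rejected.  Every run writes its outputs
plus a manifest holding the fully resolved configuration, so any run
can be reproduced bit-identically from its manifest alone.
"""

from __future__ import annotations

import argparse
import dataclasses
import hashlib
import json
import logging
import sys
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .analytic_oracle import enumerate_expected_outcomes
from .cohort_engine import OutcomeTrajectory, SimulationConfig, simulate_cohort
from .risk_model import (
    InterventionParams,
    factor_contribution_table,
    load_risk_table,
)
from .scenarios import (
    adherence_sensitivity,
    dose_response,
    run_untreated_baseline,
    subgroup_stratification,
)

__all__ = [
    "ConfigError",
    "read_config",
    "config_to_dict",
    "config_from_manifest",
    "render_outcome_table",
    "write_manifest",
    "cli",
    "main",
]

log = logging.getLogger("scdsim")

#: Flat config keys mapped onto SimulationConfig / InterventionParams.
_CONFIG_KEYS = frozenset(
    {
        "n_patients",
        "years",
        "dropout_rate",
        "seed",
        "mode",
        "risk_table",
        "baseline_annual_risk",
        "pdt_rrr",
        "adherence_mix",
        "adherence_benefit",
        "max_total_reduction",
        "gate_factors_by_adherence",
    }
)
_PARAM_KEYS = frozenset(
    {
        "baseline_annual_risk",
        "pdt_rrr",
        "adherence_mix",
        "adherence_benefit",
        "max_total_reduction",
        "gate_factors_by_adherence",
    }
)


class ConfigError(ValueError):
    """Raised on schema violations in a simulation config file."""


def _build_config(data: dict, base_dir: Optional[Path] = None) -> SimulationConfig:
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    param_kwargs = {}
    for key in _PARAM_KEYS & set(data):
        value = data[key]
        if key in {"adherence_mix", "adherence_benefit"}:
            value = tuple(float(x) for x in value)
        param_kwargs[key] = value
    config_kwargs = {
        k: v for k, v in data.items() if k not in _PARAM_KEYS and k != "risk_table"
    }
    if "risk_table" in data:
        path = Path(data["risk_table"])
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        config_kwargs["table"] = load_risk_table(path)
    try:
        if param_kwargs:
            config_kwargs["params"] = InterventionParams(**param_kwargs)
        return SimulationConfig(**config_kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def read_config(path: Union[str, Path]) -> SimulationConfig:
    """Load a YAML or JSON config; omitted keys take the model defaults."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix.lower() not in {".json"} else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return _build_config(data, base_dir=path.parent)


def config_to_dict(config: SimulationConfig) -> dict:
    """Fully resolved flat representation of a config (manifest form)."""
    p = config.params
    return {
        "n_patients": config.n_patients,
        "years": config.years,
        "dropout_rate": config.dropout_rate,
        "seed": config.seed,
        "mode": config.mode.value,
        "baseline_annual_risk": p.baseline_annual_risk,
        "pdt_rrr": p.pdt_rrr,
        "adherence_mix": list(p.adherence_mix),
        "adherence_benefit": list(p.adherence_benefit),
        "max_total_reduction": p.max_total_reduction,
        "gate_factors_by_adherence": p.gate_factors_by_adherence,
        "risk_table_rows": [
            dataclasses.asdict(f) for f in config.table
        ],
    }


def _config_from_dict(data: dict) -> SimulationConfig:
    rows = data.pop("risk_table_rows")
    table_rows = [
        {
            "name": r["name"],
            "prevalence": r["prevalence"],
            "rrr": r["rrr"],
            "modifiable": r["modifiable"],
            "effectiveness": r["effectiveness"],
        }
        for r in rows
    ]
    data = dict(data)
    data.pop("risk_table", None)
    cfg = _build_config(data)
    return cfg.replace(table=load_risk_table(table_rows))


def config_from_manifest(path: Union[str, Path]) -> SimulationConfig:
    """Rebuild the exact configuration recorded in a run manifest."""
    manifest = json.loads(Path(path).read_text())
    return _config_from_dict(dict(manifest["config"]))


# ---------------------------------------------------------------------------
# Rendering


def _round_half_away(x: float, decimals: int = 0) -> float:
    scale = 10.0 ** decimals
    scaled = x * scale
    rounded = int(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / scale


def render_outcome_table(trajectory: OutcomeTrajectory, rounding: int = 0) -> str:
    """Plain-text cumulative-outcome table, one row per year.

    Percentages are rounded half-away-from-zero to ``rounding``
    decimals, so a year's row can sum to 100 ± 1 even though the raw
    fractions sum to exactly 1.
    """
    frac = trajectory.fractions()
    header = ["Year", "Cognitively stable", "Progressed to MCI", "Dropped out"]
    rows = [header]
    for _, rec in frac.iterrows():
        cells = [str(int(rec["year"]))]
        for col in ("stable", "mci", "dropped"):
            pct = _round_half_away(100.0 * rec[col], rounding)
            cells.append(f"{pct:.{rounding}f}%" if rounding else f"{int(pct)}%")
        rows.append(cells)
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = [" | ".join(c.rjust(w) for c, w in zip(r, widths)) for r in rows]
    lines.insert(1, "-+-".join("-" * w for w in widths))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Manifests and run outputs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_dir: Path, config: SimulationConfig, outputs: Sequence[Path]
) -> Path:
    try:
        pkg_version = _pkg_version("scdsim")
    except PackageNotFoundError:  # running from a source tree
        pkg_version = "unknown"
    manifest = {
        "package": "scdsim",
        "version": pkg_version,
        "created": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": config_to_dict(config),
        "outputs": [
            {"name": p.name, "sha256": _sha256(p)} for p in outputs
        ],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def _write_trajectory(out_dir: Path, df, stem: str) -> list[Path]:
    csv_path = out_dir / f"{stem}.csv"
    df.to_csv(csv_path, index=False)
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(df.to_json(orient="records", indent=2) + "\n")
    return [csv_path, json_path]


# ---------------------------------------------------------------------------
# CLI


def _add_common(parser: argparse.ArgumentParser) -> None:
    parser.add_argument("--config", type=Path, help="YAML/JSON config file")
    parser.add_argument("--seed", type=int, help="master RNG seed")
    parser.add_argument("--n", type=int, dest="n_patients", help="cohort size")
    parser.add_argument("--years", type=int, help="simulation horizon")
    parser.add_argument("--dropout", type=float, dest="dropout_rate",
                        help="annual dropout probability")
    parser.add_argument("--mode", choices=["scaled", "bernoulli"],
                        help="risk-factor modification mode")
    parser.add_argument("--risk-table", type=Path, help="risk-factor TSV/CSV")
    parser.add_argument("--out", type=Path, default=Path("scdsim_out"),
                        help="output directory")


def _resolve_config(args: argparse.Namespace) -> SimulationConfig:
    config = read_config(args.config) if args.config else SimulationConfig()
    overrides = {}
    for attr in ("seed", "n_patients", "years", "dropout_rate", "mode"):
        value = getattr(args, attr, None)
        if value is not None:
            overrides[attr] = value
    if getattr(args, "risk_table", None) is not None:
        overrides["table"] = load_risk_table(args.risk_table)
    try:
        return config.replace(**overrides) if overrides else config
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def _cmd_simulate(args: argparse.Namespace) -> int:
    config = _resolve_config(args)
    log.info("simulating n=%d over %d years (seed=%d, mode=%s)",
             config.n_patients, config.years, config.seed, config.mode.value)
    result = simulate_cohort(config)
    out_dir = args.out
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = _write_trajectory(out_dir, result.trajectory.to_dataframe(), "trajectory")
    records_path = out_dir / "patients.csv"
    result.records.to_csv(records_path, index=False)
    outputs.append(records_path)
    write_manifest(out_dir, config, outputs)
    table = render_outcome_table(result.trajectory)
    for line in table.splitlines():
        log.info("%s", line)
    print(table)
    return 0


def _cmd_oracle(args: argparse.Namespace) -> int:
    config = _resolve_config(args)
    expected = enumerate_expected_outcomes(config)
    out_dir = args.out
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = _write_trajectory(out_dir, expected.to_dataframe(), "expected_trajectory")
    write_manifest(out_dir, config, outputs)
    df = expected.to_dataframe()
    print(df.to_string(index=False))
    log.info("year-1 expected progression: %.5f", expected.mci[0])
    return 0


def _cmd_sensitivity(args: argparse.Namespace) -> int:
    config = _resolve_config(args)
    results = adherence_sensitivity(config)
    out_dir = args.out
    out_dir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    df = pd.DataFrame(
        {
            "scenario": [r.label for r in results],
            "progression_5yr": [r.progression_5yr for r in results],
            "analytic_progression": [r.analytic_progression for r in results],
        }
    )
    path = out_dir / "adherence_sensitivity.csv"
    df.to_csv(path, index=False)
    write_manifest(out_dir, config, [path])
    print(df.to_string(index=False))
    return 0


def _cmd_subgroups(args: argparse.Namespace) -> int:
    config = _resolve_config(args)
    if config.mode.value != "bernoulli":
        config = config.replace(mode="bernoulli")
        log.info("subgroup analysis requires bernoulli mode; switching")
    result = simulate_cohort(config)
    out_dir = args.out
    out_dir.mkdir(parents=True, exist_ok=True)
    sub = subgroup_stratification(result)
    dose = dose_response(result)
    sub_path = out_dir / "subgroups.csv"
    dose_path = out_dir / "dose_response.csv"
    sub.to_csv(sub_path, index=False)
    dose.to_csv(dose_path, index=False)
    write_manifest(out_dir, config, [sub_path, dose_path])
    print(sub.to_string(index=False))
    print()
    print(dose.to_string(index=False))
    return 0


def _cmd_contributions(args: argparse.Namespace) -> int:
    config = _resolve_config(args)
    df = factor_contribution_table(config.table)
    out_dir = args.out
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "contributions.csv"
    df.to_csv(path, index=False)
    write_manifest(out_dir, config, [path])
    print(df.to_string(index=False))
    return 0


_COMMANDS = {
    "simulate": _cmd_simulate,
    "oracle": _cmd_oracle,
    "sensitivity": _cmd_sensitivity,
    "subgroups": _cmd_subgroups,
    "contributions": _cmd_contributions,
}


def cli(argv: Optional[Sequence[str]] = None) -> int:
    """Run one analysis subcommand; returns a process exit status."""
    parser = argparse.ArgumentParser(
        prog="scdsim",
        description=(
            "Monte Carlo microsimulation of progression from subjective "
            "cognitive decline to MCI under multi-domain risk-factor "
            "modification."
        ),
    )
    sub = parser.add_subparsers(dest="command", required=True)
    for name, help_text in [
        ("simulate", "run the Monte Carlo cohort simulation"),
        ("oracle", "exact expected trajectory by enumeration"),
        ("sensitivity", "adherence sensitivity sweep"),
        ("subgroups", "subgroup stratification and dose-response"),
        ("contributions", "per-factor risk-reduction contributions"),
    ]:
        _add_common(sub.add_parser(name, help=help_text))

    if not logging.getLogger().handlers:
        logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

    args = parser.parse_args(argv)
    try:
        return _COMMANDS[args.command](args)
    except (ConfigError, ValueError, OSError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 2


def main() -> None:  # console-script entry point
    sys.exit(cli())
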