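"""File formats, run configuration and report assembly.

Everything on disk is plain CSV (RFC-4180, UTF-8, '.' decimal) or YAML:

* deployment traces: one CSV per deployment with columns
  ``time_s,p1_hPa,p2_hPa,p3_hPa`` and a YAML sidecar (or shared metadata
  file) naming pump type, rpm, sensor id, water temperature, sampling rate
  and optional manual marks;
* fish records: one CSV with the fish-record dialect
  (``injury_codes`` semicolon-separated, e.g. ``2.3;3.2``);
* outputs: per-deployment parameter CSV, per-scenario ensemble CSV, coded
  fish CSV, cohort table CSV and injury-distribution CSV.

The run configuration's defaults are the processing constants used
throughout (injection threshold 1005 hPa, 20 hPa nadir change criterion
within 0.1 s, 3–75 s pump / 5–75 s control search windows, order-2 window-11
smoothing, 500 s⁻¹ strain threshold anchored at 3.45 hPa @ 5 m/s and
4.5 °C, acclimation pressure 1000 hPa, 100 Hz sampling). Every override is
recorded in the report provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import MissingMeta, MissingStage, ParseError
from .signal import DeploymentMeta, PressureTrace

__all__ = [
    "RunConfig",
    "read_deployments",
    "write_deployment",
    "read_fish",
    "write_fish",
    "ScenarioReport",
    "build_report",
]


@dataclass
class RunConfig:
    """All tunable constants of a pipeline run, with study defaults."""

    fs: float = 100.0
    acclimation_hpa: float = 1000.0
    injection_threshold_hpa: float = 1005.0
    nadir_change_hpa: float = 20.0
    nadir_change_horizon_s: float = 0.1
    pump_nadir_window_s: tuple = (3.0, 75.0)
    control_nadir_window_s: tuple = (5.0, 75.0)
    sg_order: int = 2
    sg_window: int = 11
    roc_half_window_s: float = 0.5
    strain_threshold: float = 500.0
    strain_velocity: float = 5.0
    strain_temp_c: float = 4.5
    strain_anchor_dp_hpa: float = 3.45
    tree_min_samples_split: int = 20
    tree_ccp_alpha: float = 0.01
    alpha: float = 0.05
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        unknown = [k for k in raw if not hasattr(cfg, k)]
        if unknown:
            raise ParseError(f"unknown config keys: {unknown}")
        for k, v in raw.items():
            default = getattr(cfg, k)
            if v != default:
                cfg.overrides[k] = {"default": default, "value": v}
            setattr(cfg, k, v)
        return cfg

    def to_yaml(self) -> str:
        d = asdict(self)
        d.pop("overrides")
        return yaml.safe_dump(d, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _meta_from_dict(d: dict) -> DeploymentMeta:
    try:
        rpm = d.get("rpm")
        return DeploymentMeta(
            pump=d["pump"],
            rpm=None if rpm in (None, "", "none") else int(rpm),
            sensor_id=str(d.get("sensor_id", "BDS-0")),
            water_temp_c=float(d.get("water_temp_c", 4.5)),
            acclimation_hpa=float(d.get("acclimation_hpa", 1000.0)),
            fs=float(d.get("fs", 100.0)),
            center_channel=int(d.get("center_channel", 0)),
            manual_exit_s=(
                None if d.get("manual_exit_s") in (None, "") else float(d["manual_exit_s"])
            ),
        )
    except KeyError as e:
        raise MissingMeta(f"metadata missing required field {e}") from e


def read_deployments(directory: str | Path, meta_file: str | Path) -> list[PressureTrace]:
    """Read every deployment CSV in ``directory`` with its metadata.

    ``meta_file`` is a YAML mapping from deployment file stem to the
    metadata fields of :class:`DeploymentMeta`. Non-monotone or non-uniform
    time columns and non-numeric rows are rejected with the offending file
    named.
    """
    directory = Path(directory)
    meta_map = yaml.safe_load(Path(meta_file).read_text()) or {}
    traces = []
    for csv_path in sorted(directory.glob("*.csv")):
        stem = csv_path.stem
        if stem not in meta_map:
            raise MissingMeta(f"no metadata entry for deployment {stem!r}")
        meta = _meta_from_dict(meta_map[stem])
        try:
            df = pd.read_csv(csv_path)
        except Exception as e:  # noqa: BLE001 - surface as ParseError
            raise ParseError(f"{csv_path.name}: {e}") from e
        required = {"time_s"}
        if not required <= set(df.columns):
            raise ParseError(f"{csv_path.name}: missing column(s) {required - set(df.columns)}")
        pcols = [c for c in df.columns if c.startswith("p") and c.endswith("_hPa")]
        if not pcols:
            raise ParseError(f"{csv_path.name}: no pressure columns p*_hPa")
        vals = df[pcols].to_numpy()
        if not np.isfinite(vals).all():
            bad = int(np.argwhere(~np.isfinite(vals))[0][0]) + 2  # 1-based + header
            raise ParseError(f"{csv_path.name}: non-numeric pressure at line {bad}")
        t = df["time_s"].to_numpy(float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            bad = int(np.argwhere(np.diff(t) <= 0)[0][0]) + 2
            raise ParseError(f"{csv_path.name}: non-monotone time at line {bad}")
        traces.append(PressureTrace(time=t, channels=vals.T, meta=meta))
    return traces


def write_deployment(trace: PressureTrace, path: str | Path) -> None:
    """Write one trace in the deployment CSV dialect."""
    cols = {"time_s": trace.time}
    for i in range(trace.n_channels):
        cols[f"p{i + 1}_hPa"] = trace.channels[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


FISH_COLUMNS = [
    "id", "species", "scenario_theoretical", "scenario_observed", "type", "rpm",
    "length_mm", "mass_g", "condition", "injury_codes",
    "delayed_dead_24h", "delayed_dead_48h",
]


def read_fish(path: str | Path) -> pd.DataFrame:
    """Read a fish-record CSV, validating injury codes."""
    from .coding import parse_codes

    try:
        df = pd.read_csv(path, dtype={"injury_codes": str})
    except Exception as e:  # noqa: BLE001
        raise ParseError(f"{path}: {e}") from e
    missing = [c for c in FISH_COLUMNS if c not in df.columns and c != "id"]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df["injury_codes"] = df["injury_codes"].fillna("")
    for lineno, raw in enumerate(df["injury_codes"], start=2):
        parse_codes(raw)  # raises UnknownCode naming the code
        _ = lineno
    for flag in ("delayed_dead_24h", "delayed_dead_48h"):
        df[flag] = df[flag].astype(bool)
    return df


def write_fish(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


@dataclass
class ScenarioReport:
    """Assembled report: ensemble sensor table, cohort tables, summaries."""

    ensemble_table: pd.DataFrame  # per-scenario nadir/LRP/ROC mean ± SD
    cohort_table: pd.DataFrame  # start/end/recapture/length/mass per scenario
    injury_table: pd.DataFrame  # within-class code distribution
    strain_table: pd.DataFrame | None  # per-deployment exceedance summary
    model_summaries: dict  # name -> summary text
    provenance: dict  # config hash, seed, stage counts

    def to_text(self) -> str:
        parts = [
            "Scenario report",
            "===============",
            f"provenance: {json.dumps(self.provenance, sort_keys=True)}",
            "",
            "Sensor ensemble parameters (mean/SD per scenario):",
            self.ensemble_table.to_string(),
            "",
            "Cohort accounting:",
            self.cohort_table.to_string(index=False),
            "",
            "Injury distribution (within class, %):",
            self.injury_table.to_string(index=False),
        ]
        if self.strain_table is not None:
            parts += ["", "Strain exceedance:", self.strain_table.to_string(index=False)]
        for name, text in self.model_summaries.items():
            parts += ["", f"--- {name} ---", text]
        return "\n".join(parts)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.ensemble_table.to_csv(directory / "ensemble_table.csv")
        self.cohort_table.to_csv(directory / "cohort_table.csv", index=False)
        self.injury_table.to_csv(directory / "injury_table.csv", index=False)
        if self.strain_table is not None:
            self.strain_table.to_csv(directory / "strain_table.csv", index=False)
        (directory / "report.txt").write_text(self.to_text())


def build_report(
    ensemble_table: pd.DataFrame | None = None,
    cohort_table: pd.DataFrame | None = None,
    injury_table: pd.DataFrame | None = None,
    strain_table: pd.DataFrame | None = None,
    model_summaries: dict | None = None,
    config: RunConfig | None = None,
) -> ScenarioReport:
    """Assemble stage outputs into a :class:`ScenarioReport`.

    The three core tables are required; a missing one raises
    :class:`MissingStage` naming it. Given identical inputs and config the
    report is byte-identical (no timestamps are embedded).
    """
    for name, tbl in (
        ("ensemble_table", ensemble_table),
        ("cohort_table", cohort_table),
        ("injury_table", injury_table),
    ):
        if tbl is None:
            raise MissingStage(f"missing stage output: {name}")
    config = config or RunConfig()
    provenance = {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "overrides": {k: v["value"] for k, v in config.overrides.items()},
        "n_scenarios_sensor": int(ensemble_table.shape[0]),
        "n_cohort_rows": int(cohort_table.shape[0]),
    }
    return ScenarioReport(
        ensemble_table=ensemble_table,
        cohort_table=cohort_table,
        injury_table=injury_table,
        strain_table=strain_table,
        model_summaries=model_summaries or {},
        provenance=provenance,
    )
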