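"""Dataset readers/writers and pipeline orchestration.

Lineage tables are delimited text with the canonical header
``cell_id,parent_id,sister_id,generation,t_birth,V_birth,V_G1S,V_mitosis,
tau_G1,tau_SG2,tau,alpha``; foreign tables are adapted through a column
map. Numeric CSV output is written with 6 significant digits; internal
computation stays at full precision. Pipeline configuration is TOML and a
seed is mandatory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from cellsizer import homeostasis as hom
from cellsizer import simulate as sim

__all__ = [
    "LINEAGE_COLUMNS",
    "read_lineage_table",
    "write_lineage_table",
    "read_trajectories",
    "write_trajectories",
    "write_summary",
    "load_config",
    "run_pipeline",
    "RunReport",
]

logger = logging.getLogger("cellsizer")

LINEAGE_COLUMNS = sim.LINEAGE_COLUMNS

_NUMERIC_COLUMNS = [
    "t_birth",
    "V_birth",
    "V_G1S",
    "V_mitosis",
    "tau_G1",
    "tau_SG2",
    "tau",
    "alpha",
]

_KNOWN_CONFIG_KEYS = {
    "seed",
    "outdir",
    "organism_class",
    "filter",
    "bin_policy",
    "datasets",
}
_KNOWN_DATASET_KEYS = {
    "name",
    "path",
    "column_map",
    "delimiter",
    "decimal",
    "simulate",
    "organism_class",
    "filter",
    "gamma_mode",
}


def read_lineage_table(
    path,
    column_map: dict[str, str] | None = None,
    delimiter: str = ",",
    decimal: str = ".",
) -> pd.DataFrame:
    """Read and validate a lineage table.

    ``column_map`` maps canonical column names to the file's column names.
    Rows violating basic record invariants (non-positive volumes or cycle
    durations) are dropped with a logged count; a mapped column missing from
    the file is a hard error.
    """
    df = pd.read_csv(path, sep=delimiter, decimal=decimal)
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise ValueError(
                f"mapped column(s) {missing} not found in {path}"
            )
        df = df.rename(columns={src: dst for dst, src in column_map.items()})
    for col in LINEAGE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    n0 = len(df)
    ok = (df["V_birth"] > 0) & (df["V_mitosis"] > 0)
    # tau may be absent, but when present it must be positive
    ok &= df["tau"].isna() | (df["tau"] > 0)
    df = df.loc[ok].reset_index(drop=True)
    if len(df) < n0:
        logger.info("dropped %d invalid row(s) from %s", n0 - len(df), path)
    return df[LINEAGE_COLUMNS]


def write_lineage_table(path, table: pd.DataFrame) -> None:
    table[LINEAGE_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def write_trajectories(path, trajectories) -> None:
    """Write trajectories as long-format CSV."""
    frames = [t.to_frame() for t in trajectories]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_trajectories(path) -> list:
    """Read a long-format trajectory CSV back into Trajectory objects."""
    from cellsizer.trajectory import Trajectory

    df = pd.read_csv(path)
    out = []
    for cid, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("t_min")
        t = sub["t_min"].to_numpy(dtype=float)
        interval = float(np.median(np.diff(t))) if len(sub) > 1 else 10.0
        rep = sub["reporter"].to_numpy(dtype=float) if "reporter" in sub else None
        if rep is not None and np.all(np.isnan(rep)):
            rep = None
        out.append(
            Trajectory(
                cell_id=str(cid),
                t=t,
                volume=sub["volume_um3"].to_numpy(dtype=float),
                reporter=rep,
                frame_interval=interval,
                frames=sub["frame"].to_numpy(dtype=int)
                if "frame" in sub
                else None,
            )
        )
    return out


_SUMMARY_FIELDS = [
    "name",
    "lambda",
    "se_lambda",
    "theta",
    "se_theta",
    "gamma",
    "se_gamma",
    "gamma_mode",
    "mean_G",
    "n",
    "binn",
    "minn",
    "filter_rule",
    "n_removed",
]


def summary_row(
    s: hom.HomeostasisSummary,
    binn: int,
    minn: int,
    filter_rule: str,
    n_removed: int,
) -> dict:
    return {
        "name": s.name,
        "lambda": s.lam,
        "se_lambda": s.se_lam,
        "theta": s.theta,
        "se_theta": s.se_theta,
        "gamma": s.gamma,
        "se_gamma": s.se_gamma,
        "gamma_mode": s.gamma_mode,
        "mean_G": s.mean_G,
        "n": s.n,
        "binn": binn,
        "minn": minn,
        "filter_rule": filter_rule,
        "n_removed": n_removed,
    }


def write_summary(outdir, rows: list[dict]) -> None:
    outdir = Path(outdir)
    df = pd.DataFrame(rows, columns=_SUMMARY_FIELDS)
    df.to_csv(outdir / "summary.tsv", sep="\t", index=False, float_format="%.6g")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(rows, fh, indent=2, default=float)


def load_config(path) -> dict:
    """Load and validate a TOML pipeline configuration."""
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    unknown = set(cfg) - _KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    if "seed" not in cfg:
        raise ValueError("configuration must declare a seed")
    for ds in cfg.get("datasets", []):
        bad = set(ds) - _KNOWN_DATASET_KEYS
        if bad:
            raise ValueError(
                f"unknown key(s) in dataset {ds.get('name', '?')!r}: {sorted(bad)}"
            )
        if "name" not in ds:
            raise ValueError("every dataset needs a name")
        if ("path" in ds) == ("simulate" in ds):
            raise ValueError(
                f"dataset {ds['name']!r} must declare exactly one of "
                "'path' or 'simulate'"
            )
    return cfg


@dataclass
class RunReport:
    rows: list[dict] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)
    version: str = ""
    config_hash: str = ""
    timestamp: str = ""

    @property
    def ok(self) -> bool:
        return not self.failures


def _dataset_seed(base_seed: int, name: str) -> int:
    """Deterministic per-dataset sub-seed, independent of dataset order."""
    ss = np.random.SeedSequence([base_seed, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0])


def _load_or_simulate(ds: dict, base_seed: int) -> pd.DataFrame:
    if "path" in ds:
        return read_lineage_table(
            ds["path"],
            column_map=ds.get("column_map"),
            delimiter=ds.get("delimiter", ","),
            decimal=ds.get("decimal", "."),
        )
    spec = dict(ds["simulate"])
    mode = sim.MechanisticMode(
        mode=spec.pop("mode", "linear_response"),
        mode_sd=spec.pop("mode_sd", 0.0),
        target=spec.pop("target", None),
    )
    n_founders = spec.pop("n_founders", 10)
    n_generations = spec.pop("n_generations", 10)
    burn_in = spec.pop("burn_in", sim.DEFAULT_BURN_IN)
    params = sim.ModelParams(**spec)
    return sim.simulate_lineages(
        params,
        mode,
        n_founders=n_founders,
        n_generations=n_generations,
        seed=_dataset_seed(base_seed, ds["name"]),
        burn_in=burn_in,
    )


def run_pipeline(config: dict) -> RunReport:
    """filter -> bin -> fit -> lambda/theta/gamma for every dataset.

    Deterministic given the configured seed; per-dataset failures are
    recorded and do not stop the remaining datasets.
    """
    from cellsizer import __version__

    cfg = validate_config(config)
    outdir = Path(cfg.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    base_seed = int(cfg["seed"])
    report = RunReport(
        version=__version__,
        config_hash=hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    for ds in cfg.get("datasets", []):
        name = ds["name"]
        try:
            cells = _load_or_simulate(ds, base_seed)
            organism = ds.get("organism_class", cfg.get("organism_class", "animal"))
            rule = ds.get("filter", cfg.get("filter", "3sd"))
            if rule == "3sd":
                cells, frep = hom.filter_3sd(cells, ["V_birth", "V_mitosis"])
            elif rule == "iqr":
                cells, frep = hom.filter_iqr(cells)
            elif rule == "none":
                frep = hom.FilterReport("none", len(cells), 0)
            else:
                raise ValueError(f"unknown filter rule {rule!r}")
            policy = cfg.get("bin_policy")
            binn, minn = (
                (int(policy["binn"]), int(policy["minn"]))
                if policy
                else hom.select_bin_params(len(cells), organism)
            )
            summ = hom.summarize(
                cells,
                name=name,
                gamma_mode=ds.get("gamma_mode", "auto"),
                bin_policy=(binn, minn),
            )
            report.rows.append(summary_row(summ, binn, minn, rule, frep.n_removed))
            # per-analysis regression exports
            analyses = {
                "G_vs_logVbirth": ("log_V_birth", "G"),
                "Vmitosis_vs_Vbirth": ("V_birth", "V_mitosis"),
            }
            cells2 = cells.copy()
            cells2["G"] = np.log(cells2["V_mitosis"] / cells2["V_birth"])
            cells2["log_V_birth"] = np.log(cells2["V_birth"])
            for label, (x, y) in analyses.items():
                fit = hom.homeostasis_regression(
                    cells2, x, y, bin_policy=(binn, minn)
                )
                _write_fit(outdir / f"{name}.{label}.tsv", fit)
            logger.info("dataset %s: lambda=%.3f (n=%d)", name, summ.lam, summ.n)
        except Exception as exc:  # noqa: BLE001 - per-dataset isolation
            logger.error("dataset %s failed: %s", name, exc)
            report.failures[name] = str(exc)
    write_summary(outdir, report.rows)
    with open(outdir / "report.json", "w") as fh:
        json.dump(
            {
                "version": report.version,
                "config_hash": report.config_hash,
                "timestamp": report.timestamp,
                "summaries": report.rows,
                "failures": report.failures,
            },
            fh,
            indent=2,
            default=float,
        )
    return report


def _write_fit(path, fit: hom.BinnedRegressionResult) -> None:
    head = pd.DataFrame(
        [
            {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "se_slope": fit.se_slope,
                "p_slope": fit.p_slope,
                "r2": fit.r2,
                "n_cells": fit.n_cells,
            }
        ]
    )
    with open(path, "w") as fh:
        head.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        fit.bins.to_csv(fh, sep="\t", index=False, float_format="%.6g")
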