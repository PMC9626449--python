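"""Configuration, CSV schemas, run manifests, and table rendering."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .synthetic import PlasticProfile
from .tagproc import DEPTH_BINS, DEPTH_BIN_EDGES, DielLungeRates, LungeEvent, TagTrace, TraceMetadata

__all__ = [
    "load_config",
    "default_config",
    "RunManifest",
    "write_trace_csv",
    "read_trace_csv",
    "write_profile_csv",
    "read_profile_csv",
    "write_events_csv",
    "read_events_csv",
    "write_rates_csv",
    "read_rates_csv",
    "sci_notation",
    "render_table2",
]


def default_config() -> dict:
    """The packaged default configuration."""
    text = resources.files("rorqualrisk").joinpath("config/default.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML/JSON config, falling back to the packaged defaults.

    User values are merged shallowly (top-level sections) over defaults.
    """
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key] = {**cfg[key], **val}
            else:
                cfg[key] = val
    return cfg


@dataclass(frozen=True)
class RunManifest:
    """Provenance record tying outputs to the config and seed that made them."""

    config_hash: str
    seed: int
    package_version: str
    created_utc: str
    inputs: tuple[tuple[str, str], ...] = ()

    @classmethod
    def create(cls, config: dict, seed: int, input_files: Sequence[str | Path] = ()) -> "RunManifest":
        canon = json.dumps(config, sort_keys=True, default=str).encode()
        digest = hashlib.sha256(canon + str(seed).encode()).hexdigest()[:16]
        from . import __version__

        digests = []
        for f in input_files:
            h = hashlib.sha256(Path(f).read_bytes()).hexdigest()[:16]
            digests.append((str(f), h))
        return cls(
            config_hash=digest,
            seed=seed,
            package_version=__version__,
            created_utc=pd.Timestamp.utcnow().isoformat(),
            inputs=tuple(digests),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    def header(self) -> str:
        """Comment line embedded at the top of every CSV output."""
        return f"# rorqualrisk run {self.config_hash} seed={self.seed}\n"


def _write_csv(df: pd.DataFrame, path: str | Path, manifest: RunManifest | None) -> None:
    with open(path, "w") as fh:
        if manifest is not None:
            fh.write(manifest.header())
        df.to_csv(fh, index=False)


def write_trace_csv(
    trace: TagTrace, path: str | Path, meta_path: str | Path | None = None,
    manifest: RunManifest | None = None,
) -> None:
    """Write a trace as CSV (timestamp_utc, depth_m, speed_ms) + metadata JSON."""
    df = trace.data.reset_index(names="timestamp_utc")
    df["timestamp_utc"] = df["timestamp_utc"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    _write_csv(df, path, manifest)
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(asdict(trace.metadata), indent=2) + "\n")


def read_trace_csv(path: str | Path, meta_path: str | Path | None = None) -> TagTrace:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    idx = pd.to_datetime(df["timestamp_utc"], utc=True, format="ISO8601")
    data = pd.DataFrame(
        {"depth_m": df["depth_m"].values, "speed_ms": df["speed_ms"].values}, index=idx
    )
    meta = TraceMetadata()
    if meta_path is not None:
        meta = TraceMetadata(**json.loads(Path(meta_path).read_text()))
    return TagTrace(data, meta)


def write_profile_csv(
    profile: PlasticProfile, path: str | Path, manifest: RunManifest | None = None
) -> None:
    rows = []
    for bin_label, lo, hi in zip(DEPTH_BINS, DEPTH_BIN_EDGES[:-1], DEPTH_BIN_EDGES[1:]):
        rows.append(
            {
                "depth_bin": bin_label,
                "depth_top_m": lo,
                "depth_bottom_m": "" if np.isinf(hi) else hi,
                "conc_pp_m3": profile.concentrations[bin_label],
            }
        )
    _write_csv(pd.DataFrame(rows), path, manifest)


def read_profile_csv(path: str | Path) -> PlasticProfile:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return PlasticProfile(dict(zip(df["depth_bin"], df["conc_pp_m3"].astype(float))))


def write_events_csv(
    events: Sequence[LungeEvent], path: str | Path, manifest: RunManifest | None = None
) -> None:
    df = pd.DataFrame(
        {
            "time_utc": [e.time.isoformat() for e in events],
            "depth_m": [e.depth for e in events],
            "depth_bin": [e.depth_bin for e in events],
            "diel": [e.diel_period for e in events],
            "peak_speed_ms": [e.peak_speed for e in events],
        }
    )
    _write_csv(df, path, manifest)


def read_events_csv(path: str | Path) -> list[LungeEvent]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return [
        LungeEvent(
            time=pd.Timestamp(r.time_utc),
            depth=float(r.depth_m),
            depth_bin=str(r.depth_bin),
            diel_period=str(r.diel),
            peak_speed=float(r.peak_speed_ms),
        )
        for r in df.itertuples()
    ]


def write_rates_csv(
    rates: Sequence[DielLungeRates], path: str | Path, manifest: RunManifest | None = None
) -> None:
    _write_csv(pd.DataFrame([asdict(r) for r in rates]), path, manifest)


def read_rates_csv(path: str | Path) -> list[DielLungeRates]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return [
        DielLungeRates(
            deployment_id=str(r.deployment_id),
            rate_day=float(r.rate_day),
            rate_twilight=float(r.rate_twilight),
            rate_night=float(r.rate_night),
            hours_day=float(r.hours_day),
            hours_twilight=float(r.hours_twilight),
            hours_night=float(r.hours_night),
        )
        for r in df.itertuples()
    ]


def sci_notation(x: float, sig: int = 3) -> str:
    """Format like the field's tables: 5730000 -> ``5.73 x 10^6``.

    Values with magnitude in [0.01, 10000) are printed plainly.
    """
    if x == 0 or not np.isfinite(x):
        return f"{x:g}"
    exp = int(np.floor(np.log10(abs(x))))
    if -2 <= exp < 4:
        s = f"{x:.{max(sig - 1 - exp, 0)}f}"
        return s.rstrip("0").rstrip(".") if "." in s else s
    mant = x / 10.0**exp
    return f"{round(mant, sig - 1):g} × 10^{exp}"


_ROW_LABELS = {
    "lunge_count": "Median Lunge Count",
    "pieces_from_water": "Median Plastic Pieces Retained from Water",
    "pieces_from_prey": "Median Plastic Pieces Retained from Prey",
    "pieces_total": "Median Total Plastic Pieces",
    "water_per_kg": "Pieces from Water / Animal Mass (kg)",
    "prey_per_kg": "Pieces from Prey / Animal Mass (kg)",
    "total_per_kg": "Total Pieces / Animal Mass (kg)",
}


def render_table2(table: pd.DataFrame, level: str = "medium") -> str:
    """Render a scenario summary as a median (Q1 - Q3) statistics table.

    One column per (species, prey type); seven statistic rows.  Missing
    mass-specific statistics render as NA.
    """
    sub = table[table["level"] == level]
    if sub.empty:
        raise ValueError(f"no rows for level {level!r}")
    cols = sorted({(s, p) for s, p in zip(sub["species"], sub["prey_type"])})
    header = ["Statistic"] + [f"{s} ({p})" for s, p in cols]
    lines = []
    for stat, label in _ROW_LABELS.items():
        row = [label]
        for s, p in cols:
            rec = sub[(sub["species"] == s) & (sub["prey_type"] == p) & (sub["statistic"] == stat)]
            if rec.empty or not np.isfinite(rec.iloc[0]["median"]):
                row.append("NA")
            else:
                r = rec.iloc[0]
                row.append(
                    f"{sci_notation(r['median'])} ({sci_notation(r['q1'])}–{sci_notation(r['q3'])})"
                )
        lines.append(row)
    widths = [max(len(str(l[i])) for l in [header] + lines) for i in range(len(header))]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    out = [fmt.format(*header), fmt.format(*["-" * w for w in widths])]
    out += [fmt.format(*row) for row in lines]
    return "\n".join(out) + "\n"
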