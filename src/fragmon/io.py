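"""File formats: track lists, plan spot lists, profile stores, configs, reports.

Track lists travel either as plain-text CSV (comma separated, '.' decimal,
'#' comments, header row naming the columns) or as an equivalent Parquet
container whose round trip is bit-stable for the float columns.  Plan spot
lists are columnar text in delivery order.  Per-fraction profile stores are
HDF5 files with one group per SPB plus run metadata.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import pandas as pd
import yaml

from .plan import PencilBeam
from .profiles import EmissionProfile
from .synthetic import TRACK_COLUMNS, ScenarioConfig

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_plan",
    "write_plan",
    "write_profile_store",
    "read_profile_store",
    "read_scenario",
    "write_scenario",
    "write_report",
    "config_hash",
]

PLAN_COLUMNS = ["pb_id", "x_mm", "y_mm", "energy_MeV_u", "n_ions", "field_deg"]


class SchemaError(ValueError):
    """A required column is missing or malformed."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def write_tracks(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a track list; format chosen by suffix (.csv text, .parquet binary)."""
    path = Path(path)
    _require_columns(df, TRACK_COLUMNS, "track list")
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        with open(path, "w") as fh:
            fh.write("# fragmon track list: one reconstructed fragment track per row\n")
            df.to_csv(fh, index=False)
    return path


def read_tracks(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, comment="#")
    _require_columns(df, TRACK_COLUMNS, f"track list {path.name}")
    return df


def write_plan(pbs: list[PencilBeam], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "pb_id": pb.pb_id,
            "x_mm": pb.spot_xy[0],
            "y_mm": pb.spot_xy[1],
            "energy_MeV_u": pb.energy,
            "n_ions": pb.n_ions,
            "field_deg": pb.field_angle,
        }
        for pb in pbs
    ]
    with open(path, "w") as fh:
        fh.write("# fragmon plan spot list; rows in delivery order\n")
        pd.DataFrame(rows, columns=PLAN_COLUMNS).to_csv(fh, index=False)
    return path


def read_plan(path: str | Path) -> list[PencilBeam]:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, PLAN_COLUMNS, f"plan {Path(path).name}")
    return [
        PencilBeam(
            pb_id=int(r.pb_id),
            spot_xy=(float(r.x_mm), float(r.y_mm)),
            energy=float(r.energy_MeV_u),
            n_ions=float(r.n_ions),
            field_angle=float(r.field_deg),
        )
        for r in df.itertuples()
    ]


def config_hash(obj) -> str:
    """Stable short hash of a config mapping, recorded in every output."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_profile_store(
    profiles: dict[int, EmissionProfile],
    path: str | Path,
    metadata: dict | None = None,
) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        for k, v in (metadata or {}).items():
            meta.attrs[k] = v
        g = f.create_group("spb")
        for spb_id, prof in profiles.items():
            sg = g.create_group(str(spb_id))
            sg.create_dataset("bin_edges", data=prof.bin_edges)
            sg.create_dataset("weights", data=prof.weights)
            sg.create_dataset("sumw2", data=prof.sumw2)
            sg.attrs["n_raw"] = prof.n_raw
            sg.attrs["fraction_id"] = prof.fraction_id
    return path


def read_profile_store(path: str | Path) -> tuple[dict[int, EmissionProfile], dict]:
    out: dict[int, EmissionProfile] = {}
    with h5py.File(path, "r") as f:
        metadata = dict(f["meta"].attrs) if "meta" in f else {}
        for name, sg in f["spb"].items():
            spb_id = int(name)
            out[spb_id] = EmissionProfile(
                spb_id=spb_id,
                fraction_id=int(sg.attrs["fraction_id"]),
                bin_edges=sg["bin_edges"][:],
                weights=sg["weights"][:],
                sumw2=sg["sumw2"][:],
                n_raw=int(sg.attrs["n_raw"]),
            )
    return out, metadata


def write_scenario(scenario: ScenarioConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)
    return path


def read_scenario(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ScenarioConfig.from_dict(data)


def write_report(report_dict: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report_dict, fh, indent=2)
    return path
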