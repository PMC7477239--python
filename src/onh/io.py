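"""Interchange formats, configuration, and reproducibility plumbing.

Volume interchange format: one JSON document per volume carrying the scan
geometry, the ordered BMO ring as ``[x, y, z]`` um triples, and relative
references to two TSV sidecar matrices (ILM and LC heights, ``NA`` for
missing nodes).  Heights are serialized with 17 significant digits so a
write -> read round trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, CohortParams
from .errors import FormatError, ParameterError
from .phantom import PhantomParams
from .volume import ScanGeometry, SegmentedONHVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_cohort",
    "write_cohort",
    "load_config",
    "params_from_config",
    "RunManifest",
    "config_digest",
    "stage_seed",
]

SCHEMA_VERSION = 1
_GEOMETRY_FIELDS = ("n_bscans", "n_ascans", "bscan_spacing", "ascan_spacing", "axial_unit")


def _format_grid(grid: np.ndarray) -> str:
    lines = []
    for row in grid:
        lines.append(
            "\t".join("NA" if math.isnan(v) else format(v, ".17g") for v in row)
        )
    return "\n".join(lines) + "\n"


def _parse_grid(text: str, path: Path, shape: tuple[int, int]) -> np.ndarray:
    rows = []
    for i, line in enumerate(text.rstrip("\n").split("\n")):
        row = []
        for j, token in enumerate(line.split("\t")):
            if token == "NA":
                row.append(math.nan)
            else:
                try:
                    row.append(float(token))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric token {token!r} at row {i + 1}, "
                        f"column {j + 1}"
                    ) from None
        rows.append(row)
    grid = np.array(rows, float)
    if grid.shape != shape:
        raise FormatError(f"{path}: expected a {shape} matrix, got {grid.shape}")
    return grid


def write_volume(volume: SegmentedONHVolume, path: str | Path) -> Path:
    """Write a volume as ``<base>.json`` + ``<base>.ilm.tsv`` + ``<base>.lc.tsv``."""
    base = Path(path)
    if base.suffix == ".json":
        base = base.with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)
    ilm_name, lc_name = base.name + ".ilm.tsv", base.name + ".lc.tsv"
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": volume.name,
        "geometry": {f: getattr(volume.geometry, f) for f in _GEOMETRY_FIELDS},
        "axial_convention": volume.axial_convention,
        "axial_range": list(volume.axial_range),
        "bmo_points": [[float(v) for v in p] for p in volume.bmo_points],
        "files": {"ilm": ilm_name, "lc": lc_name},
        "meta": volume.meta,
    }
    (base.parent / ilm_name).write_text(_format_grid(volume.ilm_height))
    (base.parent / lc_name).write_text(_format_grid(volume.lc_height))
    out = base.with_suffix(".json")
    out.write_text(json.dumps(doc, indent=1))
    return out


def read_volume(path: str | Path) -> SegmentedONHVolume:
    """Read a volume written by :func:`write_volume`; validates the schema."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from None
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported schema_version {doc.get('schema_version')!r}"
        )
    for key in ("geometry", "bmo_points", "files"):
        if key not in doc:
            raise FormatError(f"{path}: missing field {key!r}")
    geo = doc["geometry"]
    missing = [f for f in _GEOMETRY_FIELDS if f not in geo]
    if missing:
        raise FormatError(f"{path}: geometry missing fields {missing}")
    try:
        geometry = ScanGeometry(**{f: geo[f] for f in _GEOMETRY_FIELDS})
    except ParameterError as exc:
        raise FormatError(f"{path}: geometry: {exc}") from None

    bmo = np.asarray(doc["bmo_points"], float)
    if bmo.ndim != 2 or bmo.shape[1] != 3 or len(bmo) < 8:
        raise FormatError(
            f"{path}: bmo_points must be >= 8 [x, y, z] triples, got shape "
            f"{bmo.shape}"
        )
    shape = (geometry.n_bscans, geometry.n_ascans)
    grids = {}
    for key in ("ilm", "lc"):
        sidecar = path.parent / doc["files"][key]
        if not sidecar.exists():
            raise FormatError(f"{path}: missing TSV sidecar {sidecar.name}")
        grids[key] = _parse_grid(sidecar.read_text(), sidecar, shape)
    return SegmentedONHVolume(
        geometry=geometry,
        ilm_height=grids["ilm"],
        lc_height=grids["lc"],
        bmo_points=bmo,
        axial_range=tuple(doc.get("axial_range", (-1500.0, 2000.0))),
        name=doc.get("name", path.stem),
        meta=doc.get("meta", {}),
    )


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: cohort CSV missing columns {missing}")
    return table


def _coerce(token: str):
    text = token.strip()
    lowered = text.lower()
    if lowered in ("true", "yes", "on"):
        return True
    if lowered in ("false", "no", "off"):
        return False
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def load_config(path: str | Path) -> dict:
    """Flat ``key = value`` text config; a JSON object is accepted equivalently."""
    text = Path(path).read_text()
    if text.lstrip().startswith("{"):
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON config ({exc})") from None
        if not isinstance(doc, dict):
            raise FormatError(f"{path}: JSON config must be an object")
        return doc
    out: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line or (line.startswith("[") and line.endswith("]")):
            continue
        sep = "=" if "=" in line else (":" if ":" in line else None)
        if sep is None:
            raise FormatError(f"{path}: line {lineno}: expected 'key = value'")
        key, value = line.split(sep, 1)
        out[key.strip()] = _coerce(value)
    return out


_PARAM_KINDS = {"phantom": PhantomParams, "cohort": CohortParams}


def params_from_config(config: dict, kind: str):
    """Build PhantomParams or CohortParams from a flat config mapping."""
    cls = _PARAM_KINDS.get(kind)
    if cls is None:
        raise ParameterError(f"unknown parameter kind {kind!r}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(config) - known)
    if unknown:
        raise ParameterError(f"unknown {kind} parameter(s): {', '.join(unknown)}")
    return cls(**config)


def config_digest(config: dict) -> str:
    """SHA-256 of the canonical (sorted-key) JSON form; key order invariant."""
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Per-stage substream of one global seed.

    The stage name is hashed into the entropy so adding a stage never
    perturbs the streams of existing stages.
    """
    tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:8], "big")
    return np.random.SeedSequence(entropy=[int(seed), tag])


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record written next to every CLI artifact set."""

    command: str
    config_digest: str
    seed: int
    package_version: str
    started: str
    finished: str

    @classmethod
    def start(cls, command: str, config: dict, seed: int) -> "RunManifest":
        from . import __version__

        now = datetime.now(timezone.utc).isoformat()
        return cls(
            command=command,
            config_digest=config_digest(config),
            seed=int(seed),
            package_version=__version__,
            started=now,
            finished="",
        )

    def finish(self) -> "RunManifest":
        return dataclasses.replace(
            self, finished=datetime.now(timezone.utc).isoformat()
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path
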