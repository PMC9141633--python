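"""Delimited-text input/output.

One region = one tab-delimited matrix (rows voxels, columns timepoints); a
manifest table maps subject and region ids to files. FC matrices are square
TSV tables with region ids as header row and index column; network
assignments are two-column region/network tables. Everything is plain text
so runs are diffable and trivially generated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .measures import RegionActivity
from .network import FCMatrix, NetworkAssignment

__all__ = [
    "write_region",
    "read_region",
    "write_cohort",
    "read_manifest",
    "write_fc_matrix",
    "read_fc_matrix",
    "write_assignment",
    "read_assignment",
    "write_provenance",
    "config_hash",
]

MANIFEST_NAME = "manifest.tsv"
ASSIGNMENT_NAME = "networks.tsv"


def write_region(region: RegionActivity, path: Path) -> None:
    np.savetxt(path, region.data, delimiter="\t", fmt="%.10g")


def read_region(path: Path, region_id: str = "") -> RegionActivity:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"region file {path} not found")
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    return RegionActivity(data, region_id=region_id or path.stem)


def write_cohort(cohort: Cohort, out_dir: Path) -> Path:
    """Write one file per subject/region plus manifest and assignment tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s, regions in enumerate(cohort.subjects):
        subject_id = f"sub{s:03d}"
        sub_dir = out_dir / subject_id
        sub_dir.mkdir(exist_ok=True)
        for region in regions:
            fname = f"{subject_id}/{region.region_id}.tsv"
            write_region(region, out_dir / fname)
            rows.append({"subject": subject_id, "region": region.region_id, "file": fname})
    pd.DataFrame(rows).to_csv(out_dir / MANIFEST_NAME, sep="\t", index=False)
    write_assignment(cohort.assignment, out_dir / ASSIGNMENT_NAME)
    return out_dir / MANIFEST_NAME


def read_manifest(manifest_path: Path) -> dict[str, list[RegionActivity]]:
    """Load every region listed in a manifest, grouped by subject.

    Region order follows the manifest; shapes are validated per subject so
    ragged inputs fail with the offending file named.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest {manifest_path} not found")
    table = pd.read_csv(manifest_path, sep="\t")
    required = {"subject", "region", "file"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = manifest_path.parent
    subjects: dict[str, list[RegionActivity]] = {}
    expected_t: dict[str, int] = {}
    for row in table.itertuples():
        region = read_region(base / row.file, region_id=str(row.region))
        t_prev = expected_t.setdefault(row.subject, region.n_timepoints)
        if region.n_timepoints != t_prev:
            raise ValueError(
                f"{row.file}: expected {t_prev} timepoints for subject "
                f"{row.subject}, found {region.n_timepoints}"
            )
        subjects.setdefault(row.subject, []).append(region)
    return subjects


def write_fc_matrix(fc: FCMatrix, path: Path) -> None:
    frame = pd.DataFrame(fc.values, index=fc.region_ids, columns=fc.region_ids)
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_fc_matrix(path: Path, measure_tag: str = "", subject_id: str = "") -> FCMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: row and column region ids differ")
    return FCMatrix(
        values=frame.to_numpy(dtype=float),
        measure_tag=measure_tag,
        subject_id=subject_id,
        region_ids=tuple(str(r) for r in frame.index),
    )


def write_assignment(assign: NetworkAssignment, path: Path) -> None:
    pd.DataFrame(
        {"region": list(assign.labels), "network": list(assign.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_assignment(path: Path) -> NetworkAssignment:
    table = pd.read_csv(path, sep="\t")
    if not {"region", "network"}.issubset(table.columns):
        raise ValueError(f"{path}: assignment needs 'region' and 'network' columns")
    if table["region"].duplicated().any():
        dupes = table.loc[table["region"].duplicated(), "region"].tolist()
        raise ValueError(f"{path}: regions assigned more than once: {dupes}")
    return NetworkAssignment(
        labels=dict(zip(table["region"].astype(str), table["network"].astype(str)))
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a parameter dictionary, for provenance stamping."""
    blob = json.dumps(_plain(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_provenance(out_dir: Path, command: str, config: dict) -> str:
    """Record the full parameter echo of a run; returns the config hash."""
    import datetime

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = config_hash(config)
    payload = {
        "command": command,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config_hash": digest,
        "config": _plain(config),
    }
    with open(out_dir / f"provenance_{command}.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return digest
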