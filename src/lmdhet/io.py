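"""File formats: TSV tables, GMT gene sets, newick trees, JSON manifests.

TSV everywhere (protein ids and antibody names contain commas in the
wild); missing values are empty cells, never sentinel numbers. Floats are
written with shortest-repr formatting so write -> read -> write is
byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "write_tsv", "read_tsv",
    "write_matrix", "read_matrix",
    "read_psm_table", "read_plex_design", "read_annotation",
    "read_gmt", "write_gmt",
    "write_manifest", "hash_file",
    "load_sim_config", "load_pipeline_config",
]

_PSM_REQUIRED = ("plex_id", "spectrum_id", "peptide", "protein_accession",
                 "q_value", "isolation_interference_pct")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="")
    return path


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, sep="\t", **kwargs)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Proteins x samples matrix; empty cell = missing."""
    out = matrix.copy()
    out.index.name = "protein"
    return write_tsv(out, path, index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    df.index.name = "protein"
    bad = [c for c in df.columns if df[c].dtype == object]
    if bad:
        raise ValueError(f"{path}: non-numeric abundance columns: {bad}")
    return df


def read_psm_table(path: str | Path, keep_first_accession: bool = False) -> pd.DataFrame:
    """Read a PSM TSV; reject multi-accession rows unless ``keep_first_accession``.

    Shared-peptide razor logic is out of scope: rows whose accession field
    contains a semicolon are an error by default.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_accession": str},
                     float_precision="round_trip")
    missing = [c for c in _PSM_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing PSM columns {missing}")
    multi = df["protein_accession"].str.contains(";", na=False)
    if multi.any():
        if keep_first_accession:
            df.loc[multi, "protein_accession"] = (
                df.loc[multi, "protein_accession"].str.split(";").str[0])
        else:
            lines = (df.index[multi] + 2).tolist()[:5]
            raise ValueError(
                f"{path}: multi-accession PSM rows (e.g. lines {lines}); "
                "pass keep_first_accession=True to keep the first accession")
    intensity = [c for c in df.columns if c.startswith("intensity_")]
    if not intensity:
        raise ValueError(f"{path}: no intensity_<channel> columns")
    for c in ("q_value", "isolation_interference_pct", *intensity):
        if df[c].dtype == object:
            raise ValueError(f"{path}: non-numeric values in column {c!r}")
    return df


def read_plex_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"channel": str})
    required = {"plex_id", "channel", "sample_id", "is_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing design columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids within plex")
    if df["is_reference"].astype(bool).sum() != 1:
        raise ValueError(f"{path}: exactly one reference channel required")
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "patient", "collection_type", "level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    bad = ~df["collection_type"].isin(["ET", "ES", "BT"])
    if bad.any():
        raise ValueError(
            f"{path}: invalid collection_type values "
            f"{sorted(df.loc[bad, 'collection_type'].unique())}")
    return df


def read_gmt(path: str | Path) -> Dict[str, List[str]]:
    """Parse a GMT file: set name, description, tab-separated members."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}")
            name = fields[0]
            members = [f for f in fields[2:] if f]
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} is empty")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "na") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")
    return path


def hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, files: Sequence[str | Path],
                   config, seed: int) -> Path:
    """JSON manifest with per-file sha256 hashes and the echoed config.

    Content is fully determined by the outputs and parameters (no
    timestamps), so two runs with one seed produce identical manifests.
    """
    outdir = Path(outdir)
    if dataclasses.is_dataclass(config):
        cfg = dataclasses.asdict(config)
    else:
        cfg = dict(config)
    manifest = {
        "seed": seed,
        "config": cfg,
        "files": {
            str(Path(f).relative_to(outdir)): hash_file(f)
            for f in sorted(map(str, files))
        },
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def _load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def load_sim_config(path: str | Path):
    from .config import SimConfig
    return SimConfig.from_dict(_load_yaml(path))


def load_pipeline_config(path: str | Path):
    from .config import PipelineConfig
    return PipelineConfig.from_dict(_load_yaml(path))
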