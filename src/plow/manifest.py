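"""On-disk layout of a sampling run: TSV manifest plus optional per-minimum
PDB files, and the JSON run manifest used for provenance."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .chain import Chain, Conformation
from .io import read_conformation, write_conformation
from .search import MinimaEnsemble, MinimumRecord, SearchConfig

__all__ = ["save_ensemble", "load_ensemble", "write_run_manifest"]

MANIFEST_COLUMNS = [
    "step_index",
    "energy",
    "accepted",
    "greedy_length",
    "perturb_distance",
    "truncated",
    "file",
]


def save_ensemble(
    ensemble: MinimaEnsemble,
    outdir,
    stem: str = "ensemble",
    write_pdbs: bool = False,
) -> Path:
    """Write ``<stem>.tsv`` (one row per recorded minimum) and, optionally,
    one backbone PDB per minimum; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in ensemble.records:
        fname = ""
        if write_pdbs:
            fname = f"{stem}_min{r.step_index:05d}.pdb"
            write_conformation(outdir / fname, r.conformation)
        rows.append(
            {
                "step_index": r.step_index,
                "energy": r.energy,
                "accepted": r.accepted,
                "greedy_length": r.greedy_length,
                "perturb_distance": (
                    np.nan if r.perturb_distance is None else r.perturb_distance
                ),
                "truncated": r.truncated,
                "file": fname,
            }
        )
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    path = outdir / f"{stem}.tsv"
    with path.open("w") as fh:
        fh.write(
            f"# method={ensemble.method_tag} "
            f"evaluations_used={ensemble.evaluations_used} "
            f"sequence={_sequence_of(ensemble)}\n"
        )
        df.to_csv(fh, sep="\t", index=False)
    return path


def _sequence_of(ensemble: MinimaEnsemble) -> str:
    return ensemble.records[0].conformation.chain.sequence if ensemble.records else ""


def load_ensemble(path, config: Optional[SearchConfig] = None) -> MinimaEnsemble:
    """Rebuild a MinimaEnsemble from a manifest written with PDBs enabled."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, sep="\t")
    meta = dict(
        item.split("=", 1) for item in header.lstrip("# ").split() if "=" in item
    )
    records: List[MinimumRecord] = []
    for _, row in df.iterrows():
        fname = row["file"]
        if not isinstance(fname, str) or not fname:
            raise ValueError(
                f"{path}: manifest row {row['step_index']} has no PDB file; "
                "re-run with per-minimum PDB output to make the ensemble reloadable"
            )
        conf = read_conformation(path.parent / fname)
        pd_val = row["perturb_distance"]
        records.append(
            MinimumRecord(
                conformation=conf,
                energy=float(row["energy"]),
                step_index=int(row["step_index"]),
                accepted=bool(row["accepted"]),
                greedy_length=int(row["greedy_length"]),
                perturb_distance=None if pd.isna(pd_val) else float(pd_val),
                truncated=bool(row["truncated"]),
            )
        )
    return MinimaEnsemble(
        records=records,
        config=config if config is not None else SearchConfig(),
        evaluations_used=int(meta.get("evaluations_used", 0)),
        method_tag=meta.get("method", "plow"),
    )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_manifest(
    outdir,
    command: str,
    config: SearchConfig,
    model_name: str,
    library_path=None,
    evaluations_used: int = 0,
    wall_time_s: float = 0.0,
    outputs: Optional[List[str]] = None,
) -> Path:
    """Write the JSON run manifest that suffices to re-execute the run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": asdict(config),
        "model": model_name,
        "library": str(library_path) if library_path else None,
        "library_sha256": file_sha256(library_path) if library_path else None,
        "evaluations_used": evaluations_used,
        "wall_time_s": wall_time_s,
        "outputs": outputs or [],
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = outdir / f"{command}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
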