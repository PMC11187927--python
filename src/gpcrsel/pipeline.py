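"""Batch orchestration: manifest-driven extraction, simulation, provenance.

The pipeline stages are plain functions over the library modules; the CLI
wraps them one-to-one.  Batch extraction never aborts on one bad structure —
failures are collected per structure and the caller decides how to report
them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import constants as C
from .frame import DEFAULT_SELECTION, kabsch_superpose, to_membrane_frame
from .geometry import (
    GeometryFeatures,
    SegmentConfig,
    build_reference,
    extract_features,
    features_to_frame,
)
from .structures import (
    AnnotatedStructure,
    ManifestEntry,
    load_manifest_entry,
    read_manifest,
    write_grn_table,
    write_manifest,
    write_structure,
)
from .synth import default_group_models, make_reference_stub, sample_feature_table, stub_from_features


@dataclass
class RunConfig:
    """One reproducible run: inputs, reference, selections, seeds."""

    manifest: Optional[str] = None
    reference_id: Optional[str] = None
    superpose_selection: dict = field(default_factory=lambda: dict(DEFAULT_SELECTION))
    segment_bounds: dict = field(default_factory=dict)  # structure_id -> {tm5: [lo,hi], tm6: [...]}
    window: int = 11
    seed: int = C.DEFAULT_SEED
    output_dir: str = "runs"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def provenance(config: Optional[RunConfig] = None, seed: Optional[int] = None, **extra) -> dict:
    out = {"software": "gpcrsel", "version": __version__}
    if config is not None:
        out["config_hash"] = config.digest()
        out["seed"] = config.seed
    if seed is not None:
        out["seed"] = seed
    out.update(extra)
    return out


def _provenance_comment(prov: dict) -> str:
    return "# " + json.dumps(prov, sort_keys=True)


def write_csv_with_provenance(df: pd.DataFrame, path: str | Path, prov: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(_provenance_comment(prov) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")
    return path


def write_json_with_provenance(payload: dict, path: str | Path, prov: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(payload)
    payload["provenance"] = prov
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# extraction

def _segment_config(config: RunConfig, structure_id: str) -> SegmentConfig:
    bounds = config.segment_bounds.get(structure_id, {})
    to_pair = lambda v: tuple(v) if v else None
    return SegmentConfig(
        tm5_bounds=to_pair(bounds.get("tm5")),
        tm6_bounds=to_pair(bounds.get("tm6")),
        window=config.window,
    )


def run_extract(config: RunConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Extract the descriptor table for every structure in the manifest.

    Returns the feature frame and a per-structure failure map (empty when
    the run was clean).
    """
    if not config.manifest:
        raise ValueError("config.manifest is required")
    entries = read_manifest(config.manifest)
    if not entries:
        raise ValueError(f"manifest {config.manifest} is empty")
    by_id = {e.structure_id: e for e in entries}
    ref_id = config.reference_id or entries[0].structure_id
    if ref_id not in by_id:
        raise ValueError(f"reference structure {ref_id!r} not in manifest")

    reference = load_manifest_entry(by_id[ref_id])
    refs = build_reference(reference, _segment_config(config, ref_id).tm5_bounds)

    rows: list[GeometryFeatures] = []
    failures: dict[str, str] = {}
    for entry in entries:
        try:
            s = load_manifest_entry(entry)
            framed = to_membrane_frame(s, reference, config.superpose_selection)
            rows.append(extract_features(framed, refs, _segment_config(config, entry.structure_id)))
        except Exception as exc:  # partial-failure policy: collect and continue
            failures[entry.structure_id] = f"{type(exc).__name__}: {exc}"
    return features_to_frame(rows), failures


# ---------------------------------------------------------------------------
# simulation

def run_simulate(
    out_dir: str | Path,
    seed: int,
    n_gs_structures: int = 3,
    n_gio_structures: int = 3,
    n_gs_rows: int = C.TRAINING_COMPOSITION[C.GS],
    n_gio_rows: int = C.TRAINING_COMPOSITION[C.GIO],
) -> dict:
    """Write a self-contained synthetic dataset: stubs, tables, manifest.

    Deterministic per seed; re-running into a fresh directory reproduces the
    same files byte-for-byte.
    """
    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    models = {m.label: m for m in default_group_models()}

    entries: list[ManifestEntry] = []

    ref = make_reference_stub()
    ref_path = out_dir / "structures" / "reference.pdb"
    write_structure(ref, ref_path)
    ref_grn = out_dir / "structures" / "reference.grn.tsv"
    write_grn_table(ref, ref_grn)
    entries.append(
        ManifestEntry("reference", str(ref_path.relative_to(out_dir)), "R",
                      grn_table=str(ref_grn.relative_to(out_dir)))
    )

    for label, n in ((C.GS, n_gs_structures), (C.GIO, n_gio_structures)):
        m = models[label]
        for i in range(n):
            draw = m.mean + rng.standard_normal(4) * m.sd
            tm5_len = int(np.clip(round(draw[0]), 8, 45))
            tm5_tilt = float(np.clip(draw[1], 0, 40))
            tm6_outward = float(np.clip(draw[2], 0, 40))
            tm6_len = int(np.clip(round(draw[3]), 8, 45))
            sid = f"{label.lower()}_{i:03d}"
            stub = stub_from_features(
                tm5_len, tm5_tilt, tm6_outward, tm6_len=tm6_len,
                structure_id=sid, coupling_label=label,
            )
            p = out_dir / "structures" / f"{sid}.pdb"
            write_structure(stub, p)
            g = out_dir / "structures" / f"{sid}.grn.tsv"
            write_grn_table(stub, g)
            entries.append(
                ManifestEntry(sid, str(p.relative_to(out_dir)), "R",
                              coupling_label=label, grn_table=str(g.relative_to(out_dir)))
            )

    manifest_path = write_manifest(entries, out_dir / "manifest.csv")
    table = sample_feature_table(
        list(models.values()), {C.GS: n_gs_rows, C.GIO: n_gio_rows}, seed=seed
    )
    prov = provenance(seed=seed, stage="simulate")
    table_path = write_csv_with_provenance(table, out_dir / "feature_table.csv", prov)
    summary = {
        "manifest": str(manifest_path),
        "feature_table": str(table_path),
        "n_structures": len(entries),
        "n_rows": len(table),
    }
    write_json_with_provenance(summary, out_dir / "simulate_summary.json", prov)
    return summary


# ---------------------------------------------------------------------------
# pairwise measurements

def run_measure(
    a: AnnotatedStructure,
    b: AnnotatedStructure,
    grn: Optional[str] = None,
    rmsd: bool = False,
    interface: bool = False,
    selection: Optional[dict] = None,
) -> dict:
    """Pairwise structure comparison report (distances, RMSD, interfaces)."""
    from .frame import ca_displacement
    from .interface import analyze_interface

    selection = selection or dict(DEFAULT_SELECTION)
    report: dict = {
        "structures": [a.structure_id, b.structure_id],
        "selection": selection,
        "frame": f"superposed onto {a.structure_id}",
    }
    if rmsd:
        result = kabsch_superpose(b, a, selection)
        report["rmsd"] = {"value": round(result.rmsd, 4), "n_atoms": result.n_atoms_used}
    if grn:
        report["ca_displacement"] = {
            "grn": grn,
            "value": round(ca_displacement(a, b, grn, frame_reference=a, selection=selection), 4),
        }
    if interface:
        report["interface"] = {}
        for s in (a, b):
            if s.galpha_chain:
                res = analyze_interface(s)
                report["interface"][s.structure_id] = {
                    "buried_area_total": round(res.buried_area_total, 1),
                    "n_interface_residues_receptor": len(res.interface_residues_a),
                    "metadata": res.metadata,
                }
    return report
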