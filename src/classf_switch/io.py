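"""File I/O: PDB structures and trajectories, aligned FASTA, delimited
tables, B-factor score projection, and run provenance records.

All delimited outputs are tab-separated with one header line; generator
ground truth and other metadata travel as leading ``# key: value`` comment
lines that the paired readers skip (and can recover).  PDB reading and
writing go through Bio.PDB; by convention the first MODEL is the structure
and all MODELs are the trajectory frames.
"""

from __future__ import annotations

import hashlib
import json
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.PDB import PDBIO, PDBParser, StructureBuilder
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .contacts import AtomRecord, StructureModel
from .generic_numbering import GenericLabel, HelixSegment, SegmentMap
from .trajectory import DistanceSeries, Trajectory

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_structure",
    "read_msa",
    "write_msa",
    "read_variants",
    "write_variants",
    "read_distances",
    "write_distances",
    "read_segment_map",
    "write_segment_map",
    "read_table_metadata",
    "project_scores",
    "write_provenance",
]

B_FACTOR_MIN, B_FACTOR_MAX = -9.99, 999.99  # fixed-width PDB column limits


# ------------------------------------------------------------------ PDB

def _model_to_atoms(bio_model) -> list[AtomRecord]:
    atoms = []
    for chain in bio_model:
        for residue in chain:
            for atom in residue:
                element = atom.element or atom.get_name()[0]
                atoms.append(
                    AtomRecord(
                        chain=chain.id,
                        res_index=residue.id[1],
                        res_name=residue.get_resname().strip(),
                        atom_name=atom.get_name(),
                        element=element,
                        coords=tuple(float(c) for c in atom.coord),
                    )
                )
    return atoms


def read_structure(
    path, structure_id: str | None = None, segment_map: SegmentMap | None = None,
    model_index: int = 0,
) -> StructureModel:
    """Read a PDB file as a single structure (first MODEL by default)."""
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(structure_id or path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")
    if model_index >= len(models):
        raise ValueError(f"{path}: model {model_index} absent ({len(models)} models)")
    return StructureModel(
        structure_id or path.stem, _model_to_atoms(models[model_index]), segment_map
    )


def read_trajectory(
    path,
    replicate_id: str,
    condition: str,
    segment_map: SegmentMap | None = None,
) -> Trajectory:
    """Read a multi-model PDB (MODEL/ENDMDL) as trajectory frames."""
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    frames = [
        StructureModel(f"{path.stem}/frame{i}", _model_to_atoms(m), segment_map)
        for i, m in enumerate(structure)
    ]
    if not frames:
        raise ValueError(f"{path}: no models found")
    return Trajectory(replicate_id, condition, frames)


def write_structure(
    model: StructureModel, path, bfactors: dict[tuple[str, int], float] | None = None
) -> None:
    """Write a StructureModel as a PDB file (optionally with B-factors)."""
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure(model.structure_id)
    builder.init_model(0)
    builder.init_seg("    ")
    current_chain = None
    current_res = None
    serial = 1
    for a in model.atoms:
        if a.chain != current_chain:
            builder.init_chain(a.chain)
            current_chain, current_res = a.chain, None
        if a.res_index != current_res:
            builder.init_residue(a.res_name, " ", a.res_index, " ")
            current_res = a.res_index
        b = 0.0
        if bfactors is not None:
            b = bfactors.get((a.chain, a.res_index), 0.0)
        builder.init_atom(
            a.atom_name,
            np.asarray(a.coords, dtype=float),
            b,
            1.0,
            " ",
            a.atom_name.center(4)[:4],
            serial,
            element=a.element,
        )
        serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ------------------------------------------------------------------ FASTA

def read_msa(path) -> MultipleSeqAlignment:
    """Read an aligned FASTA file."""
    try:
        return AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ValueError(f"{path}: not a valid aligned FASTA ({exc})") from exc


def write_msa(seqs, path) -> None:
    """Write {id: aligned_seq} or a MultipleSeqAlignment as FASTA."""
    if hasattr(seqs, "items"):
        seqs = MultipleSeqAlignment(
            [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
        )
    AlignIO.write(seqs, str(path), "fasta")


# ------------------------------------------------------------- TSV tables

def _write_tsv(df: pd.DataFrame, path, metadata: dict | None = None, index=False) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def read_table_metadata(path) -> dict[str, str]:
    """Recover ``# key: value`` header metadata from a table file."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _n_comment_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def write_variants(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    _write_tsv(df, path, metadata)


def read_variants(path) -> pd.DataFrame:
    """Read a variant table, validating each row.

    Required columns: receptor_id, position, ref_aa, alt_aa, count, source.
    Malformed rows (negative counts, non-integer positions) are rejected
    with their 1-based line number in the file.
    """
    path = Path(path)
    header_offset = _n_comment_lines(path) + 1  # comments plus header line
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ValueError(f"{path}: unreadable variant table ({exc})") from exc
    required = ["receptor_id", "position", "ref_aa", "alt_aa", "count", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    for i, row in df.iterrows():
        line = header_offset + i + 1
        try:
            pos, count = int(row["position"]), int(row["count"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}: line {line}: non-integer position or count")
        if pos < 1:
            raise ValueError(f"{path}: line {line}: position must be >= 1, got {pos}")
        if count < 0:
            raise ValueError(f"{path}: line {line}: negative count {count}")
    df["position"] = df["position"].astype(int)
    df["count"] = df["count"].astype(int)
    return df


def write_distances(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    _write_tsv(df, path, metadata)


def read_distances(path) -> list[DistanceSeries]:
    """Read a per-frame distance table into DistanceSeries (one per
    replicate).  Columns: replicate_id, condition, frame, distance_A
    (res_a/res_b optional)."""
    from .simulate import series_from_table

    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["replicate_id", "condition", "frame", "distance_A"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    return series_from_table(df)


def write_segment_map(segmaps: SegmentMap | list[SegmentMap], path) -> None:
    """Write one or several segment maps to a single TSV."""
    if isinstance(segmaps, SegmentMap):
        segmaps = [segmaps]
    rows = [
        {
            "receptor_id": m.receptor_id,
            "helix": s.helix,
            "seq_start": s.seq_start,
            "seq_end": s.seq_end,
            "label_start": str(s.label_start),
        }
        for m in segmaps
        for s in m.segments
    ]
    _write_tsv(pd.DataFrame(rows), path)


def read_segment_map(path) -> dict[str, SegmentMap]:
    """Read one or more segment maps from a TSV (receptor_id, helix,
    seq_start, seq_end, label_start)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for rid, grp in df.groupby("receptor_id", sort=True):
        segments = tuple(
            HelixSegment(
                helix=int(r.helix),
                seq_start=int(r.seq_start),
                seq_end=int(r.seq_end),
                label_start=GenericLabel.parse(r.label_start),
            )
            for r in grp.itertuples(index=False)
        )
        out[str(rid)] = SegmentMap(str(rid), segments)
    return out


# -------------------------------------------------------------- projection

def project_scores(
    model: StructureModel,
    scores: dict[str, float] | pd.Series,
    path,
    sentinel: float = 0.0,
) -> int:
    """Write the model as PDB with per-residue scores in the B-factor column.

    ``scores`` maps generic labels (string form) to values; every atom of a
    mapped residue carries its residue's score (rounded to the 2-decimal
    B-factor field, clamped to the fixed-width range with a warning), and
    unscored residues carry the sentinel (default 0.00).  Returns the
    number of scored residues; raises if the model maps none of the scored
    labels.
    """
    if model.segment_map is None:
        raise ValueError("model has no segment map; cannot project by generic label")
    scores = dict(pd.Series(scores).items())
    bfactors: dict[tuple[str, int], float] = {}
    n_scored = 0
    for (chain, res_index) in model.residues():
        label = model.label_of(res_index)
        value = scores.get(str(label)) if label is not None else None
        if value is None:
            bfactors[(chain, res_index)] = sentinel
            continue
        clamped = min(max(float(value), B_FACTOR_MIN), B_FACTOR_MAX)
        if clamped != float(value):
            warnings.warn(
                f"score {value} at {label} clamped to B-factor range "
                f"[{B_FACTOR_MIN}, {B_FACTOR_MAX}]"
            )
        bfactors[(chain, res_index)] = clamped
        n_scored += 1
    if n_scored == 0:
        raise ValueError("no scored labels are mapped in the model")
    write_structure(model, path, bfactors=bfactors)
    return n_scored


# -------------------------------------------------------------- provenance

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    out_dir, command: str, parameters: dict, inputs: list | None = None
) -> Path:
    """Write a machine-readable run record (parameters, seed, input
    checksums, package version) next to the results."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "version": __version__,
        "python": sys.version.split()[0],
        "parameters": {k: str(v) for k, v in parameters.items()},
        "inputs": {
            str(p): _sha256(p) for p in (inputs or []) if Path(p).is_file()
        },
    }
    path = out_dir / f"provenance_{command}.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path
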