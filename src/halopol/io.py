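"""Plain-text readers/writers for the toolkit's external formats.

Traces: TSV (trace_id, role, time_s, extension_nm). Spectra: CSV
(wavenumber_cm1, intensity). Binding: CSV (concentration_nM, response_RU).
Sequences: FASTA wrapped at 60 columns; disorder tracks: TSV (position,
probability); domains: TSV (name, start, end, 1-based inclusive). Ground
truth / results: JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import FormatError
from .flowstretch import Trace
from .raman import Spectrum
from .seqprofile import DisorderTrack, DomainAnnotation, SequenceRecord
from .spr import BindingSeries

__all__ = [
    "read_traces_tsv",
    "write_traces_tsv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_binding_csv",
    "write_binding_csv",
    "read_fasta",
    "write_fasta",
    "read_fasta_alignment",
    "read_disorder_tsv",
    "write_disorder_tsv",
    "read_domains_tsv",
    "write_domains_tsv",
    "read_json",
    "write_json",
]

TRACE_COLUMNS = ("trace_id", "role", "time_s", "extension_nm")


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_traces_tsv(path) -> list[Trace]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, TRACE_COLUMNS, path)
    traces = []
    for tid, group in df.groupby("trace_id", sort=False):
        roles = group["role"].unique()
        if len(roles) != 1 or roles[0] not in ("reaction", "control"):
            raise FormatError(f"{path}: trace {tid!r} has invalid role values {list(roles)}")
        traces.append(
            Trace(
                trace_id=str(tid),
                role=str(roles[0]),
                time=group["time_s"].to_numpy(float),
                extension=group["extension_nm"].to_numpy(float),
            )
        )
    return traces


def write_traces_tsv(traces: Sequence[Trace], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "trace_id": t.trace_id,
                "role": t.role,
                "time_s": t.time,
                "extension_nm": t.extension,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_spectrum_csv(path) -> Spectrum:
    df = pd.read_csv(path)
    _require_columns(df, ("wavenumber_cm1", "intensity"), path)
    return Spectrum(df["wavenumber_cm1"].to_numpy(float), df["intensity"].to_numpy(float))


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": spectrum.wavenumber, "intensity": spectrum.intensity}
    ).to_csv(path, index=False, float_format="%.8g")


def read_binding_csv(path) -> BindingSeries:
    df = pd.read_csv(path)
    _require_columns(df, ("concentration_nM", "response_RU"), path)
    return BindingSeries(
        df["concentration_nM"].to_numpy(float), df["response_RU"].to_numpy(float)
    )


def write_binding_csv(series: BindingSeries, path) -> None:
    pd.DataFrame(
        {"concentration_nM": series.concentrations, "response_RU": series.responses}
    ).to_csv(path, index=False, float_format="%.8g")


def read_fasta(path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    bio = [BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")  # Biopython wraps at 60 columns


def read_fasta_alignment(path) -> tuple[tuple[str, str], tuple[str, str]]:
    """An aligned FASTA pair: returns ((query_id, gapped), (subject_id, gapped))."""
    recs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if len(recs) != 2:
        raise FormatError(f"{path}: expected exactly 2 aligned records, found {len(recs)}")
    if len(recs[0][1]) != len(recs[1][1]):
        raise FormatError(f"{path}: aligned records differ in length")
    return recs[0], recs[1]


def read_disorder_tsv(path) -> DisorderTrack:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("position", "probability"), path)
    df = df.sort_values("position")
    pos = df["position"].to_numpy(int)
    if not np.array_equal(pos, np.arange(1, pos.size + 1)):
        raise FormatError(f"{path}: positions must be 1..N without gaps")
    return DisorderTrack(probabilities=df["probability"].to_numpy(float))


def write_disorder_tsv(track: DisorderTrack, path) -> None:
    pd.DataFrame(
        {"position": np.arange(1, len(track) + 1), "probability": track.probabilities}
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_domains_tsv(path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("name", "start", "end"), path)
    return [
        DomainAnnotation(name=str(r["name"]), start=int(r["start"]), end=int(r["end"]))
        for _, r in df.iterrows()
    ]


def write_domains_tsv(domains: Sequence[DomainAnnotation], path) -> None:
    pd.DataFrame(
        {"name": [d.name for d in domains], "start": [d.start for d in domains], "end": [d.end for d in domains]}
    ).to_csv(path, sep="\t", index=False)


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
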