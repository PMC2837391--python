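"""Readers and writers for the plain-text formats used throughout the pipeline.

Tag-count tables, annotation maps and ground-truth tables are TSV with a
header row; unigene sets are FASTA.  Every writer can stamp a provenance
comment line (``# mpsspipe <key>=<value> ...``) ahead of the header so that
downstream stages can refuse to compose intermediates produced under a
different configuration.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMMENT_PREFIX = "# mpsspipe"


class ProvenanceMismatchError(RuntimeError):
    """An intermediate file was produced under a different configuration."""


def _format_meta(meta: dict | None) -> str | None:
    if not meta:
        return None
    parts = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"{COMMENT_PREFIX} {parts}"


def _parse_meta(line: str) -> dict:
    meta = {}
    for token in line[len(COMMENT_PREFIX):].split():
        if "=" in token:
            key, value = token.split("=", 1)
            meta[key] = value
    return meta


def write_tsv(frame: pd.DataFrame, path: str | Path, *, index: bool = False,
              meta: dict | None = None) -> None:
    path = Path(path)
    try:
        with open(path, "w") as handle:
            header = _format_meta(meta)
            if header:
                handle.write(header + "\n")
            frame.to_csv(handle, sep="\t", index=index)
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc


def read_tsv(path: str | Path, *, index_col=None,
             expected_meta: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Read a TSV, returning ``(frame, meta)``.

    If ``expected_meta`` is given, every key present in both the file's
    provenance line and the expectation must agree, otherwise a
    :class:`ProvenanceMismatchError` is raised.
    """
    path = Path(path)
    meta: dict = {}
    try:
        text = path.read_text()
    except OSError as exc:
        raise OSError(f"cannot read table from {path}: {exc}") from exc
    if text.startswith(COMMENT_PREFIX):
        first, _, rest = text.partition("\n")
        meta = _parse_meta(first)
        text = rest
    if expected_meta:
        for key, value in expected_meta.items():
            if key in meta and meta[key] != str(value):
                raise ProvenanceMismatchError(
                    f"{path}: provenance {key}={meta[key]!r} does not match "
                    f"expected {value!r}")
    frame = pd.read_csv(_io.StringIO(text), sep="\t", index_col=index_col)
    return frame, meta


def write_counts(counts: pd.DataFrame, path: str | Path,
                 meta: dict | None = None) -> None:
    """Write a signature count table (index = signature, one column per library)."""
    out = counts.copy()
    out.index.name = "signature"
    write_tsv(out.reset_index(), path, meta=meta)


def read_counts(path: str | Path,
                expected_meta: dict | None = None) -> pd.DataFrame:
    frame, _ = read_tsv(path, expected_meta=expected_meta)
    if "signature" not in frame.columns:
        raise ValueError(f"{path}: counts table lacks a 'signature' column")
    frame = frame.set_index("signature")
    return frame


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    try:
        SeqIO.write(records, str(path), "fasta")
    except OSError as exc:
        raise OSError(f"cannot write FASTA to {path}: {exc}") from exc


def read_fasta(path: str | Path) -> dict[str, str]:
    try:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(path), "fasta")}
    except OSError as exc:
        raise OSError(f"cannot read FASTA from {path}: {exc}") from exc


def write_annotations(annotations: pd.DataFrame, path: str | Path,
                      meta: dict | None = None) -> None:
    write_tsv(annotations, path, meta=meta)


def read_annotations(path: str | Path) -> pd.DataFrame:
    frame, _ = read_tsv(path)
    return frame
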