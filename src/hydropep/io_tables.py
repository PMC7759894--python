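"""Readers and writers for the tabular formats the pipeline touches.

Peptide identification tables follow the MaxQuant ``peptides.txt``
convention: a tab-separated file with a ``Sequence`` column and one MS1
intensity column per sample, each named ``Intensity <sample>``.  Rows are
validated into :class:`PeptideRecord` objects; sequences with characters
outside the 20 standard one-letter codes, or outside the 3--65 residue
identification window, are rejected and accounted for in a rejection
report so that record counts always reconcile with row counts.

Proteome references are plain FASTA, read through Biopython.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .properties import AMINO_ACIDS

__all__ = [
    "PeptideRecord",
    "ProteomeStats",
    "TableDialect",
    "Rejection",
    "ParsedTable",
    "ConfigurationError",
    "TableParseError",
    "read_peptide_table",
    "write_peptide_table",
    "read_fasta",
    "write_fasta",
    "write_profile_report",
    "read_profile_json",
]

MIN_PEPTIDE_LENGTH = 3
MAX_PEPTIDE_LENGTH = 65


class ConfigurationError(ValueError):
    """A configured column or option does not match the input table."""


class TableParseError(ValueError):
    """A cell could not be parsed; the row index is part of the message."""


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide in one sample.

    ``intensity`` is an MS1 precursor intensity in arbitrary units; zero
    means "not detected" and such records carry no weight in weighted
    statistics.
    """

    sequence: str
    sample: str
    intensity: float


@dataclass(frozen=True)
class ProteomeStats:
    """Summary statistics of a protein reference database."""

    n_entries: int
    mean_length: float


@dataclass(frozen=True)
class TableDialect:
    """Column conventions of the peptide table.

    ``modification_regex`` is stripped from sequences before validation so
    that inline modification marks (e.g. ``(ox)`` / bracket notations and
    flanking underscores) do not fail the residue-alphabet check.
    """

    sequence_column: str = "Sequence"
    intensity_prefix: str = "Intensity "
    modification_regex: str = r"\([^)]*\)|\[[^\]]*\]|_"


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class Rejection:
    row: int
    sequence: str
    reason: str


@dataclass
class ParsedTable:
    """Parse result: validated records plus the rejection ledger.

    ``n_rows`` x ``len(samples)`` minus rejected and (optionally) dropped
    zero-intensity entries equals ``len(records)``.
    """

    records: list[PeptideRecord]
    rejections: list[Rejection]
    samples: list[str]
    n_rows: int
    n_zero_dropped: int = 0

    def ids_per_sample(self) -> dict[str, dict[str, int]]:
        """Peptide counts per sample, both as rows and as distinct sequences.

        Upstream tools are ambiguous about whether "peptide IDs" counts
        table rows or distinct sequences, so both are reported.
        """
        out: dict[str, dict[str, int]] = {}
        for sample in self.samples:
            recs = [r for r in self.records if r.sample == sample]
            out[sample] = {
                "rows": len(recs),
                "distinct_sequences": len({r.sequence for r in recs}),
            }
        return out


def _clean_sequence(raw: str, dialect: TableDialect) -> str:
    import re

    seq = re.sub(dialect.modification_regex, "", raw.strip())
    return seq.upper()


def read_peptide_table(
    path: str | Path,
    dialect: TableDialect | None = None,
    keep_zero: bool = False,
) -> ParsedTable:
    """Parse a peptide table into one record per (row, intensity column).

    Zero-intensity entries are dropped by default (they cannot contribute
    weight); pass ``keep_zero=True`` to retain them.
    """
    dialect = dialect or DEFAULT_DIALECT
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    if dialect.sequence_column not in frame.columns:
        raise ConfigurationError(
            f"sequence column {dialect.sequence_column!r} not found in {path}"
        )
    intensity_cols = [
        c for c in frame.columns if c.startswith(dialect.intensity_prefix)
    ]
    if intensity_cols:
        samples = [c[len(dialect.intensity_prefix):] for c in intensity_cols]
    elif dialect.intensity_prefix.strip() in frame.columns:
        # single-sample table with a bare "Intensity" column
        intensity_cols = [dialect.intensity_prefix.strip()]
        samples = [dialect.intensity_prefix.strip()]
    else:
        raise ConfigurationError(
            f"no intensity column with prefix {dialect.intensity_prefix!r} in {path}"
        )

    columns = list(frame.columns)
    seq_idx = columns.index(dialect.sequence_column)
    col_idx = [columns.index(c) for c in intensity_cols]

    records: list[PeptideRecord] = []
    rejections: list[Rejection] = []
    n_zero_dropped = 0
    for row_idx, values in enumerate(frame.itertuples(index=False, name=None)):
        raw_seq = values[seq_idx]
        seq = _clean_sequence(raw_seq, dialect)
        bad = next((ch for ch in seq if ch not in AMINO_ACIDS), None)
        if not seq or bad is not None:
            reason = "empty sequence" if not seq else f"non-standard residue {bad!r}"
            rejections.append(Rejection(row_idx, raw_seq, reason))
            continue
        if not MIN_PEPTIDE_LENGTH <= len(seq) <= MAX_PEPTIDE_LENGTH:
            rejections.append(
                Rejection(row_idx, raw_seq, f"length {len(seq)} outside 3..65")
            )
            continue
        for idx, col, sample in zip(col_idx, intensity_cols, samples):
            text = str(values[idx]).strip()
            if text in ("", "NaN", "nan"):
                value = 0.0
            else:
                try:
                    value = float(text)
                except ValueError as exc:
                    raise TableParseError(
                        f"row {row_idx}: cannot parse intensity {text!r} "
                        f"in column {col!r}"
                    ) from exc
            if value < 0:
                raise TableParseError(
                    f"row {row_idx}: negative intensity {value} in column {col!r}"
                )
            if value == 0.0 and not keep_zero:
                n_zero_dropped += 1
                continue
            records.append(PeptideRecord(seq, sample, value))

    return ParsedTable(
        records=records,
        rejections=rejections,
        samples=samples,
        n_rows=len(frame),
        n_zero_dropped=n_zero_dropped,
    )


def write_peptide_table(
    records: Iterable[PeptideRecord],
    path: str | Path,
    dialect: TableDialect | None = None,
) -> Path:
    """Serialize records back to the tabular dialect (one row per sequence)."""
    dialect = dialect or DEFAULT_DIALECT
    records = list(records)
    samples = sorted({r.sample for r in records})
    by_seq: dict[str, dict[str, float]] = {}
    for rec in records:
        by_seq.setdefault(rec.sequence, {})[rec.sample] = (
            by_seq.get(rec.sequence, {}).get(rec.sample, 0.0) + rec.intensity
        )
    rows = []
    for seq in sorted(by_seq):
        row: dict[str, object] = {dialect.sequence_column: seq}
        for sample in samples:
            row[f"{dialect.intensity_prefix}{sample}"] = by_seq[seq].get(sample, 0.0)
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_fasta(path: str | Path) -> tuple[list[SeqRecord], ProteomeStats]:
    """Read a FASTA proteome and its summary statistics.

    Duplicate headers trigger a warning but both entries are kept; the mean
    length is the arithmetic mean over all sequences.
    """
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise ValueError(f"no FASTA entries in {path}")
    ids = [e.id for e in entries]
    if len(set(ids)) != len(ids):
        warnings.warn(f"duplicate FASTA headers in {path}; keeping all entries")
    lengths = [len(e.seq) for e in entries]
    return entries, ProteomeStats(len(entries), sum(lengths) / len(lengths))


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | Path) -> Path:
    """Write ``(identifier, sequence)`` pairs as FASTA."""
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


def _round_tree(obj, precision: int):
    if isinstance(obj, float):
        return round(obj, precision)
    if isinstance(obj, dict):
        return {k: _round_tree(v, precision) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v, precision) for v in obj]
    return obj


def write_profile_report(
    out_dir: str | Path,
    summaries: dict[str, dict[str, float]],
    histograms: Sequence[pd.DataFrame] = (),
    abundance: dict[str, pd.DataFrame] | None = None,
    scored: dict[str, pd.DataFrame] | None = None,
    precision: int = 6,
) -> dict[str, Path]:
    """Emit the profile result classes as TSVs plus one JSON with the same
    numbers, rounded identically so the two renderings agree exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    summary_frame = pd.DataFrame(
        [{"sample": s, **_round_tree(v, precision)} for s, v in summaries.items()]
    )
    paths["summary"] = out_dir / "summary.tsv"
    summary_frame.to_csv(paths["summary"], sep="\t", index=False)

    if histograms:
        hist_frame = pd.concat(list(histograms), ignore_index=True)
        hist_frame = hist_frame.round(precision)
        paths["histograms"] = out_dir / "histograms.tsv"
        hist_frame.to_csv(paths["histograms"], sep="\t", index=False)

    payload: dict[str, object] = {
        "summaries": _round_tree(summaries, precision),
    }
    if abundance:
        payload["abundance"] = {}
        for sample, frame in abundance.items():
            rounded = frame.round(precision)
            p = out_dir / f"abundance_{_slug(sample)}.tsv"
            rounded.to_csv(p, sep="\t", index=False)
            paths[f"abundance:{sample}"] = p
            payload["abundance"][sample] = rounded.to_dict(orient="records")
    if scored:
        payload["scored"] = {}
        for sample, frame in scored.items():
            rounded = frame.round(precision)
            p = out_dir / f"scored_{_slug(sample)}.tsv"
            rounded.to_csv(p, sep="\t", index=False)
            paths[f"scored:{sample}"] = p
            payload["scored"][sample] = rounded.to_dict(orient="records")
    if histograms:
        payload["histograms"] = hist_frame.to_dict(orient="records")

    paths["json"] = out_dir / "report.json"
    with open(paths["json"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, allow_nan=False)
    return paths


def read_profile_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name)
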