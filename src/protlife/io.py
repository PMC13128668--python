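"""Reading, validating and labeling protein sequence data.

Sequences come in as FASTA; half-life annotations come in as a two-column
TSV sidecar (id, minutes/hours or an explicit class). A protein is
*short-lived* when its half-life is strictly below the labeling threshold
(default 60 minutes), otherwise *long-lived*.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)
# ambiguity / non-standard one-letter codes we recognise but do not model
NONSTANDARD_AA = frozenset("BJOUXZ")

SHORT_LIVED = "short_lived"
LONG_LIVED = "long_lived"

#: length bounds accepted for prediction input
MIN_LENGTH = 50
MAX_LENGTH = 1655


class SequenceError(ValueError):
    """A sequence violates the input contract (alphabet, length, format)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.sequence:
            raise SequenceError(f"{self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabelingPolicy:
    """Half-life threshold separating the two stability classes.

    ``threshold_minutes`` is strict: a half-life of exactly the threshold
    is long-lived ("less than 1 h" defines the short class).
    """

    threshold_minutes: float = 60.0

    def __post_init__(self) -> None:
        if not self.threshold_minutes > 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class LabeledRecord:
    """A protein with its stability class and, optionally, its half-life."""

    record: ProteinRecord
    label: str
    half_life_minutes: float | None = None

    def __post_init__(self) -> None:
        if self.label not in (SHORT_LIVED, LONG_LIVED):
            raise ValueError(f"unknown label {self.label!r}")
        if self.half_life_minutes is not None:
            implied = assign_label(self.half_life_minutes)
            if implied != self.label:
                raise ValueError(
                    f"{self.record.id}: label {self.label} inconsistent with "
                    f"half-life {self.half_life_minutes} min"
                )


def assign_label(
    half_life_minutes: float, policy: LabelingPolicy = LabelingPolicy()
) -> str:
    """Map a half-life in minutes to ``short_lived`` or ``long_lived``.

    The comparison is strict: ``short_lived`` iff value < threshold.
    """
    if half_life_minutes < 0:
        raise ValueError(f"negative half-life: {half_life_minutes}")
    return SHORT_LIVED if half_life_minutes < policy.threshold_minutes else LONG_LIVED


def _clean_sequence(raw: str, rec_id: str, strict: bool) -> str:
    seq = raw.upper().rstrip("*")
    if not seq:
        raise SequenceError(f"{rec_id}: empty sequence")
    bad = set(seq) - _STANDARD_SET
    if not bad:
        return seq
    if any(c in "-." for c in bad):
        raise SequenceError(f"{rec_id}: gap characters present: {sorted(bad)}")
    if bad <= NONSTANDARD_AA and not strict:
        # lenient mode: collapse ambiguity codes to X; descriptor code
        # excludes terms involving X
        return "".join(c if c in _STANDARD_SET else "X" for c in seq)
    raise SequenceError(
        f"{rec_id}: non-standard residues {sorted(bad)} (strict mode)"
    )


def read_fasta(path: str | Path, strict: bool = True) -> list[ProteinRecord]:
    """Parse a FASTA file into validated records, order preserved.

    Sequences are uppercased and terminal stop characters (``*``) stripped.
    In strict mode any residue outside the 20-letter alphabet is an error;
    otherwise recognised ambiguity codes are mapped to ``X``.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise SequenceError(
                    f"{path}:{lineno}: expected FASTA header, got {line[:40]!r}"
                )
            break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(_io.StringIO(text), "fasta"):
        if entry.id in seen:
            raise SequenceError(f"duplicate FASTA id: {entry.id}")
        seen.add(entry.id)
        records.append(
            ProteinRecord(entry.id, _clean_sequence(str(entry.seq), entry.id, strict))
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def validate_for_prediction(
    record: ProteinRecord, min_len: int = MIN_LENGTH, max_len: int = MAX_LENGTH
) -> ProteinRecord:
    """Check the prediction-input contract; returns the record unchanged."""
    n = len(record)
    if not min_len <= n <= max_len:
        raise SequenceError(
            f"{record.id}: length {n} outside [{min_len}, {max_len}]"
        )
    bad = set(record.sequence) - _STANDARD_SET
    if bad:
        raise SequenceError(f"{record.id}: non-standard residues {sorted(bad)}")
    return record


def read_labels(
    path: str | Path,
    fasta_ids: Iterable[str] | None = None,
    unit: str = "minutes",
) -> dict[str, float | str]:
    """Read a two-column TSV of (id, half-life) or (id, class).

    Numeric second columns are half-lives in ``unit`` ("minutes" or
    "hours"), returned in minutes; the strings ``short_lived``/``long_lived``
    are returned as-is. Mixing the two column kinds is rejected, as are
    negative half-lives and ids absent from ``fasta_ids`` (when given).
    """
    if unit not in ("minutes", "hours"):
        raise ValueError(f"unknown unit {unit!r}")
    factor = 1.0 if unit == "minutes" else 60.0
    out: dict[str, float | str] = {}
    kinds: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            if lineno == 1:  # tolerate a header row
                continue
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        key, value = parts[0].strip(), parts[1].strip()
        if lineno == 1 and value.lower() in ("half_life", "label", "class", "minutes", "hours"):
            continue
        if key in out:
            raise ValueError(f"{path}:{lineno}: duplicate id {key}")
        if value in (SHORT_LIVED, LONG_LIVED):
            kinds.add("class")
            out[key] = value
        else:
            try:
                hl = float(value)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: {value!r} is neither a number nor a class"
                ) from exc
            if hl < 0:
                raise ValueError(f"{path}:{lineno}: negative half-life {hl}")
            kinds.add("numeric")
            out[key] = hl * factor
    if len(kinds) > 1:
        raise ValueError(f"{path}: mixed numeric and class label columns")
    if fasta_ids is not None:
        missing = sorted(set(out) - set(fasta_ids))
        if missing:
            raise ValueError(f"label ids missing from FASTA: {missing}")
    return out


def label_records(
    records: Iterable[ProteinRecord],
    labels: Mapping[str, float | str],
    policy: LabelingPolicy = LabelingPolicy(),
) -> list[LabeledRecord]:
    """Join records with their labels, applying the half-life threshold."""
    out = []
    for rec in records:
        if rec.id not in labels:
            raise ValueError(f"no label for {rec.id}")
        val = labels[rec.id]
        if isinstance(val, str):
            out.append(LabeledRecord(rec, val))
        else:
            out.append(
                LabeledRecord(rec, assign_label(val, policy), half_life_minutes=val)
            )
    return out


def write_predictions(rows: Iterable[dict], path: str | Path) -> None:
    """Write prediction rows as TSV: id, probability_long_lived, predicted_class, error."""
    with open(path, "w") as fh:
        fh.write("id\tprobability_long_lived\tpredicted_class\terror\n")
        for row in rows:
            prob = row.get("probability_long_lived")
            fh.write(
                "{}\t{}\t{}\t{}\n".format(
                    row["id"],
                    "" if prob is None else f"{prob:.6f}",
                    row.get("predicted_class", ""),
                    row.get("error", ""),
                )
            )
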