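"""Length filtering and greedy redundancy reduction at a sequence-identity cutoff.

Mirrors the CD-HIT procedure at desk scale: records are sorted longest
first and each joins the first existing cluster whose representative is at
least ``identity_cutoff`` identical, otherwise it founds a new cluster.
Identity is the number of matched residues in an optimal global alignment
(match=1, mismatch=0, gap=0 — i.e. the longest common subsequence) divided
by the shorter sequence's length. The k-mer prefilter heuristics of the
real tool are deliberately absent: exact alignment is affordable for a few
thousand sequences and keeps the procedure deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align

from .io import ProteinRecord


@dataclass(frozen=True)
class FilterConfig:
    min_length: int = 50
    identity_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.identity_cutoff <= 1:
            raise ValueError("identity_cutoff must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class ClusterAssignment:
    representative_id: str
    member_ids: list[str]


def length_filter(
    records: Sequence[ProteinRecord], min_length: int = 50
) -> list[ProteinRecord]:
    """Drop records shorter than ``min_length``; order preserved."""
    return [r for r in records if len(r) >= min_length]


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = 0
    al.open_gap_score = 0
    al.extend_gap_score = 0
    return al


_ALIGNER = _aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues in the optimal global alignment.

    Denominator is the shorter sequence's length (the CD-HIT convention);
    with match=1/mismatch=0/gap=0 the optimal score is the longest common
    subsequence length, so the result is symmetric and in [0, 1].
    """
    if not a or not b:
        raise ValueError("empty sequence")
    matches = _ALIGNER.score(a, b)
    return matches / min(len(a), len(b))


def greedy_cluster(
    records: Sequence[ProteinRecord], identity_cutoff: float = 0.5
) -> list[ClusterAssignment]:
    """Greedy incremental clustering against representatives only.

    Records are processed longest first (ties by id, lexicographic); a
    record joins the first cluster, in creation order, whose representative
    is >= ``identity_cutoff`` identical, else it starts a new cluster. The
    representative of a cluster is therefore its longest member. Output is
    independent of input order.
    """
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    clusters: list[ClusterAssignment] = []
    reps: list[ProteinRecord] = []
    for rec in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            if pairwise_identity(rec.sequence, rep.sequence) >= identity_cutoff:
                cluster.member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(ClusterAssignment(rec.id, [rec.id]))
            reps.append(rec)
    return clusters


def representatives(
    records: Sequence[ProteinRecord], clusters: Iterable[ClusterAssignment]
) -> list[ProteinRecord]:
    """The deduplicated record set, in original record order."""
    keep = {c.representative_id for c in clusters}
    return [r for r in records if r.id in keep]


def write_cluster_table(
    clusters: Iterable[ClusterAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_index\trepresentative_id\tmember_id\n")
        for i, c in enumerate(clusters):
            for member in c.member_ids:
                fh.write(f"{i}\t{c.representative_id}\t{member}\n")


def write_clstr(
    records: Sequence[ProteinRecord],
    clusters: Iterable[ClusterAssignment],
    path: str | Path,
) -> None:
    """CD-HIT ``.clstr``-style listing, for interoperability."""
    lengths = {r.id: len(r) for r in records}
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            fh.write(f">Cluster {i}\n")
            for j, member in enumerate(c.member_ids):
                mark = "*" if member == c.representative_id else ""
                fh.write(f"{j}\t{lengths[member]}aa, >{member}... {mark}\n")
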