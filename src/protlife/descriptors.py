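"""Physicochemical sequence descriptors, tagged by ablation group.

Four families are computed, each assigned to one of four groups used by
the leave-one-group-out ablation:

=====================  ==========================  ===============
family                 what it measures            group
=====================  ==========================  ===============
CKSAAP                 k-spaced residue pairs      GAPPED_KMER
DDE                    dipeptide deviation from    GROUPED_COMPOSITION
                       codon-expected frequency
CTD                    composition/transition/     PHYSCHEM_PROPERTY
                       distribution over 3-class
                       property partitions
Moran, SOCN            property autocorrelation,   SEQUENCE_ORDER
                       sequence-order coupling
=====================  ==========================  ===============

Feature order is canonical and documented: families in the order CKSAAP,
DDE, CTD, Moran, SOCN; alphabetical residues within a family; ascending
gap/lag. Degenerate denominators (e.g. zero property variance on a
homopolymer) yield 0, never NaN, so downstream selection always sees
finite values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from . import tables
from .io import ProteinRecord
from .tables import AA, AA_INDEX


class DescriptorGroup(str, Enum):
    GAPPED_KMER = "GAPPED_KMER"
    GROUPED_COMPOSITION = "GROUPED_COMPOSITION"
    PHYSCHEM_PROPERTY = "PHYSCHEM_PROPERTY"
    SEQUENCE_ORDER = "SEQUENCE_ORDER"


@dataclass(frozen=True)
class DescriptorConfig:
    """Which families to compute and their sizes."""

    cksaap_max_gap: int = 5
    moran_nlag: int = 30
    socn_nlag: int = 30
    use_grantham_socn: bool = False  # append a second SOCN block

    def __post_init__(self) -> None:
        if self.cksaap_max_gap < 0:
            raise ValueError("cksaap_max_gap must be >= 0")
        if self.moran_nlag < 1 or self.socn_nlag < 1:
            raise ValueError("lags must be >= 1")


@dataclass
class DescriptorVector:
    values: np.ndarray
    names: list[str]
    groups: list[DescriptorGroup]

    def __post_init__(self) -> None:
        if not (len(self.values) == len(self.names) == len(self.groups)):
            raise ValueError("values/names/groups length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite descriptor values")


def _indices(sequence: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[c] for c in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from exc


# --- CKSAAP --------------------------------------------------------------

def cksaap(sequence: str, max_gap: int = 5) -> np.ndarray:
    """Composition of k-spaced amino-acid pairs, gaps 0..max_gap.

    Feature (a, b, g) counts positions i with seq[i] == a and
    seq[i+g+1] == b, normalised by the number of such pairs (L - g - 1);
    each 400-feature gap block therefore sums to 1.
    """
    L = len(sequence)
    if L <= max_gap + 1:
        raise ValueError(f"sequence of length {L} too short for gap {max_gap}")
    idx = _indices(sequence)
    blocks = []
    for g in range(max_gap + 1):
        span = g + 1
        pair = idx[:-span] * 20 + idx[span:]
        counts = np.bincount(pair, minlength=400).astype(float)
        blocks.append(counts / (L - span))
    return np.concatenate(blocks)


def cksaap_names(max_gap: int = 5) -> list[str]:
    return [
        f"CKSAAP.g{g}.{a}{b}"
        for g in range(max_gap + 1)
        for a in AA
        for b in AA
    ]


# --- DDE -----------------------------------------------------------------

_CODONS = np.array([tables.CODON_COUNTS[a] for a in AA], dtype=float)


def dde(sequence: str) -> np.ndarray:
    """Dipeptide deviation from the codon-usage-expected mean.

    For dipeptide (a, b): Dc = count/(L-1); Tm = (Ca/61)(Cb/61);
    Tv = Tm(1-Tm)/(L-1); DDE = (Dc - Tm)/sqrt(Tv).
    """
    L = len(sequence)
    if L < 2:
        raise ValueError("DDE requires length >= 2")
    idx = _indices(sequence)
    pair = idx[:-1] * 20 + idx[1:]
    dc = np.bincount(pair, minlength=400).astype(float) / (L - 1)
    tm = np.outer(_CODONS / 61.0, _CODONS / 61.0).ravel()
    tv = tm * (1.0 - tm) / (L - 1)
    return (dc - tm) / np.sqrt(tv)


def dde_names() -> list[str]:
    return [f"DDE.{a}{b}" for a in AA for b in AA]


# --- CTD -----------------------------------------------------------------

_CTD_CLASS = {
    name: tables.ctd_class_array(name) for name in tables.CTD_ATTRIBUTES
}
_DIST_POINTS = (0.0, 0.25, 0.50, 0.75, 1.0)


def ctd(sequence: str) -> np.ndarray:
    """Composition/Transition/Distribution over 7 three-class partitions.

    Per attribute: 3 class fractions; 3 between-class adjacent-pair
    frequencies over (L-1); and, per class, the positions (% of L) of the
    first, 25th-, 50th-, 75th-percentile and last residue of that class
    (all 0 for an absent class). 7 x (3 + 3 + 15) = 147 features.
    """
    L = len(sequence)
    if L < 2:
        raise ValueError("CTD requires length >= 2")
    idx = _indices(sequence)
    out: list[float] = []
    for name in tables.CTD_ATTRIBUTES:
        cls = _CTD_CLASS[name][idx]
        # composition
        comp = np.bincount(cls, minlength=3).astype(float) / L
        out.extend(comp)
        # transitions between unordered class pairs (0,1), (0,2), (1,2)
        a, b = cls[:-1], cls[1:]
        for c1, c2 in ((0, 1), (0, 2), (1, 2)):
            n = np.sum(((a == c1) & (b == c2)) | ((a == c2) & (b == c1)))
            out.append(n / (L - 1))
        # distribution
        for c in range(3):
            pos = np.flatnonzero(cls == c) + 1  # 1-based
            if len(pos) == 0:
                out.extend([0.0] * len(_DIST_POINTS))
                continue
            n = len(pos)
            for p in _DIST_POINTS:
                k = max(1, int(np.ceil(p * n)))
                out.append(100.0 * pos[k - 1] / L)
    return np.asarray(out, dtype=float)


def ctd_names() -> list[str]:
    names = []
    for attr in tables.CTD_ATTRIBUTES:
        names.extend(f"CTD.{attr}.C{c + 1}" for c in range(3))
        names.extend(f"CTD.{attr}.T{pair}" for pair in ("12", "13", "23"))
        for c in range(3):
            names.extend(
                f"CTD.{attr}.D{c + 1}.p{int(p * 100)}" for p in _DIST_POINTS
            )
    return names


# --- Moran autocorrelation ----------------------------------------------

_MORAN_SCALES = np.stack(
    [tables.scale_vector(scale) for _, scale in tables.MORAN_PROPERTIES]
)  # (n_props, 20), each z-scored over residues


def moran(sequence: str, n_lag: int = 30) -> np.ndarray:
    """Moran autocorrelation of property profiles at lags 1..n_lag.

    I(d) = [(1/(L-d)) sum_i (P_i - Pbar)(P_{i+d} - Pbar)] /
           [(1/L) sum_i (P_i - Pbar)^2], Pbar the sequence mean. A zero
    denominator (constant profile) yields 0.
    """
    L = len(sequence)
    if n_lag >= L:
        raise ValueError(f"n_lag {n_lag} >= sequence length {L}")
    idx = _indices(sequence)
    profiles = _MORAN_SCALES[:, idx]  # (n_props, L)
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    denom = (centered**2).mean(axis=1)  # (n_props,)
    out = np.zeros((len(_MORAN_SCALES), n_lag))
    # constant profiles leave only rounding residue after centring; treat
    # variance below 1e-10 (profiles are O(1) after z-scoring) as degenerate
    ok = denom > 1e-10
    for d in range(1, n_lag + 1):
        num = (centered[:, :-d] * centered[:, d:]).sum(axis=1) / (L - d)
        out[ok, d - 1] = num[ok] / denom[ok]
    return out.ravel()


def moran_names(n_lag: int = 30) -> list[str]:
    return [
        f"Moran.{name}.lag{d}"
        for name, _ in tables.MORAN_PROPERTIES
        for d in range(1, n_lag + 1)
    ]


# --- Sequence-order coupling numbers ------------------------------------

_SW_DIST = tables.physicochemical_distance_matrix()
_GRANTHAM_DIST = tables.grantham_like_distance_matrix()


def socn(sequence: str, n_lag: int = 30, distance: np.ndarray | None = None) -> np.ndarray:
    """tau_d = sum_i dist(seq[i], seq[i+d])^2 for d in 1..n_lag."""
    L = len(sequence)
    if n_lag >= L:
        raise ValueError(f"n_lag {n_lag} >= sequence length {L}")
    D2 = (_SW_DIST if distance is None else distance) ** 2
    idx = _indices(sequence)
    return np.array(
        [D2[idx[:-d], idx[d:]].sum() for d in range(1, n_lag + 1)], dtype=float
    )


def socn_names(n_lag: int = 30, block: str = "physchem") -> list[str]:
    return [f"SOCN.{block}.lag{d}" for d in range(1, n_lag + 1)]


# --- assembly ------------------------------------------------------------

def descriptor_names(config: DescriptorConfig = DescriptorConfig()) -> list[str]:
    names = cksaap_names(config.cksaap_max_gap) + dde_names() + ctd_names()
    names += moran_names(config.moran_nlag) + socn_names(config.socn_nlag)
    if config.use_grantham_socn:
        names += socn_names(config.socn_nlag, block="grantham")
    return names


def descriptor_groups(
    config: DescriptorConfig = DescriptorConfig(),
) -> list[DescriptorGroup]:
    g = [DescriptorGroup.GAPPED_KMER] * (400 * (config.cksaap_max_gap + 1))
    g += [DescriptorGroup.GROUPED_COMPOSITION] * 400
    g += [DescriptorGroup.PHYSCHEM_PROPERTY] * 147
    n_order = len(tables.MORAN_PROPERTIES) * config.moran_nlag + config.socn_nlag
    if config.use_grantham_socn:
        n_order += config.socn_nlag
    g += [DescriptorGroup.SEQUENCE_ORDER] * n_order
    return g


def encode_physchem(
    sequence: str, config: DescriptorConfig = DescriptorConfig()
) -> DescriptorVector:
    """All four descriptor families for one sequence, in canonical order."""
    parts = [
        cksaap(sequence, config.cksaap_max_gap),
        dde(sequence),
        ctd(sequence),
        moran(sequence, config.moran_nlag),
        socn(sequence, config.socn_nlag),
    ]
    if config.use_grantham_socn:
        parts.append(socn(sequence, config.socn_nlag, distance=_GRANTHAM_DIST))
    return DescriptorVector(
        np.concatenate(parts), descriptor_names(config), descriptor_groups(config)
    )


def encode_records(
    records: Sequence[ProteinRecord],
    config: DescriptorConfig = DescriptorConfig(),
) -> pd.DataFrame:
    """Descriptor matrix for many records: rows ids, columns feature names."""
    names = descriptor_names(config)
    mat = np.empty((len(records), len(names)))
    for i, rec in enumerate(records):
        mat[i] = encode_physchem(rec.sequence, config).values
    return pd.DataFrame(mat, index=[r.id for r in records], columns=names)
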