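"""Aligned barcode sequences and Kimura two-parameter (K2P) distances.

The K2P model distinguishes transitions (A<->G, C<->T; proportion P of
compared sites) from transversions (proportion Q) and estimates the expected
number of substitutions per site as

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Sites where either sequence carries a gap ('-') or an ambiguous base ('N')
are excluded pair by pair (pairwise deletion), the standard practice for
ragged 16S barcode alignments.  When the observed proportions leave either
logarithm undefined (1 - 2P - Q <= 0 or 1 - 2Q <= 0) the pair is *saturated*:
the distance estimator diverges and the pair is flagged rather than given a
number.  Downstream clustering treats saturated pairs as farther apart than
any finite distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, InputError, UndefinedDistanceError

VALID_CHARS = frozenset("ACGT-N")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class Alignment:
    """An aligned set of barcode sequences (equal-length, unique ids)."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment is empty")
        if len(self.ids) != len(set(self.ids)):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        if self.length < 1:
            raise AlignmentError("alignment has zero columns")
        for sid, seq in zip(self.ids, self.seqs):
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return self.n

    def get(self, sid: str) -> str:
        return self.seqs[self.ids.index(sid)]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        recs = list(records)
        return cls(
            ids=tuple(r[0] for r in recs),
            seqs=tuple(r[1].upper() for r in recs),
        )


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; lowercase is normalized to uppercase."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return Alignment.from_records(records)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


class K2PResult(NamedTuple):
    """Outcome of a single pairwise K2P comparison."""

    distance: float | None  # None when saturated
    saturated: bool
    p: float  # transition proportion
    q: float  # transversion proportion
    sites: int  # pairwise-complete sites compared


def _site_class(x: str, y: str) -> int:
    """0 = identical, 1 = transition, 2 = transversion (both in ACGT)."""
    if x == y:
        return 0
    if (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES):
        return 1
    return 2


def k2p_counts(a: str, b: str) -> tuple[int, int, int]:
    """Count (pairwise-complete sites, transitions, transversions)."""
    if len(a) != len(b):
        raise AlignmentError(
            f"sequences have unequal lengths ({len(a)} vs {len(b)})"
        )
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            n += 1
            c = _site_class(x, y)
            if c == 1:
                ts += 1
            elif c == 2:
                tv += 1
    return n, ts, tv


def k2p_distance(a: str, b: str) -> K2PResult:
    """K2P distance between two aligned sequences under pairwise deletion.

    Raises
    ------
    UndefinedDistanceError
        If no site is pairwise complete.
    """
    n, ts, tv = k2p_counts(a.upper(), b.upper())
    if n == 0:
        raise UndefinedDistanceError("zero pairwise-comparable sites")
    p = ts / n
    q = tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(None, True, p, q, n)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    # guard against -0.0 from rounding
    return K2PResult(max(d, 0.0), False, p, q, n)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair comparable-site counts.

    Saturated pairs are stored as ``nan`` in ``d`` and flagged in
    ``saturated``; they are never silently numeric.
    """

    ids: tuple[str, ...]
    d: np.ndarray  # float, nan where saturated
    saturated: np.ndarray  # bool
    sites_used: np.ndarray  # int
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {sid: i for i, sid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        """Distance between two ids; +inf for saturated pairs."""
        i, j = self.index[a], self.index[b]
        if self.saturated[i, j]:
            return math.inf
        return float(self.d[i, j])

    def is_saturated(self, a: str, b: str) -> bool:
        return bool(self.saturated[self.index[a], self.index[b]])

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        ids = tuple(ids)
        idx = [self.index[i] for i in ids]
        return DistanceMatrix(
            ids=ids,
            d=self.d[np.ix_(idx, idx)].copy(),
            saturated=self.saturated[np.ix_(idx, idx)].copy(),
            sites_used=self.sites_used[np.ix_(idx, idx)].copy(),
        )

    def has_saturated(self) -> bool:
        return bool(self.saturated.any())

    def to_tsv(self, path: str | Path) -> None:
        """Square TSV with id header row/column; 'NA' marks saturated pairs."""
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                cells = [
                    "NA" if self.saturated[i, j] else f"{self.d[i, j]:.10g}"
                    for j in range(self.n)
                ]
                fh.write(sid + "\t" + "\t".join(cells) + "\n")

    def to_phylip(self, path: str | Path) -> None:
        """Square PHYLIP dialect; saturated pairs written as -1.0."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, sid in enumerate(self.ids):
                cells = [
                    "-1.0" if self.saturated[i, j] else f"{self.d[i, j]:.10f}"
                    for j in range(self.n)
                ]
                fh.write(f"{sid:<12s}" + "  ".join(cells) + "\n")


def distance_matrix(aln: Alignment) -> DistanceMatrix:
    """All-pairs K2P distances under pairwise deletion.

    Raises
    ------
    UndefinedDistanceError
        Naming the pair, if any pair shares zero comparable sites.
    """
    n = aln.n
    d = np.zeros((n, n), dtype=float)
    sat = np.zeros((n, n), dtype=bool)
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        sites[i, i] = sum(c in "ACGT" for c in aln.seqs[i])
        for j in range(i + 1, n):
            try:
                res = k2p_distance(aln.seqs[i], aln.seqs[j])
            except UndefinedDistanceError as exc:
                raise UndefinedDistanceError(
                    f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}): {exc}"
                ) from exc
            sites[i, j] = sites[j, i] = res.sites
            if res.saturated:
                sat[i, j] = sat[j, i] = True
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = res.distance
    return DistanceMatrix(ids=aln.ids, d=d, saturated=sat, sites_used=sites)
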