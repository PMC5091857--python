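"""Barcode-gap discovery and recursive distance-based delimitation.

The procedure mirrors automatic barcode gap discovery as used in DNA
barcoding surveys: rank all pairwise distances, skip ranks up to a prior
limit on intraspecific divergence (``prior_P``), and look for the first gap
in the ranked distribution that is large relative to the local spacing of
ranked distances.  Sequences are then partitioned by single linkage at the
gap midpoint, and the procedure is re-applied recursively within each group.

The gap test used here is normative for this package: at rank ``i`` the gap
``g_i = d[i+1] - d[i]`` is compared against ``gap_width_X`` times the mean of
the preceding ``W`` gaps (a local spacing scale), with
``W = max(2, ceil(window_frac * m))`` for ``m`` ranked distances.  The first
rank whose gap exceeds that multiple of the local scale is the barcode gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import InputError
from .seqdist import DistanceMatrix


@dataclass(frozen=True)
class AbgdConfig:
    """Tuning knobs for barcode-gap partitioning.

    prior_P
        Maximal prior intraspecific divergence (substitutions/site).  The 3%
        value is the conventional 16S threshold for Neotropical frogs.
    gap_width_X
        Relative gap width: a gap qualifies when it exceeds ``X`` times the
        local spacing of ranked distances.
    max_rounds
        Cap on recursion rounds.
    window_frac
        Width of the local-spacing window, as a fraction of the number of
        ranked distances.
    min_group_size_to_split
        Groups smaller than this are never re-split (a 2-member group has a
        single distance; no gap is definable).
    """

    prior_P: float = 0.03
    gap_width_X: float = 1.0
    max_rounds: int = 10
    window_frac: float = 0.1
    min_group_size_to_split: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_P < 1.0:
            raise InputError(f"prior_P must be in (0, 1), got {self.prior_P}")
        if self.gap_width_X <= 0:
            raise InputError(f"gap_width_X must be > 0, got {self.gap_width_X}")
        if not 1 <= self.max_rounds <= 50:
            raise InputError(f"max_rounds must be in [1, 50], got {self.max_rounds}")


@dataclass
class Partition:
    """Assignment of sequence ids to unit labels, with a decision trace.

    ``trace`` records one entry per delimitation decision:
    ``(round, group_label, threshold_or_None)``.
    """

    assignment: dict[str, str]
    trace: list[tuple[int, str, Optional[float]]] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.assignment)

    def units(self) -> dict[str, frozenset[str]]:
        """Unit label -> member ids."""
        out: dict[str, set[str]] = {}
        for sid, lab in self.assignment.items():
            out.setdefault(lab, set()).add(sid)
        return {lab: frozenset(m) for lab, m in out.items()}

    def as_frozensets(self) -> frozenset[frozenset[str]]:
        """Label-free view, for comparing groupings."""
        return frozenset(self.units().values())

    def restrict(self, ids: Iterable[str]) -> "Partition":
        keep = set(ids)
        return Partition(
            assignment={i: u for i, u in self.assignment.items() if i in keep}
        )

    @staticmethod
    def from_groups(groups: Iterable[Iterable[str]]) -> "Partition":
        """Build a partition labelling each unit by its smallest member id."""
        assignment: dict[str, str] = {}
        for g in groups:
            members = sorted(g)
            for m in members:
                assignment[m] = members[0]
        return Partition(assignment=assignment)


def rank_distances(m: DistanceMatrix, subset: Iterable[str]) -> list[float]:
    """All within-subset pairwise distances, ascending; saturated last as +inf."""
    subset = sorted(set(subset))
    if len(subset) < 2:
        raise InputError(f"need at least 2 ids to rank distances, got {len(subset)}")
    unknown = [s for s in subset if s not in m.index]
    if unknown:
        raise InputError(f"ids not in distance matrix: {unknown}")
    vals = [
        m.get(subset[i], subset[j])
        for i in range(len(subset))
        for j in range(i + 1, len(subset))
    ]
    return sorted(vals)


def find_barcode_gap(sorted_d: Sequence[float], cfg: AbgdConfig) -> Optional[float]:
    """Locate the barcode gap in an ascending list of pairwise distances.

    Returns the midpoint threshold of the first qualifying gap beyond the
    prior intraspecific limit, or ``None`` if no gap qualifies.
    """
    m = len(sorted_d)
    if m < 2:
        return None
    for a, b in zip(sorted_d, sorted_d[1:]):
        if b < a:
            raise InputError("distance list is not ascending")

    # step 1: first rank beyond the prior intraspecific limit
    i0 = next((i for i, v in enumerate(sorted_d) if v > cfg.prior_P), None)
    if i0 is None:
        return None

    w = max(2, math.ceil(cfg.window_frac * m))
    for i in range(max(i0 - 1, 1), m - 1):
        hi, lo = sorted_d[i + 1], sorted_d[i]
        gap = hi - lo
        if gap <= 0:
            continue
        window = sorted_d[max(0, i - w): i + 1]  # w preceding gaps, excluding gap i
        local = [window[k + 1] - window[k] for k in range(len(window) - 1)]
        local = [g for g in local if math.isfinite(g)]
        scale = sum(local) / len(local) if local else 0.0
        # tiny relative slack so exactly-tied gaps (constant ladders) do not
        # qualify through floating-point jitter
        if gap > cfg.gap_width_X * scale * (1.0 + 1e-9) + 1e-15:
            if math.isinf(hi):
                # only saturated pairs above: any finite value beyond the
                # largest finite distance separates them
                return lo + 1.0
            return 0.5 * (lo + hi)
    return None


def partition_at_threshold(
    m: DistanceMatrix, subset: Iterable[str], t: float
) -> Partition:
    """Single-linkage partition: ids with distance < ``t`` share a unit."""
    if t < 0:
        raise InputError(f"threshold must be >= 0, got {t}")
    ids = sorted(set(subset))
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if m.get(ids[i], ids[j]) < t:
                ra, rb = find(ids[i]), find(ids[j])
                if ra != rb:
                    parent[rb] = ra
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return Partition.from_groups(groups.values())


def abgd_recursive(m: DistanceMatrix, cfg: AbgdConfig | None = None) -> Partition:
    """Recursive barcode-gap delimitation over a full distance matrix.

    Round 1 looks for a gap among all sequences; subsequent rounds re-apply
    the gap search within each group (using only within-group distances)
    until no group splits or ``max_rounds`` is reached.  Deterministic.
    """
    cfg = cfg or AbgdConfig()
    if m.n < 2:
        raise InputError("need at least 2 sequences to delimit")
    assignment = {i: min(m.ids) for i in m.ids}
    trace: list[tuple[int, str, Optional[float]]] = []
    active = [sorted(m.ids)]  # groups examined this round
    for rnd in range(1, cfg.max_rounds + 1):
        next_active: list[list[str]] = []
        any_split = False
        for group in active:
            label = min(group)
            ranked = rank_distances(m, group)
            thr = find_barcode_gap(ranked, cfg)
            trace.append((rnd, label, thr))
            if thr is None:
                continue
            sub = partition_at_threshold(m, group, thr)
            if sub.n_units <= 1:
                continue
            any_split = True
            for members in sub.units().values():
                members_sorted = sorted(members)
                for sid in members_sorted:
                    assignment[sid] = members_sorted[0]
                if len(members) >= cfg.min_group_size_to_split:
                    next_active.append(members_sorted)
        if not any_split or not next_active:
            break
        active = next_active
    return Partition(assignment=assignment, trace=trace)


def write_partition_csv(p: Partition, path) -> None:
    """CSV with columns id, unit, round_assigned (last round that set the unit)."""
    round_of: dict[str, int] = {}
    # A unit's round is the latest trace round in which its label group was cut.
    for rnd, label, thr in p.trace:
        if thr is not None:
            round_of[label] = rnd
    with open(path, "w") as fh:
        fh.write("id,unit,round_assigned\n")
        for sid in sorted(p.assignment):
            unit = p.assignment[sid]
            fh.write(f"{sid},{unit},{round_of.get(unit, 0)}\n")


def read_partition_csv(path) -> Partition:
    import csv

    assignment: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames or "unit" not in reader.fieldnames:
            raise InputError(f"partition CSV {path} must have columns id, unit")
        for row in reader:
            assignment[row["id"]] = row["unit"]
    if not assignment:
        raise InputError(f"partition CSV {path} is empty")
    return Partition(assignment=assignment)
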