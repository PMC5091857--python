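"""Reconciliation of molecular delimitations and candidate-species status.

Two molecular partitions (distance-based and tree-based) rarely agree
perfectly.  The reconciliation rule is conservatism: within each conflict
component the grouping with fewer units wins, unless morphology, acoustics,
or a prior reference delimitation positively supports the finer split.

Final units are then assigned one of four integrative categories:

NS   nominal species — the unit carries a formally described name;
DCL  deep conspecific lineage — genetically divergent but morphology and
     acoustics both fail to separate it from a nominal species;
CCS  confirmed candidate species — unnamed but positively differentiable by
     morphology and/or advertisement calls;
UCS  unconfirmed candidate species — genetically distinct with no
     corroborating data.

Richness arithmetic counts CCS + UCS as undescribed species-level diversity
(DCL are conspecific lineages, not species).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

from .abgd import Partition
from .errors import ClassificationError, InputError

Flag = Literal["yes", "no", "unknown"]
_FLAGS = ("yes", "no", "unknown")

#: acoustic parameters whose non-overlap is diagnostic by default
DIAGNOSTIC_CALL_PARAMS = ("note_duration", "pulse_rate", "fundamental_frequency")

#: all recognized advertisement-call parameters (units: s, count, s, pulses/s, Hz)
CALL_PARAMS = (
    "note_duration",
    "pulses_per_note",
    "pulse_duration",
    "pulse_rate",
    "fundamental_frequency",
)


@dataclass(frozen=True)
class PairEvidence:
    morph_diff: Flag = "unknown"
    acoustic_diff: Flag = "unknown"
    reference_split: Flag = "unknown"

    def __post_init__(self) -> None:
        for f in (self.morph_diff, self.acoustic_diff, self.reference_split):
            if f not in _FLAGS:
                raise InputError(f"evidence flag must be one of {_FLAGS}, got {f!r}")

    @property
    def any_yes(self) -> bool:
        return "yes" in (self.morph_diff, self.acoustic_diff, self.reference_split)


@dataclass(frozen=True)
class LineageInfo:
    nominal_name: Optional[str] = None
    has_morph_data: bool = False
    has_acoustic_data: bool = False
    focal: bool = True  # part of the focal study region


@dataclass
class EvidenceTable:
    """Pairwise differentiability evidence between lineages.

    Pairs absent from ``pair_evidence`` are all-unknown, but flags present in
    the table are always explicit three-valued entries.
    """

    pair_evidence: dict[frozenset, PairEvidence] = field(default_factory=dict)
    lineage_info: dict[str, LineageInfo] = field(default_factory=dict)
    call_params: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.pair_evidence:
            for lab in key:
                if lab not in self.lineage_info:
                    raise InputError(
                        f"evidence pair references unknown lineage {lab!r}"
                    )

    def get_pair(self, a: str, b: str) -> PairEvidence:
        if a == b:
            return PairEvidence()
        return self.pair_evidence.get(frozenset((a, b)), PairEvidence())

    def set_pair(self, a: str, b: str, ev: PairEvidence) -> None:
        if a == b:
            raise InputError("cannot set evidence for a lineage against itself")
        for lab in (a, b):
            if lab not in self.lineage_info:
                raise InputError(f"unknown lineage {lab!r}")
        self.pair_evidence[frozenset((a, b))] = ev

    # -- CSV I/O (schema: lineage_a,lineage_b,morph_diff,acoustic_diff,
    #    reference_split / lineage,nominal_name,has_morph_data,
    #    has_acoustic_data[,focal]) --------------------------------------

    @classmethod
    def from_csvs(cls, evidence_csv: str | Path, lineage_csv: str | Path) -> "EvidenceTable":
        lineage_info: dict[str, LineageInfo] = {}
        with open(lineage_csv) as fh:
            reader = csv.DictReader(fh)
            required = {"lineage", "nominal_name", "has_morph_data", "has_acoustic_data"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise InputError(
                    f"lineage CSV must have columns {sorted(required)}"
                )
            for row in reader:
                name = row["nominal_name"].strip() or None
                lineage_info[row["lineage"]] = LineageInfo(
                    nominal_name=name,
                    has_morph_data=_parse_bool(row["has_morph_data"]),
                    has_acoustic_data=_parse_bool(row["has_acoustic_data"]),
                    focal=_parse_bool(row.get("focal", "true")),
                )
        pair_evidence: dict[frozenset, PairEvidence] = {}
        with open(evidence_csv) as fh:
            reader = csv.DictReader(fh)
            required = {
                "lineage_a", "lineage_b", "morph_diff", "acoustic_diff", "reference_split",
            }
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise InputError(
                    f"evidence CSV must have columns {sorted(required)}"
                )
            for row in reader:
                key = frozenset((row["lineage_a"], row["lineage_b"]))
                pair_evidence[key] = PairEvidence(
                    morph_diff=_parse_flag(row["morph_diff"]),
                    acoustic_diff=_parse_flag(row["acoustic_diff"]),
                    reference_split=_parse_flag(row["reference_split"]),
                )
        return cls(pair_evidence=pair_evidence, lineage_info=lineage_info)

    def to_csvs(self, evidence_csv: str | Path, lineage_csv: str | Path) -> None:
        with open(lineage_csv, "w") as fh:
            fh.write("lineage,nominal_name,has_morph_data,has_acoustic_data,focal\n")
            for lab in sorted(self.lineage_info):
                li = self.lineage_info[lab]
                fh.write(
                    f"{lab},{li.nominal_name or ''},{li.has_morph_data},"
                    f"{li.has_acoustic_data},{li.focal}\n"
                )
        with open(evidence_csv, "w") as fh:
            fh.write("lineage_a,lineage_b,morph_diff,acoustic_diff,reference_split\n")
            for key in sorted(self.pair_evidence, key=lambda k: tuple(sorted(k))):
                a, b = sorted(key)
                ev = self.pair_evidence[key]
                fh.write(
                    f"{a},{b},{ev.morph_diff},{ev.acoustic_diff},{ev.reference_split}\n"
                )


def _parse_bool(s: str) -> bool:
    s = s.strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise InputError(f"cannot parse boolean {s!r}")


def _parse_flag(s: str) -> Flag:
    s = s.strip().lower()
    if s not in _FLAGS:
        raise InputError(f"evidence flag must be one of {_FLAGS}, got {s!r}")
    return s  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# acoustic comparison


def acoustic_differentiable(
    a: dict[str, tuple[float, float]],
    b: dict[str, tuple[float, float]],
    diagnostic_params: Iterable[str] = DIAGNOSTIC_CALL_PARAMS,
    rule: str = "range_overlap",
    rel_threshold: float = 0.2,
) -> Flag:
    """Compare two lineages' advertisement-call parameter ranges.

    Under the default ``range_overlap`` rule the lineages are differentiable
    ("yes") when any diagnostic parameter's reported ranges are disjoint.
    The alternative ``relative`` rule calls "yes" when range midpoints differ
    by more than ``rel_threshold`` of their mean.  Returns "unknown" when the
    lineages share no recorded parameter.
    """
    for params in (a, b):
        for name, (lo, hi) in params.items():
            if lo < 0 or hi < 0:
                raise InputError(f"negative call parameter {name!r}: ({lo}, {hi})")
            if hi < lo:
                raise InputError(f"inverted range for {name!r}: ({lo}, {hi})")
    shared = [p for p in diagnostic_params if p in a and p in b]
    if not shared:
        return "unknown"
    for p in shared:
        (alo, ahi), (blo, bhi) = a[p], b[p]
        if rule == "range_overlap":
            if ahi < blo or bhi < alo:
                return "yes"
        elif rule == "relative":
            ma, mb = 0.5 * (alo + ahi), 0.5 * (blo + bhi)
            mean = 0.5 * (ma + mb)
            if mean > 0 and abs(ma - mb) / mean > rel_threshold:
                return "yes"
        else:
            raise InputError(f"unknown acoustic rule {rule!r}")
    return "no"


# ---------------------------------------------------------------------------
# reconciliation


def _aggregate_flag(flags: list[Flag]) -> Flag:
    if "yes" in flags:
        return "yes"
    if "no" in flags:
        return "no"
    return "unknown"


def reconcile_partitions(
    pi_a: Partition,
    pi_b: Partition,
    ev: EvidenceTable,
    id_to_lineage: Optional[dict[str, str]] = None,
) -> tuple[Partition, list[dict]]:
    """Reconcile two delimitations under the conservatism rule.

    Conflict components are the connected blocks of the join of the two
    partitions.  Within each, the coarser grouping (fewer units) is kept
    unless some pair split only by the finer grouping carries a positive
    morphological, acoustic, or reference-delimitation flag, in which case
    the finer grouping is kept.  Non-nested conflicts fall back to the whole
    component as one unit, with a warning in the log.
    """
    if pi_a.ids != pi_b.ids:
        diff = sorted(pi_a.ids ^ pi_b.ids)
        raise InputError(f"partitions cover different ids; symmetric difference {diff}")
    lineage_of = (id_to_lineage or {}).get

    # union-find over the join of the two partitions
    parent = {i: i for i in pi_a.ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for part in (pi_a, pi_b):
        for members in part.units().values():
            ms = sorted(members)
            for m in ms[1:]:
                ra, rb = find(ms[0]), find(m)
                if ra != rb:
                    parent[rb] = ra
    components: dict[str, set[str]] = {}
    for i in pi_a.ids:
        components.setdefault(find(i), set()).add(i)

    log: list[dict] = []
    final_groups: list[frozenset[str]] = []
    for comp in sorted(components.values(), key=lambda c: min(c)):
        sub_a = pi_a.restrict(comp).as_frozensets()
        sub_b = pi_b.restrict(comp).as_frozensets()
        if sub_a == sub_b:
            final_groups.extend(sub_a)
            log.append(
                {
                    "component": sorted(comp),
                    "rule": "concordant",
                    "chosen": "both",
                    "n_units": len(sub_a),
                }
            )
            continue
        if len(sub_a) == len(sub_b):
            nested = False
        else:
            finer, coarser = (sub_a, sub_b) if len(sub_a) > len(sub_b) else (sub_b, sub_a)
            nested = all(
                any(f <= c for c in coarser) for f in finer
            )
        if not nested:
            final_groups.append(frozenset(comp))
            log.append(
                {
                    "component": sorted(comp),
                    "rule": "non_nested_fallback",
                    "chosen": "component_as_one_unit",
                    "warning": "neither delimitation refines the other; "
                    "merged pending human review",
                    "n_units": 1,
                }
            )
            continue
        finer_name = "A" if finer is sub_a else "B"
        # pairs split by the finer grouping but joined by the coarser
        unit_of_finer = {i: g for g in finer for i in g}
        support: Optional[tuple[str, str, str]] = None
        for c in sorted(coarser, key=min):
            ms = sorted(c)
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    x, y = ms[i], ms[j]
                    if unit_of_finer[x] is unit_of_finer[y]:
                        continue
                    lx, ly = lineage_of(x, x), lineage_of(y, y)
                    pe = ev.get_pair(lx, ly)
                    if pe.any_yes:
                        which = (
                            "morph_diff" if pe.morph_diff == "yes"
                            else "acoustic_diff" if pe.acoustic_diff == "yes"
                            else "reference_split"
                        )
                        support = (x, y, which)
                        break
                if support:
                    break
            if support:
                break
        if support:
            final_groups.extend(finer)
            log.append(
                {
                    "component": sorted(comp),
                    "rule": "evidence_override",
                    "chosen": finer_name,
                    "supporting_pair": list(support[:2]),
                    "evidence": support[2],
                    "n_units": len(finer),
                }
            )
        else:
            final_groups.extend(coarser)
            log.append(
                {
                    "component": sorted(comp),
                    "rule": "conservative",
                    "chosen": "A" if coarser is sub_a else "B",
                    "n_units": len(coarser),
                }
            )
    consensus = Partition.from_groups(final_groups)
    return consensus, log


# ---------------------------------------------------------------------------
# classification


@dataclass
class OtuClassification:
    """Per-unit integrative category with a rule-by-rule decision log."""

    units: dict[str, frozenset[str]]
    category: dict[str, str]  # unit label -> NS/CCS/UCS/DCL
    dcl_attachment: dict[str, str] = field(default_factory=dict)
    decision_log: list[dict] = field(default_factory=list)

    def counts(self, restrict_ids: Optional[Iterable[str]] = None) -> dict[str, int]:
        """Category counts; optionally only units containing a given id."""
        if restrict_ids is None:
            labels = set(self.category)
        else:
            keep = set(restrict_ids)
            labels = {
                lab for lab, members in self.units.items() if members & keep
            }
        out = {"NS": 0, "CCS": 0, "UCS": 0, "DCL": 0}
        for lab in labels:
            out[self.category[lab]] += 1
        out["n_units"] = len(labels)
        return out


def _unit_pair_evidence(
    members_a: Iterable[str],
    members_b: Iterable[str],
    ev: EvidenceTable,
    lineage_of,
) -> PairEvidence:
    morph: list[Flag] = []
    ac: list[Flag] = []
    ref: list[Flag] = []
    for x in members_a:
        for y in members_b:
            lx, ly = lineage_of(x, x), lineage_of(y, y)
            if lx == ly:
                continue
            pe = ev.get_pair(lx, ly)
            morph.append(pe.morph_diff)
            ac.append(pe.acoustic_diff)
            ref.append(pe.reference_split)
    return PairEvidence(
        morph_diff=_aggregate_flag(morph),
        acoustic_diff=_aggregate_flag(ac),
        reference_split=_aggregate_flag(ref),
    )


def classify_units(
    units: Partition,
    ev: EvidenceTable,
    id_to_lineage: Optional[dict[str, str]] = None,
) -> OtuClassification:
    """Assign NS / DCL / CCS / UCS to every delimited unit.

    Rules fire in order per unit:

    1. NS  — the unit contains a lineage carrying a nominal name.
    2. DCL — morphology AND acoustics both explicitly fail (flag "no") to
       separate the unit from some NS unit; attached to that species.
    3. CCS — morphology or acoustics positively separates the unit (flag
       "yes") from its comparators.
    4. UCS — no positive flag, and either no morphological/acoustic data at
       all (all flags unknown) or no NS unit exists to anchor a DCL call.

    A unit matching no rule raises ``ClassificationError`` with its evidence
    snapshot; nothing is defaulted silently.
    """
    lineage_of = (id_to_lineage or {}).get
    unit_map = units.units()
    for lab, members in unit_map.items():
        for m in members:
            lx = lineage_of(m, m)
            if lx not in ev.lineage_info:
                raise InputError(
                    f"unit {lab!r} member {m!r} (lineage {lx!r}) has no lineage_info"
                )

    category: dict[str, str] = {}
    dcl_attachment: dict[str, str] = {}
    log: list[dict] = []

    # pass 1: nominal species anchor everything else
    ns_labels: list[str] = []
    for lab in sorted(unit_map):
        names = sorted(
            {
                ev.lineage_info[lineage_of(m, m)].nominal_name
                for m in unit_map[lab]
                if ev.lineage_info[lineage_of(m, m)].nominal_name
            }
        )
        if names:
            category[lab] = "NS"
            ns_labels.append(lab)
            log.append({"unit": lab, "rule": "NS", "nominal_names": names})

    # pass 2: DCL -> CCS -> UCS for the rest
    for lab in sorted(unit_map):
        if lab in category:
            continue
        members = sorted(unit_map[lab])
        agg_vs_ns = {
            ns: _unit_pair_evidence(members, sorted(unit_map[ns]), ev, lineage_of)
            for ns in ns_labels
        }
        dcl_anchor = next(
            (
                ns
                for ns in ns_labels
                if agg_vs_ns[ns].morph_diff == "no"
                and agg_vs_ns[ns].acoustic_diff == "no"
            ),
            None,
        )
        if dcl_anchor is not None:
            category[lab] = "DCL"
            dcl_attachment[lab] = dcl_anchor
            log.append({"unit": lab, "rule": "DCL", "attached_to": dcl_anchor})
            continue
        member_lineages = {lineage_of(x, x) for x in members}
        flags = [
            (ev.get_pair(lineage_of(x, x), la).morph_diff,
             ev.get_pair(lineage_of(x, x), la).acoustic_diff)
            for x in members
            for la in ev.lineage_info
            if la not in member_lineages
        ]
        if any("yes" in f for f in flags):
            category[lab] = "CCS"
            log.append({"unit": lab, "rule": "CCS"})
            continue
        all_unknown = all(f == ("unknown", "unknown") for f in flags)
        if all_unknown or not ns_labels:
            category[lab] = "UCS"
            log.append(
                {
                    "unit": lab,
                    "rule": "UCS",
                    "basis": "no_data" if all_unknown else "no_nominal_anchor",
                }
            )
            continue
        snapshot = {
            "members": members,
            "vs_nominal": {
                ns: {
                    "morph_diff": agg_vs_ns[ns].morph_diff,
                    "acoustic_diff": agg_vs_ns[ns].acoustic_diff,
                }
                for ns in ns_labels
            },
        }
        raise ClassificationError(
            f"unit {lab!r} matches no classification rule; evidence: {snapshot}"
        )

    return OtuClassification(
        units=unit_map,
        category=category,
        dcl_attachment=dcl_attachment,
        decision_log=log,
    )


# ---------------------------------------------------------------------------
# richness arithmetic


@dataclass(frozen=True)
class RichnessSummary:
    """Cryptic-diversity summary relative to a described-species baseline.

    ``percent_undescribed`` = 100 * U / (U + D) and ``percent_increase`` =
    100 * U / D, both rounded half-up to whole percent, where U counts
    undescribed species-level units (CCS + UCS) and D is the baseline count
    of described species.
    """

    U: int
    D: int
    percent_undescribed: int
    percent_increase: int


def _round_half_up_percent(num: int, den: int) -> int:
    # floor(100*num/den + 1/2) with exact integer arithmetic
    return (200 * num + den) // (2 * den)


def richness_stats(
    classification: OtuClassification | dict[str, int],
    baseline_D: int,
    restrict_ids: Optional[Iterable[str]] = None,
) -> RichnessSummary:
    """Richness percentages for a classification against a baseline.

    ``classification`` may be an ``OtuClassification`` or a pre-computed
    counts dict with keys CCS and UCS.  DCL units are conspecific lineages
    and never enter U.
    """
    if baseline_D < 1:
        raise InputError(f"baseline_D must be >= 1, got {baseline_D}")
    if isinstance(classification, OtuClassification):
        counts = classification.counts(restrict_ids=restrict_ids)
    else:
        counts = classification
    u = int(counts.get("CCS", 0)) + int(counts.get("UCS", 0))
    if u == 0:
        return RichnessSummary(U=0, D=baseline_D, percent_undescribed=0, percent_increase=0)
    return RichnessSummary(
        U=u,
        D=baseline_D,
        percent_undescribed=_round_half_up_percent(u, u + baseline_D),
        percent_increase=_round_half_up_percent(u, baseline_D),
    )
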