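"""Bundled worked example: the Purus-Madeira *Scinax* case study.

A lineage-level encoding of an integrative treefrog delimitation from
south-western Brazilian Amazonia: two molecular delimitations (a
distance-based and a tree-based one, each lineage represented by one id),
the morphological/acoustic/reference differentiability evidence between
lineages, and a ``focal`` flag marking the lineages sampled inside the study
region (as opposed to comparator material from elsewhere).

The reconciliation of the two delimitations under the conservatism rule and
the subsequent classification yield, among the focal units, 7 confirmed
candidate species, 2 unconfirmed candidate species, 1 deep conspecific
lineage and 2 nominal species across 12 consensus molecular units.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .abgd import Partition, read_partition_csv
from .integrate import EvidenceTable

#: described-species baselines for richness arithmetic: the two nominal
#: species recorded inside the study region, and the 21 Amazonian congeners
#: not assigned to any species group
BASELINES = {"regional": 2, "amazonia_unassigned": 21}


@dataclass
class CaseStudy:
    abgd: Partition
    gmyc: Partition
    evidence: EvidenceTable

    @property
    def focal_ids(self) -> frozenset[str]:
        return frozenset(
            lab
            for lab, info in self.evidence.lineage_info.items()
            if info.focal and lab in self.abgd.ids
        )


def load_case_study() -> CaseStudy:
    base = resources.files("delimkit") / "data" / "case_study"
    with resources.as_file(base) as path:
        return CaseStudy(
            abgd=read_partition_csv(path / "partition_abgd.csv"),
            gmyc=read_partition_csv(path / "partition_gmyc.csv"),
            evidence=EvidenceTable.from_csvs(
                path / "evidence.csv", path / "lineages.csv"
            ),
        )
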