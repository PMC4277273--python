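"""Stepping-stone comparative mapping to a non-sequenced relative.

When two species (here: sole and turbot) share no markers, homology between
their linkage groups can still be inferred through fully sequenced
intermediate species: a putative chromosome of the focal map and a linkage
group of the relative are homologous candidates whenever both map to the
same chromosome of an intermediate.  Each intermediate species contributes
one vote; relative linkage groups reaching ``min_support`` votes are
reported as homologs (several supported groups form a composite homolog,
e.g. two relative groups that likely sit on one chromosome), everything
below threshold is reported unresolved with its candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .synteny import ChromosomeAssignment

__all__ = ["BridgeTable", "BridgeEntry", "BridgeResult", "bridge"]


@dataclass
class BridgeTable:
    """Published comparative map of the relative: relative LG -> per
    intermediate species, the set of homologous chromosomes."""

    relative_name: str
    #: relative_lg -> {species: [chromosomes]}
    mapping: dict[str, dict[str, list[str]]]

    def species(self) -> list[str]:
        out: set[str] = set()
        for members in self.mapping.values():
            out.update(members)
        return sorted(out)

    @classmethod
    def from_yaml(cls, path) -> "BridgeTable":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(
            relative_name=data.get("relative", "relative"),
            mapping={
                str(lg): {sp: list(chroms) for sp, chroms in members.items()}
                for lg, members in data["mapping"].items()
            },
        )

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(
                {"relative": self.relative_name, "mapping": self.mapping},
                fh, sort_keys=True,
            )


@dataclass
class BridgeEntry:
    putative_chromosome_id: str
    primary_lg: str
    #: relative LG -> number of intermediate species supporting the homology
    support: dict[str, int]
    homologs: list[str]       # relative LGs at support >= min_support
    resolved: bool
    note: str = ""


@dataclass
class BridgeResult:
    relative_name: str
    min_support: int
    entries: list[BridgeEntry] = field(default_factory=list)


def bridge(
    assignments: list[ChromosomeAssignment],
    bridge_table: BridgeTable,
    min_support: int = 2,
) -> BridgeResult:
    """Infer relative-map homologs for every putative chromosome.

    A relative LG gains one vote per intermediate species in which it shares
    a chromosome with the putative chromosome's homolog set.  Adding an
    intermediate species can only increase votes.
    """
    shared = set(bridge_table.species()) & {
        sp for a in assignments for sp in a.homolog_chromosomes
    }
    if not shared:
        raise ValueError(
            "no intermediate species shared between assignments and bridge table"
        )
    result = BridgeResult(bridge_table.relative_name, min_support)
    for a in assignments:
        support: dict[str, int] = {}
        for rel_lg, members in bridge_table.mapping.items():
            votes = 0
            for sp in shared:
                ours = set(a.homolog_chromosomes.get(sp, ()))
                theirs = set(members.get(sp, ()))
                if ours & theirs:
                    votes += 1
            if votes:
                support[rel_lg] = votes
        homologs = sorted(lg for lg, v in support.items() if v >= min_support)
        if homologs:
            note = "composite homolog" if len(homologs) > 1 else ""
        elif support:
            note = "sub-threshold support only: " + ", ".join(
                f"{lg}({v})" for lg, v in sorted(support.items())
            )
        else:
            note = "no candidate relative linkage group"
        result.entries.append(
            BridgeEntry(
                putative_chromosome_id=a.putative_chromosome_id,
                primary_lg=a.primary_lg,
                support=dict(sorted(support.items())),
                homologs=homologs,
                resolved=bool(homologs),
                note=note,
            )
        )
    return result
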