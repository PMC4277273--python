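"""Shared builders for hand-written genotype fixtures."""

import pytest

from solemap.genotypes import Family, Marker


def snp(mid: str, contig: str | None = None) -> Marker:
    return Marker(mid, "snp", ("A", "B"), contig or f"ctg_{mid}")


def msat(mid: str) -> Marker:
    return Marker(mid, "microsatellite", ("a", "b", "c", "d"))


def family(
    fam_id: str,
    sire: dict,
    dam: dict,
    offspring: dict,
) -> Family:
    """Build a Family from genotype dicts ('AB' shorthand or None)."""

    def conv(g):
        return {m: (None if v is None else (v[0], v[1])) for m, v in g.items()}

    return Family(
        family_id=fam_id,
        sire_id=f"{fam_id}_sire",
        dam_id=f"{fam_id}_dam",
        sire=conv(sire),
        dam=conv(dam),
        offspring={o: conv(g) for o, g in offspring.items()},
    )


@pytest.fixture
def toy_markers():
    return [snp("m1", "c1"), snp("m2", "c2")]
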