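"""Expected genome length and map coverage for a fragmented linkage map.

Two classical estimators are combined.  The chromosome-end correction of
Fishman et al. adds twice the average inter-marker distance (D_av) per
linkage group; the fourth method of Chakravarti et al. inflates each group
length by (m+1)/(m-1), m being its locus count.  When the map has more
linkage groups than the karyotype's haploid chromosome number, two further
karyotype corrections apply: each surplus group adds one maximum credible
gap (30 cM by default) instead of chromosome-end terms, and acrocentric
chromosomes receive D_av once instead of twice (one usable chromosome end).
The working genome-length estimate is the mean of both estimators and map
coverage is observed length divided by that mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "Karyotype",
    "GenomeLengthEstimate",
    "SOLE_KARYOTYPE",
    "PUBLISHED_DAV_CM",
    "load_published_group_table",
    "ge1_fishman_raw",
    "ge1_corrected",
    "ge2_chakravarti",
    "summarize",
    "estimate_genome_length",
]


@dataclass(frozen=True)
class Karyotype:
    """Chromosome-level constants used by the corrections."""

    haploid_n: int
    n_acrocentric: int
    max_gap_cm: float = 30.0

    def __post_init__(self) -> None:
        if not 0 <= self.n_acrocentric <= self.haploid_n:
            raise ValueError("need 0 <= n_acrocentric <= haploid_n")


#: sole: 2n = 42, of which 13 chromosome pairs are acrocentric
SOLE_KARYOTYPE = Karyotype(haploid_n=21, n_acrocentric=13, max_gap_cm=30.0)

#: average inter-marker distance of the published sole map (cM), used as a
#: printed input alongside the published per-group table
PUBLISHED_DAV_CM = 8.1


def load_published_group_table() -> pd.DataFrame:
    """Per-linkage-group marker counts, contig counts and lengths (cM) of the
    published sole map (columns: lg, n_markers, n_contigs, length_cm)."""
    ref = resources.files("solemap").joinpath("data/sole_published_map_groups.tsv")
    with ref.open("rt") as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass(frozen=True)
class GenomeLengthEstimate:
    ge1_raw_cm: float
    ge1_corrected_cm: float
    ge2_cm: float
    ge_avg_cm: float
    coverage: float


def ge1_fishman_raw(total_length_cm: float, n_groups: int, d_av_cm: float) -> float:
    """Chromosome-end corrected genome length: L + 2 * D_av per group."""
    if n_groups < 1:
        raise ValueError("need at least one linkage group")
    if d_av_cm < 0:
        raise ValueError("D_av must be non-negative")
    return total_length_cm + 2.0 * d_av_cm * n_groups


def ge1_corrected(
    total_length_cm: float,
    n_groups: int,
    d_av_cm: float,
    karyotype: Karyotype,
) -> float:
    """Karyotype-corrected chromosome-end estimate.

    Groups in excess of the haploid chromosome number add one maximum
    credible gap each; acrocentric chromosomes add D_av once, the remaining
    chromosomes twice.
    """
    surplus = n_groups - karyotype.haploid_n
    if surplus < 0:
        warnings.warn(
            f"fewer groups ({n_groups}) than chromosomes "
            f"({karyotype.haploid_n}); surplus treated as 0",
            stacklevel=2,
        )
        surplus = 0
    acro = karyotype.n_acrocentric
    meta = karyotype.haploid_n - acro
    return (
        total_length_cm
        + surplus * karyotype.max_gap_cm
        + acro * d_av_cm
        + meta * 2.0 * d_av_cm
    )


def ge2_chakravarti(groups: list[tuple[float, int]]) -> float:
    """Chakravarti method-4 estimate: sum of length * (m+1)/(m-1) per group.

    ``groups`` holds (length_cM, m_loci) pairs; groups with fewer than two
    loci cannot be inflated and are skipped with a warning.
    """
    total = 0.0
    skipped = 0
    for length, m in groups:
        if m < 2:
            skipped += 1
            continue
        total += length * (m + 1) / (m - 1)
    if skipped:
        warnings.warn(f"{skipped} group(s) with <2 loci skipped", stacklevel=2)
    return total


def summarize(
    total_length_cm: float,
    ge1_corrected_cm: float,
    ge2_cm: float,
    ge1_raw_cm: float | None = None,
) -> GenomeLengthEstimate:
    """Average the two estimators and derive map coverage."""
    if min(total_length_cm, ge1_corrected_cm, ge2_cm) <= 0:
        raise ValueError("all lengths must be positive")
    ge_avg = (ge1_corrected_cm + ge2_cm) / 2.0
    return GenomeLengthEstimate(
        ge1_raw_cm=ge1_raw_cm if ge1_raw_cm is not None else float("nan"),
        ge1_corrected_cm=ge1_corrected_cm,
        ge2_cm=ge2_cm,
        ge_avg_cm=ge_avg,
        coverage=total_length_cm / ge_avg,
    )


def estimate_genome_length(
    group_table: list[tuple[float, int]],
    karyotype: Karyotype,
    d_av_cm: float,
) -> GenomeLengthEstimate:
    """All estimators from a (length_cM, m_loci) per-group table."""
    total = sum(length for length, _ in group_table)
    n_groups = len(group_table)
    raw = ge1_fishman_raw(total, n_groups, d_av_cm)
    corr = ge1_corrected(total, n_groups, d_av_cm, karyotype)
    ge2 = ge2_chakravarti(group_table)
    return summarize(total, corr, ge2, ge1_raw_cm=raw)
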