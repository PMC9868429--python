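"""Per-locus and panel-level SSR informativeness statistics.

Per-locus statistics (Na, Ne, Ho, He, I, PIC) are computed on diploid
genotypes only, because allele dosage at a codominant locus is ambiguous in a
triploid.  The discrimination power of the whole panel is computed over all
accessions, diploid and triploid alike, from multilocus genotype frequencies:

    DP = 1 - sum_i p_i**2

the probability that two accessions drawn with replacement differ in their
multilocus profile.

Formulas per locus, with p the allele-frequency vector and n the diploid
sample size at the locus:

    Na  = number of observed alleles
    Ne  = 1 / sum(p**2)                       (effective allele count)
    I   = -sum(p * ln p)                      (Shannon index)
    PIC = 1 - sum(p**2)                       (Nei gene diversity, plug-in)
    He  = 2n/(2n-1) * (1 - sum(p**2))         (unbiased gene diversity)
    Ho  = fraction of diploids with two distinct alleles
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .model import Accession, GermplasmTable, ModelError

PloidyFilter = Literal["strict", "calls"]


def diploid_subset(
    table: GermplasmTable, ploidy_filter: PloidyFilter = "strict", min_loci: int = 2
) -> list[Accession]:
    """Accessions treated as diploid for per-locus statistics.

    ``"strict"`` (default) excludes any accession showing three alleles at
    even a single locus, since its dosage is uninterpretable under a diploid
    model; ``"calls"`` excludes only accessions whose triallelic-locus count
    reaches the triploid call threshold ``min_loci``.
    """
    out = []
    for acc in table.accessions:
        n_tri = sum(1 for l in table.loci if acc.allele_set(l).n_alleles >= 3)
        limit = 1 if ploidy_filter == "strict" else min_loci
        if n_tri < limit:
            out.append(acc)
    return out


def allele_frequencies(
    table: GermplasmTable,
    locus: str,
    subset: Sequence[Accession] | None = None,
    ploidy_filter: PloidyFilter = "strict",
) -> dict[int, float]:
    """Diploid allele frequencies at one locus.

    A single-allele call in a diploid is counted as a homozygote (two copies).
    Returns an empty dict when no usable genotype exists (locus flagged,
    stats undefined).
    """
    if subset is None:
        subset = diploid_subset(table, ploidy_filter)
    counts: dict[int, int] = {}
    total = 0
    for acc in subset:
        aset = acc.allele_set(locus)
        if aset.missing or aset.n_alleles > 2:
            continue
        alleles = aset.alleles if aset.n_alleles == 2 else aset.alleles * 2
        for a in alleles:
            counts[a] = counts.get(a, 0) + 1
            total += 1
    if total == 0:
        return {}
    return {a: c / total for a, c in sorted(counts.items())}


@dataclass(frozen=True)
class LocusStats:
    locus_id: str
    n: int  # diploid sample size at the locus
    na: int
    ne: float
    ho: float
    he: float  # unbiased (2n/(2n-1)) gene diversity
    i: float
    pic: float  # plug-in Nei gene diversity 1 - sum(p^2)


def locus_stats(
    table: GermplasmTable, locus: str, ploidy_filter: PloidyFilter = "strict"
) -> LocusStats | None:
    """Compute :class:`LocusStats`; None when no usable diploid genotype exists."""
    subset = diploid_subset(table, ploidy_filter)
    usable = [
        acc for acc in subset
        if not acc.allele_set(locus).missing and acc.allele_set(locus).n_alleles <= 2
    ]
    freqs = allele_frequencies(table, locus, subset=usable)
    if not freqs:
        return None
    p = np.array(list(freqs.values()))
    n = len(usable)
    sum_p2 = float(np.sum(p**2))
    pic = 1.0 - sum_p2
    he = (2 * n) / (2 * n - 1) * pic if n > 0 else float("nan")
    shannon = float(-np.sum(p * np.log(p)))
    ho = sum(1 for acc in usable if acc.allele_set(locus).n_alleles == 2) / n
    return LocusStats(
        locus_id=locus,
        n=n,
        na=len(freqs),
        ne=1.0 / sum_p2,
        ho=ho,
        he=he,
        i=shannon,
        pic=pic,
    )


_SUMMARY_COLUMNS = ("n", "na", "ne", "ho", "he", "i", "pic")


def summarize_locus_stats(
    stats: Sequence[LocusStats],
) -> tuple[dict[str, float], dict[str, float]]:
    """Arithmetic column means and (population) standard deviations over loci."""
    if not stats:
        raise ModelError("no defined locus statistics to summarize")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for col in _SUMMARY_COLUMNS:
        values = np.array([getattr(s, col) for s in stats], dtype=float)
        means[col] = float(values.mean())
        sds[col] = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return means, sds


@dataclass
class PanelStats:
    locus_stats: list[LocusStats]
    undefined_loci: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    n_diploid: int
    dp: float
    n_profiles: int  # accessions contributing complete multilocus profiles
    genotype_freqs: dict[tuple, float] = field(repr=False, default_factory=dict)


def multilocus_profiles(
    table: GermplasmTable, missing: Literal["exclude", "lenient"] = "exclude"
) -> dict[str, tuple]:
    """Map accession id -> multilocus profile (tuple of allele tuples per locus).

    With ``missing="exclude"`` accessions with any missing locus are omitted.
    """
    out: dict[str, tuple] = {}
    for acc in table.accessions:
        cells = tuple(acc.allele_set(l).alleles for l in table.loci)
        if missing == "exclude" and any(len(c) == 0 for c in cells):
            continue
        out[acc.accession_id] = cells
    return out


def discrimination_power(
    table: GermplasmTable, missing: Literal["exclude", "lenient"] = "exclude"
) -> tuple[float, dict[tuple, float]]:
    """Panel discrimination power DP = 1 - sum(p_i^2) over multilocus genotypes.

    Frequencies are computed over all accessions (diploid and triploid).  In
    the default mode accessions with any missing locus are excluded; in
    ``"lenient"`` mode a missing locus matches anything and DP becomes the
    probability that two accessions drawn with replacement are distinguishable
    on some mutually scored locus (computed by pair enumeration).
    """
    if table.n == 0:
        raise ModelError("empty table")
    if missing == "exclude":
        profiles = multilocus_profiles(table, "exclude")
        if not profiles:
            raise ModelError("no complete multilocus profiles; try missing='lenient'")
        n = len(profiles)
        counts: dict[tuple, int] = {}
        for prof in profiles.values():
            counts[prof] = counts.get(prof, 0) + 1
        freqs = {prof: c / n for prof, c in counts.items()}
        dp = 1.0 - sum(f**2 for f in freqs.values())
        return dp, freqs
    # lenient: pairwise distinguishability with replacement
    cells = [
        [acc.allele_set(l).alleles for l in table.loci] for acc in table.accessions
    ]
    n = len(cells)
    distinguishable = 0
    for i in range(n):
        for j in range(i + 1, n):
            for ci, cj in zip(cells[i], cells[j]):
                if ci and cj and ci != cj:
                    distinguishable += 1
                    break
    dp = 2.0 * distinguishable / (n * n)
    return dp, {}


def panel_summary(
    table: GermplasmTable,
    ploidy_filter: PloidyFilter = "strict",
    dp_missing: Literal["exclude", "lenient"] = "exclude",
) -> PanelStats:
    """Per-locus statistics plus column means/SDs and panel discrimination power."""
    stats: list[LocusStats] = []
    undefined: list[str] = []
    for locus in table.loci:
        s = locus_stats(table, locus, ploidy_filter)
        if s is None:
            undefined.append(locus)
        else:
            stats.append(s)
    means, sds = summarize_locus_stats(stats)
    dp, freqs = discrimination_power(table, dp_missing)
    return PanelStats(
        locus_stats=stats,
        undefined_loci=undefined,
        means=means,
        sds=sds,
        n_diploid=len(diploid_subset(table, ploidy_filter)),
        dp=dp,
        n_profiles=len(multilocus_profiles(table, "exclude")) if dp_missing == "exclude" else table.n,
        genotype_freqs=freqs,
    )
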