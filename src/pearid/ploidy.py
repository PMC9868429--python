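"""Ploidy determination from SSR profiles and from flow cytometry.

A codominant SSR locus can show at most two alleles in a diploid, so a third
allele is evidence toward triploidy.  Because somatic mutations, chimerism or
segmental duplications can mimic a third allele at a single locus, the default
rule calls an accession triploid only when two or more loci are triallelic;
exactly one triallelic locus yields a "putative triploid" that is treated as
diploid in summaries.

Cytometric calls use the G1 fluorescence peak: peak position is proportional
to nuclear DNA content, so sample/reference peak ratios near 1.0 indicate
diploidy and near 1.5 triploidy.  Genome size (2C, picograms) is estimated
against co-processed internal standards of known 2C by the same linear ratio:

    2C_sample = 2C_standard * (sample peak position / standard peak position)
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import find_peaks

from .model import Accession, GermplasmTable, Histogram, ModelError

Call = Literal["diploid", "putative_triploid", "triploid", "unassigned"]


@dataclass(frozen=True)
class PloidyCall:
    accession_id: str
    call: Call
    method: Literal["ssr", "cytometry"]
    n_triallelic: int = 0
    ratio: float | None = None  # cytometry: sample/reference G1 ratio
    note: str = ""


def count_triallelic_loci(accession: Accession, loci: Sequence[str]) -> int:
    """Number of non-missing loci showing three (or more) distinct alleles."""
    return sum(1 for l in loci if accession.allele_set(l).n_alleles >= 3)


def classify_ploidy_ssr(
    accession: Accession, loci: Sequence[str], min_loci: int = 2
) -> PloidyCall:
    """SSR ploidy call from the triallelic-locus count.

    0 triallelic loci -> diploid; >= ``min_loci`` -> triploid; in between ->
    putative triploid (suggestive but not conclusive).
    """
    if min_loci < 1:
        raise ModelError(f"min_loci must be >= 1, got {min_loci}")
    n_tri = count_triallelic_loci(accession, loci)
    if n_tri == 0:
        call: Call = "diploid"
    elif n_tri >= min_loci:
        call = "triploid"
    else:
        call = "putative_triploid"
    return PloidyCall(accession.accession_id, call, "ssr", n_triallelic=n_tri)


@dataclass
class PloidyTally:
    """Panel-wide SSR ploidy tallies at both the >=1 and >=min_loci rules."""

    calls: list[PloidyCall]
    min_loci: int

    @property
    def n(self) -> int:
        return len(self.calls)

    @property
    def n_triploid(self) -> int:
        return sum(1 for c in self.calls if c.call == "triploid")

    @property
    def n_putative_or_triploid(self) -> int:
        return sum(1 for c in self.calls if c.n_triallelic >= 1)

    @property
    def pct_triploid(self) -> float:
        return 100.0 * self.n_triploid / self.n

    @property
    def pct_putative_or_triploid(self) -> float:
        return 100.0 * self.n_putative_or_triploid / self.n


def classify_panel_ssr(
    table: GermplasmTable, min_loci: int = 2
) -> PloidyTally:
    calls = [classify_ploidy_ssr(acc, table.loci, min_loci) for acc in table.accessions]
    return PloidyTally(calls=calls, min_loci=min_loci)


@dataclass
class PeakSet:
    """Detected G1 peaks: ascending channel positions with heights."""

    positions: np.ndarray
    heights: np.ndarray
    flagged: bool = False  # True when detection failed / is ambiguous

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)

    @property
    def n_peaks(self) -> int:
        return int(self.positions.size)


def detect_g1_peaks(
    hist: Histogram,
    *,
    smoothing_window: int = 5,
    min_prominence: float | None = None,
) -> PeakSet:
    """Locate G1 peaks as prominent local maxima of the smoothed histogram.

    Counts are smoothed with a centred moving average; ``min_prominence``
    defaults to 5% of the smoothed maximum.  An empty, flagged PeakSet is
    returned when nothing qualifies.
    """
    counts = hist.counts
    w = max(1, int(smoothing_window))
    kernel = np.ones(w) / w
    # edge-pad before convolving so flat histograms stay flat at the ends
    padded = np.pad(counts, (w // 2, w - 1 - w // 2), mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    if min_prominence is None:
        min_prominence = 0.05 * float(smoothed.max()) if smoothed.max() > 0 else 1.0
    idx, props = find_peaks(smoothed, prominence=min_prominence)
    if idx.size == 0:
        return PeakSet(np.array([]), np.array([]), flagged=True)
    return PeakSet(hist.channels[idx], smoothed[idx])


def call_ploidy_dapi(
    sample_peak: float,
    reference_peak: float,
    *,
    accession_id: str = "",
    window: float = 0.1,
) -> PloidyCall:
    """Cytometric ploidy from the sample/diploid-reference G1 peak ratio.

    Ratio within ``1 +/- window`` -> diploid; within ``1.5 +/- window`` ->
    triploid; ratios near 2 are flagged as tetraploid candidates; everything
    else (including ratios outside [0.75, 2.25]) is unassigned.
    """
    if sample_peak <= 0 or reference_peak <= 0:
        raise ModelError("peak positions must be positive")
    ratio = sample_peak / reference_peak
    note = ""
    if not 0.75 <= ratio <= 2.25:
        warnings.warn(f"G1 ratio {ratio:.2f} outside plausible range", stacklevel=2)
        call: Call = "unassigned"
    elif abs(ratio - 1.0) <= window:
        call = "diploid"
    elif abs(ratio - 1.5) <= window:
        call = "triploid"
    else:
        call = "unassigned"
        if abs(ratio - 2.0) <= window:
            note = "tetraploid-candidate"
    return PloidyCall(accession_id, call, "cytometry", ratio=ratio, note=note)


@dataclass
class GenomeSizeEstimate:
    accession_id: str
    per_standard: dict[str, float]  # standard name -> 2C estimate (pg)
    combined_2c_pg: float
    standards: dict[str, float]  # standard name -> reference 2C (pg)
    slope_warning: bool = False


def estimate_genome_size_pi(
    sample_peak: float,
    standard_peaks: Sequence[tuple[str, float, float]],
    *,
    accession_id: str = "",
    slope_tolerance: float = 0.10,
) -> GenomeSizeEstimate:
    """Genome size from co-run internal standards.

    ``standard_peaks`` is a sequence of ``(name, peak position, reference 2C
    in pg)``.  The combined estimate is the arithmetic mean over standards.
    A warning is raised when the standards' implied channels-per-pg slopes
    disagree by more than ``slope_tolerance`` (possible mis-assigned peaks).
    """
    if not standard_peaks:
        raise ModelError("at least one standard peak required")
    if sample_peak <= 0:
        raise ModelError("sample peak must be positive")
    per_standard: dict[str, float] = {}
    refs: dict[str, float] = {}
    slopes = []
    for name, pos, c2 in standard_peaks:
        if pos <= 0 or c2 <= 0:
            raise ModelError(f"standard {name}: position and 2C must be positive")
        per_standard[name] = c2 * sample_peak / pos
        refs[name] = c2
        slopes.append(pos / c2)
    slope_warning = False
    if len(slopes) > 1:
        spread = (max(slopes) - min(slopes)) / min(slopes)
        if spread > slope_tolerance:
            slope_warning = True
            warnings.warn(
                f"standard slopes disagree by {100 * spread:.1f}% — check peak assignment",
                stacklevel=2,
            )
    return GenomeSizeEstimate(
        accession_id=accession_id,
        per_standard=per_standard,
        combined_2c_pg=float(np.mean(list(per_standard.values()))),
        standards=refs,
        slope_warning=slope_warning,
    )


def assign_peaks_to_standards(
    positions: Sequence[float], standards: Sequence[tuple[str, float]]
) -> tuple[float, list[tuple[str, float, float]]]:
    """Identify which detected peaks belong to the co-run standards.

    Among all ways of assigning ``len(standards)`` of the detected peaks to
    the standards, picks the one whose implied channels-per-pg slopes agree
    best; the remaining (largest leftover) peak is the sample.
    """
    positions = sorted(float(p) for p in positions)
    k = len(standards)
    if len(positions) < k + 1:
        raise ModelError(
            f"need {k + 1} peaks (sample + {k} standards), found {len(positions)}"
        )
    best = None
    for combo in itertools.permutations(range(len(positions)), k):
        slopes = [positions[i] / c2 for i, (_, c2) in zip(combo, standards)]
        spread = (max(slopes) - min(slopes)) / min(slopes)
        if best is None or spread < best[0]:
            best = (spread, combo)
    _, combo = best
    assigned = [
        (name, positions[i], c2) for i, (name, c2) in zip(combo, standards)
    ]
    leftover = [p for i, p in enumerate(positions) if i not in combo]
    sample = max(leftover)  # pear 2C exceeds the smaller standard; ties break high
    return sample, assigned


@dataclass
class ConcordanceResult:
    confusion: dict[tuple[str, str], int]  # (ssr call, cytometry call) -> count
    agreement: float
    n: int
    discordant: list[str]


def concordance(
    ssr_calls: Sequence[PloidyCall],
    cytometry_calls: Sequence[PloidyCall],
    putative_as: Call = "diploid",
) -> ConcordanceResult:
    """SSR-vs-cytometry agreement over the shared accessions.

    Putative triploids are mapped to ``putative_as`` (default diploid) before
    comparison; unassigned cytometry calls are dropped from the tally.
    """
    ssr = {c.accession_id: c for c in ssr_calls}
    cyto = {c.accession_id: c for c in cytometry_calls}
    shared = sorted(set(ssr) & set(cyto))
    if not shared:
        raise ModelError("SSR and cytometry call sets share no accession ids")

    def effective(call: PloidyCall) -> str:
        if call.call == "putative_triploid":
            return putative_as
        return call.call

    confusion: dict[tuple[str, str], int] = {}
    agree = 0
    used = 0
    discordant: list[str] = []
    for acc_id in shared:
        s, c = effective(ssr[acc_id]), effective(cyto[acc_id])
        if c == "unassigned":
            continue
        used += 1
        confusion[(s, c)] = confusion.get((s, c), 0) + 1
        if s == c:
            agree += 1
        else:
            discordant.append(acc_id)
    if used == 0:
        raise ModelError("no usable cytometry calls")
    return ConcordanceResult(
        confusion=confusion, agreement=agree / used, n=used, discordant=discordant
    )
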