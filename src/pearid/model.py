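"""Core data model for SSR germplasm characterization.

The universal input of the pipeline is a :class:`GermplasmTable`: one row per
accession, one column per microsatellite (SSR) locus, each cell holding the
set of distinct allele sizes (in base pairs) scored for that accession at that
locus.  Pear cultivars are clonally propagated and may be diploid or triploid,
so a cell carries one to three distinct alleles, or is missing.

Two auxiliary inputs are modelled as well: flow-cytometry fluorescence
histograms (channel/count pairs) used for ploidy confirmation and genome-size
estimation, and tables of external Bayesian-clustering runs (K, replicate,
log-likelihood) consumed by the Evanno ΔK post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Province codes of the study region; used for name normalization and as the
#: default grouping factor of the synthetic generator.
PROVINCE_CODES = ("FR", "LT", "RI", "RM", "VT")

#: Hard ceiling on distinct alleles per locus per accession (triploid maximum).
DEFAULT_MAX_ALLELES = 3


class ModelError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class AlleleSet:
    """Distinct allele sizes scored at one locus for one accession.

    Alleles are integer fragment sizes in base pairs, stored strictly
    ascending with no duplicates.  An empty tuple means the locus is missing
    (failed amplification / not scored) for this accession.
    """

    locus_id: str
    alleles: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        alleles = tuple(int(a) for a in self.alleles)
        object.__setattr__(self, "alleles", alleles)
        if any(b <= a for a, b in zip(alleles, alleles[1:])):
            raise ModelError(
                f"alleles at {self.locus_id} must be strictly ascending, got {alleles}"
            )
        if any(a <= 0 for a in alleles):
            raise ModelError(f"allele sizes must be positive, got {alleles}")

    @property
    def missing(self) -> bool:
        return not self.alleles

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def __str__(self) -> str:
        return "/".join(str(a) for a in self.alleles)


def allele_set(locus_id: str, sizes: Iterable[int]) -> AlleleSet:
    """Build an :class:`AlleleSet` from unordered, possibly repeated sizes."""
    return AlleleSet(locus_id, tuple(sorted(set(int(s) for s in sizes))))


@dataclass
class Accession:
    """One germplasm accession: identifier, varietal name, province, genotype."""

    accession_id: str
    raw_name: str
    province: str
    genotype: dict[str, AlleleSet] = field(default_factory=dict)

    def allele_set(self, locus_id: str) -> AlleleSet:
        return self.genotype.get(locus_id, AlleleSet(locus_id))

    def n_missing(self, loci: Sequence[str]) -> int:
        return sum(1 for l in loci if self.allele_set(l).missing)


@dataclass
class GermplasmTable:
    """Accessions x loci matrix of allele-size sets with name/province metadata."""

    loci: list[str]
    accessions: list[Accession]

    def __post_init__(self) -> None:
        ids = [a.accession_id for a in self.accessions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelError(f"duplicate accession ids: {dupes}")
        locus_set = set(self.loci)
        for acc in self.accessions:
            extra = set(acc.genotype) - locus_set
            if extra:
                raise ModelError(
                    f"accession {acc.accession_id} has loci {sorted(extra)} "
                    "absent from the table's locus list"
                )
            # normalize: every locus keyed, missing cells explicit
            for l in self.loci:
                if l not in acc.genotype:
                    acc.genotype[l] = AlleleSet(l)

    @property
    def n(self) -> int:
        return len(self.accessions)

    @property
    def accession_ids(self) -> list[str]:
        return [a.accession_id for a in self.accessions]

    def get(self, accession_id: str) -> Accession:
        for a in self.accessions:
            if a.accession_id == accession_id:
                return a
        raise KeyError(accession_id)

    def locus_sample_size(self, locus_id: str) -> int:
        """Number of accessions with a non-missing call at this locus."""
        return sum(1 for a in self.accessions if not a.allele_set(locus_id).missing)

    def locus_sample_sizes(self) -> dict[str, int]:
        return {l: self.locus_sample_size(l) for l in self.loci}

    def allele_universe(self, locus_id: str) -> list[int]:
        """All distinct allele sizes observed at a locus, ascending."""
        sizes: set[int] = set()
        for a in self.accessions:
            sizes.update(a.allele_set(locus_id).alleles)
        return sorted(sizes)

    def subset(self, accession_ids: Iterable[str]) -> "GermplasmTable":
        wanted = set(accession_ids)
        return GermplasmTable(
            loci=list(self.loci),
            accessions=[a for a in self.accessions if a.accession_id in wanted],
        )


@dataclass(frozen=True)
class StructureRun:
    """One external clustering run: assumed K, replicate index, log-likelihood."""

    k: int
    replicate: int
    ln_p: float

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ModelError(f"K must be >= 1, got {self.k}")
        if self.replicate < 1:
            raise ModelError(f"replicate must be >= 1, got {self.replicate}")
        if not np.isfinite(self.ln_p):
            raise ModelError("ln_p must be finite")


@dataclass
class StructureRunTable:
    """Collection of clustering-run log-likelihoods for ΔK post-processing."""

    records: list[StructureRun]

    def ks(self) -> list[int]:
        return sorted({r.k for r in self.records})

    def replicates_per_k(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for r in self.records:
            out[r.k] = out.get(r.k, 0) + 1
        return out

    def lnp_matrix(self) -> tuple[np.ndarray, list[int]]:
        """Replicates-by-K matrix of log-likelihoods for Ks with >= 2 replicates.

        Replicates within each K are aligned by ascending replicate index and
        truncated to the smallest replicate count among retained Ks.
        Raises :class:`ModelError` if the retained K range is not contiguous.
        """
        by_k: dict[int, list[StructureRun]] = {}
        for r in self.records:
            by_k.setdefault(r.k, []).append(r)
        kept = sorted(k for k, runs in by_k.items() if len(runs) >= 2)
        if len(kept) < 3:
            raise ModelError("ΔK needs >= 3 contiguous K values with >= 2 replicates")
        if kept != list(range(kept[0], kept[-1] + 1)):
            raise ModelError(f"K values must be contiguous, got {kept}")
        n_rep = min(len(by_k[k]) for k in kept)
        mat = np.empty((n_rep, len(kept)))
        for j, k in enumerate(kept):
            runs = sorted(by_k[k], key=lambda r: r.replicate)[:n_rep]
            mat[:, j] = [r.ln_p for r in runs]
        return mat, kept


@dataclass
class Histogram:
    """Flow-cytometry fluorescence histogram: channel positions and event counts."""

    channels: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.channels.ndim != 1 or self.channels.shape != self.counts.shape:
            raise ModelError("channels and counts must be 1-D and equal length")
        if np.any(np.diff(self.channels) <= 0):
            raise ModelError("channels must be strictly increasing")
        if np.any(self.counts < 0):
            raise ModelError("counts must be non-negative")

    @property
    def n_channels(self) -> int:
        return int(self.channels.size)

    @property
    def total_events(self) -> float:
        return float(self.counts.sum())
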