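"""Genotype identity resolution: similarity matrix, synonymy and homonymy.

Multilocus SSR profiles are binarized into a band matrix (one column per
observed locus/allele combination, presence/absence, with all columns of a
missing locus marked missing).  Pairwise genetic similarity is the simple
matching coefficient

    SM = (n11 + n00) / (n11 + n10 + n01 + n00)

computed over columns non-missing in both accessions; shared absences count
as matches.  Accessions are collapsed into unique genotypes as the connected
components of the graph whose edges join pairs with similarity >= 1.0
("identical on mutually scored loci").  Groups whose members carry different
normalized varietal names are synonym cases; normalized names spanning more
than one genotype group are homonym cases.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .model import GermplasmTable, ModelError, PROVINCE_CODES

#: raw names matching this pattern are treated as anonymous samples
DEFAULT_ANONYMOUS_PATTERN = r"^pero\s*\d+$"


@dataclass
class BandMatrix:
    """Binary allele presence/absence encoding of a germplasm table."""

    accession_ids: list[str]
    columns: list[tuple[str, int]]  # (locus_id, allele size)
    presence: np.ndarray  # (n, m) int8, 1 = allele present
    valid: np.ndarray  # (n, m) bool, False where the locus is missing

    @property
    def n(self) -> int:
        return len(self.accession_ids)


def binarize(table: GermplasmTable) -> BandMatrix:
    """Encode each accession as presence/absence over all observed alleles."""
    columns: list[tuple[str, int]] = []
    for locus in table.loci:
        columns.extend((locus, a) for a in table.allele_universe(locus))
    col_index = {col: j for j, col in enumerate(columns)}
    locus_cols: dict[str, list[int]] = {}
    for j, (locus, _) in enumerate(columns):
        locus_cols.setdefault(locus, []).append(j)
    n, m = table.n, len(columns)
    presence = np.zeros((n, m), dtype=np.int8)
    valid = np.ones((n, m), dtype=bool)
    for i, acc in enumerate(table.accessions):
        for locus in table.loci:
            aset = acc.allele_set(locus)
            if aset.missing:
                valid[i, locus_cols.get(locus, [])] = False
            else:
                for a in aset.alleles:
                    presence[i, col_index[(locus, a)]] = 1
    return BandMatrix(list(table.accession_ids), columns, presence, valid)


def simple_matching_similarity(
    a_presence: np.ndarray, a_valid: np.ndarray, b_presence: np.ndarray, b_valid: np.ndarray
) -> float:
    """Simple matching coefficient of two band rows over mutually valid columns.

    Returns NaN (undefined) when the rows share no scored column.
    """
    both = a_valid & b_valid
    m = int(both.sum())
    if m == 0:
        return float("nan")
    matches = int((a_presence[both] == b_presence[both]).sum())
    return matches / m


@dataclass
class SimilarityMatrix:
    accession_ids: list[str]
    values: np.ndarray  # (n, n) float, NaN where undefined
    shared_columns: np.ndarray  # (n, n) int, mutually scored column counts

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    def of(self, id_a: str, id_b: str) -> float:
        i = self.accession_ids.index(id_a)
        j = self.accession_ids.index(id_b)
        return float(self.values[i, j])


def similarity_matrix(bands: BandMatrix) -> SimilarityMatrix:
    """All pairwise simple-matching coefficients (vectorized)."""
    p = bands.presence.astype(np.int32) * bands.valid
    q = (1 - bands.presence.astype(np.int32)) * bands.valid
    n11 = p @ p.T
    n00 = q @ q.T
    shared = bands.valid.astype(np.int32) @ bands.valid.astype(np.int32).T
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(shared > 0, (n11 + n00) / np.maximum(shared, 1), np.nan)
    return SimilarityMatrix(list(bands.accession_ids), values, shared)


def normalize_name(
    raw_name: str, province_codes: Sequence[str] = PROVINCE_CODES
) -> str:
    """Normalize a varietal name for synonym/homonym comparison.

    Case-folds, strips province-code tokens and bare numeral tokens, and
    collapses whitespace; falls back to the case-folded raw name when nothing
    remains.
    """
    if not raw_name.strip():
        raise ModelError("empty name")
    codes = {c.casefold() for c in province_codes}
    tokens = [
        t for t in raw_name.casefold().split()
        if t not in codes and not t.isdigit()
    ]
    normalized = " ".join(tokens)
    return normalized if normalized else " ".join(raw_name.casefold().split())


@dataclass
class SynonymCase:
    group_index: int
    accession_ids: list[str]
    names: list[str]
    provinces: list[str]


@dataclass
class HomonymCase:
    normalized_name: str
    group_indices: list[int]
    accession_ids: list[str]
    min_gs: float


@dataclass
class IdentityReport:
    groups: list[list[str]]  # partition of accession ids by GS=1 components
    group_of: dict[str, int]
    synonym_cases: list[SynonymCase]
    anonymous_assignments: list[tuple[str, str]]  # (anonymous id, assigned name)
    unassigned_anonymous: list[str]
    threshold: float
    shared_column_counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_unique_genotypes(self) -> int:
        return len(self.groups)

    def partition_labels(self, accession_ids: Sequence[str]) -> list[int]:
        return [self.group_of[a] for a in accession_ids]


def collapse_genotypes(
    matrix: SimilarityMatrix,
    table: GermplasmTable,
    threshold: float = 1.0,
    *,
    province_codes: Sequence[str] = PROVINCE_CODES,
    anonymous_pattern: str = DEFAULT_ANONYMOUS_PATTERN,
) -> IdentityReport:
    """Partition accessions into unique genotypes and report synonym cases.

    Groups are the connected components of the graph joining pairs with
    GS >= threshold (undefined pairs contribute no edge).  A synonym case is
    a group of >= 2 accessions carrying >= 2 distinct normalized names
    (anonymous samples excluded from the name logic and reported separately).
    """
    if threshold < 1.0:
        warnings.warn(
            "threshold < 1: groups are similarity clusters, not identical genotypes",
            stacklevel=2,
        )
    n = matrix.n
    with np.errstate(invalid="ignore"):
        adjacency = np.nan_to_num(matrix.values, nan=-1.0) >= threshold
    n_comp, labels = connected_components(csr_matrix(adjacency), directed=False)
    groups: list[list[str]] = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        groups[lab].append(matrix.accession_ids[i])
    # deterministic ordering by first member's position in the table
    order = sorted(range(n_comp), key=lambda g: matrix.accession_ids.index(groups[g][0]))
    groups = [groups[g] for g in order]
    group_of = {a: gi for gi, grp in enumerate(groups) for a in grp}

    anon_re = re.compile(anonymous_pattern)
    by_id = {a.accession_id: a for a in table.accessions}

    def is_anonymous(acc_id: str) -> bool:
        return bool(anon_re.match(by_id[acc_id].raw_name.casefold().strip()))

    synonym_cases: list[SynonymCase] = []
    anonymous_assignments: list[tuple[str, str]] = []
    unassigned_anonymous: list[str] = []
    shared_counts: dict[int, int] = {}
    for gi, grp in enumerate(groups):
        named = [a for a in grp if not is_anonymous(a)]
        anon = [a for a in grp if is_anonymous(a)]
        if len(grp) > 1:
            idx = [matrix.accession_ids.index(a) for a in grp]
            shared_counts[gi] = int(
                min(matrix.shared_columns[i, j] for i in idx for j in idx if i < j)
            )
        if anon:
            if named:
                assigned = Counter(
                    normalize_name(by_id[a].raw_name, province_codes) for a in named
                ).most_common(1)[0][0]
                anonymous_assignments.extend((a, assigned) for a in anon)
            else:
                unassigned_anonymous.extend(anon)
        if len(named) >= 2:
            norm_names = {normalize_name(by_id[a].raw_name, province_codes) for a in named}
            if len(norm_names) >= 2:
                synonym_cases.append(
                    SynonymCase(
                        group_index=gi,
                        accession_ids=list(named),
                        names=[by_id[a].raw_name for a in named],
                        provinces=[by_id[a].province for a in named],
                    )
                )
    return IdentityReport(
        groups=groups,
        group_of=group_of,
        synonym_cases=synonym_cases,
        anonymous_assignments=anonymous_assignments,
        unassigned_anonymous=unassigned_anonymous,
        threshold=threshold,
        shared_column_counts=shared_counts,
    )


def find_homonyms(
    report: IdentityReport,
    table: GermplasmTable,
    matrix: SimilarityMatrix | None = None,
    *,
    province_codes: Sequence[str] = PROVINCE_CODES,
    anonymous_pattern: str = DEFAULT_ANONYMOUS_PATTERN,
) -> list[HomonymCase]:
    """Normalized names spanning more than one genotype group.

    When the similarity matrix is supplied, each case reports the minimum
    pairwise GS across the groups sharing the name.
    """
    anon_re = re.compile(anonymous_pattern)
    by_name: dict[str, list[str]] = {}
    for acc in table.accessions:
        if anon_re.match(acc.raw_name.casefold().strip()):
            continue
        by_name.setdefault(normalize_name(acc.raw_name, province_codes), []).append(
            acc.accession_id
        )
    cases: list[HomonymCase] = []
    for name, ids in sorted(by_name.items()):
        group_indices = sorted({report.group_of[a] for a in ids})
        if len(group_indices) < 2:
            continue
        min_gs = float("nan")
        if matrix is not None:
            idx = [matrix.accession_ids.index(a) for a in ids]
            pair_vals = [
                matrix.values[i, j]
                for ii, i in enumerate(idx)
                for j in idx[ii + 1:]
                if report.group_of[matrix.accession_ids[i]]
                != report.group_of[matrix.accession_ids[j]]
            ]
            if pair_vals:
                min_gs = float(np.nanmin(pair_vals))
        cases.append(HomonymCase(name, group_indices, sorted(ids), min_gs))
    return cases
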