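"""Seeded synthetic germplasm generator with a ground-truth channel.

The generator emulates the statistical structure of a regional pear
collection genotyped at a small panel of highly polymorphic SSR loci:

* allele frequencies per locus drawn from a Dirichlet prior, with
  among-province differentiation induced by the Balding–Nichols construction
  (province frequencies ~ Dirichlet with concentration
  ``p_global * (1 - Fst) / Fst``);
* diploid genotypes formed by two independent allele draws (random mating in
  a self-incompatible outcrosser); triploids formed as an unreduced diploid
  egg (two independent maternal draws) plus one haploid pollen draw;
* planted clone groups (grafted propagation: identical genotypes) that model
  synonymy, groups of distinct genotypes sharing a varietal name that model
  homonymy, and per-cell missingness mirroring variable per-locus sample
  sizes;
* flow-cytometry fluorescence histograms whose G1 peak position is
  proportional to ploidy, with Gaussian spread and an optional uniform
  debris floor.

Every stochastic operation takes a :class:`numpy.random.Generator` derived
from a single seed, so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model import (
    Accession,
    AlleleSet,
    GermplasmTable,
    Histogram,
    ModelError,
    PROVINCE_CODES,
    StructureRun,
    StructureRunTable,
    allele_set,
)

# Default per-province accession shares of the emulated collection.
DEFAULT_PROVINCE_COUNTS = {"FR": 104, "LT": 66, "RI": 69, "RM": 57, "VT": 15}

# Default clone-group layout: 26 shared-genotype groups totalling 87 members,
# so a 311-accession panel collapses to 311 - 61 = 250 unique genotypes.
# 14 groups are alias-named (cross-name synonymies), 12 share one base name.
DEFAULT_CLONE_GROUPS: tuple[tuple[int, str], ...] = (
    tuple((2, "alias") for _ in range(8))
    + tuple((2, "same_name") for _ in range(5))
    + tuple((3, "alias") for _ in range(3))
    + tuple((3, "same_name") for _ in range(3))
    + tuple((5, "alias") for _ in range(2))
    + tuple((5, "same_name") for _ in range(2))
    + tuple((6, "alias") for _ in range(1))
    + tuple((6, "same_name") for _ in range(1))
    + ((11, "same_name"),)
)

_NAME_PREFIXES = (
    "Bor", "Cam", "Dol", "Fal", "Gra", "Lun", "Mar", "Ner", "Pol", "Ros",
    "Sal", "Tar", "Ver", "Zan", "Bel", "Cor", "Fio", "Mon", "Tor", "Vin",
)
_NAME_SUFFIXES = (
    "ina", "etta", "ona", "ella", "uccia", "ara", "ole", "anda",
    "ese", "otta", "ino", "aro", "ucci", "ante", "osa", "iera",
)


def variety_name(index: int) -> str:
    """Deterministic unique pseudo-varietal name for a variety index."""
    n = len(_NAME_SUFFIXES)
    if index >= len(_NAME_PREFIXES) * n:
        return f"Cultivaro{chr(ord('A') + index % 26)}{index}"
    return _NAME_PREFIXES[index // n] + _NAME_SUFFIXES[index % n]


@dataclass
class SyntheticConfig:
    """Study conditions of the emulated collection."""

    seed: int = 0
    n_accessions: int = 311
    n_loci: int = 9
    #: per-locus distinct allele counts; None = draw uniformly in allele_range
    alleles_per_locus: tuple[int, ...] | None = None
    allele_range: tuple[int, int] = (9, 23)
    freq_concentration: float = 0.7
    n_provinces: int = 5
    province_counts: dict[str, int] | None = None
    fst: float = 0.017
    triploid_fraction: float = 0.25
    clone_groups: tuple[tuple[int, str], ...] = DEFAULT_CLONE_GROUPS
    homonym_groups: tuple[tuple[str, int], ...] = (("Spina", 3),)
    n_anonymous_matched: int = 0
    n_anonymous_novel: int = 0
    missing_rate: float = 0.01
    genotyping_error_rate: float = 0.0
    #: mean diploid 2C DNA content (pg) and its biological CV across varieties
    diploid_2c_pg: float = 1.17
    c_value_cv: float = 0.015

    def __post_init__(self) -> None:
        for name in ("triploid_fraction", "missing_rate", "genotyping_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ModelError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.fst < 1.0:
            raise ModelError(f"fst must be in (0,1), got {self.fst}")
        if min(self.n_accessions, self.n_loci, self.n_provinces) < 1:
            raise ModelError("counts must be positive")
        if sum(s for s, _ in self.clone_groups) > self.n_accessions:
            raise ModelError("clone group members exceed n_accessions")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Truth channel for parameter-recovery tests."""

    provinces: dict[str, str]
    ploidy: dict[str, int]
    clone_group: dict[str, str]  # every accession maps to a group label
    alias_groups: set[str]  # groups planted as cross-name synonym cases
    variety: dict[str, str]
    allele_sizes: dict[str, np.ndarray]
    global_freqs: dict[str, np.ndarray]
    province_freqs: dict[str, dict[str, np.ndarray]]
    true_2c_pg: dict[str, float]

    def clone_partition(self, accession_ids: Sequence[str]) -> list[str]:
        return [self.clone_group[a] for a in accession_ids]

    @property
    def n_unique_genotypes(self) -> int:
        return len(set(self.clone_group.values()))

    @property
    def n_synonym_cases(self) -> int:
        return len(self.alias_groups)


def _province_counts(config: SyntheticConfig) -> dict[str, int]:
    if config.province_counts is not None:
        counts = dict(config.province_counts)
        if sum(counts.values()) != config.n_accessions:
            raise ModelError("province_counts must sum to n_accessions")
        return counts
    codes = PROVINCE_CODES[: config.n_provinces]
    weights = np.array([DEFAULT_PROVINCE_COUNTS.get(c, 1) for c in codes], dtype=float)
    shares = weights / weights.sum() * config.n_accessions
    counts = np.floor(shares).astype(int)
    # largest-remainder top-up so counts sum exactly to n
    order = np.argsort(shares - counts)[::-1]
    for i in order[: config.n_accessions - counts.sum()]:
        counts[i] += 1
    return dict(zip(codes, counts.tolist()))


def sample_allele_frequencies(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, np.ndarray], dict[str, dict[str, np.ndarray]], dict[str, np.ndarray]]:
    """Draw global and per-province allele frequencies and allele-size ladders.

    Returns ``(global_freqs, province_freqs, allele_sizes)`` keyed by locus id
    (province_freqs keyed province -> locus).  Province vectors follow the
    Balding–Nichols construction, so the expected among-province
    differentiation equals ``config.fst``.
    """
    if rng is None:
        rng = config.rng()
    if not 0.0 < config.fst < 1.0:
        raise ModelError("fst must be in (0,1)")
    loci = [f"SSR{i + 1:02d}" for i in range(config.n_loci)]
    if config.alleles_per_locus is not None:
        if len(config.alleles_per_locus) != config.n_loci:
            raise ModelError("alleles_per_locus length must equal n_loci")
        ks = list(config.alleles_per_locus)
    else:
        lo, hi = config.allele_range
        ks = rng.integers(lo, hi + 1, size=config.n_loci).tolist()
    provinces = PROVINCE_CODES[: config.n_provinces]
    global_freqs: dict[str, np.ndarray] = {}
    allele_sizes: dict[str, np.ndarray] = {}
    province_freqs: dict[str, dict[str, np.ndarray]] = {p: {} for p in provinces}
    scale = (1.0 - config.fst) / config.fst
    for locus, k in zip(loci, ks):
        base = int(rng.integers(100, 261))
        allele_sizes[locus] = base + 2 * np.arange(k)  # dinucleotide ladder
        p = rng.dirichlet(np.full(k, config.freq_concentration))
        p = np.maximum(p, 1e-12)
        p /= p.sum()
        global_freqs[locus] = p
        alpha = np.maximum(p * scale, 1e-9)
        for prov in provinces:
            q = rng.dirichlet(alpha)
            q = np.maximum(q, 1e-15)
            province_freqs[prov][locus] = q / q.sum()
    return global_freqs, province_freqs, allele_sizes


def _draw_genotype(
    freqs: np.ndarray, sizes: np.ndarray, ploidy: int, rng: np.random.Generator
) -> tuple[int, ...]:
    """Observed distinct alleles of one genotype.

    Diploid: two independent draws.  Triploid: an unreduced diploid egg (two
    independent maternal draws) fertilized by one haploid pollen draw.
    """
    k = len(freqs)
    n_draws = 2 if ploidy == 2 else 3
    idx = rng.choice(k, size=n_draws, p=freqs)
    return tuple(sorted(set(int(sizes[i]) for i in idx)))


def simulate_population(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[GermplasmTable, GroundTruth]:
    """Simulate a germplasm table plus its ground truth.

    Clone groups are exact genotype copies (pre-noise); alias-mode groups get
    distinct varietal names with province suffixes (synonymy), same-name
    groups share a base name with numeric suffixes; homonym groups are
    distinct genotypes sharing one base name.  Genotyping error (if enabled)
    perturbs allele sizes by one repeat unit after cloning.
    """
    if rng is None:
        rng = config.rng()
    global_freqs, province_freqs, allele_sizes = sample_allele_frequencies(config, rng)
    loci = list(global_freqs)
    counts = _province_counts(config)
    slots = [p for p, c in counts.items() for _ in range(c)]
    rng.shuffle(slots)

    n = config.n_accessions
    clone_sizes = list(config.clone_groups)
    n_clone_members = sum(s for s, _ in clone_sizes)
    n_singletons = n - n_clone_members
    n_homonym_members = sum(c for _, c in config.homonym_groups)
    if n_homonym_members > n_singletons:
        raise ModelError("homonym members exceed available non-clone accessions")

    provinces: dict[str, str] = {}
    ploidy: dict[str, int] = {}
    clone_group: dict[str, str] = {}
    alias_groups: set[str] = set()
    variety: dict[str, str] = {}
    true_2c: dict[str, float] = {}
    accessions: list[Accession] = []

    name_counter = 0
    acc_counter = 0

    def next_name() -> str:
        nonlocal name_counter
        name = variety_name(name_counter)
        name_counter += 1
        return name

    def new_accession(
        raw_name: str, prov: str, genotype: dict[str, AlleleSet], pl: int,
        group: str, base_variety: str,
    ) -> None:
        nonlocal acc_counter
        acc_counter += 1
        acc_id = f"A{acc_counter:04d}"
        accessions.append(Accession(acc_id, raw_name, prov, dict(genotype)))
        provinces[acc_id] = prov
        ploidy[acc_id] = pl
        clone_group[acc_id] = group
        variety[acc_id] = base_variety
        true_2c[acc_id] = float(
            config.diploid_2c_pg * (pl / 2.0) * (1.0 + config.c_value_cv * rng.standard_normal())
        )

    def draw_full_genotype(prov: str, pl: int) -> dict[str, AlleleSet]:
        return {
            l: allele_set(l, _draw_genotype(province_freqs[prov][l], allele_sizes[l], pl, rng))
            for l in loci
        }

    slot_iter = iter(slots)

    # clone groups: one founder genotype copied to all members
    for gi, (size, mode) in enumerate(clone_sizes):
        group = f"G{gi + 1:03d}"
        member_provs = [next(slot_iter) for _ in range(size)]
        pl = 3 if rng.random() < config.triploid_fraction else 2
        genotype = draw_full_genotype(member_provs[0], pl)
        if mode == "alias":
            alias_groups.add(group)
            base = next_name()
            for prov in member_provs:
                new_accession(f"{next_name()} {prov}", prov, genotype, pl, group, base)
        else:
            base = next_name()
            for j, prov in enumerate(member_provs, start=1):
                new_accession(f"{base} {j} {prov}", prov, genotype, pl, group, base)

    # homonym groups: distinct genotypes sharing a base name
    for name, count in config.homonym_groups:
        for j in range(1, count + 1):
            prov = next(slot_iter)
            pl = 3 if rng.random() < config.triploid_fraction else 2
            group = f"G{len(clone_sizes) + acc_counter + 1:03d}u"
            new_accession(f"{name} {j} {prov}", prov, draw_full_genotype(prov, pl), pl, group, name)

    # remaining singletons
    for _ in range(n_singletons - n_homonym_members):
        prov = next(slot_iter)
        pl = 3 if rng.random() < config.triploid_fraction else 2
        group = f"G{len(clone_sizes) + acc_counter + 1:03d}u"
        base = next_name()
        new_accession(f"{base} {prov}", prov, draw_full_genotype(prov, pl), pl, group, base)

    # anonymous relabelling: matched = rename clone-group members,
    # novel = rename singleton accessions
    anon_counter = 30
    if config.n_anonymous_matched or config.n_anonymous_novel:
        same_name_members = [
            a for a in accessions
            if clone_group[a.accession_id].startswith("G")
            and not clone_group[a.accession_id].endswith("u")
            and clone_group[a.accession_id] not in alias_groups
        ]
        for a in same_name_members[: config.n_anonymous_matched]:
            a.raw_name = f"Pero {anon_counter}"
            anon_counter += 1
        singles = [a for a in accessions if clone_group[a.accession_id].endswith("u")]
        for a in singles[: config.n_anonymous_novel]:
            a.raw_name = f"Pero {anon_counter}"
            anon_counter += 1

    # genotyping error: per-allele mis-sizing by one repeat unit, post-cloning
    if config.genotyping_error_rate > 0:
        for acc in accessions:
            for l in loci:
                aset = acc.genotype[l]
                if aset.missing:
                    continue
                sizes = list(aset.alleles)
                changed = False
                for i, s in enumerate(sizes):
                    if rng.random() < config.genotyping_error_rate:
                        sizes[i] = s + int(rng.choice((-2, 2)))
                        changed = True
                if changed:
                    acc.genotype[l] = allele_set(l, sizes)

    table = GermplasmTable(loci=loci, accessions=accessions)
    truth = GroundTruth(
        provinces=provinces,
        ploidy=ploidy,
        clone_group=clone_group,
        alias_groups=alias_groups,
        variety=variety,
        allele_sizes=allele_sizes,
        global_freqs=global_freqs,
        province_freqs=province_freqs,
        true_2c_pg=true_2c,
    )
    return table, truth


def simulate_missingness(
    table: GermplasmTable, missing_rate: float, rng: np.random.Generator
) -> GermplasmTable:
    """Return a copy of the table with per-cell Bernoulli missingness injected."""
    if not 0.0 <= missing_rate < 1.0:
        raise ModelError(f"missing_rate must be in [0,1), got {missing_rate}")
    new_accessions = []
    for acc in table.accessions:
        genotype = {}
        for l in table.loci:
            aset = acc.allele_set(l)
            if not aset.missing and rng.random() < missing_rate:
                genotype[l] = AlleleSet(l)
            else:
                genotype[l] = aset
        new_accessions.append(Accession(acc.accession_id, acc.raw_name, acc.province, genotype))
    return GermplasmTable(loci=list(table.loci), accessions=new_accessions)


def simulate_cytometry(
    true_ploidy: int,
    *,
    base_channel: float = 200.0,
    cv: float = 0.03,
    n_events: int = 20000,
    rng: np.random.Generator,
    n_channels: int = 1024,
    debris_fraction: float = 0.02,
) -> Histogram:
    """Simulate a fluorescence histogram with the G1 peak at ``base_channel * ploidy/2``.

    G1 events are Normal(mean, cv*mean), binned onto integer channels; a
    uniform debris floor occupies ``debris_fraction`` of events.
    """
    if not 0.0 < cv < 0.2:
        raise ModelError(f"cv must be in (0, 0.2), got {cv}")
    if true_ploidy not in (2, 3):
        raise ModelError(f"true_ploidy must be 2 or 3, got {true_ploidy}")
    mean = base_channel * true_ploidy / 2.0
    n_debris = int(round(n_events * debris_fraction))
    g1 = rng.normal(mean, cv * mean, size=n_events - n_debris)
    debris = rng.uniform(0, n_channels, size=n_debris)
    events = np.clip(np.concatenate([g1, debris]), 0, n_channels - 1)
    counts = np.bincount(np.round(events).astype(int), minlength=n_channels)
    return Histogram(np.arange(n_channels, dtype=float), counts.astype(float))


def simulate_pi_run(
    true_2c_pg: float,
    *,
    standards: Sequence[tuple[str, float]] = (("Raphanus sativus", 1.11), ("Solanum lycopersicum", 1.96)),
    channels_per_pg: float = 180.0,
    cv: float = 0.01,
    n_events_per_peak: int = 8000,
    rng: np.random.Generator,
    n_channels: int = 1024,
) -> Histogram:
    """Simulate a co-chopped propidium-iodide run: sample plus internal standards.

    Fluorescence is linear in DNA content, so each component's G1 peak sits at
    ``channels_per_pg * 2C``.
    """
    means = [channels_per_pg * true_2c_pg] + [channels_per_pg * c2 for _, c2 in standards]
    events = np.concatenate(
        [rng.normal(m, cv * m, size=n_events_per_peak) for m in means]
    )
    events = np.clip(events, 0, n_channels - 1)
    counts = np.bincount(np.round(events).astype(int), minlength=n_channels)
    return Histogram(np.arange(n_channels, dtype=float), counts.astype(float))


def simulate_structure_runs(
    *,
    k_min: int = 1,
    k_max: int = 15,
    n_replicates: int = 3,
    kink_k: int = 3,
    noise_sd: float = 5.0,
    rng: np.random.Generator,
) -> StructureRunTable:
    """Synthesize clustering-run log-likelihoods with a kink at ``kink_k``.

    L(K) rises steeply up to the kink and slowly beyond it, so the ΔK
    second-difference statistic peaks at the kink.
    """
    records = []
    for k in range(k_min, k_max + 1):
        mean = -6000.0 + 600.0 * min(k, kink_k) + 40.0 * max(0, k - kink_k)
        for r in range(1, n_replicates + 1):
            records.append(StructureRun(k, r, mean + noise_sd * rng.standard_normal()))
    return StructureRunTable(records)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the per-accession ground truth as a delimited sidecar file."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["accession_id", "province", "ploidy", "clone_group", "is_alias_group",
             "variety", "true_2c_pg"]
        )
        for acc_id in sorted(truth.ploidy):
            writer.writerow(
                [
                    acc_id,
                    truth.provinces[acc_id],
                    truth.ploidy[acc_id],
                    truth.clone_group[acc_id],
                    int(truth.clone_group[acc_id] in truth.alias_groups),
                    truth.variety[acc_id],
                    f"{truth.true_2c_pg[acc_id]:.4f}",
                ]
            )


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read a ground-truth sidecar written by :func:`write_ground_truth`.

    Only the per-accession columns round-trip; the generator-internal fields
    (allele sizes and frequency vectors) are left empty.
    """
    provinces: dict[str, str] = {}
    ploidy: dict[str, int] = {}
    clone_group: dict[str, str] = {}
    alias_groups: set[str] = set()
    variety: dict[str, str] = {}
    true_2c: dict[str, float] = {}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            acc_id = row["accession_id"]
            provinces[acc_id] = row["province"]
            ploidy[acc_id] = int(row["ploidy"])
            clone_group[acc_id] = row["clone_group"]
            if int(row["is_alias_group"]):
                alias_groups.add(row["clone_group"])
            variety[acc_id] = row["variety"]
            true_2c[acc_id] = float(row["true_2c_pg"])
    return GroundTruth(
        provinces=provinces,
        ploidy=ploidy,
        clone_group=clone_group,
        alias_groups=alias_groups,
        variety=variety,
        allele_sizes={},
        global_freqs={},
        province_freqs={},
        true_2c_pg=true_2c,
    )


def default_panel(
    seed: int, **overrides
) -> tuple[GermplasmTable, GroundTruth, SyntheticConfig]:
    """Simulate the default study panel (population + missingness) for a seed."""
    config = SyntheticConfig(seed=seed, **overrides)
    rng = config.rng()
    table, truth = simulate_population(config, rng)
    table = simulate_missingness(table, config.missing_rate, rng)
    return table, truth, config
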