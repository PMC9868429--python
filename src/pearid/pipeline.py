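"""End-to-end pipeline orchestration and registry-style report rendering.

Runs the full characterization over a genotype table (read from disk or
simulated): marker statistics and discrimination power, the similarity matrix
and identity report, SSR and cytometric ploidy, AMOVA, PCoA and optionally
Evanno ΔK.  All outputs are delimited text or JSON in the configured output
directory; a manifest records the seed and every setting in force, so a run
is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .identity import (
    IdentityReport,
    SimilarityMatrix,
    binarize,
    collapse_genotypes,
    find_homonyms,
)
from .io import (
    read_genotype_table,
    read_structure_runs,
    write_genotype_table,
    write_structure_runs,
)
from .markers import PanelStats, panel_summary
from .model import GermplasmTable, ModelError, PROVINCE_CODES, StructureRunTable
from .ploidy import (
    GenomeSizeEstimate,
    PloidyCall,
    PloidyTally,
    assign_peaks_to_standards,
    call_ploidy_dapi,
    classify_panel_ssr,
    concordance,
    detect_g1_peaks,
    estimate_genome_size_pi,
)
from .popstructure import (
    AmovaResult,
    EvannoResult,
    PcoaResult,
    amova,
    distance_matrix,
    evanno_delta_k,
    pcoa,
)
from .simulate import (
    GroundTruth,
    SyntheticConfig,
    simulate_cytometry,
    simulate_missingness,
    simulate_pi_run,
    simulate_population,
    simulate_structure_runs,
    write_ground_truth,
)

logger = logging.getLogger(__name__)

PI_STANDARDS = (("Raphanus sativus", 1.11), ("Solanum lycopersicum", 1.96))


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained and the manifest marks it."""


@dataclass
class PipelineConfig:
    outdir: str | Path = "pearid_out"
    seed: int = 0
    genotype_path: str | None = None  # when None, simulate
    simulate_config: SyntheticConfig | None = None
    structure_runs_path: str | None = None
    simulate_structure: bool = True  # synthesize a ΔK input in simulate mode
    min_loci: int = 2
    gs_threshold: float = 1.0
    n_permutations: int = 999
    amova_distance: str = "band_mismatch"
    amova_unique_only: bool = False
    dp_missing: str = "exclude"
    ploidy_filter: str = "strict"
    province_codes: tuple[str, ...] = PROVINCE_CODES
    do_cytometry: bool = True  # simulate mode only (needs a truth channel)
    n_dapi_diploid: int = 34
    n_dapi_triploid: int = 16
    n_pi_each: int = 3
    dapi_base_channel: float = 200.0
    dapi_cv: float = 0.03
    pi_channels_per_pg: float = 180.0
    pi_cv: float = 0.01


@dataclass
class PipelineBundle:
    config: PipelineConfig
    table: GermplasmTable
    truth: GroundTruth | None
    panel: PanelStats
    similarity: SimilarityMatrix
    identity: IdentityReport
    homonyms: list
    ssr_tally: PloidyTally
    cytometry_calls: list[PloidyCall] | None
    concordance: Any | None
    genome_sizes: list[GenomeSizeEstimate] | None
    amova: AmovaResult
    pcoa: PcoaResult
    evanno: EvannoResult | None
    paths: dict[str, Path]
    manifest: dict[str, Any]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj, key=str) if isinstance(obj, set)] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    return obj


def _write_json(data: Any, path: Path) -> None:
    path.write_text(
        json.dumps(_jsonable(data), indent=2, sort_keys=True, allow_nan=True) + "\n",
        encoding="utf-8",
    )


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    manifest: dict[str, Any] = {
        "package": "pearid",
        "version": __version__,
        "seed": config.seed,
        "settings": {
            k: v
            for k, v in _jsonable(
                dataclasses.replace(config, simulate_config=None)
            ).items()
            if k != "outdir"  # outputs must not depend on where they are written
        },
        "stages": {},
    }
    if config.simulate_config is not None:
        manifest["simulate_config"] = _jsonable(config.simulate_config)
    seedseq = np.random.SeedSequence(config.seed)
    child = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("simulate", "amova", "cytometry", "structure"), seedseq.spawn(4)
        )
    }

    truth: GroundTruth | None = None
    stage = "input"
    try:
        # ---- input ----------------------------------------------------
        if config.genotype_path is not None:
            table = read_genotype_table(config.genotype_path)
        else:
            sim = config.simulate_config or SyntheticConfig(seed=config.seed)
            rng = child["simulate"]
            table, truth = simulate_population(sim, rng)
            table = simulate_missingness(table, sim.missing_rate, rng)
            paths["genotype_table"] = outdir / "genotype_table.csv"
            write_genotype_table(table, paths["genotype_table"])
            paths["ground_truth"] = outdir / "ground_truth.csv"
            write_ground_truth(truth, paths["ground_truth"])
        manifest["stages"][stage] = "ok"

        # ---- marker statistics ----------------------------------------
        stage = "marker_stats"
        panel = panel_summary(
            table, ploidy_filter=config.ploidy_filter, dp_missing=config.dp_missing
        )
        paths["marker_stats"] = outdir / "marker_stats.csv"
        _write_marker_stats(panel, paths["marker_stats"])
        paths["panel_summary"] = outdir / "panel_summary.json"
        _write_json(
            {
                "means": panel.means,
                "sds": panel.sds,
                "dp": panel.dp,
                "n_diploid": panel.n_diploid,
                "n_profiles": panel.n_profiles,
                "undefined_loci": panel.undefined_loci,
            },
            paths["panel_summary"],
        )
        manifest["stages"][stage] = "ok"

        # ---- identity --------------------------------------------------
        stage = "identity"
        bands = binarize(table)
        sim_matrix = similarity = None
        from .identity import similarity_matrix as _simmat

        similarity = _simmat(bands)
        paths["similarity_square"] = outdir / "similarity_square.csv"
        _write_square_matrix(similarity, paths["similarity_square"])
        paths["similarity_lower"] = outdir / "similarity_lower.txt"
        _write_lower_triangle(similarity, paths["similarity_lower"])
        identity = collapse_genotypes(
            similarity, table, config.gs_threshold, province_codes=config.province_codes
        )
        homonyms = find_homonyms(
            identity, table, similarity, province_codes=config.province_codes
        )
        paths["identity_report"] = outdir / "identity_report.json"
        _write_json(
            {
                "n_unique_genotypes": identity.n_unique_genotypes,
                "n_synonym_cases": len(identity.synonym_cases),
                "groups": identity.groups,
                "synonym_cases": identity.synonym_cases,
                "homonym_cases": homonyms,
                "anonymous_assignments": identity.anonymous_assignments,
                "unassigned_anonymous": identity.unassigned_anonymous,
                "threshold": identity.threshold,
            },
            paths["identity_report"],
        )
        manifest["stages"][stage] = "ok"

        # ---- SSR ploidy -------------------------------------------------
        stage = "ploidy_ssr"
        ssr_tally = classify_panel_ssr(table, config.min_loci)
        paths["ploidy_calls"] = outdir / "ploidy_calls.csv"
        with paths["ploidy_calls"].open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["accession_id", "n_triallelic", "call"])
            for c in ssr_tally.calls:
                w.writerow([c.accession_id, c.n_triallelic, c.call])
        paths["ploidy_summary"] = outdir / "ploidy_summary.json"
        _write_json(
            {
                "min_loci": ssr_tally.min_loci,
                "n": ssr_tally.n,
                "n_triploid": ssr_tally.n_triploid,
                "pct_triploid": ssr_tally.pct_triploid,
                "n_putative_or_triploid": ssr_tally.n_putative_or_triploid,
                "pct_putative_or_triploid": ssr_tally.pct_putative_or_triploid,
            },
            paths["ploidy_summary"],
        )
        manifest["stages"][stage] = "ok"

        # ---- cytometry (simulate mode) ----------------------------------
        stage = "cytometry"
        cytometry_calls = None
        conc = None
        genome_sizes = None
        if config.do_cytometry and truth is not None:
            cytometry_calls, conc, genome_sizes = _cytometry_stage(
                config, table, truth, ssr_tally, child["cytometry"]
            )
            paths["cytometry_calls"] = outdir / "cytometry_calls.csv"
            with paths["cytometry_calls"].open("w", encoding="utf-8", newline="") as fh:
                w = csv.writer(fh, lineterminator="\n")
                w.writerow(["accession_id", "call", "g1_ratio"])
                for c in cytometry_calls:
                    w.writerow([c.accession_id, c.call, _fmt(c.ratio)])
            paths["concordance"] = outdir / "concordance.json"
            _write_json(
                {
                    "agreement": conc.agreement,
                    "n": conc.n,
                    "discordant": conc.discordant,
                    "confusion": {f"{k[0]}|{k[1]}": v for k, v in conc.confusion.items()},
                },
                paths["concordance"],
            )
            paths["genome_size"] = outdir / "genome_size.csv"
            with paths["genome_size"].open("w", encoding="utf-8", newline="") as fh:
                w = csv.writer(fh, lineterminator="\n")
                w.writerow(
                    ["accession_id", "true_ploidy", "combined_2c_pg"]
                    + [f"2c_vs_{name.replace(' ', '_')}" for name, _ in PI_STANDARDS]
                )
                for est in genome_sizes:
                    w.writerow(
                        [est.accession_id, truth.ploidy[est.accession_id],
                         _fmt(est.combined_2c_pg)]
                        + [_fmt(est.per_standard[name]) for name, _ in PI_STANDARDS]
                    )
            manifest["stages"][stage] = "ok"
        else:
            manifest["stages"][stage] = "skipped"

        # ---- AMOVA ------------------------------------------------------
        stage = "amova"
        amova_table = table
        if config.amova_unique_only:
            reps = [grp[0] for grp in identity.groups]
            amova_table = table.subset(reps)
            amova_bands = binarize(amova_table)
        else:
            amova_bands = bands
        if config.amova_distance == "one_minus_gs":
            from .identity import similarity_matrix as _sm

            src = _sm(amova_bands)
            d2 = distance_matrix(src, "one_minus_gs")
        else:
            d2 = distance_matrix(amova_bands, "band_mismatch")
        groups = [a.province for a in amova_table.accessions]
        amova_res = amova(
            d2, groups, n_permutations=config.n_permutations, rng=child["amova"],
        )
        amova_res.seed = config.seed
        paths["amova"] = outdir / "amova.json"
        _write_json(amova_res, paths["amova"])
        manifest["stages"][stage] = "ok"

        # ---- PCoA -------------------------------------------------------
        stage = "pcoa"
        d_gs = 1.0 - similarity.values
        np.fill_diagonal(d_gs, 0.0)
        pcoa_res = pcoa(d_gs)
        paths["pcoa_eigenvalues"] = outdir / "pcoa_eigenvalues.csv"
        with paths["pcoa_eigenvalues"].open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["axis", "eigenvalue", "pct_variance"])
            for i, ev in enumerate(pcoa_res.eigenvalues, start=1):
                pct = (
                    _fmt(pcoa_res.pct_variance[i - 1])
                    if i - 1 < len(pcoa_res.pct_variance)
                    else ""
                )
                w.writerow([i, _fmt(ev), pct])
        paths["pcoa_coordinates"] = outdir / "pcoa_coordinates.csv"
        with paths["pcoa_coordinates"].open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            n_axes = min(5, pcoa_res.coordinates.shape[1])
            w.writerow(["accession_id"] + [f"axis{i + 1}" for i in range(n_axes)])
            for i, acc_id in enumerate(similarity.accession_ids):
                w.writerow([acc_id] + [_fmt(pcoa_res.coordinates[i, j]) for j in range(n_axes)])
        manifest["stages"][stage] = "ok"

        # ---- Evanno ΔK ----------------------------------------------------
        stage = "evanno"
        evanno_res = None
        runs: StructureRunTable | None = None
        if config.structure_runs_path is not None:
            runs = read_structure_runs(config.structure_runs_path)
        elif config.genotype_path is None and config.simulate_structure:
            runs = simulate_structure_runs(rng=child["structure"])
            paths["structure_runs"] = outdir / "structure_runs.csv"
            write_structure_runs(runs, paths["structure_runs"])
        if runs is not None:
            evanno_res = evanno_delta_k(runs)
            paths["evanno"] = outdir / "evanno.csv"
            with paths["evanno"].open("w", encoding="utf-8", newline="") as fh:
                w = csv.writer(fh, lineterminator="\n")
                w.writerow(["K", "mean_lnP", "sd_lnP", "l_prime", "abs_l_doubleprime", "delta_K"])
                for j, k in enumerate(evanno_res.ks):
                    w.writerow(
                        [k, _fmt(evanno_res.mean_lnp[j]), _fmt(evanno_res.sd_lnp[j]),
                         _fmt(evanno_res.l_prime[j]), _fmt(evanno_res.l_doubleprime_abs[j]),
                         _fmt(evanno_res.delta_k[j])]
                    )
            manifest["stages"][stage] = "ok"
        else:
            manifest["stages"][stage] = "skipped"

        bundle = PipelineBundle(
            config=config,
            table=table,
            truth=truth,
            panel=panel,
            similarity=similarity,
            identity=identity,
            homonyms=homonyms,
            ssr_tally=ssr_tally,
            cytometry_calls=cytometry_calls,
            concordance=conc,
            genome_sizes=genome_sizes,
            amova=amova_res,
            pcoa=pcoa_res,
            evanno=evanno_res,
            paths=paths,
            manifest=manifest,
        )
        paths["report"] = outdir / "report.txt"
        paths["report"].write_text(render_report(bundle), encoding="utf-8")
        manifest["stages"]["report"] = "ok"
        paths["manifest"] = outdir / "manifest.json"
        _write_json(manifest, paths["manifest"])
        return bundle
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        _write_json(manifest, outdir / "manifest.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _write_marker_stats(panel: PanelStats, path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["locus", "sample_size", "Na", "Ne", "Ho", "He", "I", "PIC"])
        for s in panel.locus_stats:
            w.writerow(
                [s.locus_id, s.n, s.na, _fmt(s.ne), _fmt(s.ho), _fmt(s.he),
                 _fmt(s.i), _fmt(s.pic)]
            )
        m, sd = panel.means, panel.sds
        w.writerow(
            ["Mean", _fmt(m["n"]), _fmt(m["na"]), _fmt(m["ne"]), _fmt(m["ho"]),
             _fmt(m["he"]), _fmt(m["i"]), _fmt(m["pic"])]
        )
        w.writerow(
            ["St.Dev", _fmt(sd["n"]), _fmt(sd["na"]), _fmt(sd["ne"]), _fmt(sd["ho"]),
             _fmt(sd["he"]), _fmt(sd["i"]), _fmt(sd["pic"])]
        )


def _write_square_matrix(similarity: SimilarityMatrix, path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["accession_id"] + similarity.accession_ids)
        for i, acc_id in enumerate(similarity.accession_ids):
            w.writerow([acc_id] + [_fmt(v) for v in similarity.values[i]])


def _write_lower_triangle(similarity: SimilarityMatrix, path: Path) -> None:
    lines = []
    for i, acc_id in enumerate(similarity.accession_ids):
        vals = " ".join(_fmt(similarity.values[i, j]) for j in range(i + 1))
        lines.append(f"{acc_id} {vals}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _g1_position(hist, **kwargs) -> float:
    peaks = detect_g1_peaks(hist, **kwargs)
    if peaks.n_peaks == 0:
        raise ModelError("no G1 peak detected")
    return float(peaks.positions[int(np.argmax(peaks.heights))])


def _cytometry_stage(config, table, truth, ssr_tally, rng):
    """DAPI ploidy confirmation on a subsample plus PI genome sizing."""
    by_call: dict[str, list[str]] = {"diploid": [], "triploid": []}
    for c in ssr_tally.calls:
        key = "triploid" if c.call == "triploid" else "diploid"
        by_call[key].append(c.accession_id)
    chosen: list[str] = []
    for key, k in (("diploid", config.n_dapi_diploid), ("triploid", config.n_dapi_triploid)):
        pool = by_call[key]
        k = min(k, len(pool))
        chosen.extend(rng.choice(pool, size=k, replace=False).tolist())

    ref_hist = simulate_cytometry(
        2, base_channel=config.dapi_base_channel, cv=config.dapi_cv, rng=rng
    )
    ref_peak = _g1_position(ref_hist)
    cyto_calls = []
    for acc_id in chosen:
        hist = simulate_cytometry(
            truth.ploidy[acc_id],
            base_channel=config.dapi_base_channel,
            cv=config.dapi_cv,
            rng=rng,
        )
        cyto_calls.append(
            call_ploidy_dapi(_g1_position(hist), ref_peak, accession_id=acc_id)
        )
    conc = concordance(
        [c for c in ssr_tally.calls if c.accession_id in set(chosen)], cyto_calls
    )

    # PI genome sizing of a few confirmed diploids and triploids
    genome_sizes = []
    for ploidy_val in (2, 3):
        candidates = [c.accession_id for c in cyto_calls
                      if c.call == ("diploid" if ploidy_val == 2 else "triploid")]
        for acc_id in candidates[: config.n_pi_each]:
            hist = simulate_pi_run(
                truth.true_2c_pg[acc_id],
                standards=PI_STANDARDS,
                channels_per_pg=config.pi_channels_per_pg,
                cv=config.pi_cv,
                rng=rng,
            )
            peaks = detect_g1_peaks(hist)
            try:
                sample_pos, assigned = assign_peaks_to_standards(
                    peaks.positions, PI_STANDARDS
                )
            except ModelError as exc:
                # sample peak merged with a standard: unresolvable run, flag and skip
                logger.warning("PI run for %s skipped: %s", acc_id, exc)
                continue
            genome_sizes.append(
                estimate_genome_size_pi(sample_pos, assigned, accession_id=acc_id)
            )
    return cyto_calls, conc, genome_sizes


def render_report(bundle: PipelineBundle) -> str:
    """Registry-style characterization report: panel summary + per-accession sheets."""
    lines: list[str] = []
    p = bundle.panel
    lines.append("=" * 70)
    lines.append("GERMPLASM CHARACTERIZATION REPORT")
    lines.append("=" * 70)
    lines.append(f"Accessions: {bundle.table.n}   Loci: {len(bundle.table.loci)}")
    lines.append(f"Unique genotypes: {bundle.identity.n_unique_genotypes}")
    lines.append(f"Synonym cases: {len(bundle.identity.synonym_cases)}")
    lines.append(f"Homonym cases: {len(bundle.homonyms)}")
    lines.append(
        f"Discrimination power (DP): {p.dp:.4f} over {p.n_profiles} complete profiles"
    )
    lines.append(
        "Mean per-locus stats (diploids, n=%d): Na=%.1f Ho=%.2f He=%.2f I=%.2f PIC=%.2f"
        % (p.n_diploid, p.means["na"], p.means["ho"], p.means["he"],
           p.means["i"], p.means["pic"])
    )
    t = bundle.ssr_tally
    lines.append(
        f"SSR ploidy: {t.n_triploid}/{t.n} triploid (>= {t.min_loci} triallelic loci, "
        f"{t.pct_triploid:.1f}%); {t.n_putative_or_triploid}/{t.n} with >= 1 "
        f"triallelic locus ({t.pct_putative_or_triploid:.1f}%)"
    )
    a = bundle.amova
    lines.append(
        f"AMOVA: {a.pct_among:.1f}% among / {a.pct_within:.1f}% within provinces "
        f"(Phi_ST={a.phi_st:.4f}, p={a.p_value:.4f}, {a.n_permutations} permutations)"
    )
    if len(bundle.pcoa.pct_variance) >= 2:
        lines.append(
            f"PCoA: axis 1 = {bundle.pcoa.pct_variance[0]:.1f}%, "
            f"axis 2 = {bundle.pcoa.pct_variance[1]:.1f}% of molecular variation"
        )
    if bundle.concordance is not None:
        c = bundle.concordance
        lines.append(
            f"Cytometry concordance: {c.n - len(c.discordant)}/{c.n} "
            f"({100 * c.agreement:.0f}%) agree with SSR calls"
        )
    if bundle.evanno is not None:
        lines.append(
            f"Evanno ΔK optimum: K={bundle.evanno.optimal_k} "
            f"(local maxima at K={bundle.evanno.local_maxima})"
        )
    lines.append("")

    ssr_by_id = {c.accession_id: c for c in bundle.ssr_tally.calls}
    cyto_by_id = {
        c.accession_id: c for c in (bundle.cytometry_calls or [])
    }
    syn_by_group = {s.group_index: s for s in bundle.identity.synonym_cases}
    for acc in bundle.table.accessions:
        gi = bundle.identity.group_of[acc.accession_id]
        lines.append("-" * 70)
        lines.append(f"{acc.accession_id}  '{acc.raw_name}'  province {acc.province}")
        profile = "  ".join(
            f"{l}:{acc.allele_set(l) or '-'}" for l in bundle.table.loci
        )
        lines.append(f"  profile: {profile}")
        call = ssr_by_id[acc.accession_id]
        lines.append(
            f"  SSR ploidy: {call.call} ({call.n_triallelic} triallelic loci)"
        )
        if acc.accession_id in cyto_by_id:
            lines.append(f"  cytometry: {cyto_by_id[acc.accession_id].call}")
        lines.append(f"  genotype group: {gi + 1} (of {bundle.identity.n_unique_genotypes})")
        if gi in syn_by_group:
            others = [
                n for a_id, n in zip(syn_by_group[gi].accession_ids, syn_by_group[gi].names)
                if a_id != acc.accession_id
            ]
            lines.append(f"  synonym of: {', '.join(repr(n) for n in others)}")
    lines.append("=" * 70)
    return "\n".join(lines) + "\n"
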