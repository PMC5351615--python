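"""End-to-end pipeline: digest -> methylome -> DMFs -> driver screen -> validation.

Every stage writes its tables under the run directory with a metadata
header (tool version, config hash, master seed), and the run ends with a
machine-readable ``summary.json`` that is byte-identical across reruns of
the same configuration and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .differential import call_dmfs, summarize_direction
from .digest import digest_and_index, read_fasta
from .errors import ConfigError, DataError, EpidriverError
from .methylome import (
    SampleMethylome,
    cluster_samples,
    fragment_methylation,
    global_mean_methylation,
    linkage_to_newick,
    load_sample_sheet,
    load_samples,
    merge_replicates,
    methylation_histogram,
    read_coverage_file,
    replicate_correlation,
)
from .concordance import bland_altman, cohort_validate
from .regions import read_bed_intervals, read_gene_models, write_catalog_bed
from .screen import (
    annotate_dmfs,
    associate_genes,
    classify_progression_pattern,
    common_direction_dmfs,
    feature_overlap_fractions,
    intersect_dmfs,
)
from . import simulate as sim

log = logging.getLogger("epidriver")

#: planted effects used when a simulate section does not specify its own:
#: 20 shared DMFs (10 per direction) and 30 private per pair, all at the
#: designed effect size 0.5
DEFAULT_PLANTED = (
    {"scope": "shared", "direction": "hyper", "delta": 0.5, "n_fragments": 10},
    {"scope": "shared", "direction": "hypo", "delta": 0.5, "n_fragments": 10},
)


def _default_private(pair_ids: list[str]) -> list[dict]:
    out = []
    for p in pair_ids:
        out.append(
            {"scope": "private", "direction": "hyper", "delta": 0.5,
             "n_fragments": 15, "pair_id": p}
        )
        out.append(
            {"scope": "private", "direction": "hypo", "delta": 0.5,
             "n_fragments": 15, "pair_id": p}
        )
    return out


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def _simulate_inputs(config: RunConfig, run_dir: Path) -> tuple[dict, Path, sim.TruthTable]:
    params = dict(config.simulate or {})
    genome_params = params.pop("genome", {}) or {}
    planted_conf = params.pop("planted", None)
    cohort_params = params.pop("cohort", None)
    min_cpgs_planted = params.pop("min_cpgs_planted", 2)
    params.setdefault("seed", config.seed)
    if "replicate_samples" in params:
        params["replicate_samples"] = tuple(params["replicate_samples"])
    design = sim.StudyDesign(**params)

    sim_dir = run_dir / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    genome, islands = sim.generate_genome(
        seed=design.seed, **genome_params
    )
    sim.write_fasta(genome, sim_dir / "genome.fa")
    islands.to_csv(sim_dir / "islands.bed", sep="\t", header=False, index=False)

    catalog = digest_and_index(
        genome, config.thresholds.size_min, config.thresholds.size_max
    )
    if planted_conf is None:
        planted_conf = list(DEFAULT_PLANTED) + _default_private(design.pair_ids())
    planted = [sim.PlantedEffect(**p) for p in planted_conf]
    truth = sim.plan_methylation_states(
        catalog, design, planted, min_cpgs_planted=min_cpgs_planted
    )
    sim.write_truth(truth, sim_dir / "truth_levels.tsv", sim_dir / "truth_labels.tsv")
    sim.simulate_counts(truth, catalog, design, out_dir=sim_dir)
    sheet_path = sim_dir / "samples.tsv"
    sim.write_sample_sheet(design, ".", sheet_path)

    config.genome_fasta = str(sim_dir / "genome.fa")
    config.sample_sheet = str(sheet_path)
    config.tracks.setdefault("cgi", str(sim_dir / "islands.bed"))

    if cohort_params is not None:
        shared_planted = truth.planted("dmf_shared")
        cohort = sim.CohortDesign(**cohort_params)
        probes, betas, groups = sim.simulate_cohort(
            truth, cohort, list(shared_planted["fragment_id"]), catalog,
            seed=design.seed,
        )
        probes.to_csv(sim_dir / "cohort_probes.tsv", sep="\t", index=False)
        betas.to_csv(sim_dir / "cohort_betas.tsv", sep="\t")
        groups.to_csv(sim_dir / "cohort_groups.tsv", sep="\t", index=False)
        config.cohort = {
            "probes": str(sim_dir / "cohort_probes.tsv"),
            "betas": str(sim_dir / "cohort_betas.tsv"),
            "groups": str(sim_dir / "cohort_groups.tsv"),
        }
    return genome, sheet_path, truth


def study_fragment_tables(
    truth: sim.TruthTable,
    catalog,
    design: sim.StudyDesign,
    cov_min: int = 10,
    min_cpgs: int = 2,
) -> dict[str, pd.DataFrame]:
    """Simulate counts for a designed study and return per-sample fragment
    methylation tables (replicate libraries combined)."""
    counts = sim.simulate_counts(truth, catalog, design)
    by_sample: dict[str, SampleMethylome] = {}
    for lib_id, sample_id in design.library_ids():
        if sample_id == "normal":
            role, pair = "normal", None
        elif sample_id.startswith("P"):
            role, pair = "primary", sample_id
        else:
            role, pair = "metastatic", sample_id.replace("M", "P", 1)
        m = SampleMethylome(sample_id, role, counts[lib_id], pair)
        by_sample[sample_id] = (
            merge_replicates(by_sample[sample_id], m)
            if sample_id in by_sample
            else m
        )
    return {
        sid: fragment_methylation(m, catalog, cov_min, min_cpgs)
        for sid, m in by_sample.items()
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dictionary.

    Stages: (optional) simulation, MspI digestion and CpG indexing,
    methylome loading with replicate merging, per-pair DMF calling
    (normal-vs-primary when a normal sample exists, primary-vs-metastatic
    always), the cross-pair driver screen with annotation, and optional
    cohort validation.  Stage failures abort with the failing stage named;
    outputs written so far are retained.
    """
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "cov_min": thr.cov_min, "min_cpgs": thr.min_cpgs,
            "size_min": thr.size_min, "size_max": thr.size_max,
            "alpha": thr.alpha, "delta_min": thr.delta_min,
            "window": thr.window,
        },
    }
    stage = "simulate"
    truth = None
    try:
        if config.simulate is not None:
            _, _, truth = _simulate_inputs(config, run_dir)
            log.info("simulated study written under %s", run_dir / "sim")

        header = (
            f"# epidriver {__version__} config={config.content_hash()} "
            f"seed={config.seed}\n"
        )

        stage = "digest"
        genome = read_fasta(config.genome_fasta)
        catalog = digest_and_index(genome, thr.size_min, thr.size_max)
        if len(catalog) == 0:
            raise DataError("no fragments in the analysis size range")
        write_catalog_bed(catalog, run_dir / "fragments.bed")
        summary["n_fragments"] = len(catalog)
        summary["n_cpgs_in_fragments"] = int(sum(f.n_cpgs for f in catalog))
        log.info("digest: %d fragments in [%d, %d] bp",
                 len(catalog), thr.size_min, thr.size_max)

        stage = "methylome"
        sheet = load_sample_sheet(config.sample_sheet)
        samples = load_samples(sheet, base_dir=Path(config.sample_sheet).parent)
        replicate_r = {}
        for target in sorted(set(sheet["replicate_of"]) - {""}):
            libs = sheet[sheet["replicate_of"] == target]
            base = sheet[(sheet["sample_id"] == target) & (sheet["replicate_of"] == "")]
            if not base.empty and not libs.empty:
                sheet_dir = Path(config.sample_sheet).parent
                def _load(row):
                    p = Path(row["path"])
                    return read_coverage_file(
                        p if p.is_absolute() else sheet_dir / p,
                        row["sample_id"], row["role"], row["pair_id"] or None,
                    )
                a = _load(base.iloc[0])
                b = _load(libs.iloc[0])
                r, n = replicate_correlation(a, b, cov_min=thr.cov_min)
                replicate_r[target] = {"r": round(r, 6), "n_cpgs": n}
        if replicate_r:
            summary["replicate_correlation"] = replicate_r

        frag_tables = {
            sid: fragment_methylation(m, catalog, thr.cov_min, thr.min_cpgs)
            for sid, m in samples.items()
        }
        summary["global_mean_methylation_pct"] = {
            sid: round(global_mean_methylation(m, thr.cov_min), 4)
            for sid, m in samples.items()
        }
        summary["n_analysable_fragments"] = {
            sid: len(t) for sid, t in frag_tables.items()
        }
        hist_rows = []
        for sid, t in frag_tables.items():
            if len(t):
                counts, edges = methylation_histogram(t)
                hist_rows.append(pd.Series(counts, name=sid))
        if hist_rows:
            hist = pd.DataFrame(hist_rows)
            hist.columns = [f"bin_{i}" for i in range(hist.shape[1])]
            _write_tsv(hist, run_dir / "methylation_histograms.tsv", header, index=True)
        if len(samples) >= 2:
            link, labels = cluster_samples(list(samples.values()), cov_min=thr.cov_min)
            (run_dir / "clustering.nwk").write_text(
                linkage_to_newick(link, labels) + "\n"
            )

        stage = "dmf"
        roles = {sid: m.role for sid, m in samples.items()}
        pair_of = {sid: m.pair_id for sid, m in samples.items()}
        pairs = sorted({p for p in pair_of.values() if p})
        normal_id = next((s for s, r in roles.items() if r == "normal"), None)
        pm_dmfs: dict[str, pd.DataFrame] = {}
        np_dmfs: dict[str, pd.DataFrame] = {}
        dmf_counts: dict[str, dict] = {}
        for pair in pairs:
            prim = next(
                (s for s in samples if roles[s] == "primary" and pair_of[s] == pair),
                None,
            )
            met = next(
                (s for s in samples if roles[s] == "metastatic" and pair_of[s] == pair),
                None,
            )
            if prim is None or met is None:
                raise DataError(f"pair {pair}: need one primary and one metastatic")
            dmf = call_dmfs(
                frag_tables[prim], frag_tables[met], pair,
                "primary_vs_metastatic", thr.alpha, thr.delta_min,
            )
            pm_dmfs[pair] = dmf
            _write_tsv(dmf, run_dir / f"dmf_{pair}_primary_vs_metastatic.tsv", header)
            n_hyper, n_hypo = summarize_direction(dmf)
            dmf_counts[f"{pair}:primary_vs_metastatic"] = {
                "tested": len(dmf), "significant": int(dmf["significant"].sum()),
                "hyper": n_hyper, "hypo": n_hypo,
            }
            if normal_id is not None:
                dmf_np = call_dmfs(
                    frag_tables[normal_id], frag_tables[prim], pair,
                    "normal_vs_primary", thr.alpha, thr.delta_min,
                )
                np_dmfs[pair] = dmf_np
                _write_tsv(dmf_np, run_dir / f"dmf_{pair}_normal_vs_primary.tsv", header)
                n_hyper, n_hypo = summarize_direction(dmf_np)
                dmf_counts[f"{pair}:normal_vs_primary"] = {
                    "tested": len(dmf_np),
                    "significant": int(dmf_np["significant"].sum()),
                    "hyper": n_hyper, "hypo": n_hypo,
                }
            log.info("dmf %s: %s", pair, dmf_counts[f"{pair}:primary_vs_metastatic"])
        summary["dmf_counts"] = dmf_counts

        stage = "screen"
        shared = pd.DataFrame()
        if len(pm_dmfs) >= 2:
            shared, pairwise = intersect_dmfs(pm_dmfs)
            _write_tsv(shared, run_dir / "shared_dmfs.tsv", header)
            _write_tsv(pairwise, run_dir / "pairwise_overlap.tsv", header)
            hyper_all, hypo_all = common_direction_dmfs(shared)
            summary["shared_dmfs"] = {
                "n_shared": len(shared),
                "n_direction_consistent": int(shared["direction_consistent"].sum())
                if len(shared) else 0,
                "hyper_in_all": len(hyper_all),
                "hypo_in_all": len(hypo_all),
            }
            if np_dmfs:
                patterns = pd.concat(
                    [
                        classify_progression_pattern(np_dmfs[p], pm_dmfs[p])
                        for p in sorted(np_dmfs)
                    ],
                    ignore_index=True,
                )
                _write_tsv(patterns, run_dir / "progression_patterns.tsv", header)
                summary["progression_patterns"] = {
                    k: int(v)
                    for k, v in patterns["pattern"].value_counts().sort_index().items()
                }

            frags_by_id = catalog.by_id()
            shared_frags = [frags_by_id[f] for f in shared["fragment_id"]] if len(shared) else []
            genes = (
                read_gene_models(config.tracks["genes"])
                if "genes" in config.tracks
                else []
            )
            cgi = (
                read_bed_intervals(config.tracks["cgi"])
                if "cgi" in config.tracks
                else None
            )
            repeats = (
                read_bed_intervals(config.tracks["repeats"])
                if "repeats" in config.tracks
                else None
            )
            if shared_frags and (genes or cgi is not None or repeats is not None):
                ann = annotate_dmfs(
                    shared_frags, genes, cgi, thr.shore_width, repeats,
                    thr.promoter_upstream, thr.promoter_downstream,
                )
                _write_tsv(ann, run_dir / "shared_dmf_annotation.tsv", header)
                summary["cgi_context"] = {
                    k: int(v)
                    for k, v in ann["cgi_context"].value_counts().sort_index().items()
                }
                if genes:
                    gene_table = associate_genes(ann, shared, thr.gene_distance_cap)
                    _write_tsv(gene_table, run_dir / "dmf_genes.tsv", header)
                    summary["n_dmf_genes"] = int(
                        (gene_table["gene_id"] != "").sum()
                    )
            feature_tracks = {
                name: read_bed_intervals(path)
                for name, path in sorted(config.tracks.items())
                if name not in ("genes",)
            }
            if shared_frags and feature_tracks:
                frac_rows = {}
                for direction, ids in (("hyper", hyper_all), ("hypo", hypo_all)):
                    frag_subset = [frags_by_id[f] for f in sorted(ids)]
                    if frag_subset:
                        frac_rows[direction] = feature_overlap_fractions(
                            frag_subset, feature_tracks
                        )
                if frac_rows:
                    _write_tsv(
                        pd.DataFrame(frac_rows),
                        run_dir / "feature_overlap_fractions.tsv",
                        header,
                        index=True,
                    )

        if truth is not None and len(pm_dmfs) >= 2:
            summary["planted_recovery"] = _recovery_stats(truth, shared, thr.delta_min)

        stage = "validate"
        if config.cohort:
            needed = {"probes", "betas", "groups"}
            if not needed <= set(config.cohort):
                raise ConfigError(
                    f"cohort section needs {sorted(needed)}; "
                    f"got {sorted(config.cohort)}"
                )
            if len(shared) and shared["direction_consistent"].any():
                probes = pd.read_csv(config.cohort["probes"], sep="\t")
                betas = pd.read_csv(config.cohort["betas"], sep="\t", index_col=0)
                groups = pd.read_csv(config.cohort["groups"], sep="\t")
                consistent = shared[shared["direction_consistent"]]
                directions = consistent.set_index("fragment_id")["consensus_direction"]
                validation = cohort_validate(
                    directions, list(catalog), probes, betas, groups,
                    window=thr.window,
                )
                _write_tsv(validation, run_dir / "cohort_validation.tsv", header)
                summary["cohort_validation"] = {
                    "n_probes_matched": len(validation),
                    "n_significant": int((validation["p"] < thr.alpha).sum())
                    if len(validation) else 0,
                    "n_direction_concordant": int(
                        validation["direction_concordant"].sum()
                    )
                    if len(validation) else 0,
                }
            else:
                log.info("validate: no direction-consistent shared DMFs; skipped")
                summary["cohort_validation"] = {"skipped": "no shared DMFs"}
        else:
            log.info("validate: no cohort files configured; stage skipped")
    except EpidriverError as exc:
        raise type(exc)(f"stage '{stage}' failed: {exc}") from exc

    (run_dir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2) + "\n"
    )
    return summary


def _recovery_stats(truth, shared: pd.DataFrame, delta_min: float) -> dict:
    """Sensitivity of the shared, direction-consistent screen on planted truth."""
    planted = truth.planted("dmf_shared")
    above = planted[planted["delta_true"] >= delta_min]
    hyper_all, hypo_all = common_direction_dmfs(shared)
    recovered = hyper_all | hypo_all
    hits = 0
    direction_errors = 0
    for _, row in above.iterrows():
        if row["fragment_id"] in recovered:
            hits += 1
            found = "hyper" if row["fragment_id"] in hyper_all else "hypo"
            if found != row["direction"]:
                direction_errors += 1
    return {
        "n_planted_shared_above_threshold": len(above),
        "n_recovered": hits,
        "sensitivity": round(hits / len(above), 6) if len(above) else None,
        "n_direction_errors": direction_errors,
    }
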