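"""End-to-end orchestration of the selection scan on one configuration.

Stage order: synthesize (or load) data -> SNP calling and filtering -> CMH
scan -> windowed Ne estimation -> matched neutral simulation -> empirical
cutoff -> candidate calling -> region merging and AFC summaries.  Every
stage product is persisted as plain TSV/BED/sync so stages can be rerun or
inspected standalone; the report collects all headline numbers and tallies.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from erscan import calibrate, ne, regions, snp_filter, synth, wf_sim
from erscan.cmh import cmh_scan
from erscan.sync_io import AlleleCounts


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def synth_spec_from_config(cfg: dict, seed: int) -> synth.SynthSpec:
    planted = [
        synth.PlantedLocus(
            chrom=p["chrom"],
            pos=int(p["pos"]),
            s=float(p["s"]),
            block_halfwidth=int(p.get("block_halfwidth", 0)),
            rho=float(p.get("rho", 0.0)),
            p0=float(p["p0"]) if p.get("p0") is not None else None,
        )
        for p in cfg.get("planted_loci", [])
    ]
    return synth.SynthSpec(
        chromosomes={k: int(v) for k, v in cfg["chromosomes"].items()},
        n_snps={k: int(v) for k, v in cfg["n_snps"].items()},
        replicates=int(cfg.get("replicates", 3)),
        generations=int(cfg.get("generations", 60)),
        ne=int(cfg.get("ne", 285)),
        n_census=int(cfg.get("n_census", 1000)),
        founder_coverage_mean=float(cfg.get("founder_coverage_mean", 259)),
        evolved_coverage_mean=float(cfg.get("evolved_coverage_mean", 100)),
        pool_size_founder=int(cfg.get("pool_size_founder", 2000)),
        pool_size_evolved=int(cfg.get("pool_size_evolved", 2000)),
        spectrum_alpha=float(cfg.get("spectrum_alpha", 0.2)),
        spectrum_beta=float(cfg.get("spectrum_beta", 0.2)),
        planted_loci=planted,
        seed=seed,
    )


def combine_time_points(
    founder_sites: list[AlleleCounts], evolved_sites: list[AlleleCounts]
) -> list[AlleleCounts]:
    """Zip founder and evolved sync streams (same sites, same order) into
    joint per-site records with all sample columns."""
    joint = []
    for f, e in zip(founder_sites, evolved_sites, strict=True):
        if (f.chrom, f.pos) != (e.chrom, e.pos):
            raise ValueError(
                f"founder/evolved site mismatch: {f.chrom}:{f.pos} vs {e.chrom}:{e.pos}"
            )
        joint.append(
            AlleleCounts(
                f.chrom,
                f.pos,
                f.ref,
                f.samples + e.samples,
                f.sample_labels + e.sample_labels,
            )
        )
    return joint


def snp_table_for_ne(sites, founder_labels, evolved_labels) -> pd.DataFrame:
    """Per-SNP frequencies and depths per replicate, as the Ne scan wants."""
    rows = {
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
    }
    for k, (fl, el) in enumerate(zip(founder_labels, evolved_labels), start=1):
        rows[f"x_{k}"] = [s.frequency(fl) for s in sites]
        rows[f"y_{k}"] = [s.frequency(el) for s in sites]
        rows[f"depth0_{k}"] = [s.coverage(fl) for s in sites]
        rows[f"deptht_{k}"] = [s.coverage(el) for s in sites]
    return pd.DataFrame(rows)


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run all stages under one config; returns (and writes) the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rng = np.random.default_rng([seed, 0xE5CA])
    report: dict = {"species": config.get("species", "synthetic"), "seed": seed}

    # --- synthesize -------------------------------------------------------
    spec = synth_spec_from_config(config["synth"], seed)
    result = _stage("synth")(synth.generate)(spec)
    result.write(outdir)
    k = spec.replicates
    f_labels = [f"F{r + 1}" for r in range(k)]
    e_labels = [f"E{r + 1}" for r in range(k)]
    joint = combine_time_points(result.founder_sites, result.evolved_sites)
    report["n_sites_simulated"] = len(joint)

    # --- SNP calling and filtering ---------------------------------------
    fcfg = config.get("filter", {})
    filt_report = snp_filter.FilterReport()
    sites = _stage("snp_filter")(snp_filter.call_snps)(
        joint, f_labels, int(fcfg.get("min_minor_count", 1)), report=filt_report
    )
    thresholds = _stage("snp_filter")(snp_filter.coverage_thresholds)(
        joint, float(fcfg.get("coverage_quantile", 0.01))
    )
    cov_report = snp_filter.FilterReport()
    if not thresholds.degenerate:
        sites = snp_filter.apply_coverage_filter(sites, thresholds, report=cov_report)
    if fcfg.get("mask_bed"):
        mask = snp_filter.read_bed(fcfg["mask_bed"])
        sites = snp_filter.mask_intervals(sites, mask, report=cov_report)
    if fcfg.get("downsample_to"):
        sites = snp_filter.downsample_counts(sites, float(fcfg["downsample_to"]), rng)
    report["filter"] = {
        "n_in": filt_report.n_in,
        "n_snps_called": filt_report.n_out,
        "removed": {**filt_report.removed, **cov_report.removed},
        "coverage_upper": thresholds.upper,
        "coverage_lower": thresholds.lower,
        "n_after_filters": len(sites),
    }

    # --- CMH scan of observed data ---------------------------------------
    correction = bool(config.get("cmh", {}).get("continuity_correction", True))
    observed = _stage("cmh")(cmh_scan)(sites, f_labels, e_labels, correction)
    observed.to_csv(outdir / "observed_cmh.tsv", sep="\t", index=False)
    report["cmh"] = {
        "n_tests": len(observed),
        "n_undefined": observed.attrs.get("n_undefined", 0),
        "n_strata_skipped": observed.attrs.get("n_strata_skipped_total", 0),
    }

    # --- windowed Ne estimation ------------------------------------------
    ncfg = config.get("ne", {})
    snp_tab = snp_table_for_ne(sites, f_labels, e_labels)
    windows = _stage("ne")(ne.window_ne_scan)(
        snp_tab,
        [str(r + 1) for r in range(k)],
        pool0=spec.pool_size_founder,
        pool_t=spec.pool_size_evolved,
        generations=spec.generations,
        n_census=spec.n_census,
        window_snps=int(ncfg.get("window_snps", 1000)),
        min_snps=int(ncfg.get("min_snps", 500)),
        plan=str(ncfg.get("plan", "I")),
    )
    windows.to_csv(outdir / "ne_windows.tsv", sep="\t", index=False)
    if windows.empty or windows["ne_hat"].dropna().empty:
        raise PipelineError("stage 'ne' failed: no defined window estimates")
    ne_hat, medians = ne.aggregate_ne(windows)
    report["ne"] = {
        "aggregate": ne_hat,
        "replicate_medians": medians,
        "n_windows": int(len(windows)),
        "n_undefined_windows": int(windows["ne_hat"].isna().sum()),
    }

    # --- matched neutral null and empirical cutoff ------------------------
    x_cols = [f"x_{r + 1}" for r in range(k)]
    founder_freqs = snp_tab[x_cols].to_numpy().ravel()
    depth0 = snp_tab[[f"depth0_{r + 1}" for r in range(k)]].to_numpy().ravel()
    deptht = snp_tab[[f"deptht_{r + 1}" for r in range(k)]].to_numpy().ravel()
    n_null = int(config.get("null", {}).get("n_loci", 50_000))
    cohort = _stage("null")(wf_sim.neutral_cohort)(
        founder_freqs=founder_freqs,
        n_loci=n_null,
        ne=max(int(round(ne_hat)), 2),
        generations=spec.generations,
        replicates=k,
        founder_coverage=wf_sim.CoverageModel(depths=depth0[depth0 > 0]),
        evolved_coverage=wf_sim.CoverageModel(depths=deptht[deptht > 0]),
        pool_size_founder=spec.pool_size_founder,
        pool_size_evolved=spec.pool_size_evolved,
        rng=rng,
    )
    from erscan.cmh import cmh_from_counts

    null_res = cmh_from_counts(cohort.a, cohort.b, cohort.c, cohort.d, correction)
    null_scores = null_res["neg_log10_p"][~null_res["undefined"]]
    pd.DataFrame({"neg_log10_p": null_scores}).to_csv(
        outdir / "null_cmh.tsv", sep="\t", index=False
    )
    fpr = float(config.get("calibrate", {}).get("fpr", 0.02))
    cut = _stage("calibrate")(calibrate.empirical_cutoff)(null_scores, fpr)
    report["calibrate"] = {
        "fpr": cut.fpr,
        "cutoff": cut.cutoff,
        "n_neutral": cut.n_neutral,
    }

    # --- candidates, regions, AFC ----------------------------------------
    candidates = calibrate.call_candidates(observed, cut.cutoff)
    candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    rcfg = config.get("regions", {})
    chrom_lengths = {str(c): int(l) for c, l in config["synth"]["chromosomes"].items()}
    scores = _stage("regions")(regions.window_scores)(
        candidates,
        chrom_lengths,
        window=int(rcfg.get("window", 200_000)),
        step=int(rcfg.get("step", 100_000)),
    )
    scores.to_csv(outdir / "window_scores.tsv", sep="\t", index=False)
    merged, summary = regions.merge_regions(
        scores, cut.cutoff, chrom_lengths, candidates=candidates
    )
    merged.to_csv(outdir / "regions.tsv", sep="\t", index=False)
    regions.regions_to_bed(merged, outdir / "regions.bed")
    afc_table, afc_stats = regions.afc_summary(
        candidates, k, float(config.get("afc", {}).get("fixation_threshold", 0.9))
    )
    afc_table.to_csv(outdir / "afc_candidates.tsv", sep="\t", index=False)
    report["candidates"] = {"n": int(len(candidates))}
    report["regions"] = {
        "n_regions": summary.n_regions,
        "total_bp": summary.total_bp,
        "fraction_of_genome": summary.fraction_of_genome,
    }
    report["afc"] = afc_stats

    with open(outdir / "report.json", "wt") as handle:
        json.dump(report, handle, indent=2, default=float)
    with open(outdir / "report.txt", "wt") as handle:
        handle.write(format_report(report))
    return report


def format_report(report: dict) -> str:
    lines = [
        f"erscan pipeline report ({report.get('species', '?')}, seed {report.get('seed')})",
        f"  sites simulated        : {report.get('n_sites_simulated')}",
        f"  SNPs after filters     : {report['filter']['n_after_filters']}",
        f"  aggregate Ne           : {report['ne']['aggregate']:.1f}",
        f"  empirical cutoff       : {report['calibrate']['cutoff']:.3f} "
        f"(-log10 p at {report['calibrate']['fpr']:.0%} FPR, "
        f"{report['calibrate']['n_neutral']} neutral SNPs)",
        f"  candidate SNPs         : {report['candidates']['n']}",
        f"  selected regions       : {report['regions']['n_regions']} "
        f"({report['regions']['total_bp'] / 1e6:.2f} Mb, "
        f"{report['regions']['fraction_of_genome']:.1%} of genome)",
        f"  fixation fraction      : {report['afc']['fixation_fraction']:.1%} "
        f"(of {report['afc']['n']} candidates)",
    ]
    return "\n".join(lines) + "\n"
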