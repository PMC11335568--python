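"""End-to-end orchestration: from signal tracks to classified TSR tables.

Stages communicate through plain data structures in memory
(:func:`analyze_sample`) or through written TSV/bedGraph/JSON files
(:func:`run_pipeline`), so partial reruns and language-independent
inspection both work.  Every reported summary number is recomputable from
the stage tables it cites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calling, context, directionality, stability, starr as starr_mod
from .calling import CallerParams
from .context import ContextWindows
from .io import (
    CoverageTrack,
    EndProfile,
    GeneAnnotation,
    NormalizedProfile,
    read_bedgraph,
    read_fasta,
    read_gtf,
    read_region_table,
    write_bedgraph,
    write_fasta,
    write_gtf,
    write_region_table,
)


class PipelineError(RuntimeError):
    """A requested stage is missing a required input."""


@dataclass
class PipelineParams:
    caller: CallerParams = field(default_factory=CallerParams)
    stability_threshold: float = stability.STABILITY_THRESHOLD
    context_windows: ContextWindows = field(default_factory=ContextWindows)
    pair_window: int = directionality.DEFAULT_PAIR_WINDOW
    distal_cutoff: int = 2000


@dataclass
class SampleResult:
    sample: str
    tsrs: list
    stability_calls: list
    context_calls: list
    partners: dict
    style_calls: list
    distances: dict
    summary: dict


def analyze_sample(
    sample: str,
    cs: NormalizedProfile,
    input_profile: NormalizedProfile | None,
    rnaseq: CoverageTrack,
    annotation: GeneAnnotation | None,
    params: PipelineParams | None = None,
) -> SampleResult:
    """Call TSRs and classify stability, context and initiation style."""
    params = params or PipelineParams()
    tsrs = calling.call_tsrs(cs, input_profile, params.caller)
    calls = stability.classify_all(tsrs, rnaseq, params.stability_threshold)
    ctx = context.classify_all_contexts(tsrs, annotation, params.context_windows)
    partners = directionality.pair_bidirectional(tsrs, params.pair_window)
    styles = directionality.assign_styles(tsrs, partners, calls)

    if annotation is not None and len(annotation):
        index = context._AnnIndex.build(annotation)
        distances = {t.tsr_id: context.distance_to_nearest_tss(t, index) for t in tsrs}
    else:
        distances = {t.tsr_id: None for t in tsrs}

    n = len(tsrs)
    n_unstable = sum(1 for c in calls if not c.is_stable)
    ctx_counts = {k: 0 for k in context.CONTEXT_CLASSES}
    for c in ctx:
        ctx_counts[c.context] += 1
    style_counts = {k: 0 for k in directionality.STYLES}
    for s in styles:
        style_counts[s.style] += 1
    bidir = directionality.bidirectional_unstable_fraction(styles, distances, params.distal_cutoff)
    summary = {
        "sample": sample,
        "n_tsr": n,
        "n_stable": n - n_unstable,
        "n_unstable": n_unstable,
        "pct_unstable": 100.0 * n_unstable / n if n else 0.0,
        "context_counts": ctx_counts,
        "style_counts": style_counts,
        "pct_uu": bidir["pct_uu"],
        "pct_uu_distal": bidir["pct_uu_distal"],
    }
    if annotation is not None and len(annotation) and n:
        ratio, n_anti, n_sense = context.antisense_ratio(tsrs, annotation, params.context_windows.sense)
        bins = context.distance_bin_ratios(tsrs, calls, annotation)
        summary["antisense_ratio"] = ratio
        summary["distance_bins"] = {
            "labels": list(bins.labels),
            "stable": bins.stable,
            "unstable": bins.unstable,
            "ratios": bins.ratios(),
        }
    return SampleResult(
        sample=sample,
        tsrs=tsrs,
        stability_calls=calls,
        context_calls=ctx,
        partners=partners,
        style_calls=styles,
        distances=distances,
        summary=summary,
    )


def result_tables(res: SampleResult) -> dict[str, pd.DataFrame]:
    """Stage tables as DataFrames (what run_pipeline writes to disk)."""
    stab = {c.tsr_id: c for c in res.stability_calls}
    ctx = {c.tsr_id: c for c in res.context_calls}
    sty = {s.tsr_id: s for s in res.style_calls}
    tsr_rows = []
    tss_rows = []
    for t in res.tsrs:
        tsr_rows.append(
            {
                "chrom": t.chrom, "start": t.start, "end": t.end, "name": t.tsr_id,
                "score": round(t.total_norm, 4), "strand": t.strand,
                "major_tss": t.major_pos, "n_tss": len(t.members),
                "stability_score": round(stab[t.tsr_id].score, 4),
                "stability": stab[t.tsr_id].stability,
                "context": ctx[t.tsr_id].context,
                "distance": ctx[t.tsr_id].distance if ctx[t.tsr_id].distance is not None else "",
                "nearest": ctx[t.tsr_id].nearest_id or "",
                "style": sty[t.tsr_id].style,
                "partner": sty[t.tsr_id].partner_id or "",
                "bidirectional": int(sty[t.tsr_id].bidirectional),
            }
        )
        for m in t.members:
            tss_rows.append(
                {
                    "chrom": m.chrom, "position": m.position, "strand": m.strand,
                    "norm_count": round(m.norm_count, 4), "tsr_id": t.tsr_id,
                }
            )
    return {
        "tsr": pd.DataFrame(tsr_rows),
        "tss": pd.DataFrame(tss_rows),
    }


# ---------------------------------------------------------------------------
# file-based pipeline
# ---------------------------------------------------------------------------


def _load_profile(paths: dict, prefix: str, kind: str):
    plus = paths.get(f"{prefix}_plus")
    minus = paths.get(f"{prefix}_minus")
    total = paths.get(f"{prefix}_total_reads")
    if plus is None or minus is None or total is None:
        return None
    track_p = read_bedgraph(plus, "+", float(total), kind=kind)
    track_m = read_bedgraph(minus, "-", float(total), kind=kind)
    for chrom, strand, p, v in track_m.items():
        track_p.add(chrom, strand, p, v)
    return track_p


def run_pipeline(config: dict, outdir) -> dict:
    """File-driven end-to-end run.

    ``config`` (usually parsed from YAML) holds a ``samples`` manifest of
    input paths, optional ``gtf``/``starr``/``atac`` paths, and optional
    parameter overrides.  Writes per-sample TSR/TSS tables, a cross-sample
    switch table when >= 2 samples provide stability data, STARR outputs
    when provided, and a machine-readable ``summary.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = PipelineParams()
    p_over = config.get("params", {})
    if "tss_min_norm" in p_over or "tsr_min_norm" in p_over or "cluster_dist" in p_over:
        params.caller = CallerParams(
            tss_min_norm=p_over.get("tss_min_norm", 7.0),
            tsr_min_norm=p_over.get("tsr_min_norm", 10.0),
            cluster_dist=p_over.get("cluster_dist", 200),
            input_fold=p_over.get("input_fold", 1.0),
        )
    params.stability_threshold = p_over.get("stability_threshold", params.stability_threshold)
    params.pair_window = p_over.get("pair_window", params.pair_window)

    annotation = read_gtf(config["gtf"]) if config.get("gtf") else None
    samples = config.get("samples")
    if not samples:
        raise PipelineError("stage calltsr: no samples in manifest")

    results: dict[str, SampleResult] = {}
    for sample, paths in samples.items():
        cs_raw = _load_profile(paths, "csrna", "ends")
        if cs_raw is None:
            raise PipelineError(f"stage calltsr: sample {sample} lacks csRNA inputs")
        cs = cs_raw.normalize()
        inp_raw = _load_profile(paths, "input", "ends")
        inp = inp_raw.normalize() if inp_raw is not None else None
        rna_raw = _load_profile(paths, "rnaseq", "coverage")
        if rna_raw is None:
            raise PipelineError(f"stage classify: sample {sample} lacks RNA-seq inputs")
        rna = rna_raw.normalize()
        res = analyze_sample(sample, cs, inp, rna, annotation, params)
        results[sample] = res
        tables = result_tables(res)
        tables["tsr"].to_csv(outdir / f"{sample}.tsr.tsv", sep="\t", index=False)
        tables["tss"].to_csv(outdir / f"{sample}.tss.tsv", sep="\t", index=False)

    report: dict = {
        "params": {
            "tss_min_norm": params.caller.tss_min_norm,
            "tsr_min_norm": params.caller.tsr_min_norm,
            "cluster_dist": params.caller.cluster_dist,
            "input_fold": params.caller.input_fold,
            "stability_threshold": params.stability_threshold,
            "pair_window": params.pair_window,
            "distal_cutoff": params.distal_cutoff,
        },
        "samples": {s: r.summary for s, r in results.items()},
    }

    if len(results) >= 2:
        summary = stability.switch_analysis(
            {s: r.tsrs for s, r in results.items()},
            {s: r.stability_calls for s, r in results.items()},
        )
        report["switch"] = {
            "n_union": summary.n_union,
            "n_multi": summary.n_multi,
            "n_switching": summary.n_switching,
            "pct_switching": summary.pct_switching,
        }
        rows = [
            {
                "chrom": m["chrom"], "start": m["start"], "end": m["end"],
                "strand": m["strand"],
                "classes": ";".join(f"{s}={c}" for s, c in sorted(m["classes"].items())),
                "switch": int(m["switch"]),
            }
            for m in summary.per_tsr
        ]
        pd.DataFrame(rows).to_csv(outdir / "switch.tsv", sep="\t", index=False)

    if config.get("starr"):
        first = next(iter(results.values()))
        peaks = read_region_table(config["starr"], dialect="tsv")
        peaks = starr_mod.filter_fragments(peaks)
        atac = (
            read_region_table(config["atac"], dialect="bed6")
            if config.get("atac")
            else pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
        )
        merged = starr_mod.merge_and_score(
            first.tsrs, first.stability_calls, first.style_calls, atac, peaks
        )
        merged_df = pd.DataFrame(
            [
                {
                    "region_id": m.region_id, "chrom": m.chrom, "start": m.start,
                    "end": m.end, "length": m.length,
                    "activity_sum": round(m.activity_sum, 4),
                    "per_bp_activity": round(m.per_bp_activity, 4),
                    "class": m.tsr_class, "substyle": m.substyle, "covered": int(m.covered),
                }
                for m in merged
            ]
        )
        merged_df.to_csv(outdir / "starr_merged.tsv", sep="\t", index=False)
        groups = {}
        for m in merged:
            groups.setdefault(m.tsr_class, []).append(m.per_bp_activity)
        try:
            cmp_res = starr_mod.group_compare(groups)
            report["starr"] = {
                "f_stat": cmp_res.f_stat,
                "p_value": cmp_res.p_value,
                "group_medians": {
                    k: float(pd.Series(v).median()) for k, v in cmp_res.groups.items()
                },
                "tukey": cmp_res.tukey.to_dict(orient="records"),
                "tsr_coverage_fraction": starr_mod.starr_coverage_fraction(first.tsrs, merged),
            }
        except ValueError:
            report["starr"] = {"error": "too few groups for comparison"}
        signals, acts = [], []
        for m in merged:
            over = [
                t for t in first.tsrs
                if t.chrom == m.chrom and t.start < m.end and t.end > m.start
            ]
            if over and m.covered:
                strongest = max(over, key=lambda t: (t.total_norm, t.tsr_id))
                signals.append(strongest.total_norm)
                acts.append(m.per_bp_activity)
        if len(signals) >= 3:
            report["starr"]["correlation"] = starr_mod.activity_correlation(signals, acts)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# simulated-bundle writer (CLI `simulate`)
# ---------------------------------------------------------------------------


def write_simulated_bundle(sim_config, outdir) -> dict:
    """Simulate a full dataset and write it in pipeline-ready formats.

    Emits FASTA, GTF, per-strand bedGraphs for all tracks, the STARR
    activity table, the ATAC/open-chromatin BED, the truth tables and a
    ``manifest.yaml`` that run_pipeline can consume directly.
    """
    from .simulate import simulate_all

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation, truth, cs, inp, rna, gro, starr_df = simulate_all(sim_config)
    write_fasta(genome, outdir / "genome.fa")
    write_gtf(annotation, outdir / "annotation.gtf")
    for name, track in (("csrna", cs), ("input", inp), ("rnaseq", rna), ("groseq", gro)):
        write_bedgraph(track, outdir / f"{name}.plus.bedgraph", "+")
        write_bedgraph(track, outdir / f"{name}.minus.bedgraph", "-")
    starr_df.to_csv(outdir / "starr.tsv", sep="\t", index=False)
    atac = truth.open_regions.copy()
    atac["score"] = 0
    atac["strand"] = "."
    write_region_table(atac[["chrom", "start", "end", "name", "score", "strand"]],
                       outdir / "atac.bed", dialect="bed6")
    truth.write(outdir)
    manifest = {
        "gtf": str(outdir / "annotation.gtf"),
        "genome": str(outdir / "genome.fa"),
        "starr": str(outdir / "starr.tsv"),
        "atac": str(outdir / "atac.bed"),
        "genome_length": sim_config.genome_length,
        "seed": sim_config.seed,
        "samples": {
            "sim": {
                "csrna_plus": str(outdir / "csrna.plus.bedgraph"),
                "csrna_minus": str(outdir / "csrna.minus.bedgraph"),
                "csrna_total_reads": sim_config.csrna_depth,
                "input_plus": str(outdir / "input.plus.bedgraph"),
                "input_minus": str(outdir / "input.minus.bedgraph"),
                "input_total_reads": sim_config.csrna_depth,
                "rnaseq_plus": str(outdir / "rnaseq.plus.bedgraph"),
                "rnaseq_minus": str(outdir / "rnaseq.minus.bedgraph"),
                "rnaseq_total_reads": sim_config.rna_depth,
                "groseq_plus": str(outdir / "groseq.plus.bedgraph"),
                "groseq_minus": str(outdir / "groseq.minus.bedgraph"),
                "groseq_total_reads": sim_config.rna_depth,
            }
        },
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
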