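"""End-to-end pipeline: simulate or load, normalise, score, deconvolve, analyse.

The pipeline is configured with a mapping (or a YAML file): either a
``simulate`` section with :class:`~poolanchor.synthetic.SimulationConfig`
overrides, or an ``inputs`` section naming the physical map, signal matrix
and reference tables on disk.  Output is a JSON report plus TSV tables
(loci, per-bin stats, islands, comparative assignments, method log); runs
are deterministic given config + seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from poolanchor import comparative as comp
from poolanchor import genespace
from poolanchor.core_io import (
    read_genetic_map,
    read_ortholog_table,
    read_physical_map,
    read_probe_sequences,
    read_repeat_library,
    read_signal_matrix,
)
from poolanchor.deconvolve import (
    assign_bins,
    build_loci,
    deconvolve_all,
    loci_frame,
    te_filter,
)
from poolanchor.pooling import (
    PoolLayout,
    automated_scoring,
    boxplot_scoring,
    complete_manual,
    complete_semi_automated,
    normalize,
)
from poolanchor.synthetic import SimulationConfig, simulate

KNOWN_METHODS = ("automated", "boxplot", "semi_automated", "manual")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_config(config: Mapping[str, Any] | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(config: Mapping[str, Any] | str | Path) -> dict:
    """Run the full analysis and return the report dict.

    When the config has an ``outdir``, the report (JSON) and the loci,
    per-bin, island, comparative and method-log tables (TSV) are written
    there.  Identical config + seed produces byte-identical outputs.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    methods = list(cfg.get("scoring", {}).get("methods", KNOWN_METHODS))
    if not methods:
        raise PipelineError("scoring", "no scoring method configured")
    unknown = [m for m in methods if m not in KNOWN_METHODS]
    if unknown:
        raise PipelineError("scoring", f"unknown scoring methods {unknown}")

    report: dict[str, Any] = {"seed": seed, "stages": []}

    # ---- stage: inputs -------------------------------------------------
    stage = "inputs"
    try:
        simulated = "simulate" in cfg or "inputs" not in cfg
        gmap = orthologs = alignments = None
        library = probes = None
        truth = None
        if simulated:
            sim_cfg = SimulationConfig(**{**cfg.get("simulate", {}), "seed": seed})
            bundle = simulate(sim_cfg)
            pm, layout, truth = bundle.pm, bundle.layout, bundle.truth
            matrix = bundle.signals
            library = bundle.library
            probes = truth.probe_sequences
            gmap, orthologs, alignments = bundle.gmap, bundle.orthologs, bundle.alignments
            report["simulation"] = {
                "n_bacs": len(pm),
                "n_contigs": len(pm.contigs),
                "n_genes": sim_cfg.n_genes,
                "n_pools": len(layout.pool_ids()),
            }
        else:
            inputs = cfg["inputs"]
            pm = read_physical_map(inputs["physical_map"])
            geom = inputs["geometry"]
            layout = PoolLayout.from_physical_map(
                pm, geom["n_plates"], geom["n_rows"], geom["n_cols"]
            )
            matrix = read_signal_matrix(inputs["signals"], layout)
            if "genetic_map" in inputs:
                gmap = read_genetic_map(inputs["genetic_map"])
            if "orthologs" in inputs:
                orthologs = read_ortholog_table(inputs["orthologs"])
            if "probe_fasta" in inputs:
                probes = read_probe_sequences(inputs["probe_fasta"])
            if "repeats" in inputs:
                library = read_repeat_library(inputs["repeats"])
            if "alignments" in inputs:
                adf = pd.read_csv(inputs["alignments"], sep="\t", comment="#")
                alignments = {
                    pid: list(
                        g[["marker_id", "identity_pct", "length_nt"]].itertuples(
                            index=False, name=None
                        )
                    )
                    for pid, g in adf.groupby("probe_id")
                }
        report["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        raise PipelineError(stage, exc) from exc

    # ---- stage: normalise ---------------------------------------------
    stage = "normalize"
    try:
        norm = normalize(matrix, layout)
        report["stages"].append(stage)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- stage: score --------------------------------------------------
    stage = "score"
    try:
        k = cfg.get("scoring", {}).get("k")
        results = []
        auto = automated_scoring(norm, layout, k=k) if "automated" in methods else None
        base = auto
        if "automated" in methods:
            results.append(auto)
        if "boxplot" in methods:
            box = boxplot_scoring(norm, layout)
            results.append(box)
            if base is None:
                base = box
        if "semi_automated" in methods and base is not None:
            results.append(complete_semi_automated(base, layout, pm))
        if "manual" in methods and base is not None:
            results.append(complete_manual(base, layout, pm))
        report["scoring"] = {
            r.method: {
                "probes_with_positives": sum(
                    1 for c in r.calls.values() if c.n_positive
                )
                if r.calls
                else 0,
                "direct_assignments": len(r.assigned),
            }
            for r in results
        }
        report["thresholds"] = {
            "k": dict(k) if k else {"plate": 2.8, "row": 2.5, "column": 3.0},
            "boxplot_fence": "Q3 + 1.5*IQR",
        }
        report["stages"].append(stage)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- stage: deconvolve ---------------------------------------------
    stage = "deconvolve"
    try:
        addresses, method_log = deconvolve_all(results, layout, pm)
        flagged = set()
        te_table = None
        if probes is not None and library is not None:
            te_cfg = cfg.get("te_filter", {})
            flagged, te_table = te_filter(
                probes,
                library,
                min_identity=te_cfg.get("min_identity", 0.80),
                min_span_nt=te_cfg.get("min_span_nt", 45),
            )
        kept = [a for a in addresses if a.probe_id not in flagged]
        loci = build_loci(kept, pm)
        bin_summary = assign_bins(loci, pm)
        report["deconvolution"] = {
            "probes_with_addresses": len({a.probe_id for a in kept}),
            "n_addresses": len(kept),
            "n_loci": len(loci),
            "n_duplicated_loci": sum(l.duplicated for l in loci),
            "te_probes_flagged": sorted(flagged),
            "bins": bin_summary,
        }
        report["stages"].append(stage)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- stage: comparative ---------------------------------------------
    stage = "comparative"
    comparative_frames = {}
    try:
        bin_order = [b.name for b in pm.bins]
        frame = loci_frame(loci)
        report["comparative"] = {}
        if gmap is not None and alignments is not None and not frame.empty:
            barley = comp.attach_map_positions(frame, gmap, alignments)
            summary = comp.synteny_summary(barley, "3H", bin_order=bin_order)
            blocks, retained = comp.build_synteny_blocks(barley, bin_order, "3H")
            coll = comp.collinearity_summary(barley, blocks, "3H")
            report["comparative"]["barley"] = {
                "synteny": summary,
                "collinearity": coll,
                "mean_per_bin_synteny_pct": comp.mean_per_bin_synteny(
                    summary["per_bin"]
                )
                if summary["per_bin"]
                else None,
            }
            comparative_frames["barley"] = barley
        if orthologs is not None and not frame.empty:
            rice = comp.attach_ortholog_positions(frame, orthologs)
            summary = comp.synteny_summary(rice, "Os01", bin_order=bin_order)
            blocks, _ = comp.build_synteny_blocks(rice, bin_order, "Os01")
            coll = comp.collinearity_summary(rice, blocks, "Os01")
            report["comparative"]["rice"] = {"synteny": summary, "collinearity": coll}
            comparative_frames["rice"] = rice
        report["stages"].append(stage)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- stage: genespace -----------------------------------------------
    stage = "genespace"
    try:
        lengths = {
            b.name: b.contig_length_mb
            for b in pm.bins
            if b.contig_length_mb
        }
        counts = genespace.count_loci_by_bin(loci)
        gap_bp = cfg.get("islands", {}).get("gap_bp", genespace.DEFAULT_ISLAND_GAP_BP)
        assignment = genespace.detect_islands(loci, pm, gap_bp=gap_bp)
        report["genespace"] = {"island_gap_bp": gap_bp}
        if lengths:
            density = genespace.bin_density(counts, lengths)
            norm_d = genespace.normalized_density(
                density.loc[density["bin"] != "total", "density"].to_numpy()
            )
            island_stats = genespace.island_bin_stats(loci, assignment, lengths)
            report["genespace"].update(
                {
                    "bin_density": density.to_dict(orient="records"),
                    "normalized_density": dict(
                        zip(density["bin"][: len(norm_d)], norm_d.tolist())
                    ),
                    "n_islands": len(assignment.members),
                    "n_island_loci": assignment.n_island_loci,
                    "pct_island": 100.0 * assignment.n_island_loci / len(loci)
                    if loci
                    else None,
                }
            )
            distances = {
                b.name: b.midpoint_dist_mb
                for b in pm.bins
                if b.midpoint_dist_mb is not None
            }
            shared = [n for n in lengths if n in distances and counts.get(n)]
            if len(shared) >= 3:
                dens = [counts.get(n, 0) / lengths[n] for n in shared]
                if np.ptp(dens) > 0:
                    report["genespace"]["gradient"] = genespace.gradient_tests(
                        dens,
                        [distances[n] for n in shared],
                        [counts.get(n, 0) for n in shared],
                        [lengths[n] for n in shared],
                    )
        else:
            island_stats = None
        report["stages"].append(stage)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- stage: recovery (simulation only) -------------------------------
    if truth is not None:
        stage = "recovery"
        try:
            detectable = truth.detectable_probes(
                floor=sim_cfg.detectability_floor
            ) - truth.te_probes
            by_probe: dict[str, set[str]] = {}
            for locus in loci:
                by_probe.setdefault(locus.probe_id, set()).update(locus.bac_ids)
            recovered = 0
            for pid in detectable:
                true_bacs = set(truth.genes[pid].placements[0].bac_ids)
                found = by_probe.get(pid, set())
                if found and found <= true_bacs:
                    recovered += 1
            report["recovery"] = {
                "n_detectable": len(detectable),
                "n_recovered": recovered,
                "recovery_rate": recovered / len(detectable) if detectable else None,
                "detection_rate_all_placed": (
                    len(by_probe)
                    / max(
                        1,
                        sum(
                            1
                            for g in truth.genes.values()
                            if g.placements[0].bac_ids
                        ),
                    )
                ),
            }
            report["stages"].append(stage)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    # ---- output ----------------------------------------------------------
    outdir = cfg.get("outdir")
    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        loci_frame(loci).to_csv(out / "loci.tsv", sep="\t", index=False)
        method_log.to_csv(out / "method_log.tsv", sep="\t", index=False)
        if te_table is not None:
            te_table.to_csv(out / "te_filter.tsv", sep="\t", index=False)
        if lengths:
            density.to_csv(out / "bin_stats.tsv", sep="\t", index=False)
            if island_stats is not None:
                island_stats.to_csv(out / "islands.tsv", sep="\t", index=False)
        for name, frame_ in comparative_frames.items():
            frame_.to_csv(out / f"comparative_{name}.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
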