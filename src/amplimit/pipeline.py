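"""End-to-end pipeline: simulate -> detect -> threshold -> filter -> compare.

Drives the whole methodology on a (usually simulated) mock community and
writes a JSON + Markdown report: detection curves and geometric-model fits,
depth/abundance cutoffs, contamination classification and the distance-based
replicate comparison.  Everything is deterministic in the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import compare as cmp_mod
from . import detection, filtering, io as io_mod
from .community import adjust_for_copy_number, mock_community
from .simulate import simulate_library

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: io_mod.RunConfig, outdir: str | Path) -> dict:
    """Run the full analysis described by ``config``; returns the report dict.

    Stages (each failure is re-raised with the stage name):

    1. simulate: replicate mock-community libraries.
    2. detect: multiple rarefaction of the deepest library, geometric-model
       fits with bootstrap KS per taxon.
    3. threshold: depth-dependent abundance cutoffs.
    4. filter: rarefy the replicate table, apply the cutoff, classify
       contaminants against the known genera.
    5. compare: weighted UniFrac between replicates, Shannon per sample,
       PERMANOVA between the two library sizes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_resolved.yaml")
    report: dict = {"seed": config.seed, "stages": {}}
    timings = report["stages"]

    def run_stage(name, fn):
        t0 = _stage(name)
        try:
            result = fn()
        except Exception as exc:  # pragma: no cover - error path
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        return result

    # stage 1: simulate -------------------------------------------------
    sim_cfg = config.simulator
    spec_path = config.paths.get("spec")
    spec = (
        io_mod.read_community_spec(spec_path) if spec_path else mock_community()
    )
    n_small = int(sim_cfg.get("n_small", 5000))
    n_large = int(sim_cfg.get("n_large", 50_000))
    n_reps = int(sim_cfg.get("replicates", 2))
    bias = bool(sim_cfg.get("copy_number_bias", False))

    def simulate():
        libs = {}
        for rep in range(n_reps):
            libs[f"small_{rep + 1}"] = simulate_library(
                spec, n_small, seed=config.seed + rep, copy_number_bias=bias
            )
        libs["large_1"] = simulate_library(
            spec, n_large, seed=config.seed + 100, copy_number_bias=bias
        )
        return libs

    libraries = run_stage("simulate", simulate)
    report["libraries"] = {k: v.size for k, v in libraries.items()}

    # stage 2: detect ---------------------------------------------------
    det_cfg = config.detection
    n_subsamples = int(det_cfg.get("n_subsamples", 100))
    large = libraries["large_1"]
    abundances = adjust_for_copy_number(spec) if bias else spec.abundances

    def detect():
        levels = detection.default_levels(large.size)
        curves = detection.multiple_rarefaction(
            large.counts, levels, n_subsamples, seed=config.seed + 1000
        )
        fits = {}
        for curve in curves:
            p = abundances[curve.taxon_id]
            entry = {"p": p, "n95": detection.reads_required(p)}
            nondeg = [f for f in curve.proportions if 0.0 < f < 1.0]
            if nondeg:
                model = detection.GeometricDetectionModel(p=p)
                d, pv = detection.bootstrap_ks_test(
                    curve, model, seed=config.seed + 2000
                )
                entry.update({"ks_D": d, "ks_p": pv})
            fits[curve.taxon_id] = entry
        return curves, fits

    curves, fits = run_stage("detect", detect)
    report["detection"] = fits

    # stage 3: threshold ------------------------------------------------
    depths = [int(d) for d in config.filter.get("depths", [900, 400])]

    def thresholds():
        return {
            str(d): detection.min_detectable_abundance(d) for d in depths
        }

    report["thresholds"] = run_stage("threshold", thresholds)

    # stage 4: filter ---------------------------------------------------
    depth = depths[0]
    cutoff = report["thresholds"][str(depth)]

    def filter_stage():
        table = io_mod.library_counts_table(
            {k: v for k, v in libraries.items() if k.startswith("small")}, spec
        )
        norm = filtering.normalize_to_depth(
            table, depth, seed=config.seed + 3000
        )
        cut = filtering.apply_abundance_cutoff(norm, cutoff)
        contam = filtering.classify_contaminants(cut, spec.genera)
        return {
            "depth": depth,
            "cutoff": cutoff,
            "taxa_retained": cut.taxon_ids,
            "contaminant_fraction": contam.contaminant_fraction,
        }

    report["filter"] = run_stage("filter", filter_stage)

    # stage 5: compare --------------------------------------------------
    def compare_stage():
        tree = (
            io_mod.read_tree(config.paths["tree"])
            if config.paths.get("tree")
            else io_mod.genus_tree(spec)
        )
        table = io_mod.library_counts_table(libraries, spec)
        by_genus = table.collapse_genus()
        genus_tree_names = {t.name for t in tree.tips()}
        counts = (
            by_genus.counts
            if spec.genera <= genus_tree_names
            else table.counts
        )
        dm = cmp_mod.unifrac_distance_matrix(tree, counts)
        shannon = {
            s: cmp_mod.shannon_index(table.counts[s]) for s in table.sample_ids
        }
        out = {
            "unifrac_mean": float(np.mean(dm.condensed_form())),
            "shannon": shannon,
        }
        groups = ["small" if s.startswith("small") else "large"
                  for s in dm.ids]
        if len(set(groups)) == 2 and len(groups) >= 4:
            f, p = cmp_mod.permanova(
                dm, groups,
                n_perm=int(config.compare.get("n_perm", 1000)),
                seed=config.seed + 4000,
            )
            out["permanova"] = {"pseudo_F": f, "p_value": p}
        io_mod.write_distance_matrix(dm, outdir / "unifrac_distances.tsv")
        return out

    report["compare"] = run_stage("compare", compare_stage)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (outdir / "report.md").write_text(_markdown(report), encoding="utf-8")
    return report


def _markdown(report: dict) -> str:
    lines = [
        "# amplimit pipeline report",
        "",
        f"Seed: {report['seed']}",
        "",
        "## Thresholds (minimum detectable abundance, 95% confidence)",
        "",
    ]
    for depth, cutoff in sorted(report["thresholds"].items(), key=lambda x: int(x[0])):
        lines.append(f"- depth {depth}: {100 * cutoff:.1f}%")
    lines += ["", "## Detection model fits", ""]
    for taxon, entry in sorted(report["detection"].items()):
        ks = (
            f", KS D={entry['ks_D']:.3f} p={entry['ks_p']:.3f}"
            if "ks_D" in entry
            else ""
        )
        lines.append(
            f"- {taxon}: p={entry['p']:.2e}, reads for 95% detection "
            f"N95={entry['n95']}{ks}"
        )
    lines += ["", "## Filtering", ""]
    f = report["filter"]
    lines.append(
        f"- depth {f['depth']}, cutoff {100 * f['cutoff']:.2f}%: "
        f"{len(f['taxa_retained'])} taxa retained"
    )
    lines += ["", "## Comparison", ""]
    c = report["compare"]
    lines.append(f"- mean weighted UniFrac: {c['unifrac_mean']:.4f}")
    if "permanova" in c:
        lines.append(
            f"- PERMANOVA small vs large libraries: pseudo-F "
            f"{c['permanova']['pseudo_F']:.3f}, p={c['permanova']['p_value']:.4f}"
        )
    lines.append("")
    return "\n".join(lines)
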