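"""End-to-end orchestration: simulate or load inputs, genotype, sample
pairs, score kin discrimination, build identity curves and run the spatial
statistics, writing a reproducible result bundle.

A run is configured by a single mapping (usually loaded from YAML) with
sections mirroring the library modules::

    seed: 1
    mode: simulate            # or "files"
    landscape: {...}          # simulate mode: LandscapeConfig overrides
    evolution: {...}
    kd_model: {...}
    inputs:                   # files mode
      loci: {Mxan_0128: path.fasta, ...}
      sample_sheet: sheet.tsv
      kd_table: kd.tsv        # optional; simulated when absent
      clades: clades.tsv      # optional
    pairs: {n_per_scale: 4, n_replicates: 3}
    analysis: {distance_model: p, site_handling: pairwise, mantel_permutations: 9999}

Every output bundle contains a ``manifest.json`` recording the command,
config snapshot, input digests, seeds and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import ScaleGeometry, SCALES, read_sample_sheet
from .genotypes import (
    LocusAlignmentSet,
    assign_sequence_types,
    concatenate_loci,
    distance_matrix,
    diversity_table,
)
from .identity import (
    anova_tukey,
    curve_correlation,
    genetic_identity_curve,
    social_identity_curve,
)
from .kd import read_kd_table, records_from_table, score_table, social_identity
from .pairs import sample_independent_pairs, write_pairs
from .simulate import (
    EvolutionConfig,
    KDModelConfig,
    LandscapeConfig,
    simulate_kd,
    simulate_landscape,
)
from .spatial import (
    geographic_distance_matrix,
    mantel_test,
    nearest_st_concordance,
    scale_distance_curve,
    st_site_map,
)

log = logging.getLogger("myxogeo")

__all__ = ["run_pipeline", "load_config", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _stage(name: str, manifest: dict):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s finished in %.2fs", name, dt)
                manifest.setdefault("stages", []).append({"stage": name, "seconds": round(dt, 3)})
                return False
            raise PipelineError(name, str(exc)) from exc

    return _Ctx()


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute simulate/load -> genotype -> pairs -> kd -> identity ->
    spatial, writing all tables and a human-readable report to ``out_dir``.

    Returns a dict of in-memory results keyed by stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dict(config)
    seed = seed if seed is not None else cfg.get("seed")
    rng = np.random.default_rng(seed)
    mode = cfg.get("mode", "simulate")
    manifest: dict[str, Any] = {
        "command": "run_pipeline",
        "version": __version__,
        "seed": seed,
        "mode": mode,
        "config": cfg,
        "inputs": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    results: dict[str, Any] = {}
    analysis = cfg.get("analysis", {})
    geometry = ScaleGeometry.from_mapping(cfg.get("geometry", {})) if cfg.get("geometry") else ScaleGeometry()

    with _stage("inputs", manifest):
        if mode == "simulate":
            lc = LandscapeConfig(**cfg.get("landscape", {}))
            evo = EvolutionConfig(**cfg.get("evolution", {}))
            sim = simulate_landscape(lc, evo, seed=int(rng.integers(2**31)))
            sim.write(out / "simulated")
            sheet = sim.sample_sheet
            alignments = sim.alignments
            clades = {i: str(c) for i, c in sim.true_clade.items()}
            results["simulated"] = sim
        elif mode == "files":
            inputs = cfg.get("inputs")
            if not inputs:
                raise ValueError("config field 'inputs' is required in files mode")
            for field in ("loci", "sample_sheet"):
                if field not in inputs:
                    raise ValueError(f"config field 'inputs.{field}' is required")
            sheet = read_sample_sheet(inputs["sample_sheet"])
            alignments = LocusAlignmentSet.from_fasta(inputs["loci"])
            manifest["inputs"] = {
                "sample_sheet": _digest(Path(inputs["sample_sheet"])),
                **{k: _digest(Path(v)) for k, v in inputs["loci"].items()},
            }
            clades = None
            if inputs.get("clades"):
                cl = pd.read_csv(inputs["clades"], sep="\t", comment="#")
                clades = dict(zip(cl["isolate_id"].astype(str), cl["clade"].astype(str)))
        else:
            raise ValueError(f"unknown mode: {mode!r}")
        # drop sheet rows for isolates excluded at genotyping
        sheet = sheet[sheet["isolate_id"].isin(set(alignments.isolates))].reset_index(drop=True)

    with _stage("genotype", manifest):
        concatemers = concatenate_loci(alignments)
        assignment = assign_sequence_types(concatemers)
        assignment.to_frame().to_csv(out / "st_assignment.tsv", sep="\t", index=False)
        divtab = diversity_table(
            sheet, concatemers, assignment, analysis.get("site_handling", "pairwise")
        )
        divtab.to_csv(out / "diversity_table.tsv", sep="\t", index=False, float_format="%.4f")
        dmat = distance_matrix(
            concatemers,
            model=analysis.get("distance_model", "p"),
            site_handling=analysis.get("site_handling", "pairwise"),
        )
        dmat.to_csv(out / "distance_matrix.tsv", sep="\t")
        results["genotype"] = {
            "n_isolates": len(concatemers),
            "n_st": assignment.n_types,
            "assignment": assignment,
            "diversity_table": divtab,
            "distance_matrix": dmat,
        }

    with _stage("pairs", manifest):
        pcfg = cfg.get("pairs", {})
        pairset = sample_independent_pairs(
            sheet,
            n_per_scale=int(pcfg.get("n_per_scale", 4)),
            n_replicates=int(pcfg.get("n_replicates", 3)),
            seed=int(rng.integers(2**31)),
        )
        write_pairs(pairset, out / "pairs.tsv")
        results["pairs"] = pairset

    with _stage("kd", manifest):
        if mode == "files" and cfg.get("inputs", {}).get("kd_table"):
            kd_frame = read_kd_table(cfg["inputs"]["kd_table"])
            manifest["inputs"]["kd_table"] = _digest(Path(cfg["inputs"]["kd_table"]))
        else:
            kd_frame = simulate_kd(
                pairset,
                results["genotype"]["distance_matrix"],
                KDModelConfig(**cfg.get("kd_model", {})),
                seed=int(rng.integers(2**31)),
            )
        scored = score_table(kd_frame)
        scored.to_csv(out / "kd_scored.tsv", sep="\t", index=False)
        results["kd"] = scored

    with _stage("identity", manifest):
        gcurve = genetic_identity_curve(pairset, results["genotype"]["assignment"])
        labels = social_identity(pairset, records_from_table(results["kd"]))
        scurve = social_identity_curve(pairset, labels)
        gcurve.to_frame().to_csv(out / "identity_genetic.tsv", sep="\t", index=False)
        scurve.to_frame().to_csv(out / "identity_social.tsv", sep="\t", index=False)
        comparisons = {}
        for curve in (gcurve, scurve):
            comp = anova_tukey(curve)
            comp.tukey.to_csv(out / f"tukey_{curve.kind}.tsv", sep="\t", index=False)
            comparisons[curve.kind] = comp
        corr = curve_correlation(gcurve, scurve)
        with open(out / "curve_correlation.json", "w") as fh:
            json.dump(corr, fh, indent=2)
        results["identity"] = {
            "genetic": gcurve,
            "social": scurve,
            "comparisons": comparisons,
            "correlation": corr,
        }

    with _stage("spatial", manifest):
        dmat = results["genotype"]["distance_matrix"]
        sheet_d = sheet[sheet["isolate_id"].isin(dmat.index)]
        geo = geographic_distance_matrix(sheet_d, geometry)
        ids = list(geo.index)
        mres = mantel_test(
            geo,
            dmat.loc[ids, ids],
            n_perm=int(analysis.get("mantel_permutations", 9999)),
            seed=int(rng.integers(2**31)),
        )
        curve = scale_distance_curve(dmat, sheet_d, geometry=geometry)
        curve.to_frame().to_csv(out / "scale_distance_curve.tsv", sep="\t", index=False)
        spatial_out: dict[str, Any] = {
            "mantel": {"r": mres.r, "p": mres.p, "n_permutations": mres.n_permutations},
            "scale_distance_fit": list(map(float, curve.fit_coefficients)),
        }
        assignment = results["genotype"]["assignment"]
        if len(set(assignment.st_of.values())) >= 2:
            st_ids = {}
            for iso, st in assignment.st_of.items():
                st_ids.setdefault(st, iso)
            reps = [st_ids[st] for st in sorted(st_ids)]
            st_dist = dmat.loc[reps, reps]
            st_dist.index = st_dist.columns = sorted(st_ids)
            conc = nearest_st_concordance(
                st_dist,
                st_site_map(assignment, sheet_d),
                seed=int(rng.integers(2**31)),
            )
            spatial_out["nearest_st_concordance"] = {
                "observed_fraction": conc.observed_fraction,
                "expected_fraction": conc.expected_fraction,
                "p_binomial": conc.p_binomial,
                "p_permutation": conc.p_permutation,
                "n_st": conc.n_st,
            }
        with open(out / "spatial_tests.json", "w") as fh:
            json.dump(spatial_out, fh, indent=2)
        results["spatial"] = spatial_out

    with _stage("report", manifest):
        _write_report(out / "report.txt", results)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return results


def _write_report(path: Path, results: dict) -> None:
    lines = ["myxogeo pipeline report", "=" * 40, ""]
    g = results["genotype"]
    lines.append(f"isolates genotyped: {g['n_isolates']}")
    lines.append(f"sequence types:     {g['n_st']}")
    overall = g["diversity_table"].query("level == 'overall'").iloc[0]
    lines.append(f"overall pi:         {overall['pi']:.4f}")
    lines.append("")
    lines.append("identity-decay curves (pooled probability of identity per scale):")
    header = "  scale        genetic   social"
    lines.append(header)
    ident = results["identity"]
    for scale in SCALES:
        lines.append(
            f"  {scale.label:<12} {ident['genetic'].pooled[scale]:.3f}     "
            f"{ident['social'].pooled[scale]:.3f}"
        )
    corr = ident["correlation"]
    if corr["defined"]:
        lines.append(
            f"curve correlation: Pearson r = {corr['r']:.3f}"
            + (f", permutation p = {corr['p_permutation']:.3f}" if "p_permutation" in corr else "")
        )
    for kind, comp in ident["comparisons"].items():
        if comp.exact_separation:
            lines.append(f"{kind} ANOVA: exact separation (zero within-scale variance)")
        else:
            lines.append(
                f"{kind} ANOVA: F = {comp.f_statistic:.2f}, p = {comp.p_value:.2e}"
            )
    sp = results["spatial"]
    lines.append("")
    lines.append(
        f"Mantel test: r = {sp['mantel']['r']:.3f}, p = {sp['mantel']['p']:.4f} "
        f"({sp['mantel']['n_permutations']} permutations)"
    )
    if "nearest_st_concordance" in sp:
        c = sp["nearest_st_concordance"]
        lines.append(
            "nearest-ST co-site concordance: "
            f"observed {c['observed_fraction']:.2f} vs expected {c['expected_fraction']:.2f} "
            f"(binomial p = {c['p_binomial']:.3g})"
        )
    path.write_text("\n".join(lines) + "\n")
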