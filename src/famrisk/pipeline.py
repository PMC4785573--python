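"""End-to-end pipeline: simulate -> ibd -> filter -> prs -> report.

Each stage reads and writes only standard text formats (PED, VCF, TSV, BED,
JSON) under the configured output directory, so stages can be re-run in
isolation. A manifest records the configuration hash, package versions and
per-stage record counts. All randomness flows from the single ``seed``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .filtering import FilterConfig, filter_variants, write_candidates_tsv
from .ibd import genome_sharing_probability, shared_segments
from .io_formats import (GenePanel, GenotypePanel, Locus, Pedigree,
                         panel_from_variants, read_gene_panel,
                         read_locus_weights, read_pedigree, read_vcf,
                         variants_from_panel, write_bed, write_gene_panel,
                         write_locus_weights, write_vcf)
from .pedigrees import multi_branch_family, nuclear_family, two_branch_family
from .prs import (nagelkerke_r2, risk_score_table, roc_auc,
                  transmission_analysis, wilcoxon_one_sided)
from .synthetic import (FounderModel, build_genetic_map, gene_drop,
                        loci_for_weights, make_locus_table, simulate_controls)

log = logging.getLogger("famrisk")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": None,  # required
    "out_dir": "famrisk_out",
    "simulate": {
        "n_cd": 20, "n_uc": 20, "n_shared": 15, "include_nod2": True,
        "n_controls": 300,
        "chromosomes": [["1", 120_000_000], ["2", 100_000_000],
                        ["3", 80_000_000]],
        "rho_total": 1.8,
        "n_rare_per_family": 3,
    },
    "ibd": {"min_support": 2, "max_conflicts": 0, "max_af": 0.03},
    "filter": {"min_quality": 35.0, "max_af": 0.03, "max_gene_distance": 2},
    "prs": {},
}

_REQUIRED_KEYS = ("seed", "out_dir")


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        user = json.load(fh)
    return validate_config(user)


def validate_config(user: dict[str, Any]) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in user.items():
        if k in ("simulate", "ibd", "filter", "prs") and isinstance(v, dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    for k in _REQUIRED_KEYS:
        if cfg.get(k) is None:
            raise ConfigError(f"config missing required field {k!r}")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("config field 'seed' must be an integer")
    return cfg


def _config_hash(cfg: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Stage: simulate
# ---------------------------------------------------------------------------

def _demo_pedigrees() -> list[Pedigree]:
    """Five-family demo cohort: two deep multi-branch families and three
    nuclear families of varying size."""
    return [
        two_branch_family(family_id="F1"),
        multi_branch_family(family_id="F2"),
        nuclear_family("F3", 2, ["CD", "CD"], father_affection="UC"),
        nuclear_family("F4", 6, ["CD", "unaffected", "CD", "CD", "CD", "CD"]),
        nuclear_family("F5", 3, ["CD", "CD", "CD"]),
    ]


def stage_simulate(cfg: dict[str, Any]) -> dict[str, Any]:
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg["simulate"]
    rng = np.random.default_rng(cfg["seed"])

    weights = make_locus_table(sim["n_cd"], sim["n_uc"], sim["n_shared"],
                               include_nod2=sim["include_nod2"], rng=rng)
    gmap = build_genetic_map([tuple(c) for c in sim["chromosomes"]],
                             sim["rho_total"])
    chrom_names = {c for c, _ in gmap.chromosomes}
    if not all(w.chrom in chrom_names for w in weights):
        # remap off-map loci onto the simulated chromosomes
        remapped = []
        cyc = sorted(chrom_names)
        for i, w in enumerate(weights):
            chrom = cyc[i % len(cyc)]
            remapped.append(type(w)(w.locus_id, chrom,
                                    5_000_000 + 17_000 * i, w.risk_allele,
                                    w.or_cd, w.or_uc))
        weights = remapped
    write_locus_weights(weights, out / "weights.tsv")
    common_loci = loci_for_weights(weights, rng=rng)

    pedigrees = _demo_pedigrees()

    # family-private rare functional variants in panel genes
    genes = {f"GENE{i}": i % 3 for i in range(1, 16)}
    write_gene_panel(GenePanel(genes), out / "panel.tsv")
    gene_names = sorted(genes)
    rare_loci: list[Locus] = []
    injections: dict[str, list[tuple[str, str, int]]] = {}
    annot_gene: dict[str, str] = {}
    annot_csq: dict[str, str] = {}
    k = 0
    for ped in pedigrees:
        injections[ped.family_id] = []
        founders = [f.iid for f in ped.founders()]
        for _ in range(sim["n_rare_per_family"]):
            chrom = sorted(chrom_names)[k % len(chrom_names)]
            lid = f"RARE_{ped.family_id}_{k}"
            rare_loci.append(Locus(lid, chrom, 40_000_000 + 9_000 * k,
                                   "C", "T", float(rng.uniform(0, 0.01))))
            founder = founders[int(rng.integers(len(founders)))]
            injections[ped.family_id].append((lid, founder, 0))
            annot_gene[lid] = gene_names[k % len(gene_names)]
            annot_csq[lid] = "missense"
            k += 1

    all_loci = common_loci + rare_loci
    panels: list[GenotypePanel] = []
    for ped in pedigrees:
        fm = FounderModel(all_loci, injections[ped.family_id])
        res = gene_drop(ped, gmap, fm, rng=rng)
        panel = res.genotypes()
        panel.samples = [f"{ped.family_id}_{s}" for s in panel.samples]
        panels.append(panel)
    cohort = panels[0]
    for p in panels[1:]:
        cohort = cohort.concat(p)

    records = variants_from_panel(cohort, quality=60.0)
    for r in records:
        lid = r.variant_id or ""
        if lid in annot_gene:
            r.gene = annot_gene[lid]
            r.consequence = annot_csq[lid]
    write_vcf(records, out / "cohort.vcf")
    with open(out / "cohort.ped", "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write("\t".join([
                    ped.family_id, f"{ped.family_id}_{m.iid}",
                    f"{ped.family_id}_{m.father}" if m.father else "0",
                    f"{ped.family_id}_{m.mother}" if m.mother else "0",
                    {"male": "1", "female": "2", "unknown": "0"}[m.sex],
                    {"unaffected": "1", "CD": "2", "UC": "3",
                     "unknown": "0"}[m.affection]]) + "\n")

    controls = simulate_controls(sim["n_controls"], all_loci, rng=rng)
    write_vcf(variants_from_panel(controls, quality=60.0),
              out / "controls.vcf")
    log.info("simulate: %d families, %d loci, %d controls",
             len(pedigrees), len(all_loci), sim["n_controls"])
    return {"n_families": len(pedigrees), "n_loci": len(all_loci),
            "n_controls": sim["n_controls"], "n_variants": len(records)}


# ---------------------------------------------------------------------------
# Downstream stages (read their inputs from disk)
# ---------------------------------------------------------------------------

def _require(out: Path, name: str, field: str) -> Path:
    p = out / name
    if not p.exists():
        raise ConfigError(f"missing input for field {field!r}: {p}")
    return p


def _read_cohort(out: Path) -> tuple[list[Pedigree], list]:
    _require(out, "cohort.ped", "pedigree")
    _require(out, "cohort.vcf", "vcf")
    peds = []
    fam_ids = sorted({line.split()[0]
                      for line in (out / "cohort.ped").read_text().splitlines()
                      if line.strip()})
    for fid in fam_ids:
        peds.append(read_pedigree(out / "cohort.ped", family_id=fid))
    variants = read_vcf(out / "cohort.vcf")
    return peds, variants


def stage_ibd(cfg: dict[str, Any]) -> dict[str, Any]:
    out = Path(cfg["out_dir"])
    peds, variants = _read_cohort(out)
    gmap = build_genetic_map(
        [tuple(c) for c in cfg["simulate"]["chromosomes"]],
        cfg["simulate"]["rho_total"])
    icfg = cfg["ibd"]
    segments = []
    probabilities = {}
    for ped in peds:
        targets = ped.affected()
        if len(targets) < 2:
            continue
        try:
            probabilities[ped.family_id] = round(
                genome_sharing_probability(ped, targets, gmap), 6)
        except Exception as exc:  # deep/unconnected: report, don't abort
            probabilities[ped.family_id] = f"unavailable: {exc}"
        segments.extend(shared_segments(
            variants, targets, min_support=icfg["min_support"],
            max_conflicts=icfg["max_conflicts"], max_af=icfg["max_af"]))
    write_bed(segments, out / "segments.bed")
    _write_json(probabilities, out / "sharing_probabilities.json")
    log.info("ibd: %d segments across %d families", len(segments), len(peds))
    return {"n_segments": len(segments), "probabilities": probabilities}


def stage_filter(cfg: dict[str, Any]) -> dict[str, Any]:
    out = Path(cfg["out_dir"])
    peds, variants = _read_cohort(out)
    panel = read_gene_panel(_require(out, "panel.tsv", "panel"))
    fcfg = cfg["filter"]
    calls = []
    for ped in peds:
        affected = ped.affected()
        if not affected:
            continue
        config = FilterConfig(
            required_carriers=frozenset(affected),
            min_quality=fcfg["min_quality"], max_af=fcfg["max_af"],
            max_gene_distance=fcfg["max_gene_distance"])
        fam_variants = [v for v in variants
                        if any(s.startswith(ped.family_id + "_")
                               for s in v.carriers())]
        calls.extend(filter_variants(fam_variants, panel, config, ped))
    write_candidates_tsv(calls, out / "candidates.tsv")
    log.info("filter: %d candidate calls", len(calls))
    return {"n_candidates": len(calls)}


def stage_prs(cfg: dict[str, Any]) -> dict[str, Any]:
    out = Path(cfg["out_dir"])
    peds, variants = _read_cohort(out)
    weights = read_locus_weights(_require(out, "weights.tsv", "weights"))
    fam_panel = panel_from_variants(variants)
    ctrl_panel = panel_from_variants(
        read_vcf(_require(out, "controls.vcf", "controls")))

    fam_scores = risk_score_table(fam_panel, weights)
    ctrl_scores = risk_score_table(ctrl_panel, weights)
    fam_scores.to_csv(out / "scores.tsv", sep="\t")
    ctrl_scores.to_csv(out / "control_scores.tsv", sep="\t")

    report: dict[str, Any] = {}
    for subtype, col in (("CD", "s_cd"), ("UC", "s_uc")):
        # member ids in the combined PED/VCF are already family-prefixed
        case_ids = [i for p in peds for i in p.affected(subtype)]
        cases = fam_scores.loc[[i for i in case_ids
                                if i in fam_scores.index], col]
        ctrl = ctrl_scores[col]
        if len(cases) == 0:
            continue
        scores = np.concatenate([cases.to_numpy(), ctrl.to_numpy()])
        labels = np.concatenate([np.ones(len(cases), int),
                                 np.zeros(len(ctrl), int)])
        report[subtype] = {
            "n_cases": int(len(cases)),
            "mean_cases": round(float(cases.mean()), 6),
            "mean_controls": round(float(ctrl.mean()), 6),
            "wilcoxon_p": round(wilcoxon_one_sided(cases, ctrl), 6),
            "auc": round(roc_auc(scores, labels), 6),
            "nagelkerke_r2": round(nagelkerke_r2(scores, labels), 6),
        }

    transmission = {}
    for ped in peds:
        scoped = fam_scores["s_cd"]
        scoped = scoped[[i for i in scoped.index if i in ped]]
        try:
            records, p, n_excl = transmission_analysis(ped, scoped)
            transmission[ped.family_id] = {
                "mean_ratio": round(float(np.mean([r.ratio for r in records])), 6),
                "n_offspring": len(records), "t_test_p":
                    None if np.isnan(p) else round(p, 6),
                "n_excluded": n_excl,
            }
        except Exception:
            transmission[ped.family_id] = None
    report["transmission"] = transmission

    # per-family summary
    rows = {}
    for ped in peds:
        aff = [i for i in ped.affected() if i in fam_scores.index]
        rows[ped.family_id] = {
            "mean_cd": round(float(fam_scores.loc[aff, "s_cd"].mean()), 6),
            "mean_uc": round(float(fam_scores.loc[aff, "s_uc"].mean()), 6),
            "low": bool(
                fam_scores.loc[aff, "s_cd"].mean() < ctrl_scores["s_cd"].mean()
                and fam_scores.loc[aff, "s_uc"].mean() < ctrl_scores["s_uc"].mean()),
        }
    report["families"] = rows
    _write_json(report, out / "prs_report.json")
    log.info("prs: scored %d family members, %d controls",
             len(fam_scores), len(ctrl_scores))
    return {"n_scored": int(len(fam_scores)), "report": report}


def stage_report(cfg: dict[str, Any], counts: dict[str, Any]) -> dict[str, Any]:
    out = Path(cfg["out_dir"])
    manifest = {
        "config_hash": _config_hash(cfg),
        "famrisk_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "stage_counts": counts,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def run_pipeline(cfg: dict[str, Any]) -> dict[str, Any]:
    """Run every stage in order; any stage error aborts with its name."""
    cfg = validate_config(cfg)
    counts: dict[str, Any] = {}
    for name, fn in (("simulate", stage_simulate), ("ibd", stage_ibd),
                     ("filter", stage_filter), ("prs", stage_prs)):
        try:
            result = fn(cfg)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"stage {name} failed: {exc}") from exc
        counts[name] = {k: v for k, v in result.items()
                        if isinstance(v, (int, float))}
    manifest = stage_report(cfg, counts)
    return manifest
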