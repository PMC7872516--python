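"""End-to-end orchestration: simulate -> score -> transform -> associate ->
mediate -> genetic scores -> report, with a reproducibility manifest.

Each stage is a thin call into the corresponding module; all outputs are
tidy TSV/JSON files so runs are diffable and re-runs with the same config
and seed are identical.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations as assoc
from . import genetics, lifestyle, mediation, metabolites, simulate

_CONFIG_FIELDS = {
    "seed",
    "n_source",
    "hlf_mode",
    "exposure_contrast",
    "interaction",
    "fdr_level",
    "r2_threshold",
    "p_stop",
    "n_pcs",
    "pc_variance_floor",
}


@dataclass
class RunConfig:
    seed: int = 0
    n_source: int = 80_000
    hlf_mode: str = "standard"  # standard | strict_adiposity | drop_alcohol
    exposure_contrast: float = 1.0
    interaction: str = "auto"  # auto | on | off
    fdr_level: float = 0.05
    r2_threshold: float = 0.3
    p_stop: float = 0.05
    n_pcs: int = 5
    pc_variance_floor: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError(f"fdr_level {self.fdr_level} outside (0, 1)")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError(f"r2_threshold {self.r2_threshold} outside (0, 1]")
        if not 0 < self.p_stop < 1:
            raise ValueError(f"p_stop {self.p_stop} outside (0, 1)")
        if self.hlf_mode not in ("standard", "strict_adiposity", "drop_alcohol"):
            raise ValueError(f"unknown hlf_mode {self.hlf_mode!r}")
        if self.interaction not in ("auto", "on", "off"):
            raise ValueError(f"unknown interaction policy {self.interaction!r}")
        if self.exposure_contrast == 0:
            raise ValueError("exposure_contrast must be nonzero")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


MEDIATION_TERMS = ("age", "sex", "fasting", "area", "education")
HLF_MET_TERMS = MEDIATION_TERMS + ("case_status",)
MET_CHD_TERMS = MEDIATION_TERMS + ("smoking",)
SCORE_TERMS = ("age", "sex", "area", "ancestry_pcs")


def run_full_analysis(config: RunConfig, study: simulate.StudyData | None = None) -> dict:
    """Execute every stage on a simulated study; returns the result bundle.

    ``study`` may be supplied to reuse an existing simulation (the stages
    after generation are deterministic functions of it).
    """
    if study is None:
        _log("simulate", f"source cohort n={config.n_source}, seed={config.seed}")
        params = simulate.default_params(n_source=config.n_source, seed=config.seed)
        study = simulate.simulate_study(params)
    data = study.analysis.copy()
    _log("simulate", f"analysis set n={len(data)} "
         f"({(data['status'] == 'chd_case').sum()} CHD cases, "
         f"{(data['status'] == 'control').sum()} controls)")

    # lifestyle scoring
    mode = {"standard": None, "strict_adiposity": "strict_adiposity", "drop_alcohol": "drop_alcohol"}[
        config.hlf_mode
    ]
    thresholds = study.activity_thresholds  # source-cohort sex-specific medians
    profile = (
        lifestyle.classify_hlf(data, activity_thresholds=thresholds)
        if mode is None
        else lifestyle.hlf_sensitivity_variants(data, mode, activity_thresholds=thresholds)
    )
    data = pd.concat([data, profile], axis=1)
    _log("score-lifestyle", f"mean HLF count {profile['hlf_count'].mean():.2f}")

    # metabolite preparation
    panel = list(study.metabolites_raw.columns)
    transformed = metabolites.transform_matrix(study.metabolites_raw)
    pc_scores, pc_var = metabolites.top_principal_components(
        transformed, k=config.n_pcs, variance_floor=config.pc_variance_floor
    )
    data = pd.concat([data, transformed, pc_scores], axis=1)
    _log("transform", f"{len(panel)} markers transformed; "
         f"top {config.n_pcs} PCs explain {pc_var.sum():.1%}")

    # association layer 1: HLFs -> metabolites
    cov1 = assoc.design_matrix(data, HLF_MET_TERMS)
    res1 = []
    for m in panel:
        res1.extend(assoc.fit_hlf_metabolite(data[m], data["hlf_group"], cov1, marker=m))
    for contrast in {r.contrast for r in res1}:
        assoc.attach_fdr([r for r in res1 if r.contrast == contrast])
    hlf_met = assoc.results_to_frame(res1)
    n_sig1 = int(
        (hlf_met.loc[hlf_met.contrast.str.startswith("4-5"), "p_fdr"] < config.fdr_level).sum()
    )
    _log("associate", f"HLF->marker: {n_sig1} markers FDR<{config.fdr_level} at 4-5 vs 0-1")

    # association layer 2: metabolites -> CHD (stroke cases excluded)
    cc = data[data["status"].isin(["control", "chd_case"])]
    cov2 = assoc.design_matrix(cc, MET_CHD_TERMS)
    res2 = [assoc.fit_metabolite_chd(cc["status"], cc[m], cov2, marker=m) for m in panel]
    assoc.attach_fdr(res2)
    met_chd = assoc.results_to_frame(res2)
    _log("associate", f"marker->CHD: {(met_chd.p_fdr < config.fdr_level).sum()} markers FDR-significant")

    # mediation
    cov3 = assoc.design_matrix(cc, MEDIATION_TERMS)
    a_star = float(cc["hlf_count"].mean())
    med_results = []
    for m in panel:
        med_results.append(
            mediation.mediate_one(
                cc, m, "hlf_count", cov3,
                a=a_star + config.exposure_contrast, a_star=a_star,
                interaction=config.interaction,
            )
        )
    for r, q in zip(med_results, assoc.bh_fdr([r.p_nie for r in med_results])):
        r.p_fdr = float(q)
    med_frame = mediation.results_to_frame(med_results)
    joint = mediation.joint_mediation_via_pcs(
        cc, list(pc_scores.columns), "hlf_count", cov3,
        a=a_star + config.exposure_contrast, a_star=a_star,
    )
    _log("mediate", f"{(med_frame.p_fdr < config.fdr_level).sum()} markers with FDR-significant NIE; "
         f"joint PC-mediated proportion {100 * joint['joint_pm']:.2f}%")

    # genetic scores: select on the disjoint selection cohort, apply to analysis set
    sel = study.selection
    sel_cov = assoc.design_matrix(sel, ("age", "sex", "ancestry_pcs"))
    scores: dict[str, genetics.GeneticScore] = {}
    for window in study.variant_meta["gene_window"].unique():
        sc = genetics.conditional_select_variants(
            study.dosages_selection, study.variant_meta, sel["ldlc"], sel_cov,
            gene_window=window, r2_threshold=config.r2_threshold, p_stop=config.p_stop,
        )
        if sc.variants:
            genetics.build_score(study.dosages_analysis, study.variant_meta, sc)
            scores[window] = sc
            _log("genetic-score", f"{window}: {len(sc.variants)} variants selected")
    if len(scores) >= 2:
        a, b = list(scores.values())[:2]
        scores["combined"] = genetics.sum_scores(a, b)

    cov4 = assoc.design_matrix(data, SCORE_TERMS)
    score_assoc = []
    for gene, sc in scores.items():
        for m in panel:
            r = genetics.score_association(sc.standardized_scores, data[m], cov4, marker=m)
            r.contrast = f"{gene}: {r.contrast}"
            score_assoc.append(r)
    if score_assoc:
        assoc.attach_fdr(score_assoc)
    score_frame = assoc.results_to_frame(score_assoc) if score_assoc else pd.DataFrame()

    # joint 4-group analysis and HLF-score interaction for headline markers
    joint_rows, strat_rows = [], []
    if scores:
        first = next(iter(scores.values()))
        group = genetics.median_risk_group(first.standardized_scores)
        cov5 = assoc.design_matrix(data, HLF_MET_TERMS + ("ancestry_pcs",))
        for m in ("VLDL-C", "LDL-C", "HDL-C"):
            if m not in panel:
                continue
            joint_rows.extend(
                assoc.joint_group_analysis(data[m], data["hlf_group2"], group, cov5, marker=m)
            )
            strat = genetics.stratified_hlf_analysis(
                data[m], data["hlf_count"], first.standardized_scores, cov5, marker=m
            )
            for level, r in strat["strata"].items():
                row = vars(r).copy()
                row["p_interaction"] = strat["p_interaction"]
                strat_rows.append(row)

    bundle = {
        "config": config,
        "profile": profile,
        "hlf_metabolite": hlf_met,
        "metabolite_chd": met_chd,
        "mediation": med_frame,
        "joint_pc_mediation": joint,
        "pc_variance_explained": pc_var,
        "scores": scores,
        "score_metabolite": score_frame,
        "joint_group": assoc.results_to_frame(joint_rows) if joint_rows else pd.DataFrame(),
        "stratified": pd.DataFrame(strat_rows) if strat_rows else pd.DataFrame(),
        "truth": study.truth,
    }
    return bundle


def write_bundle(bundle: dict, out_dir: str | Path) -> Path:
    """Write all result tables plus the reproducibility manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = bundle["config"]
    tables = {
        "hlf_profile.tsv": bundle["profile"],
        "hlf_metabolite_associations.tsv": bundle["hlf_metabolite"],
        "metabolite_chd_associations.tsv": bundle["metabolite_chd"],
        "mediation_results.tsv": bundle["mediation"],
        "score_metabolite_associations.tsv": bundle["score_metabolite"],
        "joint_group_analysis.tsv": bundle["joint_group"],
        "stratified_hlf_analysis.tsv": bundle["stratified"],
    }
    for name, tab in tables.items():
        if isinstance(tab, pd.DataFrame) and len(tab):
            tab.to_csv(out / name, sep="\t", index=bool(tab.index.name))
    (out / "joint_pc_mediation.json").write_text(
        json.dumps({k: v for k, v in bundle["joint_pc_mediation"].items()}, indent=2, default=float)
    )
    for gene, sc in bundle["scores"].items():
        (out / f"genetic_score_{gene}.json").write_text(sc.to_json())
    (out / "simulation_truth.json").write_text(bundle["truth"].to_json())
    cfg = asdict(config)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "tables": sorted(n for n, t in tables.items() if isinstance(t, pd.DataFrame) and len(t)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def report(bundle: dict) -> str:
    """Human-readable run summary: top mediators, significant-marker counts,
    joint-group contrasts."""
    cfg = bundle["config"]
    med = bundle["mediation"]
    lines = ["== lipidomic mediation analysis summary =="]
    lines.append(f"markers analysed: {len(med)}")
    sig = med[med["p_fdr"] < cfg.fdr_level].copy()
    lines.append(f"markers with FDR<{cfg.fdr_level} mediation: {len(sig)}")
    if len(sig):
        sig = sig.sort_values("pm_pct", ascending=False, kind="stable")
        lines.append("top mediators by proportion mediated:")
        for _, r in sig.head(10).iterrows():
            lines.append(
                f"  {r['marker']:<14s} pm = {r['pm_pct']:6.2f}%  "
                f"NIE = {r['nie']:+.4f} (p_fdr = {r['p_fdr']:.3g})"
            )
    else:
        lines.append("no markers reached FDR significance")
    joint = bundle["joint_pc_mediation"]
    lines.append(f"joint mediation via top PCs: {100 * joint['joint_pm']:.2f}% of the total effect")
    if len(bundle["joint_group"]):
        lines.append("joint genetic-score x HLF groups (selected markers):")
        for _, r in bundle["joint_group"].iterrows():
            lines.append(f"  {r['marker']:<8s} {r['contrast']}: {r['estimate']:+.3f}")
    return "\n".join(lines)


def hlf_distribution_summary(counts_by_hlf: dict[int | str, int]) -> dict[str, float]:
    """Percentages of participants with >=3 and >=4 HLFs from a count table.

    Accepts keys that are integers or labels like ">=4" for a top category.
    Percentages are rounded to one decimal, matching tabulated reporting.
    """

    def level(key) -> int:
        if isinstance(key, int):
            return key
        return int(str(key).lstrip(">=≥"))

    total = sum(counts_by_hlf.values())
    ge3 = sum(v for k, v in counts_by_hlf.items() if level(k) >= 3)
    ge4 = sum(v for k, v in counts_by_hlf.items() if level(k) >= 4)
    return {
        "n_total": float(total),
        "pct_ge3": round(100.0 * ge3 / total, 1),
        "pct_ge4": round(100.0 * ge4 / total, 1),
    }
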