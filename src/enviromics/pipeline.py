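"""End-to-end orchestration: synthetic generation -> quantification ->
statistics for all three assays, from a single serializable config.

Every numeric constant with a study-defined value defaults to that value
(5 ppm, 7.5 s apex tolerance, 30 s search window, S/N 3x, floor 10,000,
alpha 0.05). Identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from enviromics import metabostats, protstats
from enviromics import cytometry as cyto
from enviromics.design import StudyDesign
from enviromics.msio import write_mzml, read_mzml
from enviromics.quant import ExtractionConfig, build_matrix, write_matrix
from enviromics.synthetic import presets
from enviromics.synthetic.cytometry import gen_damage_events, gen_dna_content_events, gen_unstained_events
from enviromics.synthetic.metabolome import gen_metabolome_runs
from enviromics.synthetic.proteome import gen_protein_matrix, write_protein_matrix

log = logging.getLogger("enviromics.pipeline")

QUADRANT_STATS = ("parp_pct", "double_pos_pct", "h2ax_pct")


@dataclass
class DetectionConfig:
    sn_multiple: float = 3.0
    floor: float = 10_000.0


@dataclass
class ProteomeConfig:
    donors_per_group: int = 4
    n_proteins: int = 600
    n_affected: int = 40
    effect_sd: float = 0.5
    noise_cv: float = 0.05
    missing_rate: float = 0.01


@dataclass
class CytometryConfig:
    samples_per_group: int = 5
    dna_events: int = 20_000
    damage_events: int = 20_000
    dna_cv: float = 0.05
    bins: int = 256
    gate_quantile: float = 0.999


@dataclass
class PipelineConfig:
    """Single config covering design, tolerances and all stage constants."""

    design: StudyDesign = field(default_factory=lambda: presets.default_design())
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    proteome: ProteomeConfig = field(default_factory=ProteomeConfig)
    cytometry: CytometryConfig = field(default_factory=CytometryConfig)
    alpha: float = 0.05
    posthoc: str = "dunnett"  # or 'holm-t'
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["design"].pop("control", None)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        design = payload.get("design", {})
        if "groups" in design:
            design["groups"] = tuple(design["groups"])
        return cls(
            design=StudyDesign(**design),
            extraction=ExtractionConfig(**payload.get("extraction", {})),
            detection=DetectionConfig(**payload.get("detection", {})),
            proteome=ProteomeConfig(**payload.get("proteome", {})),
            cytometry=CytometryConfig(**payload.get("cytometry", {})),
            alpha=payload.get("alpha", 0.05),
            posthoc=payload.get("posthoc", "dunnett"),
            seed=payload.get("seed", 0),
        )


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of human-readable invariant violations (empty = ok)."""
    violations: list[str] = []
    if not (0.0 < config.alpha < 1.0):
        violations.append(f"alpha must lie in (0, 1), got {config.alpha}")
    e = config.extraction
    if e.apex_tol > e.search_window:
        violations.append("apex_tol exceeds search_window")
    if e.ppm_tol <= 0:
        violations.append("ppm_tol must be positive")
    if config.detection.sn_multiple <= 0:
        violations.append("sn_multiple must be positive")
    if config.detection.floor < 0:
        violations.append("floor must be non-negative")
    if config.posthoc not in ("dunnett", "holm-t"):
        violations.append(f"unknown posthoc {config.posthoc!r}")
    c = config.cytometry
    if not (0.0 < c.gate_quantile <= 1.0):
        violations.append("gate_quantile must lie in (0, 1]")
    if c.dna_events < 1000 or c.damage_events < 1000:
        violations.append("cytometry event counts must be >= 1000")
    try:
        asdict(config)  # serialization round-trip must be possible
    except Exception as exc:  # pragma: no cover
        violations.append(f"config not serializable: {exc}")
    return violations


def _fingerprint(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _float_fmt(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format="%.10g", **kw)


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute generate -> quantify -> metabostats; protstats; cyto.

    Returns the run report (also written to ``report.json``): per-stage
    output paths, counts, QC summaries and a fingerprint over all written
    artifacts.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(out_dir)
    written: list[Path] = []

    # ----- metabolome ------------------------------------------------
    log.info("stage=metabolome seed=%d", config.seed)
    met_dir = out / "metabolome"
    mzml_dir = met_dir / "mzml"
    mzml_dir.mkdir(parents=True, exist_ok=True)
    design = dataclasses.replace(config.design, seed=config.seed)
    truths = presets.default_metabolite_truths()
    runs, truth = gen_metabolome_runs(
        design, truths, floor=config.detection.floor
    )
    for run in runs:
        p = mzml_dir / f"{run.sample_id}.mzML"
        write_mzml(run, p)
        written.append(p)
    _float_fmt(truth, met_dir / "ground_truth.csv", index=False)
    written.append(met_dir / "ground_truth.csv")

    matrix = build_matrix(runs, [t.entry for t in truths], config.extraction)
    write_matrix(matrix, met_dir / "matrix.tsv", met_dir / "samples.csv")
    written += [met_dir / "matrix.tsv", met_dir / "samples.csv"]

    thresholds = metabostats.compute_thresholds(
        matrix, config.detection.sn_multiple, config.detection.floor
    )
    corrected = metabostats.apply_detection(matrix, thresholds)
    corrected.provenance().to_csv(met_dir / "detection_mask.tsv", sep="\t")
    written.append(met_dir / "detection_mask.tsv")

    all_results = []
    for g in design.groups:
        if g == design.control:
            continue
        all_results += metabostats.differential(
            corrected, g, design.control, config.alpha
        )
    diff_df = metabostats.results_frame(all_results)
    _float_fmt(diff_df, met_dir / "differential.csv", index=False)
    volcano = metabostats.volcano_table(all_results)
    _float_fmt(volcano, met_dir / "volcano.csv", index=False)
    row_order, col_order = metabostats.cluster_order(corrected)
    (met_dir / "cluster_order.json").write_text(
        json.dumps({"rows": row_order, "columns": col_order}, indent=1)
    )
    written += [met_dir / "differential.csv", met_dir / "volcano.csv",
                met_dir / "cluster_order.json"]

    n_detected = int(corrected.detected.any(axis=1).sum())
    met_sig = int(diff_df["significant"].sum())

    # ----- proteome --------------------------------------------------
    log.info("stage=proteome seed=%d", config.seed)
    prot_dir = out / "proteome"
    prot_dir.mkdir(parents=True, exist_ok=True)
    pdesign = StudyDesign(
        groups=config.design.groups,
        donors_per_group=config.proteome.donors_per_group,
        blanks=0,
        seed=config.seed,
    )
    pmat, pgroups, pdonors, ptruth = gen_protein_matrix(
        pdesign,
        n_proteins=config.proteome.n_proteins,
        n_affected=config.proteome.n_affected,
        effect_sd=config.proteome.effect_sd,
        noise_cv=config.proteome.noise_cv,
        missing_rate=config.proteome.missing_rate,
    )
    write_protein_matrix(pmat, pgroups, pdonors,
                         prot_dir / "matrix.tsv", prot_dir / "samples.csv")
    _float_fmt(ptruth, prot_dir / "truth.csv", index=False)
    written += [prot_dir / "matrix.tsv", prot_dir / "samples.csv",
                prot_dir / "truth.csv"]

    pm = protstats.ProteinMatrix(pmat, pgroups, pdonors)
    complete = protstats.complete_case_filter(pm)
    normalized = protstats.log2_quantile_normalize(complete)
    _float_fmt(normalized, prot_dir / "normalized.tsv", sep="\t",
               index_label="accession")
    written.append(prot_dir / "normalized.tsv")

    qc = protstats.qc_report(complete)
    (prot_dir / "qc.json").write_text(
        json.dumps(qc.to_dict(), indent=1, sort_keys=True, default=float)
    )
    written.append(prot_dir / "qc.json")

    anova = protstats.anova_posthoc(
        normalized, pgroups, pdesign.control, config.alpha,
        random_state=config.seed,
    )
    _float_fmt(anova, prot_dir / "anova.csv")
    counts = protstats.differential_counts(
        normalized, pgroups, pdesign.control, config.alpha
    )
    counts.to_csv(prot_dir / "pairwise_counts.csv", header=["n_called"],
                  index_label="group")
    written += [prot_dir / "anova.csv", prot_dir / "pairwise_counts.csv"]

    # ----- cytometry -------------------------------------------------
    log.info("stage=cytometry seed=%d", config.seed)
    cyto_dir = out / "cytometry"
    cyto_dir.mkdir(parents=True, exist_ok=True)
    cc = config.cytometry
    frac_rows = []
    pct_rows = []
    for gi, group in enumerate(config.design.groups):
        for si in range(cc.samples_per_group):
            rng = np.random.default_rng([config.seed, 101, gi, si])
            dna = gen_dna_content_events(
                presets.dna_truth(group, cc.dna_events, cc.dna_cv), rng=rng
            )
            fit = cyto.fit_dna_content(dna, bins=cc.bins)
            frac_rows.append(
                dict(group=group, sample=f"{group}_s{si + 1}",
                     sub_g1=fit.sub_g1, g1=fit.g1, s=fit.s, g2m=fit.g2m,
                     residual=fit.residual)
            )
            rng2 = np.random.default_rng([config.seed, 202, gi, si])
            dmg = gen_damage_events(
                presets.damage_truth(group, cc.damage_events), rng=rng2
            )
            unstained = gen_unstained_events(
                rng=np.random.default_rng([config.seed, 303, gi, si])
            )
            gates = cyto.derive_thresholds(unstained, cc.gate_quantile)
            q = cyto.quadrant_gate(dmg, gates)
            pct_rows.append(
                dict(group=group, sample=f"{group}_s{si + 1}",
                     parp_pct=q.parp_positive_pct,
                     double_pos_pct=q.percentages["double_pos"],
                     h2ax_pct=q.h2ax_positive_pct)
            )
    fractions = pd.DataFrame(frac_rows)
    _float_fmt(fractions, cyto_dir / "dna_fractions.csv", index=False)
    pct = pd.DataFrame(pct_rows)
    _float_fmt(pct, cyto_dir / "quadrant_percentages.csv", index=False)
    folds = cyto.fold_change_vs_control(
        pct.drop(columns="sample"), config.design.control, config.alpha,
        random_state=config.seed,
    )
    _float_fmt(folds, cyto_dir / "fold_changes.csv", index=False)
    written += [cyto_dir / "dna_fractions.csv",
                cyto_dir / "quadrant_percentages.csv",
                cyto_dir / "fold_changes.csv"]

    report = {
        "config": {"seed": config.seed, "alpha": config.alpha,
                   "groups": list(config.design.groups)},
        "metabolome": {
            "n_runs": len(runs),
            "n_analytes": int(matrix.heights.shape[0]),
            "n_detected_analytes": n_detected,
            "n_significant_calls": met_sig,
            "outputs": sorted(str(p.relative_to(out)) for p in written
                              if "metabolome" in str(p)),
        },
        "proteome": {
            "n_proteins": int(pmat.shape[0]),
            "n_complete_case": int(complete.intensities.shape[0]),
            "pairwise_calls": {k: int(v) for k, v in counts.items()},
            "median_cv": {k: float(v) for k, v in qc.group_median_cv.items()},
            "outputs": sorted(str(p.relative_to(out)) for p in written
                              if "proteome" in str(p)),
        },
        "cytometry": {
            "n_samples": len(frac_rows),
            "outputs": sorted(str(p.relative_to(out)) for p in written
                              if "cytometry" in str(p)),
        },
        "fingerprint": _fingerprint(written),
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True)
    )
    return report
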