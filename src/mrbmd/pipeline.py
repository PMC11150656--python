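"""End-to-end MR study orchestration.

For every exposure taxon x outcome site, the pipeline runs the fixed stage
order: p-value screen -> LD clumping -> harmonization (palindromic SNPs
dropped there) -> weak-instrument (F) filter -> MR-PRESSO outlier removal ->
Egger pleiotropy screen (-> confounder-SNP exclusion and rerun) -> causal
estimation (Wald ratio with one instrument, IVW otherwise, plus the
secondary estimators when enough instruments exist) -> heterogeneity Q ->
leave-one-out with sign-flip exclusion-and-rerun -> Steiger directionality
filter -> per-level Bonferroni correction.

Every SNP that enters a pair's analysis is accounted for exactly once in
the audit trail: kept, or dropped with a single reason.  All randomness is
seeded through the config, so a rerun with the same config reproduces all
output files byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .correction import apply_bonferroni, assemble_results, bonferroni_thresholds
from .estimators import (MREstimate, ivw, mr_egger, wald_ratio,
                         weighted_median, weighted_mode)
from .exceptions import ConfigurationError
from .harmonize import HarmonizedPair, harmonize_dataset
from .instruments import (ClumpConfig, clump, load_confounder_table,
                          screen_by_pvalue)
from .sensitivity import (SensitivityReport, cochran_q, leave_one_out,
                          mr_presso, pleiotropy_screen, steiger_test)
from .summary_io import (ResultRow, TaxonMeta, parse_taxon_label,
                         read_summary_stats, write_results_table)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one study run needs; loadable from YAML."""

    exposures: dict[str, str]  # taxon label -> summary-stats path
    outcomes: dict[str, str]   # outcome label -> summary-stats path
    output_dir: str
    iv_threshold: float = 5e-6
    clump_r2: float = 0.01
    clump_window_kb: int = 10_000
    f_min: float = 10.0
    presso_n_sim: int = 1000
    presso_sig_level: float = 0.05
    presso_seed: int = 7001
    bootstrap_n: int = 1000
    bootstrap_seed: int = 7002
    ivw_model: str = "multiplicative_random"
    confounder_file: Optional[str] = None
    drop_palindromic: bool = True
    run_secondary_estimators: bool = True
    min_presso_k: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} is not a mapping")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def __post_init__(self):
        if not self.exposures or not self.outcomes:
            raise ConfigurationError("need at least one exposure and one outcome")
        if not 0 < self.iv_threshold < 1:
            raise ConfigurationError(f"iv_threshold must be in (0,1): {self.iv_threshold}")


@dataclass
class PairAnalysis:
    """Audit record for one exposure-outcome analysis."""

    exposure: str
    outcome: str
    status: str  # "ok" | "no_instruments" | "steiger_failed"
    n_input_snps: int = 0
    snp_fates: dict = field(default_factory=dict)  # snp_id -> "kept" or reason
    estimate: Optional[MREstimate] = None
    secondary: dict = field(default_factory=dict)  # method -> MREstimate
    report: SensitivityReport = field(default_factory=SensitivityReport)


@dataclass
class StudyReport:
    rows: list[ResultRow]
    analyses: list[PairAnalysis]
    thresholds: Mapping


def _record_fates(fates: dict, snps: Sequence[str], reason: str) -> None:
    for s in snps:
        fates.setdefault(s, reason)


def analyze_pair(
    exposure_label: str,
    exposure_records,
    outcome_label: str,
    outcome_records,
    cfg: RunConfig,
    confounders: Optional[Mapping[str, str]] = None,
) -> PairAnalysis:
    """Run the full stage order for one exposure-outcome pair."""
    pa = PairAnalysis(exposure=exposure_label, outcome=outcome_label, status="ok")
    fates = pa.snp_fates
    pa.n_input_snps = len(exposure_records)

    # 1. p-value screen
    screened = screen_by_pvalue(exposure_records, cfg.iv_threshold)
    _record_fates(fates, [r.snp_id for r in exposure_records
                          if r not in screened], "pvalue_screen")

    # 2. greedy clumping (distance-only unless an LD lookup is configured)
    clumped = clump(screened, ClumpConfig(r2_max=cfg.clump_r2,
                                          window_kb=cfg.clump_window_kb))
    _record_fates(fates, [r.snp_id for r in screened if r not in clumped], "clumped")

    # 3. harmonize (palindromes and allele mismatches drop here)
    pairs, drop_report = harmonize_dataset(clumped, outcome_records,
                                           drop_palindromic=cfg.drop_palindromic)
    for snp, reason in drop_report.dropped:
        fates.setdefault(snp, reason)

    # 4. weak-instrument filter on the exposure side
    strong: list[HarmonizedPair] = []
    for p in pairs:
        f = (p.beta_exp / p.se_exp) ** 2
        if f < cfg.f_min:
            fates.setdefault(p.snp_id, "weak_instrument")
        else:
            strong.append(p)
    pairs = strong

    # 5. MR-PRESSO outlier removal (needs k >= 4)
    if len(pairs) >= cfg.min_presso_k:
        presso = mr_presso(pairs, n_sim=cfg.presso_n_sim,
                           seed=cfg.presso_seed,
                           sig_level=cfg.presso_sig_level)
        pa.report.presso = presso
        if presso.outlier_indices:
            pairs = [p for p in pairs if p.snp_id not in presso.outlier_indices]
            for snp in presso.outlier_indices:
                fates.setdefault(snp, "presso_outlier")

    # 6. Egger pleiotropy screen; on detection, exclude confounder SNPs and rerun
    if len(pairs) >= 3:
        intercept, detected = pleiotropy_screen(pairs)
        pa.report.egger_intercept = intercept
        pa.report.pleiotropy_detected = detected
        if detected and confounders:
            confounded = {p.snp_id for p in pairs} & set(confounders)
            if confounded:
                keep_ids = {p.snp_id for p in pairs} - confounded
                pairs = [p for p in pairs if p.snp_id in keep_ids]
                for snp in confounded:
                    fates.setdefault(snp, "confounder")
                if len(pairs) >= 3:
                    intercept, detected = pleiotropy_screen(pairs)
                    pa.report.egger_intercept = intercept
                    pa.report.pleiotropy_detected = detected

    if not pairs:
        pa.status = "no_instruments"
        return pa

    def primary(ps: Sequence[HarmonizedPair]) -> MREstimate:
        return wald_ratio(ps[0]) if len(ps) == 1 else ivw(ps, model=cfg.ivw_model)

    pa.estimate = primary(pairs)

    # 7. heterogeneity Q (warn, do not halt)
    if len(pairs) >= 2:
        q = cochran_q(pairs)
        pa.report.q = q
        if q.heterogeneous:
            logger.warning("%s/%s: heterogeneity Q p = %.3g <= 0.05",
                           exposure_label, outcome_label, q.pval)

    # 8. leave-one-out; sign-flipping SNPs are excluded and the MR rerun
    if len(pairs) >= 2:
        loo = leave_one_out(pairs, model=cfg.ivw_model)
        pa.report.loo = loo
        flagged = {r.omitted_snp for r in loo if r.sign_flip}
        if flagged and len(pairs) - len(flagged) >= 1:
            pairs = [p for p in pairs if p.snp_id not in flagged]
            for snp in flagged:
                fates.setdefault(snp, "loo_sign_flip")
            pa.estimate = primary(pairs)
            pa.report.q = cochran_q(pairs) if len(pairs) >= 2 else None
            pa.report.loo = leave_one_out(pairs, model=cfg.ivw_model) if len(pairs) >= 2 else []

    # 9. secondary estimators for k >= 3
    if cfg.run_secondary_estimators and len(pairs) >= 3:
        slope, _ = mr_egger(pairs)
        pa.secondary["egger"] = slope
        pa.secondary["weighted_median"] = weighted_median(
            pairs, n_boot=cfg.bootstrap_n, seed=cfg.bootstrap_seed)
        pa.secondary["weighted_mode"] = weighted_mode(
            pairs, n_boot=cfg.bootstrap_n, seed=cfg.bootstrap_seed)

    # 10. Steiger directionality
    pa.report.steiger = steiger_test(pairs)
    if not pa.report.steiger.correct_direction:
        pa.status = "steiger_failed"

    for p in pairs:
        fates.setdefault(p.snp_id, "kept")
    return pa


def run_mr_study(cfg: RunConfig) -> StudyReport:
    """Execute the study over all exposure-outcome pairs and write outputs.

    Emits, under ``cfg.output_dir``: one result table per outcome, a
    sensitivity table, a per-SNP audit table, and a machine-readable run
    manifest.  Byte-identical across reruns with the same config.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    confounders = (load_confounder_table(cfg.confounder_file)
                   if cfg.confounder_file else None)
    outcome_data = {label: read_summary_stats(path)
                    for label, path in cfg.outcomes.items()}

    analyses: list[PairAnalysis] = []
    taxa: dict[str, TaxonMeta] = {}
    for exp_label, exp_path in cfg.exposures.items():
        taxa[exp_label] = parse_taxon_label(exp_label)
        exp_records = read_summary_stats(exp_path)
        for out_label, out_records in outcome_data.items():
            pa = analyze_pair(exp_label, exp_records, out_label,
                              out_records, cfg, confounders)
            if pa.status == "no_instruments":
                logger.info("%s/%s skipped: no_instruments", exp_label, out_label)
            analyses.append(pa)

    # Bonferroni n = number of taxa analyzed (with instruments) per level
    level_counts: dict[str, set] = {}
    for pa in analyses:
        if pa.estimate is not None:
            meta = taxa[pa.exposure]
            level_counts.setdefault(meta.level, set()).add(meta.taxon_id)
    thresholds = (bonferroni_thresholds({k: len(v) for k, v in level_counts.items()})
                  if level_counts else bonferroni_thresholds({"genus": 1}))

    estimates = {(pa.exposure, pa.outcome): pa.estimate
                 for pa in analyses if pa.estimate is not None}
    reports = {(pa.exposure, pa.outcome): pa.report
               for pa in analyses if pa.estimate is not None}
    rows = assemble_results(estimates, reports, taxa)
    rows = apply_bonferroni(rows, thresholds)

    for out_label in cfg.outcomes:
        sub = [r for r in rows if r.outcome == out_label]
        if sub:
            write_results_table(sub, out_dir / f"results.{out_label}.tsv")

    _write_sensitivity_table(analyses, out_dir / "sensitivity.tsv")
    _write_audit(analyses, out_dir / "audit.tsv")
    _write_manifest(cfg, thresholds, rows, out_dir / "manifest.json")
    return StudyReport(rows=rows, analyses=analyses,
                       thresholds=thresholds.by_level)


def _write_sensitivity_table(analyses: Sequence[PairAnalysis], path: Path) -> None:
    recs = []
    for pa in analyses:
        rep = pa.report
        recs.append({
            "exposure": pa.exposure, "outcome": pa.outcome, "status": pa.status,
            "q": f"{rep.q.q:.6g}" if rep.q else "NA",
            "q_df": rep.q.df if rep.q else "NA",
            "q_pval": f"{rep.q.pval:.6g}" if rep.q else "NA",
            "egger_intercept": f"{rep.egger_intercept.intercept:.6g}" if rep.egger_intercept else "NA",
            "egger_intercept_pval": f"{rep.egger_intercept.pval:.6g}" if rep.egger_intercept else "NA",
            "pleiotropy_detected": str(rep.pleiotropy_detected).upper() if rep.pleiotropy_detected is not None else "NA",
            "presso_global_pval": f"{rep.presso.global_pval:.6g}" if rep.presso else "NA",
            "presso_outliers": ";".join(rep.presso.outlier_indices) if rep.presso else "NA",
            "loo_sign_flips": ";".join(r.omitted_snp for r in rep.loo if r.sign_flip) if rep.loo else "",
            "steiger_direction": str(rep.steiger.correct_direction).upper() if rep.steiger else "NA",
            "steiger_pval": f"{rep.steiger.pval:.6g}" if rep.steiger else "NA",
        })
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def _write_audit(analyses: Sequence[PairAnalysis], path: Path) -> None:
    recs = [
        {"exposure": pa.exposure, "outcome": pa.outcome,
         "snp_id": snp, "fate": fate}
        for pa in analyses
        for snp, fate in sorted(pa.snp_fates.items())
    ]
    pd.DataFrame(recs, columns=["exposure", "outcome", "snp_id", "fate"]).to_csv(
        path, sep="\t", index=False)


def _write_manifest(cfg: RunConfig, thresholds, rows, path: Path) -> None:
    manifest = {
        "package": "mrbmd",
        "version": __version__,
        "config": asdict(cfg),
        "bonferroni_thresholds": {
            lvl: {"n_taxa": t.n_taxa, "threshold": t.threshold,
                  "threshold_display": t.threshold_display}
            for lvl, t in sorted(thresholds.by_level.items())
        },
        "n_result_rows": len(rows),
        "n_nominal_significant": sum(1 for r in rows if r.nominal_significant),
        "n_bonferroni_significant": sum(1 for r in rows if r.bonferroni_significant),
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
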