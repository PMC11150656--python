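"""Per-taxonomic-level Bonferroni correction and result-table assembly.

Microbiome exposures are tested once per taxon, so multiple-testing control
is applied within each taxonomic level: the significance threshold for a
level with n analyzed taxa is 0.05/n.  Comparisons always use the exact
0.05/n value; a two-significant-figure rounding is kept for display only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .exceptions import ConfigurationError, DomainError
from .sensitivity import SensitivityReport
from .summary_io import ResultRow, TaxonMeta

logger = logging.getLogger(__name__)

ALPHA = 0.05


def _round_sig(x: float, sig: int = 2) -> float:
    from math import floor, log10
    if x == 0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class LevelThreshold:
    level: str
    n_taxa: int
    threshold: float  # exact 0.05/n
    threshold_display: float  # rounded to 2 significant figures


@dataclass
class LevelThresholds:
    """Per-level Bonferroni thresholds; comparisons use the exact values."""

    by_level: dict[str, LevelThreshold]

    def __getitem__(self, level: str) -> LevelThreshold:
        return self.by_level[level]

    def __contains__(self, level: str) -> bool:
        return level in self.by_level


def bonferroni_thresholds(taxon_counts: Mapping[str, int]) -> LevelThresholds:
    """Threshold 0.05/n per taxonomic level with n analyzed taxa.

    Only levels with at least one analyzed taxon get a threshold; a zero or
    negative count is a usage error.
    """
    by_level = {}
    for level, n in taxon_counts.items():
        if n < 1:
            raise DomainError(f"taxon count for {level!r} must be >= 1, got {n}")
        exact = ALPHA / n
        by_level[level] = LevelThreshold(
            level=level, n_taxa=n, threshold=exact,
            threshold_display=_round_sig(exact, 2),
        )
    return LevelThresholds(by_level=by_level)


def apply_bonferroni(
    rows: Iterable[ResultRow], thresholds: LevelThresholds
) -> list[ResultRow]:
    """Flag rows that survive their level's Bonferroni threshold.

    Sets ``bonferroni_significant`` (p < 0.05/n for the row's level) and
    ``nominal_significant`` (p < 0.05) on each row, in place, and returns
    the list.  Every row's level must be present in ``thresholds``.
    """
    out = []
    for row in rows:
        level = row.exposure.level
        if level not in thresholds:
            raise ConfigurationError(f"no Bonferroni threshold for level {level!r}")
        row.bonferroni_significant = row.pval < thresholds[level].threshold
        row.nominal_significant = row.pval < ALPHA
        out.append(row)
    return out


_LEVEL_ORDER = {lvl: i for i, lvl in enumerate(
    ("phylum", "class", "order", "family", "genus"))}


def assemble_results(
    estimates: Mapping[tuple[str, str], "object"],
    reports: Mapping[tuple[str, str], SensitivityReport],
    taxa: Mapping[str, TaxonMeta],
    drop_steiger_failed: bool = True,
) -> list[ResultRow]:
    """Build final result rows from per-analysis estimates and diagnostics.

    ``estimates`` maps (exposure_label, outcome) to the primary MREstimate
    (Wald ratio when a single instrument survived, IVW otherwise).  Analyses
    whose Steiger test indicates the wrong causal direction are excluded
    (and logged) rather than reported.  Rows are ordered by outcome, then
    taxonomy.
    """
    keys = list(estimates.keys())
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate exposure-outcome keys")
    rows: list[ResultRow] = []
    for (exposure_label, outcome), est in estimates.items():
        meta = taxa[exposure_label]
        report = reports.get((exposure_label, outcome), SensitivityReport())
        steiger = report.steiger
        if steiger is not None and drop_steiger_failed and not steiger.correct_direction:
            logger.info("excluding %s / %s: steiger_failed", exposure_label, outcome)
            continue
        q = report.q
        rows.append(ResultRow(
            exposure=meta,
            outcome=outcome,
            method="Wald ratio" if est.method == "wald_ratio" else est.method.upper()
            if est.method == "ivw" else est.method,
            n_snps=est.k,
            beta=est.beta, se=est.se, pval=est.pval,
            or_=est.or_, ci_low=est.ci_low, ci_high=est.ci_high,
            steiger_direction=steiger.correct_direction if steiger else True,
            steiger_p=steiger.pval if steiger else float("nan"),
            q=q.q if q else None,
            q_df=q.df if q else None,
            q_pval=q.pval if q else None,
        ))
    rows.sort(key=lambda r: (
        r.outcome, _LEVEL_ORDER.get(r.exposure.level, 99),
        r.exposure.name, r.exposure.taxon_id,
    ))
    return rows


def count_taxa_per_level(rows: Sequence[ResultRow]) -> dict[str, int]:
    """Number of distinct analyzed taxa at each level (the Bonferroni n)."""
    seen: dict[str, set] = {}
    for row in rows:
        seen.setdefault(row.exposure.level, set()).add(row.exposure.taxon_id)
    return {level: len(ids) for level, ids in seen.items()}
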