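"""Instrument selection: p-value screen, LD clumping, strength filtering.

Instruments for a microbiome exposure are genome-wide-significant SNPs
(5e-8, or the looser 5e-6 screen used when few taxa reach genome-wide
significance), pruned for linkage disequilibrium by greedy clumping
(r2 < 0.01 within 10,000 kb) and screened for weak-instrument bias by the
single-SNP F statistic F = (beta/se)^2, with F < 10 flagged as weak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .exceptions import DomainError
from .summary_io import SummaryStatRecord

logger = logging.getLogger(__name__)

#: pairwise LD provider: (snp_a, snp_b) -> r^2
LDLookup = Callable[[str, str], float]

GENOME_WIDE = 5e-8
SUGGESTIVE = 5e-6


@dataclass
class ClumpConfig:
    """Greedy-clumping parameters.

    ``r2_max`` and ``window_kb`` default to the conventional microbiome-GWAS
    settings (r2 < 0.01 within 10,000 kb).  ``ld_lookup`` supplies pairwise
    r2; when absent, clumping is distance-only: every unaccepted SNP within
    the window of an accepted one is removed.
    """

    r2_max: float = 0.01
    window_kb: int = 10_000
    ld_lookup: Optional[LDLookup] = None

    def __post_init__(self):
        if not 0 < self.r2_max < 1:
            raise DomainError(f"r2_max must be in (0,1), got {self.r2_max}")
        if self.window_kb <= 0:
            raise DomainError(f"window_kb must be positive, got {self.window_kb}")


@dataclass(frozen=True)
class FStatResult:
    snp_id: str
    f: float
    weak: bool


def screen_by_pvalue(
    records: Iterable[SummaryStatRecord], threshold: float
) -> list[SummaryStatRecord]:
    """Retain records with p-value strictly below ``threshold``, in order."""
    if not 0 < threshold < 1:
        raise DomainError(f"threshold must be in (0,1), got {threshold}")
    return [r for r in records if r.pval < threshold]


def clump(
    records: Sequence[SummaryStatRecord], cfg: Optional[ClumpConfig] = None
) -> list[SummaryStatRecord]:
    """Greedy LD clumping.

    SNPs are visited in order of ascending p-value (ties broken by
    (chrom, pos, snp_id) for determinism).  Each accepted index SNP removes
    all not-yet-accepted SNPs on the same chromosome within ±window_kb that
    are in LD with it (r2 >= r2_max), or simply all of them when no LD
    lookup is configured.  Output preserves the input record order.
    """
    cfg = cfg or ClumpConfig()
    ids = [r.snp_id for r in records]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate snp_id(s) in clump input: {sorted(dupes)}")

    order = sorted(range(len(records)),
                   key=lambda i: (records[i].pval, records[i].chrom,
                                  records[i].pos, records[i].snp_id))
    window_bp = cfg.window_kb * 1000
    accepted: list[int] = []
    removed: set[int] = set()
    for i in order:
        if i in removed:
            continue
        accepted.append(i)
        lead = records[i]
        for j in order:
            if j == i or j in removed or j in accepted:
                continue
            other = records[j]
            if other.chrom != lead.chrom or abs(other.pos - lead.pos) > window_bp:
                continue
            if cfg.ld_lookup is None:
                removed.add(j)
            elif cfg.ld_lookup(lead.snp_id, other.snp_id) >= cfg.r2_max:
                removed.add(j)
    keep = set(accepted)
    return [r for i, r in enumerate(records) if i in keep]


def compute_f_stat(record: SummaryStatRecord, f_min: float = 10.0) -> FStatResult:
    """Single-SNP instrument strength, F = (beta/se)^2.

    Equals the square of the Wald z statistic; F below ``f_min`` (10 by
    convention) marks a weak instrument.
    """
    if record.se <= 0:
        raise DomainError(f"{record.snp_id}: se must be positive")
    f = (record.beta / record.se) ** 2
    return FStatResult(snp_id=record.snp_id, f=f, weak=f < f_min)


def filter_weak_instruments(
    records: Iterable[SummaryStatRecord], f_min: float = 10.0
) -> list[SummaryStatRecord]:
    """Drop SNPs with F < ``f_min``; F = f_min is kept.

    Per-SNP F values are logged so the run audit can show instrument
    strength for every candidate.
    """
    kept = []
    for r in records:
        res = compute_f_stat(r, f_min)
        logger.info("F(%s) = %.3f%s", r.snp_id, res.f, " [weak, dropped]" if res.weak else "")
        if not res.weak:
            kept.append(r)
    if not kept:
        logger.warning("all instruments weak (F < %g); empty instrument set", f_min)
    return kept


def load_confounder_table(path: str | Path) -> dict[str, str]:
    """Load a two-column (snp_id, trait) delimited file, e.g. a PhenoScanner
    export curated to confounder traits (diet, BMI, physical activity, ...)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("confounder table needs two columns: snp_id, trait")
    c0, c1 = df.columns[:2]
    return dict(zip(df[c0].str.strip(), df[c1].str.strip()))


def exclude_confounder_snps(
    records: Iterable[SummaryStatRecord],
    confounder_table: Mapping[str, str],
) -> list[SummaryStatRecord]:
    """Remove SNPs known to associate with confounder traits.

    The table maps snp_id to the confounding trait; excluded pairs are
    logged so the exclusion is auditable.
    """
    records = list(records)
    kept = []
    for r in records:
        if r.snp_id in confounder_table:
            logger.info("excluding %s (confounder: %s)", r.snp_id, confounder_table[r.snp_id])
        else:
            kept.append(r)
    if confounder_table and len(kept) == len(records):
        logger.info("confounder table matched no instrument SNPs; set unchanged")
    return kept
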