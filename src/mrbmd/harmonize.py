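"""Align exposure and outcome GWAS to a common effect allele.

Two-sample MR requires that the SNP-exposure and SNP-outcome effects refer
to the same effect allele.  Files from different consortia may code the
opposite allele as the effect allele (flip: negate the outcome beta and
complement the frequency) or report the opposite strand (complement the
alleles first, then compare).  Palindromic SNPs (A/T, G/C) are ambiguous
between these two cases and are dropped unconditionally; a frequency-based
rescue exists behind a switch but is off by default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .exceptions import DomainError
from .summary_io import VALID_ALLELES, SummaryStatRecord

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: drop reasons emitted by harmonization
REASON_PALINDROME = "palindrome"
REASON_ALLELE_MISMATCH = "allele_mismatch"
REASON_ABSENT = "absent_in_outcome"
REASON_MULTIALLELIC = "multiallelic"


@dataclass(frozen=True)
class HarmonizedPair:
    """One SNP's exposure and outcome effects on the same effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    pval_exp: float
    n_exp: int
    n_out: int
    eaf: Optional[float] = None

    def __post_init__(self):
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError(f"{self.snp_id}: standard errors must be positive")

    @property
    def ratio(self) -> float:
        """Per-SNP Wald ratio beta_out / beta_exp."""
        return self.beta_out / self.beta_exp

    @property
    def ratio_se(self) -> float:
        """First-order delta-method SE of the ratio."""
        return self.se_out / abs(self.beta_exp)


@dataclass
class DropReport:
    """Counts and identities of SNPs lost during harmonization."""

    counts: Counter
    dropped: list  # (snp_id, reason)

    @classmethod
    def empty(cls) -> "DropReport":
        return cls(counts=Counter(), dropped=[])

    def add(self, snp_id: str, reason: str) -> None:
        self.counts[reason] += 1
        self.dropped.append((snp_id, reason))


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {G,C})."""
    if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
        raise DomainError(f"invalid allele pair ({a1!r}, {a2!r})")
    return {a1, a2} in ({"A", "T"}, {"G", "C"})


def harmonize_pair(
    exp_rec: SummaryStatRecord,
    out_rec: SummaryStatRecord,
    drop_palindromic: bool = True,
) -> tuple[Optional[HarmonizedPair], Optional[str]]:
    """Harmonize one SNP's exposure and outcome records.

    Returns ``(pair, None)`` on success or ``(None, reason)`` when the SNP
    must be dropped.  Resolution order: exact allele match (copy), swapped
    alleles (negate beta_out, eaf -> 1 - eaf), strand complement (complement
    outcome alleles, then as above).  Palindromic exposure SNPs are dropped
    before any of that, because strand and allele flips are indistinguishable
    for them.
    """
    if exp_rec.snp_id != out_rec.snp_id:
        raise ValueError(
            f"snp_id mismatch: {exp_rec.snp_id!r} vs {out_rec.snp_id!r}"
        )
    if drop_palindromic and (
        is_palindromic(exp_rec.effect_allele, exp_rec.other_allele)
        or is_palindromic(out_rec.effect_allele, out_rec.other_allele)
    ):
        return None, REASON_PALINDROME

    e1, e2 = exp_rec.effect_allele, exp_rec.other_allele
    o1, o2 = out_rec.effect_allele, out_rec.other_allele

    def build(beta_out: float, eaf_out: Optional[float]) -> HarmonizedPair:
        return HarmonizedPair(
            snp_id=exp_rec.snp_id,
            beta_exp=exp_rec.beta, se_exp=exp_rec.se,
            beta_out=beta_out, se_out=out_rec.se,
            pval_exp=exp_rec.pval,
            n_exp=exp_rec.n, n_out=out_rec.n,
            eaf=exp_rec.eaf if exp_rec.eaf is not None else eaf_out,
        )

    if (o1, o2) == (e1, e2):
        return build(out_rec.beta, out_rec.eaf), None
    if (o1, o2) == (e2, e1):
        eaf = None if out_rec.eaf is None else 1.0 - out_rec.eaf
        return build(-out_rec.beta, eaf), None
    # try the other strand
    c1, c2 = COMPLEMENT[o1], COMPLEMENT[o2]
    if (c1, c2) == (e1, e2):
        return build(out_rec.beta, out_rec.eaf), None
    if (c1, c2) == (e2, e1):
        eaf = None if out_rec.eaf is None else 1.0 - out_rec.eaf
        return build(-out_rec.beta, eaf), None
    return None, REASON_ALLELE_MISMATCH


def harmonize_dataset(
    exposure: Sequence[SummaryStatRecord],
    outcome: Iterable[SummaryStatRecord],
    drop_palindromic: bool = True,
) -> tuple[list[HarmonizedPair], DropReport]:
    """Inner-join exposure and outcome records by snp_id and harmonize each.

    SNPs absent from the outcome GWAS are dropped and counted (no proxy
    lookup); SNPs appearing with conflicting allele sets across rows are
    dropped as multiallelic.
    """
    report = DropReport.empty()

    out_by_id: dict[str, SummaryStatRecord] = {}
    multi: set[str] = set()
    for rec in outcome:
        prev = out_by_id.get(rec.snp_id)
        if prev is not None and {prev.effect_allele, prev.other_allele} != {
            rec.effect_allele, rec.other_allele
        }:
            multi.add(rec.snp_id)
        out_by_id[rec.snp_id] = rec

    exp_allele_sets: dict[str, frozenset] = {}
    for rec in exposure:
        aset = frozenset((rec.effect_allele, rec.other_allele))
        if exp_allele_sets.setdefault(rec.snp_id, aset) != aset:
            multi.add(rec.snp_id)

    pairs: list[HarmonizedPair] = []
    seen: set[str] = set()
    for exp_rec in exposure:
        if exp_rec.snp_id in seen:
            continue
        seen.add(exp_rec.snp_id)
        if exp_rec.snp_id in multi:
            report.add(exp_rec.snp_id, REASON_MULTIALLELIC)
            continue
        out_rec = out_by_id.get(exp_rec.snp_id)
        if out_rec is None:
            report.add(exp_rec.snp_id, REASON_ABSENT)
            continue
        pair, reason = harmonize_pair(exp_rec, out_rec, drop_palindromic)
        if pair is None:
            report.add(exp_rec.snp_id, reason)
        else:
            pairs.append(pair)
    return pairs, report
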