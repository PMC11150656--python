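"""Read and write GWAS summary-statistics tables and MR result tables.

Summary statistics arrive as delimited text with one row per SNP
(identifier, position, alleles, effect-allele frequency, effect size,
standard error, p-value, sample size).  Column headers differ between
consortia, so ingestion goes through an explicit column map with defaults
covering the two common dialects (``effect_allele``/``other_allele`` and
``A1``/``A2``).  Microbiome exposure traits are labelled with a taxonomy
grammar of the form ``Genus.Tyzzerella3.id.11335``; :func:`parse_taxon_label`
turns those labels into structured metadata that later drives per-level
multiple-testing correction.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .exceptions import ConfigurationError, TaxonLabelError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

TAXONOMIC_LEVELS = ("phylum", "class", "order", "family", "genus")

#: canonical field -> acceptable column headers (matched case-insensitively,
#: first hit wins).  The first entry of each tuple is the canonical header
#: used when writing.
DEFAULT_COLUMN_ALIASES: Mapping[str, tuple[str, ...]] = {
    "snp_id": ("snp_id", "snp", "rsid", "markername", "id"),
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
    "effect_allele": ("effect_allele", "a1", "ea", "allele1"),
    "other_allele": ("other_allele", "a2", "oa", "nea", "allele2"),
    "eaf": ("eaf", "frq", "freq", "effect_allele_frequency", "maf"),
    "beta": ("beta", "b", "effect"),
    "se": ("se", "stderr", "standard_error"),
    "pval": ("pval", "p", "pvalue", "p_value"),
    "n": ("n", "samplesize", "n_total"),
}

MANDATORY_FIELDS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval", "n",
)

RESULT_COLUMNS = (
    "exposure", "outcome", "method", "n_snps", "beta", "se", "pval",
    "or", "ci_low", "ci_high", "steiger_direction", "steiger_p",
    "q", "q_df", "q_pval",
)


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds or SD
    units depending on the trait); ``eaf`` may be absent in older consortium
    files and is therefore optional.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: Optional[float] = None

    def __post_init__(self):
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not 0 < self.pval <= 1:
            raise ValueError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if self.n < 1:
            raise ValueError(f"{self.snp_id}: n must be >= 1, got {self.n}")
        if self.eaf is not None and not 0 <= self.eaf <= 1:
            raise ValueError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class TaxonMeta:
    """Taxonomic level/name/id parsed from a microbiome exposure label."""

    level: str
    name: str
    taxon_id: int

    def __post_init__(self):
        if self.level not in TAXONOMIC_LEVELS:
            raise ValueError(f"unknown taxonomic level {self.level!r}")
        if self.taxon_id < 0:
            raise ValueError("taxon_id must be non-negative")

    @property
    def label(self) -> str:
        return f"{self.level.capitalize()}.{self.name}.id.{self.taxon_id}"


@dataclass
class ResultRow:
    """One row of a final MR result table (one exposure-outcome-method)."""

    exposure: TaxonMeta
    outcome: str
    method: str
    n_snps: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    steiger_direction: bool
    steiger_p: float
    q: Optional[float] = None
    q_df: Optional[int] = None
    q_pval: Optional[float] = None
    bonferroni_significant: Optional[bool] = field(default=None, compare=False)
    nominal_significant: Optional[bool] = field(default=None, compare=False)


# the name may itself contain dots (e.g. "Escherichia.Shigella") and the id
# may be followed by a residual suffix such as ".summary"
_TAXON_RE = re.compile(
    r"^(?P<level>[A-Za-z]+)\.(?P<name>.+)\.id\.(?P<id>\d+)(?:\.[A-Za-z].*)?$"
)


def parse_taxon_label(label: str) -> TaxonMeta:
    """Parse a microbiome taxon label like ``Genus.Tyzzerella3.id.11335``.

    The first dot-separated token is the taxonomic level (case-insensitive);
    the trailing ``.id.<int>`` carries the taxon identifier.  Interior dots
    are preserved in the name so labels such as unknown families parse
    correctly.  A trailing alphabetic suffix after the id (seen in some
    published labels, e.g. ``...id.2162.summary``) is tolerated and ignored.
    """
    if not label:
        raise TaxonLabelError(label, "empty label")
    m = _TAXON_RE.match(label.strip())
    if m is None:
        raise TaxonLabelError(label, "expected '<Level>.<name>.id.<int>'")
    level = m.group("level").lower()
    if level not in TAXONOMIC_LEVELS:
        raise TaxonLabelError(label, f"unknown taxonomic level {m.group('level')!r}")
    return TaxonMeta(level=level, name=m.group("name"), taxon_id=int(m.group("id")))


def _resolve_columns(
    header: Sequence[str], column_map: Optional[Mapping[str, str]]
) -> dict[str, str]:
    """Map canonical field names onto actual file headers."""
    lower = {h.lower(): h for h in header}
    resolved: dict[str, str] = {}
    explicit = dict(column_map or {})
    for canon, aliases in DEFAULT_COLUMN_ALIASES.items():
        if canon in explicit:
            col = explicit[canon]
            if col not in header:
                raise ConfigurationError(
                    f"mapped column {col!r} for field {canon!r} not found in file header"
                )
            resolved[canon] = col
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    missing = [f for f in MANDATORY_FIELDS if f not in resolved]
    if missing:
        raise ConfigurationError(
            "missing mandatory column(s): " + ", ".join(sorted(missing))
        )
    return resolved


def read_summary_stats(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: Optional[str] = None,
    rejections: Optional[list] = None,
) -> list[SummaryStatRecord]:
    """Read GWAS summary statistics from a TSV/CSV file.

    Parameters
    ----------
    path
        Delimited text file with one header row.  Tab or comma delimiter is
        auto-detected unless ``delimiter`` is given.
    column_map
        Optional mapping from canonical field names (``snp_id``, ``chrom``,
        ``pos``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``,
        ``se``, ``pval``, ``n``) to this file's column headers.  Unmapped
        fields fall back to the built-in alias table.
    rejections
        If a list is supplied, one ``(line_number, snp_id, reason)`` tuple is
        appended per rejected row in addition to the log record.

    Rows violating record invariants (non-positive SE, p outside (0, 1],
    identical alleles, ...) are rejected row-by-row with a logged diagnostic
    rather than failing the whole file.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=delimiter if delimiter is not None else None,
        engine="python",
        dtype=str,
        keep_default_na=False,
    )
    cols = _resolve_columns(list(df.columns), column_map)
    records: list[SummaryStatRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        line_no = i + 2  # 1-based, after the header line
        snp = str(row[cols["snp_id"]]).strip()
        try:
            eaf_raw = row.get(cols["eaf"], "") if "eaf" in cols else ""
            eaf = float(eaf_raw) if str(eaf_raw).strip() not in ("", "NA", "nan", ".") else None
            rec = SummaryStatRecord(
                snp_id=snp,
                chrom=str(row[cols["chrom"]]).strip(),
                pos=int(float(row[cols["pos"]])),
                effect_allele=str(row[cols["effect_allele"]]).strip().upper(),
                other_allele=str(row[cols["other_allele"]]).strip().upper(),
                beta=float(row[cols["beta"]]),
                se=float(row[cols["se"]]),
                pval=float(row[cols["pval"]]),
                n=int(float(row[cols["n"]])),
                eaf=eaf,
            )
        except (ValueError, KeyError) as exc:
            logger.warning("%s line %d (%s): rejected: %s", path.name, line_no, snp, exc)
            if rejections is not None:
                rejections.append((line_no, snp, str(exc)))
            continue
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# result-table formatting

def format_scientific(x: float, sig: int = 3) -> str:
    """Format with ``sig`` significant digits in E notation, e.g. 2.80E-01."""
    if x == 0:
        return "0.00E+00"
    return f"{x:.{sig - 1}E}"


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the reporting convention for OR/CI)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def format_pvalue(p: float) -> str:
    """p at up to 4 decimals, switching to scientific below 1e-4."""
    if p < 1e-4:
        return format_scientific(p, sig=3)
    return f"{round_half_away(p, 4):.4g}"


def _fmt_opt(x, fmt) -> str:
    return "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else fmt(x)


def write_results_table(rows: Iterable[ResultRow], path: str | Path) -> None:
    """Write MR result rows as a TSV mirroring the published table layout.

    Effect sizes and SEs are written in scientific notation with three
    significant digits; OR and CI bounds at three decimals; p-values at up
    to four decimals (scientific below 1e-4).
    """
    rows = list(rows)
    if not rows:
        raise ValueError("cannot write an empty results table")
    out = []
    for r in rows:
        out.append({
            "exposure": r.exposure.label,
            "outcome": r.outcome,
            "method": r.method,
            "n_snps": r.n_snps,
            "beta": format_scientific(r.beta),
            "se": format_scientific(r.se),
            "pval": format_pvalue(r.pval),
            "or": f"{round_half_away(r.or_, 3):.3f}",
            "ci_low": f"{round_half_away(r.ci_low, 3):.3f}",
            "ci_high": f"{round_half_away(r.ci_high, 3):.3f}",
            "steiger_direction": str(bool(r.steiger_direction)).upper(),
            "steiger_p": format_scientific(r.steiger_p),
            "q": _fmt_opt(r.q, lambda v: f"{v:.4g}"),
            "q_df": _fmt_opt(r.q_df, lambda v: str(int(v))),
            "q_pval": _fmt_opt(r.q_pval, lambda v: f"{v:.4g}"),
        })
    pd.DataFrame(out, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> list[ResultRow]:
    """Read back a table written by :func:`write_results_table`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    rows = []
    for rec in df.to_dict("records"):
        rows.append(ResultRow(
            exposure=parse_taxon_label(rec["exposure"]),
            outcome=rec["outcome"],
            method=rec["method"],
            n_snps=int(rec["n_snps"]),
            beta=float(rec["beta"]),
            se=float(rec["se"]),
            pval=float(rec["pval"]),
            or_=float(rec["or"]),
            ci_low=float(rec["ci_low"]),
            ci_high=float(rec["ci_high"]),
            steiger_direction=str(rec["steiger_direction"]).upper() == "TRUE",
            steiger_p=float(rec["steiger_p"]),
            q=None if pd.isna(rec["q"]) else float(rec["q"]),
            q_df=None if pd.isna(rec["q_df"]) else int(rec["q_df"]),
            q_pval=None if pd.isna(rec["q_pval"]) else float(rec["q_pval"]),
        ))
    return rows


def write_summary_stats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    """Write records in the canonical TSV dialect this package reads."""
    df = pd.DataFrame([
        {
            "snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos,
            "effect_allele": r.effect_allele, "other_allele": r.other_allele,
            "eaf": "" if r.eaf is None else repr(r.eaf),
            "beta": repr(r.beta), "se": repr(r.se), "pval": repr(r.pval),
            "n": r.n,
        }
        for r in records
    ])
    df.to_csv(path, sep="\t", index=False)
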