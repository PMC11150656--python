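"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of a microbiome-exposure / bone-density
-outcome MR design: an exposure GWAS of modest size (default n = 18,340)
with a handful of genome-wide-significant instruments per taxon, and a
single much larger outcome GWAS.  The data-generating model is the standard
one underlying two-sample MR:

    Gamma_j = beta_causal * gamma_j + alpha_j

where gamma_j is the true SNP-exposure effect, alpha_j a pleiotropic effect
on the outcome (zero, balanced, or directional), and observed effects are
drawn around the truths with GWAS-scale standard errors
se = 1/sqrt(2 maf (1-maf) n) appropriate for standardized traits.
Planted outliers, palindromic alleles, and weak instruments are all
controllable, and the ground truth is returned alongside the records so
every pipeline stage can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
from scipy import stats

from .exceptions import ConfigurationError
from .summary_io import SummaryStatRecord, write_summary_stats

# sample sizes of the cohorts the generator emulates
N_EXPOSURE_DEFAULT = 18_340   # 16S microbiome GWAS meta-analysis
N_OUTCOME_DEFAULTS = {
    "FN-BMD": 32_735,
    "FA-BMD": 8_143,
    "LS-BMD": 28_498,
    "HE-BMD": 426_824,
}

_NONPALINDROMIC = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
_PALINDROMIC = [("A", "T"), ("G", "C")]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults mirror the study design the
    package targets (small-n exposure GWAS, large-n outcome GWAS, a few
    strong instruments per taxon, no pleiotropy unless requested)."""

    n_snps: int = 30
    n_exp: int = N_EXPOSURE_DEFAULT
    n_out: int = N_OUTCOME_DEFAULTS["FN-BMD"]
    beta_causal: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_h2_per_snp: float = 0.002
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    outlier_count: int = 0
    outlier_scale: float = 10.0
    palindromic_fraction: float = 0.0
    weak_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        for name in ("palindromic_fraction", "weak_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.exposure_h2_per_snp < 0 or self.pleiotropy_sd < 0:
            raise ConfigurationError("variances must be non-negative")
        if self.exposure_h2_per_snp * self.n_snps >= 1:
            raise ConfigurationError(
                "total exposure heritability >= 1 is infeasible: "
                f"{self.n_snps} SNPs x h2 {self.exposure_h2_per_snp}"
            )
        if self.outlier_count > self.n_snps:
            raise ConfigurationError("more outliers than SNPs")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth paired with a generated dataset."""

    beta_causal: float
    gamma: np.ndarray           # true SNP-exposure effects
    alpha: np.ndarray           # per-SNP pleiotropic effects on the outcome
    outlier_ids: frozenset
    palindromic_ids: frozenset
    weak_ids: frozenset


# F expected for the deliberately weakened subset: well under the F = 10 rule
_WEAK_TARGET_F = 4.0

# spacing (bp) between same-chromosome SNPs; larger than the default
# 10,000 kb clump window so clumping is neutral unless configured otherwise
_POSITION_SPACING = 20_000_000
_N_CHROMS = 22


def _positions(n: int) -> tuple[list[str], list[int]]:
    chroms, pos = [], []
    for i in range(n):
        chroms.append(str(i % _N_CHROMS + 1))
        pos.append((i // _N_CHROMS) * _POSITION_SPACING + 1_000_000)
    return chroms, pos


def generate_two_sample_dataset(
    cfg: SimConfig,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], SimTruth]:
    """Generate matched exposure and outcome summary statistics.

    Deterministic given ``cfg.seed``.  Every SNP appears in both GWAS with
    the same allele coding, so harmonization losses come only from the
    planted palindromic fraction.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    maf = rng.uniform(*cfg.maf_range, size=n)
    var_geno = 2.0 * maf * (1.0 - maf)

    gamma = np.sqrt(cfg.exposure_h2_per_snp / var_geno) * rng.choice([-1.0, 1.0], size=n)
    se_exp = 1.0 / np.sqrt(var_geno * cfg.n_exp)
    se_out = 1.0 / np.sqrt(var_geno * cfg.n_out)

    n_weak = int(round(cfg.weak_fraction * n))
    weak_idx = rng.choice(n, size=n_weak, replace=False) if n_weak else np.array([], dtype=int)
    gamma[weak_idx] = (
        np.sqrt(_WEAK_TARGET_F) * se_exp[weak_idx] * np.sign(gamma[weak_idx])
    )

    # pleiotropic effects are defined relative to the exposure-increasing
    # allele (the convention under which "directional" pleiotropy is
    # identifiable); multiplying by sign(gamma) expresses them on this
    # dataset's arbitrary effect-allele coding
    alpha = (
        rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n) * np.sign(gamma)
        if (cfg.pleiotropy_mean != 0 or cfg.pleiotropy_sd > 0)
        else np.zeros(n)
    )
    candidates = np.setdiff1d(np.arange(n), weak_idx)
    outlier_idx = (
        rng.choice(candidates, size=cfg.outlier_count, replace=False)
        if cfg.outlier_count else np.array([], dtype=int)
    )
    alpha = alpha.copy()
    alpha[outlier_idx] += (
        cfg.outlier_scale * se_out[outlier_idx]
        * rng.choice([-1.0, 1.0], size=len(outlier_idx))
    )

    big_gamma = cfg.beta_causal * gamma + alpha
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(big_gamma, se_out)

    n_pal = int(round(cfg.palindromic_fraction * n))
    pal_idx = set(
        rng.choice(n, size=n_pal, replace=False).tolist() if n_pal else []
    )

    chroms, positions = _positions(n)
    exp_records, out_records = [], []
    pal_ids, weak_ids, out_ids = set(), set(), set()
    for j in range(n):
        snp = f"rs{j + 1:06d}"
        if j in pal_idx:
            a1, a2 = _PALINDROMIC[int(rng.integers(len(_PALINDROMIC)))]
            pal_ids.add(snp)
        else:
            a1, a2 = _NONPALINDROMIC[int(rng.integers(len(_NONPALINDROMIC)))]
        if j in weak_idx:
            weak_ids.add(snp)
        if j in outlier_idx:
            out_ids.add(snp)
        p_exp = float(2.0 * stats.norm.sf(abs(beta_exp[j] / se_exp[j])))
        p_out = float(2.0 * stats.norm.sf(abs(beta_out[j] / se_out[j])))
        common = dict(chrom=chroms[j], pos=positions[j],
                      effect_allele=a1, other_allele=a2, eaf=float(maf[j]))
        exp_records.append(SummaryStatRecord(
            snp_id=snp, beta=float(beta_exp[j]), se=float(se_exp[j]),
            pval=max(p_exp, 1e-300), n=cfg.n_exp, **common))
        out_records.append(SummaryStatRecord(
            snp_id=snp, beta=float(beta_out[j]), se=float(se_out[j]),
            pval=max(p_out, 1e-300), n=cfg.n_out, **common))

    truth = SimTruth(
        beta_causal=cfg.beta_causal,
        gamma=gamma, alpha=alpha,
        outlier_ids=frozenset(out_ids),
        palindromic_ids=frozenset(pal_ids),
        weak_ids=frozenset(weak_ids),
    )
    return exp_records, out_records, truth


#: named fixture scenarios for the packaged test/doc suite
FIXTURE_CONFIGS: dict[str, SimConfig] = {
    "null": SimConfig(beta_causal=0.0, seed=101),
    "causal": SimConfig(beta_causal=0.15, seed=102),
    "pleiotropic": SimConfig(beta_causal=0.1, pleiotropy_mean=0.01,
                             pleiotropy_sd=0.005, seed=103),
    "outlier": SimConfig(beta_causal=0.1, outlier_count=1, outlier_scale=10.0,
                         seed=104),
    "palindrome_rich": SimConfig(beta_causal=0.1, palindromic_fraction=0.4,
                                 seed=105),
    "weak_instrument": SimConfig(beta_causal=0.1, weak_fraction=0.5, seed=106),
}


def write_truth(truth: SimTruth, cfg: SimConfig, path: Path) -> None:
    lines = [
        f"beta_causal\t{truth.beta_causal!r}",
        f"seed\t{cfg.seed}",
        f"n_snps\t{cfg.n_snps}",
        f"n_exp\t{cfg.n_exp}",
        f"n_out\t{cfg.n_out}",
        "outlier_ids\t" + ",".join(sorted(truth.outlier_ids)),
        "palindromic_ids\t" + ",".join(sorted(truth.palindromic_ids)),
        "weak_ids\t" + ",".join(sorted(truth.weak_ids)),
    ]
    path.write_text("\n".join(lines) + "\n")


def make_fixture_suite(out_dir: str | Path) -> list[Path]:
    """Write the deterministic fixture family (exposure/outcome/truth per
    scenario) in the TSV dialect the I/O layer reads.  Returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, cfg in FIXTURE_CONFIGS.items():
        exp, out, truth = generate_two_sample_dataset(cfg)
        e_path = out_dir / f"{name}.exposure.tsv"
        o_path = out_dir / f"{name}.outcome.tsv"
        t_path = out_dir / f"{name}.truth.tsv"
        write_summary_stats(exp, e_path)
        write_summary_stats(out, o_path)
        write_truth(truth, cfg, t_path)
        written += [e_path, o_path, t_path]
    return written
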