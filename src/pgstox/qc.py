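"""Genotype quality control: HWE exact test, variant/sample filters, PCA.

The filter thresholds default to the standard array-QC rules used for the
cohort: drop variants missing in >5% of samples, with MAF < 1%, with
MAF < 5% and missing in >1% of samples, or deviating from Hardy-Weinberg
equilibrium at p < 1e-5; drop samples missing >10% of variants.  All
thresholds are strict inequalities, so boundary values pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .dosage import DosageMatrix

__all__ = [
    "GenotypeCounts",
    "QCThresholds",
    "QCReport",
    "hwe_exact_test",
    "hwe_het_pvalues",
    "hard_calls_from_dosages",
    "variant_qc",
    "sample_qc",
    "apply_qc",
    "compute_pcs",
]

# relative tie tolerance when comparing configuration probabilities
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class GenotypeCounts:
    """Hard genotype counts at one biallelic variant."""

    n_hom_major: int
    n_het: int
    n_hom_minor: int

    def __post_init__(self) -> None:
        if min(self.n_hom_major, self.n_het, self.n_hom_minor) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom_major + self.n_het + self.n_hom_minor

    @property
    def minor_allele_count(self) -> int:
        return 2 * self.n_hom_minor + self.n_het


def _het_log_probs(n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Given ``n`` diploid samples and ``m`` copies of the minor allele
    (``m <= n``), the heterozygote count ``h`` ranges over values of the
    same parity as ``m`` with ``0 <= h <= m``; the number of genotype
    configurations is ``n! / (a! b! h!) * 2^h`` with ``a = (m - h) / 2``
    minor homozygotes and ``b = n - a - h`` major homozygotes.  Returns the
    admissible ``h`` values and their normalised log-probabilities.
    """
    h = np.arange(m % 2, m + 1, 2)
    a = (m - h) // 2
    b = n - a - h
    valid = b >= 0
    h, a, b = h[valid], a[valid], b[valid]
    logp = (
        gammaln(n + 1)
        - gammaln(a + 1)
        - gammaln(b + 1)
        - gammaln(h + 1)
        + h * np.log(2.0)
    )
    return h, logp - logsumexp(logp)


def hwe_het_pvalues(n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact HWE p-value for every admissible heterozygote count.

    Probability-ordering convention: the p-value of an observed ``h`` is the
    total probability of all heterozygote counts whose conditional
    probability does not exceed that of ``h`` (with a 1e-12 relative tie
    tolerance).  Returns ``(h_values, p_values)``.
    """
    h, logp = _het_log_probs(n, m)
    p = np.exp(logp)
    order = np.argsort(p)
    csum = np.cumsum(p[order])
    pvals = np.empty_like(p)
    sorted_p = p[order]
    # rank of the largest probability <= p_obs * (1 + tol)
    idx = np.searchsorted(sorted_p, p * (1.0 + _TIE_RTOL), side="right") - 1
    pvals = np.minimum(csum[idx], 1.0)
    return h, pvals


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditions on the minor-allele count and sums the probabilities of all
    heterozygote configurations no more probable than the observed one.
    Returns a p-value in (0, 1]; a sample with zero copies of the minor
    allele admits exactly one configuration and returns 1.
    """
    n = counts.n
    if n < 1:
        raise ValueError("HWE test requires at least one sample")
    m = counts.minor_allele_count
    if m > n:  # counts given with major/minor swapped; fold
        m = 2 * n - m
    h, pvals = hwe_het_pvalues(n, m)
    obs = counts.n_het
    where = np.nonzero(h == obs)[0]
    if where.size == 0:
        raise ValueError(
            f"heterozygote count {obs} inconsistent with allele count {m}"
        )
    return float(pvals[where[0]])


@dataclass(frozen=True)
class QCThresholds:
    max_variant_missing: float = 0.05
    min_maf: float = 0.01
    lowfreq_maf: float = 0.05
    lowfreq_max_missing: float = 0.01
    min_hwe_p: float = 1e-5
    max_sample_missing: float = 0.10


@dataclass
class QCReport:
    """Outcome of variant- and/or sample-level filtering.

    ``variants``/``samples`` are tables with one row per id carrying the
    computed statistics, a ``pass`` flag and a semicolon-joined ``reasons``
    string (empty iff passing).
    """

    variants: pd.DataFrame = field(default_factory=pd.DataFrame)
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def retained_variants(self) -> list[str]:
        if self.variants.empty:
            return []
        return list(self.variants.loc[self.variants["pass"], "rsid"])

    @property
    def retained_samples(self) -> list[str]:
        if self.samples.empty:
            return []
        return list(self.samples.loc[self.samples["pass"], "sample_id"])


def hard_calls_from_dosages(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to the nearest genotype call (NaN preserved)."""
    calls = np.rint(dosages)
    return calls


def _genotype_counts(calls_col: np.ndarray) -> GenotypeCounts:
    obs = calls_col[np.isfinite(calls_col)].astype(int)
    n0 = int(np.sum(obs == 0))
    n1 = int(np.sum(obs == 1))
    n2 = int(np.sum(obs == 2))
    # orient so the minor allele is the one counted by n_hom_minor
    if 2 * n2 + n1 <= 2 * n0 + n1:
        return GenotypeCounts(n_hom_major=n0, n_het=n1, n_hom_minor=n2)
    return GenotypeCounts(n_hom_major=n2, n_het=n1, n_hom_minor=n0)


def variant_qc(
    matrix: DosageMatrix,
    hard_calls: np.ndarray | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Per-variant filters: missingness, MAF, low-frequency missingness, HWE.

    MAF is computed from non-missing dosages as ``min(mean/2, 1 - mean/2)``;
    the HWE exact test runs on hard genotype calls (supplied, or obtained by
    rounding dosages — appropriate when QC precedes imputation noise).  A
    variant fails iff at least one rule fires; every fired rule is recorded.
    """
    if matrix.n_variants == 0 or matrix.n_samples == 0:
        raise ValueError("variant_qc requires a non-empty matrix")
    if hard_calls is None:
        hard_calls = hard_calls_from_dosages(matrix.dosages)
    t = thresholds
    rows = []
    for j, rsid in enumerate(matrix.variant_ids):
        col = matrix.dosages[:, j]
        observed = np.isfinite(col)
        # direct ratio, not 1 - mean(observed): keeps boundary cases exact
        missing_fraction = float(np.sum(~observed)) / matrix.n_samples
        reasons: list[str] = []
        if observed.any():
            mean = float(col[observed].mean())
            maf = min(mean / 2.0, 1.0 - mean / 2.0)
            hwe_p = hwe_exact_test(_genotype_counts(hard_calls[:, j]))
        else:
            maf = np.nan
            hwe_p = np.nan
        if missing_fraction > t.max_variant_missing:
            reasons.append(f"missing>{t.max_variant_missing:g}")
        if np.isnan(maf) or maf < t.min_maf:
            reasons.append(f"MAF<{t.min_maf:g}")
        if (
            not np.isnan(maf)
            and maf < t.lowfreq_maf
            and missing_fraction > t.lowfreq_max_missing
        ):
            reasons.append(
                f"MAF<{t.lowfreq_maf:g}&missing>{t.lowfreq_max_missing:g}"
            )
        if not np.isnan(hwe_p) and hwe_p < t.min_hwe_p:
            reasons.append(f"HWE p<{t.min_hwe_p:g}")
        rows.append(
            {
                "rsid": rsid,
                "missing_fraction": missing_fraction,
                "maf": maf,
                "hwe_p": hwe_p,
                "pass": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    return QCReport(variants=pd.DataFrame(rows))


def sample_qc(
    matrix: DosageMatrix, thresholds: QCThresholds = QCThresholds()
) -> QCReport:
    """Drop samples missing more than ``max_sample_missing`` of variants."""
    if matrix.n_variants == 0 or matrix.n_samples == 0:
        raise ValueError("sample_qc requires a non-empty matrix")
    missing = np.mean(~np.isfinite(matrix.dosages), axis=1)
    ok = missing <= thresholds.max_sample_missing  # strict ">" fails
    df = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "missing_fraction": missing,
            "pass": ok,
            "reasons": np.where(
                ok, "", f"missing>{thresholds.max_sample_missing:g}"
            ),
        }
    )
    return QCReport(samples=df)


def apply_qc(
    matrix: DosageMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[DosageMatrix, QCReport]:
    """Alternate variant and sample filters until a fixed point.

    Removing samples can change variant missingness and vice versa, so the
    two filters are iterated on the retained set until neither removes
    anything; the fixpoint is unique for a given input.
    """
    current = matrix
    last_v: QCReport | None = None
    last_s: QCReport | None = None
    while True:
        vrep = variant_qc(current, thresholds=thresholds)
        keep_v = vrep.retained_variants
        if not keep_v:
            raise ValueError("all variants removed by QC")
        trimmed = (
            current
            if len(keep_v) == current.n_variants
            else current.subset(variant_ids=keep_v)
        )
        srep = sample_qc(trimmed, thresholds=thresholds)
        keep_s = srep.retained_samples
        if not keep_s:
            raise ValueError("all samples removed by QC")
        changed = len(keep_v) < current.n_variants or len(keep_s) < trimmed.n_samples
        current = (
            trimmed
            if len(keep_s) == trimmed.n_samples
            else trimmed.subset(sample_ids=keep_s)
        )
        last_v, last_s = vrep, srep
        if not changed:
            break
    return current, QCReport(variants=last_v.variants, samples=last_s.samples)


def compute_pcs(matrix: DosageMatrix, k: int) -> pd.DataFrame:
    """Principal components of the column-standardised dosage matrix.

    Missing dosages are mean-imputed per variant, each variant column is
    centred and scaled to unit variance (zero-variance variants dropped),
    and the leading ``k`` left singular vectors scaled by their singular
    values form the per-sample coordinates.  Signs are fixed by making each
    component's largest-magnitude variant loading positive.  Requesting more
    components than the rank returns the available ones with a warning.
    """
    if matrix.n_samples < 2 or matrix.n_variants < 2:
        raise ValueError("PCA requires at least 2 samples and 2 variants")
    if k < 1:
        raise ValueError("k must be >= 1")
    X = matrix.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_rows, nan_cols = np.nonzero(~np.isfinite(X))
    X[nan_rows, nan_cols] = col_mean[nan_cols]
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S.max() * max(X.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int(np.sum(S > tol))
    if k > rank:
        warnings.warn(
            f"requested {k} components but rank is {rank}; returning {rank}"
        )
        k = rank
    scores = U[:, :k] * S[:k]
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            scores[:, c] = -scores[:, c]
    return pd.DataFrame(
        scores,
        index=pd.Index(matrix.sample_ids, name="sample_id"),
        columns=[f"pc{i + 1}" for i in range(k)],
    )
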