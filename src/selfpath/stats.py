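"""Per-individual genotypic counts, homozygosity, and cohort/marker statistics.

The atom of every statistic here is the triple of genotypic class counts
(n_AA, n_AB, n_BB) for one individual over its genotyped SNPs.  Observed
homozygosity is the fraction of genotyped calls that are homozygous; cohort
summaries add Hardy–Weinberg expectations and the inbreeding coefficient
F = 1 − Ho/He.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AA, AB, BB, MISSING, GenotypeMatrix


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotypic class counts for one individual.

    Counts are real-valued so that surrogate (sibling-averaged) parents and
    Mendelian expectations can share the type.
    """

    n_aa: float
    n_ab: float
    n_bb: float
    n_missing: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_aa, self.n_ab, self.n_bb, self.n_missing) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> float:
        """Genotyped total (missing excluded)."""
        return self.n_aa + self.n_ab + self.n_bb

    @property
    def n_hom(self) -> float:
        return self.n_aa + self.n_bb

    def as_array(self) -> np.ndarray:
        return np.array([self.n_aa, self.n_ab, self.n_bb], dtype=float)


def count_genotypes(matrix: GenotypeMatrix, sample_id: str) -> GenotypeCounts:
    """Count AA/AB/BB/missing calls in one sample's row."""
    row = matrix.row(sample_id)
    return GenotypeCounts(
        n_aa=int((row == AA).sum()),
        n_ab=int((row == AB).sum()),
        n_bb=int((row == BB).sum()),
        n_missing=int((row == MISSING).sum()),
    )


def observed_homozygosity(counts: GenotypeCounts) -> float:
    """(n_AA + n_BB) / genotyped total — fraction of homozygous calls."""
    if counts.total <= 0:
        raise ValueError("no genotyped calls: homozygosity undefined")
    return counts.n_hom / counts.total


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if alpha <= 0 or n_tests < 1:
        raise ValueError("alpha must be > 0 and n_tests >= 1")
    return alpha / n_tests


def hwe_chi_square(n_aa: float, n_ab: float, n_bb: float) -> tuple[float, float]:
    """Pearson chi-square (df=1) of genotype counts against p^2, 2pq, q^2.

    One allele frequency is estimated from the data, leaving a single degree
    of freedom for three genotype classes.  No continuity correction.
    """
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("no genotyped calls")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    if p in (0.0, 1.0):  # monomorphic: test undefined
        return float("nan"), float("nan")
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(sps.chi2.sf(chi2, df=1))


def marker_stats(matrix: GenotypeMatrix, min_informative: int = 2) -> pd.DataFrame:
    """Per-marker genotype counts, MAF and HWE test.

    Markers with fewer than ``min_informative`` genotyped samples, or
    monomorphic markers, are flagged and not scored.  Returns a DataFrame
    indexed by marker id with columns n_aa, n_ab, n_bb, n_missing, maf,
    hwe_chi2, hwe_p, flag.
    """
    calls = matrix.calls
    n_aa = (calls == AA).sum(axis=0)
    n_ab = (calls == AB).sum(axis=0)
    n_bb = (calls == BB).sum(axis=0)
    n_missing = (calls == MISSING).sum(axis=0)
    typed = n_aa + n_ab + n_bb
    rows = []
    for j, mk in enumerate(matrix.marker_ids):
        maf = chi2 = p = float("nan")
        flag = ""
        if typed[j] < min_informative:
            flag = "too_few_informative"
        else:
            p_b = (2 * n_bb[j] + n_ab[j]) / (2 * typed[j])
            maf = min(p_b, 1 - p_b)
            if maf == 0.0:
                flag = "monomorphic"
            else:
                chi2, p = hwe_chi_square(n_aa[j], n_ab[j], n_bb[j])
                # min expected class count p^2*n (or q^2*n); flag sparse tests
                if min(maf * maf, (1 - maf) ** 2) * typed[j] < 1:
                    flag = "low_expected_count"
        rows.append((mk, n_aa[j], n_ab[j], n_bb[j], n_missing[j], maf, chi2, p, flag))
    return pd.DataFrame(
        rows,
        columns=["marker", "n_aa", "n_ab", "n_bb", "n_missing", "maf", "hwe_chi2", "hwe_p", "flag"],
    ).set_index("marker")


def per_sample_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Genotypic counts and observed homozygosity per sample."""
    rows = []
    for sid in matrix.sample_ids:
        c = count_genotypes(matrix, sid)
        rows.append(
            (sid, c.n_aa, c.n_ab, c.n_bb, c.total, observed_homozygosity(c) if c.total else np.nan)
        )
    return pd.DataFrame(
        rows, columns=["sample", "n_aa", "n_ab", "n_bb", "total", "obs_hom"]
    ).set_index("sample")


@dataclass(frozen=True)
class CohortStats:
    """Cohort-level homozygosity and inbreeding summary."""

    n_samples: int
    n_markers_polymorphic: int
    mean_obs_hom: float
    sd_obs_hom: float
    median_obs_hom: float
    mean_exp_hom_hwe: float
    f: float
    maf_mean: float
    maf_sd: float
    maf_median: float
    n_maf_ge: dict[float, int]


def cohort_summary(
    matrix: GenotypeMatrix,
    sample_subset: list[str] | None = None,
    f_method: str = "ratio-of-means",
    maf_thresholds: tuple[float, ...] = (0.01, 0.05, 0.25),
) -> CohortStats:
    """Cohort homozygosity, HWE-expected homozygosity and inbreeding coefficient.

    Expected homozygosity under HWE is the per-marker mean of ``1 - 2pq``
    averaged over polymorphic markers (unweighted).  F is the heterozygosity
    deficit ``1 - Ho/He``:

    - ``ratio-of-means`` (default): Ho and He are each averaged over markers
      first, then the ratio is taken;
    - ``per-locus-mean``: F is computed per marker and averaged.

    Monomorphic markers (He = 0) are excluded from both estimators.
    """
    if sample_subset is not None:
        if not sample_subset:
            raise ValueError("empty sample subset")
        matrix = matrix.subset(samples=sample_subset)
    if matrix.n_samples < 2:
        raise ValueError("cohort summary needs at least 2 samples")

    hom = per_sample_stats(matrix)["obs_hom"].to_numpy(dtype=float)

    ms = marker_stats(matrix)
    scored = ms[ms["flag"].isin(["", "low_expected_count"])]
    if scored.empty:
        raise ValueError("no polymorphic markers: F and He undefined")
    typed = (scored["n_aa"] + scored["n_ab"] + scored["n_bb"]).to_numpy(dtype=float)
    p = (2 * scored["n_bb"] + scored["n_ab"]).to_numpy(dtype=float) / (2 * typed)
    he = 2 * p * (1 - p)
    ho = scored["n_ab"].to_numpy(dtype=float) / typed
    if f_method == "ratio-of-means":
        f = 1.0 - ho.mean() / he.mean()
    elif f_method == "per-locus-mean":
        f = float(np.mean(1.0 - ho / he))
    else:
        raise ValueError(f"unknown f_method: {f_method!r}")

    maf = ms["maf"].dropna().to_numpy(dtype=float)
    return CohortStats(
        n_samples=matrix.n_samples,
        n_markers_polymorphic=len(scored),
        mean_obs_hom=float(np.mean(hom)),
        sd_obs_hom=float(np.std(hom, ddof=1)),
        median_obs_hom=float(np.median(hom)),
        mean_exp_hom_hwe=float(np.mean(1.0 - he)),
        f=float(f),
        maf_mean=float(np.mean(maf)) if maf.size else float("nan"),
        maf_sd=float(np.std(maf, ddof=1)) if maf.size > 1 else float("nan"),
        maf_median=float(np.median(maf)) if maf.size else float("nan"),
        n_maf_ge={t: int((maf >= t).sum()) for t in maf_thresholds},
    )
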