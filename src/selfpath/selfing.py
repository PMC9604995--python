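"""Mendelian homozygosity expectations under selfing, deviation tests, and
family-level selection — the core model of the package.

Under self-pollination each heterozygous (AB) locus segregates 1:2:1, so from
a parent's genotypic counts (n_AA, n_AB, n_BB) the offspring expectation is

    E[AA] = n_AA + n_AB/4,   E[AB] = n_AB/2,   E[BB] = n_BB + n_AB/4,

i.e. each homozygous class gains 25 % of the parent's heterozygous calls and
the heterozygous class halves.  Equivalently, observed homozygosity h
propagates as ``h_g = 1 - (1 - h_0) / 2**g``.  Each offspring is scored by a
Pearson chi-square (df = 2) of its genotypic counts against that expectation,
and ranked within its family by standardized homozygosity
``z = (h - mu) / sigma``.

:class:`SelfingFamilyModel` bundles the bookkeeping: built from a genotype
matrix plus a selfing pedigree (or directly from a table of genotypic
counts), its :meth:`~SelfingFamilyModel.fit` returns a
:class:`SelfingResults` with per-offspring and per-family tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeMatrix, PedigreeRecord, validate_pedigree
from .stats import GenotypeCounts, count_genotypes, observed_homozygosity


@dataclass(frozen=True)
class ExpectedCounts:
    """Real-valued Mendelian expectation of offspring genotypic counts."""

    e_aa: float
    e_ab: float
    e_bb: float

    @property
    def total(self) -> float:
        return self.e_aa + self.e_ab + self.e_bb

    @property
    def hom_fraction(self) -> float:
        return (self.e_aa + self.e_bb) / self.total

    def as_array(self) -> np.ndarray:
        return np.array([self.e_aa, self.e_ab, self.e_bb], dtype=float)


def expected_next_counts(
    parent: GenotypeCounts, rescale_to: float | None = None
) -> ExpectedCounts:
    """One-generation selfing expectation from a parent's genotypic counts.

    The expectation conserves the parent's genotyped total.  Offspring are in
    practice genotyped at slightly different totals; by default the expected
    counts are *not* rescaled to the offspring total, so the chi-square is
    taken directly against the parent-scale expectation.  Pass
    ``rescale_to=offspring_total`` to rescale (statistically cleaner when
    totals differ appreciably).
    """
    if parent.total <= 0:
        raise ValueError("parent has no genotyped calls")
    e = ExpectedCounts(
        e_aa=parent.n_aa + parent.n_ab / 4.0,
        e_ab=parent.n_ab / 2.0,
        e_bb=parent.n_bb + parent.n_ab / 4.0,
    )
    if rescale_to is not None:
        s = rescale_to / e.total
        e = ExpectedCounts(e.e_aa * s, e.e_ab * s, e.e_bb * s)
    return e


def propagate_homozygosity(h0: float, g: int) -> float:
    """Expected homozygosity after ``g`` selfed generations: 1 - (1 - h0)/2**g."""
    if not 0.0 <= h0 <= 1.0:
        raise ValueError(f"h0 must be in [0, 1], got {h0}")
    if g < 0:
        raise ValueError("g must be >= 0")
    if g == 0:
        return float(h0)
    return 1.0 - (1.0 - h0) / 2.0**g


@dataclass(frozen=True)
class DeviationTest:
    """Chi-square test of offspring genotypic counts against Mendelian expectation."""

    chi2: float
    df: int
    p: float
    direction: str  # "above" | "below" expectation in homozygous fraction
    significant: bool
    infinite_deviation: bool = False


def mendelian_deviation_test(
    observed: GenotypeCounts,
    parent: GenotypeCounts,
    alpha: float = 0.05,
    rescale: bool = False,
) -> DeviationTest:
    """Pearson chi-square (df = 2) of observed counts vs the selfing expectation.

    ``direction`` reports whether the offspring's homozygous fraction lies
    above or below the expected fraction.  An expected class of zero with
    non-zero observed count is flagged as an infinite deviation.
    """
    if observed.total <= 0:
        raise ValueError("offspring has no genotyped calls")
    expected = expected_next_counts(parent, rescale_to=observed.total if rescale else None)
    obs = observed.as_array()
    exp = expected.as_array()
    direction = "above" if observed_homozygosity(observed) >= expected.hom_fraction else "below"
    if np.any((exp == 0) & (obs > 0)):
        return DeviationTest(math.inf, 2, 0.0, direction, True, infinite_deviation=True)
    mask = exp > 0
    chi2 = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
    p = float(sps.chi2.sf(chi2, df=2))
    return DeviationTest(chi2, 2, p, direction, p <= alpha)


def surrogate_parent_counts(sibling_counts: Sequence[GenotypeCounts]) -> GenotypeCounts:
    """Class-wise mean of sibling genotypic counts, standing in for an
    ungenotyped parent."""
    if not sibling_counts:
        raise ValueError("need at least one sibling to build a surrogate parent")
    arr = np.array([c.as_array() for c in sibling_counts], dtype=float).mean(axis=0)
    miss = float(np.mean([c.n_missing for c in sibling_counts]))
    return GenotypeCounts(n_aa=arr[0], n_ab=arr[1], n_bb=arr[2], n_missing=miss)


def standardized_homozygosity(family_homs: Sequence[float]) -> np.ndarray:
    """z_i = (h_i - mu) / sigma within a family; sigma uses the n-1 denominator."""
    h = np.asarray(family_homs, dtype=float)
    if h.size < 2:
        raise ValueError("standardization needs at least 2 offspring")
    sigma = h.std(ddof=1)
    if np.ptp(h) == 0 or sigma == 0:
        raise ValueError("all offspring homozygosities equal: z undefined (sigma = 0)")
    return (h - h.mean()) / sigma


@dataclass(frozen=True)
class FamilySummary:
    """One family's homozygosity summary (one column of the family report)."""

    family_id: str
    parent_id: str
    n_offspring: int
    generation: str
    starting_hom: float  # parent's observed homozygosity
    expected_mean_hom: float
    observed_mean_hom: float
    sd: float
    min_hom: float
    max_hom: float
    rmsd: float
    t_stat: float
    t_p: float


def family_summary(
    offspring: Sequence[GenotypeCounts],
    parent: GenotypeCounts,
    alpha: float = 0.05,
    family_id: str = "",
    parent_id: str = "",
    generation: str = "",
) -> FamilySummary:
    """Family-level summary of observed vs Mendelian-expected homozygosity.

    mu/sigma/min/max are taken over full-precision per-offspring observed
    homozygosities (sigma with the n-1 denominator); RMSD against the
    one-generation prediction uses the n denominator.  The t statistic is a
    one-sample two-sided t of per-offspring (observed - expected) homozygous
    call counts against zero.
    """
    if len(offspring) < 2:
        raise ValueError("family summary needs at least 2 offspring")
    homs = np.array([observed_homozygosity(c) for c in offspring])
    h_parent = observed_homozygosity(parent)
    expected_hom = propagate_homozygosity(h_parent, 1)
    rmsd = float(np.sqrt(np.mean((homs - expected_hom) ** 2)))
    exp_counts = expected_next_counts(parent)
    diffs = np.array([c.n_hom for c in offspring]) - (exp_counts.e_aa + exp_counts.e_bb)
    if np.allclose(diffs, 0.0):
        t_res = type("T", (), {"statistic": 0.0, "pvalue": 1.0})  # exactly at expectation
    else:
        t_res = sps.ttest_1samp(diffs, 0.0)
    return FamilySummary(
        family_id=family_id,
        parent_id=parent_id,
        n_offspring=len(offspring),
        generation=generation,
        starting_hom=h_parent,
        expected_mean_hom=expected_hom,
        observed_mean_hom=float(homs.mean()),
        sd=float(homs.std(ddof=1)),
        min_hom=float(homs.min()),
        max_hom=float(homs.max()),
        rmsd=rmsd,
        t_stat=float(t_res.statistic),
        t_p=float(t_res.pvalue),
    )


def rank_and_select(
    offspring_table: pd.DataFrame,
    k: int | None = None,
    z_cutoff: float | None = None,
) -> pd.DataFrame:
    """Select candidates to advance, per family, from a fitted offspring table.

    Ordering is deterministic: z descending, ties broken by individual id
    ascending.  Exactly one of ``k`` (top-k per family) or ``z_cutoff``
    (all offspring with z >= cutoff) must be given.
    """
    if (k is None) == (z_cutoff is None):
        raise ValueError("give exactly one of k or z_cutoff")
    ranked = offspring_table.dropna(subset=["z"]).copy()
    ranked = ranked.sort_values(
        by=["family", "z", "individual"], ascending=[True, False, True]
    )
    out = []
    for fam, grp in ranked.groupby("family", sort=True):
        if k is not None:
            if k > len(grp):
                raise ValueError(f"k={k} exceeds family {fam!r} size {len(grp)}")
            out.append(grp.head(k))
        else:
            out.append(grp[grp["z"] >= z_cutoff])
    return pd.concat(out, axis=0) if out else ranked.iloc[:0]


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class SelfingFamilyModel:
    """Homozygosity-tracking model for selfed families.

    Parameters
    ----------
    counts
        Mapping individual id -> :class:`GenotypeCounts`.  Individuals that
        appear in the pedigree but were never genotyped are simply absent.
    pedigree
        Selfing pedigree records (validated and topologically sorted).

    Use :meth:`from_matrix` to build from an AB-coded genotype matrix, or
    :meth:`from_counts_table` to build from a per-individual counts table
    (the "counts-only" input mode, for published summary tables).
    """

    def __init__(
        self,
        counts: Mapping[str, GenotypeCounts],
        pedigree: Sequence[PedigreeRecord],
    ) -> None:
        self.counts = dict(counts)
        self.pedigree = validate_pedigree(list(pedigree))
        self._by_id = {r.individual_id: r for r in self.pedigree}
        unknown = set(self.counts) - set(self._by_id)
        if unknown:
            raise ValueError(f"counts given for ids absent from pedigree: {sorted(unknown)}")

    @classmethod
    def from_matrix(
        cls, matrix: GenotypeMatrix, pedigree: Sequence[PedigreeRecord]
    ) -> "SelfingFamilyModel":
        counts = {
            r.individual_id: count_genotypes(matrix, r.individual_id)
            for r in pedigree
            if r.individual_id in matrix
        }
        return cls(counts, pedigree)

    @classmethod
    def from_counts_table(cls, table: pd.DataFrame) -> "SelfingFamilyModel":
        """Build from a DataFrame with columns individual, parent, generation,
        family, n_aa, n_ab, n_bb (counts may be NaN for ungenotyped members)."""
        records = []
        counts: dict[str, GenotypeCounts] = {}
        for _, row in table.iterrows():
            ind = str(row["individual"])
            parent = row.get("parent")
            parent = None if (pd.isna(parent) or str(parent).strip() == "") else str(parent)
            records.append(
                PedigreeRecord(ind, parent, str(row["generation"]), str(row["family"]))
            )
            if not pd.isna(row["n_aa"]):
                counts[ind] = GenotypeCounts(
                    float(row["n_aa"]), float(row["n_ab"]), float(row["n_bb"])
                )
        return cls(counts, records)

    # -- parent resolution ---------------------------------------------------

    def _resolve_parent_counts(
        self, record: PedigreeRecord, parent_override: Mapping[str, str]
    ) -> tuple[GenotypeCounts | None, bool]:
        """Counts to use as the Mendelian parent of ``record``.

        Returns (counts, is_surrogate).  If the true parent is ungenotyped,
        either a named override individual (per family) or the class-wise mean
        of the parent's genotyped siblings stands in.
        """
        pid = record.parent_id
        if pid is None:
            return None, False
        if pid in self.counts:
            return self.counts[pid], False
        if record.family_id in parent_override:
            ov = parent_override[record.family_id]
            if ov not in self.counts:
                raise ValueError(f"override individual {ov!r} has no counts")
            return self.counts[ov], True
        parent_rec = self._by_id[pid]
        sibs = [
            r.individual_id
            for r in self.pedigree
            if r.parent_id == parent_rec.parent_id
            and r.individual_id != pid
            and r.individual_id in self.counts
        ]
        if parent_rec.parent_id is None or not sibs:
            return None, False
        return surrogate_parent_counts([self.counts[s] for s in sibs]), True

    # -- fitting ---------------------------------------------------------------

    def fit(
        self,
        alpha: float = 0.05,
        rescale_expected: bool = False,
        parent_override: Mapping[str, str] | None = None,
    ) -> "SelfingResults":
        """Run the per-offspring deviation tests and family summaries.

        Parameters
        ----------
        alpha
            Significance level of the per-offspring chi-square test.
        rescale_expected
            Rescale expected counts to each offspring's genotyped total
            (default off: the chi-square is taken on the parent scale).
        parent_override
            Mapping family id -> individual id whose counts replace that
            family's parent (e.g. a designated sibling of an ungenotyped
            parent).  Default: ungenotyped parents are replaced by the mean
            counts of their genotyped siblings.
        """
        override = dict(parent_override or {})
        rows = []
        for rec in self.pedigree:
            c = self.counts.get(rec.individual_id)
            if c is None:
                continue
            parent_counts, surrogate = self._resolve_parent_counts(rec, override)
            row = {
                "individual": rec.individual_id,
                "family": rec.family_id,
                "generation": rec.generation,
                "parent": rec.parent_id,
                "n_aa": float(c.n_aa),
                "n_ab": float(c.n_ab),
                "n_bb": float(c.n_bb),
                "total": float(c.total),
                "obs_hom": observed_homozygosity(c),
                "exp_hom": np.nan,
                "chi2": np.nan,
                "p": np.nan,
                "significant": False,
                "direction": "",
                "surrogate_parent": surrogate,
                "z": np.nan,
                "rank": np.nan,
            }
            if parent_counts is not None:
                test = mendelian_deviation_test(c, parent_counts, alpha, rescale_expected)
                row.update(
                    exp_hom=propagate_homozygosity(observed_homozygosity(parent_counts), 1),
                    chi2=test.chi2,
                    p=test.p,
                    significant=test.significant,
                    direction=test.direction,
                )
            rows.append(row)
        offspring = pd.DataFrame(rows)

        families = []
        if not offspring.empty:
            for fam, grp in offspring.groupby("family", sort=True):
                top_gen = max(
                    self._by_id[i].generation_index for i in grp["individual"]
                )
                group = grp[
                    [self._by_id[i].generation_index == top_gen for i in grp["individual"]]
                ]
                if len(group) < 2:
                    continue
                parents = set(group["parent"])
                if len(parents) != 1 or parents == {None}:
                    continue  # mixed or founder group: no single selfed parent
                homs = group["obs_hom"].to_numpy()
                if np.ptp(homs) > 0:
                    z = standardized_homozygosity(homs)
                    order = np.lexsort((group["individual"].to_numpy(), -z))
                    ranks = np.empty(len(z), dtype=int)
                    ranks[order] = np.arange(1, len(z) + 1)
                    offspring.loc[group.index, "z"] = z
                    offspring.loc[group.index, "rank"] = ranks
                rec0 = self._by_id[group["individual"].iloc[0]]
                parent_counts, _ = self._resolve_parent_counts(rec0, override)
                if parent_counts is None:
                    continue
                fs = family_summary(
                    [self.counts[i] for i in group["individual"]],
                    parent_counts,
                    alpha=alpha,
                    family_id=str(fam),
                    parent_id=str(group["parent"].iloc[0]),
                    generation=rec0.generation,
                )
                families.append(fs)

        fam_df = pd.DataFrame(
            [
                {
                    "family": f.family_id,
                    "parent": f.parent_id,
                    "generation": f.generation,
                    "n_offspring": f.n_offspring,
                    "starting_hom": f.starting_hom,
                    "expected_mean_hom": f.expected_mean_hom,
                    "observed_mean_hom": f.observed_mean_hom,
                    "sd": f.sd,
                    "min_hom": f.min_hom,
                    "max_hom": f.max_hom,
                    "rmsd": f.rmsd,
                    "t_stat": f.t_stat,
                    "t_p": f.t_p,
                }
                for f in families
            ]
        )
        if not fam_df.empty:
            fam_df = fam_df.set_index("family")
        return SelfingResults(self, offspring, fam_df, alpha)


class SelfingResults:
    """Fitted per-offspring and per-family homozygosity tables.

    Attributes
    ----------
    offspring : pandas.DataFrame
        One row per genotyped pedigree member: counts, observed and expected
        homozygosity, chi-square deviation test, standardized homozygosity z
        and within-family rank.
    families : pandas.DataFrame
        One row per family: parent, expected vs observed mean homozygosity,
        sd, min/max, RMSD and the family t test.
    """

    def __init__(
        self,
        model: SelfingFamilyModel,
        offspring: pd.DataFrame,
        families: pd.DataFrame,
        alpha: float,
    ) -> None:
        self.model = model
        self.offspring = offspring
        self.families = families
        self.alpha = alpha

    def select(self, k: int | None = None, z_cutoff: float | None = None) -> pd.DataFrame:
        """Top offspring to advance per family (z descending, id tie-break)."""
        return rank_and_select(self.offspring, k=k, z_cutoff=z_cutoff)

    def summary(self, precision: tuple[int, int, int] = (3, 2, 3)) -> str:
        """Human-readable report; homozygosities, chi-square and z rounded to
        the given decimal places (default 3/2/3)."""
        hp, cp, zp = precision
        off = self.offspring.copy()
        for col in ("obs_hom", "exp_hom"):
            off[col] = off[col].round(hp)
        off["chi2"] = off["chi2"].round(cp)
        off["z"] = off["z"].round(zp)
        off["sig"] = np.where(off["significant"], "**", "ns")
        off.loc[off["chi2"].isna(), "sig"] = ""
        cols = [
            "family", "generation", "individual", "n_aa", "n_ab", "n_bb",
            "total", "obs_hom", "exp_hom", "z", "chi2", "sig",
        ]
        lines = [
            "Selfing homozygosity analysis",
            f"alpha = {self.alpha}",
            "",
            "Per-offspring deviation from Mendelian expectation:",
            off[cols].to_string(index=False),
        ]
        if not self.families.empty:
            fam = self.families.copy()
            for col in (
                "starting_hom", "expected_mean_hom", "observed_mean_hom",
                "sd", "min_hom", "max_hom", "rmsd",
            ):
                fam[col] = fam[col].round(hp)
            fam["t_stat"] = fam["t_stat"].round(3)
            fam["t_p"] = fam["t_p"].round(3)
            lines += ["", "Family summaries:", fam.T.to_string()]
        return "\n".join(lines)

    def save_reports(self, outdir) -> None:
        """Write offspring and family tables (full precision) as CSV."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.offspring.to_csv(out / "offspring_report.csv", index=False)
        self.families.to_csv(out / "family_report.csv")
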