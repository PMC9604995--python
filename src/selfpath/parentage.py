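"""Selfed parent-offspring verification by opposing-genotype counting.

Under selfing, a homozygous parental locus cannot segregate: parent AA can
only give AA, parent BB only BB.  A heterozygous parent (AB) is compatible
with any offspring call.  Counting loci that violate this rule separates true
selfed offspring (violations only from genotyping error) from mislabeled or
outcrossed individuals (violations at a large fraction of polymorphic loci).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AA, BB, MISSING, GenotypeMatrix, PedigreeRecord


def selfing_incompatibility(parent_call: int, offspring_call: int) -> bool:
    """True iff the (parent, offspring) call pair is impossible under selfing.

    Both calls must be non-missing: parent AA with offspring AB or BB, or
    parent BB with offspring AA or AB, is incompatible; parent AB never is.
    """
    if parent_call == MISSING or offspring_call == MISSING:
        raise ValueError("incompatibility undefined for missing calls")
    if parent_call == AA:
        return offspring_call != AA
    if parent_call == BB:
        return offspring_call != BB
    return False


@dataclass(frozen=True)
class ParentageResult:
    offspring_id: str
    parent_id: str
    n_compared: int
    n_incompatible: int
    verdict: str  # "confirmed" | "excluded" | "inconclusive"

    @property
    def incompatibility_rate(self) -> float:
        return self.n_incompatible / self.n_compared if self.n_compared else float("nan")


def pair_incompatibility(
    parent_row: np.ndarray, offspring_row: np.ndarray
) -> tuple[int, int]:
    """(n_compared, n_incompatible) over loci non-missing in both members."""
    ok = (parent_row != MISSING) & (offspring_row != MISSING)
    p, o = parent_row[ok], offspring_row[ok]
    incompat = ((p == AA) & (o != AA)) | ((p == BB) & (o != BB))
    return int(ok.sum()), int(incompat.sum())


def verify_parentage(
    matrix: GenotypeMatrix,
    pedigree: Sequence[PedigreeRecord],
    max_rate: float = 0.02,
    min_compared: int = 500,
) -> list[ParentageResult]:
    """Screen every genotyped offspring against its genotyped selfed parent.

    Verdicts: ``excluded`` when the incompatibility rate exceeds ``max_rate``
    (with at least ``min_compared`` comparable loci), ``inconclusive`` when too
    few loci are comparable, ``confirmed`` otherwise.  The default
    ``max_rate`` of 2 % tolerates ~1 % per-call genotyping error hitting
    either member; pairs from unrelated individuals on a polymorphic panel
    typically show incompatibilities at hundreds of loci.
    """
    results = []
    for rec in pedigree:
        if rec.parent_id is None or rec.individual_id not in matrix:
            continue
        if rec.parent_id not in matrix:
            continue
        n_cmp, n_inc = pair_incompatibility(
            matrix.row(rec.parent_id), matrix.row(rec.individual_id)
        )
        if n_cmp < min_compared:
            verdict = "inconclusive"
        elif n_cmp and n_inc / n_cmp > max_rate:
            verdict = "excluded"
        else:
            verdict = "confirmed"
        results.append(
            ParentageResult(rec.individual_id, rec.parent_id, n_cmp, n_inc, verdict)
        )
    return results


def parentage_table(results: Sequence[ParentageResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "offspring": [r.offspring_id for r in results],
            "parent": [r.parent_id for r in results],
            "n_compared": [r.n_compared for r in results],
            "n_incompatible": [r.n_incompatible for r in results],
            "incompatibility_rate": [r.incompatibility_rate for r in results],
            "verdict": [r.verdict for r in results],
        }
    )
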