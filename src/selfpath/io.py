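"""Reading, writing and quality control of AB-coded SNP genotype matrices.

Genotypes follow the Illumina AB convention for biallelic SNPs: calls are
``AA``, ``AB`` or ``BB`` (A/T nucleotides map to allele "A", G/C to allele
"B").  Internally calls are stored as the allele-B dosage in ``int8``:
0 = AA, 1 = AB, 2 = BB, -1 = missing.  The dosage coding makes homozygosity,
parentage and distance computations simple vectorised arithmetic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AA: int = 0
AB: int = 1
BB: int = 2
MISSING: int = -1

#: tokens accepted as a missing call on input; "--" is always written on output
MISSING_TOKENS = frozenset({"--", "NC", ""})

_CALL_TO_CODE = {"AA": AA, "AB": AB, "BA": AB, "BB": BB}
_CODE_TO_CALL = {AA: "AA", AB: "AB", BB: "BB", MISSING: "--"}


class GenotypeParseError(ValueError):
    """Malformed genotype or pedigree input (ragged rows, bad tokens, duplicate ids)."""


def encode_call(token: str, missing_tokens: frozenset[str] = MISSING_TOKENS) -> int:
    token = token.strip()
    if token in missing_tokens:
        return MISSING
    try:
        return _CALL_TO_CODE[token.upper()]
    except KeyError:
        raise GenotypeParseError(f"unknown genotype call token: {token!r}") from None


@dataclass
class GenotypeMatrix:
    """Samples x markers grid of AB-coded SNP calls.

    Parameters
    ----------
    calls
        ``int8`` array of shape (n_samples, n_markers) with values in
        {0, 1, 2, -1} (AA, AB, BB, missing).
    sample_ids, marker_ids
        Unique identifiers for rows and columns.
    """

    calls: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        n, m = self.calls.shape
        if n < 1 or m < 1:
            raise ValueError("matrix needs at least one sample and one marker")
        if n != len(self.sample_ids) or m != len(self.marker_ids):
            raise ValueError("calls shape does not match id lists")
        if len(set(self.sample_ids)) != n:
            raise GenotypeParseError("duplicate sample ids")
        if len(set(self.marker_ids)) != m:
            raise GenotypeParseError("duplicate marker ids")
        bad = ~np.isin(self.calls, (AA, AB, BB, MISSING))
        if bad.any():
            raise ValueError(f"invalid call codes present: {np.unique(self.calls[bad])}")
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def row(self, sample_id: str) -> np.ndarray:
        """Dosage-coded call vector for one sample."""
        try:
            return self.calls[self._sample_index[sample_id]]
        except KeyError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._sample_index

    def sample_call_rate(self) -> pd.Series:
        """Fraction of non-missing calls per sample, across all current markers."""
        return pd.Series(
            (self.calls != MISSING).mean(axis=1), index=self.sample_ids, name="call_rate"
        )

    def marker_call_frequency(self) -> pd.Series:
        """Fraction of non-missing calls per marker, across all current samples."""
        return pd.Series(
            (self.calls != MISSING).mean(axis=0), index=self.marker_ids, name="call_frequency"
        )

    def marker_maf(self) -> pd.Series:
        """Minor allele frequency per marker (folded to <= 0.5) over current samples."""
        ok = self.calls != MISSING
        dosage = np.where(ok, self.calls, 0)
        n_typed = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_b = dosage.sum(axis=0) / np.maximum(2 * n_typed, 1)
        p_b = np.where(n_typed > 0, p_b, np.nan)
        return pd.Series(np.minimum(p_b, 1.0 - p_b), index=self.marker_ids, name="maf")

    def subset(
        self,
        samples: Sequence[str] | None = None,
        markers: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        samples = list(samples) if samples is not None else self.sample_ids
        markers = list(markers) if markers is not None else self.marker_ids
        ridx = [self._sample_index[s] for s in samples]
        midx_map = {m: j for j, m in enumerate(self.marker_ids)}
        cidx = [midx_map[m] for m in markers]
        return GenotypeMatrix(self.calls[np.ix_(ridx, cidx)], samples, markers)

    def to_dataframe(self) -> pd.DataFrame:
        """String-call DataFrame (samples in rows), as written to disk."""
        mapped = np.vectorize(_CODE_TO_CALL.get)(self.calls)
        return pd.DataFrame(mapped, index=self.sample_ids, columns=self.marker_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        codes = np.empty(df.shape, dtype=np.int8)
        values = df.to_numpy(dtype=object)
        for (i, j), tok in np.ndenumerate(values):
            codes[i, j] = encode_call(str(tok))
        return cls(codes, list(df.index.astype(str)), list(df.columns.astype(str)))


def read_genotype_matrix(
    path,
    sep: str | None = None,
    transpose: bool = False,
    missing_tokens: Iterable[str] = MISSING_TOKENS,
) -> GenotypeMatrix:
    """Read a delimited genotype file: header row of marker ids, first column sample ids.

    Unknown call tokens raise :class:`GenotypeParseError` rather than being
    coerced to missing; ragged rows and duplicate ids are errors.  ``transpose``
    handles files with markers in rows.
    """
    missing_tokens = frozenset(t.strip() for t in missing_tokens)
    path = str(path)
    with open(path, newline="") as fh:
        if sep is None:
            first = fh.readline()
            sep = "\t" if first.count("\t") >= first.count(",") else ","
            fh.seek(0)
        rows = list(csv.reader(fh, delimiter=sep))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise GenotypeParseError(f"{path}: need a header row and at least one data row")
    header = [c.strip() for c in rows[0][1:]]
    width = len(rows[0])
    ids: list[str] = []
    codes = np.empty((len(rows) - 1, len(header)), dtype=np.int8)
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != width:
            raise GenotypeParseError(f"{path}: ragged row {i + 1} ({len(row)} != {width} fields)")
        ids.append(row[0].strip())
        for j, tok in enumerate(row[1:]):
            codes[i - 1, j] = encode_call(tok, missing_tokens)
    gm = GenotypeMatrix(codes, ids, header)
    if transpose:
        gm = GenotypeMatrix(gm.calls.T.copy(), gm.marker_ids, gm.sample_ids)
    return gm


def write_genotype_matrix(matrix: GenotypeMatrix, path, sep: str = ",") -> None:
    """Write in the dialect :func:`read_genotype_matrix` accepts; missing is ``--``."""
    with open(str(path), "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["sample"] + matrix.marker_ids)
        for sid, row in zip(matrix.sample_ids, matrix.calls):
            writer.writerow([sid] + [_CODE_TO_CALL[int(c)] for c in row])


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeRecord:
    """One individual in a selfing pedigree: a single selfed parent per offspring."""

    individual_id: str
    parent_id: str | None
    generation: str  # "S0", "S1", ...
    family_id: str

    @property
    def generation_index(self) -> int:
        g = self.generation.strip().upper()
        if not g.startswith("S") or not g[1:].isdigit():
            raise GenotypeParseError(f"bad generation label: {self.generation!r}")
        return int(g[1:])

    @property
    def is_founder(self) -> bool:
        return self.parent_id is None


def _toposort(records: list[PedigreeRecord]) -> list[PedigreeRecord]:
    by_id = {r.individual_id: r for r in records}
    order: list[PedigreeRecord] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(r: PedigreeRecord, stack: tuple[str, ...]) -> None:
        if state.get(r.individual_id) == 1:
            return
        if r.individual_id in stack:
            raise GenotypeParseError(f"pedigree cycle involving {r.individual_id!r}")
        if r.parent_id is not None and r.parent_id in by_id:
            visit(by_id[r.parent_id], stack + (r.individual_id,))
        state[r.individual_id] = 1
        order.append(r)

    for r in records:
        visit(r, ())
    return order


def read_pedigree(path, sep: str | None = None) -> list[PedigreeRecord]:
    """Read a pedigree CSV with columns individual,parent,generation,family.

    Returns topologically ordered records (parents before offspring).  An
    offspring's generation index must be its parent's + 1; cycles are errors.
    Parents referenced but not listed in the file are errors (founders have an
    empty parent field).
    """
    df = pd.read_csv(str(path), sep=sep, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"individual", "parent", "generation", "family"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(f"pedigree must have columns {sorted(required)}")
    records = [
        PedigreeRecord(
            individual_id=row["individual"].strip(),
            parent_id=(row["parent"].strip() or None),
            generation=row["generation"].strip(),
            family_id=row["family"].strip(),
        )
        for _, row in df.iterrows()
    ]
    return validate_pedigree(records)


def validate_pedigree(records: list[PedigreeRecord]) -> list[PedigreeRecord]:
    ids = [r.individual_id for r in records]
    if len(set(ids)) != len(ids):
        raise GenotypeParseError("duplicate individual ids in pedigree")
    by_id = {r.individual_id: r for r in records}
    for r in records:
        r.generation_index  # validates label format
        if r.parent_id is not None:
            if r.parent_id not in by_id:
                raise GenotypeParseError(
                    f"{r.individual_id!r}: parent {r.parent_id!r} absent from pedigree"
                )
            if r.generation_index != by_id[r.parent_id].generation_index + 1:
                raise GenotypeParseError(
                    f"{r.individual_id!r}: generation {r.generation} is not parent's + 1"
                )
    return _toposort(records)


def write_pedigree(records: Sequence[PedigreeRecord], path) -> None:
    pd.DataFrame(
        {
            "individual": [r.individual_id for r in records],
            "parent": [r.parent_id or "" for r in records],
            "generation": [r.generation for r in records],
            "family": [r.family_id for r in records],
        }
    ).to_csv(str(path), index=False)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcThresholds:
    """Marker- and sample-level retention thresholds.

    Defaults follow standard Infinium-panel practice: marker call frequency
    >= 0.95, MAF >= 0.01, sample call rate >= 0.87.
    """

    min_marker_call_frequency: float = 0.95
    min_maf: float = 0.01
    min_sample_call_rate: float = 0.87

    def __post_init__(self) -> None:
        for name in (
            "min_marker_call_frequency",
            "min_maf",
            "min_sample_call_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QcReport:
    """Dropped ids with reasons; one entry per (id, reason)."""

    entries: list[tuple[str, str, str, float]] = field(default_factory=list)
    # (id, type "sample"|"marker", reason, offending value)

    def add(self, ident: str, kind: str, reason: str, value: float) -> None:
        self.entries.append((ident, kind, reason, float(value)))

    @property
    def dropped_samples(self) -> list[str]:
        return [e[0] for e in self.entries if e[1] == "sample"]

    @property
    def dropped_markers(self) -> list[str]:
        return sorted({e[0] for e in self.entries if e[1] == "marker"})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["id", "type", "reason", "value"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(str(path), sep="\t", index=False)


def qc_filter(
    matrix: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply sample- then marker-level filters, in a fixed, documented order.

    1. drop samples with call rate < ``min_sample_call_rate`` (computed over
       all markers present before any marker filtering);
    2. drop markers with call frequency < ``min_marker_call_frequency`` over
       the retained samples;
    3. drop markers with MAF < ``min_maf`` computed on the retained samples.

    The order matters because MAF is defined on the post-sample-filter cohort;
    running the filter a second time changes nothing (idempotence).
    """
    report = QcReport()
    cr = matrix.sample_call_rate()
    keep_samples = [s for s in matrix.sample_ids if cr[s] >= thresholds.min_sample_call_rate]
    for s in matrix.sample_ids:
        if s not in keep_samples:
            report.add(s, "sample", "call_rate", cr[s])
    if not keep_samples:
        raise ValueError("all samples removed by call-rate filter")
    m = matrix.subset(samples=keep_samples)

    cf = m.marker_call_frequency()
    keep_cf = [mk for mk in m.marker_ids if cf[mk] >= thresholds.min_marker_call_frequency]
    for mk in m.marker_ids:
        if mk not in keep_cf:
            report.add(mk, "marker", "call_frequency", cf[mk])
    if not keep_cf:
        raise ValueError("all markers removed by call-frequency filter")
    m = m.subset(markers=keep_cf)

    maf = m.marker_maf()
    keep_maf = [mk for mk in m.marker_ids if maf[mk] >= thresholds.min_maf]
    for mk in m.marker_ids:
        if mk not in keep_maf:
            report.add(mk, "marker", "maf", 0.0 if np.isnan(maf[mk]) else maf[mk])
    if not keep_maf:
        raise ValueError("all markers removed by MAF filter")
    return m.subset(markers=keep_maf), report


def replicate_concordance(
    matrix: GenotypeMatrix, pairs: Sequence[tuple[str, str]]
) -> Mapping[tuple[str, str], float]:
    """Per-pair fraction of matching calls over loci non-missing in both members.

    Used to confirm genotyping reproducibility on replicated samples (panels
    are typically expected to show > 99 % concordance).
    """
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        ra, rb = matrix.row(a), matrix.row(b)
        ok = (ra != MISSING) & (rb != MISSING)
        n = int(ok.sum())
        if n == 0:
            raise ValueError(f"no comparable loci for pair ({a!r}, {b!r})")
        out[(a, b)] = float((ra[ok] == rb[ok]).mean())
    return out
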