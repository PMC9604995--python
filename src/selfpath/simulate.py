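"""Synthetic genotype matrices and selfing pedigrees with the statistical
structure the analysis assumes, plus a forward simulator of marker-assisted
vs random advancement.

Founders are drawn marker-by-marker from an allele-frequency model with a
tunable baseline inbreeding coefficient F (genotype probabilities
p^2 + Fpq, 2pq(1-F), q^2 + Fpq; F may be negative down to the admissible
bound to emulate outbred clones with excess heterozygosity).  Selfed
offspring segregate 1:2:1 at parental heterozygous loci, independently
across loci (no linkage).  A symmetric noise model adds per-call missingness
and class-swap genotyping error.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so outputs are byte-identical for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AA, AB, BB, MISSING, GenotypeMatrix, PedigreeRecord, validate_pedigree

_SEGREGATION = np.array([AA, AB, AB, BB], dtype=np.int8)  # 1:2:1 via uniform on 4


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generator.

    Defaults mirror a mid-density Infinium panel ascertained toward
    informative SNPs: 3,380 markers whose minor allele frequency follows a
    Beta(5, 2) draw scaled to [0, 0.5] (left-skewed toward high MAF, mean
    ~0.36), outbred founders (F0 = 0), families of 8 offspring, and clean
    calls (no missingness or error) unless noise rates are set.
    """

    n_markers: int = 3380
    maf_model: tuple = ("beta", 5.0, 2.0)  # or ("uniform", lo, hi)
    founder_f: float = 0.0
    founder_h0: float | None = None  # exact founder homozygous-call fraction
    n_generations: int = 2
    family_size: int = 8
    missing_rate: float = 0.0
    error_rate: float = 0.0
    selection_strategy: str = "max_z"  # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        for r in (self.missing_rate, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not -1.0 <= self.founder_f <= 1.0:
            raise ValueError("founder_f must be in [-1, 1]")
        if self.founder_h0 is not None and not 0.0 <= self.founder_h0 <= 1.0:
            raise ValueError("founder_h0 must be in [0, 1]")
        if self.selection_strategy not in ("max_z", "random"):
            raise ValueError("selection_strategy must be 'max_z' or 'random'")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def draw_allele_frequencies(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-marker frequency of allele B under the configured MAF model."""
    kind = config.maf_model[0]
    if kind == "beta":
        _, a, b = config.maf_model
        maf = 0.5 * rng.beta(a, b, size=config.n_markers)
    elif kind == "uniform":
        _, lo, hi = config.maf_model
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError("uniform MAF bounds must satisfy 0 <= lo <= hi <= 0.5")
        maf = rng.uniform(lo, hi, size=config.n_markers)
    else:
        raise ValueError(f"unknown maf_model: {kind!r}")
    # assign the minor allele to A or B at random so both labels occur
    flip = rng.random(config.n_markers) < 0.5
    return np.where(flip, maf, 1.0 - maf)


def simulate_founder(
    config: SimulationConfig,
    rng: np.random.Generator,
    allele_freqs: np.ndarray | None = None,
) -> np.ndarray:
    """One founder row from inbreeding-adjusted genotype frequencies.

    With p the B-allele frequency, genotype probabilities are
    AA: q^2 + Fpq, AB: 2pq(1-F), BB: p^2 + Fpq.  F below the admissible
    lower bound (-min(p/q, q/p)) at any marker is an error.
    """
    p = allele_freqs if allele_freqs is not None else draw_allele_frequencies(config, rng)
    q = 1.0 - p
    f = config.founder_f
    pr_ab = 2 * p * q * (1.0 - f)
    pr_aa = q * q + f * p * q
    if np.any(pr_aa < 0) or np.any(pr_ab < 0):
        raise ValueError(f"founder_f={f} infeasible for the drawn allele frequencies")
    u = rng.random(config.n_markers)
    return np.select([u < pr_aa, u < pr_aa + pr_ab], [AA, AB], default=BB).astype(np.int8)


def founder_with_homozygosity(
    n_markers: int, h0: float, rng: np.random.Generator
) -> np.ndarray:
    """Founder with an exact homozygous-call fraction h0 (hom calls split AA/BB)."""
    n_ab = int(round(n_markers * (1.0 - h0)))
    row = np.full(n_markers, AB, dtype=np.int8)
    hom_pos = rng.permutation(n_markers)[n_ab:]
    half = len(hom_pos) // 2
    row[hom_pos[:half]] = AA
    row[hom_pos[half:]] = BB
    return row


def simulate_founder_cohort(
    config: SimulationConfig, n_samples: int
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Cohort of unrelated founders sharing one set of marker allele frequencies.

    Returns the matrix and the true allele-frequency vector (oracle truth for
    parameter-recovery tests).
    """
    rng_p, rng_g, rng_noise = _spawn(config.seed, 3)
    p = draw_allele_frequencies(config, rng_p)
    rows = np.stack([simulate_founder(config, rng_g, allele_freqs=p) for _ in range(n_samples)])
    rows = apply_noise(rows, config.missing_rate, config.error_rate, rng_noise)
    ids = [f"S{i:04d}" for i in range(n_samples)]
    markers = [f"M{j:05d}" for j in range(config.n_markers)]
    return GenotypeMatrix(rows, ids, markers), p


def simulate_selfing_offspring(
    parent_row: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` selfed offspring rows: parental homozygous and missing calls are
    copied; heterozygous loci segregate AA:AB:BB = 1:2:1 independently."""
    if n < 1:
        raise ValueError("n must be >= 1")
    parent_row = np.asarray(parent_row, dtype=np.int8)
    out = np.tile(parent_row, (n, 1))
    het = parent_row == AB
    k = int(het.sum())
    if k:
        out[:, het] = _SEGREGATION[rng.integers(0, 4, size=(n, k))]
    return out


def apply_noise(
    rows: np.ndarray, missing_rate: float, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent per-call missingness, then class-swap error on surviving calls.

    An erroneous call is replaced by one of the two *other* genotype classes,
    chosen uniformly.
    """
    rows = np.array(rows, dtype=np.int8, copy=True)
    if missing_rate > 0:
        rows[rng.random(rows.shape) < missing_rate] = MISSING
    if error_rate > 0:
        hit = (rng.random(rows.shape) < error_rate) & (rows != MISSING)
        shift = rng.integers(1, 3, size=rows.shape)  # +1 or +2 mod 3 ≠ identity
        rows[hit] = ((rows[hit] + shift[hit]) % 3).astype(np.int8)
    return rows


def _observed_hom(rows: np.ndarray) -> np.ndarray:
    """Observed homozygosity per row over non-missing calls."""
    ok = rows != MISSING
    hom = (rows == AA) | (rows == BB)
    with np.errstate(invalid="ignore"):
        return hom.sum(axis=1) / ok.sum(axis=1)


@dataclass
class SimulatedStudy:
    """A generated study: noisy genotype matrix, pedigree, and oracle truth."""

    matrix: GenotypeMatrix
    pedigree: list[PedigreeRecord]
    true_calls: GenotypeMatrix  # pre-noise genotypes
    allele_freqs: np.ndarray


def simulate_selfing_study(
    config: SimulationConfig, n_families: int = 3
) -> SimulatedStudy:
    """Generate founders and selfed families emulating a small inbred-line study.

    Each family starts from its own founder; at every generation one member
    (random) is selfed to produce ``family_size`` genotyped offspring.
    """
    rngs = _spawn(config.seed, 3 + n_families)
    rng_p, rng_noise, rng_pick = rngs[0], rngs[1], rngs[2]
    p = draw_allele_frequencies(config, rng_p)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    records: list[PedigreeRecord] = []
    for f in range(n_families):
        fam = chr(ord("A") + f)
        rng = rngs[3 + f]
        if config.founder_h0 is not None:
            founder = founder_with_homozygosity(config.n_markers, config.founder_h0, rng)
        else:
            founder = simulate_founder(config, rng, allele_freqs=p)
        parent_id = f"{fam}_S0"
        ids.append(parent_id)
        rows.append(founder)
        records.append(PedigreeRecord(parent_id, None, "S0", fam))
        parent_row = founder
        for g in range(1, config.n_generations + 1):
            kids = simulate_selfing_offspring(parent_row, config.family_size, rng)
            kid_ids = [f"{fam}_S{g}_{j + 1}" for j in range(config.family_size)]
            for kid_id, kid in zip(kid_ids, kids):
                ids.append(kid_id)
                rows.append(kid)
                records.append(PedigreeRecord(kid_id, parent_id, f"S{g}", fam))
            pick = int(rng_pick.integers(0, config.family_size))
            parent_id = kid_ids[pick]
            parent_row = kids[pick]
    markers = [f"M{j:05d}" for j in range(config.n_markers)]
    true_calls = np.stack(rows)
    noisy = apply_noise(true_calls, config.missing_rate, config.error_rate, rng_noise)
    return SimulatedStudy(
        matrix=GenotypeMatrix(noisy, ids, markers),
        pedigree=validate_pedigree(records),
        true_calls=GenotypeMatrix(true_calls, list(ids), list(markers)),
        allele_freqs=p,
    )


def simulate_program(config: SimulationConfig) -> pd.DataFrame:
    """Forward-simulate one breeding program under both advancement strategies.

    From a common founder, each strategy independently advances one selected
    individual per generation: ``max_z`` picks the offspring with the highest
    measured homozygosity (the top standardized-homozygosity candidate —
    within a single family the z ranking equals the homozygosity ranking);
    ``random`` picks uniformly.  Returns a tidy trajectory table with columns
    strategy, generation, mean_hom, max_hom, selected_id, selected_hom.
    Generation 0 rows carry the founder's homozygosity.
    """
    if config.n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng_f, rng_traj = _spawn(config.seed, 2)
    if config.founder_h0 is not None:
        founder = founder_with_homozygosity(config.n_markers, config.founder_h0, rng_f)
    else:
        founder = simulate_founder(config, rng_f)
    h0 = float(_observed_hom(founder[None, :])[0])
    out = []
    for strategy_idx, strategy in enumerate(("max_z", "random")):
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence((config.seed, strategy_idx))
        ))
        parent = founder
        out.append((strategy, 0, h0, h0, "founder", h0))
        for g in range(1, config.n_generations + 1):
            kids = simulate_selfing_offspring(parent, config.family_size, rng)
            measured = apply_noise(kids, config.missing_rate, config.error_rate, rng)
            homs = _observed_hom(measured)
            if strategy == "max_z":
                pick = int(np.argmax(homs))  # first index wins ties (id order)
            else:
                pick = int(rng.integers(0, config.family_size))
            true_homs = _observed_hom(kids)
            out.append(
                (
                    strategy,
                    g,
                    float(np.nanmean(homs)),
                    float(np.nanmax(homs)),
                    f"S{g}_{pick + 1}",
                    float(true_homs[pick]),
                )
            )
            parent = kids[pick]
    return pd.DataFrame(
        out,
        columns=["strategy", "generation", "mean_hom", "max_hom", "selected_id", "selected_hom"],
    )


def program_replicates(
    config: SimulationConfig, n_reps: int
) -> pd.DataFrame:
    """Run :func:`simulate_program` ``n_reps`` times with per-replicate seeds
    derived from ``config.seed``; adds a ``rep`` column."""
    frames = []
    for i, child in enumerate(np.random.SeedSequence(config.seed).spawn(n_reps)):
        rep_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        df = simulate_program(replace(config, seed=rep_seed))
        df.insert(0, "rep", i)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
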