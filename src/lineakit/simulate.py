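"""Synthetic two-population lineage-marker data.

The study design this package supports contrasts a query set of mitotypes
against two reference populations with distinct haplogroup spectra.  Raw
casework reference panels are never public, so this module generates the
statistical structure the analysis assumes:

* two mtDNA reference populations over a shared founder set of haplogroups,
  with nearly disjoint frequency spectra (defaults: an "ashkenazi_like" panel
  concentrated on the eight fine case subclades and a "polish_like" panel
  concentrated on their ancestral/other clades);
* within each founder haplogroup, a small pool of distinct *lineages*
  (mitotypes): lineage 0 is the founder motif itself and the others add
  Poisson-distributed private substitutions.  Individuals are drawn from the
  lineage pool with geometrically decaying weights, so common mitotypes recur
  across individuals — the finite-haplotype-diversity regime that makes
  forensic database matching informative.  Private variants never fall on
  haplogroup-diagnostic positions, keeping generating labels recoverable;
* a small case set of queries drawn from one population's generative process
  (sharing that population's lineage pools);
* Y-STR haplotypes generated around founder haplotypes (including the Cohen
  Modal Haplotype for the "J-P58" founder) under a symmetric single-step
  stepwise mutation model.

All randomness derives from the single spec seed through named integer
substreams, so output is reproducible across platforms.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .haplogroups import HaplogroupTree
from .matching import HaplotypeDB
from .profiles import CONTROL_REGION, MtProfile, SeqRange, Variant, SUBSTITUTION
from .reference import synthetic_reference
from .ystr import CMH_REFERENCE, YstrHaplotype


class SpecError(ValueError):
    """Invalid synthetic-data specification."""


_BASES = "ACGT"

#: Default mtDNA haplogroup frequency spectra.  The query-source population
#: concentrates on the eight fine subclades; the contrast population on other
#: clades of the same tree.  The spectra are disjoint (overlap 0 <= 10%).
DEFAULT_MT_FREQUENCIES: dict[str, dict[str, float]] = {
    "ashkenazi_like": {
        "K1a1b1a": 0.20, "K2a2a1": 0.15, "H3p": 0.12, "HV1b2": 0.12,
        "I1c1a": 0.11, "J1c14": 0.10, "V7a": 0.10, "X2b7": 0.10,
    },
    "polish_like": {
        "H": 0.30, "H3": 0.15, "HV1b": 0.10, "V": 0.12,
        "U": 0.10, "J": 0.10, "I": 0.08, "X": 0.05,
    },
}

#: Default Y-STR founder haplotypes over the 12 CMH loci.  "J-P58" is founded
#: on the Cohen Modal Haplotype; the others are synthetic founders at least
#: three loci away from it and from each other.
DEFAULT_YSTR_FOUNDERS: dict[str, YstrHaplotype] = {
    "J-P58": YstrHaplotype("founder_J-P58", dict(CMH_REFERENCE.alleles)),
    "R1a": YstrHaplotype(
        "founder_R1a",
        {"DYS19": 16, "DYS388": 12, "DYS390": 25, "DYS391": 11, "DYS392": 11,
         "DYS393": 13, "DYS385a": 11, "DYS385b": 14, "DYS389I": 13,
         "DYS389II": 31, "DYS426": 12, "DYS439": 10},
    ),
    "I2a": YstrHaplotype(
        "founder_I2a",
        {"DYS19": 15, "DYS388": 13, "DYS390": 24, "DYS391": 10, "DYS392": 11,
         "DYS393": 13, "DYS385a": 14, "DYS385b": 15, "DYS389I": 13,
         "DYS389II": 31, "DYS426": 11, "DYS439": 11},
    ),
    "E1b": YstrHaplotype(
        "founder_E1b",
        {"DYS19": 13, "DYS388": 12, "DYS390": 24, "DYS391": 10, "DYS392": 11,
         "DYS393": 13, "DYS385a": 16, "DYS385b": 18, "DYS389I": 13,
         "DYS389II": 30, "DYS426": 11, "DYS439": 12},
    ),
}

DEFAULT_YSTR_FREQUENCIES: dict[str, dict[str, float]] = {
    "ashkenazi_like": {"J-P58": 0.55, "E1b": 0.25, "R1a": 0.20},
    "polish_like": {"R1a": 0.60, "I2a": 0.40},
}


@dataclass
class SyntheticSpec:
    """Parameters of the two-population generator.

    ``lambda_private`` is the Poisson mean of private substitutions per
    non-founder lineage; ``n_lineages`` the pool size per founder haplogroup;
    ``mu_smm`` the per-locus single-step Y-STR mutation probability.
    """

    mt_frequencies: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(v) for p, v in DEFAULT_MT_FREQUENCIES.items()}
    )
    ystr_frequencies: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(v) for p, v in DEFAULT_YSTR_FREQUENCIES.items()}
    )
    ystr_founders: dict[str, YstrHaplotype] = field(
        default_factory=lambda: dict(DEFAULT_YSTR_FOUNDERS)
    )
    tree: HaplogroupTree = field(default_factory=HaplogroupTree.default)
    reference: str = field(default_factory=synthetic_reference)
    coverage: tuple[SeqRange, ...] = CONTROL_REGION
    n_per_population: int = 500
    n_lineages: int = 6
    lambda_private: float = 1.0
    mu_smm: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for pop, freqs in self.mt_frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-12:
                raise SpecError(f"{pop}: mt frequencies sum to {total}, not 1")
            for hg in freqs:
                if hg not in self.tree.nodes:
                    raise SpecError(f"{pop}: unknown founder haplogroup {hg!r}")
        for pop, freqs in self.ystr_frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-12:
                raise SpecError(f"{pop}: Y frequencies sum to {total}, not 1")
            for hg in freqs:
                if hg not in self.ystr_founders:
                    raise SpecError(f"{pop}: unknown Y founder {hg!r}")
        if self.lambda_private < 0:
            raise SpecError("lambda_private must be >= 0")
        if not 0 <= self.mu_smm <= 0.5:
            raise SpecError("mu_smm must lie in [0, 0.5]")
        if self.n_per_population < 1 or self.n_lineages < 1:
            raise SpecError("n_per_population and n_lineages must be >= 1")

    def spectral_overlap(self, pop_a: str, pop_b: str) -> float:
        """Sum of elementwise minima of the two mt frequency vectors."""
        fa, fb = self.mt_frequencies[pop_a], self.mt_frequencies[pop_b]
        return sum(min(fa.get(h, 0.0), fb.get(h, 0.0)) for h in set(fa) | set(fb))


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    return SyntheticSpec(seed=seed, **overrides)


def _stream(spec: SyntheticSpec, *names: str | int) -> np.random.Generator:
    """Named substream: deterministic, independent of generation order."""
    words = [spec.seed & 0x7FFFFFFF]
    for name in names:
        if isinstance(name, int):
            words.append(name & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(name.encode()))
    return np.random.default_rng(words)


def _founder_profile(spec: SyntheticSpec, haplogroup: str, sample_id: str) -> MtProfile:
    return MtProfile(
        sample_id=sample_id,
        variants=tuple(spec.tree.expected(haplogroup)),
        coverage=spec.coverage,
    )


def _coverage_positions(spec: SyntheticSpec) -> np.ndarray:
    return np.concatenate(
        [np.arange(r.start, r.end + 1) for r in spec.coverage]
    )


def mt_lineage_pools(
    spec: SyntheticSpec, population: str
) -> dict[str, tuple[list[tuple[Variant, ...]], np.ndarray]]:
    """Per-founder pools of lineage variant sets with sampling weights.

    Lineage 0 is the founder motif; lineages 1..n-1 add Poisson(lambda)
    private substitutions at uniform non-diagnostic positions.  Weights decay
    geometrically (w_j ∝ 2^-j), making the founder motif modal.  Pools depend
    only on (seed, population), so reference records and case queries drawn
    from the same population share them.
    """
    if population not in spec.mt_frequencies:
        raise SpecError(f"unknown population {population!r}")
    diag = spec.tree.diagnostic_positions()
    candidates = np.array(
        [p for p in _coverage_positions(spec) if p not in diag], dtype=int
    )
    pools: dict[str, tuple[list[tuple[Variant, ...]], np.ndarray]] = {}
    for hg in spec.mt_frequencies[population]:
        rng = _stream(spec, "mt-pool", population, hg)
        founder = tuple(sorted(spec.tree.expected(hg), key=lambda v: v.sort_key))
        lineages: list[tuple[Variant, ...]] = [founder]
        for _ in range(1, spec.n_lineages):
            k = int(rng.poisson(spec.lambda_private))
            used: set[int] = set()
            privates: list[Variant] = []
            for _ in range(k):
                pos = int(rng.choice(candidates))
                while pos in used:
                    pos = int(rng.choice(candidates))
                used.add(pos)
                ref_base = spec.reference[pos - 1]
                alt = _BASES.replace(ref_base, "")[int(rng.integers(0, 3))]
                privates.append(Variant(position=pos, kind=SUBSTITUTION, base=alt))
            lineages.append(
                tuple(sorted(founder + tuple(privates), key=lambda v: v.sort_key))
            )
        weights = 0.5 ** np.arange(spec.n_lineages, dtype=float)
        pools[hg] = (lineages, weights / weights.sum())
    return pools


def _draw_mt_records(
    spec: SyntheticSpec,
    population: str,
    n: int,
    rng: np.random.Generator,
    id_prefix: str,
) -> tuple[list[MtProfile], pd.DataFrame]:
    pools = mt_lineage_pools(spec, population)
    freqs = spec.mt_frequencies[population]
    groups = list(freqs)
    probs = np.array([freqs[g] for g in groups])
    records: list[MtProfile] = []
    truth_rows = []
    for i in range(n):
        hg = groups[int(rng.choice(len(groups), p=probs))]
        lineages, weights = pools[hg]
        lineage_idx = int(rng.choice(len(lineages), p=weights))
        sample_id = f"{id_prefix}{i + 1:04d}"
        records.append(
            MtProfile(sample_id, lineages[lineage_idx], spec.coverage)
        )
        truth_rows.append(
            {"sample": sample_id, "haplogroup": hg, "lineage": lineage_idx}
        )
    return records, pd.DataFrame(truth_rows)


def generate_mt_population(
    spec: SyntheticSpec, population: str
) -> tuple[HaplotypeDB, pd.DataFrame]:
    """A reference mtDNA database for one population, plus truth labels."""
    rng = _stream(spec, "mt-records", population)
    records, truth = _draw_mt_records(
        spec, population, spec.n_per_population, rng, f"{population}_"
    )
    return HaplotypeDB(population=population, records=records), truth


def generate_case_set(
    spec: SyntheticSpec, population: str, k: int = 10
) -> tuple[list[MtProfile], pd.DataFrame]:
    """k query mitotypes drawn from one population's generative process."""
    if k < 1:
        raise SpecError("k must be >= 1")
    if population not in spec.mt_frequencies:
        raise SpecError(f"unknown population {population!r}")
    rng = _stream(spec, "mt-case", population)
    queries, truth = _draw_mt_records(spec, population, k, rng, "case_")
    truth = truth.assign(population=population)
    return queries, truth


def _mutate_smm(
    alleles: Mapping[str, float], mu: float, rng: np.random.Generator
) -> dict[str, float]:
    out = {}
    for marker in alleles:
        value = alleles[marker]
        if rng.random() < mu:
            step = 1.0 if rng.random() < 0.5 else -1.0
            value = max(value + step, 1.0)
        out[marker] = value
    return out


def generate_ystr_population(
    spec: SyntheticSpec, population: str
) -> tuple[list[YstrHaplotype], pd.DataFrame]:
    """Y-STR haplotypes for one population under the stepwise mutation model."""
    if population not in spec.ystr_frequencies:
        raise SpecError(f"unknown population {population!r}")
    rng = _stream(spec, "ystr-records", population)
    freqs = spec.ystr_frequencies[population]
    groups = list(freqs)
    probs = np.array([freqs[g] for g in groups])
    haplotypes: list[YstrHaplotype] = []
    truth_rows = []
    for i in range(spec.n_per_population):
        hg = groups[int(rng.choice(len(groups), p=probs))]
        founder = spec.ystr_founders[hg]
        sample_id = f"{population}_y{i + 1:04d}"
        haplotypes.append(
            YstrHaplotype(sample_id, _mutate_smm(founder.alleles, spec.mu_smm, rng))
        )
        truth_rows.append({"sample": sample_id, "haplogroup": hg})
    return haplotypes, pd.DataFrame(truth_rows)


def generate_ystr_case_set(
    spec: SyntheticSpec, population: str, k: int = 10
) -> tuple[list[YstrHaplotype], pd.DataFrame]:
    """k case Y-STR haplotypes from one population's generative process."""
    if k < 1:
        raise SpecError("k must be >= 1")
    if population not in spec.ystr_frequencies:
        raise SpecError(f"unknown population {population!r}")
    rng = _stream(spec, "ystr-case", population)
    freqs = spec.ystr_frequencies[population]
    groups = list(freqs)
    probs = np.array([freqs[g] for g in groups])
    haplotypes, truth_rows = [], []
    for i in range(k):
        hg = groups[int(rng.choice(len(groups), p=probs))]
        founder = spec.ystr_founders[hg]
        sample_id = f"case_{i + 1:04d}"
        haplotypes.append(
            YstrHaplotype(sample_id, _mutate_smm(founder.alleles, spec.mu_smm, rng))
        )
        truth_rows.append(
            {"sample": sample_id, "haplogroup": hg, "population": population}
        )
    return haplotypes, pd.DataFrame(truth_rows)
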