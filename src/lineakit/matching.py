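"""Range-adjusted haplotype matching and the two-population probability contrast.

The forensic question behind this module: given a query mitotype, is it more
probable in population A or population B?  Each population is represented by
a database of reference mitotypes.  Match counting is *range adjusted*: the
comparison window is intersected with what the data actually cover, and only
records fully covering the window enter the denominator.  Haplotype
frequencies use the augmented counting estimator (x+1)/(n+1), where x is the
number of matching records among n comparable ones; the contrast reports the
ratio of the two augmented probabilities and the winning population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .profiles import (
    CoverageError,
    MtProfile,
    SeqRange,
    format_range_spec,
    intersect_ranges,
    normalise_ranges,
    profile_diff,
    read_profile_table,
    restrict_profile,
)


class MatchingError(ValueError):
    """Raised when a match count or contrast cannot be computed."""


@dataclass
class HaplotypeDB:
    """A labelled collection of reference mitotypes from one population."""

    population: str
    records: list[MtProfile] = field(default_factory=list)
    origins: list[str | None] | None = None

    def __post_init__(self) -> None:
        if self.origins is not None and len(self.origins) != len(self.records):
            raise MatchingError("origins must align with records")

    @property
    def n(self) -> int:
        return len(self.records)

    @classmethod
    def from_tsv(cls, path, population: str) -> "HaplotypeDB":
        return cls(population=population, records=read_profile_table(path))


@dataclass(frozen=True)
class ContrastResult:
    """Augmented-probability contrast of one query between two populations.

    ``lr`` is p_a / p_b with populations in user-declared order; ``winner``
    is the label with the larger probability or the explicit string
    ``"tie"`` — a tie is never silently broken.
    """

    query_id: str
    pop_a: str
    pop_b: str
    x_a: int
    n_a: int
    x_b: int
    n_b: int
    p_a: float
    p_b: float
    lr: float
    winner: str


def range_adjusted_match_count(
    query: MtProfile,
    db: HaplotypeDB,
    window: Iterable[SeqRange],
    comparability: str = "full-cover",
) -> tuple[int, int]:
    """Count matches of a query against a database over a window.

    A record is *comparable* iff its coverage contains the whole window
    (default policy); ``comparability="per-record"`` instead intersects the
    window with each record's coverage, which makes x values across records
    incomparable and is therefore not the default.  Returns ``(x, n)``:
    matching and comparable record counts.
    """
    win = normalise_ranges(window)
    if not query.covers(win):
        raise CoverageError(
            f"window {format_range_spec(win)} not covered by query {query.sample_id}"
        )
    if comparability not in ("full-cover", "per-record"):
        raise MatchingError(f"unknown comparability policy {comparability!r}")
    x = n = 0
    for rec in db.records:
        if comparability == "full-cover":
            if not rec.covers(win):
                continue
            pair_win = win
        else:
            pair_win = intersect_ranges(win, rec.coverage)
            if not pair_win:
                continue
        n += 1
        _, count = profile_diff(
            restrict_profile(query, pair_win), restrict_profile(rec, pair_win), pair_win
        )
        if count == 0:
            x += 1
    if n == 0:
        raise MatchingError(
            f"no comparable records in {db.population} for window {format_range_spec(win)}"
        )
    return x, n


def augmented_probability(x: int, n: int) -> float:
    """Augmented counting haplotype frequency estimator (x+1)/(n+1).

    x matches among n comparable database records; the +1 augmentation places
    the query itself in the database, so the estimate is never zero.
    """
    if n < 1:
        raise MatchingError(f"need n >= 1, got n={n}")
    if not 0 <= x <= n:
        raise MatchingError(f"need 0 <= x <= n, got x={x}, n={n}")
    return (x + 1) / (n + 1)


def population_contrast(
    query: MtProfile,
    db_a: HaplotypeDB,
    db_b: HaplotypeDB,
    window: Iterable[SeqRange],
    comparability: str = "full-cover",
) -> ContrastResult:
    """Contrast a query's augmented probabilities between two populations."""
    counts = {}
    for db in (db_a, db_b):
        try:
            counts[db.population] = range_adjusted_match_count(
                query, db, window, comparability
            )
        except MatchingError as err:
            raise MatchingError(f"population {db.population!r}: {err}") from err
    x_a, n_a = counts[db_a.population]
    x_b, n_b = counts[db_b.population]
    p_a = augmented_probability(x_a, n_a)
    p_b = augmented_probability(x_b, n_b)
    # exact integer cross-comparison: (x_a+1)/(n_a+1) vs (x_b+1)/(n_b+1)
    lhs = (x_a + 1) * (n_b + 1)
    rhs = (x_b + 1) * (n_a + 1)
    if lhs > rhs:
        winner = db_a.population
    elif lhs < rhs:
        winner = db_b.population
    else:
        winner = "tie"
    return ContrastResult(
        query_id=query.sample_id,
        pop_a=db_a.population,
        pop_b=db_b.population,
        x_a=x_a,
        n_a=n_a,
        x_b=x_b,
        n_b=n_b,
        p_a=p_a,
        p_b=p_b,
        lr=p_a / p_b,
        winner=winner,
    )


def contrast_table(
    queries: Sequence[MtProfile],
    db_a: HaplotypeDB,
    db_b: HaplotypeDB,
    window: Iterable[SeqRange],
    comparability: str = "full-cover",
) -> pd.DataFrame:
    """One contrast row per query; the report behind the population inference."""
    rows = [
        vars(population_contrast(q, db_a, db_b, window, comparability))
        for q in queries
    ]
    return pd.DataFrame(rows)


def copies_to_cell_equivalents(
    copies_per_ul: float, copies_per_cell: float = 250
) -> float:
    """Convert an mtDNA copy-number concentration to cell equivalents.

    Forensic extracts are quantified in mtDNA copies/ul; dividing by the
    assumed per-cell mtDNA copy number (default 250) expresses the yield as
    cell equivalents of nuclear DNA.
    """
    if copies_per_cell <= 0:
        raise MatchingError(f"copies_per_cell must be positive, got {copies_per_cell}")
    if copies_per_ul < 0:
        raise MatchingError(f"copies_per_ul must be non-negative, got {copies_per_ul}")
    return copies_per_ul / copies_per_cell
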