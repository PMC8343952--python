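"""Forensic mtDNA profiles coded as differences to a reference sequence.

A *mitotype* (``MtProfile``) is a sample's set of variants relative to the
rCRS together with the sequence range(s) the sample was actually typed over.
Coordinates are 1-based, inclusive, rCRS numbering; the genome is treated as
linear (no circular wrap) with fixed length 16,569.

Variant tokens follow standard forensic nomenclature:

* ``73G``      substitution to G at position 73
* ``315.1C``   insertion of C after position 315, first inserted base
* ``249DEL``   deletion of position 249 (dialect ``249-`` accepted on read)

Bases coded ``N`` are treated as missing and excluded from matching and
distance computations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .reference import MT_LENGTH

#: Hypervariable segment I of the control region.
HV1_RANGE = (16024, 16365)
#: Hypervariable segment II of the control region.
HV2_RANGE = (73, 340)


class ProfileError(ValueError):
    """Malformed profile data (bad token, invariant violation)."""


class CoverageError(ProfileError):
    """A requested window is not covered by a profile."""


@dataclass(frozen=True, order=True)
class SeqRange:
    """Closed interval of rCRS positions, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= MT_LENGTH):
            raise ProfileError(
                f"invalid range {self.start}-{self.end}: need 1 <= start <= end <= {MT_LENGTH}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def intersect(self, other: "SeqRange") -> "SeqRange | None":
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return SeqRange(lo, hi) if lo <= hi else None

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


HV1 = SeqRange(*HV1_RANGE)
HV2 = SeqRange(*HV2_RANGE)
#: The forensic control-region window: HV1 + HV2 in positional order.
CONTROL_REGION = (HV2, HV1)


def normalise_ranges(ranges: Iterable[SeqRange]) -> tuple[SeqRange, ...]:
    """Sort ranges by start and merge any overlapping or adjacent ones."""
    ordered = sorted(ranges, key=lambda r: (r.start, r.end))
    merged: list[SeqRange] = []
    for r in ordered:
        if merged and r.start <= merged[-1].end + 1:
            merged[-1] = SeqRange(merged[-1].start, max(merged[-1].end, r.end))
        else:
            merged.append(r)
    return tuple(merged)


def intersect_ranges(
    a: Iterable[SeqRange], b: Iterable[SeqRange]
) -> tuple[SeqRange, ...]:
    """Intersection of two coverage sets, returned normalised."""
    out: list[SeqRange] = []
    for ra in normalise_ranges(a):
        for rb in normalise_ranges(b):
            x = ra.intersect(rb)
            if x is not None:
                out.append(x)
    return normalise_ranges(out)


def ranges_contain(cover: Iterable[SeqRange], window: Iterable[SeqRange]) -> bool:
    """True iff every window range is fully inside the coverage set."""
    cov = normalise_ranges(cover)
    for w in normalise_ranges(window):
        if not any(c.start <= w.start and w.end <= c.end for c in cov):
            return False
    return True


_SUB_INS_RE = re.compile(r"^(\d+)(?:\.(\d+))?([ACGTN])$", re.IGNORECASE)
_DEL_RE = re.compile(r"^(\d+)(?:DEL|-)$", re.IGNORECASE)

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"


@dataclass(frozen=True)
class Variant:
    """A single difference to the reference.

    ``insert_index`` is the ``.1`` in ``315.1C`` (None for non-insertions);
    ``base`` is None for deletions.
    """

    position: int
    kind: str
    insert_index: int | None = None
    base: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.position <= MT_LENGTH):
            raise ProfileError(f"position {self.position} outside 1..{MT_LENGTH}")
        if self.kind == INSERTION and (self.insert_index is None or self.insert_index < 1):
            raise ProfileError(f"insertion at {self.position} needs insert_index >= 1")
        if self.kind in (SUBSTITUTION, INSERTION) and self.base not in set("ACGTN"):
            raise ProfileError(f"invalid base {self.base!r} at {self.position}")
        if self.kind == DELETION and (self.base is not None or self.insert_index is not None):
            raise ProfileError("deletion carries neither base nor insert_index")

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.position, self.insert_index or 0)

    def token(self) -> str:
        if self.kind == DELETION:
            return f"{self.position}DEL"
        if self.kind == INSERTION:
            return f"{self.position}.{self.insert_index}{self.base}"
        return f"{self.position}{self.base}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


def parse_variant(token: str) -> Variant:
    """Parse one forensic variant token (``73G``, ``315.1C``, ``249DEL``/``249-``)."""
    tok = token.strip()
    m = _DEL_RE.match(tok)
    if m:
        return Variant(position=int(m.group(1)), kind=DELETION)
    m = _SUB_INS_RE.match(tok)
    if m:
        pos = int(m.group(1))
        base = m.group(3).upper()
        if m.group(2) is not None:
            k = int(m.group(2))
            if k < 1:
                raise ProfileError(f"malformed variant token {token!r}: insertion index 0")
            return Variant(position=pos, kind=INSERTION, insert_index=k, base=base)
        return Variant(position=pos, kind=SUBSTITUTION, base=base)
    raise ProfileError(f"malformed variant token {token!r}")


@dataclass(frozen=True)
class MtProfile:
    """A sample's mitotype: variants relative to the rCRS plus coverage.

    ``coverage`` is a sorted tuple of non-overlapping ranges; every variant
    position lies inside coverage; variants are sorted by
    (position, insert_index).  An empty coverage is allowed only as the
    flagged result of restricting to a disjoint window (``is_empty``).
    """

    sample_id: str
    variants: tuple[Variant, ...] = ()
    coverage: tuple[SeqRange, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "coverage", normalise_ranges(self.coverage))
        object.__setattr__(
            self, "variants", tuple(sorted(self.variants, key=lambda v: v.sort_key))
        )
        seen_point: set[int] = set()
        seen_ins: set[tuple[int, int]] = set()
        outside = []
        for v in self.variants:
            if not any(v.position in r for r in self.coverage):
                outside.append(v.token())
            if v.kind == INSERTION:
                key = (v.position, v.insert_index)
                if key in seen_ins:
                    raise ProfileError(f"{self.sample_id}: duplicate insertion {v.token()}")
                seen_ins.add(key)
            else:
                if v.position in seen_point:
                    raise ProfileError(
                        f"{self.sample_id}: multiple substitutions/deletions at {v.position}"
                    )
                seen_point.add(v.position)
        if outside:
            raise ProfileError(
                f"{self.sample_id}: variants outside declared range: {' '.join(outside)}"
            )

    @property
    def is_empty(self) -> bool:
        """True for the flagged empty-coverage result of a disjoint restriction."""
        return len(self.coverage) == 0

    def covers(self, window: Iterable[SeqRange]) -> bool:
        return ranges_contain(self.coverage, window)

    def variants_in(self, window: Iterable[SeqRange]) -> tuple[Variant, ...]:
        win = normalise_ranges(window)
        return tuple(v for v in self.variants if any(v.position in r for r in win))

    def informative_variants(self, window: Iterable[SeqRange]) -> frozenset[Variant]:
        """Variants inside the window, with missing ('N') calls dropped."""
        return frozenset(v for v in self.variants_in(window) if v.base != "N")


def parse_range_spec(spec: str) -> tuple[SeqRange, ...]:
    """Parse a declared range spec such as ``"16024-16365;73-340"``."""
    ranges = []
    for part in spec.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        m = re.match(r"^(\d+)-(\d+)$", part)
        if not m:
            raise ProfileError(f"malformed range spec {part!r}")
        ranges.append(SeqRange(int(m.group(1)), int(m.group(2))))
    if not ranges:
        raise ProfileError(f"empty range spec {spec!r}")
    return normalise_ranges(ranges)


def format_range_spec(ranges: Iterable[SeqRange]) -> str:
    return ";".join(str(r) for r in normalise_ranges(ranges))


def parse_profile(record: str) -> MtProfile:
    """Parse one delimited profile line: ``id  range_spec  tok tok ...``."""
    fields = record.split()
    if len(fields) < 2:
        raise ProfileError(f"profile record needs at least id and range: {record!r}")
    sample_id, range_spec, *tokens = fields
    coverage = parse_range_spec(range_spec)
    variants = tuple(parse_variant(t) for t in tokens)
    return MtProfile(sample_id=sample_id, variants=variants, coverage=coverage)


def restrict_profile(profile: MtProfile, window: Iterable[SeqRange]) -> MtProfile:
    """Adjust a mitotype to a window: intersect coverage, drop outside variants.

    A disjoint window yields an explicitly flagged empty-coverage profile
    (``result.is_empty``), never a silent error.
    """
    new_cov = intersect_ranges(profile.coverage, window)
    kept = tuple(v for v in profile.variants if any(v.position in r for r in new_cov))
    return MtProfile(sample_id=profile.sample_id, variants=kept, coverage=new_cov)


def profile_diff(
    a: MtProfile, b: MtProfile, window: Iterable[SeqRange]
) -> tuple[frozenset[Variant], int]:
    """Symmetric difference of two mitotypes inside a shared window.

    Returns the differing variants and their count; count 0 means the two
    profiles are an exact haplotype match over the window.  Positions called
    'N' are missing data and never count as differences.
    """
    win = normalise_ranges(window)
    for p in (a, b):
        if not p.covers(win):
            raise CoverageError(
                f"window {format_range_spec(win)} not covered by {p.sample_id}"
            )
    diff = a.informative_variants(win) ^ b.informative_variants(win)
    return diff, len(diff)


def profile_to_sequence(profile: MtProfile, reference: str, window: SeqRange) -> str:
    """Expand a mitotype into nucleotides over a single window.

    Substitutions are applied, deletions emitted as ``-`` (keeping outputs over
    a common window alignable), insertions appended after their anchor position
    in insert_index order.
    """
    if len(reference) != MT_LENGTH:
        raise ProfileError(f"reference length {len(reference)} != {MT_LENGTH}")
    if not profile.covers([window]):
        raise CoverageError(
            f"window {window} not covered by {profile.sample_id} "
            f"({format_range_spec(profile.coverage)})"
        )
    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins: dict[int, list[tuple[int, str]]] = {}
    for v in profile.variants_in([window]):
        if v.kind == SUBSTITUTION:
            subs[v.position] = v.base  # type: ignore[assignment]
        elif v.kind == DELETION:
            dels.add(v.position)
        else:
            ins.setdefault(v.position, []).append((v.insert_index, v.base))  # type: ignore[arg-type]
    out: list[str] = []
    for pos in range(window.start, window.end + 1):
        if pos in dels:
            out.append("-")
        else:
            out.append(subs.get(pos, reference[pos - 1]))
        for _, base in sorted(ins.get(pos, [])):
            out.append(base)
    return "".join(out)


def build_alignment_rows(
    profiles: Sequence[MtProfile],
    reference: str,
    window: Iterable[SeqRange],
) -> list[tuple[str, str]]:
    """Expand reference-coded profiles into a gapless-width multiple alignment.

    The union of observed insertion slots (position, insert_index) across all
    profiles defines extra columns, filled with ``-`` for profiles lacking
    that insertion; deletions stay as ``-``.  Because all profiles share rCRS
    coordinates this produces a valid alignment without running an aligner.
    """
    win = normalise_ranges(window)
    for p in profiles:
        if not p.covers(win):
            raise CoverageError(f"window not covered by {p.sample_id}")
    slots: set[tuple[int, int]] = set()
    for p in profiles:
        for v in p.variants_in(win):
            if v.kind == INSERTION:
                slots.add((v.position, v.insert_index))  # type: ignore[arg-type]
    slot_order: dict[int, list[int]] = {}
    for pos, idx in sorted(slots):
        slot_order.setdefault(pos, []).append(idx)

    rows: list[tuple[str, str]] = []
    for p in profiles:
        subs: dict[int, str] = {}
        dels: set[int] = set()
        ins: dict[tuple[int, int], str] = {}
        for v in p.variants_in(win):
            if v.kind == SUBSTITUTION:
                subs[v.position] = v.base  # type: ignore[assignment]
            elif v.kind == DELETION:
                dels.add(v.position)
            else:
                ins[(v.position, v.insert_index)] = v.base  # type: ignore[index]
        chars: list[str] = []
        for r in win:
            for pos in range(r.start, r.end + 1):
                if pos in dels:
                    chars.append("-")
                else:
                    chars.append(subs.get(pos, reference[pos - 1]))
                for idx in slot_order.get(pos, []):
                    chars.append(ins.get((pos, idx), "-"))
        rows.append((p.sample_id, "".join(chars)))
    return rows


# ---------------------------------------------------------------------------
# Tabular I/O (EMPOP-style TSV: sample_id, range, space-separated variants)

def read_profile_table(path) -> list[MtProfile]:
    """Read an EMPOP-style TSV of mitotypes.

    Columns: ``sample_id``, ``range`` (e.g. ``16024-16365;73-340``) and
    ``variants`` (space-separated tokens, possibly empty).  A header line is
    detected by the literal column name ``sample_id`` and skipped.
    """
    profiles = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if line_no == 1 and parts[0].strip() == "sample_id":
                continue
            if len(parts) < 2:
                raise ProfileError(f"{path}:{line_no}: need sample_id and range columns")
            sample_id = parts[0].strip()
            coverage = parse_range_spec(parts[1])
            tokens = parts[2].split() if len(parts) > 2 else []
            profiles.append(
                MtProfile(sample_id, tuple(parse_variant(t) for t in tokens), coverage)
            )
    return profiles


def write_profile_table(path, profiles: Sequence[MtProfile]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\trange\tvariants\n")
        for p in profiles:
            toks = " ".join(v.token() for v in p.variants)
            fh.write(f"{p.sample_id}\t{format_range_spec(p.coverage)}\t{toks}\n")
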