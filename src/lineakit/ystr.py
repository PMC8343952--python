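"""Y-STR haplotypes, Cohen Modal Haplotype scoring and a reference-set scorer.

The extended Cohen Modal Haplotype (CMH) is a 12-locus Y-STR haplotype
characteristic of the Jewish priestly (Cohanim) lineage:

    DYS19, DYS388, DYS390, DYS391, DYS392, DYS393, DYS385a/b,
    DYS389I, DYS389II, DYS426, DYS439
    alleles: 14-16-23-10-11-12-13/15-13-30-11-12

The hyphenated allele string is mapped onto the locus list in that order
(DYS385a/b as the slash-separated pair); this ordering is an assumption — it
is the unique mapping consistent with the published neighbour haplotypes.
DYS389II is stored as reported by typing kits (not DYS389I-subtracted).

Scoring compares a (possibly partial) haplotype locus-by-locus against the
CMH; multi-copy loci are compared as multisets, each differing member
counting one mismatch.  Classification: a full match needs all 12 loci typed
and zero mismatches; a "close neighbour" has 1..neighbour_max mismatches with
at most 2 loci untyped; fewer than 10 typed loci is "insufficient".

``ystr_assign`` is a deliberately simple reference-set haplogroup scorer
(mean smoothed allele frequency across shared loci); it approximates what a
dedicated haplogroup predictor does without replicating any particular tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd


class YstrError(ValueError):
    """Invalid Y-STR haplotype or scoring input."""


#: Loci whose `a`/`b` suffixed names form a multi-copy pair.
PAIR_LOCI = {
    "DYS385": ("DYS385a", "DYS385b"),
    "DYF387S1": ("DYF387S1a", "DYF387S1b"),
}
_PAIR_MEMBERS = {m: base for base, pair in PAIR_LOCI.items() for m in pair}


@dataclass(frozen=True)
class MarkerPanel:
    """Named, ordered list of unique Y-STR marker names."""

    name: str
    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise YstrError(f"panel {self.name!r} has duplicate loci")

    def __len__(self) -> int:
        return len(self.loci)


#: The 12 loci of the extended Cohen Modal Haplotype.
CMH12 = MarkerPanel(
    "CMH12",
    (
        "DYS19", "DYS388", "DYS390", "DYS391", "DYS392", "DYS393",
        "DYS385a", "DYS385b", "DYS389I", "DYS389II", "DYS426", "DYS439",
    ),
)

#: 27-locus commercial Y-STR kit panel (public locus list of the Yfiler Plus
#: kit, counting DYS385 and DYF387S1 as two loci each).
YFILER_PLUS_27 = MarkerPanel(
    "YfilerPlus27",
    (
        "DYS576", "DYS389I", "DYS635", "DYS389II", "DYS627", "DYS460",
        "DYS458", "DYS19", "YGATAH4", "DYS448", "DYS391", "DYS456",
        "DYS390", "DYS438", "DYS392", "DYS518", "DYS570", "DYS437",
        "DYS385a", "DYS385b", "DYS449", "DYS393", "DYS439", "DYS481",
        "DYF387S1a", "DYF387S1b", "DYS533",
    ),
)


@dataclass(frozen=True)
class YstrHaplotype:
    """Marker → allele map; pair loci carry both members, sorted ascending."""

    sample_id: str
    alleles: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalised: dict[str, float] = {}
        for marker, value in self.alleles.items():
            v = float(value)
            if v <= 0:
                raise YstrError(f"{self.sample_id}: allele {marker}={value} must be > 0")
            normalised[marker] = v
        for base, (a, b) in PAIR_LOCI.items():
            if (a in normalised) != (b in normalised):
                # partial pair is allowed (partial haplotypes are routine) but
                # a lone value is stored under the 'a' slot for determinism
                lone = a if a in normalised else b
                if lone == b:
                    normalised[a] = normalised.pop(b)
            elif a in normalised and normalised[a] > normalised[b]:
                normalised[a], normalised[b] = normalised[b], normalised[a]
        object.__setattr__(self, "alleles", normalised)

    def typed_loci(self) -> frozenset[str]:
        return frozenset(self.alleles)


def _format_allele(v: float) -> str:
    return f"{v:g}"


#: The extended CMH reference haplotype (14-16-23-10-11-12-13/15-13-30-11-12).
CMH_REFERENCE = YstrHaplotype(
    "CMH",
    {
        "DYS19": 14, "DYS388": 16, "DYS390": 23, "DYS391": 10,
        "DYS392": 11, "DYS393": 12, "DYS385a": 13, "DYS385b": 15,
        "DYS389I": 13, "DYS389II": 30, "DYS426": 11, "DYS439": 12,
    },
)


def parse_cmh_string(sample_id: str, text: str) -> YstrHaplotype:
    """Parse a hyphenated 11-field CMH-order allele string.

    Example: ``"14-16-23-10-11-12-13/15-13-30-11-12"`` — fields follow the
    CMH12 locus order with DYS385a/b as the single slash-separated field.
    """
    fields = text.strip().split("-")
    if len(fields) != 11:
        raise YstrError(f"expected 11 hyphen-separated fields, got {len(fields)}")
    order = ["DYS19", "DYS388", "DYS390", "DYS391", "DYS392", "DYS393",
             "DYS385", "DYS389I", "DYS389II", "DYS426", "DYS439"]
    alleles: dict[str, float] = {}
    for locus, value in zip(order, fields):
        if locus == "DYS385":
            parts = value.split("/")
            if len(parts) != 2:
                raise YstrError(f"DYS385 field {value!r} must be 'a/b'")
            alleles["DYS385a"], alleles["DYS385b"] = float(parts[0]), float(parts[1])
        else:
            alleles[locus] = float(value)
    return YstrHaplotype(sample_id, alleles)


def cmh_mismatch_count(h: YstrHaplotype) -> tuple[int, int, int]:
    """Compare a haplotype to the CMH over its 12 loci.

    Returns ``(mismatches, compared, missing)`` with
    ``mismatches + matches = compared`` and ``missing = 12 - compared``.
    Pair loci are compared as multisets when both members are typed; each
    differing member counts one mismatch.
    """
    ref = CMH_REFERENCE.alleles
    mismatches = compared = 0
    handled_pairs: set[str] = set()
    for locus in CMH12.loci:
        base = _PAIR_MEMBERS.get(locus)
        if base is not None:
            if base in handled_pairs:
                continue
            handled_pairs.add(base)
            a, b = PAIR_LOCI[base]
            typed = [m for m in (a, b) if m in h.alleles]
            if len(typed) == 2:
                obs = sorted([h.alleles[a], h.alleles[b]])
                exp = sorted([ref[a], ref[b]])
                common = 0
                exp_left = list(exp)
                for v in obs:
                    if v in exp_left:
                        exp_left.remove(v)
                        common += 1
                compared += 2
                mismatches += 2 - common
            elif len(typed) == 1:
                compared += 1
                if h.alleles[typed[0]] not in (ref[a], ref[b]):
                    mismatches += 1
            continue
        if locus in h.alleles:
            compared += 1
            if h.alleles[locus] != ref[locus]:
                mismatches += 1
    return mismatches, compared, len(CMH12) - compared


FULL_MATCH = "full_match"
CLOSE_NEIGHBOUR = "close_neighbour"
OTHER = "other"
INSUFFICIENT = "insufficient"


def classify_cmh(h: YstrHaplotype, neighbour_max: int = 3) -> str:
    """Classify a haplotype's relation to the Cohen Modal Haplotype."""
    mismatches, compared, missing = cmh_mismatch_count(h)
    if mismatches == 0 and missing == 0:
        return FULL_MATCH
    if compared < 10:
        return INSUFFICIENT
    if 1 <= mismatches <= neighbour_max and missing <= 2:
        return CLOSE_NEIGHBOUR
    return OTHER


def cmh_report(haplotypes: Sequence[YstrHaplotype], neighbour_max: int = 3) -> pd.DataFrame:
    rows = []
    for h in haplotypes:
        mismatches, compared, missing = cmh_mismatch_count(h)
        rows.append(
            {
                "sample": h.sample_id,
                "mismatches": mismatches,
                "compared": compared,
                "missing": missing,
                "class": classify_cmh(h, neighbour_max),
            }
        )
    return pd.DataFrame(rows)


def panel_coverage(panel: MarkerPanel, target: MarkerPanel) -> int:
    """Number of target loci a typing panel covers."""
    return len(set(panel.loci) & set(target.loci))


def ystr_assign(
    h: YstrHaplotype,
    refsets: Mapping[str, Sequence[YstrHaplotype]],
) -> pd.DataFrame:
    """Rank candidate Y haplogroups by mean smoothed allele frequency.

    For each reference set g, score(g) is the mean over loci typed in both h
    and g of (count of h's allele in g + 1) / (records typing the locus + 1).
    The table is ranked descending with ``predicted`` True on the top row, or
    marked ``ambiguous`` when the top two scores differ by under 5% relative.
    """
    if not refsets:
        raise YstrError("refsets must be non-empty")
    rows = []
    for group, refs in refsets.items():
        if not refs:
            raise YstrError(f"reference set {group!r} is empty")
        shared_scores = []
        for locus, allele in h.alleles.items():
            typed = [r.alleles[locus] for r in refs if locus in r.alleles]
            if not typed:
                continue
            count = sum(1 for v in typed if v == allele)
            shared_scores.append((count + 1) / (len(typed) + 1))
        if not shared_scores:
            raise YstrError(f"no shared typed loci between {h.sample_id} and {group!r}")
        rows.append({"haplogroup": group, "score": sum(shared_scores) / len(shared_scores)})
    table = pd.DataFrame(rows).sort_values(
        ["score", "haplogroup"], ascending=[False, True], ignore_index=True
    )
    top = table.loc[0, "score"]
    second = table.loc[1, "score"] if len(table) > 1 else 0.0
    ambiguous = len(table) > 1 and top > 0 and (top - second) / top < 0.05
    table["predicted"] = [i == 0 and not ambiguous for i in range(len(table))]
    table["ambiguous"] = ambiguous
    return table


# ---------------------------------------------------------------------------
# Tabular I/O (TSV: sample column + one column per marker; pairs as "a,b")


def read_ystr_table(path) -> list[YstrHaplotype]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise YstrError("Y-STR table needs a sample_id column")
    out = []
    for _, row in df.iterrows():
        alleles: dict[str, float] = {}
        for marker in df.columns:
            if marker == "sample_id":
                continue
            value = row[marker]
            if pd.isna(value) or str(value).strip() == "":
                continue
            if marker in PAIR_LOCI:
                a, b = str(value).split(",")
                m_a, m_b = PAIR_LOCI[marker]
                alleles[m_a], alleles[m_b] = float(a), float(b)
            else:
                alleles[marker] = float(value)
        out.append(YstrHaplotype(str(row["sample_id"]), alleles))
    return out


def write_ystr_table(path, haplotypes: Sequence[YstrHaplotype]) -> None:
    markers: list[str] = []
    for h in haplotypes:
        for m in h.alleles:
            base = _PAIR_MEMBERS.get(m)
            col = base if base is not None else m
            if col not in markers:
                markers.append(col)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(markers) + "\n")
        for h in haplotypes:
            cells = [h.sample_id]
            for col in markers:
                if col in PAIR_LOCI:
                    a, b = PAIR_LOCI[col]
                    if a in h.alleles and b in h.alleles:
                        cells.append(
                            f"{_format_allele(h.alleles[a])},{_format_allele(h.alleles[b])}"
                        )
                    elif a in h.alleles:
                        cells.append(_format_allele(h.alleles[a]))
                    else:
                        cells.append("")
                else:
                    cells.append(
                        _format_allele(h.alleles[col]) if col in h.alleles else ""
                    )
            fh.write("\t".join(cells) + "\n")
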