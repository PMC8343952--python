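"""Mitochondrial reference sequence handling.

Forensic mtDNA profiles are coded as differences to the revised Cambridge
Reference Sequence (rCRS), the canonical 16,569-bp human mitochondrial
reference.  This module loads a reference from FASTA and, for fully
self-contained runs, builds a deterministic *synthetic* stand-in of the same
length.  All match counting and probability statistics operate on variant
tokens and never depend on reference content; the reference sequence is only
needed to expand profiles into nucleotide strings for alignment building.
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO

#: Length of the human mitochondrial genome in rCRS numbering.
MT_LENGTH = 16569

# True rCRS bases at the control-region positions referenced by the shipped
# haplogroup table (the base a variant token such as "263G" replaces).  The
# synthetic stand-in reference is pinned to these so that diagnostic variants
# remain genuine substitutions; every other position is arbitrary.
ANCHOR_BASES: dict[int, str] = {
    73: "A", 114: "C", 146: "T", 152: "T", 185: "G", 195: "T", 199: "T",
    200: "A", 203: "G", 204: "T", 225: "G", 228: "G", 250: "T", 263: "A",
    16048: "G", 16067: "C", 16069: "C", 16092: "T", 16093: "T", 16111: "C",
    16126: "T", 16129: "G", 16145: "G", 16153: "G", 16172: "T", 16183: "A",
    16189: "T", 16223: "C", 16224: "T", 16234: "C", 16256: "C", 16278: "C",
    16298: "T", 16304: "T", 16311: "T", 16319: "G",
}

_SYNTHETIC_SEED = 424242  # fixed: the stand-in is a constant, not a sample


def synthetic_reference() -> str:
    """Return a synthetic 16,569-bp reference sequence.

    A deterministic stand-in for the rCRS used when no reference FASTA is
    supplied (e.g. fully synthetic pipelines and tests).  It matches the true
    rCRS at the anchor positions in :data:`ANCHOR_BASES` and is random but
    fixed elsewhere.  It is *not* the rCRS and must not be used to interpret
    real casework profiles.
    """
    rng = np.random.default_rng(_SYNTHETIC_SEED)
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, size=MT_LENGTH)]
    for pos, base in ANCHOR_BASES.items():
        seq[pos - 1] = base
    return "".join(seq)


def load_reference(path) -> str:
    """Read a single-record reference FASTA (e.g. the rCRS, NC_012920.1).

    Raises ``ValueError`` if the file does not contain exactly one record of
    length :data:`MT_LENGTH`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly 1 FASTA record, found {len(records)}")
    seq = str(records[0].seq).upper()
    if len(seq) != MT_LENGTH:
        raise ValueError(
            f"reference length {len(seq)} != expected mitogenome length {MT_LENGTH}"
        )
    return seq


def write_reference(path, seq: str, name: str = "synthetic_mt_reference") -> None:
    """Write a reference sequence as FASTA (60-column wrapped)."""
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
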