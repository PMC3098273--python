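"""GC-content computation and cluster-versus-genome comparison.

A gene cluster whose GC composition departs from the genome background is a
candidate horizontally transferred region (e.g. a pfaA homolog at 46% GC in
a 39% GC genome).  Only unambiguous bases (A, C, G, T/U) enter the
calculation; N and IUPAC ambiguity codes are excluded from numerator and
denominator alike.  No significance is attached to the delta: composition
alone does not establish transfer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .model import ValidationError

IUPAC_NUCLEOTIDES = set("ACGTUNRYSWKMBDHV")
UNAMBIGUOUS = set("ACGTU")


@dataclass(frozen=True)
class GcReport:
    region_id: str
    region_gc: float
    background_gc: float

    @property
    def delta(self) -> float:
        return self.region_gc - self.background_gc


def gc_fraction(seq: str) -> float:
    """(#G + #C) / #unambiguous bases, case-insensitive."""
    s = seq.upper()
    bad = set(s) - IUPAC_NUCLEOTIDES
    if bad:
        raise ValidationError(f"illegal nucleotide characters: {sorted(bad)}")
    unambiguous = sum(s.count(b) for b in UNAMBIGUOUS)
    if unambiguous == 0:
        raise ValidationError("no unambiguous bases; GC fraction undefined")
    return (s.count("G") + s.count("C")) / unambiguous


def compare_gc(region: str, background: str, region_id: str = "region",
               ) -> GcReport:
    """GC fraction of a region versus its background sequence."""
    return GcReport(region_id=region_id,
                    region_gc=gc_fraction(region),
                    background_gc=gc_fraction(background))


def compare_gc_fasta(region_path: str | Path, background_path: str | Path,
                     ) -> pd.DataFrame:
    """Compare every region record against the concatenated background."""
    background = "".join(str(rec.seq) for rec in
                         SeqIO.parse(str(background_path), "fasta"))
    rows = []
    for rec in SeqIO.parse(str(region_path), "fasta"):
        rep = compare_gc(str(rec.seq), background, region_id=rec.id)
        rows.append({"region_id": rep.region_id,
                     "region_gc": rep.region_gc,
                     "background_gc": rep.background_gc,
                     "delta": rep.delta})
    return pd.DataFrame(rows)
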