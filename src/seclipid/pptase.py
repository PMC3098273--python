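"""Phosphopantetheinyl transferase (PPTase) motif scanning and classification.

PPTases activate ACP domains by attaching the 4'-phosphopantetheine arm, and
their variable sequence motifs separate PUFA-associated synthases from
PKS/NRPS systems.  The informative motifs are P0 (hRxhLS), P1a (x(G/D)xP)
and P1b ((F/S)NxSH) in PUFA-type PPTases, and P1b' (hShxH) in PKS/NRPS-type
PPTases, where ``h`` is any hydrophobic residue and ``x`` any residue.  A
PPTase carrying P1a and P1b (in order) is called PUFA-like; one carrying
P1b' but no P1b is called PKS/NRPS-like.  P0 is reported but not required
for the PUFA call, because the phenolic-lipid (Type P) PPTase lacks it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .model import ValidationError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Default hydrophobic residue set for the ``h`` wildcard.  It must contain
#: L and V (h generalises (L/V) in the P0 motif) and G and I (h generalises
#: G and I in the P1b' motif); the remaining members follow the common
#: hydrophobicity grouping.
DEFAULT_HYDROPHOBIC = frozenset("GAVLIMFWYC")


@dataclass(frozen=True)
class MotifPosition:
    """One position of a motif pattern: 'h', 'x', or a residue alternation."""

    symbol: str              # 'h', 'x' or 'literal'
    residues: frozenset[str] = frozenset()

    def matches(self, residue: str, hydrophobic_set: frozenset[str]) -> bool:
        if residue == "X":
            return self.symbol == "x"
        if self.symbol == "x":
            return True
        if self.symbol == "h":
            return residue in hydrophobic_set
        return residue in self.residues


@dataclass(frozen=True)
class MotifDefinition:
    motif_id: str
    pattern: str
    positions: tuple[MotifPosition, ...]

    def __len__(self) -> int:
        return len(self.positions)


def parse_pattern(motif_id: str, pattern: str) -> MotifDefinition:
    """Parse a compact motif pattern such as ``x(G/D)xP`` or ``hRxhLS``."""
    positions: list[MotifPosition] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "(":
            j = pattern.index(")", i)
            residues = frozenset(pattern[i + 1:j].split("/"))
            if not residues <= AMINO_ACIDS:
                raise ValidationError(f"bad alternation in pattern {pattern!r}")
            positions.append(MotifPosition("literal", residues))
            i = j + 1
        elif ch in ("h", "x"):
            positions.append(MotifPosition(ch))
            i += 1
        elif ch in AMINO_ACIDS:
            positions.append(MotifPosition("literal", frozenset(ch)))
            i += 1
        else:
            raise ValidationError(f"bad character {ch!r} in pattern {pattern!r}")
    return MotifDefinition(motif_id=motif_id, pattern=pattern,
                           positions=tuple(positions))


DEFAULT_MOTIFS: dict[str, MotifDefinition] = {
    "P0": parse_pattern("P0", "hRxhLS"),
    "P1a": parse_pattern("P1a", "x(G/D)xP"),
    "P1b": parse_pattern("P1b", "(F/S)NxSH"),
    "P1b_prime": parse_pattern("P1b_prime", "hShxH"),
}


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start: int            # 1-based residue position
    matched_subsequence: str


@dataclass
class PPTaseClassification:
    sequence_id: str
    hits: list[MotifHit]
    call: str             # PUFA_like | PKS_NRPS_like | ambiguous
    p0_present: bool
    note: str = ""

    def hits_for(self, motif_id: str) -> list[MotifHit]:
        return [h for h in self.hits if h.motif_id == motif_id]


def _validate_protein(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - AMINO_ACIDS - {"X"}
    if bad:
        raise ValidationError(f"illegal protein characters: {sorted(bad)}")
    return seq


def scan_motif(seq: str, motif: MotifDefinition,
               hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC,
               ) -> list[MotifHit]:
    """All (possibly overlapping) matches of a motif, left to right.

    ``X`` in the sequence matches only the any-residue wildcard ``x``.
    """
    seq = _validate_protein(seq)
    L = len(motif)
    hits = []
    for start in range(len(seq) - L + 1):
        window = seq[start:start + L]
        if all(p.matches(r, hydrophobic_set)
               for p, r in zip(motif.positions, window)):
            hits.append(MotifHit(motif.motif_id, start + 1, window))
    return hits


def classify_pptase(seq: str, sequence_id: str = "",
                    motifs: dict[str, MotifDefinition] | None = None,
                    hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC,
                    require_order: bool = True) -> PPTaseClassification:
    """Classify one PPTase sequence from its motif content.

    PUFA_like requires a P1a hit and a P1b hit (with P1a before P1b when
    ``require_order``); PKS_NRPS_like requires a P1b' hit and no P1b hit;
    anything else is ambiguous.  ``p0_present`` reports the P0 motif
    independently of the call.
    """
    motifs = motifs or DEFAULT_MOTIFS
    seq = _validate_protein(seq)
    all_hits: list[MotifHit] = []
    by_motif: dict[str, list[MotifHit]] = {}
    for mid, motif in motifs.items():
        found = scan_motif(seq, motif, hydrophobic_set)
        by_motif[mid] = found
        all_hits.extend(found)
    all_hits.sort(key=lambda h: (h.start, h.motif_id))

    p1a = by_motif.get("P1a", [])
    p1b = by_motif.get("P1b", [])
    p1b_prime = by_motif.get("P1b_prime", [])
    p0 = by_motif.get("P0", [])

    chosen_pair = None
    if require_order:
        for ha in p1a:
            later = [hb for hb in p1b if hb.start > ha.start]
            if later:
                chosen_pair = (ha, later[0])
                break
    elif p1a and p1b:
        chosen_pair = (p1a[0], p1b[0])

    note = ""
    if p1b and p1b_prime:
        note = "both P1b and P1b' present; PUFA rule takes precedence"

    if chosen_pair is not None:
        if require_order:
            p0_present = any(h.start < chosen_pair[0].start for h in p0)
        else:
            p0_present = bool(p0)
        call = "PUFA_like"
    else:
        p0_present = bool(p0)
        call = "PKS_NRPS_like" if (p1b_prime and not p1b) else "ambiguous"
    return PPTaseClassification(sequence_id=sequence_id, hits=all_hits,
                                call=call, p0_present=p0_present, note=note)


def classify_fasta(path: str | Path,
                   motifs: dict[str, MotifDefinition] | None = None,
                   hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC,
                   require_order: bool = True) -> pd.DataFrame:
    """Classify every protein record of a FASTA file; returns a table with
    one row per sequence (call, P0 presence, per-motif hit positions)."""
    motifs = motifs or DEFAULT_MOTIFS
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cls = classify_pptase(str(rec.seq), sequence_id=rec.id, motifs=motifs,
                              hydrophobic_set=hydrophobic_set,
                              require_order=require_order)
        row = {"sequence_id": rec.id, "call": cls.call,
               "p0_present": int(cls.p0_present), "note": cls.note}
        for mid in motifs:
            row[f"{mid}_positions"] = ",".join(
                str(h.start) for h in cls.hits_for(mid)) or "NA"
        rows.append(row)
    return pd.DataFrame(rows)
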