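"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure the analysis assumes:
gene clusters derived from Type templates with ACP copy-number variation
and per-domain indels/substitutions; PPTase protein sequences with ordered
planted motifs on a motif-free random background; binary life-history trait
matrices with a tunable group-trait association strength; and genomes with
a planted region of aberrant GC composition.  All outputs are fully
determined by their seed, and generated files round-trip through the module
readers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (DomainAnnotation, DomainKind, Gene, GeneCluster,
                    TypeDefinition, ValidationError)
from .pptase import DEFAULT_MOTIFS, AMINO_ACIDS, MotifDefinition, scan_motif
from .traits import TraitMatrix

_SUBSTITUTABLE = [k for k in DomainKind if k is not DomainKind.OTHER]
_AA = sorted(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# gene clusters
# ---------------------------------------------------------------------------

def gen_clusters_from_type(type_def: TypeDefinition, n: int,
                           perturb_p: float, seed: int,
                           id_prefix: str | None = None,
                           ) -> list[GeneCluster]:
    """Clusters derived from one Type template.

    Each template architecture entry (one domain, or one tandem-ACP run) is
    independently perturbed with probability ``perturb_p``: deleted, or
    substituted by a uniformly random different domain kind, with equal
    probability.  Surviving ACP entries expand to a run whose length is
    drawn uniformly from the template's copy-number range.  The source Type
    letter is recorded in ``assigned_type`` as generative ground truth.
    """
    if not 0.0 <= perturb_p <= 1.0:
        raise ValidationError("perturb_p must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, ord(type_def.letter)]))
    prefix = id_prefix or f"sim_{type_def.letter}"
    out = []
    for i in range(n):
        genes = []
        for tg in type_def.template_genes:
            perturbed: list[DomainKind] = []
            for td in tg.domains:
                kind = td.kind
                if rng.random() < perturb_p:
                    if rng.random() < 0.5:
                        continue  # entry deleted
                    choices = [k for k in _SUBSTITUTABLE if k is not kind]
                    kind = choices[int(rng.integers(len(choices)))]
                    perturbed.append(kind)
                    continue
                copies = (int(rng.integers(td.acp_min, td.acp_max + 1))
                          if kind is DomainKind.ACP else 1)
                perturbed.extend([kind] * copies)
            if perturbed:
                genes.append(Gene(
                    locus_id=f"{prefix}_{i:04d}:{tg.slot}",
                    domains=tuple(DomainAnnotation(k, j + 1)
                                  for j, k in enumerate(perturbed))))
        if not genes:  # pathological full deletion; keep one template domain
            first = type_def.template_genes[0]
            genes = [Gene(locus_id=f"{prefix}_{i:04d}:{first.slot}",
                          domains=(DomainAnnotation(first.domains[0].kind, 1),))]
        cluster = GeneCluster(cluster_id=f"{prefix}_{i:04d}",
                              organism=f"synthetic organism {prefix}_{i:04d}",
                              genes=tuple(genes))
        cluster.assigned_type = type_def.letter
        out.append(cluster)
    return out


# ---------------------------------------------------------------------------
# PPTase sequences with planted motifs
# ---------------------------------------------------------------------------

def _sample_instance(motif: MotifDefinition, rng: np.random.Generator,
                     hydrophobic: Sequence[str]) -> str:
    residues = []
    for pos in motif.positions:
        if pos.symbol == "x":
            pool = _AA
        elif pos.symbol == "h":
            pool = sorted(hydrophobic)
        else:
            pool = sorted(pos.residues)
        residues.append(pool[int(rng.integers(len(pool)))])
    return "".join(residues)


def _motif_free_background(length: int, rng: np.random.Generator,
                           motifs: Mapping[str, MotifDefinition],
                           max_rounds: int = 10000) -> str:
    seq = [_AA[int(i)] for i in rng.integers(len(_AA), size=length)]
    for _ in range(max_rounds):
        dirty: set[int] = set()
        for motif in motifs.values():
            for hit in scan_motif("".join(seq), motif):
                dirty.update(range(hit.start - 1, hit.start - 1 + len(motif)))
        if not dirty:
            return "".join(seq)
        for i in sorted(dirty):
            seq[i] = _AA[int(rng.integers(len(_AA)))]
    raise ValidationError("failed to produce a motif-free background")


def gen_pptase(class_label: str, length: int = 300, seed: int = 0,
               motifs: Mapping[str, MotifDefinition] | None = None,
               hydrophobic: Sequence[str] = tuple("GAVLIMFWYC"),
               ) -> tuple[str, dict[str, int]]:
    """A synthetic PPTase protein with planted, ordered motifs.

    PUFA_like sequences receive P0, then P1a, then P1b; PKS_NRPS_like
    sequences receive only P1b'.  The background is rejection-sampled to be
    free of all motifs, and the planted 1-based positions are returned as
    ground truth.
    """
    motifs = dict(motifs or DEFAULT_MOTIFS)
    if class_label == "PUFA_like":
        plan = ["P0", "P1a", "P1b"]
    elif class_label == "PKS_NRPS_like":
        plan = ["P1b_prime"]
    else:
        raise ValidationError(f"unknown class label {class_label!r}")
    if length < 60:
        raise ValidationError("length must be >= 60")
    total_motif = sum(len(motifs[m]) for m in plan)
    if length < total_motif + 2 * (len(plan) + 1):
        raise ValidationError("length too short to hold the ordered motifs")
    rng = np.random.default_rng(np.random.SeedSequence([seed, len(plan)]))
    seq = list(_motif_free_background(length, rng, motifs))
    # spread planting sites evenly with at least one spacer residue
    slots = np.linspace(2, length - max(len(motifs[m]) for m in plan) - 2,
                        num=len(plan), dtype=int)
    planted: dict[str, int] = {}
    for mid, start in zip(plan, slots):
        inst = _sample_instance(motifs[mid], rng, hydrophobic)
        seq[start:start + len(inst)] = list(inst)
        planted[mid] = int(start) + 1
    return "".join(seq), planted


def write_pptase_fasta(records: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# trait matrices
# ---------------------------------------------------------------------------

def gen_trait_matrix(group_sizes: Mapping[str, int], n_traits: int = 33,
                     theta: float = 0.5, seed: int = 0) -> TraitMatrix:
    """Binary trait matrix with tunable group-trait association.

    Each trait is group-informative with probability ``theta``; informative
    traits give each group a Bernoulli rate drawn from {0.1, 0.9}, while
    uninformative traits use a common rate of 0.5.  ``theta = 0`` is the
    null (traits independent of groups); ``theta = 1`` is maximally
    informative.  All-zero organisms are resampled so Bray-Curtis stays
    defined.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValidationError("theta must be in [0, 1]")
    if any(n < 1 for n in group_sizes.values()) or not group_sizes:
        raise ValidationError("every group must have at least one organism")
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_traits]))
    letters = sorted(group_sizes)
    groups = [g for g in letters for _ in range(group_sizes[g])]
    N = len(groups)
    rates = np.full((len(letters), n_traits), 0.5)
    informative = rng.random(n_traits) < theta
    for t in np.flatnonzero(informative):
        rates[:, t] = rng.choice([0.1, 0.9], size=len(letters))
    gidx = np.array([letters.index(g) for g in groups])
    values = (rng.random((N, n_traits)) < rates[gidx]).astype(np.int8)
    for i in np.flatnonzero(values.sum(axis=1) == 0):
        values[i, int(rng.integers(n_traits))] = 1
    organisms = tuple(f"org_{g}_{i:03d}" for i, g in enumerate(groups))
    return TraitMatrix(organisms=organisms,
                       traits=tuple(f"trait_{t+1:02d}" for t in range(n_traits)),
                       values=values, groups=tuple(groups))


# ---------------------------------------------------------------------------
# genomes with planted regions
# ---------------------------------------------------------------------------

def _sample_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(["A", "C", "G", "T"]), size=n, p=p)


def gen_genome_with_cluster(genome_len: int, genome_gc: float,
                            cluster_len: int, cluster_gc: float,
                            seed: int = 0) -> tuple[str, tuple[int, int]]:
    """A genome with a planted cluster region of different GC composition.

    Bases are sampled i.i.d. at the stated GC fractions; the planted region
    is centred in the genome and its 1-based inclusive coordinates are
    returned.
    """
    if genome_len <= 0 or cluster_len <= 0:
        raise ValidationError("lengths must be positive")
    if cluster_len > genome_len:
        raise ValidationError("cluster longer than genome")
    if not (0 <= genome_gc <= 1 and 0 <= cluster_gc <= 1):
        raise ValidationError("GC targets must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, genome_len]))
    genome = _sample_bases(genome_len, genome_gc, rng)
    start = (genome_len - cluster_len) // 2
    genome[start:start + cluster_len] = _sample_bases(cluster_len, cluster_gc, rng)
    return "".join(genome), (start + 1, start + cluster_len)


# ---------------------------------------------------------------------------
# bundle emission
# ---------------------------------------------------------------------------

def write_ground_truth(rows: Sequence[Mapping], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
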