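"""Domain-level data model for secondary lipid synthase gene clusters.

Secondary lipid synthases are iterative type I FAS/PKS enzyme complexes
(archetype: the Pfa synthase encoded by *pfaA-E*) whose products include
long-chain omega-3 PUFAs such as EPA and DHA, heterocyst glycolipid alkyl
chains and phenolic lipid alkyl chains.  A gene cluster is modelled as an
ordered list of genes, each carrying an ordered list of typed biosynthetic
domains (KS, MAT, AT, ACP, KR, DH, ER, CLF, PPTase).  The module also ships
the packaged catalog of the 20 cluster Types (A-T) with their member
organisms and template architectures, and the candidate-screening helpers
(e-value filter on tabular homology hits, tandem-ACP detection).
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class CatalogError(ValueError):
    """Malformed or inconsistent catalog input."""


class ValidationError(ValueError):
    """A value violates a model invariant."""


class DomainKind(str, enum.Enum):
    """Enzymatic domain vocabulary of iterative type I FAS/PKS clusters."""

    KS = "KS"          # ketoacyl synthase (condensation)
    MAT = "MAT"        # malonyl-CoA:ACP transacylase
    AT = "AT"          # acyltransferase
    ACP = "ACP"        # acyl carrier protein
    KR = "KR"          # ketoacyl reductase
    DH = "DH"          # dehydratase/isomerase (single combined label)
    ER = "ER"          # enoyl reductase
    CLF = "CLF"        # chain length factor
    PPTase = "PPTase"  # phosphopantetheinyl transferase
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Letter code used when concatenating domain architectures into strings.
#: The first six assignments are fixed by the worked example
#: KS-MAT-ACP2-KR-ER-PPTase -> "ABCCDEF"; the remainder follow
#: first-appearance order in the canonical Type A architecture.
DEFAULT_LETTER_MAP: dict[DomainKind, str] = {
    DomainKind.KS: "A",
    DomainKind.MAT: "B",
    DomainKind.ACP: "C",
    DomainKind.KR: "D",
    DomainKind.ER: "E",
    DomainKind.PPTase: "F",
    DomainKind.AT: "G",
    DomainKind.CLF: "H",
    DomainKind.DH: "I",
}

#: Number of finished/draft genomes screened in the survey that the packaged
#: catalog summarises; used to express catalog size as a hit rate.
GENOMES_SCREENED = 3839


@dataclass(frozen=True)
class DomainAnnotation:
    """A single typed domain at a 1-based position within its gene."""

    kind: DomainKind
    ordinal: int
    has_active_site: bool | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.kind, DomainKind):
            object.__setattr__(self, "kind", DomainKind(self.kind))
        if self.ordinal < 1:
            raise ValidationError(f"domain ordinal must be >= 1, got {self.ordinal}")


@dataclass(frozen=True)
class Gene:
    """One gene of a cluster with its ordered domain annotations."""

    locus_id: str
    domains: tuple[DomainAnnotation, ...] = ()
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValidationError("locus_id must be non-empty")
        if self.strand not in ("+", "-", "unknown"):
            raise ValidationError(f"invalid strand {self.strand!r}")
        object.__setattr__(self, "domains", tuple(self.domains))
        ordinals = [d.ordinal for d in self.domains]
        if any(b <= a for a, b in zip(ordinals, ordinals[1:])):
            raise ValidationError(
                f"domain ordinals in gene {self.locus_id} must be strictly increasing"
            )

    @property
    def kinds(self) -> tuple[DomainKind, ...]:
        return tuple(d.kind for d in self.domains)


def genus_of(organism: str) -> str:
    """First whitespace token of the organism name.

    A leading "Candidatus" qualifier and quoting characters are stripped, so
    e.g. ``Candidatus Koribacter versatilis Ellin345`` -> ``Koribacter``.
    """
    name = organism.strip().strip("'\"‘’“”")
    tokens = name.split()
    if tokens and tokens[0].lower() == "candidatus":
        tokens = tokens[1:]
    if not tokens:
        raise ValidationError(f"cannot derive genus from organism {organism!r}")
    return tokens[0].strip("'\"‘’“”")


@dataclass
class GeneCluster:
    """An ordered run of genes; the unit being typed and compared."""

    cluster_id: str
    organism: str
    genes: tuple[Gene, ...]
    genus: str = ""
    assigned_type: str | None = None

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if not self.genus:
            self.genus = genus_of(self.organism) if self.organism.strip() else ""

    @property
    def domain_kinds(self) -> tuple[DomainKind, ...]:
        """Domains concatenated across genes in cluster order."""
        return tuple(k for g in self.genes for k in g.kinds)

    @property
    def n_domains(self) -> int:
        return len(self.domain_kinds)


@dataclass(frozen=True)
class TemplateDomain:
    """One token of a template architecture.

    ACP tokens carry the copy-number range seen in that Type; all other
    kinds represent exactly one domain.
    """

    kind: DomainKind
    acp_min: int = 1
    acp_max: int = 1

    def __post_init__(self) -> None:
        if self.acp_min < 1 or self.acp_min > self.acp_max:
            raise CatalogError(
                f"invalid ACP copy-number range ({self.acp_min},{self.acp_max})"
            )


@dataclass(frozen=True)
class TemplateGene:
    slot: str
    domains: tuple[TemplateDomain, ...]


@dataclass
class TypeDefinition:
    """A canonical cluster Type (A-T): template architecture plus members."""

    letter: str
    template_genes: tuple[TemplateGene, ...]
    member_organisms: tuple[str, ...] = ()
    fully_specified: bool = True

    @property
    def collapsed_tokens(self) -> tuple[TemplateDomain, ...]:
        """Template tokens concatenated across gene slots (ACP runs are
        already single tokens carrying their copy-number range)."""
        return tuple(d for g in self.template_genes for d in g.domains)

    def canonical_cluster(self, cluster_id: str | None = None,
                          organism: str = "") -> GeneCluster:
        """Instantiate the template as a concrete cluster.

        ACP runs are expanded to the midpoint of their copy-number range
        (rounded down), e.g. a 4-6 range yields five tandem ACPs.
        """
        genes = []
        for tg in self.template_genes:
            domains = []
            ordinal = 1
            for td in tg.domains:
                copies = (td.acp_min + td.acp_max) // 2 if td.kind is DomainKind.ACP else 1
                for _ in range(copies):
                    domains.append(DomainAnnotation(td.kind, ordinal))
                    ordinal += 1
            genes.append(Gene(locus_id=f"{self.letter}:{tg.slot}", domains=tuple(domains)))
        cid = cluster_id or f"type_{self.letter}_template"
        org = organism or f"Type {self.letter} template"
        return GeneCluster(cluster_id=cid, organism=org, genes=tuple(genes),
                           genus=genus_of(org))


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular homology-search hit table."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"e-value must be non-negative, got {self.evalue}")
        if self.alignment_length < 0:
            raise ValidationError("alignment_length must be non-negative")


# ---------------------------------------------------------------------------
# architecture encoding and screening operations
# ---------------------------------------------------------------------------

def encode_architecture(cluster: GeneCluster,
                        letter_map: Mapping[DomainKind, str] = DEFAULT_LETTER_MAP,
                        ) -> str:
    """Letter-code a cluster's domain architecture.

    Domains are concatenated across genes in cluster order; gene boundaries
    are ignored.  With the default map, KS-MAT-ACP2-KR-ER-PPTase encodes to
    ``"ABCCDEF"``.
    """
    letters = []
    for kind in cluster.domain_kinds:
        try:
            letters.append(letter_map[kind])
        except KeyError:
            raise ValidationError(
                f"no letter assigned for domain kind {kind.value!r}"
            ) from None
    return "".join(letters)


def collapse_acp_runs(kinds: Sequence[DomainKind],
                      ) -> list[tuple[DomainKind, int]]:
    """Replace each maximal run of consecutive ACP domains by a single token
    carrying the run length; non-ACP domains become (kind, 1) tokens."""
    out: list[tuple[DomainKind, int]] = []
    for k in kinds:
        if k is DomainKind.ACP and out and out[-1][0] is DomainKind.ACP:
            out[-1] = (DomainKind.ACP, out[-1][1] + 1)
        else:
            out.append((k, 1))
    return out


def detect_tandem_acp(gene: Gene) -> tuple[int, bool]:
    """Longest run of consecutive ACP domains in a gene.

    Tandem ACPs (run >= 2) are the hallmark of secondary lipid synthases and
    the most informative screening signature.
    """
    max_run = run = 0
    for kind in gene.kinds:
        run = run + 1 if kind is DomainKind.ACP else 0
        max_run = max(max_run, run)
    return max_run, max_run >= 2


def filter_hits(hits: Iterable[HitRecord], evalue_max: float = 1e-30,
                ) -> list[HitRecord]:
    """Keep hits with evalue <= evalue_max (inclusive), preserving order."""
    if evalue_max < 0:
        raise ValidationError("evalue_max must be non-negative")
    return [h for h in hits if h.evalue <= evalue_max]


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tab-separated homology hit table (no header)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["query_id", "subject_id", "percent_identity",
                            "alignment_length", "mismatches", "gap_opens",
                            "q_start", "q_end", "s_start", "s_end",
                            "evalue", "bitscore"])
    return [HitRecord(**row) for row in df.to_dict("records")]


def write_hit_table(hits: Sequence[HitRecord], path: str | Path) -> None:
    cols = ["query_id", "subject_id", "percent_identity", "alignment_length",
            "mismatches", "gap_opens", "q_start", "q_end", "s_start",
            "s_end", "evalue", "bitscore"]
    df = pd.DataFrame([{c: getattr(h, c) for c in cols} for h in hits])
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# cluster TSV dialect
# ---------------------------------------------------------------------------

CLUSTER_TSV_COLUMNS = ["cluster_id", "organism", "gene_locus", "gene_index",
                       "domain_index", "domain_kind", "has_active_site"]


def read_clusters_tsv(path: str | Path) -> list[GeneCluster]:
    """Read gene clusters from the domain-architecture TSV dialect.

    Columns: cluster_id, organism, gene_locus, gene_index, domain_index,
    domain_kind, has_active_site (0/1/NA).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CLUSTER_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise CatalogError(f"cluster TSV missing columns: {sorted(missing)}")
    clusters: list[GeneCluster] = []
    for cid, cdf in df.groupby("cluster_id", sort=False):
        organism = cdf["organism"].iloc[0]
        genes = []
        cdf = cdf.assign(gene_index=cdf["gene_index"].astype(int),
                         domain_index=cdf["domain_index"].astype(int))
        for (_, locus), gdf in cdf.sort_values(["gene_index", "domain_index"]) \
                                  .groupby(["gene_index", "gene_locus"], sort=True):
            domains = []
            for _, row in gdf.iterrows():
                has_as = row["has_active_site"]
                has_as = None if pd.isna(has_as) or has_as == "NA" else bool(int(has_as))
                try:
                    kind = DomainKind(row["domain_kind"])
                except ValueError:
                    raise CatalogError(
                        f"unknown domain kind {row['domain_kind']!r} in cluster {cid}"
                    ) from None
                domains.append(DomainAnnotation(kind, int(row["domain_index"]),
                                                has_active_site=has_as))
            genes.append(Gene(locus_id=str(locus), domains=tuple(domains)))
        clusters.append(GeneCluster(cluster_id=str(cid), organism=str(organism),
                                    genes=tuple(genes)))
    return clusters


def write_clusters_tsv(clusters: Sequence[GeneCluster], path: str | Path) -> None:
    rows = []
    for c in clusters:
        for gi, g in enumerate(c.genes, start=1):
            for d in g.domains:
                has_as = "NA" if d.has_active_site is None else str(int(d.has_active_site))
                rows.append([c.cluster_id, c.organism, g.locus_id, gi,
                             d.ordinal, d.kind.value, has_as])
    pd.DataFrame(rows, columns=CLUSTER_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged catalog
# ---------------------------------------------------------------------------

TYPE_LETTERS = tuple("ABCDEFGHIJKLMNOPQRST")


@dataclass
class Catalog:
    """The packaged catalog: 20 Type definitions and their memberships."""

    types: dict[str, TypeDefinition]

    @property
    def letters(self) -> list[str]:
        return sorted(self.types)

    def memberships(self) -> list[tuple[str, str]]:
        """(organism, type_letter) pairs, one per membership."""
        return [(org, t.letter) for t in self.types.values()
                for org in t.member_organisms]

    def organisms(self) -> list[str]:
        return sorted({org for org, _ in self.memberships()})

    def clusters(self) -> list[GeneCluster]:
        """One canonical cluster per (organism, Type) membership."""
        out = []
        for letter in self.letters:
            tdef = self.types[letter]
            for org in tdef.member_organisms:
                cid = f"{letter}:{org}"
                cluster = tdef.canonical_cluster(cluster_id=cid, organism=org)
                cluster.assigned_type = letter
                out.append(cluster)
        return out

    def template_clusters(self, fully_specified_only: bool = False,
                          ) -> list[GeneCluster]:
        out = []
        for letter in self.letters:
            tdef = self.types[letter]
            if fully_specified_only and not tdef.fully_specified:
                continue
            c = tdef.canonical_cluster()
            c.assigned_type = letter
            out.append(c)
        return out


def _packaged(name: str) -> Path:
    return Path(importlib.resources.files("seclipid.data") / name)


def load_catalog(membership_path: str | Path | None = None,
                 template_path: str | Path | None = None) -> Catalog:
    """Load the Type catalog (packaged transcription by default).

    The membership TSV has columns organism, genus, type_letters (comma
    separated for organisms whose genome carries two cluster Types); the
    template TSV has one row per template domain token with columns
    type_letter, gene_slot, domain_kind, acp_min, acp_max, fully_specified.
    """
    membership_path = membership_path or _packaged("memberships.tsv")
    template_path = template_path or _packaged("templates.tsv")

    def _read(path, columns):
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            return pd.DataFrame(columns=columns)
        if set(df.columns) != set(columns):
            raise CatalogError(
                f"{Path(path).name}: columns {sorted(df.columns)} != {sorted(columns)}")
        return df

    tdf = _read(template_path, ["type_letter", "gene_slot", "domain_kind",
                                "acp_min", "acp_max", "fully_specified"])
    types: dict[str, TypeDefinition] = {}
    for letter, ldf in tdf.groupby("type_letter", sort=True):
        genes: list[TemplateGene] = []
        fully = bool(int(ldf["fully_specified"].iloc[0]))
        for i, row in enumerate(ldf.itertuples(index=False), start=2):
            try:
                kind = DomainKind(row.domain_kind)
            except ValueError:
                raise CatalogError(
                    f"template row {i}: unknown domain kind {row.domain_kind!r}"
                ) from None
            amin = 1 if row.acp_min in (None, "NA") or pd.isna(row.acp_min) \
                else int(row.acp_min)
            amax = 1 if row.acp_max in (None, "NA") or pd.isna(row.acp_max) \
                else int(row.acp_max)
            td = TemplateDomain(kind, amin, amax)
            if genes and genes[-1].slot == row.gene_slot:
                genes[-1] = TemplateGene(row.gene_slot, genes[-1].domains + (td,))
            else:
                genes.append(TemplateGene(row.gene_slot, (td,)))
        if letter in types:
            raise CatalogError(f"duplicate Type letter {letter}")
        types[letter] = TypeDefinition(letter=str(letter),
                                       template_genes=tuple(genes),
                                       fully_specified=fully)

    mdf = _read(membership_path, ["organism", "genus", "type_letters"])
    seen: set[tuple[str, str]] = set()
    members: dict[str, list[str]] = {letter: [] for letter in types}
    for i, row in enumerate(mdf.itertuples(index=False), start=2):
        if pd.isna(row.organism) or not str(row.organism).strip():
            raise CatalogError(f"membership row {i}: empty organism")
        org = str(row.organism).strip()
        expected_genus = genus_of(org)
        if str(row.genus).strip() != expected_genus:
            raise CatalogError(
                f"membership row {i}: genus {row.genus!r} does not match "
                f"organism token {expected_genus!r}")
        for letter in str(row.type_letters).split(","):
            letter = letter.strip()
            if letter not in types:
                raise CatalogError(f"membership row {i}: unknown Type {letter!r}")
            if (org, letter) in seen:
                raise CatalogError(
                    f"membership row {i}: duplicate membership ({org}, {letter})")
            seen.add((org, letter))
            members[letter].append(org)
    for letter, tdef in types.items():
        tdef.member_organisms = tuple(sorted(members[letter]))
    return Catalog(types=types)


def write_catalog(catalog: Catalog,
                  membership_path: str | Path,
                  template_path: str | Path) -> None:
    """Write a catalog back to the two-file TSV form (canonical row order)."""
    by_org: dict[str, list[str]] = {}
    for org, letter in catalog.memberships():
        by_org.setdefault(org, []).append(letter)
    mrows = [[org, genus_of(org), ",".join(sorted(letters))]
             for org, letters in sorted(by_org.items())]
    pd.DataFrame(mrows, columns=["organism", "genus", "type_letters"]) \
        .to_csv(membership_path, sep="\t", index=False)

    trows = []
    for letter in catalog.letters:
        tdef = catalog.types[letter]
        fully = str(int(tdef.fully_specified))
        for tg in tdef.template_genes:
            for td in tg.domains:
                if td.kind is DomainKind.ACP:
                    amin, amax = str(td.acp_min), str(td.acp_max)
                else:
                    amin = amax = "NA"
                trows.append([letter, tg.slot, td.kind.value, amin, amax, fully])
    pd.DataFrame(trows, columns=["type_letter", "gene_slot", "domain_kind",
                                 "acp_min", "acp_max", "fully_specified"]) \
        .to_csv(template_path, sep="\t", index=False)


def catalog_summary(catalog: Catalog) -> dict:
    """Headline counts: Types, distinct genomes, distinct genera, per-Type
    membership sizes.  Organisms carrying two Types count once as genomes."""
    memberships = catalog.memberships()
    organisms = {org for org, _ in memberships}
    genera = {genus_of(org) for org in organisms}
    per_type = {letter: len(catalog.types[letter].member_organisms)
                for letter in catalog.letters}
    return {
        "n_types": len(catalog.types),
        "n_genomes": len(organisms),
        "n_genera": len(genera),
        "per_type_counts": per_type,
    }
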