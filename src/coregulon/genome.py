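"""Gene order, adjacency, and partition of gene families into clusters and singletons.

A *functional cluster* is a maximal run of two or more members of the same
gene family occupying consecutive positions in the gene order of one
chromosome; every other family member is a *singleton*.  Adjacency is defined
on the rank order of the retained (non-dubious) gene set, not on base-pair
distance, because the downstream significance model is positional.  Strand is
deliberately ignored when deciding adjacency — convergent, divergent and
tandem neighbour pairs all count — and is recorded separately via
:func:`classify_orientation`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

VALID_STRANDS = frozenset({"+", "-"})
VALID_STATUS = frozenset({"verified", "uncharacterized", "dubious"})


class AnnotationError(ValueError):
    """Malformed or inconsistent gene annotation input."""


class EmptyFamilyError(ValueError):
    """No member of the family is present in the genome layout."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene.

    Coordinates are 1-based inclusive (GFF3 convention).  ``status`` follows
    the usual ORF curation vocabulary; *dubious* ORFs are excluded from the
    gene count N used by the adjacency significance model.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    status: str = "verified"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise AnnotationError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise AnnotationError(f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(f"{self.gene_id}: strand must be one of +/-, got {self.strand!r}")
        if self.status not in VALID_STATUS:
            raise AnnotationError(f"{self.gene_id}: unknown status {self.status!r}")


@dataclass
class GenomeLayout:
    """Ordered gene records per chromosome; the source of adjacency and of N.

    ``n_genes`` counts records with status != dubious, i.e. the genome size N
    of the adjacency significance model.
    """

    chromosomes: dict[str, tuple[GeneRecord, ...]]

    _rank: dict[str, tuple[str, int]] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        chroms: dict[str, tuple[GeneRecord, ...]] = {}
        for chrom in sorted(self.chromosomes):
            recs = tuple(sorted(self.chromosomes[chrom], key=lambda r: (r.start, r.end, r.gene_id)))
            for r in recs:
                if r.gene_id in seen:
                    raise AnnotationError(f"duplicate gene_id {r.gene_id!r}")
                seen.add(r.gene_id)
            chroms[chrom] = recs
        self.chromosomes = chroms
        self._rank = {
            r.gene_id: (chrom, i)
            for chrom, recs in self.chromosomes.items()
            for i, r in enumerate(recs)
        }

    @property
    def n_genes(self) -> int:
        return sum(1 for recs in self.chromosomes.values() for r in recs if r.status != "dubious")

    def __len__(self) -> int:
        return sum(len(recs) for recs in self.chromosomes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._rank

    def genes(self) -> Iterable[GeneRecord]:
        for recs in self.chromosomes.values():
            yield from recs

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.genes()]

    def record(self, gene_id: str) -> GeneRecord:
        chrom, i = self._rank[gene_id]
        return self.chromosomes[chrom][i]

    def position(self, gene_id: str) -> tuple[str, int]:
        """(chromosome, rank within chromosome) of a gene."""
        return self._rank[gene_id]

    def are_adjacent(self, a: str, b: str, window: int = 0) -> bool:
        """True if genes a and b sit on the same chromosome with at most
        ``window`` intervening genes (window=0 means directly adjacent)."""
        ca, ia = self._rank[a]
        cb, ib = self._rank[b]
        return ca == cb and 0 < abs(ia - ib) <= 1 + window


@dataclass(frozen=True)
class GeneFamily:
    """A set of genes grouped by shared function (a regulon)."""

    family_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id}: members must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusterPartition:
    """A family split into maximal adjacent runs (clusters) and singletons."""

    family_id: str
    clusters: tuple[tuple[str, ...], ...]
    singletons: tuple[str, ...]

    @property
    def j_clustered(self) -> int:
        return sum(len(c) for c in self.clusters)

    @property
    def n_members(self) -> int:
        return self.j_clustered + len(self.singletons)

    def clustered_genes(self) -> list[str]:
        return [g for c in self.clusters for g in c]


# ---------------------------------------------------------------------------
# loading

_TSV_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "status"]


def _parse_tsv(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TSV_COLUMNS)] != _TSV_COLUMNS:
            raise AnnotationError(
                f"{path}: expected header {_TSV_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise AnnotationError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            gid, chrom, start, end, strand, status = parts[:6]
            try:
                records.append(GeneRecord(gid, chrom, int(start), int(end), strand, status))
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return records


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _parse_gff3(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            attributes = _parse_gff3_attributes(attrs)
            gid = attributes.get("ID")
            if gid is None:
                raise AnnotationError(f"{path}:{lineno}: gene feature without ID attribute")
            status = attributes.get("status", "verified")
            try:
                records.append(GeneRecord(gid, chrom, int(start), int(end), strand, status))
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return records


def load_annotation(path: str | Path, format: str = "tsv", exclude_dubious: bool = True) -> GenomeLayout:
    """Read gene annotations into a :class:`GenomeLayout`.

    Parameters
    ----------
    path:
        Annotation file.
    format:
        ``"tsv"`` (columns gene_id, chromosome, start, end, strand, status)
        or ``"gff3"`` (feature type ``gene``; gene_id from the ID attribute,
        curation status from an optional ``status`` attribute).
    exclude_dubious:
        Drop dubious ORFs before establishing gene order (the default, and
        the convention under which the genome size N is counted).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        records = _parse_tsv(path)
    elif format == "gff3":
        records = _parse_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if exclude_dubious:
        records = [r for r in records if r.status != "dubious"]
    chroms: dict[str, list[GeneRecord]] = {}
    for r in records:
        chroms.setdefault(r.chromosome, []).append(r)
    return GenomeLayout({c: tuple(rs) for c, rs in chroms.items()})


def write_annotation_tsv(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in layout.genes():
            fh.write(f"{r.gene_id}\t{r.chromosome}\t{r.start}\t{r.end}\t{r.strand}\t{r.status}\n")


def write_annotation_gff3(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in layout.genes():
            fh.write(
                f"{r.chromosome}\tcoregulon\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t"
                f"ID={r.gene_id};status={r.status}\n"
            )


def load_families(path: str | Path) -> list[GeneFamily]:
    """Read family membership from a TSV with columns family_id, name, gene_id
    (one row per membership)."""
    path = Path(path)
    rows: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["family_id", "name", "gene_id"]:
            raise AnnotationError(f"{path}: expected header family_id/name/gene_id, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationError(f"{path}:{lineno}: expected 3 columns")
            fid, name, gid = parts[:3]
            rows.setdefault(fid, (name, []))[1].append(gid)
    return [GeneFamily(fid, name, frozenset(gids)) for fid, (name, gids) in rows.items()]


def write_families_tsv(families: Sequence[GeneFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tname\tgene_id\n")
        for fam in families:
            for gid in sorted(fam.members):
                fh.write(f"{fam.family_id}\t{fam.name}\t{gid}\n")


# ---------------------------------------------------------------------------
# partitioning

def partition_family(layout: GenomeLayout, family: GeneFamily) -> ClusterPartition:
    """Split a family into maximal adjacent clusters and singletons.

    Members absent from the layout are dropped with a warning and do not
    count toward the family size M.  Raises :class:`EmptyFamilyError` if no
    member is present.
    """
    present = [g for g in family.members if g in layout]
    missing = len(family.members) - len(present)
    if missing:
        logger.warning(
            "family %s: %d member(s) absent from layout, dropped", family.family_id, missing
        )
    if not present:
        raise EmptyFamilyError(f"family {family.family_id}: no member present in layout")
    positions = sorted(layout.position(g) for g in present)
    by_pos = {layout.position(g): g for g in present}

    clusters: list[tuple[str, ...]] = []
    singletons: list[str] = []
    run: list[str] = [by_pos[positions[0]]]
    prev = positions[0]
    for pos in positions[1:]:
        if pos[0] == prev[0] and pos[1] == prev[1] + 1:
            run.append(by_pos[pos])
        else:
            if len(run) >= 2:
                clusters.append(tuple(run))
            else:
                singletons.append(run[0])
            run = [by_pos[pos]]
        prev = pos
    if len(run) >= 2:
        clusters.append(tuple(run))
    else:
        singletons.append(run[0])
    return ClusterPartition(family.family_id, tuple(clusters), tuple(singletons))


def adjacent_pairs(partition: ClusterPartition) -> list[tuple[str, str]]:
    """Directly adjacent within-cluster gene pairs, in gene order."""
    return [(c[i], c[i + 1]) for c in partition.clusters for i in range(len(c) - 1)]


def classify_orientation(a: GeneRecord, b: GeneRecord, layout: GenomeLayout | None = None) -> str:
    """Relative orientation of an adjacent gene pair with ``a`` upstream of ``b``.

    (+,-) is convergent (-> <-), (-,+) divergent (<- ->), co-oriented pairs
    are tandem.  If a layout is supplied, direct adjacency is verified.
    """
    if a.chromosome != b.chromosome:
        raise ValueError(f"{a.gene_id}/{b.gene_id}: different chromosomes")
    if a.start > b.start:
        raise ValueError(f"{a.gene_id} is not upstream of {b.gene_id}")
    if layout is not None and not layout.are_adjacent(a.gene_id, b.gene_id):
        raise ValueError(f"{a.gene_id}/{b.gene_id}: not directly adjacent in layout")
    if (a.strand, b.strand) == ("+", "-"):
        return "convergent"
    if (a.strand, b.strand) == ("-", "+"):
        return "divergent"
    return "tandem"
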