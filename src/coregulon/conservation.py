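"""Cross-species conservation of exact adjacent-gene pairings.

An adjacent pair identified in the anchor genome (S. cerevisiae) is
*conserved* in a target species when both genes have orthologs there and
those orthologs are themselves directly adjacent in that species' gene
order.  Orthology is input, not inferred: a pillar table maps each ortholog
set across species (one row per pillar, one column per species, missing
entries blank or ``---``).  Post-whole-genome-duplication species may carry
two ortholog copies in one cell (``|``-separated); the pairing counts as
conserved if *any* copy combination is adjacent.

Only anchor-genome pairings are scored — the analysis asks whether an
existing pairing survives, not whether new pairings arose elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .genome import GenomeLayout

MISSING = ("", "---", "NA")


class PillarError(ValueError):
    pass


@dataclass
class PillarTable:
    """Ortholog pillars: one row per ortholog set, one column per species.

    ``pillars[i][species]`` is a tuple of gene ids (possibly several for
    post-WGD paralog tracks), absent key = no ortholog.
    """

    species_ids: list[str]
    pillars: list[dict[str, tuple[str, ...]]]

    _index: dict[tuple[str, str], int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        index: dict[tuple[str, str], int] = {}
        for i, row in enumerate(self.pillars):
            if not row:
                raise PillarError(f"pillar row {i}: every entry missing")
            for sp, genes in row.items():
                if sp not in self.species_ids:
                    raise PillarError(f"pillar row {i}: unknown species {sp!r}")
                for g in genes:
                    key = (sp, g)
                    if key in index:
                        raise PillarError(f"duplicate gene {g!r} in species {sp!r}")
                    index[key] = i
        self._index = index

    def orthologs(self, anchor_species: str, gene_id: str, species: str) -> tuple[str, ...]:
        """Orthologs of an anchor gene in a target species (possibly empty)."""
        row_i = self._index.get((anchor_species, gene_id))
        if row_i is None:
            return ()
        return self.pillars[row_i].get(species, ())


def load_pillars(path: str | Path) -> PillarTable:
    """Read a pillar TSV: header row of species names, one row per pillar,
    ``---`` or empty for a missing ortholog, ``|`` separating WGD copies."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or not any(header):
            raise PillarError(f"{path}: missing species header")
        pillars = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise PillarError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            row: dict[str, tuple[str, ...]] = {}
            for sp, cell in zip(header, cells):
                cell = cell.strip()
                if cell in MISSING:
                    continue
                genes = tuple(g.strip() for g in cell.split("|") if g.strip())
                if genes:
                    row[sp] = genes
            if not row:
                raise PillarError(f"{path}:{lineno}: all entries missing")
            pillars.append(row)
    return PillarTable(species_ids=header, pillars=pillars)


def write_pillars_tsv(table: PillarTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(table.species_ids) + "\n")
        for row in table.pillars:
            fh.write(
                "\t".join("|".join(row.get(sp, ())) or "---" for sp in table.species_ids)
                + "\n"
            )


def pair_conserved(
    pair: tuple[str, str],
    species: str,
    pillars: PillarTable,
    order: GenomeLayout,
    anchor_species: str,
    window: int = 0,
) -> bool:
    """Is an anchor-genome adjacent pair conserved as the exact pairing?

    True iff both genes have >= 1 ortholog in ``species`` and some ortholog
    combination is adjacent in that species' gene order (``window`` allows up
    to that many intervening genes; 0 = strict adjacency).  A missing
    ortholog, or an ortholog absent from the species order, scores False.
    """
    a, b = pair
    orth_a = pillars.orthologs(anchor_species, a, species)
    orth_b = pillars.orthologs(anchor_species, b, species)
    if not orth_a or not orth_b:
        return False
    for ga in orth_a:
        for gb in orth_b:
            if ga == gb:
                continue
            if ga in order and gb in order and order.are_adjacent(ga, gb, window=window):
                return True
    return False


@dataclass(frozen=True)
class ConservationMatrix:
    """Pairs x species boolean conservation matrix with marginal counts."""

    pairs: tuple[tuple[str, str], ...]
    species_ids: tuple[str, ...]
    conserved: tuple[tuple[bool, ...], ...]   # rows = pairs
    pair_families: tuple[str, ...] = ()

    def species_counts(self) -> dict[str, int]:
        return {
            sp: sum(row[k] for row in self.conserved)
            for k, sp in enumerate(self.species_ids)
        }

    def species_fraction(self, species: str) -> float:
        k = self.species_ids.index(species)
        return sum(row[k] for row in self.conserved) / len(self.pairs)

    def pair_counts(self) -> dict[tuple[str, str], int]:
        return {p: sum(row) for p, row in zip(self.pairs, self.conserved)}

    def family_counts(self) -> dict[str, dict[str, int]]:
        """Per family, per species, number of conserved pairs."""
        out: dict[str, dict[str, int]] = {}
        for fam, row in zip(self.pair_families, self.conserved):
            acc = out.setdefault(fam, {sp: 0 for sp in self.species_ids})
            for sp, v in zip(self.species_ids, row):
                acc[sp] += int(v)
        return out


def conservation_matrix(
    pairs: Sequence[tuple[str, str]],
    species_ids: Sequence[str],
    pillars: PillarTable,
    orders: dict[str, GenomeLayout],
    anchor_species: str,
    window: int = 0,
    pair_families: Sequence[str] | None = None,
) -> ConservationMatrix:
    """Score every anchor pair in every species."""
    missing = [sp for sp in species_ids if sp not in orders]
    if missing:
        raise PillarError(f"gene order missing for species: {missing}")
    rows = []
    for pair in pairs:
        rows.append(
            tuple(
                pair_conserved(pair, sp, pillars, orders[sp], anchor_species, window)
                for sp in species_ids
            )
        )
    return ConservationMatrix(
        pairs=tuple(tuple(p) for p in pairs),
        species_ids=tuple(species_ids),
        conserved=tuple(rows),
        pair_families=tuple(pair_families) if pair_families is not None else (),
    )


def write_matrix_tsv(
    matrix: ConservationMatrix, path: str | Path, header_comments: list[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        fams = matrix.pair_families or ("",) * len(matrix.pairs)
        fh.write("pair_id\tfamily_id\t" + "\t".join(matrix.species_ids) + "\n")
        for (a, b), fam, row in zip(matrix.pairs, fams, matrix.conserved):
            fh.write(f"{a}--{b}\t{fam}\t" + "\t".join(str(int(v)) for v in row) + "\n")
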