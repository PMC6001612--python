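import numpy as np
import pytest

from coregulon.expression import ConditionSeries, build_expression_set
from coregulon.genome import GeneFamily, GeneRecord, GenomeLayout


def make_layout(chrom_genes: dict[str, list[str]], strands: dict[str, str] | None = None,
                status: dict[str, str] | None = None) -> GenomeLayout:
    """Build a layout from an explicit per-chromosome gene order."""
    strands = strands or {}
    status = status or {}
    chroms = {}
    for chrom, genes in chrom_genes.items():
        recs = []
        for i, g in enumerate(genes):
            start = 1 + i * 1000
            recs.append(
                GeneRecord(g, chrom, start, start + 500,
                           strands.get(g, "+"), status.get(g, "verified"))
            )
        chroms[chrom] = tuple(recs)
    return GenomeLayout(chroms)


def make_expression(vectors: dict[str, dict[str, list[float]]],
                    times: list[float] | None = None):
    """One-replicate expression set from {condition: {gene: vector}} (already
    anchored: first position treated as the t=0 reference)."""
    series = []
    for cond in sorted(vectors):
        genes = vectors[cond]
        nt = len(next(iter(genes.values())))
        series.append(
            ConditionSeries(
                condition_id=cond,
                time_points=tuple(times or [float(i) for i in range(nt)]),
                reference_index=0,
                values={g: np.asarray(v, dtype=float)[None, :] for g, v in genes.items()},
                replicate_count=1,
            )
        )
    return build_expression_set(series)


@pytest.fixture
def six_gene_layout() -> GenomeLayout:
    return make_layout({"chr1": ["g1", "g2", "g3", "g4", "g5", "g6"]})


@pytest.fixture
def two_chrom_layout() -> GenomeLayout:
    return make_layout({"chr1": ["g1", "g2"], "chr2": ["g3", "g4"]})


def family(*genes: str, fid: str = "fam", name: str = "test family") -> GeneFamily:
    return GeneFamily(fid, name, frozenset(genes))
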