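"""Model/results facade tying the pipeline stages together.

:class:`AdjacentGeneCoregulation` is built from a genome layout, gene
families, and optionally expression and ortholog data; :meth:`fit` partitions
every family, scores adjacency significance, computes coherence scores,
bootstraps the null of the cluster score, and scores cross-species pair
conservation, returning a :class:`CoregulationResults` whose ``summary()``
is the human-readable account and whose tables are the machine-readable one.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import coherence as coh
from . import conservation as cons
from . import expression as expr_mod
from . import genome as gen
from . import significance as sig

__version__ = "0.1.0"


class AdjacentGeneCoregulation:
    """Adjacent-gene coregulation analysis of functional gene families.

    Parameters
    ----------
    layout:
        Gene order of the anchor genome (dubious ORFs excluded).
    families:
        Functional gene families (regulons) to analyse.
    expression:
        Optional raw expression set; replicates are averaged and every
        condition anchored to its reference during ``fit``.
    pillars, species_orders, anchor_species:
        Optional ortholog pillars plus per-species gene orders for pair
        conservation scoring.
    tail:
        Binomial tail convention for adjacency p-values reported as the
        headline column (both are always computed).
    composite:
        ``"concat"`` scores concatenated condition blocks; ``"mean"``
        averages per-condition scores instead.
    """

    def __init__(
        self,
        layout: gen.GenomeLayout,
        families: Sequence[gen.GeneFamily],
        expression: expr_mod.ExpressionSet | None = None,
        pillars: cons.PillarTable | None = None,
        species_orders: dict[str, gen.GenomeLayout] | None = None,
        anchor_species: str = "Scer",
        tail: str = "greater_exclusive",
        composite: str = "concat",
        cluster_pairing: str = "all",
        expression_space: str = "log2ratio",
        conservation_window: int = 0,
    ) -> None:
        if tail not in sig.TAIL_CONVENTIONS:
            raise ValueError(f"tail must be one of {sig.TAIL_CONVENTIONS}")
        if composite not in ("concat", "mean"):
            raise ValueError("composite must be 'concat' or 'mean'")
        self.layout = layout
        self.families = list(families)
        self.expression = expression
        self.pillars = pillars
        self.species_orders = species_orders or {}
        self.anchor_species = anchor_species
        self.tail = tail
        self.composite = composite
        self.cluster_pairing = cluster_pairing
        self.expression_space = expression_space
        self.conservation_window = conservation_window

    @classmethod
    def from_files(
        cls,
        annotation: str | Path,
        families: str | Path,
        expression: str | Path | None = None,
        pillars: str | Path | None = None,
        orders_dir: str | Path | None = None,
        annotation_format: str = "tsv",
        **kwargs,
    ) -> "AdjacentGeneCoregulation":
        layout = gen.load_annotation(annotation, format=annotation_format)
        fams = gen.load_families(families)
        expr = expr_mod.load_expression(expression) if expression else None
        pil = cons.load_pillars(pillars) if pillars else None
        orders = None
        if orders_dir is not None:
            orders = {
                p.stem: gen.load_annotation(p, format="tsv")
                for p in sorted(Path(orders_dir).glob("*.tsv"))
            }
        return cls(layout, fams, expr, pil, orders, **kwargs)

    @classmethod
    def from_bundle(cls, bundle, **kwargs) -> "AdjacentGeneCoregulation":
        return cls(
            bundle.layout,
            bundle.families,
            bundle.expression,
            bundle.pillars,
            bundle.species_orders,
            **kwargs,
        )

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        n_bootstrap: int = 10_000,
        seed: int = 0,
        bootstrap: bool = True,
        per_condition: bool = True,
    ) -> "CoregulationResults":
        prepared = (
            expr_mod.prepare(self.expression, self.expression_space)
            if self.expression is not None
            else None
        )
        partitions: dict[str, gen.ClusterPartition] = {}
        rows = []
        coherences: dict[str, coh.CoherenceResult] = {}
        bootstraps: dict[str, coh.BootstrapNull] = {}
        N = self.layout.n_genes
        for i, fam in enumerate(self.families):
            part = gen.partition_family(self.layout, fam)
            partitions[fam.family_id] = part
            M, j = part.n_members, part.j_clustered
            row = {
                "family_id": fam.family_id,
                "name": fam.name,
                "set_size": M,
                "n_clustered": j,
                "n_clusters": len(part.clusters),
                "p_exclusive": sig.cluster_pvalue(M, j, N, "greater_exclusive"),
                "p_inclusive": sig.cluster_pvalue(M, j, N, "greater_inclusive"),
            }
            row["p_value"] = row[
                "p_exclusive" if self.tail == "greater_exclusive" else "p_inclusive"
            ]
            row["significant"] = row["p_value"] < 0.05
            if prepared is not None:
                mode = "per_condition" if (per_condition or self.composite == "mean") else "composite"
                res = coh.family_scores(part, prepared, mode=mode, cluster_pairing=self.cluster_pairing)
                if self.composite == "mean" and res.per_condition:
                    singles = [s for s, _ in res.per_condition.values()]
                    clusters = [c for _, c in res.per_condition.values()]
                    res = coh.CoherenceResult(
                        family_id=res.family_id,
                        singleton_score=float(np.nanmean(singles)) if singles else float("nan"),
                        cluster_score=float(np.nanmean(clusters)) if clusters else float("nan"),
                        n_singletons=res.n_singletons,
                        n_clustered=res.n_clustered,
                        n_excluded_pairs=res.n_excluded_pairs,
                        per_condition=res.per_condition,
                    )
                coherences[fam.family_id] = res
                row["singleton_score"] = res.singleton_score
                row["cluster_score"] = res.cluster_score
                row["difference"] = res.difference
                row["flag"] = res.flag()
                if bootstrap and j >= 2:
                    group = j - (j % 2)
                    null = coh.bootstrap_null(
                        fam,
                        prepared,
                        group_size=group,
                        n_iterations=n_bootstrap,
                        # independent stream per family, derived from one seed
                        seed=(seed + 104_729 * i) % (2**31),
                        observed_score=res.cluster_score,
                    )
                    bootstraps[fam.family_id] = null
                    row["boot_percentile_low"] = null.empirical_percentile
                    row["boot_percentile_high"] = null.upper_percentile
                    row["boot_ks_halves"] = null.convergence_ks
            rows.append(row)

        matrix = None
        if self.pillars is not None and self.species_orders:
            pairs, fams_of_pairs = [], []
            for fam in self.families:
                for p in gen.adjacent_pairs(partitions[fam.family_id]):
                    pairs.append(p)
                    fams_of_pairs.append(fam.family_id)
            if pairs:
                matrix = cons.conservation_matrix(
                    pairs,
                    self.pillars.species_ids,
                    self.pillars,
                    self.species_orders,
                    self.anchor_species,
                    window=self.conservation_window,
                    pair_families=fams_of_pairs,
                )
        return CoregulationResults(
            model=self,
            family_table=pd.DataFrame(rows),
            partitions=partitions,
            coherences=coherences,
            bootstraps=bootstraps,
            conservation=matrix,
            seed=seed,
            n_bootstrap=n_bootstrap,
        )


@dataclass
class CoregulationResults:
    """Fitted results: per-family adjacency significance, coherence scores,
    bootstrap percentiles, and the cross-species conservation matrix."""

    model: AdjacentGeneCoregulation
    family_table: pd.DataFrame
    partitions: dict[str, gen.ClusterPartition]
    coherences: dict[str, coh.CoherenceResult]
    bootstraps: dict[str, coh.BootstrapNull]
    conservation: cons.ConservationMatrix | None
    seed: int
    n_bootstrap: int

    def config_hash(self) -> str:
        m = self.model
        payload = "|".join(
            str(x)
            for x in (
                m.tail, m.composite, m.cluster_pairing, m.expression_space,
                m.conservation_window, self.seed, self.n_bootstrap,
                m.layout.n_genes, len(m.families),
            )
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def _header(self) -> list[str]:
        return [
            f"coregulon {__version__}",
            f"seed: {self.seed}",
            f"config: {self.config_hash()}",
        ]

    def summary(self) -> str:
        lines = [
            "Adjacent-gene coregulation analysis",
            "=" * 72,
            f"Genome: {self.model.layout.n_genes} genes "
            f"({len(self.model.layout.chromosomes)} chromosomes), "
            f"tail convention: {self.model.tail}, composite: {self.model.composite}",
            "",
        ]
        cols = [
            c for c in (
                "family_id", "set_size", "n_clustered", "p_value",
                "singleton_score", "cluster_score", "difference", "flag",
                "boot_percentile_high",
            ) if c in self.family_table.columns
        ]
        with pd.option_context("display.width", 120, "display.float_format", "{:.4g}".format):
            lines.append(self.family_table[cols].to_string(index=False))
        if self.conservation is not None:
            lines += ["", "Pair conservation (fraction of anchor pairs conserved):"]
            n = len(self.conservation.pairs)
            for sp in self.conservation.species_ids:
                frac = self.conservation.species_fraction(sp)
                lines.append(f"  {sp:>12s}  {frac:6.3f}  ({int(round(frac * n))}/{n})")
        return "\n".join(lines)

    def save_tables(self, directory: str | Path) -> dict[str, Path]:
        """Write scan/coherence/histogram/conservation TSVs (deterministic:
        headers carry only version, seed and config hash)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        header = self._header()
        out: dict[str, Path] = {}

        scan_rows = [
            sig.FamilySignificance(
                r.family_id, r.name, int(r.set_size), int(r.n_clustered),
                float(r.p_exclusive), float(r.p_inclusive),
            )
            for r in self.family_table.itertuples()
        ]
        out["scan"] = d / "scan.tsv"
        sig.write_significance_tsv(
            scan_rows, out["scan"], N=self.model.layout.n_genes, header_comments=header
        )

        if self.coherences:
            cond_ids = (
                self.model.expression.condition_ids if self.model.expression else []
            )
            out["coherence"] = d / "coherence.tsv"
            coh.write_coherence_tsv(
                [self.coherences[f] for f in self.family_table["family_id"]],
                out["coherence"],
                condition_ids=cond_ids,
                header_comments=header,
            )
        for fid, null in self.bootstraps.items():
            edges, counts = coh.bin_for_histogram(null.null_scores)
            p = d / f"bootstrap_{fid}.tsv"
            coh.write_histogram_tsv(
                edges, counts, p, observed_score=null.observed_score,
                header_comments=header + [
                    f"iterations: {null.n_iterations}",
                    f"observed: {null.observed_score:.6f}",
                    f"percentile_low: {null.empirical_percentile:.6f}",
                    f"percentile_high: {null.upper_percentile:.6f}",
                    f"self_pair_redraws: {null.n_self_pair_redraws}",
                    f"convergence_ks_halves: {null.convergence_ks:.6f}",
                ],
            )
            out[f"bootstrap_{fid}"] = p
            diag = coh.selection_uniformity(null.selection_counts)
            ps = d / f"selection_{fid}.tsv"
            with open(ps, "w") as fh:
                for line in header:
                    fh.write(f"# {line}\n")
                fh.write(
                    f"# cv: {diag.cv:.6f}\tchisq_p: {diag.chisq_p:.6g}"
                    f"\tbias_warning: {int(diag.bias_warning)}\n"
                )
                fh.write("gene_id\tcount\n")
                for g in sorted(null.selection_counts):
                    fh.write(f"{g}\t{null.selection_counts[g]}\n")
            out[f"selection_{fid}"] = ps
        if self.conservation is not None:
            out["conservation"] = d / "conservation.tsv"
            cons.write_matrix_tsv(self.conservation, out["conservation"], header_comments=header)
        return out
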