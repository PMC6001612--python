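"""Expression time courses: loading, replicate averaging, reference anchoring.

Each condition (a stress or nutritional time course) is held as a
:class:`ConditionSeries` of per-gene vectors over an ordered time grid with a
declared reference time point — the unperturbed state, normally t = 0.  The
analysis pipeline averages replicates first, then anchors every vector to the
reference (log2 ratios are shifted, raw intensities are log2-ratioed), so the
reference value is exactly zero and serves as the fixed offset of the
similarity statistic downstream.  Composite scoring concatenates the
per-condition vectors, each block anchored to its own reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ExpressionParseError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class ConditionSeries:
    """One condition's time course for a set of genes.

    ``values[gene]`` has shape (replicate_count, n_time_points); NaN marks a
    missing observation.  ``reference_index`` points at the unperturbed state
    within ``time_points``.
    """

    condition_id: str
    time_points: tuple[float, ...]
    reference_index: int
    values: dict[str, np.ndarray]
    replicate_count: int

    def __post_init__(self) -> None:
        nt = len(self.time_points)
        if not 0 <= self.reference_index < nt:
            raise ValueError(
                f"{self.condition_id}: reference_index {self.reference_index} out of range"
            )
        for g, v in self.values.items():
            if v.shape != (self.replicate_count, nt):
                raise ValueError(
                    f"{self.condition_id}/{g}: expected shape {(self.replicate_count, nt)}, "
                    f"got {v.shape}"
                )

    @property
    def genes(self) -> set[str]:
        return set(self.values)

    def vector(self, gene: str) -> np.ndarray:
        """Single time-course vector; requires replicates already averaged."""
        v = self.values[gene]
        if v.shape[0] != 1:
            raise ValueError(
                f"{self.condition_id}: {v.shape[0]} replicates present; average first"
            )
        return v[0]


@dataclass(frozen=True)
class ExpressionSet:
    """An ordered collection of condition series sharing a gene universe."""

    series: tuple[ConditionSeries, ...]
    gene_universe: frozenset[str]

    @property
    def condition_ids(self) -> list[str]:
        return [s.condition_id for s in self.series]

    def get(self, condition_id: str) -> ConditionSeries:
        for s in self.series:
            if s.condition_id == condition_id:
                return s
        raise KeyError(condition_id)


# ---------------------------------------------------------------------------
# I/O

EXPR_COLUMNS = ["gene_id", "condition", "time", "replicate", "value"]


def load_expression(
    path: str | Path,
    policy: Literal["intersection", "union"] = "intersection",
) -> ExpressionSet:
    """Read a long-format expression TSV (gene_id, condition, time,
    replicate, value) into an :class:`ExpressionSet`.

    ``policy`` controls the gene universe: *intersection* keeps genes present
    in every condition (dropped genes are logged), *union* keeps all.
    The reference index of each condition is the position of its earliest
    time point.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in EXPR_COLUMNS if c not in df.columns]
    if missing:
        raise ExpressionParseError(f"{path}: missing columns {missing}")
    if df["value"].isna().all():
        raise ExpressionParseError(f"{path}: no values")
    series = []
    for cond, sub in df.groupby("condition", sort=True):
        times = np.sort(sub["time"].unique())
        reps = np.sort(sub["replicate"].unique())
        t_index = {t: i for i, t in enumerate(times)}
        r_index = {r: i for i, r in enumerate(reps)}
        values: dict[str, np.ndarray] = {}
        for gene, gsub in sub.groupby("gene_id", sort=True):
            arr = np.full((len(reps), len(times)), np.nan)
            arr[
                gsub["replicate"].map(r_index).to_numpy(),
                gsub["time"].map(t_index).to_numpy(),
            ] = gsub["value"].to_numpy(dtype=float)
            values[str(gene)] = arr
        series.append(
            ConditionSeries(
                condition_id=str(cond),
                time_points=tuple(float(t) for t in times),
                reference_index=0,
                values=values,
                replicate_count=len(reps),
            )
        )
    return build_expression_set(series, policy=policy)


def build_expression_set(
    series: list[ConditionSeries],
    policy: Literal["intersection", "union"] = "intersection",
) -> ExpressionSet:
    gene_sets = [s.genes for s in series]
    if policy == "intersection":
        universe = set.intersection(*gene_sets) if gene_sets else set()
        dropped = set.union(*gene_sets) - universe if gene_sets else set()
        if dropped:
            logger.warning("%d gene(s) absent from some condition, dropped", len(dropped))
        series = [
            replace(s, values={g: v for g, v in s.values.items() if g in universe})
            for s in series
        ]
    elif policy == "union":
        universe = set.union(*gene_sets) if gene_sets else set()
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return ExpressionSet(series=tuple(series), gene_universe=frozenset(universe))


def write_expression_tsv(expr: ExpressionSet, path: str | Path, fmt: str = "%.10g") -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EXPR_COLUMNS) + "\n")
        for s in expr.series:
            for gene in sorted(s.values):
                arr = s.values[gene]
                for rep in range(arr.shape[0]):
                    for ti, t in enumerate(s.time_points):
                        v = arr[rep, ti]
                        if np.isnan(v):
                            continue
                        fh.write(
                            f"{gene}\t{s.condition_id}\t{t:.10g}\t{rep + 1}\t{fmt % v}\n"
                        )


def load_wide_expression(path: str | Path, sample_sheet: str | Path) -> ExpressionSet:
    """Read a series-matrix-style wide table (one row per gene, one column per
    sample) using a YAML sample sheet mapping each sample column to its
    condition, time and replicate."""
    import yaml

    with open(sample_sheet) as fh:
        sheet = yaml.safe_load(fh)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    long_rows = []
    for sample, meta in sheet.items():
        if sample not in df.columns:
            raise ExpressionParseError(f"sample {sample!r} not found in {path}")
        for gene, value in df[sample].items():
            long_rows.append(
                (str(gene), str(meta["condition"]), float(meta["time"]),
                 int(meta.get("replicate", 1)), float(value))
            )
    long_df = pd.DataFrame(long_rows, columns=EXPR_COLUMNS)
    tmp = Path(path).with_suffix(".long.tmp.tsv")
    long_df.to_csv(tmp, sep="\t", index=False)
    try:
        return load_expression(tmp)
    finally:
        tmp.unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# transforms

def average_replicates(series: ConditionSeries) -> ConditionSeries:
    """Element-wise mean over replicates (NaNs ignored; all-NaN stays NaN)."""
    if series.replicate_count == 1:
        return series
    values = {}
    for g, v in series.values.items():
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(v, axis=0)
        values[g] = mean[None, :]
    return replace(series, values=values, replicate_count=1)


def normalize_to_reference(
    series: ConditionSeries, space: Literal["intensity", "log2ratio"] = "log2ratio"
) -> ConditionSeries:
    """Anchor every vector to the reference time point.

    In intensity space v -> log2(v / v_ref); in log2-ratio space v -> v - v_ref.
    The reference value becomes exactly 0 (idempotent in log2-ratio space).
    """
    ri = series.reference_index
    values = {}
    for g, v in series.values.items():
        ref = v[:, ri : ri + 1]
        if space == "intensity":
            if np.any(ref <= 0) or np.any(np.isnan(ref)):
                raise NormalizationError(
                    f"{series.condition_id}/{g}: non-positive or missing intensity at reference"
                )
            values[g] = np.log2(v / ref)
        elif space == "log2ratio":
            if np.any(np.isnan(ref)):
                raise NormalizationError(
                    f"{series.condition_id}/{g}: missing value at reference"
                )
            values[g] = v - ref
        else:
            raise ValueError(f"unknown space {space!r}")
    return replace(series, values=values)


def prepare(expr: ExpressionSet, space: Literal["intensity", "log2ratio"] = "log2ratio") -> ExpressionSet:
    """Average replicates then anchor to the reference, per condition.

    Averaging precedes anchoring; in log2-ratio space the two orders agree,
    in intensity space averaging first matches the convention of producing a
    single time course per condition before any ratioing.
    """
    series = [normalize_to_reference(average_replicates(s), space) for s in expr.series]
    return ExpressionSet(series=tuple(series), gene_universe=expr.gene_universe)


def concatenate_conditions(expr: ExpressionSet, gene: str) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate a gene's per-condition vectors in series order.

    Returns ``(values, block_index)`` where ``block_index[i]`` names the
    condition block position ``i`` came from.  Every block must already be
    anchored (replicates averaged, reference at zero); each block carries its
    own zero offset, so the composite similarity uses offset 0 throughout.
    """
    parts = []
    blocks = []
    for bi, s in enumerate(expr.series):
        if gene not in s.values:
            raise KeyError(f"gene {gene!r} missing from condition {s.condition_id!r}")
        v = s.vector(gene)
        parts.append(v)
        blocks.append(np.full(v.size, bi))
    return np.concatenate(parts), np.concatenate(blocks)
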