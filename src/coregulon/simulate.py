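"""Synthetic genomes, families, expression time courses, and pillar tables.

The generator plants known structure at every level so each pipeline stage
can be tested against ground truth:

* a multi-chromosome genome of N ordered genes, each family placed with an
  exact number of members in adjacent runs (the planted j) and the rest as
  singletons with no family neighbour;
* stress-response-shaped expression: per condition a smooth family-level
  latent curve anchored at 0 at t = 0, a block-level latent curve shared by
  each planted adjacent run, and i.i.d. Gaussian noise per time point per
  replicate — with amplitudes calibrated so the expected within-pair
  similarity and the expected singleton-singleton similarity hit the
  requested targets;
* ortholog pillar tables and per-species gene orders in which each planted
  pair stays adjacent with a per-species conservation probability, and is
  otherwise broken by relocating or deleting one member.

All randomness flows from the single ``seed`` in :class:`SimulationConfig`;
regenerating with the same config is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .conservation import PillarTable, write_pillars_tsv
from .expression import (
    ConditionSeries,
    ExpressionSet,
    build_expression_set,
    write_expression_tsv,
)
from .genome import (
    GeneFamily,
    GeneRecord,
    GenomeLayout,
    ClusterPartition,
    write_annotation_gff3,
    write_annotation_tsv,
    write_families_tsv,
)

ANCHOR_SPECIES = "Scer"

#: Calibration tolerance on planted similarity targets.
CALIBRATION_TOL = 0.05


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SpeciesSpec:
    """A target species for conservation simulation."""

    name: str
    pair_conservation: float  # probability a planted pair stays adjacent
    ortholog_loss: float = 0.05  # probability the broken pair loses a member
                                 # (also applied to non-pair genes)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pair_conservation <= 1.0:
            raise ValueError("pair_conservation must be in [0, 1]")
        if not 0.0 <= self.ortholog_loss <= 1.0:
            raise ValueError("ortholog_loss must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Planted-structure parameters.

    Defaults emulate the study's shape: five stress time courses of six
    points each with duplicate arrays, log2 ratios anchored at the
    unperturbed t = 0 state, and one strongly clustered regulon — 80 genes
    of which 40 sit in 20 adjacent pairs — in a 5,000-gene, 16-chromosome
    genome, compared against a ladder of species with decaying synteny.
    """

    n_genes: int = 5000
    n_chromosomes: int = 16
    family_sizes: tuple[int, ...] = (80,)
    planted_clustered: tuple[int, ...] = (40,)
    conditions: int = 5
    time_points_per_condition: int = 6
    replicates: int = 2
    pair_correlation: float = 0.9
    family_correlation: float = 0.5
    noise_sd: float = 0.3
    species: tuple[SpeciesSpec, ...] = (
        SpeciesSpec("Spar", 0.90, 0.02),
        SpeciesSpec("Smik", 0.75, 0.05),
        SpeciesSpec("Skud", 0.60, 0.05),
        SpeciesSpec("Cgla", 0.30, 0.10),
        SpeciesSpec("Klac", 0.15, 0.15),
    )
    #: optional explicit run decomposition per family (default: runs of 2,
    #: with one run of 3 when the planted count is odd)
    run_lengths: tuple[tuple[int, ...], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.family_sizes) != len(self.planted_clustered):
            raise ValueError("family_sizes and planted_clustered must align")
        for m, j in zip(self.family_sizes, self.planted_clustered):
            if j > m:
                raise ValueError(f"planted j={j} exceeds family size {m}")
            if j == 1:
                raise ValueError("planted j must be 0 or >= 2 (a cluster needs 2 genes)")
        if self.run_lengths is not None:
            if len(self.run_lengths) != len(self.family_sizes):
                raise ValueError("run_lengths must align with family_sizes")
            for runs, j in zip(self.run_lengths, self.planted_clustered):
                if any(r < 2 for r in runs):
                    raise ValueError("every run must have length >= 2")
                if sum(runs) != j:
                    raise ValueError(f"run lengths {runs} do not sum to planted j={j}")
        if sum(self.family_sizes) > self.n_genes:
            raise ValueError("families exceed genome size")
        if not 0.0 <= self.family_correlation <= self.pair_correlation < 1.0:
            raise ValueError(
                "need 0 <= family_correlation <= pair_correlation < 1 "
                f"(got {self.family_correlation}, {self.pair_correlation})"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.conditions < 1 or self.time_points_per_condition < 2 or self.replicates < 1:
            raise ValueError("need >= 1 condition, >= 2 time points, >= 1 replicate")


@dataclass
class SyntheticBundle:
    """A generated data set plus the exact truth that produced it."""

    config: SimulationConfig
    layout: GenomeLayout
    families: list[GeneFamily]
    expression: ExpressionSet
    pillars: PillarTable
    species_orders: dict[str, GenomeLayout]
    truth: dict


# ---------------------------------------------------------------------------
# genome

def _run_lengths(j: int) -> list[int]:
    """Decompose the planted clustered count into runs of 2 (one run of 3
    when j is odd)."""
    if j == 0:
        return []
    runs = [2] * (j // 2)
    if j % 2:
        runs[0] = 3
    return runs


def _chromosome_sizes(n_genes: int, n_chrom: int) -> list[int]:
    base, extra = divmod(n_genes, n_chrom)
    return [base + (1 if i < extra else 0) for i in range(n_chrom)]


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[GenomeLayout, list[GeneFamily], dict]:
    """Place genes and families; returns (layout, families, truth).

    Truth records, per family, the realized clusters (gene-id runs) and
    singletons.  Raises :class:`GenerationError` when the requested packing
    cannot be placed (too dense).
    """
    sizes = _chromosome_sizes(config.n_genes, config.n_chromosomes)
    chrom_of = np.concatenate(
        [np.full(s, ci, dtype=np.int64) for ci, s in enumerate(sizes)]
    )
    chrom_start = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    fam_of = np.full(config.n_genes, -1, dtype=np.int64)

    def flanks_ok(lo: int, hi: int, fam: int) -> bool:
        """Positions lo..hi-1 inclusive run; flanks must not hold family `fam`."""
        if lo - 1 >= 0 and chrom_of[lo - 1] == chrom_of[lo] and fam_of[lo - 1] == fam:
            return False
        if hi < config.n_genes and chrom_of[hi] == chrom_of[hi - 1] and fam_of[hi] == fam:
            return False
        return True

    truth_families = []
    max_tries = 20_000
    for fi, (m, j) in enumerate(zip(config.family_sizes, config.planted_clustered)):
        lengths = (
            list(config.run_lengths[fi]) if config.run_lengths is not None
            else _run_lengths(j)
        )
        runs: list[list[int]] = []
        for length in lengths:
            for attempt in range(max_tries):
                p = int(rng.integers(0, config.n_genes - length + 1))
                window = slice(p, p + length)
                if (
                    np.all(fam_of[window] == -1)
                    and chrom_of[p] == chrom_of[p + length - 1]
                    and flanks_ok(p, p + length, fi)
                ):
                    fam_of[window] = fi
                    runs.append(list(range(p, p + length)))
                    break
            else:
                raise GenerationError(
                    f"family {fi}: cannot place a run of {length}; "
                    "reduce family sizes or planted clustering"
                )
        singles: list[int] = []
        for _ in range(m - j):
            for attempt in range(max_tries):
                p = int(rng.integers(0, config.n_genes))
                if fam_of[p] != -1:
                    continue
                if flanks_ok(p, p + 1, fi):
                    fam_of[p] = fi
                    singles.append(p)
                    break
            else:
                raise GenerationError(
                    f"family {fi}: cannot place singleton; genome too dense"
                )
        truth_families.append((runs, singles))

    width = len(str(config.n_genes))
    gene_ids = [f"g{p:0{width}d}" for p in range(config.n_genes)]
    strands = rng.choice(["+", "-"], size=config.n_genes)
    chroms: dict[str, list[GeneRecord]] = {}
    for p in range(config.n_genes):
        ci = int(chrom_of[p])
        k = p - int(chrom_start[ci])
        start = 1 + k * 2000
        chroms.setdefault(f"chr{ci + 1:02d}", []).append(
            GeneRecord(gene_ids[p], f"chr{ci + 1:02d}", start, start + 999, str(strands[p]))
        )
    layout = GenomeLayout({c: tuple(rs) for c, rs in chroms.items()})

    families = []
    truth: dict = {"families": {}}
    for fi, (runs, singles) in enumerate(truth_families):
        fid = f"fam{fi + 1:02d}"
        members = [gene_ids[p] for run in runs for p in run] + [gene_ids[p] for p in singles]
        families.append(GeneFamily(fid, f"planted family {fi + 1}", frozenset(members)))
        truth["families"][fid] = {
            "clusters": [[gene_ids[p] for p in run] for run in runs],
            "singletons": sorted(gene_ids[p] for p in singles),
            "j": sum(len(r) for r in runs),
            "size": len(members),
        }
    return layout, families, truth


def truth_partition(truth: dict, family_id: str) -> ClusterPartition:
    rec = truth["families"][family_id]
    return ClusterPartition(
        family_id,
        tuple(tuple(c) for c in rec["clusters"]),
        tuple(rec["singletons"]),
    )


# ---------------------------------------------------------------------------
# expression

def _latent_curve(rng: np.random.Generator, times: np.ndarray) -> np.ndarray:
    """Smooth random response curve, exactly 0 at the first time point and
    unit RMS over the remaining points (a quadratic through random knots)."""
    t0, tm, te = times[0], times[len(times) // 2], times[-1]
    for _ in range(100):
        a, b = rng.normal(size=2)
        coeffs = np.polyfit([t0, tm, te], [0.0, a, b], 2)
        v = np.polyval(coeffs, times)
        v -= v[0]
        rms = math.sqrt(float(np.mean(v[1:] ** 2)))
        if rms > 1e-3:
            return v / rms
    raise GenerationError("degenerate latent curve")  # pragma: no cover


def _initial_amplitudes(config: SimulationConfig) -> tuple[float, float]:
    """Closed-form variance-share initialisation for (family, block) amplitudes.

    With unit-RMS latent curves, effective post-averaging noise variance
    w = noise_sd^2 / replicates, and targets rho_fam <= rho_pair, the shares
    a^2 = rho_fam * T, b^2 = (rho_pair - rho_fam) * T with
    T = w / (1 - rho_pair) give E[S] ~ the targets.
    """
    w = config.noise_sd**2 / config.replicates
    T = w / (1.0 - config.pair_correlation)
    a = math.sqrt(config.family_correlation * T)
    b = math.sqrt((config.pair_correlation - config.family_correlation) * T)
    return a, b


def _pilot_similarity(
    config: SimulationConfig, a: float, b: float, rng: np.random.Generator, n_pilot: int = 150
) -> tuple[float, float]:
    """Mean within-pair and singleton-singleton similarity of a pilot draw
    generated exactly like the real data (replicates averaged, t0 anchored)."""
    from .coherence import similarity

    times = _time_grid(config)
    s_pair, s_fam = [], []
    for _ in range(n_pilot):
        vec = {}
        for role in ("p1", "p2", "s1", "s2"):
            vec[role] = []
        for _c in range(config.conditions):
            f = _latent_curve(rng, times)
            g_pair = _latent_curve(rng, times)
            for role in ("p1", "p2", "s1", "s2"):
                g = g_pair if role in ("p1", "p2") else _latent_curve(rng, times)
                base = a * f + b * g
                reps = base + rng.normal(0.0, config.noise_sd, size=(config.replicates, times.size))
                v = reps.mean(axis=0)
                v[0] = 0.0
                vec[role].append(v)
        cat = {k: np.concatenate(v) for k, v in vec.items()}
        s_pair.append(similarity(cat["p1"], cat["p2"]))
        s_fam.append(similarity(cat["s1"], cat["s2"]))
    return float(np.mean(s_pair)), float(np.mean(s_fam))


def _calibrate_amplitudes(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[float, float, dict]:
    """Empirically adjust (a, b) so pilot similarities land within
    CALIBRATION_TOL of the planted targets."""
    a, b = _initial_amplitudes(config)
    info = {"initial": (a, b)}
    if a == 0.0 and b == 0.0:
        info["final"] = (a, b)
        return a, b, info
    for _ in range(3):
        s_pair, s_fam = _pilot_similarity(config, a, b, rng)
        info["pilot"] = (s_pair, s_fam)
        # pilot SE is ~0.01-0.02; only correct discrepancies clearly beyond it
        ok_pair = abs(s_pair - config.pair_correlation) <= 0.03
        ok_fam = abs(s_fam - config.family_correlation) <= 0.03
        if ok_pair and ok_fam:
            break
        # damped odds-matching multiplicative step on the shared-variance shares
        u, v = a * a, b * b
        uv = _odds_step(u + v, s_pair, config.pair_correlation)
        u_new = _odds_step(u, s_fam, config.family_correlation) if u > 0 else 0.0
        u_new = min(u_new, uv)
        a, b = math.sqrt(u_new), math.sqrt(max(uv - u_new, 0.0))
    info["final"] = (a, b)
    return a, b, info


def _odds_step(share: float, measured: float, target: float) -> float:
    if target <= 0.0:
        return 0.0
    measured = min(max(measured, 1e-6), 1 - 1e-6)
    kappa = (target / (1 - target)) / (measured / (1 - measured))
    kappa = math.sqrt(min(max(kappa, 0.6), 1.6))  # damped, trust-region step
    return share * kappa


def _time_grid(config: SimulationConfig) -> np.ndarray:
    return np.linspace(0.0, 60.0, config.time_points_per_condition)


def simulate_expression(
    config: SimulationConfig,
    layout: GenomeLayout,
    families: list[GeneFamily],
    truth: dict,
    rng: np.random.Generator,
) -> tuple[ExpressionSet, dict]:
    """Generate log2-ratio time courses for all family members.

    Per condition every family shares one latent response curve; each planted
    adjacent run additionally shares a block-level curve, while singletons
    carry private curves of the same amplitude (so all genes have equal
    variance and only the *shared* structure differs).  Values at t = 0 are
    exactly 0.  Returns the expression set and calibration metadata.
    """
    a, b, calib = _calibrate_amplitudes(config, rng)
    times = _time_grid(config)
    series = []
    # per-gene block assignment: cluster runs share a block id, singletons private
    blocks: dict[str, tuple[str, int]] = {}
    for fam in families:
        rec = truth["families"][fam.family_id]
        for bi, run in enumerate(rec["clusters"]):
            for g in run:
                blocks[g] = (fam.family_id, bi)
        for si, g in enumerate(rec["singletons"]):
            blocks[g] = (fam.family_id, -1 - si)
    for c in range(config.conditions):
        cond_id = f"cond{c + 1}"
        fam_curves = {
            fam.family_id: _latent_curve(rng, times) for fam in families
        }
        block_curves = {
            key: _latent_curve(rng, times) for key in sorted(set(blocks.values()))
        }
        values: dict[str, np.ndarray] = {}
        for fam in families:
            for g in sorted(fam.members):
                base = a * fam_curves[fam.family_id] + b * block_curves[blocks[g]]
                reps = base + rng.normal(
                    0.0, config.noise_sd, size=(config.replicates, times.size)
                )
                reps[:, 0] = 0.0
                values[g] = reps
        series.append(
            ConditionSeries(
                condition_id=cond_id,
                time_points=tuple(float(t) for t in times),
                reference_index=0,
                values=values,
                replicate_count=config.replicates,
            )
        )
    expr = build_expression_set(series, policy="intersection")
    return expr, {"amplitudes": (a, b), "calibration": calib}


# ---------------------------------------------------------------------------
# pillars

def planted_pairs(truth: dict, family_id: str | None = None) -> list[tuple[str, str]]:
    """Adjacent within-run gene pairs planted by the generator."""
    pairs = []
    for fid, rec in truth["families"].items():
        if family_id is not None and fid != family_id:
            continue
        for run in rec["clusters"]:
            pairs.extend((run[i], run[i + 1]) for i in range(len(run) - 1))
    return pairs


def simulate_pillars(
    config: SimulationConfig,
    layout: GenomeLayout,
    families: list[GeneFamily],
    truth: dict,
    rng: np.random.Generator,
) -> tuple[PillarTable, dict[str, GenomeLayout], dict]:
    """Build per-species gene orders and the ortholog pillar table.

    Every planted adjacent pair is kept adjacent in a species with its
    ``pair_conservation`` probability; otherwise one member is deleted (with
    the species' ``ortholog_loss`` probability) or relocated to a position
    that breaks the pairing without disturbing pairs decided conserved.
    Background genes are lost independently at the same loss rate.  The truth
    records the *realized* conservation (recomputed from the final orders).
    """
    pairs = planted_pairs(truth)
    pair_genes = {g for p in pairs for g in p}
    anchor_order = [
        [r.gene_id for r in recs] for recs in layout.chromosomes.values()
    ]
    species_orders: dict[str, GenomeLayout] = {ANCHOR_SPECIES: layout}
    ortho_name: dict[str, dict[str, str]] = {ANCHOR_SPECIES: {g: g for g in layout.gene_ids()}}
    conservation_truth: dict[str, dict[str, bool]] = {}

    for spec in config.species:
        chrom_lists = [list(c) for c in anchor_order]
        decisions = {p: bool(rng.random() < spec.pair_conservation) for p in pairs}
        protected: set[frozenset[str]] = {
            frozenset(p) for p, keep in decisions.items() if keep
        }
        deleted: set[str] = set()

        def locate(g: str) -> tuple[int, int]:
            for ci, lst in enumerate(chrom_lists):
                try:
                    return ci, lst.index(g)
                except ValueError:
                    continue
            raise KeyError(g)

        for p in pairs:
            if decisions[p]:
                continue
            # a gene shared with a conserved pair (runs of 3) cannot be moved
            candidates = [g for g in p if not any(g in fp for fp in protected)]
            if not candidates:
                continue  # breaking would damage a conserved pair; leave as is
            victim = candidates[int(rng.integers(0, len(candidates)))]
            partner = p[0] if victim == p[1] else p[1]
            if victim in deleted:
                continue
            if rng.random() < spec.ortholog_loss:
                ci, k = locate(victim)
                del chrom_lists[ci][k]
                deleted.add(victim)
                continue
            ci, k = locate(victim)
            del chrom_lists[ci][k]
            for _try in range(10_000):
                tc = int(rng.integers(0, len(chrom_lists)))
                tk = int(rng.integers(0, len(chrom_lists[tc]) + 1))
                left = chrom_lists[tc][tk - 1] if tk > 0 else None
                right = chrom_lists[tc][tk] if tk < len(chrom_lists[tc]) else None
                if partner in (left, right):
                    continue  # would remain adjacent to its partner
                if (
                    left is not None
                    and right is not None
                    and frozenset((left, right)) in protected
                ):
                    continue  # would split a conserved pair
                chrom_lists[tc].insert(tk, victim)
                break
            else:  # pragma: no cover
                raise GenerationError("cannot relocate gene; genome too constrained")

        # independent background ortholog loss (never a protected-pair member)
        for ci, lst in enumerate(chrom_lists):
            keep = []
            for g in lst:
                if g not in pair_genes and rng.random() < spec.ortholog_loss:
                    deleted.add(g)
                    continue
                keep.append(g)
            chrom_lists[ci] = keep

        names = {g: f"{spec.name}_{g}" for lst in chrom_lists for g in lst}
        chroms: dict[str, tuple[GeneRecord, ...]] = {}
        for ci, lst in enumerate(chrom_lists):
            if not lst:
                continue
            recs = []
            for k, g in enumerate(lst):
                start = 1 + k * 2000
                recs.append(
                    GeneRecord(names[g], f"chr{ci + 1:02d}", start, start + 999, "+")
                )
            chroms[f"chr{ci + 1:02d}"] = tuple(recs)
        sp_layout = GenomeLayout(chroms)
        species_orders[spec.name] = sp_layout
        ortho_name[spec.name] = names
        conservation_truth[spec.name] = {
            f"{p[0]}--{p[1]}": (
                names.get(p[0]) is not None
                and names.get(p[1]) is not None
                and sp_layout.are_adjacent(names[p[0]], names[p[1]])
            )
            for p in pairs
        }

    species_ids = [ANCHOR_SPECIES] + [s.name for s in config.species]
    pillar_rows = []
    for g in layout.gene_ids():
        row = {ANCHOR_SPECIES: (g,)}
        for spec in config.species:
            name = ortho_name[spec.name].get(g)
            if name is not None:
                row[spec.name] = (name,)
        pillar_rows.append(row)
    pillars = PillarTable(species_ids=species_ids, pillars=pillar_rows)
    truth_update = {"conservation": conservation_truth, "pairs": [f"{a}--{b}" for a, b in pairs]}
    return pillars, species_orders, truth_update


# ---------------------------------------------------------------------------
# bundle

def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate a complete, internally consistent synthetic data set."""
    rng = np.random.default_rng(config.seed)
    layout, families, truth = simulate_genome(config, rng)
    expression, expr_meta = simulate_expression(config, layout, families, truth, rng)
    pillars, orders, cons_truth = simulate_pillars(config, layout, families, truth, rng)
    truth.update(cons_truth)
    truth["expression"] = {
        "pair_correlation": config.pair_correlation,
        "family_correlation": config.family_correlation,
        "amplitudes": [float(x) for x in expr_meta["amplitudes"]],
    }
    truth["seed"] = config.seed
    return SyntheticBundle(
        config=config,
        layout=layout,
        families=families,
        expression=expression,
        pillars=pillars,
        species_orders=orders,
        truth=truth,
    )


def write_fixtures(bundle: SyntheticBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text fixtures; re-reading through the module
    loaders reproduces the in-memory structures."""
    import yaml

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation_tsv": d / "annotation.tsv",
        "annotation_gff3": d / "annotation.gff3",
        "families": d / "families.tsv",
        "expression": d / "expression.tsv",
        "pillars": d / "pillars.tsv",
        "truth": d / "truth.yaml",
    }
    write_annotation_tsv(bundle.layout, paths["annotation_tsv"])
    write_annotation_gff3(bundle.layout, paths["annotation_gff3"])
    write_families_tsv(bundle.families, paths["families"])
    write_expression_tsv(bundle.expression, paths["expression"])
    write_pillars_tsv(bundle.pillars, paths["pillars"])
    orders_dir = d / "orders"
    orders_dir.mkdir(exist_ok=True)
    for sp, lay in bundle.species_orders.items():
        p = orders_dir / f"{sp}.tsv"
        write_annotation_tsv(lay, p)
        paths[f"order_{sp}"] = p
    truth = dict(bundle.truth)
    truth["config"] = _listify(asdict(bundle.config))
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return paths


def _listify(obj):
    """Recursively turn tuples into lists for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj
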