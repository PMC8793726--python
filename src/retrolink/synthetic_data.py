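"""Synthetic genomes, parental genes, networks and retrocopies for testing.

The generator emulates the shape of a curated retrocopy dataset — a
multi-chromosome genome with one X, monotone genetic maps, parental genes
with Poisson retrocopy multiplicities and sparse parent-partner regulatory
networks — while giving precise control over the survival mechanism.

Each retrocopy is placed uniformly over the genome and survives (becomes a
retrogene rather than a pseudogene) with probability

    logistic(beta0 + beta_x * 1[parent on X and copy autosomal]
                   + beta_d * dist(parent, copy)),

so ``beta_x = beta_d = 0`` is the null of survival independent of placement
(surviving retrogenes are uniform over the genome), ``beta_x > 0`` plants an
out-of-the-X excess, and ``beta_d < 0`` plants a linkage-attraction effect.
The survival model is a synthetic testbed, not an inference target.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from retrolink.genetic_distance import MareyMap, dist, validate_map
from retrolink.genome_io import (
    GeneLocus,
    GenomeAssembly,
    RegulatoryNetwork,
    RetrocopyRecord,
    RetrocopyTable,
    ValidationError,
    read_assembly,
    read_gene_table,
    read_marey_table,
    read_network,
    read_retrocopy_table,
    write_assembly,
    write_gene_table,
    write_marey_table,
    write_network,
    write_retrocopy_table,
)

logger = logging.getLogger("retrolink")


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines a synthetic scenario.

    ``retrocopies_per_parent`` and ``partners_per_parent`` are Poisson means
    when given as floats, exact counts when given as ints.  ``beta_d`` is in
    units of inverse Morgans.  Defaults describe the standard small genome:
    five 100 Mb chromosomes at a uniform 1 cM/Mb (1 Morgan each), one X,
    60 parents with on average 1.4 retrocopies each (~84 copies), and a
    near-certain baseline survival so the null scenario yields ~80 uniform
    retrogenes.
    """

    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    x_index: int | None = 4
    map_style: str = "uniform"  # "uniform" | "random_monotone"
    cm_per_mb: float = 1.0
    markers_per_chrom: int = 11
    n_parents: int = 60
    retrocopies_per_parent: float | int = 1.4
    partners_per_parent: float | int = 2.0
    parent_placement: str = "genome"  # "genome" | "autosomes"
    gene_span_bp: int = 1_000
    beta0: float = 8.0
    beta_x: float = 0.0
    beta_d: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValidationError("need at least one chromosome")
        if self.x_index is not None and not (0 <= self.x_index < self.n_chromosomes):
            raise ValidationError("x_index out of range")
        if self.map_style not in {"uniform", "random_monotone"}:
            raise ValidationError(f"unknown map_style {self.map_style!r}")
        if self.parent_placement not in {"genome", "autosomes"}:
            raise ValidationError(f"unknown parent_placement {self.parent_placement!r}")
        if self.n_parents < 0 or self.gene_span_bp < 1:
            raise ValidationError("counts must be non-negative and spans positive")


@dataclass
class Scenario:
    """A fully generated scenario, in memory."""

    config: ScenarioConfig
    assembly: GenomeAssembly
    raw_marey: dict
    marey: MareyMap
    parents: dict[str, GeneLocus]
    partner_loci: dict[str, GeneLocus]
    network: RegulatoryNetwork
    table: RetrocopyTable


PRESETS = {
    # survival independent of placement; parents autosomal so the
    # out-of-the-X filter is a no-op and the X2/X3 scope is the full table
    "null": dict(parent_placement="autosomes", beta0=8.0, beta_x=0.0, beta_d=0.0),
    # strong survival bonus for X-parent -> autosome copies on a weak baseline
    "out_of_x": dict(
        parent_placement="genome", retrocopies_per_parent=3.0, beta0=-2.0, beta_x=5.0, beta_d=0.0
    ),
    # survival decays steeply with genetic distance from the parent
    "linkage": dict(
        parent_placement="autosomes",
        n_parents=100,
        retrocopies_per_parent=5.0,
        beta0=1.0,
        beta_x=0.0,
        beta_d=-8.0,
    ),
}


def preset(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """A named scenario configuration: ``null``, ``out_of_x`` or ``linkage``."""
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return ScenarioConfig(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_genome(config: ScenarioConfig, rng: np.random.Generator | None = None):
    """Build the assembly and a strictly monotone Marey map per chromosome.

    Uniform style places markers on a constant cM/Mb line; random monotone
    style draws interior marker positions and positive genetic increments.
    Returns ``(assembly, raw_markers, validated_map)``.
    """
    rng = rng or np.random.default_rng(config.seed)
    names = []
    for i in range(config.n_chromosomes):
        names.append("chrX" if i == config.x_index else f"chr{i + 1}")
    chroms = tuple((name, config.chrom_length_bp) for name in names)
    x_name = names[config.x_index] if config.x_index is not None else None
    assembly = GenomeAssembly(chromosomes=chroms, x_name=x_name)

    raw = {}
    L = config.chrom_length_bp
    for name in names:
        if config.map_style == "uniform":
            bp = np.array([0, L], dtype=np.int64)
            cm = bp / 1e6 * config.cm_per_mb
        else:
            k = max(config.markers_per_chrom, 3)
            interior = np.sort(rng.choice(np.arange(1, L), size=k - 2, replace=False))
            bp = np.concatenate(([0], interior, [L])).astype(np.int64)
            incr = rng.exponential(scale=1.0, size=k - 1)
            cm = np.concatenate(([0.0], np.cumsum(incr)))
            cm *= (L / 1e6 * config.cm_per_mb) / cm[-1]
        raw[name] = (bp, cm)
    return assembly, raw, validate_map(raw)


def _place_gene(
    config: ScenarioConfig,
    assembly: GenomeAssembly,
    rng: np.random.Generator,
    gene_id: str,
    restrict: str,
) -> GeneLocus:
    names = assembly.names
    lengths = assembly.lengths
    if restrict == "autosomes" and assembly.x_name is not None:
        idx = np.array([i for i, n in enumerate(names) if n != assembly.x_name])
    else:
        idx = np.arange(len(names))
    probs = lengths[idx] / lengths[idx].sum()
    i = int(idx[rng.choice(len(idx), p=probs)])
    span = min(config.gene_span_bp, int(lengths[i]))
    start0 = int(rng.integers(0, lengths[i] - span + 1))
    return GeneLocus(gene_id=gene_id, chrom=names[i], start0=start0, end0=start0 + span)


def _draw_count(value: float | int, rng: np.random.Generator) -> int:
    if isinstance(value, (int, np.integer)):
        return int(value)
    return int(rng.poisson(value))


def make_parents_and_network(
    config: ScenarioConfig, assembly: GenomeAssembly, rng: np.random.Generator | None = None
):
    """Place parental genes and their network partners; wire parent-partner edges.

    Each parent gets its own partner genes (no sharing), so the edge count is
    the sum of drawn partner degrees.  Returns
    ``(parents, partner_loci, network)``.
    """
    rng = rng or np.random.default_rng(config.seed)
    parents: dict[str, GeneLocus] = {}
    partner_loci: dict[str, GeneLocus] = {}
    edges: list[tuple[str, str]] = []
    n_partner = 0
    for i in range(config.n_parents):
        pid = f"parent{i:04d}"
        parents[pid] = _place_gene(config, assembly, rng, pid, config.parent_placement)
        for _ in range(_draw_count(config.partners_per_parent, rng)):
            qid = f"partner{n_partner:04d}"
            n_partner += 1
            partner_loci[qid] = _place_gene(config, assembly, rng, qid, "genome")
            edges.append((pid, qid))
    return parents, partner_loci, RegulatoryNetwork.from_pairs(edges)


def generate_retrocopies(
    config: ScenarioConfig,
    assembly: GenomeAssembly,
    marey: MareyMap,
    parents: dict[str, GeneLocus],
    rng: np.random.Generator | None = None,
) -> RetrocopyTable:
    """Place retrocopies uniformly and assign survival by the logistic model."""
    if not parents:
        raise ValidationError("no parental genes")
    rng = rng or np.random.default_rng(config.seed)
    records: list[RetrocopyRecord] = []
    n_copy = 0
    for pid in parents:
        parent = parents[pid]
        for _ in range(_draw_count(config.retrocopies_per_parent, rng)):
            rid = f"retro{n_copy:05d}"
            n_copy += 1
            locus = _place_gene(config, assembly, rng, rid, "genome")
            out_of_x = (
                assembly.x_name is not None
                and parent.chrom == assembly.x_name
                and locus.chrom != assembly.x_name
            )
            d = dist(parent, locus, marey)
            p_survive = float(expit(config.beta0 + config.beta_x * out_of_x + config.beta_d * d))
            status = "retrogene" if rng.random() < p_survive else "pseudogene"
            records.append(RetrocopyRecord(rid, pid, locus, status))
    return RetrocopyTable(records=records, parents=dict(parents))


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate a complete scenario from one seed, deterministically."""
    rng = np.random.default_rng(config.seed)
    assembly, raw, marey = make_genome(config, rng)
    parents, partner_loci, network = make_parents_and_network(config, assembly, rng)
    table = generate_retrocopies(config, assembly, marey, parents, rng)
    n_retro = len(table.retrogenes())
    logger.info(
        "scenario: %d parents, %d retrocopies (%d retrogenes), %d network edges",
        len(parents), table.n, n_retro, len(network),
    )
    return Scenario(
        config=config,
        assembly=assembly,
        raw_marey=raw,
        marey=marey,
        parents=parents,
        partner_loci=partner_loci,
        network=network,
        table=table,
    )


# ---------------------------------------------------------------------------
# on-disk bundles
# ---------------------------------------------------------------------------

_FILES = {
    "assembly": "assembly.tsv",
    "marey": "marey.tsv",
    "parents": "parents.tsv",
    "partners": "partners.tsv",
    "network": "network.tsv",
    "retrocopies": "retrocopies.tsv",
    "manifest": "manifest.json",
}


def write_scenario(scenario: Scenario, out_dir: str | Path) -> None:
    """Write the full TSV bundle plus a manifest echoing the configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_assembly(scenario.assembly, out / _FILES["assembly"])
    write_marey_table(scenario.raw_marey, out / _FILES["marey"])
    write_gene_table(scenario.parents.values(), out / _FILES["parents"])
    write_gene_table(scenario.partner_loci.values(), out / _FILES["partners"])
    write_network(scenario.network, out / _FILES["network"])
    write_retrocopy_table(scenario.table, out / _FILES["retrocopies"])
    manifest = {"config": asdict(scenario.config), "format": "retrolink-scenario-v1"}
    (out / _FILES["manifest"]).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def load_scenario(in_dir: str | Path) -> Scenario:
    """Read a scenario bundle written by :func:`write_scenario`."""
    src = Path(in_dir)
    manifest = json.loads((src / _FILES["manifest"]).read_text())
    config = ScenarioConfig(**manifest["config"])
    assembly = read_assembly(src / _FILES["assembly"])
    raw = read_marey_table(src / _FILES["marey"])
    marey = validate_map(raw)
    parents = {loc.gene_id: loc for loc in read_gene_table(src / _FILES["parents"], assembly)}
    partner_loci = {loc.gene_id: loc for loc in read_gene_table(src / _FILES["partners"], assembly)}
    network = read_network(src / _FILES["network"])
    table = read_retrocopy_table(src / _FILES["retrocopies"], assembly, parents)
    return Scenario(
        config=config,
        assembly=assembly,
        raw_marey=raw,
        marey=marey,
        parents=parents,
        partner_loci=partner_loci,
        network=network,
        table=table,
    )
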