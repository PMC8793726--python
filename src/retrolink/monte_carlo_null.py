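"""Monte Carlo reference distributions under uniform retrogene placement.

The null hypothesis throughout: retrogene insertion sites are i.i.d. uniform
over the genome, independent of parental gene location.  A uniform point is
drawn by choosing a chromosome with probability proportional to its physical
length and a base uniformly within it.  Each statistic's reference
distribution is built by redrawing the random elements of the statistic
(retrogene positions; for X1-X3 also fresh parental positions) and
recomputing it, 1,000 times by default.

The observed statistic is then compared against the reference sample with a
two-tailed empirical p-value using the add-one permutation estimator

    p = min(1, 2 * min(#{s <= obs} + 1, #{s >= obs} + 1) / (N + 1)),

which can never return 0 from a finite null sample.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from retrolink.genetic_distance import INTERCHROMOSOMAL_DISTANCE, MareyMap
from retrolink.genome_io import (
    GeneLocus,
    GenomeAssembly,
    RegulatoryNetwork,
    RetrocopyTable,
    ValidationError,
)
from retrolink import retrostats

logger = logging.getLogger("retrolink")

_STREAMS = {"x1": 0, "x2": 1, "x3": 2, "x4": 3}


@dataclass(frozen=True)
class NullDistribution:
    """A Monte Carlo reference sample for one statistic."""

    name: str
    samples: np.ndarray
    iterations: int
    seed: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if len(samples) != self.iterations:
            raise ValidationError("null sample length does not match iteration count")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("null sample contains non-finite values")


@dataclass(frozen=True)
class TestConfig:
    """Knobs of a Monte Carlo test run.

    ``parent_restrict`` controls where null parental genes are drawn:
    ``"autosomes"`` (default, matching the post-filter scope of the observed
    statistics) or ``"all"``.  ``x4_mode`` selects whether the
    nearest-partner null keeps the empirical parent/partner geometry fixed
    (``"fixed-partners"``) or redraws it each realization
    (``"random-partners"``).
    """

    __test__ = False  # not a pytest class despite the name

    iterations: int = 1000
    alpha: float = 0.05
    seed: int = 0
    cap_half: bool = False
    parent_restrict: str = "autosomes"
    x4_mode: str = "fixed-partners"
    x3_include_pseudogenes: bool = False

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.parent_restrict not in {"autosomes", "all"}:
            raise ValidationError(f"unknown parent_restrict {self.parent_restrict!r}")
        if self.x4_mode not in {"fixed-partners", "random-partners"}:
            raise ValidationError(f"unknown x4 mode {self.x4_mode!r}")


@dataclass(frozen=True)
class TestResult:
    """Observed statistic, its reference distribution, and the two-tailed p."""

    __test__ = False  # not a pytest class despite the name

    observed: retrostats.StatisticValue
    null: NullDistribution
    p_two_tailed: float
    alpha: float
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# uniform sampling over the genome
# ---------------------------------------------------------------------------


def _allowed_chromosomes(assembly: GenomeAssembly, restrict: str) -> np.ndarray:
    if restrict == "all":
        return np.arange(len(assembly.names))
    if restrict == "autosomes":
        idx = [i for i, name in enumerate(assembly.names) if name != assembly.x_name]
        if not idx:
            raise ValidationError("restrict='autosomes' but the assembly has no autosome")
        return np.array(idx)
    raise ValidationError(f"unknown restrict {restrict!r}")


def _sample_points(
    assembly: GenomeAssembly, rng: np.random.Generator, shape, restrict: str = "all"
) -> tuple[np.ndarray, np.ndarray]:
    """Draw uniform genomic points: chromosome index (assembly order) and 0-based bp."""
    allowed = _allowed_chromosomes(assembly, restrict)
    lengths = assembly.lengths
    probs = lengths[allowed] / lengths[allowed].sum()
    chrom_idx = allowed[rng.choice(len(allowed), size=shape, p=probs)]
    pos = rng.integers(0, lengths[chrom_idx])
    return chrom_idx, pos


def sample_uniform_locus(
    assembly: GenomeAssembly, rng: np.random.Generator, restrict: str = "all", gene_id: str = "random"
) -> GeneLocus:
    """One uniform random point locus: chromosome by length, base uniform within it."""
    chrom_idx, pos = _sample_points(assembly, rng, (), restrict)
    return GeneLocus.point(gene_id, assembly.names[int(chrom_idx)], int(pos))


def _morgans_matrix(
    marey: MareyMap, assembly: GenomeAssembly, chrom_idx: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    """Genetic positions (Morgans) for point arrays; NaN marks unmapped chromosomes."""
    out = np.full(chrom_idx.shape, np.nan, dtype=float)
    for i, name in enumerate(assembly.names):
        mask = chrom_idx == i
        if mask.any() and marey.is_mapped(name):
            out[mask] = marey.positions(name, pos[mask])
    return out


def _pair_dist_matrix(
    marey: MareyMap,
    assembly: GenomeAssembly,
    c1: np.ndarray,
    p1: np.ndarray,
    c2: np.ndarray,
    p2: np.ndarray,
    cap_half: bool = False,
) -> np.ndarray:
    """Vectorized pairwise distance with the interchromosomal 0.5 rule."""
    g1 = _morgans_matrix(marey, assembly, c1, p1)
    g2 = _morgans_matrix(marey, assembly, c2, p2)
    d = np.full(c1.shape, INTERCHROMOSOMAL_DISTANCE, dtype=float)
    same = c1 == c2
    gap = np.abs(g1 - g2)[same]
    d[same] = np.where(np.isnan(gap), 0.0, gap)  # shared unmapped chromosome -> 0
    if cap_half:
        np.minimum(d, INTERCHROMOSOMAL_DISTANCE, out=d)
    return d


# ---------------------------------------------------------------------------
# null simulations
# ---------------------------------------------------------------------------


def simulate_null_x1(
    assembly: GenomeAssembly, n_pairs: int, iterations: int = 1000, seed: int = 0
) -> NullDistribution:
    """Null for X1: n_pairs independent uniform (parent, retrogene) pairs per realization.

    Only chromosome identity matters for X1, so positions within chromosomes
    are not materialized.
    """
    if assembly.x_index is None:
        raise ValidationError("assembly has no X chromosome designated")
    rng = np.random.default_rng(seed)
    x = assembly.x_index
    pc, _ = _sample_points(assembly, rng, (iterations, n_pairs)) if n_pairs else (np.empty((iterations, 0), int), None)
    rc, _ = _sample_points(assembly, rng, (iterations, n_pairs)) if n_pairs else (np.empty((iterations, 0), int), None)
    samples = np.sum((pc == x) & (rc != x), axis=1).astype(float)
    return NullDistribution(name="X1", samples=samples, iterations=iterations, seed=seed)


def simulate_null_x3(
    assembly: GenomeAssembly,
    marey: MareyMap,
    group_sizes: Sequence[int],
    iterations: int = 1000,
    seed: int = 0,
    parent_restrict: str = "autosomes",
    cap_half: bool = False,
    name: str = "X3_mu_hat",
) -> NullDistribution:
    """Null for the parent-weighted mean: fresh parents and grouped retrocopies.

    Each realization draws one uniform parent per group (restricted per
    ``parent_restrict``) and ``|C|`` uniform genome-wide retrocopy positions
    for it, preserving the empirical multiset of group sizes; per-parent mean
    distances are averaged into one sample of mu-hat.
    """
    sizes = np.asarray(list(group_sizes), dtype=np.int64)
    if sizes.size == 0:
        raise ValidationError("group_sizes is empty")
    if np.any(sizes < 1):
        raise ValidationError("group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    total = int(sizes.sum())
    pc, pp = _sample_points(assembly, rng, (iterations, len(sizes)), parent_restrict)
    pc = np.repeat(pc, sizes, axis=1)
    pp = np.repeat(pp, sizes, axis=1)
    rc, rp = _sample_points(assembly, rng, (iterations, total))
    d = _pair_dist_matrix(marey, assembly, pc, pp, rc, rp, cap_half=cap_half)
    offsets = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    per_parent = np.add.reduceat(d, offsets, axis=1) / sizes
    samples = per_parent.mean(axis=1)
    return NullDistribution(name=name, samples=samples, iterations=iterations, seed=seed)


def simulate_null_x2(
    assembly: GenomeAssembly,
    marey: MareyMap,
    n: int,
    iterations: int = 1000,
    seed: int = 0,
    parent_restrict: str = "autosomes",
    cap_half: bool = False,
) -> NullDistribution:
    """Null for X2: n independent uniform (parent, retrogene) pairs per realization.

    This is exactly the grouped null with every group of size one, and is
    implemented as that special case, so the two samplers coincide sample for
    sample at equal seeds.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    null = simulate_null_x3(
        assembly,
        marey,
        group_sizes=np.ones(n, dtype=int),
        iterations=iterations,
        seed=seed,
        parent_restrict=parent_restrict,
        cap_half=cap_half,
        name="X2",
    )
    return null


def simulate_null_x4(
    assembly: GenomeAssembly,
    marey: MareyMap,
    candidate_sets: Sequence[Sequence[GeneLocus]],
    iterations: int = 1000,
    seed: int = 0,
    mode: str = "fixed-partners",
    parent_restrict: str = "autosomes",
    cap_half: bool = False,
) -> NullDistribution:
    """Null for the nearest-partner mean: uniform retrogenes against candidate sets.

    ``candidate_sets`` holds, per empirical retrogene, the located
    {parent} ∪ partners set (parent first).  In ``fixed-partners`` mode the
    empirical candidate coordinates stay fixed and only retrogene positions
    are redrawn — the minimal permutation consistent with the null.  In
    ``random-partners`` mode each realization also redraws candidate points
    of matching count (parent per ``parent_restrict``, partners genome-wide).
    """
    if mode not in {"fixed-partners", "random-partners"}:
        raise ValidationError(f"unknown x4 mode {mode!r}")
    n_retro = len(candidate_sets)
    if n_retro == 0:
        raise ValidationError("no candidate sets")
    if any(len(c) == 0 for c in candidate_sets):
        raise ValidationError("empty candidate set (the parent must always be present)")
    rng = np.random.default_rng(seed)
    name_to_idx = {name: i for i, name in enumerate(assembly.names)}

    rc, rp = _sample_points(assembly, rng, (iterations, n_retro))
    rg = _morgans_matrix(marey, assembly, rc, rp)

    mins = np.full((iterations, n_retro), np.inf)
    for j, cands in enumerate(candidate_sets):
        k = len(cands)
        if mode == "fixed-partners":
            cc = np.tile(np.array([name_to_idx[c.chrom] for c in cands]), (iterations, 1))
            cp = np.tile(np.array([c.point_bp for c in cands], dtype=np.int64), (iterations, 1))
        else:
            cc = np.empty((iterations, k), dtype=np.int64)
            cp = np.empty((iterations, k), dtype=np.int64)
            cc[:, :1], cp[:, :1] = _sample_points(assembly, rng, (iterations, 1), parent_restrict)
            if k > 1:
                cc[:, 1:], cp[:, 1:] = _sample_points(assembly, rng, (iterations, k - 1))
        cg = _morgans_matrix(marey, assembly, cc, cp)
        d = np.full((iterations, k), INTERCHROMOSOMAL_DISTANCE)
        same = cc == rc[:, j : j + 1]
        gap = np.abs(cg - rg[:, j : j + 1])[same]
        d[same] = np.where(np.isnan(gap), 0.0, gap)
        if cap_half:
            np.minimum(d, INTERCHROMOSOMAL_DISTANCE, out=d)
        mins[:, j] = d.min(axis=1)
    samples = mins.mean(axis=1)
    return NullDistribution(name="X4_mu_hat", samples=samples, iterations=iterations, seed=seed)


# ---------------------------------------------------------------------------
# p-values and orchestration
# ---------------------------------------------------------------------------


def empirical_p_two_tailed(null: NullDistribution, observed: float) -> float:
    """Two-tailed empirical p-value, add-one estimator, capped at 1."""
    if not np.isfinite(observed):
        raise ValidationError("observed statistic is not finite")
    s = null.samples
    if len(s) == 0:
        raise ValidationError("empty null sample")
    n_le = int(np.sum(s <= observed))
    n_ge = int(np.sum(s >= observed))
    n = len(s)
    return min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n + 1))


def _derive_seed(root_seed: int, which: str) -> int:
    """A per-test child seed, deterministic in the root seed, < 2**31."""
    state = np.random.SeedSequence(root_seed).generate_state(len(_STREAMS), dtype=np.uint64)
    return int(state[_STREAMS[which]] % (2**31))


def run_test(
    which: str,
    assembly: GenomeAssembly,
    marey: MareyMap,
    table: RetrocopyTable,
    network: RegulatoryNetwork | None = None,
    partner_loci: Mapping[str, GeneLocus] | None = None,
    config: TestConfig | None = None,
) -> TestResult:
    """Compute an observed statistic, its matching null, and the two-tailed p.

    X1 runs on the full table (it is the data-quality check for the
    out-of-the-X effect); X2-X4 run after the out-of-the-X filter so the
    linkage question concerns strictly autosomal parental genes.
    """
    config = config or TestConfig()
    which = which.lower()
    if which not in _STREAMS:
        raise ValidationError(f"unknown test {which!r}")
    seed = _derive_seed(config.seed, which)

    if which == "x1":
        observed = retrostats.out_of_x_count(table, assembly)
        null = simulate_null_x1(assembly, n_pairs=observed.n_units, iterations=config.iterations, seed=seed)
    else:
        scoped = retrostats.filter_out_of_x(table, assembly) if assembly.x_name is not None else table
        if which == "x2":
            observed = retrostats.mean_parent_distance(scoped, marey, cap_half=config.cap_half)
            null = simulate_null_x2(
                assembly,
                marey,
                n=observed.n_units,
                iterations=config.iterations,
                seed=seed,
                parent_restrict=config.parent_restrict,
                cap_half=config.cap_half,
            )
        elif which == "x3":
            observed = retrostats.parent_weighted_mean(
                scoped, marey, include_pseudogenes=config.x3_include_pseudogenes, cap_half=config.cap_half
            )
            sizes = []
            for group in scoped.groups.values():
                members = (
                    group
                    if config.x3_include_pseudogenes
                    else [r for r in group if r.status == "retrogene"]
                )
                if members:
                    sizes.append(len(members))
            null = simulate_null_x3(
                assembly,
                marey,
                group_sizes=sizes,
                iterations=config.iterations,
                seed=seed,
                parent_restrict=config.parent_restrict,
                cap_half=config.cap_half,
            )
        else:  # x4
            if network is None:
                raise ValidationError("the nearest-partner test needs a regulatory network")
            loci = dict(partner_loci or {})
            observed = retrostats.nearest_partner_mean(scoped, network, loci, marey, cap_half=config.cap_half)
            cands = retrostats.candidate_sets(scoped, network, loci)
            null = simulate_null_x4(
                assembly,
                marey,
                cands,
                iterations=config.iterations,
                seed=seed,
                mode=config.x4_mode,
                parent_restrict=config.parent_restrict,
                cap_half=config.cap_half,
            )

    p = empirical_p_two_tailed(null, observed.value)
    echo = asdict(config)
    echo["which"] = which
    echo["derived_seed"] = seed
    return TestResult(observed=observed, null=null, p_two_tailed=p, alpha=config.alpha, config=echo)
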