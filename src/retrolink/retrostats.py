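"""Observed statistics X1-X4 and the out-of-the-X filter.

* X1 — count of (parental gene on the X, retrogene elsewhere) pairs; the
  out-of-the-X excess is well documented, so recovering it is a data-quality
  check before the linkage tests.
* X2 — mean genetic distance between each retrogene and its parental gene,
  weighting every retrogene equally.
* X3 (reported as its estimator mu-hat) — the same distances first averaged
  within each parent's retrocopy set C and then averaged over parents, which
  removes the bias from parents that spawned many copies.
* X4 (mu-hat) — per retrogene, the minimum distance to any member of
  {parental gene} ∪ {its network partners}; averaged over retrogenes.

X2-X4 are computed on retrogenes after the out-of-the-X filter, so the
linkage question is asked on strictly autosomal parental genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from retrolink.genetic_distance import MareyMap, dist
from retrolink.genome_io import (
    GeneLocus,
    GenomeAssembly,
    RegulatoryNetwork,
    RetrocopyTable,
    ValidationError,
)

logger = logging.getLogger("retrolink")


@dataclass(frozen=True)
class StatisticValue:
    """A computed statistic: its name, value, and the number of averaged units."""

    name: str
    value: float
    n_units: int

    def __post_init__(self) -> None:
        if self.n_units < 0:
            raise ValidationError("n_units must be non-negative")


def _scope(table: RetrocopyTable, scope: str):
    if scope == "retrogene":
        return table.retrogenes()
    if scope == "all":
        return list(table.records)
    raise ValueError(f"unknown scope {scope!r}")


def out_of_x_count(
    table: RetrocopyTable, assembly: GenomeAssembly, scope: str = "retrogene"
) -> StatisticValue:
    """X1: number of pairs with an X-linked parent and the copy on another chromosome."""
    if assembly.x_name is None:
        raise ValidationError("assembly has no X chromosome designated")
    records = _scope(table, scope)
    count = sum(
        1
        for rec in records
        if table.parents[rec.parent_id].chrom == assembly.x_name and rec.locus.chrom != assembly.x_name
    )
    return StatisticValue(name="X1", value=float(count), n_units=len(records))


def filter_out_of_x(table: RetrocopyTable, assembly: GenomeAssembly) -> RetrocopyTable:
    """Remove every record whose parental gene is X-linked (the whole group leaves).

    Controls for the out-of-the-X effect so the remaining tests run on
    strictly autosomal parental genes; applying the filter twice is a no-op.
    """
    if assembly.x_name is None:
        raise ValidationError("assembly has no X chromosome designated")
    keep_parents = {pid: loc for pid, loc in table.parents.items() if loc.chrom != assembly.x_name}
    records = [rec for rec in table.records if rec.parent_id in keep_parents]
    n_removed = table.n - len(records)
    if n_removed:
        logger.info("out-of-the-X filter: removed %d records with X-linked parents", n_removed)
    if not records:
        logger.warning("out-of-the-X filter: no records remain")
    return RetrocopyTable(records=records, parents=keep_parents)


def mean_parent_distance(
    table: RetrocopyTable, marey: MareyMap, cap_half: bool = False
) -> StatisticValue:
    """X2: mean genetic distance from each retrogene to its parental gene."""
    retro = table.retrogenes()
    if not retro:
        raise ValidationError("no retrogenes in scope")
    total = sum(dist(table.parents[r.parent_id], r.locus, marey, cap_half=cap_half) for r in retro)
    return StatisticValue(name="X2", value=total / len(retro), n_units=len(retro))


def parent_weighted_mean(
    table: RetrocopyTable,
    marey: MareyMap,
    include_pseudogenes: bool = False,
    cap_half: bool = False,
) -> StatisticValue:
    """X3 mu-hat: per-parent mean distance to its retrocopy set C, averaged over parents.

    By default C contains surviving retrogenes only; ``include_pseudogenes``
    widens it to all retrocopies.  Parents with empty C do not contribute.
    """
    per_parent: list[float] = []
    for pid, group in table.groups.items():
        members = group if include_pseudogenes else [r for r in group if r.status == "retrogene"]
        if not members:
            continue
        parent = table.parents[pid]
        dsum = sum(dist(parent, r.locus, marey, cap_half=cap_half) for r in members)
        per_parent.append(dsum / len(members))
    if not per_parent:
        raise ValidationError("no parent with a non-empty retrocopy set")
    return StatisticValue(
        name="X3_mu_hat", value=sum(per_parent) / len(per_parent), n_units=len(per_parent)
    )


def nearest_partner_mean(
    table: RetrocopyTable,
    network: RegulatoryNetwork,
    loci: Mapping[str, GeneLocus],
    marey: MareyMap,
    cap_half: bool = False,
) -> StatisticValue:
    """X4 mu-hat: per retrogene, minimum distance to {parent} ∪ partners(parent); averaged.

    Network partners without coordinates in ``loci`` are excluded (logged);
    a candidate set can never empty because the parental gene, which always
    has a locus, is a member.
    """
    retro = table.retrogenes()
    if not retro:
        raise ValidationError("no retrogenes in scope")
    n_missing = 0
    total = 0.0
    for rec in retro:
        parent = table.parents[rec.parent_id]
        candidates = [parent]
        for partner in sorted(network.partners(rec.parent_id)):
            loc = loci.get(partner)
            if loc is None:
                n_missing += 1
                continue
            candidates.append(loc)
        total += min(dist(rec.locus, c, marey, cap_half=cap_half) for c in candidates)
    if n_missing:
        logger.info("nearest-partner statistic: %d partner references lacked coordinates", n_missing)
    return StatisticValue(name="X4_mu_hat", value=total / len(retro), n_units=len(retro))


def candidate_sets(
    table: RetrocopyTable,
    network: RegulatoryNetwork,
    loci: Mapping[str, GeneLocus],
) -> list[list[GeneLocus]]:
    """Per retrogene, the located candidate set {parent} ∪ partners(parent).

    The parent locus comes first.  This is the fixed geometry the
    nearest-partner null permutes retrogenes against.
    """
    sets = []
    for rec in table.retrogenes():
        parent = table.parents[rec.parent_id]
        cand = [parent]
        for partner in sorted(network.partners(rec.parent_id)):
            loc = loci.get(partner)
            if loc is not None:
                cand.append(loc)
        sets.append(cand)
    return sets
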