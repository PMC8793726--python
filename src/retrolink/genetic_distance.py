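"""Genetic position via Marey-map interpolation and the pairwise distance rule.

A Marey map is a per-chromosome table of (physical position in bp, cumulative
genetic position in cM).  Genetic position at an arbitrary base is obtained
by piecewise-linear interpolation between flanking markers — the standard
local Marey-map estimate.  All public distances are in Morgans; cM appears
only at file boundaries.

The distance between two loci is:

* different chromosomes: exactly 0.5 Morgans (unlinked loci behave as if at
  recombination fraction one half);
* same mapped chromosome: absolute difference of interpolated genetic
  positions, optionally capped at 0.5;
* same unmapped chromosome (fewer than two markers, e.g. a non-recombining
  dot chromosome): 0, with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import isotonic_regression

from retrolink.genome_io import GeneLocus, ValidationError, read_marey_table

logger = logging.getLogger("retrolink")

INTERCHROMOSOMAL_DISTANCE = 0.5  # Morgans


class UnmappedChromosomeError(KeyError):
    """Genetic position requested on a chromosome without a usable map."""


@dataclass(frozen=True)
class MareyMap:
    """Validated monotone Marey maps, one marker series per chromosome.

    ``series`` maps chromosome name to ``(position_bp, morgans)`` arrays with
    strictly increasing positions and non-decreasing genetic values.
    ``unmapped`` lists chromosomes that had fewer than two markers and hence
    support no interpolation.
    """

    series: Mapping[str, tuple[np.ndarray, np.ndarray]]
    unmapped: frozenset[str] = field(default_factory=frozenset)

    def is_mapped(self, chrom: str) -> bool:
        return chrom in self.series and chrom not in self.unmapped

    def terminal_length(self, chrom: str) -> float:
        """Terminal genetic length of a chromosome, in Morgans."""
        if not self.is_mapped(chrom):
            return 0.0
        return float(self.series[chrom][1][-1])

    def positions(self, chrom: str, bp) -> np.ndarray:
        """Vectorized genetic position (Morgans) for an array of bp coordinates."""
        if not self.is_mapped(chrom):
            raise UnmappedChromosomeError(chrom)
        pos, morgans = self.series[chrom]
        return np.interp(np.asarray(bp, dtype=float), pos, morgans)


def validate_map(raw: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> MareyMap:
    """Validate raw markers into a monotone :class:`MareyMap`.

    Physical positions must be strictly increasing per chromosome after
    sorting (duplicated positions are an error).  Genetic values that dip
    (map noise) are projected onto the nearest non-decreasing series by
    isotonic regression (pool-adjacent-violators); the number of adjusted
    markers is logged.  Chromosomes with fewer than two markers are flagged
    unmapped rather than rejected.
    """
    series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    unmapped: set[str] = set()
    for chrom, (bp, cm) in raw.items():
        bp = np.asarray(bp, dtype=np.int64)
        cm = np.asarray(cm, dtype=float)
        if bp.shape != cm.shape:
            raise ValidationError(f"{chrom}: marker position/genetic arrays differ in length")
        if len(bp) < 2:
            logger.warning("marey map: chromosome %s has %d marker(s); flagged unmapped", chrom, len(bp))
            unmapped.add(chrom)
            series[chrom] = (bp, cm / 100.0)
            continue
        order = np.argsort(bp, kind="stable")
        bp, cm = bp[order], cm[order]
        if np.any(np.diff(bp) == 0):
            raise ValidationError(f"{chrom}: duplicate marker positions")
        if np.any(cm < 0):
            raise ValidationError(f"{chrom}: negative genetic positions")
        if np.any(np.diff(cm) < 0):
            fitted = isotonic_regression(cm).x
            n_adj = int(np.sum(~np.isclose(fitted, cm)))
            logger.info("marey map: %s non-monotone; %d marker(s) adjusted by isotonic projection", chrom, n_adj)
            cm = fitted
        series[chrom] = (bp, cm / 100.0)
    return MareyMap(series=series, unmapped=frozenset(unmapped))


def load_marey_map(path: str | Path) -> MareyMap:
    """Read and validate a Marey-map TSV in one step."""
    return validate_map(read_marey_table(path))


def genetic_position(marey: MareyMap, chrom: str, bp: int) -> float:
    """Genetic position of a base, in Morgans.

    Piecewise-linear interpolation between the flanking markers; positions
    outside the marker range clamp to the terminal marker's genetic value,
    so no extrapolated (possibly negative) rate is ever produced at
    telomeres.
    """
    return float(marey.positions(chrom, bp))


def dist(a: GeneLocus, b: GeneLocus, marey: MareyMap, cap_half: bool = False) -> float:
    """Pairwise genetic distance between two loci, in Morgans.

    Interchromosomal pairs return exactly 0.5 regardless of the maps.  On a
    shared mapped chromosome the distance is the absolute difference of
    interpolated genetic positions of the gene midpoints, optionally capped
    at 0.5.  On a shared unmapped chromosome the distance is 0 (zero
    recombination is the biological reading) with a warning.
    """
    if a.chrom != b.chrom:
        return INTERCHROMOSOMAL_DISTANCE
    if not marey.is_mapped(a.chrom):
        logger.warning("dist: chromosome %s unmapped; intrachromosomal distance taken as 0", a.chrom)
        return 0.0
    d = abs(genetic_position(marey, a.chrom, a.point_bp) - genetic_position(marey, b.chrom, b.point_bp))
    if cap_half:
        d = min(d, INTERCHROMOSOMAL_DISTANCE)
    return d
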