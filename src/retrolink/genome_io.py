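"""Input/output for assemblies, gene tables, retrocopy tables and networks.

All on-disk tables are UTF-8, tab-separated, with a header row; lines
starting with ``#`` are comments.  Coordinates in files are 1-based
inclusive (GFF-like).  Internally every locus is 0-based half-open; the
conversion happens here, once, and nowhere else.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("retrolink")

VALID_STATUSES = frozenset({"retrogene", "pseudogene", "unknown"})


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeAssembly:
    """Chromosome names and physical lengths; the sampling space of the null.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    x_name
        Name of the X chromosome, or ``None`` if no chromosome is flagged.
    """

    chromosomes: tuple[tuple[str, int], ...]
    x_name: str | None = None

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValidationError("no chromosomes")
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
        if self.x_name is not None and self.x_name not in names:
            raise ValidationError(f"x_name {self.x_name!r} not among chromosomes")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.chromosomes)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([c[1] for c in self.chromosomes], dtype=np.int64)

    @property
    def total_bp(self) -> int:
        return int(self.lengths.sum())

    @property
    def x_index(self) -> int | None:
        if self.x_name is None:
            return None
        return self.names.index(self.x_name)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names


@dataclass(frozen=True)
class GeneLocus:
    """A gene span on a chromosome, stored 0-based half-open.

    ``point_bp`` is the representative coordinate that enters the genetic
    distance function: the floor midpoint of the span, strand-free.
    """

    gene_id: str
    chrom: str
    start0: int
    end0: int

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("empty gene_id")
        if not (0 <= self.start0 < self.end0):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid 0-based half-open span [{self.start0}, {self.end0})"
            )

    @property
    def point_bp(self) -> int:
        """0-based midpoint, ``(start0 + end0) // 2``."""
        return (self.start0 + self.end0) // 2

    @property
    def point_bp_1based(self) -> int:
        return self.point_bp + 1

    @classmethod
    def from_1based(cls, gene_id: str, chrom: str, start: int, end: int) -> "GeneLocus":
        """Build from 1-based inclusive coordinates as they appear in files."""
        if start < 1 or end < start:
            raise ValidationError(f"gene {gene_id!r}: invalid 1-based span {start}..{end}")
        return cls(gene_id=gene_id, chrom=chrom, start0=start - 1, end0=end)

    @classmethod
    def point(cls, gene_id: str, chrom: str, point0: int) -> "GeneLocus":
        """A single-base locus at 0-based position ``point0``."""
        return cls(gene_id=gene_id, chrom=chrom, start0=point0, end0=point0 + 1)


@dataclass(frozen=True)
class RetrocopyRecord:
    """One retrocopy, linked to its parental gene, with survival status."""

    retro_id: str
    parent_id: str
    locus: GeneLocus
    status: str

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUSES:
            raise ValidationError(f"retrocopy {self.retro_id!r}: unknown status {self.status!r}")


@dataclass
class RetrocopyTable:
    """Retrocopy records plus the parental loci they point at.

    ``groups`` maps each parent to its retrocopies (the per-parent set C of
    the parent-weighted statistic); ``n`` is the number of records.
    """

    records: list[RetrocopyRecord]
    parents: dict[str, GeneLocus]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.parent_id not in self.parents:
                raise ValidationError(
                    f"retrocopy {rec.retro_id!r}: parent {rec.parent_id!r} has no locus"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def groups(self) -> dict[str, list[RetrocopyRecord]]:
        out: dict[str, list[RetrocopyRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.parent_id, []).append(rec)
        return out

    def retrogenes(self) -> list[RetrocopyRecord]:
        return [r for r in self.records if r.status == "retrogene"]


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Undirected regulatory-interaction edges between gene labels.

    Edges are symmetrized on load: direction is discarded, duplicates are
    collapsed and self-edges removed.
    """

    edges: frozenset[frozenset[str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for edge in self.edges:
            if len(edge) != 2 or any(not g for g in edge):
                raise ValidationError(f"malformed edge {set(edge)!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "RegulatoryNetwork":
        edges = set()
        n_self = 0
        n_dup = 0
        for a, b in pairs:
            if a == b:
                n_self += 1
                continue
            e = frozenset((a, b))
            if e in edges:
                n_dup += 1
            else:
                edges.add(e)
        if n_self or n_dup:
            logger.info("network load: removed %d self-edges, collapsed %d duplicates", n_self, n_dup)
        return cls(edges=frozenset(edges))

    def partners(self, gene_id: str) -> frozenset[str]:
        out = set()
        for edge in self.edges:
            if gene_id in edge:
                out.update(edge - {gene_id})
        return frozenset(out)

    @property
    def nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for edge in self.edges:
            out.update(edge)
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def read_assembly(path: str | Path) -> GenomeAssembly:
    """Read a genome assembly table (columns ``chrom``, ``length_bp``, optional ``is_x``)."""
    df = _read_tsv(path, ["chrom", "length_bp"])
    if df.empty:
        raise ValidationError(f"{path}: no chromosomes")
    chroms = []
    x_name = None
    for i, row in df.iterrows():
        name = str(row["chrom"])
        try:
            length = int(row["length_bp"])
        except (TypeError, ValueError):
            raise ValidationError(f"{path} row {i}: bad length_bp {row['length_bp']!r}") from None
        chroms.append((name, length))
        if "is_x" in df.columns and str(row.get("is_x", "0")).strip() in {"1", "true", "True"}:
            if x_name is not None:
                raise ValidationError(f"{path}: more than one chromosome flagged is_x")
            x_name = name
    return GenomeAssembly(chromosomes=tuple(chroms), x_name=x_name)


def read_gene_table(path: str | Path, assembly: GenomeAssembly) -> list[GeneLocus]:
    """Read a gene-locus table (``gene_id``, ``chrom``, ``start``, ``end``; 1-based inclusive)."""
    df = _read_tsv(path, ["gene_id", "chrom", "start", "end"])
    loci = []
    for i, row in df.iterrows():
        chrom = str(row["chrom"])
        if chrom not in assembly:
            raise ValidationError(f"{path} row {i}: chromosome {chrom!r} not in assembly")
        locus = GeneLocus.from_1based(str(row["gene_id"]), chrom, int(row["start"]), int(row["end"]))
        if locus.end0 > assembly.length_of(chrom):
            raise ValidationError(
                f"{path} row {i}: gene {locus.gene_id!r} extends past end of {chrom}"
            )
        loci.append(locus)
    return loci


def read_retrocopy_table(
    path: str | Path, assembly: GenomeAssembly, parents: Mapping[str, GeneLocus]
) -> RetrocopyTable:
    """Read a retrocopy table (``retro_id``, ``parent_id``, ``chrom``, ``start``, ``end``, ``status``).

    Rows with missing identifiers, unknown status, coordinates outside the
    assembly, or a parent absent from the parental table are dropped with a
    logged count — the cleaning step is drop-and-log, never impute.
    """
    df = _read_tsv(path, ["retro_id", "parent_id", "chrom", "start", "end", "status"])
    records: list[RetrocopyRecord] = []
    kept_parents: dict[str, GeneLocus] = {}
    n_dropped = 0
    for i, row in df.iterrows():
        vals = {k: row[k] for k in ("retro_id", "parent_id", "chrom", "start", "end", "status")}
        if any(pd.isna(v) or str(v).strip() == "" for v in vals.values()):
            n_dropped += 1
            continue
        status = str(vals["status"]).strip()
        chrom = str(vals["chrom"])
        parent_id = str(vals["parent_id"])
        if status not in VALID_STATUSES or chrom not in assembly or parent_id not in parents:
            n_dropped += 1
            continue
        try:
            locus = GeneLocus.from_1based(str(vals["retro_id"]), chrom, int(vals["start"]), int(vals["end"]))
        except (ValidationError, ValueError):
            n_dropped += 1
            continue
        if locus.end0 > assembly.length_of(chrom):
            n_dropped += 1
            continue
        records.append(RetrocopyRecord(str(vals["retro_id"]), parent_id, locus, status))
        kept_parents[parent_id] = parents[parent_id]
    if n_dropped:
        logger.info("retrocopy load: dropped %d records with missing/invalid fields", n_dropped)
    if not records:
        logger.warning("retrocopy load: no usable records in %s", path)
    return RetrocopyTable(records=records, parents=kept_parents)


def read_network(path: str | Path) -> RegulatoryNetwork:
    """Read an edge list (columns ``source``, ``target``); direction is discarded."""
    df = _read_tsv(path, ["source", "target"])
    pairs = []
    for i, row in df.iterrows():
        src, tgt = row["source"], row["target"]
        if pd.isna(src) or pd.isna(tgt) or not str(src).strip() or not str(tgt).strip():
            raise ValidationError(f"{path} row {i}: malformed edge ({src!r}, {tgt!r})")
        pairs.append((str(src), str(tgt)))
    return RegulatoryNetwork.from_pairs(pairs)


def read_marey_table(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read raw Marey-map markers (``chrom``, ``marker_id``, ``position_bp``, ``genetic_cM``).

    Returns per-chromosome ``(position_bp, genetic_cM)`` arrays in file order;
    validation and monotone repair live in :mod:`retrolink.genetic_distance`.
    """
    df = _read_tsv(path, ["chrom", "position_bp", "genetic_cM"])
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = (
            sub["position_bp"].astype(np.int64).to_numpy(),
            sub["genetic_cM"].astype(float).to_numpy(),
        )
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_test_result(result, path: str | Path, null_tsv: str | Path | None = None) -> None:
    """Write a finished test result as JSON, optionally dumping the null sample as TSV.

    Refuses non-finite observed values: a NaN statistic means an upstream
    invariant failed, and silently persisting it would hide that.
    """
    if not math.isfinite(result.observed.value):
        raise ValidationError("refusing to write non-finite observed statistic")
    payload = {
        "statistic": result.observed.name,
        "observed": result.observed.value,
        "n_units": result.observed.n_units,
        "p_two_tailed": result.p_two_tailed,
        "alpha": result.alpha,
        "iterations": result.null.iterations,
        "seed": result.null.seed,
        "significant": bool(result.p_two_tailed <= result.alpha),
        "null_mean": float(np.mean(result.null.samples)),
        "null_sd": float(np.std(result.null.samples, ddof=1)) if result.null.iterations > 1 else 0.0,
        "config": dict(result.config),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if null_tsv is not None:
        df = pd.DataFrame({"sample": np.asarray(result.null.samples, dtype=float)})
        df.to_csv(null_tsv, sep="\t", index=False, float_format="%.10g")


def write_assembly(assembly: GenomeAssembly, path: str | Path) -> None:
    lines = ["chrom\tlength_bp\tis_x"]
    for name, length in assembly.chromosomes:
        lines.append(f"{name}\t{length}\t{1 if name == assembly.x_name else 0}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_gene_table(loci: Iterable[GeneLocus], path: str | Path) -> None:
    lines = ["gene_id\tchrom\tstart\tend"]
    for loc in loci:
        lines.append(f"{loc.gene_id}\t{loc.chrom}\t{loc.start0 + 1}\t{loc.end0}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_retrocopy_table(table: RetrocopyTable, path: str | Path) -> None:
    lines = ["retro_id\tparent_id\tchrom\tstart\tend\tstatus"]
    for rec in table.records:
        loc = rec.locus
        lines.append(
            f"{rec.retro_id}\t{rec.parent_id}\t{loc.chrom}\t{loc.start0 + 1}\t{loc.end0}\t{rec.status}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_network(network: RegulatoryNetwork, path: str | Path) -> None:
    lines = ["source\ttarget"]
    for a, b in sorted(tuple(sorted(e)) for e in network.edges):
        lines.append(f"{a}\t{b}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_marey_table(raw: Mapping[str, tuple[np.ndarray, np.ndarray]], path: str | Path) -> None:
    lines = ["chrom\tmarker_id\tposition_bp\tgenetic_cM"]
    for chrom, (bp, cm) in raw.items():
        for k, (p, c) in enumerate(zip(bp, cm)):
            lines.append(f"{chrom}\tm{chrom}_{k}\t{int(p)}\t{c:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
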