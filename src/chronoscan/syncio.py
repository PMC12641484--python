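"""Reading/writing the pool-seq synchronized ("sync") format, gene
annotations and term maps, and the per-site filters of the scan.

The sync dialect is the PoPoolation2 one: one row per site with
``scaffold``, 1-based ``position``, ``ref_base``, then one column per pool
holding six colon-separated counts in the fixed order A:T:C:G:N:deletion.

Positions are 1-based and intervals closed everywhere inside the package;
conversion to 0-based half-open happens only when writing BED.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

#: Fixed nucleotide order of the sync count columns.
NUCLEOTIDES = "ATCG"
SYNC_COLUMNS = "ATCGN*"  # A, T, C, G, N, deletion

#: Tie-break preference for allele ranking: A < T < C < G.
_NUC_RANK = {c: i for i, c in enumerate(NUCLEOTIDES)}


class SyncParseError(ValueError):
    """Raised when a sync/GFF3/TSV line cannot be parsed; names the line."""


@dataclass
class SyncRecord:
    """Per-site, per-pool nucleotide counts — the pipeline's atomic input.

    ``counts`` has shape (n_pools, 6), columns ordered A, T, C, G, N,
    deletion.
    """

    scaffold: str
    position: int
    ref_base: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.counts.ndim != 2 or self.counts.shape[1] != 6:
            raise ValueError("counts must have shape (n_pools, 6)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_pools(self) -> int:
        return self.counts.shape[0]

    def coverage(self, pool: int) -> int:
        """Allele coverage of one pool: A+T+C+G (N and deletions are not
        allele observations)."""
        return int(self.counts[pool, :4].sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyncRecord):
            return NotImplemented
        return (
            self.scaffold == other.scaffold
            and self.position == other.position
            and self.ref_base == other.ref_base
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class FilterSettings:
    """Site filters of the scan.

    min_count
        Minimum minor-allele count *summed over the two compared pools*
        (the PoPoolation2 convention; a per-pool reading would drop
        pool-private variants the exact test needs).
    min_coverage, max_coverage
        Per-pool bounds on allele coverage (A+T+C+G); every compared pool
        must satisfy both. The maximum guards against collapsed repeats.
    """

    min_count: int = 2
    min_coverage: int = 5
    max_coverage: int = 57

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.min_coverage > self.max_coverage:
            raise ValueError("min_coverage must be <= max_coverage")


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval from the annotation (1-based, closed)."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class BiallelicSite:
    """Result of reducing a site to its two top alleles for one pool pair."""

    major: str
    minor: str
    #: 2x2 table: rows = pools, columns = (major, minor) counts.
    table: tuple[tuple[int, int], tuple[int, int]]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sync(path, n_pools: int | None = None) -> list[SyncRecord]:
    """Parse a sync file into :class:`SyncRecord` objects.

    If ``n_pools`` is given, every row must have exactly ``3 + n_pools``
    fields; otherwise the pool count is inferred from the first row and
    enforced on the rest. Malformed rows raise :class:`SyncParseError`
    naming the offending line.
    """
    records: list[SyncRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if n_pools is None:
                n_pools = len(fields) - 3
                if n_pools < 1:
                    raise SyncParseError(
                        f"{path}:{lineno}: expected at least 4 fields, "
                        f"got {len(fields)}"
                    )
            if len(fields) != 3 + n_pools:
                raise SyncParseError(
                    f"{path}:{lineno}: expected {3 + n_pools} fields "
                    f"({n_pools} pools), got {len(fields)}"
                )
            scaffold, pos_s, ref = fields[:3]
            try:
                position = int(pos_s)
            except ValueError:
                raise SyncParseError(
                    f"{path}:{lineno}: non-integer position {pos_s!r}"
                ) from None
            counts = np.empty((n_pools, 6), dtype=np.int64)
            for j, col in enumerate(fields[3:]):
                parts = col.split(":")
                if len(parts) != 6:
                    raise SyncParseError(
                        f"{path}:{lineno}: pool column {j + 1} has "
                        f"{len(parts)} values, expected 6 (A:T:C:G:N:del)"
                    )
                try:
                    counts[j] = [int(x) for x in parts]
                except ValueError:
                    raise SyncParseError(
                        f"{path}:{lineno}: non-integer count in pool "
                        f"column {j + 1}: {col!r}"
                    ) from None
            try:
                records.append(SyncRecord(scaffold, position, ref, counts))
            except ValueError as exc:
                raise SyncParseError(f"{path}:{lineno}: {exc}") from None
    return records


def format_sync_record(record: SyncRecord) -> str:
    cols = [
        ":".join(str(int(c)) for c in record.counts[j])
        for j in range(record.n_pools)
    ]
    return "\t".join(
        [record.scaffold, str(record.position), record.ref_base, *cols]
    )


def write_sync(records: Iterable[SyncRecord], path) -> None:
    """Write records in the sync dialect, one row per site."""
    with _open_text(path, "wt") as fh:
        for record in records:
            fh.write(format_sync_record(record) + "\n")


def reduce_biallelic(
    record: SyncRecord, pools: tuple[int, int] = (0, 1)
) -> BiallelicSite | None:
    """Reduce a site to its top two alleles over one pool pair.

    Alleles are ranked by count summed over the two pools; only A/T/C/G are
    eligible (N and deletions never are). Ties are broken by the fixed
    nucleotide order A < T < C < G. Returns ``None`` (REJECT) when fewer
    than two alleles have nonzero pooled count — such monomorphic sites
    carry no differentiation signal.
    """
    i, j = pools
    pooled = record.counts[i, :4] + record.counts[j, :4]
    # sort by (count desc, nucleotide order asc); stable on the rank key
    order = sorted(range(4), key=lambda a: (-pooled[a], a))
    top, second = order[0], order[1]
    if pooled[second] == 0:
        return None
    major, minor = NUCLEOTIDES[top], NUCLEOTIDES[second]
    table = (
        (int(record.counts[i, top]), int(record.counts[i, second])),
        (int(record.counts[j, top]), int(record.counts[j, second])),
    )
    return BiallelicSite(major=major, minor=minor, table=table)


#: Reasons a site can be dropped, in the order the rules are checked.
DROP_MONOMORPHIC = "monomorphic"
DROP_MIN_COVERAGE = "min_coverage"
DROP_MAX_COVERAGE = "max_coverage"
DROP_MIN_COUNT = "min_count"


def filter_sites(
    records: Sequence[SyncRecord],
    settings: FilterSettings | None = None,
    pools: tuple[int, int] = (0, 1),
) -> tuple[list[tuple[SyncRecord, BiallelicSite]], list[str | None]]:
    """Apply the scan's site filters to one pairwise comparison.

    A site is kept iff it is biallelic over the compared pools, the
    minor-allele count summed across the two pools is >= ``min_count``, and
    every compared pool's allele coverage (A+T+C+G) lies in
    [``min_coverage``, ``max_coverage``].

    Returns the kept ``(record, biallelic_site)`` pairs and a per-input-site
    mask holding ``None`` for kept sites or the first rule that removed the
    site. Kept and dropped sites partition the input.
    """
    if settings is None:
        settings = FilterSettings()
    kept: list[tuple[SyncRecord, BiallelicSite]] = []
    mask: list[str | None] = []
    for record in records:
        covs = [record.coverage(p) for p in pools]
        if any(c < settings.min_coverage for c in covs):
            mask.append(DROP_MIN_COVERAGE)
            continue
        if any(c > settings.max_coverage for c in covs):
            mask.append(DROP_MAX_COVERAGE)
            continue
        bi = reduce_biallelic(record, pools)
        if bi is None:
            mask.append(DROP_MONOMORPHIC)
            continue
        minor_sum = bi.table[0][1] + bi.table[1][1]
        if minor_sum < settings.min_count:
            mask.append(DROP_MIN_COUNT)
            continue
        kept.append((record, bi))
        mask.append(None)
    return kept, mask


def read_gff_genes(path) -> list[GeneFeature]:
    """Read gene features (type ``gene`` only) from a GFF3 file.

    The gene identifier is the ``ID`` attribute (falling back to ``Name``,
    then ``gene_id``). Coordinates are 1-based closed, as in GFF3.
    """
    genes: list[GeneFeature] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise SyncParseError(
                    f"{path}:{lineno}: expected 9 GFF3 fields, "
                    f"got {len(fields)}"
                )
            if fields[2] != "gene":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise SyncParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            attrs = {}
            for item in fields[8].split(";"):
                item = item.strip()
                if "=" in item:
                    key, value = item.split("=", 1)
                    attrs[key] = value
            gene_id = attrs.get("ID") or attrs.get("Name") or attrs.get("gene_id")
            if gene_id is None:
                raise SyncParseError(
                    f"{path}:{lineno}: gene feature without ID attribute"
                )
            try:
                genes.append(
                    GeneFeature(
                        gene_id=gene_id,
                        scaffold=fields[0],
                        start=start,
                        end=end,
                        strand=fields[6],
                    )
                )
            except ValueError as exc:
                raise SyncParseError(f"{path}:{lineno}: {exc}") from None
    return genes


def read_term_map(path) -> dict[str, set[str]]:
    """Read a two-column TSV mapping gene_id -> term_id (many-to-many).

    Duplicate (gene, term) pairs are deduplicated.
    """
    mapping: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise SyncParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            gene, term = fields
            mapping.setdefault(gene, set()).add(term)
    return mapping


def write_bed(intervals, path) -> None:
    """Write (scaffold, start_1based, end_1based, name, score, strand)
    rows as BED6 (0-based half-open conversion at this boundary)."""
    with _open_text(path, "wt") as fh:
        for scaffold, start, end, name, score, strand in intervals:
            fh.write(
                f"{scaffold}\t{start - 1}\t{end}\t{name}\t{score}\t{strand}\n"
            )
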