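"""Reading and writing the genomic/tabular formats the pipeline touches.

Coordinates are 0-based half-open (BED convention) throughout.  A
:class:`CoverageTrack` holds per-chromosome per-base signal depth parsed
from a 4-column bedGraph; positions not covered by any record read as
depth 0.  Chromosome names are matched verbatim ("chr6" and "6" are
different chromosomes); a warning lists names queried but absent from the
track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SERecord",
    "CoverageTrack",
    "BedParseError",
    "BedGraphError",
    "read_se_bed",
    "read_bedgraph",
    "interval_signal",
    "write_enrichment_table",
    "read_enrichment_table",
    "write_bed",
    "write_bedgraph",
]

ENRICHMENT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "se_id",
    "total_signal",
    "binding_density",
    "enriched",
    "rank",
]


class BedParseError(ValueError):
    """A BED line could not be parsed; the message names the line."""


class BedGraphError(ValueError):
    """A bedGraph record is malformed, negative, or overlaps another."""


@dataclass(frozen=True)
class SERecord:
    """A named super-enhancer interval (0-based, half-open).

    ``length_kb`` is ``(end - start) / 1000`` — the divisor used for
    binding density.
    """

    chrom: str
    start: int
    end: int
    se_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise BedParseError(
                f"interval {self.se_id!r} ({self.chrom}:{self.start}-{self.end}) "
                "is empty or inverted (end must exceed start)"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return (self.end - self.start) / 1000.0


@dataclass
class CoverageTrack:
    """Per-chromosome step coverage: sorted non-overlapping [start, end) → depth.

    Internally each chromosome keeps three parallel arrays (starts, ends,
    values).  ``depth(chrom, pos)`` and :func:`interval_signal` expand to
    per-base vectors on demand, so sparse tracks over large coordinates
    stay cheap.
    """

    _chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    _warned_chroms: set[str] = field(default_factory=set, repr=False)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        track = cls()
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            values = np.array([r[2] for r in recs], dtype=np.float64)
            if np.any(ends <= starts):
                bad = int(np.argmax(ends <= starts))
                raise BedGraphError(
                    f"empty or inverted interval on {chrom}: "
                    f"{starts[bad]}-{ends[bad]}"
                )
            if np.any(values < 0):
                raise BedGraphError(f"negative depth on {chrom}")
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                bad = int(np.argmax(starts[1:] < ends[:-1]))
                raise BedGraphError(
                    f"overlapping records on {chrom}: interval ending at "
                    f"{ends[bad]} overlaps interval starting at {starts[bad + 1]}"
                )
            track._chroms[chrom] = (starts, ends, values)
        return track

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._chroms)

    def depth(self, chrom: str, pos: int) -> float:
        """Depth at a single base; 0 for uncovered positions or absent chroms."""
        if chrom not in self._chroms:
            return 0.0
        starts, ends, values = self._chroms[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def region(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depths over [start, end); absent chromosomes give zeros."""
        n = end - start
        if n < 0:
            raise ValueError(f"inverted query {chrom}:{start}-{end}")
        out = np.zeros(n, dtype=np.float64)
        if chrom not in self._chroms:
            if chrom not in self._warned_chroms:
                self._warned_chroms.add(chrom)
                warnings.warn(
                    f"chromosome {chrom!r} not present in coverage track "
                    f"(track has: {', '.join(self.chromosomes) or 'none'}); "
                    "names are matched verbatim",
                    stacklevel=2,
                )
            return out
        starts, ends, values = self._chroms[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            a = max(int(s), start) - start
            b = min(int(e), end) - start
            if b > a:
                out[a:b] = v
        return out

    def iter_steps(self, chrom: str) -> Iterable[tuple[int, int, float]]:
        starts, ends, values = self._chroms.get(
            chrom, (np.empty(0), np.empty(0), np.empty(0))
        )
        for s, e, v in zip(starts, ends, values):
            yield int(s), int(e), float(v)


def read_se_bed(path: str | Path) -> list[SERecord]:
    """Parse a BED3+ file into :class:`SERecord` rows, in file order.

    Lines missing the name column get ``SE_<line#>`` (1-based data-line
    number).  Malformed lines raise :class:`BedParseError` naming the line.
    """
    records: list[SERecord] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}, line {lineno}: expected at least 3 columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}, line {lineno}: non-integer coordinates "
                    f"({fields[1]!r}, {fields[2]!r})"
                ) from exc
            se_id = fields[3] if len(fields) > 3 and fields[3] else f"SE_{lineno}"
            if start >= end:
                raise BedParseError(
                    f"{path}, line {lineno}: start >= end ({start} >= {end})"
                )
            if se_id in seen_ids:
                raise BedParseError(
                    f"{path}, line {lineno}: duplicate interval id {se_id!r}"
                )
            seen_ids.add(se_id)
            records.append(SERecord(chrom, start, end, se_id))
    return records


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Parse a 4-column bedGraph into a :class:`CoverageTrack`.

    Records may be unsorted; overlapping records and negative values are
    errors (overlaps are never silently summed).
    """
    recs: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise BedGraphError(
                    f"{path}, line {lineno}: expected 4 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise BedGraphError(
                    f"{path}, line {lineno}: could not parse coordinates/value"
                ) from exc
            if value < 0:
                raise BedGraphError(
                    f"{path}, line {lineno}: negative value {value}"
                )
            recs.append((fields[0], start, end, value))
    return CoverageTrack.from_records(recs)


def interval_signal(track: CoverageTrack, se: SERecord) -> np.ndarray:
    """Per-base depth vector over ``se``; element i is the depth at start+i.

    Always has length ``end - start``; an SE on a chromosome absent from
    the track gives an all-zero vector (with a one-time warning).
    """
    return track.region(se.chrom, se.start, se.end)


def write_enrichment_table(
    table: pd.DataFrame, path: str | Path
) -> None:
    """Write a classified-SE table as TSV.

    Expects the columns produced by the enrichment pipeline
    (:data:`ENRICHMENT_COLUMNS`); rows are emitted in ascending
    binding-density order with ``se_id`` breaking ties, and ``rank`` is
    re-derived from that order (1 = lowest density).
    """
    missing = [c for c in ENRICHMENT_COLUMNS if c not in table.columns and c != "rank"]
    if missing:
        raise ValueError(f"enrichment table missing columns: {missing}")
    out = table.sort_values(
        ["binding_density", "se_id"], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out = out[ENRICHMENT_COLUMNS]
    # repr-precision floats so a round trip is bit-exact
    out.to_csv(path, sep="\t", index=False, float_format=None)


def read_enrichment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ENRICHMENT_COLUMNS:
        raise ValueError(
            f"{path}: unexpected columns {list(df.columns)}; "
            f"expected {ENRICHMENT_COLUMNS}"
        )
    return df


def write_bed(records: Sequence[SERecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.se_id}\n")


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track back out as bedGraph (sorted, zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            for s, e, v in track.iter_steps(chrom):
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")
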