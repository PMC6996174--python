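"""Core genomic coordinate types.

All coordinates are 0-based, half-open (BED convention). GFF3 input is
converted on read. Every region object in the package — hypersensitive
sites, peaks from other assays, genes, transposable elements, methylated
regions, motif occurrences — is carried by :class:`GenomicInterval` /
:class:`IntervalSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ChromSizes",
    "GenomicInterval",
    "IntervalSet",
    "FragmentRecord",
    "GeneModel",
    "SignalTrack",
]

STRANDS = ("+", "-", ".")


class ChromSizes:
    """Mapping of chromosome name to length in bp."""

    def __init__(self, sizes: Dict[str, int]):
        for name, length in sizes.items():
            if not name:
                raise ValueError("empty chromosome name")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._sizes = dict(sizes)

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromSizes) and self._sizes == other._sizes

    def items(self):
        return self._sizes.items()

    def total_bp(self) -> int:
        return sum(self._sizes.values())

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r})"


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region [start, end) with optional score/label."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap

    def distance_to(self, other: "GenomicInterval") -> Optional[int]:
        """Gap in bp between two intervals; 0 if they overlap, None if trans."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end

    def with_score(self, score: float) -> "GenomicInterval":
        return replace(self, score=score)


class IntervalSet:
    """An ordered, named collection of intervals on a shared genome.

    Backed by column arrays so that million-fragment sets stay cheap;
    :class:`GenomicInterval` objects are materialised lazily on access.
    Intervals are kept sorted by (chrom, start, end).
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        name: str = "",
        genome: Optional[ChromSizes] = None,
    ):
        ivs = list(intervals)
        self._init_from_columns(
            chrom=np.array([iv.chrom for iv in ivs], dtype=object),
            start=np.array([iv.start for iv in ivs], dtype=np.int64),
            end=np.array([iv.end for iv in ivs], dtype=np.int64),
            strand=np.array([iv.strand for iv in ivs], dtype=object),
            score=np.array(
                [np.nan if iv.score is None else float(iv.score) for iv in ivs], dtype=float
            ),
            label=np.array([iv.label for iv in ivs], dtype=object),
            name=name,
            genome=genome,
            validate=False,  # each GenomicInterval validated itself
        )

    @classmethod
    def from_arrays(
        cls,
        chrom: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        strand: Optional[np.ndarray] = None,
        score: Optional[np.ndarray] = None,
        label: Optional[np.ndarray] = None,
        name: str = "",
        genome: Optional[ChromSizes] = None,
    ) -> "IntervalSet":
        obj = cls.__new__(cls)
        n = len(start)
        obj._init_from_columns(
            chrom=np.asarray(chrom, dtype=object),
            start=np.asarray(start, dtype=np.int64),
            end=np.asarray(end, dtype=np.int64),
            strand=np.full(n, ".", dtype=object) if strand is None else np.asarray(strand, dtype=object),
            score=np.full(n, np.nan) if score is None else np.asarray(score, dtype=float),
            label=np.full(n, None, dtype=object) if label is None else np.asarray(label, dtype=object),
            name=name,
            genome=genome,
            validate=True,
        )
        return obj

    def _init_from_columns(self, chrom, start, end, strand, score, label, name, genome, validate):
        self.name = name
        self.genome = genome
        if validate and len(start):
            if np.any(start < 0) or np.any(start >= end):
                raise ValueError("invalid intervals: need 0 <= start < end")
        order = np.lexsort((end, start, chrom))
        self._chrom = chrom[order]
        self._start = start[order]
        self._end = end[order]
        self._strand = strand[order]
        self._score = score[order]
        self._label = label[order]
        self._intervals: Optional[List[GenomicInterval]] = None
        self._by_chrom_cache: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None
        if genome is not None:
            for c in set(self._chrom.tolist()):
                if c not in genome:
                    raise ValueError(f"interval chromosome {c!r} not in genome")

    @property
    def intervals(self) -> List[GenomicInterval]:
        if self._intervals is None:
            self._intervals = [
                GenomicInterval(
                    c, int(s), int(e), str(st),
                    None if np.isnan(sc) else float(sc),
                    lb,
                )
                for c, s, e, st, sc, lb in zip(
                    self._chrom, self._start, self._end, self._strand, self._score, self._label
                )
            ]
        return self._intervals

    def __len__(self) -> int:
        return len(self._start)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def chroms(self) -> List[str]:
        return sorted(set(self._chrom.tolist()))

    def by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start."""
        if self._by_chrom_cache is None:
            out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
            for chrom in self.chroms():
                mask = self._chrom == chrom
                out[chrom] = (self._start[mask], self._end[mask])
            self._by_chrom_cache = out
        return self._by_chrom_cache

    def midpoints(self) -> Dict[str, np.ndarray]:
        return {
            chrom: (starts + ends) // 2 for chrom, (starts, ends) in self.by_chrom().items()
        }

    def total_bp(self) -> int:
        return int((self._end - self._start).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self._chrom,
                "start": self._start,
                "end": self._end,
                "label": self._label,
                "score": self._score,
                "strand": self._strand,
            }
        )

    def __repr__(self) -> str:
        return f"IntervalSet(name={self.name!r}, n={len(self)})"


@dataclass(frozen=True)
class FragmentRecord:
    """A mapped sequencing fragment with alignment-quality metadata.

    ``aligned_fraction`` is the fraction of the read aligned without
    soft/hard clipping; a full-length alignment has 1.0.
    """

    interval: GenomicInterval
    mapq: int = 0
    aligned_fraction: float = 1.0

    def __post_init__(self):
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if not (0.0 <= self.aligned_fraction <= 1.0):
            raise ValueError("aligned_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GeneModel:
    """A gene extent with strand-aware TSS and TTS."""

    interval: GenomicInterval
    gene_id: str

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand != "-" else self.interval.end

    @property
    def tts(self) -> int:
        return self.interval.end if self.interval.strand != "-" else self.interval.start


class SignalTrack:
    """Per-chromosome nonnegative signal at fixed resolution (bp/element)."""

    def __init__(
        self,
        genome: ChromSizes,
        values: Dict[str, np.ndarray],
        resolution: int = 1,
        name: str = "",
    ):
        if resolution < 1:
            raise ValueError("resolution must be >= 1")
        self.genome = genome
        self.resolution = int(resolution)
        self.name = name
        self.values: Dict[str, np.ndarray] = {}
        for chrom in genome:
            n = -(-genome[chrom] // resolution)  # ceil division
            vec = np.asarray(values.get(chrom, np.zeros(n)), dtype=float)
            if len(vec) != n:
                raise ValueError(
                    f"track {name!r} chrom {chrom}: expected {n} elements, got {len(vec)}"
                )
            if np.any(vec < 0):
                raise ValueError(f"track {name!r} chrom {chrom}: negative values")
            self.values[chrom] = vec

    @classmethod
    def zeros(cls, genome: ChromSizes, resolution: int = 1, name: str = "") -> "SignalTrack":
        return cls(genome, {}, resolution=resolution, name=name)

    def per_bp(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Signal expanded to one value per bp over [start, end)."""
        if start < 0 or end > self.genome[chrom]:
            raise IndexError(f"window {chrom}:{start}-{end} outside chromosome")
        r = self.resolution
        if r == 1:
            return self.values[chrom][start:end]
        lo, hi = start // r, -(-end // r)
        expanded = np.repeat(self.values[chrom][lo:hi], r)
        return expanded[start - lo * r : start - lo * r + (end - start)]

    def all_values(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.genome])
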