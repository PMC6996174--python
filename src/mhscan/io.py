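"""Readers and writers for the plain-text genomics formats the toolkit uses.

BED3–BED6 and bedGraph are 0-based half-open; GFF3 is converted from its
1-based inclusive convention on read. A two-column ``chrom.sizes`` TSV
describes the genome, and per-cytosine bisulfite counts come in a
bismark-CX-like TSV dialect (see :func:`read_cx_table`).
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GeneModel, GenomicInterval, IntervalSet, SignalTrack

__all__ = [
    "BedParseError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gff3_genes",
    "read_cx_table",
    "write_cx_table",
    "read_bam_fragments",
]


class BedParseError(ValueError):
    """Malformed line in a BED-like file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def read_chrom_sizes(path) -> ChromSizes:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(path, i, "expected two tab-separated columns")
            sizes[fields[0]] = int(fields[1])
    return ChromSizes(sizes)


def write_chrom_sizes(genome: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(
    path,
    genome: Optional[ChromSizes] = None,
    name: str = "",
    on_unknown_chrom: str = "error",
) -> IntervalSet:
    """Read a BED3–BED6 file into a sorted IntervalSet.

    Columns beyond the third are optional: name, score, strand. Lines on
    chromosomes absent from ``genome`` raise by default; pass
    ``on_unknown_chrom="warn"`` to drop them with a warning.
    """
    if on_unknown_chrom not in ("error", "warn"):
        raise ValueError("on_unknown_chrom must be 'error' or 'warn'")
    intervals: List[GenomicInterval] = []
    n_dropped = 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise BedParseError(path, i, "fewer than 3 columns")
            chrom = f[0]
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise BedParseError(path, i, f"non-integer coordinate: {exc}") from None
            if not (0 <= start < end):
                raise BedParseError(path, i, f"invalid interval {start}-{end}")
            label = f[3] if len(f) > 3 and f[3] != "." else None
            score = None
            if len(f) > 4 and f[4] != ".":
                try:
                    score = float(f[4])
                except ValueError:
                    raise BedParseError(path, i, f"non-numeric score {f[4]!r}") from None
            strand = f[5] if len(f) > 5 else "."
            if strand not in ("+", "-", "."):
                raise BedParseError(path, i, f"invalid strand {strand!r}")
            if genome is not None and chrom not in genome:
                if on_unknown_chrom == "warn":
                    n_dropped += 1
                    continue
                raise BedParseError(path, i, f"chromosome {chrom!r} not in genome")
            intervals.append(GenomicInterval(chrom, start, end, strand, score, label))
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} lines on unknown chromosomes")
    return IntervalSet(intervals, name=name or str(path), genome=genome)


def _fmt_score(score: Optional[float]) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(intervals, path) -> None:
    """Write intervals as BED6 (name/score/strand dotted when absent)."""
    if isinstance(intervals, IntervalSet):
        df = intervals.to_dataframe()
        df["label"] = df["label"].map(lambda x: x if x else ".")
        df["score"] = df["score"].map(lambda s: "." if pd.isna(s) else _fmt_score(s))
        df[["chrom", "start", "end", "label", "score", "strand"]].to_csv(
            path, sep="\t", header=False, index=False
        )
        return
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t"
                f"{_fmt_score(iv.score)}\t{iv.strand}\n"
            )


def read_bedgraph(path, genome: ChromSizes, resolution: int = 1, name: str = "") -> SignalTrack:
    """Read a bedGraph into a fixed-resolution SignalTrack.

    Each bedGraph record's value is painted over the elements its interval
    covers; later records overwrite earlier ones where they overlap.
    """
    values = {c: np.zeros(-(-genome[c] // resolution)) for c in genome}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise BedParseError(path, i, "bedGraph needs 4 columns")
            chrom, start, end, val = f[0], int(f[1]), int(f[2]), float(f[3])
            if chrom not in genome:
                raise BedParseError(path, i, f"chromosome {chrom!r} not in genome")
            values[chrom][start // resolution : -(-end // resolution)] = val
    return SignalTrack(genome, values, resolution=resolution, name=name or str(path))


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a SignalTrack as bedGraph, run-length collapsing equal values."""
    r = track.resolution
    with open(path, "w") as fh:
        for chrom in track.genome:
            vec = track.values[chrom]
            if len(vec) == 0:
                continue
            change = np.nonzero(np.diff(vec))[0]
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [len(vec)]))
            L = track.genome[chrom]
            for s, e in zip(starts, ends):
                v = vec[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s * r}\t{min(e * r, L)}\t{v:g}\n")


def read_gff3_genes(path, genome: Optional[ChromSizes] = None) -> List[GeneModel]:
    """Extract gene features from a GFF3 file (1-based inclusive -> half-open)."""
    genes: List[GeneModel] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise BedParseError(path, i, "GFF3 needs 9 columns")
            if f[2] != "gene":
                continue
            chrom, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
            if strand not in ("+", "-"):
                strand = "."
            gene_id = f"gene_{i}"
            for kv in f[8].split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if genome is not None and chrom not in genome:
                raise BedParseError(path, i, f"chromosome {chrom!r} not in genome")
            genes.append(
                GeneModel(GenomicInterval(chrom, start, end, strand, label=gene_id), gene_id)
            )
    return genes


CX_COLUMNS = ["chrom", "pos", "strand", "count_methylated", "count_unmethylated", "context"]


def read_cx_table(path) -> pd.DataFrame:
    """Read a bismark-CX-like per-cytosine TSV.

    Columns: chrom, pos (1-based in file, converted to 0-based), strand,
    count_methylated, count_unmethylated, context (CG/CHG/CHH).
    """
    df = pd.read_csv(path, sep="\t", header=None, names=CX_COLUMNS, comment="#")
    df["pos"] = df["pos"].astype(np.int64) - 1
    if (df["pos"] < 0).any():
        raise ValueError(f"{path}: positions must be 1-based (found 0)")
    bad = ~df["context"].isin(["CG", "CHG", "CHH"])
    if bad.any():
        raise ValueError(f"{path}: unknown context {df.loc[bad, 'context'].iloc[0]!r}")
    df["count_total"] = df["count_methylated"] + df["count_unmethylated"]
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_cx_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["pos"] = out["pos"] + 1
    out[CX_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bam_fragments(path, genome: Optional[ChromSizes] = None):
    """Yield FragmentRecord from a BAM (optional; requires pysam).

    Single-end reads become their aligned extent; proper pairs become the
    outer template span (emitted once, from read 1).
    """
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("BAM input requires pysam (pip install mhscan[bam])") from exc
    from .intervals import FragmentRecord

    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            chrom = read.reference_name
            if genome is not None and chrom not in genome:
                continue
            if read.is_paired and read.is_proper_pair:
                if read.is_read2 or read.template_length <= 0:
                    continue
                start = read.reference_start
                end = start + read.template_length
            else:
                start, end = read.reference_start, read.reference_end
            clipped = sum(
                n for op, n in (read.cigartuples or []) if op in (4, 5)
            )
            aligned_fraction = 1.0 - clipped / max(read.infer_read_length() or 1, 1)
            yield FragmentRecord(
                GenomicInterval(chrom, start, end), read.mapping_quality, aligned_fraction
            )
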