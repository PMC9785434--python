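"""Core genomic-interval containers and operations.

Every coordinate in this package is 0-based, half-open (BED convention):
an interval covers positions ``start .. end-1`` and its width is
``end - start``.  File formats with other conventions (GFF3) are converted
at the I/O boundary, never internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "PeakSet",
    "GenomeAnnotation",
    "ValidationError",
    "merge",
    "intersect_count",
    "nearest_tss",
    "shuffle_intervals",
]

_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class ValidationError(ValueError):
    """Raised when intervals violate coordinate or chromosome constraints."""


@dataclass(frozen=True)
class GenomicInterval:
    """A single 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """An ordered collection of genomic intervals backed by a DataFrame.

    Parameters
    ----------
    data
        DataFrame with at least ``chrom``, ``start``, ``end`` columns, or an
        iterable of :class:`GenomicInterval` / (chrom, start, end, ...) tuples.
    chrom_sizes
        Optional mapping chrom -> length (bp).  When bound, every interval
        must lie on a known chromosome and within its bounds.
    """

    def __init__(self, data=None, chrom_sizes: Mapping[str, int] | None = None):
        if data is None:
            df = pd.DataFrame({c: [] for c in _COLUMNS})
        elif isinstance(data, pd.DataFrame):
            df = data.copy()
        else:
            rows = []
            for item in data:
                if isinstance(item, GenomicInterval):
                    rows.append(
                        (item.chrom, item.start, item.end, item.name, item.score, item.strand)
                    )
                else:
                    t = tuple(item)
                    rows.append(tuple(list(t) + ["", 0.0, "."][len(t) - 3 :])[:6])
            df = pd.DataFrame(rows, columns=_COLUMNS)
        for col, default in (("name", ""), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        self._df = df
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes is not None else None
        self._validate()

    def _validate(self) -> None:
        df = self._df
        if len(df) == 0:
            return
        bad = df.index[~(df["start"] < df["end"]) | (df["start"] < 0)]
        if len(bad):
            r = df.loc[bad[0]]
            raise ValidationError(
                f"invalid interval {r.chrom}:{r.start}-{r.end}: require 0 <= start < end"
            )
        if self.chrom_sizes is not None:
            known = set(self.chrom_sizes)
            unknown = set(df["chrom"]) - known
            if unknown:
                raise ValidationError(
                    f"chromosome(s) {sorted(unknown)} absent from bound chrom sizes"
                )
            sizes = df["chrom"].map(self.chrom_sizes).to_numpy()
            over = df.index[df["end"].to_numpy() > sizes]
            if len(over):
                r = df.loc[over[0]]
                raise ValidationError(
                    f"interval {r.chrom}:{r.start}-{r.end} exceeds chromosome length"
                )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self):
        for r in self._df.itertuples(index=False):
            yield GenomicInterval(r.chrom, int(r.start), int(r.end), r.name, r.score, r.strand)

    def __getitem__(self, i: int) -> GenomicInterval:
        r = self._df.iloc[i]
        return GenomicInterval(r.chrom, int(r.start), int(r.end), r["name"], r.score, r.strand)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._df.equals(other._df)

    @property
    def df(self) -> pd.DataFrame:
        """The underlying DataFrame (copy-on-write: treat as read-only)."""
        return self._df

    @property
    def widths(self) -> np.ndarray:
        return (self._df["end"] - self._df["start"]).to_numpy()

    @property
    def centers(self) -> np.ndarray:
        return ((self._df["start"] + self._df["end"]) // 2).to_numpy()

    def normalize(self) -> "IntervalSet":
        """Return a copy sorted by (chrom lexicographic, start, end)."""
        df = self._df.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
        return IntervalSet(df, self.chrom_sizes)

    def total_coverage(self) -> int:
        """Number of distinct bases covered (union of intervals)."""
        return int(merge(self).widths.sum())


class PeakSet:
    """Peaks: an IntervalSet plus per-peak summit offsets and sample labels.

    ``summit_offset`` is measured in bp from each peak's start; -1 (or NaN)
    marks an undefined summit, mirroring the narrowPeak sentinel.
    """

    def __init__(
        self,
        intervals: IntervalSet,
        summit_offset: Sequence[int] | None = None,
        sample: str = "",
        group: str = "",
    ):
        self.intervals = intervals
        n = len(intervals)
        if summit_offset is None:
            so = np.full(n, -1, dtype=np.int64)
        else:
            so = np.asarray(summit_offset, dtype=np.int64)
            if so.shape != (n,):
                raise ValidationError("summit_offset length must match peak count")
        w = intervals.widths
        defined = so >= 0
        if np.any(so[defined] >= w[defined]):
            raise ValidationError("summit_offset must satisfy 0 <= offset < width")
        self.summit_offset = so
        self.sample = sample
        self.group = group

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def summits(self) -> np.ndarray:
        """Absolute summit positions; -1 where undefined."""
        s = self.intervals.df["start"].to_numpy() + self.summit_offset
        s[self.summit_offset < 0] = -1
        return s

    @property
    def names(self) -> np.ndarray:
        return self.intervals.df["name"].to_numpy()


@dataclass
class GenomeAnnotation:
    """Gene models over a genome: gene bodies, TSSs, exons and UTRs.

    ``genes`` columns: gene_id, chrom, strand (+/-), start, end, tss.
    The TSS is the strand-aware 5' end: ``start`` for + genes, ``end - 1``
    for - genes.  ``exons`` / ``five_prime_utr`` / ``three_prime_utr`` are
    DataFrames with gene_id, chrom, start, end.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    five_prime_utr: pd.DataFrame
    three_prime_utr: pd.DataFrame
    chrom_sizes: dict = field(default_factory=dict)

    def __post_init__(self):
        g = self.genes
        if len(g):
            plus = g["strand"] == "+"
            expected = np.where(plus, g["start"], g["end"] - 1)
            if not np.array_equal(expected, g["tss"].to_numpy()):
                raise ValidationError("TSS must equal start (+) or end-1 (-) per gene")
            if (~g["strand"].isin(["+", "-"])).any():
                raise ValidationError("gene records require explicit +/- strand")
        self._tss_index: dict | None = None

    def n_genes(self) -> int:
        return len(self.genes)

    def tss_index(self) -> dict:
        """Per-chromosome sorted TSS arrays: chrom -> (positions, gene_ids).

        Positions are deduplicated keeping the lexicographically smallest
        gene id at each coordinate, which implements the nearest-gene
        tie-break deterministically.
        """
        if self._tss_index is None:
            idx = {}
            for chrom, sub in self.genes.sort_values(["tss", "gene_id"]).groupby("chrom"):
                dedup = sub.drop_duplicates(subset="tss", keep="first")
                idx[chrom] = (
                    dedup["tss"].to_numpy(np.int64),
                    dedup["gene_id"].to_numpy(object),
                    dedup["strand"].to_numpy(object),
                )
            self._tss_index = idx
        return self._tss_index


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def merge(intervals: IntervalSet, gap: int = 0) -> IntervalSet:
    """Merge overlapping (and book-ended, when ``gap`` >= 0) intervals.

    Two intervals are merged when ``next.start <= current.end + gap``; at the
    default ``gap=0`` book-ended intervals ([0,10), [10,20)) therefore merge.
    The union of covered bases is preserved.
    """
    if len(intervals) == 0:
        return IntervalSet(None, intervals.chrom_sizes)
    df = intervals.normalize().df
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    out = []
    cur = [chroms[0], starts[0], ends[0]]
    for c, s, e in zip(chroms[1:], starts[1:], ends[1:]):
        if c == cur[0] and s <= cur[2] + gap:
            cur[2] = max(cur[2], e)
        else:
            out.append(tuple(cur))
            cur = [c, s, e]
    out.append(tuple(cur))
    res = pd.DataFrame(out, columns=["chrom", "start", "end"])
    return IntervalSet(res, intervals.chrom_sizes)


def intersect_count(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """For each interval of ``a``, the number of ``b`` intervals overlapping it.

    Overlap means sharing >= 1 base under half-open semantics.
    """
    counts = np.zeros(len(a), dtype=np.int64)
    if len(a) == 0 or len(b) == 0:
        return counts
    bdf = b.df
    by_chrom = {
        c: (np.sort(sub["start"].to_numpy()), np.sort(sub["end"].to_numpy()))
        for c, sub in bdf.groupby("chrom")
    }
    adf = a.df
    for c, sub in adf.groupby("chrom"):
        if c not in by_chrom:
            continue
        bs, be = by_chrom[c]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        # overlapping b = those starting before a ends, minus those ended by a start
        n_started = np.searchsorted(bs, e, side="left")
        n_finished = np.searchsorted(be, s, side="right")
        counts[sub.index.to_numpy()] = n_started - n_finished
    return counts


def nearest_tss(peaks: IntervalSet, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Nearest TSS per peak, by distance from the peak center.

    Returns a DataFrame aligned with ``peaks`` rows: ``gene_id``,
    ``distance`` (signed: TSS - center, sign flipped for - strand genes so
    that positive always means the peak lies upstream of the TSS) and
    ``abs_distance``.  Peaks on chromosomes with no gene get gene_id None
    and NaN distances.
    """
    idx = annotation.tss_index()
    n = len(peaks)
    gene_ids = np.full(n, None, dtype=object)
    dist = np.full(n, np.nan)
    absd = np.full(n, np.nan)
    df = peaks.df
    centers_all = peaks.centers
    for chrom, sub in df.groupby("chrom"):
        if chrom not in idx:
            continue
        pos, gids, strands = idx[chrom]
        centers = centers_all[sub.index.to_numpy()]
        i = np.searchsorted(pos, centers)
        left = np.clip(i - 1, 0, len(pos) - 1)
        right = np.clip(i, 0, len(pos) - 1)
        d_left = np.abs(centers - pos[left])
        d_right = np.abs(pos[right] - centers)
        # no left candidate when i == 0, no right when i == len(pos)
        d_left = np.where(i == 0, np.iinfo(np.int64).max, d_left)
        d_right = np.where(i == len(pos), np.iinfo(np.int64).max, d_right)
        use_left = d_left < d_right
        tie = d_left == d_right
        # ties broken by the lexicographically smaller gene id
        if tie.any():
            lid = gids[left[tie]]
            rid = gids[right[tie]]
            use_left[tie] = lid < rid
        chosen = np.where(use_left, left, right)
        for k, row_i in enumerate(sub.index.to_numpy()):
            j = chosen[k]
            gene_ids[row_i] = gids[j]
            raw = pos[j] - centers[k]
            dist[row_i] = raw if strands[j] == "+" else -raw
            absd[row_i] = abs(raw)
    return pd.DataFrame({"gene_id": gene_ids, "distance": dist, "abs_distance": absd})


def _place_uniform(widths: np.ndarray, chrom_sizes: Mapping[str, int], rng):
    """Uniform random placement of widths over all valid start positions.

    Chromosome chosen with probability proportional to ``size - width + 1``,
    start uniform on ``[0, size - width]``.  Returns (chrom array, starts).
    """
    names = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in names], dtype=np.int64)
    n = len(widths)
    npos = np.maximum(sizes[:, None] - widths[None, :] + 1, 0)  # n_chrom x n
    tot = npos.sum(axis=0)
    if np.any(tot == 0):
        bad = int(np.argmax(tot == 0))
        raise ValidationError(f"interval of width {widths[bad]} exceeds every chromosome")
    cum = np.cumsum(npos / tot[None, :], axis=0)
    cidx = np.minimum(np.sum(cum < rng.random(n)[None, :], axis=0), len(names) - 1)
    starts = (rng.random(n) * npos[cidx, np.arange(n)]).astype(np.int64)
    return np.array(names, dtype=object)[cidx], starts


def shuffle_intervals(
    intervals: IntervalSet,
    chrom_sizes: Mapping[str, int],
    seed,
    same_chrom: bool = False,
) -> IntervalSet:
    """Relocate each interval uniformly at random, preserving its width.

    Placement is uniform over all valid start positions genome-wide: a
    chromosome is chosen with probability proportional to
    ``size - width + 1`` (its number of valid starts for that width) and the
    start is uniform on ``[0, size - width]``.  Shuffled intervals may
    overlap each other.  With ``same_chrom`` each interval stays on its
    source chromosome.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(intervals)
    if n == 0:
        return IntervalSet(None, dict(chrom_sizes))
    w = intervals.widths
    if same_chrom:
        src = intervals.df["chrom"].to_numpy()
        csize = np.array([chrom_sizes[c] for c in src], dtype=np.int64)
        npos = csize - w + 1
        if np.any(npos < 1):
            bad = int(np.argmax(npos < 1))
            raise ValidationError(
                f"interval of width {w[bad]} does not fit on its chromosome"
            )
        starts = rng.integers(0, npos)
        out_chrom = src
    else:
        out_chrom, starts = _place_uniform(w, chrom_sizes, rng)
    res = pd.DataFrame(
        {
            "chrom": out_chrom,
            "start": starts,
            "end": starts + w,
            "name": intervals.df["name"].to_numpy(),
            "score": intervals.df["score"].to_numpy(),
            "strand": intervals.df["strand"].to_numpy(),
        }
    )
    return IntervalSet(res, dict(chrom_sizes))
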