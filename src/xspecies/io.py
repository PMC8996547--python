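"""Readers and writers for the standard formats the pipeline consumes.

Formats: narrowPeak (10-column, summit = start + column-10 offset), a
"bed+summit" dialect (BED6 plus an absolute-summit column), FASTA (random
access via pyfaidx), bedGraph conservation tracks, ortholog-map TSV (the
tabular output of a liftover-style mapper) and divergence-time TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, ValidationError


class ParseError(ValueError):
    pass


def read_peaks(
    path, format: str = "narrowPeak", species: str = "", tissue: str = "", dataset_id: str = ""
) -> list[Peak]:
    """Read peaks with absolute summits from narrowPeak or bed+summit files.

    narrowPeak: 10 columns, the 10th is the summit offset from ``start``
    (-1 means no summit; such peaks default to the interval midpoint).
    bed_summit: BED6 with a 7th column holding the absolute summit position.
    """
    if format not in ("narrowPeak", "bed_summit"):
        raise ValueError(f"unknown peak format {format!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"peak{lineno}"
                if format == "narrowPeak":
                    if len(fields) < 10:
                        raise ParseError("narrowPeak needs 10 columns")
                    offset = int(fields[9])
                    summit = start + offset if offset >= 0 else (start + end) // 2
                else:
                    if len(fields) < 7:
                        raise ParseError("bed_summit needs 7 columns")
                    summit = int(fields[6])
            except (ValueError, IndexError, ParseError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed line ({exc})") from exc
            try:
                peaks.append(
                    Peak(
                        interval=GenomicInterval(species, chrom, start, end),
                        summit=summit,
                        tissue=tissue,
                        dataset_id=dataset_id,
                        name=name,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Iterable[Peak], path, format: str = "narrowPeak") -> None:
    """Write peaks; round-trips coordinates and summits bit-exactly."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak{i + 1}"
            if format == "narrowPeak":
                fh.write(
                    f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{name}"
                    f"\t0\t.\t0\t-1\t-1\t{p.summit - p.interval.start}\n"
                )
            elif format == "bed_summit":
                fh.write(
                    f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{name}"
                    f"\t0\t.\t{p.summit}\n"
                )
            else:
                raise ValueError(f"unknown peak format {format!r}")


def read_bed_intervals(path, species: str = "") -> list[GenomicInterval]:
    """Read plain BED3+ intervals (e.g. exon or TSS annotations)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                out.append(GenomicInterval(species, fields[0], int(fields[1]), int(fields[2])))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED line") from exc
    return out


class GenomeSequences:
    """Random-access genome sequence, from a FASTA file or in-memory dict."""

    def __init__(self, chroms: Mapping[str, str]):
        self._chroms = dict(chroms)

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequences":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=False)
        obj = cls.__new__(cls)
        obj._chroms = None
        obj._fasta = fa
        return obj

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if self._chroms is not None:
            return self._chroms[chrom][start:end]
        return str(self._fasta[chrom][start:end])

    def chrom_size(self, chrom: str) -> int:
        if self._chroms is not None:
            return len(self._chroms[chrom])
        return len(self._fasta[chrom])

    def chrom_names(self) -> list[str]:
        if self._chroms is not None:
            return list(self._chroms)
        return list(self._fasta.keys())


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class ConservationTrack:
    """Per-base conservation scores as interval runs per chromosome.

    Stores (starts, ends, values) arrays per chromosome; uncovered bases are
    treated as missing, and window means average covered bases only.
    """

    score_type: str = "phastcons_like"
    _runs: dict = field(default_factory=dict)

    @classmethod
    def from_arrays(cls, per_chrom: Mapping[str, np.ndarray], score_type: str = "phastcons_like"):
        obj = cls(score_type=score_type)
        for chrom, arr in per_chrom.items():
            arr = np.asarray(arr, dtype=float)
            obj._runs[chrom] = _to_runs(arr)
        return obj

    @classmethod
    def read_bedgraph(cls, path, score_type: str = "phastcons_like"):
        rows: dict[str, list] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                c, s, e, v = line.split()[:4]
                rows.setdefault(c, []).append((int(s), int(e), float(v)))
        obj = cls(score_type=score_type)
        for chrom, triples in rows.items():
            triples.sort()
            starts, ends, vals = (np.array(x) for x in zip(*triples))
            obj._runs[chrom] = (starts.astype(int), ends.astype(int), vals.astype(float))
        return obj

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._runs):
                starts, ends, vals = self._runs[chrom]
                for s, e, v in zip(starts, ends, vals):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")

    def window_mean(self, chrom: str, start: int, end: int) -> tuple[float, float]:
        """(mean over covered bases, covered fraction); mean is NaN if none."""
        runs = self._runs.get(chrom)
        if runs is None:
            return math.nan, 0.0
        starts, ends, vals = runs
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return math.nan, 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        w = np.maximum(e - s, 0)
        covered = int(w.sum())
        if covered == 0:
            return math.nan, 0.0
        mean = float((vals[lo:hi] * w).sum() / covered)
        return mean, covered / (end - start)


def _to_runs(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode a dense per-base array (NaN = uncovered)."""
    n = len(arr)
    if n == 0:
        return np.array([], int), np.array([], int), np.array([], float)
    change = np.flatnonzero(
        np.diff(arr) != 0
    )  # NaN != NaN, so NaN stretches break at every base; drop them below
    bounds = np.concatenate(([0], change + 1, [n]))
    starts, ends, vals = [], [], []
    for s, e in zip(bounds[:-1], bounds[1:]):
        v = arr[s]
        if np.isnan(v):
            continue
        starts.append(int(s))
        ends.append(int(e))
        vals.append(float(v))
    return np.array(starts, int), np.array(ends, int), np.array(vals, float)


@dataclass(frozen=True)
class OrthRecord:
    """One mapped ortholog: target interval plus mapped summit."""

    interval: GenomicInterval
    summit: Optional[int]

    def __post_init__(self) -> None:
        if self.summit is not None and not self.interval.contains(self.summit):
            raise ValidationError(
                f"mapped summit {self.summit} outside {self.interval.chrom}:"
                f"{self.interval.start}-{self.interval.end}"
            )


class OrthologMap:
    """(source species, source peak id) -> per-target-species mapped record.

    The tabular dialect mirrors liftover-style mapper output: one row per
    (source peak, target species) with the target interval and mapped summit
    (empty = summit did not map).  At most one record per target species.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], dict[str, OrthRecord]] = {}

    def add(self, source_species: str, source_id: str, target_species: str, record: OrthRecord):
        per_target = self._entries.setdefault((source_species, source_id), {})
        if target_species in per_target:
            raise ValidationError(
                f"duplicate ortholog record {source_species}/{source_id} -> {target_species}"
            )
        per_target[target_species] = record

    def get(self, source_species: str, source_id: str, target_species: str) -> Optional[OrthRecord]:
        return self._entries.get((source_species, source_id), {}).get(target_species)

    def targets(self, source_species: str, source_id: str) -> dict[str, OrthRecord]:
        return dict(self._entries.get((source_species, source_id), {}))

    def __len__(self) -> int:
        return sum(len(v) for v in self._entries.values())

    HEADER = [
        "source_species",
        "source_id",
        "target_species",
        "target_chrom",
        "target_start",
        "target_end",
        "mapped_summit",
    ]

    @classmethod
    def read_tsv(cls, path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", dtype={"target_chrom": str})
        omap = cls()
        for row in df.itertuples(index=False):
            summit = None if pd.isna(row.mapped_summit) else int(row.mapped_summit)
            omap.add(
                str(row.source_species),
                str(row.source_id),
                str(row.target_species),
                OrthRecord(
                    GenomicInterval(
                        str(row.target_species),
                        str(row.target_chrom),
                        int(row.target_start),
                        int(row.target_end),
                    ),
                    summit,
                ),
            )
        return omap

    def write_tsv(self, path) -> None:
        rows = []
        for (src_sp, src_id), per_target in sorted(self._entries.items()):
            for tgt, rec in sorted(per_target.items()):
                rows.append(
                    (
                        src_sp,
                        src_id,
                        tgt,
                        rec.interval.chrom,
                        rec.interval.start,
                        rec.interval.end,
                        "" if rec.summit is None else rec.summit,
                    )
                )
        pd.DataFrame(rows, columns=self.HEADER).to_csv(path, sep="\t", index=False)


def read_divergence_table(path) -> dict[str, float]:
    """TSV with columns species, mya: divergence times from the reference."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["species"].astype(str), df["mya"].astype(float)))


def write_divergence_table(table: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"species": list(table), "mya": [table[s] for s in table]}
    ).to_csv(path, sep="\t", index=False)
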