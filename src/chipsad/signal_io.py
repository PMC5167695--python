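"""Probe-table I/O, replicate merging, and window-parameter estimation.

The pipeline consumes per-experiment probe tables: tab-separated files with
one row per array probe carrying its genomic placement (replicon, strand,
1-based inclusive start/end) and one or more log2-ratio (M) measurements,
one column per hybridization replicate.  This module reads and writes those
tables, collapses replicates into a single M value per probe, and estimates
the two data-driven segmentation parameters:

* ``w`` — the initial window size, the mean distance between consecutive
  probe starts;
* ``m(w)`` — the minimum number of probes observed in any window of width
  ``w`` anchored at a probe start (floored at 2, the smallest count for
  which a dispersion can be pooled).

All genomic coordinates are 1-based inclusive (GenBank convention)
throughout the package; the BED writer converts at the boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("chipsad")

_FIXED_COLUMNS = ["probe_id", "replicon", "strand", "start", "end"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ProbeMeasurement:
    """A single array probe and its log2-ratio signal."""

    probe_id: str
    replicon: str
    strand: str
    start: int
    end: int
    M: float = math.nan
    replicate_Ms: list[float] | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"probe {self.probe_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"probe {self.probe_id}: bad strand {self.strand!r}")


@dataclass
class ProbeTrack:
    """Ordered probes of one (experiment, replicon, strand) — the signal axis.

    Probes are kept sorted strictly ascending by start; two probes may not
    share an identical (start, end) placement.
    """

    experiment_id: str
    replicon: str
    strand: str
    probes: list[ProbeMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probes = sorted(self.probes, key=lambda p: (p.start, p.end))
        seen: set[tuple[int, int]] = set()
        for p in self.probes:
            key = (p.start, p.end)
            if key in seen:
                raise ValueError(
                    f"duplicate probe placement ({p.start}, {p.end}) in track "
                    f"{self.experiment_id}/{self.replicon}/{self.strand}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def starts(self) -> np.ndarray:
        return np.array([p.start for p in self.probes], dtype=np.int64)

    @property
    def ends(self) -> np.ndarray:
        return np.array([p.end for p in self.probes], dtype=np.int64)

    @property
    def M(self) -> np.ndarray:
        return np.array([p.M for p in self.probes], dtype=float)


# ---------------------------------------------------------------------------
# probe-table reading / writing
# ---------------------------------------------------------------------------

def read_probe_table(path, experiment_id: str | None = None) -> list[ProbeTrack]:
    """Read a tab-separated probe table into one ProbeTrack per replicon/strand.

    The file must carry a header with the fixed columns
    ``probe_id replicon strand start end`` followed by one or more numeric
    M columns.  A single value column named exactly ``M`` is taken as the
    final merged M; any other set of value columns is stored as replicate
    measurements (merge with :func:`merge_replicates`).

    Malformed rows raise ``ValueError`` naming the offending line number.
    Unsorted input is sorted silently; duplicated (start, end) placements
    are an error.
    """
    path = str(path)
    if experiment_id is None:
        experiment_id = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in _FIXED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    value_cols = [c for c in df.columns if c not in _FIXED_COLUMNS]
    if not value_cols:
        raise ValueError(f"{path}: no M value column found")
    single_m = value_cols == ["M"]

    tracks: dict[tuple[str, str], list[ProbeMeasurement]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        rec = dict(zip(df.columns, row))
        try:
            start = int(rec["start"])
            end = int(rec["end"])
        except (TypeError, ValueError):
            raise ValueError(f"{path} line {line_no}: non-integer coordinate")
        ms: list[float] = []
        for c in value_cols:
            raw = rec[c]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
                ms.append(math.nan)
                continue
            try:
                ms.append(float(raw))
            except ValueError:
                raise ValueError(
                    f"{path} line {line_no}: non-numeric M value {raw!r} in column {c!r}"
                )
        strand = str(rec["strand"])
        try:
            probe = ProbeMeasurement(
                probe_id=str(rec["probe_id"]),
                replicon=str(rec["replicon"]),
                strand=strand,
                start=start,
                end=end,
                M=ms[0] if single_m else math.nan,
                replicate_Ms=None if single_m else ms,
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {line_no}: {exc}")
        tracks.setdefault((probe.replicon, strand), []).append(probe)

    return [
        ProbeTrack(experiment_id=experiment_id, replicon=rep, strand=strand, probes=ps)
        for (rep, strand), ps in sorted(tracks.items())
    ]


def write_probe_table(tracks: ProbeTrack | list[ProbeTrack], path) -> None:
    """Write one or more ProbeTracks back to the tab-separated dialect.

    The round trip through :func:`read_probe_table` is lossless: floats are
    serialized with ``repr`` so values survive bit-exactly.
    """
    if isinstance(tracks, ProbeTrack):
        tracks = [tracks]
    n_rep = 0
    for t in tracks:
        for p in t.probes:
            if p.replicate_Ms is not None:
                n_rep = max(n_rep, len(p.replicate_Ms))
    if n_rep:
        value_cols = [f"M_{i + 1}" for i in range(n_rep)]
    else:
        value_cols = ["M"]
    with open(path, "w") as fh:
        fh.write("\t".join(_FIXED_COLUMNS + value_cols) + "\n")
        for t in tracks:
            for p in t.probes:
                vals = p.replicate_Ms if n_rep else [p.M]
                fh.write(
                    "\t".join(
                        [p.probe_id, t.replicon, t.strand, str(p.start), str(p.end)]
                        + [repr(float(v)) for v in vals]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# replicate merging (global normalization + per-probe averaging)
# ---------------------------------------------------------------------------

def merge_replicates(track: ProbeTrack) -> ProbeTrack:
    """Collapse replicate M columns into a single M per probe.

    Global normalization is median-centering: each replicate column has its
    median (over the probes of the track) subtracted, so a constant offset
    in any one hybridization cancels.  The per-probe M is then the
    arithmetic mean of the centered replicate values, ignoring missing
    entries.  Probes whose replicates are all missing are dropped with a
    logged warning.
    """
    if not track.probes:
        return track
    n_rep = max(
        len(p.replicate_Ms) if p.replicate_Ms is not None else 0 for p in track.probes
    )
    if n_rep == 0:
        raise ValueError("track carries no replicate measurements to merge")
    mat = np.full((len(track.probes), n_rep), np.nan)
    for i, p in enumerate(track.probes):
        if p.replicate_Ms is not None:
            mat[i, : len(p.replicate_Ms)] = p.replicate_Ms
    import warnings

    with warnings.catch_warnings():
        # all-NaN columns / rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(mat, axis=0)
        medians = np.where(np.isnan(medians), 0.0, medians)
        merged = np.nanmean(mat - medians, axis=1)

    probes: list[ProbeMeasurement] = []
    for p, m in zip(track.probes, merged):
        if math.isnan(m):
            logger.warning(
                "probe %s (%s:%d-%d) dropped: all replicate values missing",
                p.probe_id, track.replicon, p.start, p.end,
            )
            continue
        probes.append(
            ProbeMeasurement(
                probe_id=p.probe_id,
                replicon=p.replicon,
                strand=p.strand,
                start=p.start,
                end=p.end,
                M=float(m),
                replicate_Ms=p.replicate_Ms,
            )
        )
    return ProbeTrack(track.experiment_id, track.replicon, track.strand, probes)


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

def estimate_window_size(track: ProbeTrack) -> int:
    """Initial window size w: mean distance between consecutive probe starts.

    Rounded up to an integer number of base pairs.  Probe position is the
    probe start, which keeps the estimate independent of probe length.
    """
    if len(track) < 2:
        raise ValueError("window size estimation needs at least 2 probes")
    gaps = np.diff(track.starts)
    return int(math.ceil(float(gaps.mean())))


def estimate_min_probes(track: ProbeTrack, w: int) -> int:
    """m(w): minimum probe count over all width-w windows anchored at probes.

    Windows are half-open ``[x, x + w)`` with the anchor ``x`` placed at each
    probe start, so every window contains at least its own anchor probe.
    Windows truncated by the end of the track (no probe at or beyond the
    window's right edge) are excluded — they undercount by construction.
    The result is floored at 2 because the change-point t-statistic pools a
    dispersion and needs at least two observations per side.
    """
    if w <= 0:
        raise ValueError("w must be positive")
    starts = track.starts
    lo = np.searchsorted(starts, starts, side="left")
    hi = np.searchsorted(starts, starts + w, side="left")
    counts = hi - lo
    complete = hi < len(starts)
    if complete.any():
        counts = counts[complete]
    return max(2, int(counts.min()))


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def _record_fields(rec):
    """Normalize a SignalArea / ConsensusSAS / ClassifiedTranscript for output."""
    cls = None
    flags = ()
    if hasattr(rec, "transcript_class"):  # ClassifiedTranscript
        cls = rec.display_class
        flags = tuple(getattr(rec, "flags", ()))
        rec = rec.sas
    exp = getattr(rec, "experiment_id", None)
    if exp is None:
        exp = "consensus"
    m = getattr(rec, "pseudomedian_M", None)
    if m is None:
        m = getattr(rec, "M", math.nan)
    return {
        "experiment_id": exp,
        "replicon": rec.replicon,
        "strand": rec.strand,
        "start": int(rec.start),
        "end": int(rec.end),
        "pseudomedian_M": float(m),
        "class": cls,
        "flags": ",".join(flags),
    }


def write_transcripts(records, path, format: str = "tsv") -> None:
    """Write signal areas / transcripts as GFF3, BED6 or TSV.

    GFF3 and TSV are 1-based inclusive; BED is converted to 0-based
    half-open.  The BED score is the pseudomedian M scaled by 100 and
    clamped to [0, 1000].
    """
    rows = [_record_fields(r) for r in records]
    if format == "tsv":
        cols = ["experiment_id", "replicon", "strand", "start", "end",
                "pseudomedian_M", "class", "flags"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in rows:
                fh.write(
                    "\t".join(
                        "" if r[c] is None else
                        (repr(r[c]) if c == "pseudomedian_M" else str(r[c]))
                        for c in cols
                    ) + "\n"
                )
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, r in enumerate(rows):
                ftype = r["class"] if r["class"] else "transcript"
                attrs = (
                    f"ID=sas{i + 1};experiment={r['experiment_id']};"
                    f"pseudomedian_M={r['pseudomedian_M']!r}"
                )
                if r["flags"]:
                    attrs += f";flags={r['flags']}"
                fh.write(
                    "\t".join(
                        [r["replicon"], "chipsad", ftype, str(r["start"]),
                         str(r["end"]), f"{r['pseudomedian_M']:.4f}", r["strand"],
                         ".", attrs]
                    ) + "\n"
                )
    elif format == "bed":
        with open(path, "w") as fh:
            for i, r in enumerate(rows):
                score = min(1000, max(0, int(round(r["pseudomedian_M"] * 100))))
                name = r["class"] if r["class"] else f"sas{i + 1}"
                fh.write(
                    "\t".join(
                        [r["replicon"], str(r["start"] - 1), str(r["end"]),
                         name, str(score), r["strand"]]
                    ) + "\n"
                )
    else:
        raise ValueError(f"unknown output format {format!r}")


def read_transcripts(path, format: str = "tsv"):
    """Read signal areas written by :func:`write_transcripts` (tsv or gff3).

    Returns a list of :class:`~chipsad.segmentation.SignalArea`; coordinates
    round-trip exactly.  Probe-level membership is not stored in the flat
    files, so ``probe_Ms`` comes back empty.
    """
    from .segmentation import SignalArea  # local import avoids a cycle

    out = []
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for row in df.itertuples(index=False):
            rec = dict(zip(df.columns, row))
            out.append(
                SignalArea(
                    experiment_id=str(rec["experiment_id"]),
                    replicon=str(rec["replicon"]),
                    strand=str(rec["strand"]),
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    pseudomedian_M=float(rec["pseudomedian_M"]),
                    n_probes=0,
                )
            )
    elif format == "gff3":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                out.append(
                    SignalArea(
                        experiment_id=attrs.get("experiment", "unknown"),
                        replicon=f[0],
                        strand=f[6],
                        start=int(f[3]),
                        end=int(f[4]),
                        pseudomedian_M=float(attrs.get("pseudomedian_M", "nan")),
                        n_probes=0,
                    )
                )
    else:
        raise ValueError(f"unknown input format {format!r}")
    return out
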