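"""Binned depth quantification and copy-number estimation.

Dosage of each amplicon class is measured as mean per-base read depth over
fixed-size bins tiled across the class intervals, normalized against a
single-copy control region:

    raw_cn[c] = reference_copies[c] * depth[c] / depth[control]

Two per-class summary statistics are supported.  MEDIAN_BIN (the median of
per-bin mean depths) is robust to localized artifacts and is the default at
ordinary coverage.  AGGREGATE (total read-bases / total tiled length) is used
at ultra-low coverage, where most bins hold zero or one read and the per-bin
median collapses onto small integers.  Mode auto-selection switches to
AGGREGATE when the control aggregate depth falls below
``AGGREGATE_DEPTH_CUTOFF``.

Because the amplicon copies are near-identical, multi-mapped reads (MAPQ 0)
carry the dosage signal; depth sources should therefore count all primary
alignments regardless of mapping quality.

To counter batch effects and marker-specific multiplicative biases, a cohort
median-centering adjustment rescales each class so that the cohort median
lands on the wild-type copy number.  This assumes carriers are a minority in
every class (<50%), which is checked and warned about.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .errors import (
    CohortTooSmallError,
    DefinitionError,
    DepthSourceError,
    NormalizationError,
)
from .reference import AmpliconClassDef

DEFAULT_BIN_SIZE = 1000
AGGREGATE_DEPTH_CUTOFF = 2.0


class Mode(str, Enum):
    MEDIAN_BIN = "MEDIAN_BIN"
    AGGREGATE = "AGGREGATE"


class CenteringAssumptionWarning(UserWarning):
    """Cohort median of a class is far from its reference copy number.

    Either the marker bias for that class is strong, or carriers are not a
    minority of the batch; centering may be pulling toward the wrong anchor.
    """


@dataclass(frozen=True)
class Bin:
    contig: str
    start: int
    end: int
    class_id: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BinDepthTable:
    """Per-sample mean depth for every bin.

    ``read_count`` (reads assigned per bin) is carried when known — the
    simulator fills it, and binomial downsampling requires it.
    """

    sample_id: str
    bins: list[Bin]
    mean_depth: np.ndarray
    read_count: np.ndarray | None = None
    read_length: float | None = None

    def __post_init__(self) -> None:
        self.mean_depth = np.asarray(self.mean_depth, dtype=float)
        if len(self.mean_depth) != len(self.bins):
            raise ValueError("one depth per bin required")
        if not np.all(np.isfinite(self.mean_depth)) or np.any(self.mean_depth < 0):
            raise ValueError("depths must be finite and non-negative")
        if self.read_count is not None:
            self.read_count = np.asarray(self.read_count)
            if len(self.read_count) != len(self.bins):
                raise ValueError("one read count per bin required")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "contig": [b.contig for b in self.bins],
                "start": [b.start for b in self.bins],
                "end": [b.end for b in self.bins],
                "class_id": [b.class_id for b in self.bins],
                "mean_depth": self.mean_depth,
                "sample_id": self.sample_id,
            }
        )
        if self.read_count is not None:
            df["read_count"] = self.read_count
        return df


def make_bins(
    defs: Sequence[AmpliconClassDef], bin_size: int = DEFAULT_BIN_SIZE
) -> list[Bin]:
    """Tile every class interval left-to-right with fixed-size bins.

    A trailing partial bin is kept iff its length is at least half a bin;
    a class whose intervals produce no bins at all is a definition error.
    """
    if bin_size < 100:
        raise ValueError(f"bin_size must be >= 100 (got {bin_size})")
    bins: list[Bin] = []
    for d in defs:
        n_before = len(bins)
        for contig, start, end in d.intervals:
            pos = start
            while pos + bin_size <= end:
                bins.append(Bin(contig, pos, pos + bin_size, d.class_id))
                pos += bin_size
            rem = end - pos
            if rem > 0 and 2 * rem >= bin_size:
                bins.append(Bin(contig, pos, end, d.class_id))
        if len(bins) == n_before:
            raise DefinitionError(
                f"class {d.class_id!r} produced zero bins at bin_size={bin_size}"
            )
    return bins


@runtime_checkable
class DepthSource(Protocol):
    """Adapter interface for per-base depth extraction (e.g. from BAM/CRAM)."""

    def mean_depth(self, contig: str, start: int, end: int) -> float: ...

    def contigs(self) -> set[str]: ...


def compute_bin_depths(
    depth_source: pd.DataFrame | DepthSource,
    bins: Sequence[Bin],
    sample_id: str = "sample",
) -> BinDepthTable:
    """Mean per-base depth per bin from a per-base table or an adapter.

    A DataFrame source has columns ``contig``, ``pos`` (0-based), ``depth``;
    positions absent from the source count as depth 0.  A contig required by
    the bins but absent entirely from the source is an error.
    """
    if isinstance(depth_source, pd.DataFrame):
        per_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig, sub in depth_source.groupby("contig"):
            pos = sub["pos"].to_numpy(dtype=np.int64)
            dep = sub["depth"].to_numpy(dtype=float)
            order = np.argsort(pos, kind="stable")
            pos, dep = pos[order], dep[order]
            cum = np.concatenate([[0.0], np.cumsum(dep)])
            per_contig[contig] = (pos, cum)
        available = set(per_contig)
        means = np.empty(len(bins))
        for i, b in enumerate(bins):
            if b.contig not in available:
                raise DepthSourceError(
                    f"contig {b.contig!r} required by bins but absent from source"
                )
            pos, cum = per_contig[b.contig]
            i0 = np.searchsorted(pos, b.start, side="left")
            i1 = np.searchsorted(pos, b.end, side="left")
            means[i] = (cum[i1] - cum[i0]) / b.length
        return BinDepthTable(sample_id, list(bins), means)

    available = depth_source.contigs()
    missing = {b.contig for b in bins} - available
    if missing:
        raise DepthSourceError(
            f"contigs required by bins but absent from source: {sorted(missing)}"
        )
    means = np.array([depth_source.mean_depth(b.contig, b.start, b.end) for b in bins])
    return BinDepthTable(sample_id, list(bins), means)


@dataclass(frozen=True)
class ClassStats:
    median_bin_depth: float
    aggregate_depth: float
    n_bins: int
    total_length: int


@dataclass
class ClassDepthSummary:
    sample_id: str
    per_class: dict[str, ClassStats]


def class_indices(bins: Sequence[Bin]) -> dict[str, np.ndarray]:
    """Index arrays into ``bins`` per class (reusable across a cohort)."""
    idx: dict[str, list[int]] = {}
    for i, b in enumerate(bins):
        idx.setdefault(b.class_id, []).append(i)
    return {c: np.asarray(v, dtype=np.intp) for c, v in idx.items()}


def summarize_class_depths(
    t: BinDepthTable, indices: Mapping[str, np.ndarray] | None = None
) -> ClassDepthSummary:
    """Per-class median and aggregate (read-bases / length) depth."""
    if not t.bins:
        raise ValueError("empty depth table")
    if indices is None:
        indices = class_indices(t.bins)
    lengths = np.array([b.length for b in t.bins], dtype=float)
    per_class = {}
    for class_id, idx in indices.items():
        d = t.mean_depth[idx]
        ln = lengths[idx]
        per_class[class_id] = ClassStats(
            median_bin_depth=float(np.median(d)),
            aggregate_depth=float((d * ln).sum() / ln.sum()),
            n_bins=len(idx),
            total_length=int(ln.sum()),
        )
    return ClassDepthSummary(t.sample_id, per_class)


@dataclass
class CopyNumberProfile:
    """Per-class copy-number estimates for one sample.

    ``centered_cn`` is absent until cohort median centering (or explicit
    single-sample mode) has been applied.
    """

    sample_id: str
    raw_cn: dict[str, float]
    control_depth: float
    mode: Mode
    centered_cn: dict[str, float] | None = None
    flags: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = []

    @property
    def values(self) -> dict[str, float]:
        """Centered estimates when available, raw otherwise."""
        return self.centered_cn if self.centered_cn is not None else self.raw_cn


def choose_mode(s: ClassDepthSummary, defs: Sequence[AmpliconClassDef]) -> Mode:
    """AGGREGATE below the ultra-low-coverage cutoff, MEDIAN_BIN otherwise."""
    ctrl = _control_stats(s, defs)
    return Mode.AGGREGATE if ctrl.aggregate_depth < AGGREGATE_DEPTH_CUTOFF else Mode.MEDIAN_BIN


def _control_stats(
    s: ClassDepthSummary, defs: Sequence[AmpliconClassDef]
) -> ClassStats:
    controls = [d for d in defs if d.is_control]
    if not controls:
        raise DefinitionError("definition set has no control class")
    stats = [s.per_class[d.class_id] for d in controls]
    if len(stats) == 1:
        return stats[0]
    # Pool multiple control classes, length- and bin-weighted.
    total_len = sum(st.total_length for st in stats)
    total_bins = sum(st.n_bins for st in stats)
    agg = sum(st.aggregate_depth * st.total_length for st in stats) / total_len
    med = sum(st.median_bin_depth * st.n_bins for st in stats) / total_bins
    return ClassStats(med, agg, total_bins, total_len)


def estimate_copy_numbers(
    s: ClassDepthSummary,
    defs: Sequence[AmpliconClassDef],
    mode: Mode | None = None,
) -> CopyNumberProfile:
    """Scale class depth by the control to estimate copies per class.

    ``mode=None`` auto-selects (see :func:`choose_mode`); the active mode is
    recorded in the profile.
    """
    ctrl = _control_stats(s, defs)
    if mode is None:
        mode = choose_mode(s, defs)
    ctrl_stat = (
        ctrl.median_bin_depth if mode is Mode.MEDIAN_BIN else ctrl.aggregate_depth
    )
    if ctrl_stat <= 0:
        raise NormalizationError(
            f"sample {s.sample_id!r}: control depth is zero in mode {mode.value}; "
            f"sample cannot be normalized"
        )
    raw_cn = {}
    for d in defs:
        if d.is_control:
            continue
        st = s.per_class.get(d.class_id)
        if st is None:
            raise DefinitionError(
                f"class {d.class_id!r} missing from depth summary of "
                f"{s.sample_id!r}"
            )
        stat = st.median_bin_depth if mode is Mode.MEDIAN_BIN else st.aggregate_depth
        raw_cn[d.class_id] = d.reference_copies * stat / ctrl_stat
    return CopyNumberProfile(
        sample_id=s.sample_id,
        raw_cn=raw_cn,
        control_depth=ctrl_stat,
        mode=mode,
    )


def median_center(
    profiles: Sequence[CopyNumberProfile], defs: Sequence[AmpliconClassDef]
) -> list[CopyNumberProfile]:
    """Rescale each class so its cohort median equals the reference copies.

        centered_cn[c] = current_cn[c] * reference_copies[c] / median_s(current_cn[c])

    Operates on the latest estimates (centered if present, raw otherwise),
    so the operation is idempotent.  Classes with cohort median 0 are left
    uncentered and flagged.  Requires a cohort of at least three samples;
    for fewer, use :func:`single_sample_mode`.
    """
    if len(profiles) < 3:
        raise CohortTooSmallError(
            f"median centering needs >= 3 samples (got {len(profiles)}); "
            f"use single_sample_mode() to skip centering explicitly"
        )
    ref = {d.class_id: d.reference_copies for d in defs if not d.is_control}
    classes = set(profiles[0].raw_cn)
    for p in profiles:
        if set(p.raw_cn) != classes:
            raise ValueError("profiles must share an identical class set")
    if classes - set(ref):
        raise ValueError("profile classes not covered by definition set")

    current = np.array([[p.values[c] for c in sorted(classes)] for p in profiles])
    medians = np.median(current, axis=0)
    out = []
    cohort_flags: dict[str, str] = {}
    scale = np.ones_like(medians)
    for j, c in enumerate(sorted(classes)):
        if medians[j] == 0:
            cohort_flags[c] = f"uncentered_zero_median:{c}"
        else:
            scale[j] = ref[c] / medians[j]
            if round(medians[j]) != ref[c]:
                warnings.warn(
                    f"class {c!r}: cohort median {medians[j]:.2f} rounds away "
                    f"from reference copies {ref[c]}; strong marker bias or "
                    f"carrier-majority batch",
                    CenteringAssumptionWarning,
                    stacklevel=2,
                )
    for i, p in enumerate(profiles):
        centered = {
            c: current[i, j] * scale[j] for j, c in enumerate(sorted(classes))
        }
        flags = list(p.flags) + [cohort_flags[c] for c in sorted(cohort_flags)]
        out.append(replace(p, centered_cn=centered, flags=flags))
    return out


def single_sample_mode(p: CopyNumberProfile) -> CopyNumberProfile:
    """Explicitly skip centering: centered = raw, with a provenance flag."""
    return replace(
        p,
        centered_cn=dict(p.raw_cn),
        flags=list(p.flags) + ["uncentered_single_sample"],
    )


# ---------------------------------------------------------------------------
# TSV dialects


def write_depth_table(t: BinDepthTable, path, header: Mapping | None = None) -> None:
    """Write the per-bin depth TSV (``#key=value`` comment header lines)."""
    with open(path, "w") as fh:
        meta = dict(header or {})
        meta.setdefault("sample_id", t.sample_id)
        if t.read_length is not None:
            meta.setdefault("read_length", t.read_length)
        for k, v in meta.items():
            fh.write(f"#{k}={v}\n")
        t.to_frame().to_csv(fh, sep="\t", index=False)


def read_depth_table(path, bins: Sequence[Bin] | None = None) -> BinDepthTable:
    """Read a per-bin depth TSV written by :func:`write_depth_table`."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if "=" in line:
                k, v = line[1:].rstrip("\n").split("=", 1)
                meta[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df else meta.get(
        "sample_id", "sample"
    )
    table_bins = [
        Bin(str(r.contig), int(r.start), int(r.end), str(r.class_id))
        for r in df.itertuples()
    ]
    if bins is not None and list(bins) != table_bins:
        raise ValueError(f"bins in {path} do not match the expected bin set")
    read_count = df["read_count"].to_numpy() if "read_count" in df else None
    read_length = float(meta["read_length"]) if "read_length" in meta else None
    return BinDepthTable(
        sample_id, table_bins, df["mean_depth"].to_numpy(), read_count, read_length
    )


def read_per_base_table(path) -> pd.DataFrame:
    """Read a per-base depth TSV: contig, pos (0-based), depth."""
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["contig", "pos", "depth"],
        dtype={"contig": str, "pos": int, "depth": float},
        header=0,
    )
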