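"""Truth-labeled synthetic WGS bin-depth simulation.

Stands in for restricted population WGS cohorts: per-bin read counts are
Poisson with mean

    lambda = coverage * bin_length / read_length
             * (copies_c / reference_copies_c) * class_bias_c

so a class present at its wild-type copy number has expected mean depth equal
to the nominal haploid coverage, and dosage enters purely through the mean —
consistent with depth-only calling.  Read placement, sequence errors and
mappability are not modeled.  An optional gamma-Poisson ``dispersion`` knob
adds overdispersion when wanted; the default is pure Poisson.

Binomial per-bin thinning (:func:`downsample`) emulates samtools-style read
subsampling: retaining each read independently with probability ``p`` turns a
Poisson(lambda) count into Poisson(p * lambda), which is how an ultra-low
~0.7X dataset is derived from a 7.4X one with ``p=0.1``.

Case-control cohorts draw carrier labels per arm: given a control-arm carrier
frequency ``q`` and an odds ratio ``OR``, the case-arm frequency is

    p1 = OR * q / (1 - q + OR * q).

Seeds are mandatory and echoed into all outputs; identical specs + seeds give
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .depth import Bin, BinDepthTable
from .errors import SimulationError
from .reference import (
    AmpliconClassDef,
    ArchitectureSignature,
    SignatureCatalog,
    SignatureCategory,
    build_catalog,
)

DEFAULT_READ_LENGTH = 150


@dataclass
class SimSampleSpec:
    """One synthetic sample: which architecture, at what coverage."""

    architecture: str
    coverage: float
    seed: int
    read_length: int = DEFAULT_READ_LENGTH
    class_bias: Mapping[str, float] | None = None
    dispersion: float = 0.0  # gamma-Poisson excess dispersion; 0 = pure Poisson

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise SimulationError("coverage must be > 0")
        if self.class_bias:
            if any(b <= 0 for b in self.class_bias.values()):
                raise SimulationError("class biases must be > 0")


@dataclass
class SimCohortSpec:
    """A case-control cohort with a specified carrier-phenotype odds ratio."""

    n_cases: int
    n_controls: int
    carrier_freq_controls: float
    odds_ratio: float
    coverage: float
    seed: int
    other_cnv_freq: float = 0.0
    read_length: int = DEFAULT_READ_LENGTH
    class_bias: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for name, p in (
            ("carrier_freq_controls", self.carrier_freq_controls),
            ("other_cnv_freq", self.other_cnv_freq),
        ):
            if not 0 <= p <= 1:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.odds_ratio <= 0:
            raise SimulationError("odds_ratio must be > 0")
        if self.carrier_freq_case + self.other_cnv_freq > 1:
            raise SimulationError("case-arm frequencies exceed 1; spec infeasible")

    @property
    def carrier_freq_case(self) -> float:
        return case_carrier_freq(self.carrier_freq_controls, self.odds_ratio)


def case_carrier_freq(q: float, odds_ratio: float) -> float:
    """Case-arm carrier frequency implied by control frequency q and an OR."""
    p1 = odds_ratio * q / (1 - q + odds_ratio * q)
    if p1 > 1:
        raise SimulationError("implied case carrier frequency exceeds 1")
    return p1


# Per-bin geometry/class layout is invariant across a cohort; cache it so the
# per-sample expected-count computation is a few vectorized operations.
_BIN_LAYOUT_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, list[str]]] = {}


def _bin_layout(bins: Sequence[Bin]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    key = (id(bins), len(bins))
    cached = _BIN_LAYOUT_CACHE.get(key)
    if cached is None:
        classes = sorted({b.class_id for b in bins})
        index = {c: i for i, c in enumerate(classes)}
        codes = np.array([index[b.class_id] for b in bins], dtype=np.intp)
        lengths = np.array([b.length for b in bins], dtype=float)
        cached = (lengths, codes, classes)
        _BIN_LAYOUT_CACHE[key] = cached
    return cached


def _expected_counts(
    spec: SimSampleSpec,
    defs: Sequence[AmpliconClassDef],
    bins: Sequence[Bin],
    catalog: SignatureCatalog,
) -> np.ndarray:
    try:
        sig = catalog.by_name(spec.architecture)
    except KeyError:
        raise SimulationError(
            f"architecture {spec.architecture!r} not in catalog"
        ) from None
    ref = {d.class_id: d.reference_copies for d in defs}
    bias = dict(spec.class_bias or {})
    lengths, codes, classes = _bin_layout(bins)
    # controls are absent from copy vectors and sit at their reference dosage
    ratio = np.array(
        [sig.copy_vector.get(c, ref[c]) / ref[c] for c in classes]
    )[codes]
    bias_vec = np.array([bias.get(c, 1.0) for c in classes])[codes]
    return spec.coverage * lengths / spec.read_length * ratio * bias_vec


def simulate_depths(
    spec: SimSampleSpec,
    defs: Sequence[AmpliconClassDef],
    bins: Sequence[Bin],
    catalog: SignatureCatalog,
    sample_id: str = "sim",
) -> BinDepthTable:
    """Draw per-bin read counts for one sample and convert to mean depths."""
    lam = _expected_counts(spec, defs, bins, catalog)
    rng = np.random.default_rng(spec.seed)
    if spec.dispersion > 0:
        lam = lam * rng.gamma(1 / spec.dispersion, spec.dispersion, size=lam.shape)
    counts = rng.poisson(lam)
    lengths = np.array([b.length for b in bins], dtype=float)
    depth = counts * spec.read_length / lengths
    return BinDepthTable(
        sample_id, list(bins), depth, read_count=counts, read_length=spec.read_length
    )


def downsample(t: BinDepthTable, p: float, seed: int) -> BinDepthTable:
    """Binomially thin each bin's read count with retention probability p."""
    if not 0 <= p <= 1:
        raise ValueError("retention probability must be in [0, 1]")
    if t.read_count is None or t.read_length is None:
        raise ValueError(
            "downsampling requires per-bin read counts and a read length"
        )
    rng = np.random.default_rng(seed)
    counts = rng.binomial(t.read_count.astype(np.int64), p)
    lengths = np.array([b.length for b in t.bins], dtype=float)
    depth = counts * t.read_length / lengths
    return BinDepthTable(
        t.sample_id, t.bins, depth, read_count=counts, read_length=t.read_length
    )


def simulate_truth_labels(spec: SimCohortSpec) -> pd.DataFrame:
    """Draw per-sample architecture labels for a case-control cohort.

    Returns the truth manifest only (no depths): sample_id, phenotype
    (1=case), architecture category (``grgr``/``other``/``reference``), arm
    frequencies and the child seed each sample's depth simulation would use.
    """
    rng = np.random.default_rng(spec.seed)
    p1 = spec.carrier_freq_case
    n = spec.n_cases + spec.n_controls
    phenotype = np.concatenate(
        [np.ones(spec.n_cases, dtype=int), np.zeros(spec.n_controls, dtype=int)]
    )
    freq = np.where(phenotype == 1, p1, spec.carrier_freq_controls)
    u = rng.random(n)
    v = rng.random(n)
    label = np.where(
        u < freq, "grgr", np.where(v < spec.other_cnv_freq, "other", "reference")
    )
    child_seeds = (
        np.random.SeedSequence(spec.seed).generate_state(n, np.uint64) % (2**31)
    ).astype(np.int64)
    arm = np.where(phenotype == 1, "case", "control")
    within = np.concatenate(
        [np.arange(spec.n_cases), np.arange(spec.n_controls)]
    )
    sample_id = [f"{a}_{j:06d}" for a, j in zip(arm, within)]
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "phenotype": phenotype,
            "arm": arm,
            "label": label,
            "carrier": (label == "grgr").astype(int),
            "arm_carrier_freq": freq,
            "seed": child_seeds,
        }
    )


def _signature_names(catalog: SignatureCatalog) -> dict[str, str]:
    names = {"reference": catalog.reference.name}
    for s in catalog.signatures:
        if s.category is SignatureCategory.GRGR_DEL and "grgr" not in names:
            names["grgr"] = s.name
        if s.category is SignatureCategory.OTHER_CNV and "other" not in names:
            names["other"] = s.name
    return names


def simulate_cohort(
    spec: SimCohortSpec,
    defs: Sequence[AmpliconClassDef],
    bins: Sequence[Bin],
    catalog: SignatureCatalog,
) -> tuple[pd.DataFrame, list[BinDepthTable]]:
    """Labels plus per-sample depth tables for a case-control cohort."""
    names = _signature_names(catalog)
    if "grgr" not in names:
        raise SimulationError("catalog has no GRGR_DEL signature")
    if spec.other_cnv_freq > 0 and "other" not in names:
        raise SimulationError("other_cnv_freq > 0 but catalog has no OTHER_CNV")
    manifest = simulate_truth_labels(spec)
    manifest = manifest.assign(
        architecture=manifest["label"].map(names)
    )
    tables = []
    for row in manifest.itertuples():
        sspec = SimSampleSpec(
            architecture=row.architecture,
            coverage=spec.coverage,
            seed=row.seed,
            read_length=spec.read_length,
            class_bias=spec.class_bias,
        )
        tables.append(
            simulate_depths(sspec, defs, bins, catalog, sample_id=row.sample_id)
        )
    return manifest, tables


def simulate_validation_cohort(
    defs: Sequence[AmpliconClassDef],
    bins: Sequence[Bin],
    catalog: SignatureCatalog,
    n_samples: int,
    n_carriers: int,
    coverage: float,
    seed: int,
    bias_range: tuple[float, float] = (0.8, 1.25),
    read_length: int = DEFAULT_READ_LENGTH,
) -> tuple[pd.DataFrame, list[BinDepthTable]]:
    """Coverage-titration benchmark cohort with an exact carrier count.

    Exactly ``n_carriers`` of ``n_samples`` carry the gr/gr architecture
    (positions randomized), and every class gets a cohort-wide multiplicative
    marker bias drawn log-uniformly from ``bias_range`` — the regime median
    centering exists to correct.  Returns (truth manifest, depth tables).
    """
    if n_carriers > n_samples:
        raise SimulationError("more carriers than samples")
    names = _signature_names(catalog)
    rng = np.random.default_rng(seed)
    lo, hi = bias_range
    classes = sorted({b.class_id for b in bins})
    bias = {
        c: float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for c in classes
    }
    carrier = np.zeros(n_samples, dtype=bool)
    carrier[rng.permutation(n_samples)[:n_carriers]] = True
    child_seeds = np.random.SeedSequence(seed).spawn(n_samples)
    tables, rows = [], []
    for i in range(n_samples):
        arch = names["grgr"] if carrier[i] else names["reference"]
        child = int(child_seeds[i].generate_state(1)[0] % (2**31))
        sspec = SimSampleSpec(
            architecture=arch,
            coverage=coverage,
            seed=child,
            read_length=read_length,
            class_bias=bias,
        )
        sample_id = f"s{i:05d}"
        tables.append(simulate_depths(sspec, defs, bins, catalog, sample_id))
        rows.append(
            {
                "sample_id": sample_id,
                "carrier": int(carrier[i]),
                "architecture": arch,
                "seed": child,
            }
        )
    return pd.DataFrame(rows), tables


def miniature_azfc(
    class_kb: int = 200, control_kb: int = 200
) -> tuple[list[AmpliconClassDef], SignatureCatalog]:
    """A miniature AZFc-style architecture for simulation studies.

    Same class structure and copy numbers as the shipped AZFc definition
    (six amplicon classes + two IRs + a single-copy control) but with one
    compact interval per class, so cohort-scale simulations stay cheap.
    """
    layout = [
        ("ctrl", 1, True),
        ("teal", 2, False),
        ("blue", 4, False),
        ("green", 3, False),
        ("red", 4, False),
        ("gray", 2, False),
        ("yellow", 2, False),
        ("ir1", 2, False),
        ("ir2", 2, False),
    ]
    defs = []
    pos = 1_000_000
    for class_id, copies, is_control in layout:
        size = (control_kb if is_control else class_kb) * 1000
        defs.append(
            AmpliconClassDef(
                class_id=class_id,
                reference_copies=copies,
                intervals=((f"chrY", pos, pos + size),),
                is_control=is_control,
            )
        )
        pos += size + 50_000
    ref_vec = {d.class_id: d.reference_copies for d in defs if not d.is_control}
    grgr = dict(ref_vec, green=2, red=2)
    b2b3 = dict(ref_vec, blue=3, green=2, red=2)
    dup = dict(ref_vec, green=4, red=6)
    catalog = build_catalog(
        defs,
        [
            ArchitectureSignature("reference", ref_vec, SignatureCategory.REFERENCE),
            ArchitectureSignature("grgr_deletion", grgr, SignatureCategory.GRGR_DEL),
            ArchitectureSignature("b2b3_deletion", b2b3, SignatureCategory.OTHER_CNV),
            ArchitectureSignature("grgr_duplication", dup, SignatureCategory.OTHER_CNV),
        ],
    )
    return defs, catalog


def write_manifest(manifest: pd.DataFrame, path, header: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"#{k}={v}\n")
        manifest.to_csv(fh, sep="\t", index=False)
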