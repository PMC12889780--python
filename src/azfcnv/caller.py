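"""Signature-match calling of AZFc CNVs from copy-number profiles.

Centered per-class estimates are rounded to the nearest integer and looked
up in the signature catalog by exact match.  A match to the gr/gr signature
yields GRGR_POSITIVE; a match to the wild-type architecture yields
GRGR_NEGATIVE; any other vector — whether it matches a rarer cataloged CNV
or nothing at all — is OTHER_AZFC_CNV and excluded from association testing.
Samples that cannot be normalized (zero control depth) surface as
CALL_FAILED rather than as exceptions at cohort level.

The exact-match criterion is deliberate: near-misses are not force-assigned
to the closest signature, which is conservative for association since
unmatched samples are excluded anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .depth import (
    BinDepthTable,
    CopyNumberProfile,
    Mode,
    class_indices,
    estimate_copy_numbers,
    median_center,
    single_sample_mode,
    summarize_class_depths,
)
from .errors import ManifestMismatchError, NormalizationError
from .reference import AmpliconClassDef, SignatureCatalog, SignatureCategory, lookup_signature


class CallStatus(str, Enum):
    GRGR_POSITIVE = "GRGR_POSITIVE"
    GRGR_NEGATIVE = "GRGR_NEGATIVE"
    OTHER_AZFC_CNV = "OTHER_AZFC_CNV"
    CALL_FAILED = "CALL_FAILED"


_CATEGORY_TO_STATUS = {
    SignatureCategory.GRGR_DEL: CallStatus.GRGR_POSITIVE,
    SignatureCategory.REFERENCE: CallStatus.GRGR_NEGATIVE,
    SignatureCategory.OTHER_CNV: CallStatus.OTHER_AZFC_CNV,
}


@dataclass
class CallResult:
    sample_id: str
    status: CallStatus
    matched_signature: str | None
    rounded_vector: dict[str, int] | None
    raw_vector: dict[str, float] | None
    mode: Mode | None
    flags: list[str] = field(default_factory=list)


def round_profile(p: CopyNumberProfile) -> dict[str, int]:
    """Nearest-integer copies per class; halves round away from zero, floor 0."""
    return {c: max(0, math.floor(v + 0.5)) for c, v in p.values.items()}


def call_sample(p: CopyNumberProfile, catalog: SignatureCatalog) -> CallResult:
    """Match one profile's rounded copy vector against the catalog."""
    rounded = round_profile(p)
    sig = lookup_signature(catalog, rounded)
    if sig is None:
        status, name = CallStatus.OTHER_AZFC_CNV, None
    else:
        status, name = _CATEGORY_TO_STATUS[sig.category], sig.name
    return CallResult(
        sample_id=p.sample_id,
        status=status,
        matched_signature=name,
        rounded_vector=rounded,
        raw_vector=dict(p.values),
        mode=p.mode,
        flags=list(p.flags),
    )


def call_cohort(
    profiles: Sequence[CopyNumberProfile], catalog: SignatureCatalog
) -> list[CallResult]:
    """Call every profile of a (median-centered) batch, order preserved."""
    return [call_sample(p, catalog) for p in profiles]


def run_calling_pipeline(
    tables: Sequence[BinDepthTable],
    defs: Sequence[AmpliconClassDef],
    catalog: SignatureCatalog,
    mode: Mode | None = None,
    center: bool = True,
) -> list[CallResult]:
    """Depth tables -> summaries -> copy numbers -> centering -> calls.

    Samples failing normalization become CALL_FAILED results and are held out
    of the centering cohort; everything else proceeds normally.  With fewer
    than three normalizable samples (or ``center=False``), centering is
    skipped explicitly via single-sample mode.
    """
    if not tables:
        return []
    indices = class_indices(tables[0].bins)
    profiles: list[CopyNumberProfile] = []
    failed: dict[int, CallResult] = {}
    for i, t in enumerate(tables):
        try:
            summary = summarize_class_depths(t, indices)
            profiles.append(estimate_copy_numbers(summary, defs, mode))
        except NormalizationError as exc:
            failed[i] = CallResult(
                sample_id=t.sample_id,
                status=CallStatus.CALL_FAILED,
                matched_signature=None,
                rounded_vector=None,
                raw_vector=None,
                mode=mode,
                flags=[f"normalization_failed: {exc}"],
            )
            profiles.append(None)  # placeholder keeps order

    ok = [p for p in profiles if p is not None]
    if center and len(ok) >= 3:
        centered = iter(median_center(ok, defs))
    else:
        centered = iter(single_sample_mode(p) for p in ok)

    results = []
    for i, p in enumerate(profiles):
        if p is None:
            results.append(failed[i])
        else:
            results.append(call_sample(next(centered), catalog))
    return results


def filter_for_association(
    calls: Sequence[CallResult],
    manifest: pd.DataFrame,
    spermatocytic_label: str = "spermatocytic seminoma",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Build the association table, excluding non-gr/gr CNVs and failures.

    Retains only GRGR_POSITIVE (carrier=1) and GRGR_NEGATIVE (carrier=0)
    samples; OTHER_AZFC_CNV carriers are excluded to avoid confounding by
    rarer CNV types, and CALL_FAILED samples cannot be scored.  Exclusion
    counts are reported alongside the table.

    The manifest must have a ``sample_id`` column plus ``phenotype`` and any
    ``histology``/covariate columns, and must cover every called sample.
    Samples labeled as spermatocytic seminoma are retained in the overall
    table but flagged ``histology_eval=False`` so histology-stratified
    analyses can drop them.
    """
    ids = [c.sample_id for c in calls]
    manifest_ids = set(manifest["sample_id"])
    missing = [s for s in ids if s not in manifest_ids]
    if missing:
        raise ManifestMismatchError(
            f"samples called but absent from manifest: {missing[:20]}"
            + ("..." if len(missing) > 20 else "")
        )
    if manifest["sample_id"].duplicated().any():
        dupes = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"]
        raise ManifestMismatchError(f"duplicate manifest ids: {sorted(set(dupes))[:20]}")

    exclusions = {
        CallStatus.OTHER_AZFC_CNV.value: 0,
        CallStatus.CALL_FAILED.value: 0,
    }
    keep: dict[str, int] = {}
    for c in calls:
        if c.status is CallStatus.GRGR_POSITIVE:
            keep[c.sample_id] = 1
        elif c.status is CallStatus.GRGR_NEGATIVE:
            keep[c.sample_id] = 0
        else:
            exclusions[c.status.value] += 1

    table = manifest[manifest["sample_id"].isin(keep)].copy()
    table["carrier"] = table["sample_id"].map(keep)
    if "histology" in table.columns:
        table["histology_eval"] = table["histology"] != spermatocytic_label
    # carrier first among the analysis columns, sample order as called
    order = {s: i for i, s in enumerate(ids)}
    table = table.sort_values("sample_id", key=lambda s: s.map(order))
    table = table.reset_index(drop=True)
    return table, exclusions


def calls_to_frame(calls: Sequence[CallResult]) -> pd.DataFrame:
    """Flatten calls into the documented TSV shape (one row per sample)."""
    classes = sorted(
        {c for r in calls if r.rounded_vector for c in r.rounded_vector}
    )
    rows = []
    for r in calls:
        row = {
            "sample_id": r.sample_id,
            "status": r.status.value,
            "matched_signature": r.matched_signature or "",
            "mode": r.mode.value if r.mode else "",
            "flags": ";".join(r.flags),
        }
        for c in classes:
            row[f"cn_{c}"] = r.rounded_vector.get(c) if r.rounded_vector else ""
            row[f"raw_{c}"] = (
                round(r.raw_vector.get(c), 4) if r.raw_vector else ""
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_calls_tsv(
    calls: Sequence[CallResult], path, header: Mapping | None = None
) -> None:
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"#{k}={v}\n")
        calls_to_frame(calls).to_csv(fh, sep="\t", index=False)
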