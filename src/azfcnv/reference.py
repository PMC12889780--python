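"""Ampliconic architecture definitions and the CNV signature catalog.

The AZFc region of the human Y chromosome is built from families of long,
near-identical repeats ("amplicon classes", conventionally named for colors),
plus inverted-repeat (IR) elements.  Each class has a fixed copy number in the
wild-type architecture; structural variants arising by non-allelic homologous
recombination change those copy numbers in characteristic ways.  A *signature*
is the integer copy-number vector over the non-control classes that a given
architecture produces; the gr/gr deletion, for example, removes one green and
two red amplicon copies while leaving the remaining classes untouched.

This module holds the machinery for loading and validating a definition set
(BED intervals + a YAML config of reference copy numbers and signatures) and
for exact lookup of observed integer vectors in the catalog.  IR elements are
modeled as ordinary classes: their dosage is quantified through the same
mechanism as the amplicon classes.

Coordinates are 0-based, half-open (BED convention) throughout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import (
    DefinitionError,
    DuplicateSignatureError,
    IntervalOverlapError,
    MissingControlClassError,
    SignatureKeyMismatchError,
    UnknownClassError,
)

Interval = tuple[str, int, int]


class SignatureCategory(str, Enum):
    REFERENCE = "REFERENCE"
    GRGR_DEL = "GRGR_DEL"
    OTHER_CNV = "OTHER_CNV"


@dataclass(frozen=True)
class AmpliconClassDef:
    """One repeat class: its label, wild-type copy number and genomic intervals.

    ``is_control`` marks single-copy regions used solely for depth
    normalization; control classes never appear in signature copy vectors.
    """

    class_id: str
    reference_copies: int
    intervals: tuple[Interval, ...]
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.reference_copies < 1:
            raise DefinitionError(
                f"class {self.class_id!r}: reference_copies must be >= 1"
            )
        if not self.intervals:
            raise DefinitionError(f"class {self.class_id!r}: no intervals")
        for contig, start, end in self.intervals:
            if end <= start:
                raise DefinitionError(
                    f"class {self.class_id!r}: empty interval {contig}:{start}-{end}"
                )
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in self.intervals:
            by_contig.setdefault(contig, []).append((start, end))
        for contig, ivs in by_contig.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise IntervalOverlapError(
                        f"class {self.class_id!r}: intervals overlap on {contig} "
                        f"({s1}-{e1} vs {s2}-{e2})"
                    )

    @property
    def total_length(self) -> int:
        return sum(end - start for _, start, end in self.intervals)


@dataclass(frozen=True)
class ArchitectureSignature:
    """A named architecture and its expected integer copy-number vector."""

    name: str
    copy_vector: Mapping[str, int]
    category: SignatureCategory

    def __post_init__(self) -> None:
        object.__setattr__(self, "copy_vector", dict(self.copy_vector))
        for class_id, copies in self.copy_vector.items():
            if int(copies) != copies or copies < 0:
                raise DefinitionError(
                    f"signature {self.name!r}: copy number for {class_id!r} "
                    f"must be a non-negative integer"
                )

    def vector_key(self) -> tuple[tuple[str, int], ...]:
        return tuple(sorted((k, int(v)) for k, v in self.copy_vector.items()))


@dataclass
class SignatureCatalog:
    """The set of recognized architectures, bound to one definition set."""

    signatures: list[ArchitectureSignature]
    definition_checksum: str

    _by_vector: dict[tuple[tuple[str, int], ...], ArchitectureSignature] = field(
        init=False, repr=False
    )

    def __post_init__(self) -> None:
        self._by_vector = {}
        for sig in self.signatures:
            key = sig.vector_key()
            if key in self._by_vector:
                raise DuplicateSignatureError(
                    f"signatures {self._by_vector[key].name!r} and {sig.name!r} "
                    f"share a copy vector; matching would be ambiguous"
                )
            self._by_vector[key] = sig
        n_ref = sum(
            1 for s in self.signatures if s.category is SignatureCategory.REFERENCE
        )
        if n_ref != 1:
            raise DefinitionError(
                f"catalog must contain exactly one REFERENCE signature (found {n_ref})"
            )

    @property
    def reference(self) -> ArchitectureSignature:
        return next(
            s for s in self.signatures if s.category is SignatureCategory.REFERENCE
        )

    @property
    def class_ids(self) -> frozenset[str]:
        return frozenset(self.reference.copy_vector)

    def by_name(self, name: str) -> ArchitectureSignature:
        for s in self.signatures:
            if s.name == name:
                return s
        raise KeyError(name)


def definition_checksum(defs: Sequence[AmpliconClassDef]) -> str:
    """Stable identifier of a definition set (order-insensitive)."""
    payload = sorted(
        (d.class_id, d.reference_copies, d.is_control, sorted(d.intervals))
        for d in defs
    )
    digest = hashlib.sha256(json.dumps(payload).encode()).hexdigest()
    return digest[:12]


def _validate(
    defs: Sequence[AmpliconClassDef], signatures: Sequence[ArchitectureSignature]
) -> SignatureCatalog:
    if not any(d.is_control for d in defs):
        raise MissingControlClassError(
            "definition set has no class with is_control: true"
        )
    seen: set[str] = set()
    for d in defs:
        if d.class_id in seen:
            raise DefinitionError(f"duplicate class id {d.class_id!r}")
        seen.add(d.class_id)

    catalog = SignatureCatalog(list(signatures), definition_checksum(defs))

    noncontrol = {d.class_id for d in defs if not d.is_control}
    ref_copies = {d.class_id: d.reference_copies for d in defs if not d.is_control}
    for sig in catalog.signatures:
        keys = set(sig.copy_vector)
        if keys != noncontrol:
            raise SignatureKeyMismatchError(
                f"signature {sig.name!r}: copy vector keys {sorted(keys)} do not "
                f"match non-control classes {sorted(noncontrol)}"
            )
    ref_sig = catalog.reference
    if {k: int(v) for k, v in ref_sig.copy_vector.items()} != ref_copies:
        raise DefinitionError(
            f"REFERENCE signature {ref_sig.name!r} does not equal the classes' "
            f"reference_copies"
        )
    return catalog


def load_definitions(
    bed_path, config_path
) -> tuple[list[AmpliconClassDef], SignatureCatalog]:
    """Load and validate a definition set and signature catalog.

    ``bed_path``: tab-separated BED, columns contig/start/end/class_id
    (0-based half-open).  ``config_path``: YAML with ``classes`` (mapping
    class_id -> {reference_copies, is_control}) and ``signatures`` (list of
    {name, category, copy_vector}).
    """
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["contig", "start", "end", "class_id"],
        dtype={"contig": str, "start": int, "end": int, "class_id": str},
    )
    with open(config_path) as fh:
        config = yaml.safe_load(fh)

    classes_cfg: Mapping[str, Mapping] = config.get("classes", {})
    bed_classes = set(bed["class_id"])
    missing = bed_classes - set(classes_cfg)
    if missing:
        raise UnknownClassError(
            f"classes in BED but not in config: {sorted(missing)}"
        )
    no_intervals = set(classes_cfg) - bed_classes
    if no_intervals:
        raise UnknownClassError(
            f"classes in config with no BED intervals: {sorted(no_intervals)}"
        )

    defs = []
    for class_id, cfg in classes_cfg.items():
        sub = bed[bed["class_id"] == class_id]
        intervals = tuple(
            (row.contig, int(row.start), int(row.end)) for row in sub.itertuples()
        )
        defs.append(
            AmpliconClassDef(
                class_id=class_id,
                reference_copies=int(cfg["reference_copies"]),
                intervals=intervals,
                is_control=bool(cfg.get("is_control", False)),
            )
        )

    signatures = [
        ArchitectureSignature(
            name=entry["name"],
            copy_vector={k: int(v) for k, v in entry["copy_vector"].items()},
            category=SignatureCategory(entry["category"]),
        )
        for entry in config.get("signatures", [])
    ]
    catalog = _validate(defs, signatures)
    return defs, catalog


def build_catalog(
    defs: Sequence[AmpliconClassDef], signatures: Iterable[ArchitectureSignature]
) -> SignatureCatalog:
    """Validate an in-memory definition set + signatures into a catalog."""
    return _validate(list(defs), list(signatures))


def save_definitions(
    defs: Sequence[AmpliconClassDef],
    catalog: SignatureCatalog,
    bed_path,
    config_path,
) -> None:
    """Write a definition set and catalog back to BED + YAML (round-trippable)."""
    rows = [
        (contig, start, end, d.class_id)
        for d in defs
        for contig, start, end in d.intervals
    ]
    pd.DataFrame(rows, columns=["contig", "start", "end", "class_id"]).to_csv(
        bed_path, sep="\t", header=False, index=False
    )
    config = {
        "classes": {
            d.class_id: {
                "reference_copies": d.reference_copies,
                "is_control": d.is_control,
            }
            for d in defs
        },
        "signatures": [
            {
                "name": s.name,
                "category": s.category.value,
                "copy_vector": {k: int(v) for k, v in s.copy_vector.items()},
            }
            for s in catalog.signatures
        ],
    }
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def lookup_signature(
    catalog: SignatureCatalog, vector: Mapping[str, int]
) -> ArchitectureSignature | None:
    """Exact-match lookup of an integer copy vector in the catalog.

    Returns the unique signature whose copy vector equals ``vector``, or
    ``None`` if no catalog entry matches.  The query must cover exactly the
    catalog's class set.
    """
    if set(vector) != catalog.class_ids:
        raise SignatureKeyMismatchError(
            f"query classes {sorted(vector)} do not match catalog classes "
            f"{sorted(catalog.class_ids)}"
        )
    key = tuple(sorted((k, int(v)) for k, v in vector.items()))
    return catalog._by_vector.get(key)


def default_definitions() -> tuple[list[AmpliconClassDef], SignatureCatalog]:
    """Load the packaged AZFc architecture (six amplicon classes, two IRs,
    one single-copy control) and its signature catalog.

    The copy vectors are editable configuration shipped as data files, not
    code; see ``azfcnv/data/azfc_signatures.yaml``.
    """
    data = resources.files("azfcnv.data")
    with resources.as_file(data / "azfc_amplicons.bed") as bed_path, resources.as_file(
        data / "azfc_signatures.yaml"
    ) as cfg_path:
        return load_definitions(bed_path, cfg_path)
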