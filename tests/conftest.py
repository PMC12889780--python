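import numpy as np
import pytest

from azfcnv import (
    AmpliconClassDef,
    ArchitectureSignature,
    SignatureCategory,
    build_catalog,
    make_bins,
    miniature_azfc,
)


@pytest.fixture
def toy():
    """Three-class toy architecture: control x1, green x3, red x4."""
    defs = [
        AmpliconClassDef("ctrl", 1, (("chrY", 0, 100_000),), is_control=True),
        AmpliconClassDef("green", 3, (("chrY", 200_000, 300_000),)),
        AmpliconClassDef("red", 4, (("chrY", 400_000, 500_000),)),
    ]
    catalog = build_catalog(
        defs,
        [
            ArchitectureSignature(
                "reference", {"green": 3, "red": 4}, SignatureCategory.REFERENCE
            ),
            ArchitectureSignature(
                "grgr_deletion", {"green": 2, "red": 2}, SignatureCategory.GRGR_DEL
            ),
            ArchitectureSignature(
                "grgr_duplication", {"green": 4, "red": 6}, SignatureCategory.OTHER_CNV
            ),
        ],
    )
    return defs, catalog


@pytest.fixture(scope="session")
def mini():
    """Miniature AZFc-style architecture plus its fixed-size bins."""
    defs, catalog = miniature_azfc()
    bins = make_bins(defs, 1000)
    return defs, catalog, bins


def make_profile(raw, mode=None, sample_id="s", centered=None):
    from azfcnv.depth import CopyNumberProfile, Mode

    return CopyNumberProfile(
        sample_id=sample_id,
        raw_cn=dict(raw),
        control_depth=1.0,
        mode=mode or Mode.MEDIAN_BIN,
        centered_cn=dict(centered) if centered is not None else None,
    )
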