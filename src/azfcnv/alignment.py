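"""Thin alignment-file adapter implementing the :class:`~azfcnv.depth.DepthSource`
protocol on top of pysam.

Kept in its own module so the core library (and the test suite) never needs
alignment files or the pysam dependency.  All primary alignments are counted
regardless of mapping quality: the amplicon copies are near-identical, so
multi-mapped (MAPQ 0) reads carry the dosage signal and excluding them would
null the method.
"""

from __future__ import annotations


class AlignmentDepthSource:
    """Per-region mean depth from an indexed BAM/CRAM file."""

    def __init__(self, path: str, reference: str | None = None) -> None:
        import pysam  # deferred: optional dependency

        self._af = pysam.AlignmentFile(path, reference_filename=reference)

    def contigs(self) -> set[str]:
        return set(self._af.references)

    def mean_depth(self, contig: str, start: int, end: int) -> float:
        cov = self._af.count_coverage(
            contig,
            start,
            end,
            quality_threshold=0,
            read_callback=lambda r: not (
                r.is_secondary or r.is_supplementary or r.is_unmapped
            ),
        )
        total = sum(sum(track) for track in cov)
        return total / (end - start)

    def close(self) -> None:
        self._af.close()

    def __enter__(self) -> "AlignmentDepthSource":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
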