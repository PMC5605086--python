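"""Optional adapter: per-base depth from indexed BAM files via pysam.

The study design slices pre-mapped reads over the 45S-bearing scaffold
(GL000220.1) and the 1q42 window around the 5S array
(chr1:228,743,523-228,781,906) rather than re-mapping raw reads.  This
adapter extracts per-base depth over such configured intervals so real BAMs
can feed the same estimator as the synthetic depth tables.  pysam is only
imported here; no other part of the package needs it.
"""

from __future__ import annotations

import numpy as np

#: default slicing intervals, 1-based inclusive
DEFAULT_INTERVALS = {
    "45S": ("GL000220.1", None, None),  # whole scaffold
    "5S_1q42": ("1", 228_743_523, 228_781_906),
}


def depth_from_bam(bam_path, intervals: dict | None = None) -> dict:
    """Per-base depth arrays over named intervals of an indexed BAM.

    ``intervals`` maps output name -> (reference, start, end) with 1-based
    inclusive coordinates (start/end of ``None`` meaning the full reference).
    Returns {name -> numpy array of depth, position 1 = interval start}.
    """
    import pysam  # optional dependency

    intervals = DEFAULT_INTERVALS if intervals is None else intervals
    out = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for name, (ref, start, end) in intervals.items():
            if start is None or end is None:
                length = bam.get_reference_length(ref)
                start, end = 1, length
            arr = np.zeros(end - start + 1, dtype=float)
            # count_coverage is 0-based half-open
            cov = bam.count_coverage(ref, start - 1, end)
            arr[:] = np.sum(cov, axis=0)
            out[name] = arr
    return out
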