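"""Per-probe and per-region ToR values and activity-type calls.

Breakpoint localization is uncertain, so probes near segment ends are
left ``undefined``: within 120 kb of a CTR segment end or 180 kb of a
TTR segment end (the distances at which simulated calls reach 80%
certainty).  Chromosome (and block) ends count as segment ends.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GenomicRegion
from .segmentation import SegmentationResult

CTR_MARGIN = 120_000   # bp
TTR_MARGIN = 180_000   # bp
UNDEFINED = "undefined"


def classify_probes(result: SegmentationResult, ctr_margin: int = CTR_MARGIN,
                    ttr_margin: int = TTR_MARGIN) -> pd.DataFrame:
    """Per-probe fitted ToR + activity call in {CTR, TTR, undefined}.

    A probe inherits its segment's type unless its distance to the
    nearer segment end is below that type's margin, in which case it is
    undefined.  Returns a DataFrame with columns chromosome, position,
    fitted_tor, activity, dist_to_breakpoint.
    """
    if ctr_margin < 0 or ttr_margin < 0:
        raise ValueError("margins must be >= 0")
    idx = result.probe_segment_index()
    pos = result.positions.astype(float)
    dist = np.minimum(pos - result.seg_start_x[idx], result.seg_end_x[idx] - pos)
    dist = np.maximum(dist, 0.0)
    seg_type = result.seg_type[idx]
    margin = np.where(seg_type == "CTR", ctr_margin, ttr_margin)
    activity = np.where(dist < margin, UNDEFINED, seg_type)
    return pd.DataFrame({
        "chromosome": result.chromosome,
        "position": result.positions,
        "fitted_tor": result.fitted,
        "activity": activity,
        "dist_to_breakpoint": dist,
    })


def assign_region(result: SegmentationResult, region: GenomicRegion,
                  ctr_margin: int = CTR_MARGIN,
                  ttr_margin: int = TTR_MARGIN) -> tuple[float, str]:
    """ToR and activity type of a genomic region (gene, lincRNA exon, ...).

    The region's ToR is the fitted value at its midpoint (regions almost
    never span enough of the map for the midpoint to misrepresent them).
    Its activity is the midpoint segment's type if any part of the
    region reaches that segment's defined (non-margin) zone, else
    undefined.  A midpoint exactly on a breakpoint goes to the left
    segment.
    """
    mid = region.midpoint
    lo = result.seg_start_x[0]
    hi = result.seg_end_x[-1]
    if mid < lo or mid > hi:
        raise ValueError(
            f"region {region.chromosome}:{region.start}-{region.end} midpoint "
            "outside segmented territory")
    seg = int(np.clip(np.searchsorted(result.seg_end_x, mid, side="left"),
                      0, result.n_segments - 1))
    tor = float(result.value_at(mid)[0])
    typ = str(result.seg_type[seg])
    margin = ctr_margin if typ == "CTR" else ttr_margin
    def_lo = result.seg_start_x[seg] + margin
    def_hi = result.seg_end_x[seg] - margin
    overlaps_defined = def_lo < def_hi and region.start < def_hi and region.end > def_lo
    return tor, (typ if overlaps_defined else UNDEFINED)


def assign_regions(result: SegmentationResult, regions: list[GenomicRegion],
                   ctr_margin: int = CTR_MARGIN,
                   ttr_margin: int = TTR_MARGIN) -> pd.DataFrame:
    """Vectorized convenience wrapper over :func:`assign_region`."""
    rows = []
    for r in regions:
        tor, act = assign_region(result, r, ctr_margin, ttr_margin)
        rows.append((r.chromosome, r.start, r.end, r.name, tor, act))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "name",
                                       "tor", "activity"])
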