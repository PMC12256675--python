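"""Registration-accuracy evaluation in the benchmark's two-stratum layout.

For a course, the fixed (last-ICBT) frame's organ masks are the reference;
every other frame's masks are warped into the fixed frame with each method's
displacement field and compared by DSC and the Hausdorff family.  Rows are
stratified into the EBRT-vs-last-ICBT and ICBT-vs-last-ICBT comparisons, and
a ``before_dir`` method row (identity transform) is always included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import Course, DisplacementField, Mask3D
from .metrics import dsc, mask_distances
from .registration.warp import warp_array

METRICS = ["dsc", "hd", "hd95", "hdmean"]


def _warped_mask(mask: Mask3D, field: DisplacementField | None) -> Mask3D:
    if field is None:
        return mask
    warped = warp_array(mask.data.astype(np.float64), field.u, mask.spacing, mode="nearest")
    return Mask3D(warped > 0.5, mask.spacing, organ=mask.organ)


def evaluate_registration(
    course: Course,
    fields_per_method: dict[str, dict[int, DisplacementField]],
    case_id: str | int = 0,
) -> pd.DataFrame:
    """Per-frame, per-organ, per-method metric rows for one course."""
    fixed = course.fixed_frame
    methods = {"before_dir": None, **fields_per_method}
    rows = []
    for method, fields in methods.items():
        for idx in course.moving_indices:
            frame = course.frames[idx]
            stratum = "ebrt_vs_last_icbt" if frame.role == "ebrt" else "icbt_vs_last_icbt"
            for organ, moving_mask in frame.masks.items():
                if organ not in fixed.masks:
                    raise ValueError(f"fixed frame lacks mask {organ!r}")
                field = None if fields is None else fields[idx]
                warped = _warped_mask(moving_mask, field)
                d = dsc(fixed.masks[organ], warped)
                hd, hd95, hdmean = mask_distances(fixed.masks[organ], warped)
                rows.append(
                    {
                        "case": case_id,
                        "method": method,
                        "frame": idx,
                        "stratum": stratum,
                        "organ": organ,
                        "dsc": d,
                        "hd": hd,
                        "hd95": hd95,
                        "hdmean": hdmean,
                    }
                )
    df = pd.DataFrame(rows)
    for stratum in ("ebrt_vs_last_icbt", "icbt_vs_last_icbt"):
        if not (df["stratum"] == stratum).any():
            raise ValueError(f"course is missing the {stratum} stratum")
    return df


def evaluate_courses(
    courses: list[Course],
    fields_per_method_per_course: list[dict[str, dict[int, DisplacementField]]],
) -> pd.DataFrame:
    frames = [
        evaluate_registration(course, fields, case_id=i)
        for i, (course, fields) in enumerate(zip(courses, fields_per_method_per_course))
    ]
    return pd.concat(frames, ignore_index=True)


def summarize(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean ± std per (stratum, organ, method), recomputable from the rows."""
    g = rows.groupby(["stratum", "organ", "method"])[METRICS]
    summary = g.agg(["mean", "std", "count"])
    summary.columns = ["_".join(c) for c in summary.columns]
    return summary.reset_index()
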