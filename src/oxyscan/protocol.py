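"""Pre-analytic sample-preparation computations and QC rules.

The assay standardises the number of red cells per run: the whole-blood
volume that yields 200 x 10^6 RBCs is ``200 / RBC count`` microliters, with
the count expressed in 10^6 cells/ul.  Samples are stored at 4 deg C and run
16-32 h after collection; storage beyond 24 h may affect EI_max and EI_min,
so it is flagged (advisory only, never a hard filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Nominal number of red cells loaded per measurement.
TARGET_CELLS = 200e6

# QC flag names
WITHIN_PROTOCOL_WINDOW = "within_protocol_window"
STORAGE_GT_24H = "storage_gt_24h"
AGE_UNKNOWN = "age_unknown"

PROTOCOL_WINDOW_HOURS = (16.0, 32.0)
STORAGE_CAUTION_HOURS = 24.0


@dataclass(frozen=True)
class PrepResult:
    """Computed sample volume and any QC flags for one sample."""

    sample_volume_uL: float
    target_cells: float = TARGET_CELLS
    qc_flags: frozenset[str] = field(default_factory=frozenset)


def compute_sample_volume(rbc_count_1e6_ul: float) -> PrepResult:
    """Whole-blood volume (ul) yielding 200 x 10^6 RBCs.

    ``volume_uL = 200 / rbc_count``, with the count in 10^6 cells/ul.
    """
    if not rbc_count_1e6_ul > 0:
        raise ValueError(
            f"RBC count must be positive, got {rbc_count_1e6_ul!r}"
        )
    return PrepResult(sample_volume_uL=200.0 / rbc_count_1e6_ul)


def qc_sample_age(collection_to_run_hours: float | None) -> frozenset[str]:
    """QC flags for the collection-to-analysis interval.

    ``within_protocol_window`` iff 16 <= h <= 32; ``storage_gt_24h`` iff
    h > 24 (storage beyond 24 h may affect EI_max/EI_min while the point of
    sickling stays fairly stable); ``age_unknown`` when the interval was not
    recorded.
    """
    if collection_to_run_hours is None:
        return frozenset({AGE_UNKNOWN})
    if collection_to_run_hours < 0:
        raise ValueError("collection_to_run_hours must be non-negative")
    flags = set()
    lo, hi = PROTOCOL_WINDOW_HOURS
    if lo <= collection_to_run_hours <= hi:
        flags.add(WITHIN_PROTOCOL_WINDOW)
    if collection_to_run_hours > STORAGE_CAUTION_HOURS:
        flags.add(STORAGE_GT_24H)
    return frozenset(flags)
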