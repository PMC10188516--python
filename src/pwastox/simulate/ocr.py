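"""Mito-stress oxygen-consumption-rate trace generator.

Each trace has four segments (basal, post-oligomycin, post-FCCP,
post-rotenone/antimycin-A) of three measurement cycles each, at piecewise
levels determined by the configured truth, plus Gaussian noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimConfig

SEGMENTS = ("basal", "oligomycin", "fccp", "rot_aa")
CYCLES_PER_SEGMENT = 3


def gen_ocr(config: SimConfig) -> pd.DataFrame:
    """Trace table: trace_id, segment, cycle, time_min, ocr."""
    t = config.ocr_truth
    levels = {
        "basal": t.non_mito + t.basal,
        "oligomycin": t.non_mito + t.basal - t.atp_linked,
        "fccp": t.non_mito + t.maximal,
        "rot_aa": t.non_mito,
    }
    rng = config.rng("ocr")
    rows = []
    for trace in range(config.n_ocr_traces):
        cycle = 0
        for seg in SEGMENTS:
            for _ in range(CYCLES_PER_SEGMENT):
                cycle += 1
                rows.append({
                    "trace_id": f"T{trace:02d}",
                    "segment": seg,
                    "cycle": cycle,
                    "time_min": 6.5 * cycle,
                    "ocr": levels[seg] + (rng.normal(0.0, t.noise_sd) if t.noise_sd else 0.0),
                })
    return pd.DataFrame(rows)
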