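"""The published 13-biomarker knee-osteoarthritis panel.

A commonly analysed baseline panel from a 678-knee OAI-derived cohort:
WOMAC pain, medial minimum joint space width, semi-quantitative osteophyte
and sclerosis grades per tibial/femoral compartment, and quantitative MRI
cartilage thickness per femoral sub-region.  For each biomarker the number
of retained z-score events (thresholds drawn from z = 1, 2, 3, 5) and the
published maximum z-score input are recorded; the 13 biomarkers carry 32
z-score events in total.

Direction is +1 for measures that increase with severity (pain,
osteophytes, sclerosis) and -1 for those that decrease (joint space width,
cartilage thickness).
"""

from __future__ import annotations

import pandas as pd

from .events import BiomarkerDef, EventSet, event_set_from_counts

_PANEL = [
    # (name, direction, n_events, published max z)
    ("womac_pain", 1, 3, 5),
    ("medial_min_jsw", -1, 3, 5),
    ("osteophytes_tibia_medial", 1, 3, 3),
    ("osteophytes_tibia_lateral", 1, 2, 3),
    ("osteophytes_femur_lateral", 1, 3, 3),
    ("osteophytes_femur_medial", 1, 2, 3),
    ("sclerosis_femur_medial", 1, 2, 3),
    ("sclerosis_tibia_medial", 1, 1, 3),
    ("cartilage_cmf_external", -1, 3, 5),
    ("cartilage_cmf_center", -1, 3, 5),
    ("cartilage_cmf_internal", -1, 2, 2),
    ("cartilage_clf_internal", -1, 2, 3),
    ("cartilage_clf_external", -1, 3, 3),
]


def koa_biomarker_table() -> pd.DataFrame:
    """The panel as a table: name, direction, n_events, published max z."""
    return pd.DataFrame(
        _PANEL, columns=["name", "direction", "n_events", "published_max_z"]
    )


def koa_biomarker_defs() -> list[BiomarkerDef]:
    """Biomarker definitions for the 13-biomarker panel."""
    return [BiomarkerDef(name=n, direction=d) for n, d, _, _ in _PANEL]


def koa_event_set() -> EventSet:
    """The 32-event set implied by the panel's published event counts.

    Events fill from the lowest candidate threshold; each biomarker's
    maximum z-score follows the standard mapping from its largest event.
    (One published row lists maximum z 2 alongside 2 events, which the
    mapping cannot produce; the mapping's value 3 is used there.)
    """
    counts = {n: k for n, _, k, _ in _PANEL}
    return event_set_from_counts(counts)
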