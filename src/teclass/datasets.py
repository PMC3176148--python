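"""Small built-in datasets.

``characterized_te_profiles`` holds headline mol% composition values for
acyl-ACP thioesterases that have been characterized by in vivo expression
in E. coli, as reported in the literature (dominant products only).  The
unreported remainder of each composition is spread uniformly over the
remaining fatty-acid species so every vector sums to 100 mol%; those
filled-in minor components are a synthetic completion, not measured data.
The set is intended for demonstrations and as a sanity fixture for the
class-clustering stage, not as a faithful reconstruction of any full
published table.
"""

from __future__ import annotations

import pandas as pd

from .specificity import carbon_number

#: Fatty-acid species universe used to complete the vectors.
_UNIVERSE = (
    "4:0", "6:0", "8:0", "10:0", "12:0", "14:0", "14:1", "16:0", "16:1",
    "18:0", "18:1",
)

#: Reported dominant products (enzyme -> {species: mol%}).
_REPORTED: dict[str, dict[str, float]] = {
    "Cuphea_palustris": {"8:0": 97.0, "10:0": 0.8},
    "Ulmus_americana": {"8:0": 44.0, "10:0": 23.0},
    "Elaeis_guineensis": {"14:0": 47.0, "16:1": 26.0},
    "CnFatB3": {"12:0": 34.0, "14:1": 22.0},
    "CvFatB1": {"8:0": 51.0, "10:0": 25.0},
    "CvFatB2": {"14:0": 46.0, "16:0": 25.0, "16:1": 20.0},
    "CvFatB3": {"14:0": 84.0},
    "Anaerococcus_tetradius": {"8:0": 87.0},
    "Clostridium_perfringens": {"6:0": 14.0, "8:0": 70.0},
    "Lactobacillus_brevis": {"4:0": 7.0, "6:0": 14.0, "8:0": 55.0},
    "Lactobacillus_plantarum": {"6:0": 11.0, "8:0": 68.0},
}


def characterized_te_profiles(subset: list[str] | None = None) -> pd.DataFrame:
    """Wide mol% matrix (enzyme x fatty-acid species), rows summing to 100."""
    names = subset or sorted(_REPORTED)
    rows = {}
    for name in names:
        reported = _REPORTED[name]
        vec = {s: reported.get(s, 0.0) for s in _UNIVERSE}
        missing = [s for s in _UNIVERSE if s not in reported]
        remainder = 100.0 - sum(reported.values())
        for s in missing:
            vec[s] = remainder / len(missing)
        rows[name] = vec
    frame = pd.DataFrame(rows).T
    return frame[
        sorted(frame.columns, key=lambda s: (carbon_number(s), s))
    ]
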