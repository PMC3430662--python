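"""Normative rest-position muscle-tendon geometry for the human ankle.

Group means and standard deviations of ultrasound-measured rest geometry for
the lateral (GL) and medial (GM) heads of the gastrocnemius and the soleus
(SOL) in healthy adult males: fascicle length, pennation angle, free tendon
length and aponeurosis length.  The tibialis anterior (TA) carries only a
literature tendon/(tendon+aponeurosis) ratio of 0.5; its rest lengths were not
measured.  These values seed the synthetic-subject generator and provide the
rest-length ratios used to scale the T-A curve across muscles.
"""

from __future__ import annotations

import math

from .ta_characterization import MuscleId, RestGeometry, ta_ratio

#: (mean, sd) per muscle; lengths mm, pennation degrees.
REST_GEOMETRY_STATS: dict[MuscleId, dict[str, tuple[float, float]]] = {
    MuscleId.GL: {
        "fascicle_length_mm": (70.2, 2.9),
        "pennation_deg": (13.2, 3.2),
        "tendon_length_mm": (222.1, 32.9),
        "aponeurosis_length_mm": (194.0, 11.3),
    },
    MuscleId.GM: {
        "fascicle_length_mm": (59.5, 3.6),
        "pennation_deg": (19.4, 1.7),
        "tendon_length_mm": (209.9, 34.0),
        "aponeurosis_length_mm": (219.3, 9.1),
    },
    MuscleId.SOL: {
        "fascicle_length_mm": (43.8, 4.9),
        "pennation_deg": (19.4, 1.2),
        "tendon_length_mm": (61.4, 14.6),
        "aponeurosis_length_mm": (217.8, 19.3),
    },
}

#: Literature rest-length ratio for the tibialis anterior.
TA_RATIO = 0.5


def mean_rest_geometry(muscle: MuscleId) -> RestGeometry:
    """RestGeometry built from the normative group means."""
    muscle = MuscleId(muscle)
    if muscle is MuscleId.TA:
        return RestGeometry(muscle_id=MuscleId.TA, ratio=TA_RATIO)
    stats = REST_GEOMETRY_STATS[muscle]
    return RestGeometry(
        muscle_id=muscle,
        fascicle_length_rest=stats["fascicle_length_mm"][0],
        pennation_rest=math.radians(stats["pennation_deg"][0]),
        tendon_length_rest=stats["tendon_length_mm"][0],
        aponeurosis_length_rest=stats["aponeurosis_length_mm"][0],
    )


def mean_ta_ratios() -> dict[MuscleId, float]:
    """Tendon/(tendon+aponeurosis) rest ratios at the normative means."""
    out = {
        m: ta_ratio(REST_GEOMETRY_STATS[m]["tendon_length_mm"][0],
                    REST_GEOMETRY_STATS[m]["aponeurosis_length_mm"][0])
        for m in (MuscleId.GL, MuscleId.GM, MuscleId.SOL)
    }
    out[MuscleId.TA] = TA_RATIO
    return out
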