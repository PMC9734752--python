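"""Published reference values used for validation and as defaults.

``TRAINING_PARAMS`` holds the mean +/- sd of the model parameters
estimated from training trials (circle radius and angular velocity per
hand).  ``QUESTIONNAIRE_EFFECTS`` holds the reported Cliff's delta for
each of the ten post-trial questionnaire items in the coupling vs
no-coupling comparison, with the qualitative size label attached to it
(items without a label are negligible).  These are validation anchors
for :func:`mirrorgame.stats_pipeline.effect_label` and plausibility
bands for parameter estimation; they are inputs, never outputs, of this
package.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

__all__ = ["TRAINING_PARAMS", "QUESTIONNAIRE_EFFECTS", "QUESTION_TEXTS"]

#: mean, sd of parameters estimated in the training condition.
TRAINING_PARAMS: Dict[str, Tuple[float, float]] = {
    "radius_right": (0.163, 0.049),   # m
    "radius_left": (0.161, 0.046),    # m
    "omega_right": (2.695, 1.025),    # rad/s
    "omega_left": (2.698, 1.025),     # rad/s
}

#: question index -> (Cliff's delta, reported size label)
QUESTIONNAIRE_EFFECTS: List[Tuple[int, float, str]] = [
    (1, -0.4, "medium"),
    (2, -0.1, "negligible"),
    (3, 0.0, "negligible"),
    (4, -0.1, "negligible"),
    (5, -0.3, "small"),
    (6, 0.3, "small"),
    (7, -0.4, "medium"),
    (8, 0.3, "small"),
    (9, -0.5, "medium"),
    (10, 0.1, "negligible"),
]

#: Abbreviated stems of the ten post-trial items (flow: 1-4;
#: embodiment / self-other: 5-10).
QUESTION_TEXTS: Dict[int, str] = {
    1: "did the task fluidly and smoothly",
    2: "no problem concentrating",
    3: "right amount of challenge",
    4: "did not notice time passing",
    5: "moving arms felt like my own",
    6: "character felt like another person",
    7: "my movements influenced the character",
    8: "the character influenced my movements",
    9: "character moved like my mirror image",
    10: "felt the instinct to move with the character",
}
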