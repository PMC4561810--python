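"""Reference parameter sets and reward-structure defaults.

``PATTERN_PARAMS`` holds, for each utility model, the published average
maximum-likelihood parameter values of players whose dyads showed each of the
four behavioral patterns (plus undefined play).  They are the canonical
generator settings for reproducing the patterns in simulation: for example,
self-concept agents at the "unfair" values -- one player with benevolence near
+1, the other near -1 -- produce games dominated by unfair windows.

Values are stored as plain ``(player 1, player 2)`` tuples of parameter
tuples in the order ``(alpha, beta)`` for ``fs`` and
``(alpha, beta, gamma, delta)`` for ``cox`` / ``sc``.  Note that the ``fs``
rows are averages over players and several violate the joint constraint
``beta <= alpha`` that individual fits respect, so they cannot be turned into
validated :class:`~hawkdove.models.FSParams` objects; use them as raw arrays.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .models import ModelParams, params_from_array

__all__ = ["PATTERN_PARAMS", "pattern_params"]

PATTERN_PARAMS = {
    "fs": {
        "switching": ((0.2301, 0.3642), (0.0863, 0.1695)),
        "mutual_rush": ((0.0538, 0.5824), (0.0013, 0.2924)),
        "mutual_avoid": ((0.0586, 0.2500), (0.0475, 0.2500)),
        "unfair": ((0.0187, 0.0000), (0.0187, 0.0117)),
        "undefined": ((0.0719, 0.261), (0.0483, 0.1168)),
    },
    "cox": {
        "switching": ((0.9904, -0.0653, 0.0264, 0.9872), (0.9911, -0.0213, 0.0357, 0.9787)),
        "mutual_rush": ((0.9031, -0.7186, 0.5791, 0.6693), (0.7820, -0.5580, 0.4555, 0.7516)),
        "mutual_avoid": ((0.9893, 0.1341, 0.3645, 0.9945), (0.9999, 0.2317, 0.3545, 0.9996)),
        "unfair": ((0.9435, 0.9130, 0.7067, 0.0301), (0.6106, -0.4942, 0.932, 0.1556)),
        "undefined": ((0.9123, -0.1407, 0.3300, 0.8087), (0.8635, -0.0684, 0.4038, 0.7397)),
    },
    "sc": {
        "switching": ((0.9764, -0.0689, 0.1102, 0.6099), (0.9650, -0.0657, 0.0638, 0.6494)),
        "mutual_rush": ((0.8632, -0.7388, 0.6731, 0.6965), (0.7860, -0.4299, 0.4423, 0.7893)),
        "mutual_avoid": ((0.8648, 0.1266, 0.3703, 0.9786), (0.9968, 0.1704, 0.2729, 0.9171)),
        "unfair": ((0.6443, 0.9683, 0.9303, 0.9316), (0.9112, -0.8921, 0.1993, 0.9905)),
        "undefined": ((0.8256, -0.2006, 0.5741, 0.6464), (0.7488, -0.0681, 0.4533, 0.7824)),
    },
}


def pattern_params(model: str, pattern: str) -> Tuple[ModelParams, ModelParams]:
    """Validated parameter objects for both players of a reference pattern.

    Raises ``ValueError`` for ``fs`` rows whose averaged values fall outside
    the model's joint parameter constraints.
    """
    p1, p2 = PATTERN_PARAMS[model][pattern]
    return (
        params_from_array(model, np.asarray(p1)),
        params_from_array(model, np.asarray(p2)),
    )
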