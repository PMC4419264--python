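"""Published reference selections for the BCI Competition III Data Set V task.

These are the per-user feature subsets reported for the four selection
methods (statistic/fuzzy criterion x order/GMDH wrapper) on the three-user
benchmark, used as fixed inputs for cross-user unified-model construction and
for subset-size bookkeeping.  Feature indices are 1-based in the standard
8-channel x 12-band channel-major layout.
"""

from __future__ import annotations

__all__ = ["N_FEATURES_FULL", "REFERENCE_SELECTIONS"]

N_FEATURES_FULL = 96

#: user -> method -> selected feature tuple (selection order preserved).
REFERENCE_SELECTIONS: dict[str, dict[str, tuple[int, ...]]] = {
    "user1": {
        "statistic_order": (38, 2),
        "statistic_gmdh": (38, 2, 31),
        "fuzzy_order": (26, 27, 25, 38, 2, 3, 61, 39, 62),
        "fuzzy_gmdh": (38, 2, 27, 62),
    },
    "user2": {
        "statistic_order": (26, 2, 1),
        "statistic_gmdh": (2, 26, 5),
        "fuzzy_order": (26, 2, 1),
        "fuzzy_gmdh": (2, 26, 27, 61),
    },
    "user3": {
        "statistic_order": (39, 3, 1, 2, 4, 31),
        "statistic_gmdh": (4, 3, 30),
        "fuzzy_order": (3, 74, 39, 4, 73),
        "fuzzy_gmdh": (4, 3, 49),
    },
}
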