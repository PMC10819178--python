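"""Numeric constants of the screening pipeline.

All thresholds and type sets used by the prediction and post-processing
stages live here so that every module draws them from one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Number of interaction types distinguished by the classifier.
N_TYPES = 86

#: Morgan (circular) fingerprint parameters.
FP_RADIUS = 2
FP_NBITS = 2048

#: Reduced dimension of a structural similarity profile; a pair feature
#: is the concatenation of two reduced profiles (length 2 * PCA_DIM).
PCA_DIM = 50

#: Default output-neuron activation threshold of the original model.
DEFAULT_THRESHOLD = 0.47

#: Doubled threshold used to obtain the final high-confidence predictions
#: for medication-plan screening.
SCREEN_THRESHOLD = 0.94

#: Minimum Dice coefficient between a food compound and an approved drug
#: for a predicted drug-food interaction to be considered validated.
DFI_DICE_MIN = 0.75

#: The 14 interaction types regarded as having clear negative health
#: effects; these drive the substitution safety check.
CRITICAL_TYPES = frozenset(range(18, 24)) | frozenset(range(25, 33))

#: Interaction type whose sentence reads "risk or severity of adverse
#: effects can be increased"; mechanism inference looks for co-predicted
#: types that could explain it.
ADVERSE_EFFECT_TYPE = 26

#: Concentration-altering types used for the food-interaction network:
#: absorption (1/2), bioavailability (4/5), metabolism (6/7) and serum
#: concentration (9/10) of a drug decreased or increased by a food
#: compound.
CONC_DECREASE_TYPES = frozenset({1, 4, 7, 9})
CONC_INCREASE_TYPES = frozenset({2, 5, 6, 10})
CONCENTRATION_TYPES = CONC_DECREASE_TYPES | CONC_INCREASE_TYPES

#: Number of top food sources reported per food compound.
TOP_SOURCES_K = 10


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of all numeric constants, overridable per run."""

    n_types: int = N_TYPES
    fp_radius: int = FP_RADIUS
    fp_nbits: int = FP_NBITS
    pca_dim: int = PCA_DIM
    default_threshold: float = DEFAULT_THRESHOLD
    screen_threshold: float = SCREEN_THRESHOLD
    dfi_dice_min: float = DFI_DICE_MIN
    critical_types: frozenset[int] = field(default=CRITICAL_TYPES)
    conc_decrease_types: frozenset[int] = field(default=CONC_DECREASE_TYPES)
    conc_increase_types: frozenset[int] = field(default=CONC_INCREASE_TYPES)
    top_sources_k: int = TOP_SOURCES_K
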