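"""Packaged default preterm-birth hierarchy.

The six risk dimensions and their weights follow the published FAHP
elicitation from a panel of 35 experienced obstetricians: information
during pregnancy 0.339, medical history of previous pregnancies 0.306,
clinical medical history 0.166, gynecological and obstetric history
0.1342, behavioral / mother's lifestyle 0.042, and socio/personal/
economic 0.0115 (printed rounded weights; they sum to 0.9987).

Factor-level weights of that elicitation were never published in
machine-readable form, so the packaged hierarchy is *reconstructed*: it
ships the factor names attested in the published narrative plus neutral
placeholders, with uniform local weights inside every dimension.  Users
with access to true per-factor weights should supply them through the
hierarchy configuration file instead.
"""

from __future__ import annotations

from .model import Dimension, Factor, RiskHierarchy

__all__ = ["preterm_hierarchy", "PRETERM_DIMENSION_WEIGHTS"]

#: Published dimension weights, in printed (descending) order.
PRETERM_DIMENSION_WEIGHTS = {
    "information_during_pregnancy": 0.339,
    "medical_history_previous_pregnancies": 0.306,
    "clinical_medical_history": 0.166,
    "gynecological_obstetric_history": 0.1342,
    "behavioral_lifestyle": 0.042,
    "socio_personal_economic": 0.0115,
}

_FACTORS = {
    "information_during_pregnancy": [
        "early_rupture_of_amniotic_sac",
        "fetal_fibronectin",
    ],
    "medical_history_previous_pregnancies": [
        "previous_early_gestational_age",
        "previous_stillbirth",
    ],
    "clinical_medical_history": [
        "type_1_2_diabetes",
        "chronic_blood_pressure",
        "cardiovascular_disease",
    ],
    # the three gynecological/obstetric factors are unnamed in the
    # published narrative; neutral placeholders keep the structure intact
    "gynecological_obstetric_history": [
        "goh_factor_1",
        "goh_factor_2",
        "goh_factor_3",
    ],
    "behavioral_lifestyle": [
        "substance_use",
        "alcohol_use",
        "smoking",
    ],
    "socio_personal_economic": [
        "late_booking",
        "maternal_age",
        "education_level",
        "marital_status",
    ],
}


def preterm_hierarchy() -> RiskHierarchy:
    """The packaged preterm-birth risk hierarchy (reconstructed factors).

    Dimension weights are the published panel-elicited values; factor
    local weights are uniform within each dimension because the true
    per-factor weights are not recoverable from the published record.
    """
    dims = []
    for name, weight in PRETERM_DIMENSION_WEIGHTS.items():
        factors = _FACTORS[name]
        w = 1.0 / len(factors)
        dims.append(
            Dimension(name, weight, tuple(Factor(f, w) for f in factors))
        )
    return RiskHierarchy(goal="preterm birth risk", dimensions=tuple(dims))
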