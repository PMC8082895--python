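"""Health states of the colorectal-cancer screening cohort model.

The cohort moves annually between nine states: three screening-behaviour
states without diagnosed neoplasia (compliant with the screening programme,
lapsed after a colonoscopy, never engaged with screening), a post-polypectomy
surveillance state, two cancer states (early / advanced-metastatic), a
remission state reachable after treated early cancer, and two absorbing
death states (colorectal-cancer death vs. death from other causes).
"""

from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    COMPLIANT_SCREENING = 0
    NONCOMPLIANT_POST_COLONOSCOPY = 1
    NONCOMPLIANT_WITH_SYSTEM = 2
    ADENOMA_SURVEILLANCE = 3
    EARLY_CRC = 4
    ADVANCED_CRC = 5
    REMISSION = 6
    DEATH_CRC = 7
    DEATH_OTHER = 8


N_STATES = len(HealthState)

ABSORBING_STATES = (HealthState.DEATH_CRC, HealthState.DEATH_OTHER)
DEATH_STATES = ABSORBING_STATES
CRC_STATES = (HealthState.EARLY_CRC, HealthState.ADVANCED_CRC)

#: mapping from model state to the utility-bucket key used in
#: ``ParameterSet.utility_by_state``
UTILITY_KEY = {
    HealthState.COMPLIANT_SCREENING: "no_crc",
    HealthState.NONCOMPLIANT_POST_COLONOSCOPY: "no_crc",
    HealthState.NONCOMPLIANT_WITH_SYSTEM: "no_crc",
    HealthState.ADENOMA_SURVEILLANCE: "adenoma_surveillance",
    HealthState.EARLY_CRC: "early_crc",
    HealthState.ADVANCED_CRC: "advanced_crc",
    HealthState.REMISSION: "remission",
    HealthState.DEATH_CRC: "death",
    HealthState.DEATH_OTHER: "death",
}
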