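"""Published relaxivities and water baselines for the Gd/Mn agent pair.

Relaxivities (mM^-1 ms^-1) of gadobenate dimeglumine ("Gd") and manganese
chloride ("Mn") in deionized water, measured three ways: on a 60 MHz
benchtop relaxometer at 37 degC, by conventional 3 T spin-echo relaxometry
(inversion-recovery for r1, single-echo spin echo for r2), and by 3 T MR
fingerprinting; plus the pre-contrast water relaxation times measured by
each modality.  These are the default parameter sets for the synthetic
studies in this package.
"""

from .types import AgentRelaxivity, BaselineRelaxation

__all__ = [
    "GD_60MHZ", "MN_60MHZ",
    "GD_3T_SE", "MN_3T_SE",
    "GD_3T_MRF", "MN_3T_MRF",
    "WATER_60MHZ", "WATER_3T_MRF",
]

# 60 MHz relaxometer, 37 degC
GD_60MHZ = AgentRelaxivity("Gd", r1=0.0040, r2=0.0048)
MN_60MHZ = AgentRelaxivity("Mn", r1=0.0054, r2=0.0652)

# 3 T conventional spin echo, room temperature
GD_3T_SE = AgentRelaxivity("Gd", r1=0.0051, r2=0.0060)
MN_3T_SE = AgentRelaxivity("Mn", r1=0.0068, r2=0.1079)

# 3 T MR fingerprinting, room temperature
GD_3T_MRF = AgentRelaxivity("Gd", r1=0.0056, r2=0.0076)
MN_3T_MRF = AgentRelaxivity("Mn", r1=0.0067, r2=0.1144)

# Deionized water baselines (T1_0, T2_0), ms
WATER_60MHZ = BaselineRelaxation(T1_0=4250.0, T2_0=2760.0)
WATER_3T_MRF = BaselineRelaxation(T1_0=2897.0, T2_0=946.0)
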