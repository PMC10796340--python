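muscle,joint,moment_arm_cm,rest_fiber_norm
BICLong,elbow_flexion,3.0,1.25
BICShort,elbow_flexion,3.0,1.25
BRA,elbow_flexion,2.0,1.25
PT,forearm_pronation,1.0,1.0
PQ,forearm_pronation,0.5,1.0
BICLong,forearm_pronation,-0.8,1.0
BICShort,forearm_pronation,-0.7,1.0
brachioradialis,forearm_pronation,-0.8,1.0
SUP,forearm_pronation,-0.9,1.0
DELT1,shoulder_flexion,2.5,1.2
BICLong,shoulder_flexion,1.5,1.2
BICShort,shoulder_flexion,1.0,1.2
PECM1,shoulder_flexion,1.5,1.2
PECM2,shoulder_flexion,1.0,1.2
PECM3,shoulder_flexion,0.5,1.2
DELT3,shoulder_flexion,-2.5,0.85
TRILong,shoulder_flexion,-1.5,0.85
DELT2,shoulder_abduction,2.5,1.2
SUPSP,shoulder_abduction,1.5,1.15
TMAJ,shoulder_abduction,-2.0,0.85
PECM1,shoulder_abduction,-1.0,0.9
PECM2,shoulder_abduction,-1.5,0.9
PECM3,shoulder_abduction,-2.0,0.9
TRILong,shoulder_abduction,-0.8,0.9
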