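name,f_max_n,l_opt_cm,l_slack_cm,v_max,pennation_rad,tau_act_s,tau_deact_s,segment
BICLong,625,11.6,27.2,10,0.0,0.01,0.04,upperarm
BICShort,435,13.2,19.2,10,0.0,0.01,0.04,upperarm
BRA,990,8.6,5.4,10,0.0,0.01,0.04,upperarm
brachioradialis,260,17.3,13.3,10,0.0,0.01,0.04,forearm
PT,560,9.2,9.8,10,0.17,0.01,0.04,forearm
PQ,75,2.8,0.5,10,0.17,0.01,0.04,forearm
SUP,475,3.3,2.0,10,0.0,0.01,0.04,forearm
DELT1,1100,9.8,9.3,10,0.38,0.01,0.04,upperarm
DELT2,1140,10.8,11.0,10,0.26,0.01,0.04,upperarm
DELT3,260,13.7,3.8,10,0.31,0.01,0.04,upperarm
TRILong,800,13.4,14.3,10,0.21,0.01,0.04,upperarm
TMAJ,425,16.3,2.0,10,0.28,0.01,0.04,upperarm
PECM1,365,14.4,0.3,10,0.30,0.01,0.04,upperarm
PECM2,515,13.8,8.9,10,0.44,0.01,0.04,upperarm
PECM3,390,13.8,13.2,10,0.44,0.01,0.04,upperarm
SUPSP,490,6.8,4.0,10,0.12,0.01,0.04,upperarm
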