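R_shoulder	R_elbow	R_radius	R_ulna	R_wrist	R_palm	L_shoulder	neck_base	spine_02	R_clavicle	sternum	pelvis	head	L_elbow
R_Shoulder	R_Elbow	R_Radius	R_Ulna	WristRight	R_Hand	L_Shoulder	C7	T10	Clavicle	Sternum	Pelvis	Head	L_Elbow
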