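node_label	module_name
L_IFG_tri	perisylvian
L_IFG_oper	perisylvian
L_IFG_orb	perisylvian
L_SFG	dFP
L_MFG	FP
L_PrCG	dFP
L_PoCG	dFP
L_SMA	dFP
L_Paracentral	dFP
L_SPL	FP
L_SMG	perisylvian
L_AngularGyrus	FP
L_Precuneus	FP
L_Cuneus	occipital_temporal
L_SOG	occipital_temporal
L_MOG	occipital_temporal
L_IOG	occipital_temporal
L_LingualGyrus	occipital_temporal
L_Fusiform	occipital_temporal
L_STG	perisylvian
L_MTG	temporal
L_ITG	temporal
L_TemporalPole	temporal
L_Hippocampus	subcortical
L_PHG	temporal
L_Amygdala	subcortical
L_Entorhinal	temporal
L_Insula	perisylvian
L_ACC	FP
L_MCC	FP
L_PCC	FP
L_RectusGyrus	vmPFC
L_MedialOFC	vmPFC
L_LateralOFC	vmPFC
L_Caudate	subcortical
L_Putamen	subcortical
L_GlobusPallidus	subcortical
L_Thalamus	subcortical
R_IFG_tri	perisylvian
R_IFG_oper	perisylvian
R_IFG_orb	perisylvian
R_SFG	dFP
R_MFG	FP
R_PrCG	dFP
R_PoCG	dFP
R_SMA	dFP
R_Paracentral	dFP
R_SPL	FP
R_SMG	perisylvian
R_AngularGyrus	FP
R_Precuneus	FP
R_Cuneus	occipital_temporal
R_SOG	occipital_temporal
R_MOG	occipital_temporal
R_IOG	occipital_temporal
R_LingualGyrus	occipital_temporal
R_Fusiform	occipital_temporal
R_STG	perisylvian
R_MTG	temporal
R_ITG	temporal
R_TemporalPole	temporal
R_Hippocampus	subcortical
R_PHG	temporal
R_Amygdala	subcortical
R_Entorhinal	temporal
R_Insula	perisylvian
R_ACC	FP
R_MCC	FP
R_PCC	FP
R_RectusGyrus	vmPFC
R_MedialOFC	vmPFC
R_LateralOFC	vmPFC
R_Caudate	subcortical
R_Putamen	subcortical
R_GlobusPallidus	subcortical
R_Thalamus	subcortical
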