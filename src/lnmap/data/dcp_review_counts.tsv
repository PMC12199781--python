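study_id	finding	n_total	n_affected	excluded_for_bias
pooled-grey	grey_matter_injury	893	451	0
pooled-white	white_matter_injury	1019	281	0
pooled-misc	miscellaneous	718	91	0
pooled-normal	normal	1140	182	0
pooled-malform	maldevelopment	786	74	0
pooled-bg	bg_thalamus	597	296	0
pooled-cortsub	cortical_subcortical	571	116	0
pooled-focal	focal_infarct	195	8	0
pooled-thalamus	thalamus	289	146	0
pooled-pallidum	pallidum	190	85	0
pooled-putamen	putamen	221	96	0
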