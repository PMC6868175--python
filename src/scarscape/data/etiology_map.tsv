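signature	etiology
SIG_AGE	Aging
SIG_MSI	MSI
SIG_HRD	HRD
SIG_APOBEC	APOBEC
SIG_GEN	Unknown
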