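pathogen,susceptible_mic_mg_L,source
P. aeruginosa,1.0,CLSI M100 29th ed.
S. pneumoniae,2.0,CLSI M100 29th ed.
S. aureus,1.0,CLSI M100 29th ed.
H. influenzae,2.0,CLSI M100 29th ed.
Enterobacteriaceae,0.5,CLSI M100 29th ed.
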