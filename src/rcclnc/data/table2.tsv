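study	n_common	n_concordant	pct_printed
Takahashi	4	4	100.0
Skubitz	2	2	100.0
Higgins	35	29	82.9
Lenburg	93	78	83.9
Liou	4	4	100.0
Jones	42	38	90.5
Gumz	109	94	86.2
Beroukhim	1	1	100.0
Brito	29	29	100.0
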