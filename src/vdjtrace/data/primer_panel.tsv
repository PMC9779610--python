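name	sequence	orientation	target_region	intronic_tail_len
IGHV1-FR	GCCTTGCAGTTCTCCATGCC	forward	V	0
IGHV3-FR	CACAGTCCCACTCCAGGCAT	forward	V	0
IGHV4-FR	GAAAATGCGTCTTCCAATGG	forward	V	0
IGHV5-FR	CTTTGGGCCAGTAATGTGGC	forward	V	0
IGH-J-A-1	ATTCTTACTACCCGAGCC	reverse	J	8
IGH-J-A-2	TCTTACTACCCGAGCCTT	reverse	J	6
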