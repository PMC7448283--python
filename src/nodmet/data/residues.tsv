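# nodmet residue table v1
# Residue (-H2O) elemental formulas for the 20 proteinogenic amino acids
# plus ornithine (Orn), which occurs in the tyrocidines.
# columns: name	one_letter	formula
Gly	G	C2H3NO
Ala	A	C3H5NO
Ser	S	C3H5NO2
Pro	P	C5H7NO
Val	V	C5H9NO
Thr	T	C4H7NO2
Cys	C	C3H5NOS
Leu	L	C6H11NO
Ile	I	C6H11NO
Asn	N	C4H6N2O2
Asp	D	C4H5NO3
Gln	Q	C5H8N2O2
Lys	K	C6H12N2O
Glu	E	C5H7NO3
Met	M	C5H9NOS
His	H	C6H7N3O
Phe	F	C9H9NO
Arg	R	C6H12N4O
Tyr	Y	C9H9NO2
Trp	W	C11H10N2O
Orn	O	C5H10N2O
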