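# SYNTHETIC Stachelhaus code tables (nodmet fixture, v1).
# These 10-letter binding-pocket signatures are constructed stand-ins, NOT
# transcribed from any characterised NRPS: they are internally consistent
# with the britacidin/gramicidin module architecture (17- vs 15-module
# clusters, two extra A domains in the second gene of the 17-module cluster
# at chemical positions 7/8, and a strongly divergent code at position 11)
# and exist so the comparison and prediction machinery can be exercised
# without external sequence data.
# columns: cluster_id	gene	module_index	code	known_substrate
ref	refVal	1	DAFWIGGTFK	Val
ref	refGly	2	DILQLGLIWK	Gly
ref	refAla	3	DLLNNAWQYK	Ala
ref	refLeu	4	DAWFLGNVVK	Leu
ref	refTrp	5	DVSALTAYCK	Trp
ref	refIle	6	DGFFLGVVYK	Ile
ref	refTyr	7	DASTVAGEWK	Tyr
lgr	lgrA	1	DAFWIGGTFK	Val
lgr	lgrA	2	DILQLGLIWK	Gly
lgr	lgrB	3	DLLNNAWQYK	Ala
lgr	lgrB	4	DAWFLGNVVK	Leu
lgr	lgrB	5	DLLNNAWQYK	Ala
lgr	lgrB	6	DAFWIGGTFK	Val
lgr	lgrC	7	DAFWIGGTFK	Val
lgr	lgrC	8	DAFWIGGTFK	Val
lgr	lgrC	9	DVSALTAYCK	Trp
lgr	lgrC	10	DAWFLGNVVK	Leu
lgr	lgrC	11	DVSALTAYCK	Trp
lgr	lgrC	12	DAWFLGNVVK	Leu
lgr	lgrD	13	DVSALTAYCK	Trp
lgr	lgrD	14	DAWFLGNVVK	Leu
lgr	lgrD	15	DVSALTAYCK	Trp
bri	briA	1	DGFFIGVVYK
bri	briA	2	DILQLGLIWK
bri	briB	3	DLLNNAWQYK
bri	briB	4	DAWFLGNVVK
bri	briB	5	DLLNNAWQYK
bri	briB	6	DAFWIGGTFK
bri	briB	7	DLLNSAWQYK
bri	briB	8	DAFWIGGSFK
bri	briC	9	DAFWIGGTFK
bri	briC	10	DAFWIGGTFK
bri	briC	11	DASTVAGEWK
bri	briC	12	DAWFLGNVVK
bri	briC	13	DVSALTAYCK
bri	briC	14	DAWFLGNVVK
bri	briD	15	DVSALTAYCK
bri	briD	16	DAWFLGNVVK
bri	briD	17	DVSALTAYCK
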