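gene	exon	hotspot	region
AKT1	2. exon	E17	14:104780165-104780282
CDH1	2. exon	Q23	16:68738248-68738338
EGFR	18. exon	G719	7:55173903-55174022
EGFR	19. exon	K745-N756	7:55174737-55174858
EGFR	21. exon	L858, L861	7:55191787-55191907
ESR1	7. exon	E380	6:152011675-152011743
ESR1	9. exon	S463	6:152094359-152094471
ESR1	10. exon	V533-D538	6:152098737-152098851
FGFR1	14. exon	K656	8:38414742-38414820
FGFR4	9. exon	G388	5:177093190-177093300
HER2	8. exon	G309, S310	17:39711902-39712010
HER2	19. exon	L755-D769	17:39723953-39724061
HER2	20. exon	E770-V777	17:39724713-39724788
HRAS	2. exon	G12; G13	11:534221-534315
HRAS	3. exon	Q61	11:533852-533947
KRAS	2. exon	G12; G13	12:25245314-25245378
KRAS	3. exon	Q61	12:25227309-25227407
MET	14. exon	T1003	7:116771871-116771968
PIK3CA	10. exon	E542; E545	3:179218259-179218324
PIK3CA	21. exon	H1047	3:179234190-179234298
TP53	5-8 exon	coding sequence	17:7673701-7675222
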