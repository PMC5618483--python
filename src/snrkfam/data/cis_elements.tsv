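element	pattern	function
ABRE	TACGTG	ABA Response Element
ABRE	CACGTG	ABA Response Element
ABRE	ACGTGGC	ABA Response Element
ABRE	CCTACGTGGC	ABA Response Element
ABRE	GACACGTGGC	ABA Response Element
ABRE	AGTACGTGGC	ABA Response Element
ABRE	CCGCGTAGGC	ABA Response Element
AuxRR-core	GGTCCAT	Auxin Response Element
CGTCA-motif	CGTCA	MeJA Response Element
ERE	ATTTCAAA	Ethylene Response Element
GARE-motif	AAACAGA	Gibberellin Response Element
GARE-motif	TCTGTTG	Gibberellin Response Element
P-box	CCTTTTG	Gibberellin Response Element
P-box	GCCTTTTGAGT	Gibberellin Response Element
TATC-box	TATCCCA	Gibberellin Response Element
TCA-element	CCATCTTTTT	Salicylic acid Response Element
TCA-element	GAGAAGAATA	Salicylic acid Response Element
TCA-element	CAGAAAAGGA	Salicylic acid Response Element
TCA-element	TCAGAAGAGG	Salicylic acid Response Element
TGA-element	AACGAC	Auxin Response Element
TGACG-motif	TGACG	MeJA Response Element
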