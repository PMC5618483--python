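gene	group	element	pattern	position	strand
GmSnRK2.5	1	CGTCA-motif	CGTCA	410	-
GmSnRK2.5	1	ERE	ATTTCAAA	526	-
GmSnRK2.5	1	ERE	ATTTCAAA	911	+
GmSnRK2.5	1	ERE	ATTTCAAA	750	+
GmSnRK2.5	1	P-box	CCTTTTG	68	-
GmSnRK2.5	1	P-box	GCCTTTTGAGT	308	-
GmSnRK2.5	1	TGACG-motif	TGACG	410	+
GmSnRK2.7	1	CGTCA-motif	CGTCA	717	-
GmSnRK2.7	1	CGTCA-motif	CGTCA	834	-
GmSnRK2.7	1	TGACG-motif	TGACG	717	+
GmSnRK2.7	1	TGACG-motif	TGACG	834	+
GmSnRK2.7	1	GARE-motif	TCTGTTG	293	-
GmSnRK2.7	1	TCA-element	CCATCTTTTT	1412	-
GmSnRK2.7	1	TGA-element	AACGAC	836	-
GmSnRK2.7	1	TGA-element	AACGAC	1438	+
GmSnRK2.10	1	ERE	ATTTCAAA	359	-
GmSnRK2.14	1	ERE	ATTTCAAA	211	+
GmSnRK2.14	1	TATC-box	TATCCCA	1289	-
GmSnRK2.15	1	AuxRR-core	GGTCCAT	1409	-
GmSnRK2.15	1	ERE	ATTTCAAA	972	-
GmSnRK2.15	1	TGA-element	AACGAC	559	+
GmSnRK2.18	1	ABRE	TACGTG	516	+
GmSnRK2.18	1	CGTCA-motif	CGTCA	1228	-
GmSnRK2.18	1	TGACG-motif	TGACG	1228	+
GmSnRK2.18	1	ERE	ATTTCAAA	394	+
GmSnRK2.18	1	ERE	ATTTCAAA	628	+
GmSnRK2.18	1	TCA-element	GAGAAGAATA	325	-
GmSnRK2.18	1	TCA-element	CCATCTTTTT	377	+
GmSnRK2.18	1	TGA-element	AACGAC	837	+
GmSnRK2.4	2	ABRE	CACGTG	1258	-
GmSnRK2.4	2	GARE-motif	AAACAGA	1347	-
GmSnRK2.6	2	GARE-motif	AAACAGA	314	+
GmSnRK2.6	2	TCA-element	CAGAAAAGGA	317	+
GmSnRK2.6	2	TCA-element	CCATCTTTTT	1352	-
GmSnRK2.6	2	TCA-element	CAGAAAAGGA	564	+
GmSnRK2.13	2	ABRE	GACACGTGGC	657	-
GmSnRK2.13	2	ABRE	TACGTG	1212	-
GmSnRK2.13	2	ERE	ATTTCAAA	99	-
GmSnRK2.13	2	ERE	ATTTCAAA	1336	+
GmSnRK2.13	2	P-box	GCCTTTTGAGT	510	+
GmSnRK2.13	2	TGA-element	AACGAC	84	+
GmSnRK2.19	2	ABRE	CACGTG	1401	-
GmSnRK2.19	2	GARE-motif	AAACAGA	1483	-
GmSnRK2.1	3	ABRE	TACGTG	79	+
GmSnRK2.1	3	AuxRR-core	GGTCCAT	1158	-
GmSnRK2.1	3	P-box	CCTTTTG	115	-
GmSnRK2.1	3	TCA-element	CCATCTTTTT	164	-
GmSnRK2.1	3	TCA-element	GAGAAGAATA	412	-
GmSnRK2.3	3	CGTCA-motif	CGTCA	261	+
GmSnRK2.3	3	CGTCA-motif	CGTCA	1314	+
GmSnRK2.3	3	CGTCA-motif	CGTCA	295	+
GmSnRK2.3	3	TGACG-motif	TGACG	261	-
GmSnRK2.3	3	TGACG-motif	TGACG	1314	-
GmSnRK2.3	3	TGACG-motif	TGACG	295	-
GmSnRK2.3	3	ERE	ATTTCAAA	481	-
GmSnRK2.3	3	GARE-motif	AAACAGA	62	+
GmSnRK2.3	3	P-box	CCTTTTG	1451	-
GmSnRK2.3	3	TCA-element	GAGAAGAATA	934	+
GmSnRK2.9	3	ABRE	CCGCGTAGGC	1360	-
GmSnRK2.9	3	CGTCA-motif	CGTCA	1386	+
GmSnRK2.9	3	ERE	ATTTCAAA	334	-
GmSnRK2.9	3	GARE-motif	AAACAGA	403	-
GmSnRK2.11	3	TCA-element	CCATCTTTTT	1352	+
GmSnRK2.11	3	TCA-element	CCATCTTTTT	1469	-
GmSnRK2.12	3	ABRE	CACGTG	538	+
GmSnRK2.12	3	ABRE	TACGTG	1147	-
GmSnRK2.12	3	AuxRR-core	GGTCCAT	1345	+
GmSnRK2.12	3	CGTCA-motif	CGTCA	117	+
GmSnRK2.12	3	CGTCA-motif	CGTCA	1361	+
GmSnRK2.12	3	TGACG-motif	TGACG	117	-
GmSnRK2.12	3	TGACG-motif	TGACG	1361	-
GmSnRK2.12	3	TCA-element	CCATCTTTTT	98	-
GmSnRK2.12	3	TCA-element	CCATCTTTTT	710	+
GmSnRK2.17	3	ABRE	CACGTG	207	+
GmSnRK2.17	3	ABRE	AGTACGTGGC	410	-
GmSnRK2.17	3	AuxRR-core	GGTCCAT	981	-
GmSnRK2.17	3	ERE	ATTTCAAA	371	-
GmSnRK2.17	3	GARE-motif	AAACAGA	126	-
GmSnRK2.17	3	TATC-box	TATCCCA	1305	+
GmSnRK2.17	3	TCA-element	CCATCTTTTT	780	+
GmSnRK2.21	3	ABRE	CCTACGTGGC	1349	+
GmSnRK2.21	3	ABRE	ACGTGGC	1352	+
GmSnRK2.21	3	ABRE	TACGTG	1351	+
GmSnRK2.21	3	CGTCA-motif	CGTCA	1374	+
GmSnRK2.21	3	ERE	ATTTCAAA	309	-
GmSnRK2.21	3	TGACG-motif	TGACG	1374	-
GmSnRK2.22	3	TGACG-motif	TGACG	705	-
GmSnRK2.22	3	CGTCA-motif	CGTCA	705	+
GmSnRK2.22	3	TCA-element	GAGAAGAATA	425	+
GmSnRK2.22	3	TCA-element	TCAGAAGAGG	792	+
GmSnRK2.2	4	CGTCA-motif	CGTCA	477	-
GmSnRK2.2	4	TGACG-motif	TGACG	477	+
GmSnRK2.2	4	TCA-element	CCATCTTTTT	82	+
GmSnRK2.16	4	CGTCA-motif	CGTCA	865	-
GmSnRK2.16	4	TGACG-motif	TGACG	865	+
GmSnRK2.16	4	TCA-element	CCATCTTTTT	449	+
GmSnRK2.20	4	GARE-motif	AAACAGA	281	+
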