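gene	group
GmSnRK2.5	1
GmSnRK2.7	1
GmSnRK2.10	1
GmSnRK2.14	1
GmSnRK2.15	1
GmSnRK2.18	1
GmSnRK2.4	2
GmSnRK2.6	2
GmSnRK2.13	2
GmSnRK2.19	2
GmSnRK2.1	3
GmSnRK2.3	3
GmSnRK2.9	3
GmSnRK2.11	3
GmSnRK2.12	3
GmSnRK2.17	3
GmSnRK2.21	3
GmSnRK2.22	3
GmSnRK2.2	4
GmSnRK2.8	4
GmSnRK2.16	4
GmSnRK2.20	4
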