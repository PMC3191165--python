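name	kind	start	end	length
9F13/10A1-2	interband	10792800	10793400	600
10A1-2	band	10793401	10984199	190798
10A1-2/10A3	interband	10984200	10985600	1400
10A3	band	10985601	11002399	16798
10A3/10A4-5	interband	11002400	11004400	2000
10A4-5	band	11004401	11017399	12998
10A4-5/10A6	interband	11017400	11020400	3000
10A6	band	11020401	11022399	1998
10A6/10A7	interband	11022400	11024000	1600
10A7	band	11024001	11029999	5998
10A7/10A8-9	interband	11030000	11033000	3000
10A8-9	band	11033001	11041199	8198
10A8-9/10A10	interband	11041200	11044000	2800
10A10-11	band	11044001	11048599	4598
10A10-11/10B1-2	interband	11048600	11050000	1400
10B1-2	band	11050001	11217799	167798
10B1-2/10B3	interband	11217800	11220400	2600
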