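name	a_um	a_sd
9F13/10A1-2	0.043	0.009
10A1-2	0.410	0.046
10A1-2/10A3	0.095	0.019
10A3	0.078	0.006
10A3/10A4-5	0.065	0.008
10A4-5	0.092	0.007
10A4-5/10A6	0.144	0.023
10A6	0.057	0.006
10A6/10A7	0.045	0.008
10A7	0.064	0.005
10A7/10A8-9	0.144	0.006
10A8-9	0.087	0.003
10A8-9/10A10	0.117	0.006
10A10-11	0.073	0.003
10A10-11/10B1-2	0.0975	0.0055
10B1-2	0.279	0.011
10B1-2/10B3	0.086	0.006
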