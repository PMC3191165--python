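name	target_interband	start	end
CG1582	9F13/10A1-2	10791234	10791994
spas_9F_10A	9F13/10A1-2	10793537	10794176
CG15208	9F13/10A1-2	10794863	10795492
Vago	10A1-2/10A3	10983458	10983987
CG2076	10A1-2/10A3	10984947	10985771
CG32668	10A8-9/10B1-2	11050925	11051486
l(1)10Bb	10B1-2/10B3	11218702	11219201
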