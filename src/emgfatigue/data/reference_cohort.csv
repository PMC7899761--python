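subject,tmlm_r2,tmlm_sd,cmlm_r2,cmlm_sd,fmlm_r2,fmlm_sd
1,0.9093,0.0205,0.9255,0.0063,0.9572,0.0030
2,0.8910,0.0092,0.9210,0.0039,0.9548,0.0009
3,0.8255,0.0043,0.8517,0.0064,0.8938,0.0189
4,0.8224,0.0042,0.8464,0.0049,0.8805,0.0028
5,0.8286,0.0012,0.8571,0.0014,0.9070,0.0190
6,0.9293,0.0132,0.9411,0.0209,0.9554,0.0182
7,0.9199,0.0126,0.9262,0.0050,0.9426,0.0181
8,0.8802,0.0431,0.9359,0.0088,0.9438,0.0088
9,0.8153,0.0268,0.8526,0.0131,0.8753,0.0267
10,0.8350,0.0097,0.8620,0.0130,0.8983,0.0121
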