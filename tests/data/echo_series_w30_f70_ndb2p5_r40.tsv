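te_ms	value
2.38	21.4728530765615
4.76	69.6181737894384
7.15	11.6198008942314
9.53	41.6549882445908
11.91	14.1852710681024
14.29	31.4226735608055
16.67	14.3938218961341
19.06	29.0048500843913
21.44	11.8074412501603
23.82	25.1672868268023
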