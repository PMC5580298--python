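population	n_producers	n_total
Elyana_x_Mara_des_Bois	37	114
Mieze_Schindler_x_Elsanta	46	189
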