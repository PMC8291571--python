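site,delta_e_fibril,delta_e_solvent,delta_e_total
AD-tau site 1,-35.3,-20.5,-55.8
CTE-tau site 4,-27.3,-22.1,-49.4
PiD-tau site 3,-53.1,-8.1,-61.2
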