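site,delta_e_fibril,delta_e_solvent,delta_e_total
AD-tau site C1,-80.5,-14.4,-94.9
AD-tau site C3,-41.1,-3.2,-44.3
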