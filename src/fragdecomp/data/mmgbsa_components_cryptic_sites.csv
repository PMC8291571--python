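site,e_vdw,e_elec,g_gb,g_sa,g_binding
AD-tau site C1,-37.6,-21.0,29.2,-4.1,-33.6
AD-tau site C3,-43.2,-19.4,26.2,-4.9,-41.3
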