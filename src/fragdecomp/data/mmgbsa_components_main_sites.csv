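site,e_vdw,e_elec,g_gb,g_sa,g_binding
AD-tau site 1,-39.2,-11.8,24.1,-4.3,-31.2
AD-tau site 2,-13.0,-0.3,6.2,-1.3,-8.4
AD-tau site 3,-24.7,-15.1,24.1,-3.0,-18.6
AD-tau site 4,-26.5,-24.6,35.3,-3.4,-19.3
CTE-tau site 1,-35.3,-7.9,24.7,-4.2,-22.7
CTE-tau site 2,-35.6,-20.9,36.3,-3.8,-24.0
CTE-tau site 3,-27.3,-24.2,34.5,-3.0,-20.1
CTE-tau site 4,-30.0,-14.0,22.6,-4.3,-25.8
CTE-tau site 5,-30.9,-6.8,17.5,-2.9,-23.1
PiD-tau site 1,-27.6,-9.5,21.3,-3.4,-19.2
PiD-tau site 2,-31.5,-12.7,25.9,-3.7,-21.9
PiD-tau site 3,-41.2,-19.0,28.9,-4.6,-35.9
PiD-tau site 4,-19.7,-7.2,16.6,-2.3,-12.5
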