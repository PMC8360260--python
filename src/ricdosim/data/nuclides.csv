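name,half_life_s,emission_kind,energy_MeV,abundance_fraction
Cu-64,45720,beta+,0.653,0.174
Cu-64,45720,beta-,0.579,0.385
Cu-64,45720,gamma,1.346,0.0054
Lu-177,578880,beta-,0.497,0.786
Lu-177,578880,beta-,0.380,0.091
Lu-177,578880,beta-,0.176,0.122
Lu-177,578880,gamma,0.113,0.064
Lu-177,578880,gamma,0.208,0.110
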