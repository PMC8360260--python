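organ,mass_g
heart,0.15
lungs,0.20
stomach,0.50
pancreas,0.30
intestine,3.00
spleen,0.10
liver,1.75
kidneys,0.45
bone,2.90
skin,5.00
muscle,11.50
blood,2.30
tumour,0.30
whole_body,30.0
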