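species,M_doses,mu_factor,r_animals
cattle,585,0.8,25
sheep,198,0.8,25
goat,105,0.8,25
horse,58,0.8,25
pig,150,0.8,25
poultry,46,0.8,25
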