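bank,species,cf_eur_per_animal,cc_eur_per_animal
B1,cattle,100,182
B1,sheep,100,30
B1,goat,100,30
B1,horse,150,50
B1,pig,340,30
B1,poultry,15,15
B2,cattle,50,50
B2,sheep,100,30
B2,goat,100,30
B2,horse,150,50
B2,pig,340,30
B2,poultry,30,30
B3,cattle,100,182
B3,sheep,100,30
B3,goat,100,30
B3,horse,150,50
B3,pig,340,30
B3,poultry,15,15
B4,cattle,100,182
B4,sheep,100,30
B4,goat,100,30
B4,horse,150,50
B4,pig,340,30
B4,poultry,15,15
B5,cattle,100,182
B5,sheep,100,30
B5,goat,100,30
B5,horse,150,50
B5,pig,340,30
B5,poultry,1,1
B6,cattle,100,182
B6,sheep,100,30
B6,goat,100,30
B6,horse,150,50
B6,pig,340,30
B6,poultry,15,15
B7,cattle,300,300
B7,sheep,150,150
B7,goat,150,150
B7,horse,300,300
B7,pig,150,150
B7,poultry,15,15
B8,cattle,60,60
B8,sheep,30,30
B8,goat,40,30
B8,horse,60,60
B8,pig,40,40
B8,poultry,15,15
B9,cattle,500,500
B9,sheep,100,30
B9,goat,100,30
B9,horse,150,50
B9,pig,340,30
B9,poultry,15,15
B10,cattle,30,30
B10,sheep,30,30
B10,goat,30,30
B10,horse,30,30
B10,pig,30,30
B10,poultry,30,30
B11,cattle,100,182
B11,sheep,100,30
B11,goat,100,30
B11,horse,150,50
B11,pig,340,30
B11,poultry,15,15
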