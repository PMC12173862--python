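category,L,U
grains_tubers_legumes,250,400
vegetables,300,500
fruits,200,350
meat_poultry,40,75
eggs,40,50
aquatic,40,75
dairy,300,500
nuts_seeds,25,35
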