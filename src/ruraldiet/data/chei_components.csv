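component,kind,R,L,U
cereals,adequacy,250,,
tubers,adequacy,75,,
dried_legumes,adequacy,25,,
vegetables,adequacy,400,,
fungi_algae,adequacy,15,,
fruits,adequacy,275,,
nuts_seeds,adequacy,10,,
meat,adequacy,50,,
poultry,adequacy,25,,
dairy,adequacy,300,,
eggs,adequacy,45,,
aquatic,adequacy,55,,
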