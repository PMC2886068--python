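species,character,state
lobe_finned_fish,C27_alcohol_present,present
Mammalia,C27_alcohol_present,absent
tuatara,C27_alcohol_present,absent
lizards,C27_alcohol_present,absent
snakes,C27_alcohol_present,absent
Testudines,C27_alcohol_present,present
Crocodylia,C27_alcohol_present,absent
Aves,C27_alcohol_present,present
lobe_finned_fish,C27_acid_present,absent
Mammalia,C27_acid_present,absent
tuatara,C27_acid_present,present
lizards,C27_acid_present,present
snakes,C27_acid_present,absent
Testudines,C27_acid_present,present
Crocodylia,C27_acid_present,present
Aves,C27_acid_present,present
lobe_finned_fish,C24_acid_present,absent
Mammalia,C24_acid_present,present
tuatara,C24_acid_present,absent
lizards,C24_acid_present,present
snakes,C24_acid_present,present
Testudines,C24_acid_present,absent
Crocodylia,C24_acid_present,absent
Aves,C24_acid_present,present
lobe_finned_fish,OH24R_C27_acid_present,absent
Mammalia,OH24R_C27_acid_present,absent
tuatara,OH24R_C27_acid_present,present
lizards,OH24R_C27_acid_present,present
snakes,OH24R_C27_acid_present,absent
Testudines,OH24R_C27_acid_present,absent
Crocodylia,OH24R_C27_acid_present,absent
Aves,OH24R_C27_acid_present,absent
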