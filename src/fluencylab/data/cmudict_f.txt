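;;; pronunciations extracted from the CMU Pronouncing Dictionary (cmudict 0.7b)
FOUR  F AO1 R
FIVE  F AY1 V
FOOD  F UW1 D
FOX  F AA1 K S
FERTILE  F ER1 T AH0 L
FERTILE(1)  F ER0 T AY1 L
FEN  F EH1 N
FIND  F AY1 N D
FIRE  F AY1 ER0
FIRE(1)  F AY1 R
FRY  F R AY1
FLY  F L AY1
FLIP  F L IH1 P
FLOP  F L AA1 P
FAIR  F EH1 R
FARE  F EH1 R
FAN  F AE1 N
FISH  F IH1 SH
FUN  F AH1 N
FIT  F IH1 T
FARM  F AA1 R M
FACE  F EY1 S
FACT  F AE1 K T
FALL  F AO1 L
FALL(1)  F AA1 L
FAST  F AE1 S T
FAT  F AE1 T
FATHER  F AA1 DH ER0
FEAR  F IH1 R
FEEL  F IY1 L
FEW  F Y UW1
FIELD  F IY1 L D
FIGHT  F AY1 T
FIGURE  F IH1 G Y ER0
FINE  F AY1 N
FINE(1)  F IH1 N AH0
FINGER  F IH1 NG G ER0
FINISH  F IH1 N IH0 SH
FLOOR  F L AO1 R
FLOWER  F L AW1 ER0
FOLLOW  F AA1 L OW0
FOOT  F UH1 T
FORCE  F AO1 R S
FOREST  F AO1 R AH0 S T
FOREST(1)  F AO1 R IH0 S T
FORGET  F ER0 G EH1 T
FORGET(1)  F AO0 R G EH1 T
FORM  F AO1 R M
FORT  F AO1 R T
FORWARD  F AO1 R W ER0 D
FRIEND  F R EH1 N D
FROG  F R AA1 G
FRUIT  F R UW1 T
FULL  F UH1 L
FUTURE  F Y UW1 CH ER0
DOG  D AO1 G
CAT  K AE1 T
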