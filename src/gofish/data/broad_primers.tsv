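name	category	segment	tm_printed	tail	core	amplicon_length	cycles	annealing_c
M13Li-F	bony_fish	Li	56.6	TGTAAAACGACGGCCAGT	GYCGGTAAAAYTCGTGCCAG	760	35	57
M13Li-R	bony_fish	Li	60.6	CAGGAAACAGCTATGAC	YCCAAGYGCACCTTCCGGTA	760	35	57
M13Li-S-F	cartilaginous_fish	Li	54.6	TGTAAAACGACGGCCAGT	GTTGGTHAATCTCGTGCCAG	760	35	57
M13Li-S-R	cartilaginous_fish	Li	52.1	CAGGAAACAGCTATGAC	TCCAAGTRCACTTTCCAGTA	760	35	57
MiFish-U-F	bony_fish	MiFish	58.7		GTCGGTAAAACTCGTGCCAGC	220	40	60
MiFish-U-R	bony_fish	MiFish	56.7		CATAGTGGGGTATCTAATCCCAGTTTG	220	40	60
MiFish-E-F	cartilaginous_fish	MiFish	56.5		GTTGGTAAATCTCGTGCCAGC	220	40	55
MiFish-E2-R	cartilaginous_fish	MiFish	52.2		CATAGTAGGGTATCTAATCCTAGTTTG	220	40	55
MiFish-W-F	mammal	MiFish	55.1		GTTGGTAAATTTCGTGCCAGC	220	40	60
ECO-V5-F	bony_fish	ECO	50.1	TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG	ACTGGGATTAGATACCCC	200	40	52
ECO-V5-R	bony_fish	ECO	49.6	GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG	TAGAACAGGCTCCTCTAG	200	40	52
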