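>CsgA_precursor major curli subunit CsgA precursor; signal 1-20, mature 21-151
MKLLKVAAIAAIVFSGSALAGVVPQYGGGGNHGGGGNNSGPNSELNIYQYGGGNSALALQ
TDARNSDLTITQHGGGNGADVGQGSDDSSIDLTQRGFGNSATLDQWNGKNSEMTVKQFGG
GNGAAVDQTASNSSVNVTQVGFGNNATAHQY
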