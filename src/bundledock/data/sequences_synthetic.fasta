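>FtsB_like_25-88 synthetic stand-in for a periplasmic FtsB segment (not the natural sequence)
KAQETARDQGTTTAEQDTQRGKLNETEENLDNIEEELDDLDDDLEELQANLKGAEANASFAYGN
>FtsL_like_61-109 synthetic stand-in for a periplasmic FtsL segment (not the natural sequence)
LQKQQKRLTSINNTLTATARQLSKIEEDGDHSEDESDGAAEEQNAATTA
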