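# Starter binding-site list for factor VIII -- INCOMPLETE.
# Contains only a handful of FIXa-interface residues commonly cited in the
# mutagenesis literature (legacy mature numbering, 2R7E chain A); real
# analyses should supply a curated file aggregating the primary studies
# for FIXa, FX, thrombin, vWF and the phospholipid membrane.
partner	chain	position	source
FIXa	A	557	literature_starter
FIXa	A	562	literature_starter
FIXa	A	568	literature_starter
FIXa	A	712	literature_starter
FIXa	A	713	literature_starter
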