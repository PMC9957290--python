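pfam_acc	family_name	broad_function	ig_like
pfam11999	DUF3494	IBP	false
pfam16130	DUF4842	β-barrel Ig fold	true
pfam07589	PEP C-term motif	Sorting/Exopolysaccharides	false
pfam01345	DUF11	Cell wall-related	false
pfam02010	REJ domain	Membrane associated	false
pfam04519	Polymer-forming cytoskeletal	Cytoskeleton	false
pfam13517	FG-GAP-like repeat	Cell adhesion	false
pfam07593	ASPIC and UnbV	Cell adhesion	false
pfam03797	Autotransporter β-domain	Secretion	false
pfam13205	BIg-like domain	Tethering	true
pfam02412	Thrombospondin type 3 repeat	Cell adhesion	false
pfam01391	Collagen triple helix repeat	Cell adhesion	false
pfam07603	DUF1566	Unknown	false
pfam02494	HYR domain	Cell adhesion	false
pfam14341	PilX N-terminal	Cell adhesion	false
pfam04862	DUF642	Unknown (thought to be exclusive to plants)	false
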