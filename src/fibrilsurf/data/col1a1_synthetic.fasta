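>col1a1_synthetic_mature_chain
SQSVQDEKSANVDQEFGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGNOGPQGLOGARGP
SGVEGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGNOGPQGLOGARGPSGVEGPOGERGA
OGPKGQOGDRGSPGPAGEOGKAGNOGPQGLOGARGPSGVEGPOGERGAOGPKGQOGDRGS
PGPAGEOGKAGNOGPQGLOGARGPSGVEGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGN
OGPQGLOGARGPSGVEGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGNOGPQGLOGARGP
SGVEGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGNOGPQGLOGARGPSGVEGPOGERGA
OGPKGQOGDRGSPGPAGEOGKAGNOGPQGLOGARGPSGVEGPOGERGAOGPKGQOGDRGS
PGPAGEOGKAGNOGPQGLOGARGPSGVEGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGN
OGPQGLOGARGPSGVEGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGNOGPQGLOGARGP
SGVEGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGNOGPQGLOGARGPSGVEGPOGERGA
OGPKGQOGDRGSPGPAGEOGKAGNOGPQGLOGARGPSGVEGPOGERGAOGPKGQOGDRGS
PGPAGEOGKAGNOGPQGLOGARGPSGVEGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGN
OGPQGLOGARGPSGVEGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGNOGPQGLOGARGP
SGVEGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGNOGQRGERGARGPSGVEGPOGERGA
OGPKGQOGDRGSPGPAGEOGKAGNOGPQGLOGARGPSGVEGPOGERGAOGPKGQOGDRGS
PGPAGEOGKAGNOGPQGLOGARGPSGVEGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGN
OGPQGLOGARGPSGVEGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGNOGPQGLOGARGP
SGVEGPOGERGAOGPKGQOGDRGSPGPAGEOGKAGNOGPDEKSADNVQFSATEVKDQSPA
EFKV
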