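>col1a2_synthetic_mature_chain
SQSVQDEKSANVDQEFGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGAOGRPGSOGPEGK
VGAQGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGAOGRPGSOGPEGKVGAQGPOGAVGE
RGPSGKOGDAGQPGPOGNAGLEGAOGRPGSOGPEGKVGAQGPOGAVGERGPSGKOGDAGQ
PGPOGNAGLEGAOGRPGSOGPEGKVGAQGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGA
OGRPGSOGPEGKVGAQGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGAOGRPGSOGPEGK
VGAQGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGAOGRPGSOGPEGKVGAQGPOGAVGE
RGPSGKOGDAGQPGPOGNAGLEGAOGRPGSOGPEGKVGAQGPOGAVGERGPSGKOGDAGQ
PGPOGNAGLEGAOGRPGSOGPEGKVGAQGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGA
OGRPGSOGPEGKVGAQGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGAOGRPGSOGPEGK
VGAQGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGAOGRPGSOGPEGKVGAQGPOGAVGE
RGPSGKOGDAGQPGPOGNAGLEGAOGRPGSOGPEGKVGAQGPOGAVGERGPSGKOGDAGQ
PGPOGNAGLEGAOGRPGSOGPEGKVGAQGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGA
OGRPGSOGPEGKVGAQGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGAOGRPGSOGPEGK
VGAQGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGAOGRPGSOGPEGKVGAQGPOGAVGE
RGPSGKOGDAGQPGPOGNAGLEGAOGRPGSOGPEGKVGAQGPOGAVGERGPSGKOGDAGQ
PGPOGNAGLEGAOGRPGSOGPEGKVGAQGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGA
OGRPGSOGPEGKVGAQGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGAOGRPGSOGPEGK
VGAQGPOGAVGERGPSGKOGDAGQPGPOGNAGLEGAOGRDEKSADNVQFSATEVKDQSPA
EFKV
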