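>FUS_PLD_RGG1 human FUS residues 1-267 (UniProt P35637); PLD=1-167, RGG1=168-267
MASNDYTQQATQSYGAYPTQPGQGYSQQSSQPYGQQSYSGYSQSTDTSGYGQSSYSSYGQ
SQNTGYGTQSTPQGYGSTGGYGSSQSSQSSYGQQSSYPGYGQQPAPSSTSGSYGSSSQSS
SYGQPQSGSYSQQPSYGGQQQSYGQQQSYNPPQGYGQQNQYNSSSGGGGGGGGGGNYGQD
QSSMSSGGGSGGGYGNQDQSGGGGSGGYGQQDRGGRGRGGSGGGGGGGGGGYNRSSGGYE
PRGRGGGRGGRGGMGGSDRGGFNKFGG
>TDP43_CTD human TDP-43 C-terminal IDR, residues 273-414 (UniProt Q13148)
SGRFGGNPGGFGNQGGFGNSRGGGAGLGNNQGSNMGGGMNFGAFSINPAMMAAAQAALQS
SWGMMGMLASQQNQSGPSGNNQNQGNMQREPNQAFGSGNNSYSGSNSGAAIGWGSASNAG
SGSGFNGGFGSSMDSKSSGWGM
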