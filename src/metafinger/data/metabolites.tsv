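name	formula	human
alanine	C3H7NO2	True
arginine	C6H14N4O2	True
asparagine	C4H8N2O3	True
aspartate	C4H7NO4	True
citrulline	C6H13N3O3	True
glutamate	C5H9NO4	True
glutamine	C5H10N2O3	True
histidine	C6H9N3O2	True
leucine	C6H13NO2	True
lysine	C6H14N2O2	True
methionine	C5H11NO2S	True
ornithine	C5H12N2O2	True
phenylalanine	C9H11NO2	True
proline	C5H9NO2	True
serine	C3H7NO3	True
tyrosine	C9H11NO3	True
O-phosphoserine	C3H8NO6P	True
N,N-dimethylarginine	C8H18N4O2	True
N6,N6,N6-trimethyllysine	C9H20N2O2	True
putrescine	C4H12N2	True
cadaverine	C5H14N2	True
spermidine	C7H19N3	True
spermine	C10H26N4	True
N-acetylputrescine	C6H14N2O	True
N-acetylcadaverine	C7H16N2O	True
N1-acetylspermidine	C9H21N3O	True
N1,N8-diacetylspermidine	C11H23N3O2	True
N1,N12-diacetylspermine	C14H30N4O2	True
histamine	C5H9N3	True
1-methylhistamine	C6H11N3	True
taurine	C2H7NO3S	True
hypotaurine	C2H7NO2S	True
cysteate	C3H7NO5S	True
glucose	C6H12O6	True
lactate	C3H6O3	True
2-ketoglutarate	C5H6O5	True
urocanate	C6H6N2O2	True
hypoxanthine	C5H4N4O	True
xanthine	C5H4N4O2	True
urate	C5H4N4O3	True
adenine	C5H5N5	True
uracil	C4H4N2O2	True
thymine	C5H6N2O2	True
cytidine	C9H13N3O5	True
uridine	C9H12N2O6	True
thymidine	C10H14N2O5	True
inosine	C10H12N4O5	True
guanosine	C10H13N5O5	True
xanthosine	C10H12N4O6	True
AMP	C10H14N5O7P	True
UMP	C9H13N2O9P	True
S-adenosylhomocysteine	C14H20N6O5S	True
sphingosine 1-phosphate	C18H38NO5P	True
carnitine	C7H15NO3	True
acetylcarnitine	C9H17NO4	True
butyrylcarnitine	C11H21NO4	True
palmitoylcarnitine	C23H45NO4	True
stearoylcarnitine	C25H49NO4	True
oleoylcarnitine	C25H47NO4	True
caprylate	C8H16O2	True
palmitate	C16H32O2	True
oleate	C18H34O2	True
linoleate	C18H32O2	True
alpha-linolenate	C18H30O2	True
arachidonate	C20H32O2	True
glycerol 3-phosphate	C3H9O6P	True
glycerophosphocholine	C8H20NO6P	True
glycerophosphoethanolamine	C5H14NO6P	True
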