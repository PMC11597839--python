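# IUPAC 2021 abridged standard atomic weights (g/mol) and principal-isotope
# monoisotopic masses (Da, AME2020). monoisotopic(C) = 12 by definition.
element,average_mass,monoisotopic_mass
H,1.008,1.00782503207
C,12.011,12.0
N,14.007,14.0030740048
O,15.999,15.9949146196
F,18.998403163,18.9984031627
P,30.973761998,30.9737619984
S,32.06,31.9720711744
Cl,35.45,34.968852682
Br,79.904,78.9183376
I,126.90447,126.904473
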